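"""Synthetic corpus generator with planted cause and gender structure.

Generates MediaWiki-format dumps whose entries are built from per-cause
description templates that embed lexicon patterns, with names drawn from
the packaged name dictionary so that truth tables are exact: a pipeline run
over a generated corpus should recover the planted mixtures up to binomial
sampling error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from cinemort.causes import CauseLexicon
from cinemort.gender import NameDictionary, load_name_dictionary
from cinemort.stemming import stem_text

logger = logging.getLogger(__name__)

# Filler frames; every non-placeholder word must stay clear of lexicon stems
# (asserted by the test suite against the packaged lexicon).
_FRAMES = (
    "Succumbs to {phrase} during the final act.",
    "Meets an untimely end when {phrase} strikes near the climax.",
    "Perishes via {phrase} moments before the credits.",
    "The character is lost to {phrase} at the midpoint.",
)

_TITLE_ADJ = ("Silent", "Crimson", "Broken", "Golden", "Hidden", "Distant", "Restless", "Empty")
_TITLE_NOUN = ("Harbor", "Mirror", "Garden", "Summit", "Letter", "Voyage", "Orchard", "Signal")

_SURNAMES = (
    "Stone", "Rivers", "Calloway", "Mercer", "Whitfield", "Ashford",
    "Langley", "Bennett", "Hargrove", "Ellsworth", "Marchetti", "Okafor",
)


@dataclass
class GeneratorConfig:
    """Sampling plan for one synthetic corpus."""

    n_entries: int
    cause_mixture: dict[str, float]
    gender_mixture_by_cause: dict[str, float] = field(default_factory=dict)
    default_p_man: float = 0.5
    ambiguous_name_fraction: float = 0.0
    media_mixture: dict[str, float] = field(default_factory=lambda: {"film": 1.0})
    year_range: tuple[int, int] = (1895, 2023)
    entries_per_page: tuple[int, int] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 0:
            raise ValueError("n_entries must be non-negative")
        probs = list(self.cause_mixture.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("cause_mixture probabilities must lie in [0, 1]")
        if self.n_entries and abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("cause_mixture probabilities must sum to 1")
        if not 0.0 <= self.ambiguous_name_fraction <= 1.0:
            raise ValueError("ambiguous_name_fraction must lie in [0, 1]")
        for cause, p in self.gender_mixture_by_cause.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gender mixture for {cause!r} out of [0, 1]")
        if abs(sum(self.media_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("media_mixture probabilities must sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (min, max)")
        lo, hi = self.entries_per_page
        if not 1 <= lo <= hi:
            raise ValueError("entries_per_page must be (lo, hi) with 1 <= lo <= hi")


@dataclass
class NamePools:
    """Gendered first-name pools used by the generator."""

    man: list[str]
    woman: list[str]
    ambiguous: list[str]

    @classmethod
    def from_dictionary(cls, dictionary: NameDictionary | None = None, max_per_pool: int = 2000) -> "NamePools":
        d = dictionary or load_name_dictionary()

        def pool(labels) -> list[str]:
            names = [n for n in d.names_with_label(labels) if n.isalpha() and n.isascii()]
            return [n.capitalize() for n in names[:max_per_pool]]

        return cls(man=pool("male"), woman=pool("female"), ambiguous=pool("androgynous"))


# fallback-cause phrases; none may match any lexicon pattern
_OTHER_PHRASES = ("a sudden ambush", "an unexplained collapse", "a rooftop duel", "a poisoned chalice")


def build_templates(lexicon: CauseLexicon, causes: list[str], max_phrases: int = 3) -> dict[str, list[str]]:
    """Per-cause description templates, each embedding one lexicon phrase.

    ``other`` is the classifier fallback, so its templates embed neutral
    phrases that match no lexicon pattern at all.
    """
    templates: dict[str, list[str]] = {}
    for cause in causes:
        if cause == "other":
            phrases: tuple[str, ...] | list[str] = _OTHER_PHRASES
        else:
            phrases = lexicon.raw_patterns.get(cause, [])[:max_phrases]
            if not phrases:
                raise ValueError(f"cause {cause!r} has no lexicon pattern to embed")
        templates[cause] = [frame.format(phrase=ph) for ph in phrases for frame in _FRAMES]
    return templates


@dataclass
class SyntheticCorpus:
    xml: str
    entries: pd.DataFrame  # actor_name, film_title, year, medium, description
    truth: pd.DataFrame  # entry_id, actor_name, first_name, cause, gender, ambiguous, medium, year
    seed: int

    def write(self, out_dir: str | Path, stem: str = "synthetic") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "xml": out / f"{stem}_dump.xml",
            "entries": out / f"{stem}_entries.csv",
            "truth": out / f"{stem}_truth.csv",
        }
        paths["xml"].write_text(self.xml, encoding="utf-8")
        self.entries.to_csv(paths["entries"], index=False)
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            fh.write(f"# seed={self.seed}\n")
            self.truth.to_csv(fh, index=False)
        return paths


def generate_corpus(
    config: GeneratorConfig,
    lexicon: CauseLexicon,
    name_pools: NamePools | None = None,
) -> SyntheticCorpus:
    """Sample a corpus per the config; identical seeds give identical output.

    Each page holds one actor with 1-2 entries sharing the planted gender
    and medium; category tags mark non-film pages so the medium detector
    can recover them.
    """
    pools = name_pools or NamePools.from_dictionary()
    rng = np.random.default_rng(config.seed)

    causes = list(config.cause_mixture)
    cause_p = np.array([config.cause_mixture[c] for c in causes], dtype=float)
    templates = build_templates(lexicon, causes)

    media = list(config.media_mixture)
    media_p = np.array([config.media_mixture[m] for m in media], dtype=float)

    records = []  # one per entry, in document order
    pages = []  # (actor_name, medium, [entry wikitext lines])
    i = 0
    lo_pp, hi_pp = config.entries_per_page
    while i < config.n_entries:
        per_page = int(rng.integers(lo_pp, hi_pp + 1))
        per_page = min(per_page, config.n_entries - i)
        medium = media[int(rng.choice(len(media), p=media_p))]

        ambiguous = bool(rng.random() < config.ambiguous_name_fraction)
        # cause and gender are planted once per page (one actor, one gender);
        # every entry on the page shares them, so per-entry marginals equal
        # the configured mixtures exactly
        page_cause = causes[int(rng.choice(len(causes), p=cause_p))]
        p_man = config.gender_mixture_by_cause.get(page_cause, config.default_p_man)
        gender = "man" if rng.random() < p_man else "woman"
        if ambiguous:
            pool = pools.ambiguous
        else:
            pool = pools.man if gender == "man" else pools.woman
        first = pool[int(rng.integers(len(pool)))]
        actor = f"{first} {_SURNAMES[int(rng.integers(len(_SURNAMES)))]}"

        lines = []
        for j in range(per_page):
            cause = page_cause
            tmpl = templates[cause][int(rng.integers(len(templates[cause])))]
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            title = (
                f"The {_TITLE_ADJ[int(rng.integers(len(_TITLE_ADJ)))]} "
                f"{_TITLE_NOUN[int(rng.integers(len(_TITLE_NOUN)))]}"
            )
            lines.append(f"*''{title}'' ({year}): {tmpl}")
            records.append(
                {
                    "entry_id": i + j,
                    "actor_name": actor,
                    "first_name": first,
                    "film_title": title,
                    "year": year,
                    "medium": medium,
                    "cause": cause,
                    "gender": gender,
                    "ambiguous": ambiguous,
                    "description": tmpl,
                }
            )
        pages.append((actor, medium, lines))
        i += per_page

    xml = _render_dump(pages, seed=config.seed)
    truth = pd.DataFrame(
        records,
        columns=[
            "entry_id", "actor_name", "first_name", "film_title", "year",
            "medium", "cause", "gender", "ambiguous", "description",
        ],
    )
    entries = truth[["actor_name", "film_title", "year", "medium", "description"]].copy()
    return SyntheticCorpus(xml=xml, entries=entries, truth=truth, seed=config.seed)


_MEDIUM_CATEGORY = {
    "television": "[[Category:Television deaths]]",
    "video_game": "[[Category:Video game deaths]]",
    "other_media": "[[Category:Other media deaths]]",
}


def _render_dump(pages: list[tuple[str, str, list[str]]], seed: int) -> str:
    parts = ['<mediawiki xml:lang="en">', f"<!-- synthetic dump, seed={seed} -->"]
    for actor, medium, lines in pages:
        body_lines = list(lines)
        if medium in _MEDIUM_CATEGORY:
            body_lines.append(_MEDIUM_CATEGORY[medium])
        body = escape("\n".join(body_lines))
        parts.append(
            "  <page>\n"
            f"    <title>{escape(actor)}</title>\n"
            "    <revision>\n"
            f"      <text>{body}</text>\n"
            "    </revision>\n"
            "  </page>"
        )
    parts.append("</mediawiki>\n")
    return "\n".join(parts)


def evaluate_recovery(truth: pd.DataFrame, pipeline_output: pd.DataFrame) -> dict:
    """Score pipeline output against the generator truth table.

    ``pipeline_output`` needs columns entry_id, cause, gender (consolidated
    man/woman/excluded).  Returns per-cause recall/precision, the gender
    agreement rate over entries planted with an unambiguous name, and the
    excluded fraction.
    """
    if sorted(truth["entry_id"]) != sorted(pipeline_output["entry_id"]):
        raise ValueError("truth and pipeline output entry ids do not match")
    merged = truth.merge(pipeline_output, on="entry_id", suffixes=("_true", "_pred"))

    per_cause = {}
    for cause in sorted(set(merged["cause_true"]) | set(merged["cause_pred"])):
        tp = int(((merged["cause_true"] == cause) & (merged["cause_pred"] == cause)).sum())
        n_true = int((merged["cause_true"] == cause).sum())
        n_pred = int((merged["cause_pred"] == cause).sum())
        per_cause[cause] = {
            "recall": tp / n_true if n_true else float("nan"),
            "precision": tp / n_pred if n_pred else float("nan"),
            "n_true": n_true,
            "n_pred": n_pred,
        }

    unambiguous = merged[~merged["ambiguous"]]
    gender_agreement = (
        float((unambiguous["gender_true"] == unambiguous["gender_pred"]).mean())
        if len(unambiguous)
        else float("nan")
    )
    excluded_fraction = float((merged["gender_pred"] == "excluded").mean())
    return {
        "per_cause": per_cause,
        "gender_agreement": gender_agreement,
        "excluded_fraction": excluded_fraction,
        "n": int(len(merged)),
    }
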