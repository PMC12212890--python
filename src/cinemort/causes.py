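"""Rule-based cause-of-death classification over stemmed descriptions.

The cause vocabulary is the 12 named leading-cause categories of the NVSS
2021 report plus ``other`` (the fallback).  Patterns are single stems or
stem n-grams matched on adjacent stems after stop-word removal; ties between
causes are broken by a fixed priority order (the reference-table row order,
heart first) and logged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from cinemort.corpus import Corpus
from cinemort.stemming import stem_text, tokenize, stem_token

logger = logging.getLogger(__name__)

#: Cause codes in reference-table order; doubles as the tie-break priority.
CAUSE_CODES = (
    "heart",
    "cancer",
    "covid19",
    "accidents",
    "cerebrovascular",
    "chronic_lower_respiratory",
    "alzheimer",
    "diabetes",
    "chronic_liver",
    "nephritis",
    "suicide",
    "hypertension",
    "other",
)

NAMED_CAUSES = CAUSE_CODES[:-1]

DISPLAY_NAMES = {
    "heart": "Diseases of heart",
    "cancer": "Cancer",
    "covid19": "COVID-19",
    "accidents": "Accidents",
    "cerebrovascular": "Cerebrovascular disease",
    "chronic_lower_respiratory": "Chronic lower respiratory diseases",
    "alzheimer": "Alzheimer disease",
    "diabetes": "Diabetes mellitus",
    "chronic_liver": "Chronic liver disease",
    "nephritis": "Nephritis",
    "suicide": "Suicide",
    "hypertension": "Essential hypertension",
    "other": "Other",
}


class LexiconError(ValueError):
    """Raised for invalid lexicon configuration (duplicate or missing patterns)."""


@dataclass
class CauseLexicon:
    """Mapping from cause code to stemmed keyword patterns.

    ``patterns[code]`` is a list of stem tuples; a 1-tuple matches a single
    stem anywhere, longer tuples match adjacent stems after stop-word
    removal.
    """

    patterns: dict[str, list[tuple[str, ...]]]
    stopwords: frozenset[str] = frozenset()
    version: str = "unversioned"
    raw_patterns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = set(self.patterns) - set(CAUSE_CODES)
        if unknown:
            raise LexiconError(f"unknown cause codes in lexicon: {sorted(unknown)}")
        seen: dict[tuple[str, ...], str] = {}
        for code in CAUSE_CODES:
            pats = self.patterns.get(code, [])
            if code == "other":
                if pats:
                    raise LexiconError("'other' is the fallback and must have no patterns")
                continue
            if not pats:
                raise LexiconError(f"cause {code!r} has no patterns")
            for pat in pats:
                if not pat:
                    raise LexiconError(f"empty pattern under cause {code!r}")
                if pat in seen and seen[pat] != code:
                    raise LexiconError(
                        f"pattern {' '.join(pat)!r} appears under both {seen[pat]!r} and {code!r}"
                    )
                seen[pat] = code


def compile_pattern(phrase: str, stopwords: frozenset[str]) -> tuple[str, ...]:
    """Stem a plain-word phrase into a match tuple, dropping stop-word stems.

    ``stopwords`` must already be stemmed so that pattern compilation and
    description matching drop exactly the same tokens.
    """
    return tuple(s for s in (stem_token(t) for t in tokenize(phrase)) if s not in stopwords)


def load_lexicon(source: str | Path | dict | None = None) -> CauseLexicon:
    """Load a cause lexicon from YAML (or a parsed dict).

    With no argument, loads the packaged default lexicon.
    """
    if source is None:
        with resources.files("cinemort.data").joinpath("lexicon.yml").open("r") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, dict):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)

    stopwords = frozenset(stem_token(str(w).lower()) for w in doc.get("stopwords", []))
    raw = {code: list(map(str, pats or [])) for code, pats in doc.get("patterns", {}).items()}
    compiled: dict[str, list[tuple[str, ...]]] = {}
    for code, phrases in raw.items():
        pats = []
        for phrase in phrases:
            pat = compile_pattern(phrase, stopwords)
            if pat and pat not in pats:
                pats.append(pat)
        compiled[code] = pats
    return CauseLexicon(
        patterns=compiled,
        stopwords=stopwords,
        version=str(doc.get("version", "unversioned")),
        raw_patterns=raw,
    )


def _matches(content: list[str], pattern: tuple[str, ...]) -> bool:
    k = len(pattern)
    if k == 1:
        return pattern[0] in content
    return any(tuple(content[i : i + k]) == pattern for i in range(len(content) - k + 1))


def classify_cause(stems: list[str], lexicon: CauseLexicon) -> str:
    """Assign a single cause code to a stemmed description.

    Returns the unique matching cause, the highest-priority cause on a
    multi-match (logged), or ``"other"`` when nothing matches.
    """
    content = [s for s in stems if s not in lexicon.stopwords]
    hits = [
        code
        for code in NAMED_CAUSES
        if any(_matches(content, pat) for pat in lexicon.patterns.get(code, []))
    ]
    if not hits:
        return "other"
    if len(hits) > 1:
        logger.debug("multi-cause match %s; tie broken to %r", hits, hits[0])
    return hits[0]


def classify_entry(description: str, lexicon: CauseLexicon) -> str:
    return classify_cause(stem_text(description), lexicon)


def classify_corpus(corpus: Corpus, lexicon: CauseLexicon) -> tuple[Counter, list[str]]:
    """Classify every entry; returns (per-cause counts, per-entry assignments).

    Counts cover all 13 codes (zeros included) and sum to the corpus size;
    the assignment list is index-aligned with ``corpus.entries`` for audit
    output.
    """
    assignments = [classify_entry(e.description, lexicon) for e in corpus.entries]
    counts = Counter({code: 0 for code in CAUSE_CODES})
    counts.update(assignments)
    return counts, assignments
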