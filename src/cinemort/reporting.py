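"""End-to-end pipeline orchestration and the run manifest.

``run_pipeline`` wires ingest -> medium filter -> cause classification ->
gender classification -> reference comparison, writes every table the
analysis needs (year percentiles, gender tallies, the chi-square battery,
share scatter and gender-bar figures) plus audit CSVs, and records a
machine-readable manifest with stage counts and fixture versions so any
result is attributable to a lexicon / dictionary revision.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from cinemort import plots
from cinemort.causes import CAUSE_CODES, classify_corpus, load_lexicon
from cinemort.corpus import Corpus, filter_medium, parse_dump, write_entries_csv, year_percentiles
from cinemort.gender import classify_actor, consolidate, load_name_dictionary, tally_genders
from cinemort.reference import load_reference
from cinemort.stats import (
    film_table_from_gender_counts,
    format_p,
    overall_shares,
    run_battery,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance and stage-count record for one pipeline run."""

    input_path: str
    input_sha256: str
    lexicon_version: str
    name_dictionary_source: str
    reference_source: str
    media_filter: list[str]
    n_ingested: int
    n_filtered: int
    n_removed_by_medium: int
    n_gender_excluded: int
    timestamp: str = ""
    seeds: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_ingested != self.n_filtered + self.n_removed_by_medium:
            raise ValueError("stage counts inconsistent: ingested != filtered + removed")


@dataclass
class ReportBundle:
    manifest: RunManifest
    year_percentiles: list[tuple[float, int]]
    gender_tally: "pd.DataFrame"
    battery: "pd.DataFrame"
    shares: "pd.DataFrame"
    out_dir: Path


def load_run_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full analysis described by a config mapping.

    Config keys: ``dump`` (XML or CSV path; required), ``media`` (allowed
    media list, default ``[film]``), ``lexicon`` / ``name_dictionary`` /
    ``reference`` (optional paths; packaged fixtures by default),
    ``out_dir`` (report directory).
    """
    out = Path(out_dir or config.get("out_dir", "report"))
    out.mkdir(parents=True, exist_ok=True)

    dump = config["dump"]
    media = list(config.get("media", ["film"]))

    try:
        corpus = parse_dump(dump)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage=ingest failed on {dump!r}: {exc}") from exc
    n_ingested = len(corpus)

    filtered = filter_medium(corpus, media)
    n_filtered = len(filtered)

    lexicon = load_lexicon(config.get("lexicon"))
    cause_counts, cause_assignments = classify_corpus(filtered, lexicon)

    dictionary = load_name_dictionary(config.get("name_dictionary"))
    raw_labels = [classify_actor(e.actor_name, dictionary) for e in filtered.entries]
    consolidated = [consolidate(lab) for lab in raw_labels]
    tally = tally_genders(raw_labels)

    gender_counts: dict[str, tuple[int, int]] = {}
    for cause, cons in zip(cause_assignments, consolidated):
        men, women = gender_counts.get(cause, (0, 0))
        if cons == "man":
            men += 1
        elif cons == "woman":
            women += 1
        gender_counts[cause] = (men, women)

    reference = load_reference(config.get("reference"))
    film_gender_table = film_table_from_gender_counts(gender_counts, population_id="film:gendered")
    battery = run_battery(film_gender_table, reference, threshold=int(config.get("threshold", 5)))

    # Figure-1 shares use ALL classified entries (gender-excluded retained)
    film_full_table = film_table_from_gender_counts(
        {c: (cause_counts.get(c, 0), 0) for c in CAUSE_CODES}, population_id="film:all"
    )
    shares = overall_shares(film_full_table, reference)

    percentiles = year_percentiles(filtered) if any(e.year is not None for e in filtered.entries) else []

    manifest = RunManifest(
        input_path=str(dump),
        input_sha256=_sha256(dump),
        lexicon_version=lexicon.version,
        name_dictionary_source=dictionary.source,
        reference_source=reference.population_id,
        media_filter=media,
        n_ingested=n_ingested,
        n_filtered=n_filtered,
        n_removed_by_medium=n_ingested - n_filtered,
        n_gender_excluded=tally.after["excluded"],
        timestamp=datetime.now(timezone.utc).isoformat(),
        seeds=dict(config.get("seeds", {})),
    )
    manifest.validate()
    logger.info(
        "stage=ingest n=%d | stage=filter n=%d | stage=gender_excluded n=%d",
        n_ingested, n_filtered, manifest.n_gender_excluded,
    )

    bundle = _write_bundle(
        out, filtered, cause_assignments, raw_labels, consolidated,
        tally, battery, shares, percentiles, manifest,
    )
    return bundle


def _sha256(path: str | Path) -> str:
    p = Path(path)
    if not p.exists():
        return ""
    return hashlib.sha256(p.read_bytes()).hexdigest()


def _write_bundle(out, filtered, cause_assignments, raw_labels, consolidated,
                  tally, battery, shares, percentiles, manifest) -> ReportBundle:
    write_entries_csv(filtered, out / "entries.csv")

    audit = pd.DataFrame(
        {
            "entry_id": range(len(filtered.entries)),
            "actor_name": [e.actor_name for e in filtered.entries],
            "cause": cause_assignments,
            "raw_gender": raw_labels,
            "gender": consolidated,
        }
    )
    audit.to_csv(out / "audit.csv", index=False)

    if percentiles:
        with open(out / "year_percentiles.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["percentile", "year"])
            w.writerows(percentiles)

    tally_df = pd.DataFrame(
        {
            "label": list(tally.before) + list(tally.after),
            "stage": ["before"] * len(tally.before) + ["after"] * len(tally.after),
            "count": list(tally.before.values()) + list(tally.after.values()),
        }
    )
    tally_df.to_csv(out / "gender_tally.csv", index=False)

    battery_df = pd.DataFrame([asdict(r) for r in battery])
    battery_df["p_display"] = [format_p(r.p_value) for r in battery]
    battery_df.to_csv(out / "battery.csv", index=False, float_format="%.10g")

    shares_df = pd.DataFrame([asdict(s) for s in shares])
    shares_df.to_csv(out / "shares.csv", index=False, float_format="%.10g")

    plots.plot_share_scatter(shares, out / "share_scatter.png")
    plots.plot_share_scatter(shares, out / "share_scatter.svg")
    plots.plot_gender_bars(battery, out / "gender_bars.png")
    plots.plot_gender_bars(battery, out / "gender_bars.svg")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)

    summary = {
        "n_ingested": manifest.n_ingested,
        "n_filtered": manifest.n_filtered,
        "n_gender_excluded": manifest.n_gender_excluded,
        "lexicon_version": manifest.lexicon_version,
        "battery": [
            {
                "cause": r.cause,
                "chi2": r.chi2,
                "df": r.df,
                "p_value": r.p_value,
                "p_display": format_p(r.p_value),
                "applicable": r.applicable,
            }
            for r in battery
        ],
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)

    return ReportBundle(
        manifest=manifest,
        year_percentiles=percentiles,
        gender_tally=tally_df,
        battery=battery_df,
        shares=shares_df,
        out_dir=out,
    )
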