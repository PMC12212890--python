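"""The NVSS 2021 leading-cause-by-gender reference table.

The packaged fixture stores the published counts as printed; rows whose
women + men does not equal the printed total are flagged (never silently
corrected), and per-cause gender proportions are always recomputed from the
women/men counts so flagged rows still yield valid proportions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from cinemort.causes import CAUSE_CODES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CauseRow:
    cause: str
    total: int
    women: int
    men: int

    @property
    def consistent(self) -> bool:
        return self.women + self.men == self.total


@dataclass
class MortalityTable:
    """Per-cause, per-gender death counts for one population."""

    rows: list[CauseRow]
    population_id: str = ""
    year: int | None = None
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.rows:
            if min(r.total, r.women, r.men) < 0:
                raise ValueError(f"negative count in row {r.cause!r}")
        self.flagged = [r.cause for r in self.rows if not r.consistent]
        for cause in self.flagged:
            logger.warning(
                "%s: row %r is internally inconsistent (women+men != total); kept as stored",
                self.population_id or "mortality table", cause,
            )

    def __getitem__(self, cause: str) -> CauseRow:
        for r in self.rows:
            if r.cause == cause:
                return r
        raise KeyError(cause)

    @property
    def causes(self) -> list[str]:
        return [r.cause for r in self.rows]

    def cause_totals(self) -> dict[str, int]:
        return {r.cause: r.total for r in self.rows}

    def grand_total(self) -> int:
        return sum(r.total for r in self.rows)


def load_reference(fixture: str | Path | None = None) -> MortalityTable:
    """Load the reference table (packaged NVSS 2021 fixture by default).

    The file is CSV with header ``cause,total,women,men``; ``#`` lines are
    provenance comments.  A missing cause row is a fatal configuration
    error.
    """
    if fixture is None:
        text = resources.files("cinemort.data").joinpath("nvss2021.csv").read_text(encoding="utf-8")
        source_id = "packaged:nvss2021.csv"
    else:
        text = Path(fixture).read_text(encoding="utf-8")
        source_id = str(fixture)

    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["cause", "total", "women", "men"]:
        raise ValueError(f"{source_id}: expected header cause,total,women,men")
    rows = [
        CauseRow(
            cause=rec["cause"].strip(),
            total=int(rec["total"]),
            women=int(rec["women"]),
            men=int(rec["men"]),
        )
        for rec in reader
    ]
    present = {r.cause for r in rows}
    missing = set(CAUSE_CODES) - present
    if missing:
        raise ValueError(f"{source_id}: missing cause rows: {sorted(missing)}")
    unknown = present - set(CAUSE_CODES)
    if unknown:
        raise ValueError(f"{source_id}: unknown cause rows: {sorted(unknown)}")
    return MortalityTable(rows=rows, population_id=source_id, year=2021)


def gender_proportion(table: MortalityTable, cause: str) -> tuple[float, float]:
    """(p_men, p_women) for a cause, computed from the women/men counts.

    The denominator is men + women (not the printed total), so rows flagged
    as inconsistent still yield proportions summing to exactly 1.
    """
    row = table[cause]
    denom = row.men + row.women
    if denom == 0:
        raise ZeroDivisionError(f"cause {cause!r} has no gendered deaths")
    p_men = row.men / denom
    return p_men, 1.0 - p_men
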