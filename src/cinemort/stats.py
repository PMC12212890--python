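"""Representation statistics: shares, ratios, and the chi-square battery.

The per-cause gender test is a one-sample goodness-of-fit of the film
gender counts against fixed reference proportions (two cells, df = 1, no
continuity correction).  A 2x2 independence test is available as an
optional mode; it is *not* equivalent when the film sample is non-negligible
relative to the reference counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats as sps

from cinemort.causes import CAUSE_CODES, DISPLAY_NAMES
from cinemort.reference import MortalityTable, gender_proportion

logger = logging.getLogger(__name__)

DEFAULT_APPLICABILITY_THRESHOLD = 5


@dataclass(frozen=True)
class ShareRow:
    cause: str
    share_film: float
    share_ref: float
    representation_ratio: float | None  # None when share_ref == 0


@dataclass(frozen=True)
class CauseGenderResult:
    """Per-cause film-vs-reference gender comparison."""

    cause: str
    film_men: int
    film_women: int
    ref_p_men: float
    film_p_men: float | None
    share_film: float
    share_ref: float
    representation_ratio: float | None
    applicable: bool
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None


def overall_shares(film_table: MortalityTable, ref_table: MortalityTable) -> list[ShareRow]:
    """Within-dataset cause shares and the film/reference representation ratio."""
    film_totals = film_table.cause_totals()
    ref_totals = ref_table.cause_totals()
    if set(film_totals) != set(ref_totals):
        raise ValueError("film and reference tables must share one cause vocabulary")
    n_film = sum(film_totals.values())
    n_ref = sum(ref_totals.values())
    if n_film == 0:
        raise ValueError("film table is empty")
    rows = []
    for cause in film_table.causes:
        sf = film_totals[cause] / n_film
        sr = ref_totals[cause] / n_ref
        ratio = sf / sr if sr > 0 else None
        if ratio is None:
            logger.warning("cause %r has zero reference share; ratio undefined", cause)
        rows.append(ShareRow(cause=cause, share_film=sf, share_ref=sr, representation_ratio=ratio))
    return rows


def gender_gof_chisq(film_men: int, film_women: int, ref_p_men: float) -> tuple[float, int, float]:
    """Two-cell goodness-of-fit chi-square of film gender counts vs a
    reference male proportion.

    Expected counts are ``n * ref_p_men`` and ``n * (1 - ref_p_men)``; the
    statistic is the Pearson sum over the two cells, df = 1, upper-tail
    p-value, no continuity correction.
    """
    n = film_men + film_women
    if n <= 0:
        raise ValueError("gender goodness-of-fit requires a positive film count")
    if not 0.0 < ref_p_men < 1.0:
        raise ValueError(f"ref_p_men must be in (0, 1), got {ref_p_men}")
    expected = [n * ref_p_men, n * (1.0 - ref_p_men)]
    chi2, p_value = sps.chisquare([film_men, film_women], f_exp=expected)
    return float(chi2), 1, float(p_value)


def gender_independence_chisq(
    film_men: int, film_women: int, ref_men: int, ref_women: int
) -> tuple[float, int, float]:
    """Optional mode: 2x2 (source x gender) independence test, no correction."""
    chi2, p, df, _ = sps.chi2_contingency(
        [[film_men, film_women], [ref_men, ref_women]], correction=False
    )
    return float(chi2), int(df), float(p)


def applicability(film_count_for_cause: int, threshold: int = DEFAULT_APPLICABILITY_THRESHOLD) -> bool:
    """Small-count rule: the test applies iff the observed film count >= threshold."""
    if film_count_for_cause < 0:
        raise ValueError("count must be non-negative")
    return film_count_for_cause >= threshold


def format_p(p_value: float | None) -> str:
    """Display formatting: 3 decimals, '<.001' below 0.001, '—' when absent."""
    if p_value is None:
        return "—"
    if p_value < 0.001:
        return "<.001"
    return f"{p_value:.3f}".lstrip("0") or ".000"


def run_battery(
    film_table: MortalityTable,
    ref_table: MortalityTable,
    threshold: int = DEFAULT_APPLICABILITY_THRESHOLD,
    method: str = "gof",
) -> list[CauseGenderResult]:
    """Per-cause gender chi-square battery over the shared cause vocabulary.

    The film table must carry per-gender counts with gender-excluded entries
    already removed.  Causes below the applicability threshold carry no
    statistic.  Results are ordered by display name (ASCII sort, matching
    the published table layout).
    """
    extra = set(film_table.causes) - set(ref_table.causes)
    if extra:
        raise ValueError(f"film causes missing from reference vocabulary: {sorted(extra)}")
    if method not in ("gof", "independence"):
        raise ValueError(f"unknown method {method!r}")

    shares = {s.cause: s for s in overall_shares(film_table, ref_table)}
    results = []
    for cause in film_table.causes:
        film_row = film_table[cause]
        n = film_row.men + film_row.women
        ref_p_men, _ = gender_proportion(ref_table, cause)
        ok = applicability(n, threshold)
        chi2 = df = p = None
        if ok:
            if method == "gof":
                chi2, df, p = gender_gof_chisq(film_row.men, film_row.women, ref_p_men)
            else:
                ref_row = ref_table[cause]
                chi2, df, p = gender_independence_chisq(
                    film_row.men, film_row.women, ref_row.men, ref_row.women
                )
        results.append(
            CauseGenderResult(
                cause=cause,
                film_men=film_row.men,
                film_women=film_row.women,
                ref_p_men=ref_p_men,
                film_p_men=film_row.men / n if n else None,
                share_film=shares[cause].share_film,
                share_ref=shares[cause].share_ref,
                representation_ratio=shares[cause].representation_ratio,
                applicable=ok,
                chi2=chi2,
                df=df,
                p_value=p,
            )
        )
    results.sort(key=lambda r: DISPLAY_NAMES.get(r.cause, r.cause))
    return results


def film_table_from_gender_counts(
    counts_by_cause: dict[str, tuple[int, int]], population_id: str = "film"
) -> MortalityTable:
    """Build a film-side MortalityTable from {cause: (men, women)} counts.

    Causes absent from the mapping get zero rows so the vocabulary always
    matches the reference.
    """
    from cinemort.reference import CauseRow

    rows = []
    for cause in CAUSE_CODES:
        men, women = counts_by_cause.get(cause, (0, 0))
        rows.append(CauseRow(cause=cause, total=men + women, women=women, men=men))
    return MortalityTable(rows=rows, population_id=population_id)
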