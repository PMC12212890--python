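"""Figure builders for the representation analysis.

Two figures: a film-vs-reference share scatter with the identity line
(points above the line are causes overrepresented in film), and per-cause
paired gender-proportion bars for film and reference.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cinemort.causes import DISPLAY_NAMES
from cinemort.stats import CauseGenderResult, ShareRow


def plot_share_scatter(
    shares: list[ShareRow], out_path: str | Path, log_scale: bool = True, raw_counts: bool = False
) -> None:
    """Share (or raw count) scatter with identity line on log-log axes."""
    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [s.share_ref for s in shares]
    ys = [s.share_film for s in shares]
    ax.scatter(xs, ys, zorder=3)
    for s in shares:
        ax.annotate(DISPLAY_NAMES.get(s.cause, s.cause), (s.share_ref, s.share_film), fontsize=7)
    lo = min(x for x in xs + ys if x > 0) * 0.5
    hi = max(xs + ys) * 2
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity line")
    if log_scale:
        ax.set_xscale("log")
        ax.set_yscale("log")
    label = "count" if raw_counts else "share of deaths"
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel(f"film {label}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_gender_bars(results: list[CauseGenderResult], out_path: str | Path) -> None:
    """Paired bars: proportion of men by cause, film vs reference."""
    rows = [r for r in results if r.film_p_men is not None]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    idx = range(len(rows))
    width = 0.38
    ax.bar([i - width / 2 for i in idx], [r.film_p_men for r in rows], width, label="film")
    ax.bar([i + width / 2 for i in idx], [r.ref_p_men for r in rows], width, label="reference")
    ax.axhline(0.5, color="grey", lw=0.8, ls=":")
    ax.set_xticks(list(idx))
    ax.set_xticklabels([DISPLAY_NAMES.get(r.cause, r.cause) for r in rows], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("proportion of deaths that are men")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
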