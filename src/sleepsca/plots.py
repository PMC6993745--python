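"""Specification-curve dashboard and participants-per-specification plots.

Figures are data-faithful rather than pixel-faithful: ranked standardized
coefficients on top (teal = significant, pink = not), a decision-indicator
dashboard underneath, faceted by day type, with an optional bootstrap band.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

# deterministic SVG output (stable element ids, no embedded timestamp)
matplotlib.rcParams["svg.hashsalt"] = "sleepsca"

from .engine import SCACurve, SpecResult
from .grid import CONTROL_OPTIONS, DAY_OPTIONS, SLEEP_OPTIONS, TECH_OPTIONS

SIG_COLOR = "teal"
NONSIG_COLOR = "#f4a6c0"  # pink

DECISION_ROWS = (
    ("day_type", DAY_OPTIONS),
    ("sleep_measure", SLEEP_OPTIONS),
    ("tech_measure", TECH_OPTIONS),
    ("control_set", CONTROL_OPTIONS),
)


class PlotError(ValueError):
    pass


def _facets(curve: SCACurve) -> list[tuple[str, list[SpecResult]]]:
    ok = curve.ok_results()
    if not ok:
        raise PlotError("cannot plot an empty curve")
    days = sorted({r.spec.day_type for r in ok if r.spec})
    if not days:
        return [("all", ok)]
    return [
        (day, [r for r in ok if r.spec and r.spec.day_type == day]) for day in days
    ]


def _save(fig, out_base: str | Path, formats: Sequence[str]) -> list[Path]:
    paths = []
    for fmt in formats:
        path = Path(f"{out_base}.{fmt}")
        metadata = {"Date": None} if fmt == "svg" else None
        fig.savefig(path, dpi=150, bbox_inches="tight", metadata=metadata)
        paths.append(path)
    plt.close(fig)
    return paths


def plot_curve(
    curve: SCACurve, out_base: str | Path, formats: Sequence[str] = ("png", "svg")
) -> list[Path]:
    """Two-panel ranked curve + decision dashboard, one column per day type."""
    facets = _facets(curve)
    n_rows = sum(len(opts) for _, opts in DECISION_ROWS)
    fig, axes = plt.subplots(
        2,
        len(facets),
        figsize=(6.5 * len(facets), 7.5),
        sharex="col",
        gridspec_kw={"height_ratios": [2.2, 1.8]},
        squeeze=False,
    )
    for col, (day, results) in enumerate(facets):
        ranked = sorted(results, key=lambda r: r.beta)
        xs = np.arange(1, len(ranked) + 1)
        betas = np.array([r.beta for r in ranked])
        colors = [SIG_COLOR if r.significant else NONSIG_COLOR for r in ranked]

        top = axes[0][col]
        if curve.boot is not None:
            lo = np.array([curve.boot.spec_ci.get(r.spec_id, (np.nan, np.nan))[0] for r in ranked])
            hi = np.array([curve.boot.spec_ci.get(r.spec_id, (np.nan, np.nan))[1] for r in ranked])
            if np.isfinite(lo).any():
                top.fill_between(xs, lo, hi, color="lightgray", alpha=0.6, label="bootstrap CI")
        top.scatter(xs, betas, c=colors, s=18, zorder=3)
        top.axhline(0.0, color="black", lw=0.7)
        top.set_ylabel("standardized β")
        top.set_title(f"{day} ({len(ranked)} specifications)")

        bottom = axes[1][col]
        y = 0
        yticks, ylabels = [], []
        for field, options in DECISION_ROWS:
            for option in options:
                hits = [x for x, r in zip(xs, ranked) if r.spec and getattr(r.spec, field) == option]
                bottom.scatter(hits, [y] * len(hits), marker="|", s=40, color="dimgray")
                yticks.append(y)
                ylabels.append(f"{field}: {option}")
                y += 1
            y += 0.5  # visual gap between decision groups
        bottom.set_yticks(yticks)
        bottom.set_yticklabels(ylabels, fontsize=6)
        bottom.invert_yaxis()
        bottom.set_xlabel("specification rank")
    fig.suptitle("Specification curve", y=0.995)
    fig.tight_layout()
    return _save(fig, out_base, formats)


def plot_n_per_spec(
    curve: SCACurve, out_base: str | Path, formats: Sequence[str] = ("png", "svg")
) -> list[Path]:
    """Analysed sample size per specification, same ranking as the curve."""
    facets = _facets(curve)
    fig, axes = plt.subplots(
        1, len(facets), figsize=(6.5 * len(facets), 3.5), squeeze=False
    )
    for col, (day, results) in enumerate(facets):
        ranked = sorted(results, key=lambda r: r.beta)
        xs = np.arange(1, len(ranked) + 1)
        ax = axes[0][col]
        ax.scatter(xs, [r.n for r in ranked], s=14, color="steelblue")
        ax.set_title(f"{day}")
        ax.set_xlabel("specification rank")
        ax.set_ylabel("participants (n)")
    fig.suptitle("Participants per specification", y=0.98)
    fig.tight_layout()
    return _save(fig, out_base, formats)
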