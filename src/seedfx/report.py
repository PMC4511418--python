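"""Figure and summary-table rendering for correlation analyses.

The main figure style mirrors the field's convention for presenting
correlation groups against an empirical null: stacked histogram panels
sharing the [-1, 1] axis, a dashed vertical line at the null's
percentile threshold, and per-panel annotations of n and the percentage
of correlations above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import CorrelationGroup, NullModel, fraction_significant

__all__ = ["PanelSpec", "render_distribution_figure", "write_summary"]

#: fixed histogram bin width over [-1, 1]
BIN_WIDTH = 0.05


@dataclass(frozen=True)
class PanelSpec:
    """Ordered correlation groups to draw as stacked panels."""

    panels: tuple[tuple[CorrelationGroup, str], ...]
    null_model: NullModel


def render_distribution_figure(spec: PanelSpec, path: str | Path) -> Path:
    """One histogram panel per group, shared axes and threshold line.

    Annotations are computed with :func:`fraction_significant`, the same
    function the summary tables use, so figure and table can never
    disagree.
    """
    if not spec.panels:
        raise ValueError("no panels to render")
    for group, label in spec.panels:
        if group.n == 0:
            raise ValueError(f"panel {label!r} has no correlations")
    bins = np.arange(-1.0, 1.0 + BIN_WIDTH / 2, BIN_WIDTH)
    n_panels = len(spec.panels)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(6, 2.2 * n_panels), sharex=True, squeeze=False
    )
    threshold = spec.null_model.threshold
    for ax, (group, label) in zip(axes.ravel(), spec.panels):
        ax.hist(group.rhos, bins=bins, color="#4878a8", edgecolor="white")
        ax.axvline(threshold, linestyle="--", color="black", linewidth=1)
        pct = fraction_significant(group, spec.null_model)
        ax.annotate(
            f"n = {group.n}\n{pct:.0f}% > thr",
            xy=(0.02, 0.95), xycoords="axes fraction", va="top", fontsize=9,
        )
        ax.set_ylabel(label, fontsize=9)
        ax.set_xlim(-1, 1)
    axes.ravel()[-1].set_xlabel("Spearman correlation")
    fig.suptitle(
        f"threshold = {spec.null_model.percentile:g}th percentile of null "
        f"({threshold:.3f})",
        fontsize=9,
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata=_stable_metadata(path))
    plt.close(fig)
    return path


def _stable_metadata(path: Path) -> dict | None:
    # strip timestamps so identical input gives identical bytes
    if path.suffix.lower() == ".png":
        return {"Software": None}
    if path.suffix.lower() in (".svg", ".pdf"):
        return {"Date": None}
    return None


def write_summary(results: dict, path: str | Path) -> pd.DataFrame:
    """Flatten a results bundle into one summary row per (level, relation).

    Columns: level, relation, n, mean_rho, pct_significant, threshold,
    p_welch_vs_null, p_student_vs_null. The table round-trips through
    CSV without loss of information relevant to the headline statistics.
    """
    rows = []
    for level_key in ("well", "sequence"):
        sub = results[level_key]
        for _, row in sub["summary"].iterrows():
            rel = row["relation"]
            comp = sub["comparisons"].get(f"{rel}_vs_null")
            rows.append({
                "level": row["level"],
                "relation": rel,
                "n": int(row["n"]),
                "mean_rho": row["mean_rho"],
                "pct_significant": row["pct_significant"],
                "threshold": row["threshold"],
                "p_welch_vs_null": comp.p_welch if comp else np.nan,
                "p_student_vs_null": comp.p_student if comp else np.nan,
            })
    out = pd.DataFrame(rows, columns=[
        "level", "relation", "n", "mean_rho", "pct_significant", "threshold",
        "p_welch_vs_null", "p_student_vs_null",
    ])
    out.to_csv(path, index=False)
    return out
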