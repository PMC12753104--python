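"""Scoring cell groups against an ordered differentiation time-course.

Each timepoint of the reference carries a gene signature (typically the
top-k differentially expressed genes of that timepoint's population versus
naive). Query groups are scored per timepoint with the same randomized-
control net score used elsewhere; the resulting group x timepoint score
curves expose whether a group keeps differentiating (score keeps rising),
plateaus (late-window slope near zero), or diverges from another group
(confidence intervals stop overlapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionMatrix
from .signatures import TimecourseReference
from .scoring import (
    control_score,
    net_score,
    score_by_group,
    score_cells,
    standardize_genes,
)

__all__ = [
    "TrajectoryResult",
    "score_timecourse",
    "divergence_timepoint",
    "TrajectoryModel",
]


@dataclass
class TrajectoryResult:
    """Group x timepoint net-score summaries.

    ``table`` columns: group, day, mean, ci_lo, ci_hi, control_mean, n.
    """

    table: pd.DataFrame
    days: list
    groups: list
    n_iter: int
    seed: int
    late_window: int

    def __post_init__(self) -> None:
        need = {"group", "day", "mean", "ci_lo", "ci_hi", "control_mean", "n"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        expected = len(self.groups) * len(self.days)
        if len(self.table) != expected:
            raise ValueError(
                f"table has {len(self.table)} rows, expected {expected}"
            )

    def curve(self, group) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values("day").reset_index(drop=True)

    def late_window_slope(self, group, window: int | None = None) -> float:
        """Least-squares slope of mean score vs day over the last timepoints.

        The window defaults to the last ceil(T/2) timepoints.
        """
        w = window or self.late_window
        sub = self.curve(group).tail(w)
        if len(sub) < 2:
            raise ValueError("late window must span >= 2 timepoints")
        return float(np.polyfit(sub["day"], sub["mean"], 1)[0])

    def slopes(self, window: int | None = None) -> dict:
        return {g: self.late_window_slope(g, window) for g in self.groups}

    def plot(self, ax=None):
        """Per-group score curves with CI bands plus the control curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g in self.groups:
            sub = self.curve(g)
            ax.plot(sub["day"], sub["mean"], marker="o", label=str(g))
            ax.fill_between(sub["day"], sub["ci_lo"], sub["ci_hi"], alpha=0.2)
        ctl = self.table.groupby("day")["control_mean"].mean()
        ax.plot(ctl.index, ctl.values, color="gray", ls="--",
                label="randomized control")
        ax.set_xlabel("day post infection")
        ax.set_ylabel("net signature score")
        ax.legend()
        return ax


def score_timecourse(
    expr: ExpressionMatrix,
    group_labels: np.ndarray,
    ref: TimecourseReference,
    *,
    n_iter: int = 100,
    seed: int = 0,
    scale: bool = True,
    late_window: int | None = None,
) -> TrajectoryResult:
    """Score every group against every timepoint signature of ``ref``.

    Genes are standardized once across all query cells; each timepoint's
    signature is scored with its own randomized control (seed offset by the
    timepoint index, so curves are reproducible and independent).
    """
    group_labels = np.asarray(group_labels)
    if group_labels.size != expr.n_cells:
        raise ValueError("group_labels length != number of cells")
    pool = set(expr.gene_names)
    for day, sig in ref:
        if not (set(sig.up_genes) & pool):
            raise ValueError(
                f"timepoint day {day:g} ({sig.name!r}): no signature gene "
                "present in the expression matrix"
            )
    z = standardize_genes(expr, scale=scale)
    names = expr.gene_names
    groups = list(pd.unique(group_labels))
    rows = []
    for t, (day, sig) in enumerate(ref):
        raw = score_cells(z, names, sig)
        ctl = control_score(z, names, sig, n_iter=n_iter, seed=seed + t)
        res = net_score(raw, ctl, signature_name=sig.name,
                        n_control_iterations=n_iter, seed=seed + t)
        summary = score_by_group(res.net, group_labels)
        for _, r in summary.iterrows():
            rows.append(
                {
                    "group": r["group"],
                    "day": day,
                    "mean": r["mean"],
                    "ci_lo": r["ci_lo"],
                    "ci_hi": r["ci_hi"],
                    "control_mean": float(
                        ctl[group_labels == r["group"]].mean()
                    ),
                    "n": int(r["n"]),
                }
            )
    window = late_window or math.ceil(ref.n_timepoints / 2)
    return TrajectoryResult(
        table=pd.DataFrame(rows),
        days=list(ref.days),
        groups=groups,
        n_iter=n_iter,
        seed=seed,
        late_window=window,
    )


def divergence_timepoint(
    result: TrajectoryResult, group_a, group_b
) -> float | None:
    """Earliest day from which the two groups' CIs stay disjoint.

    Scans timepoints in order and returns the first day such that the 95%
    confidence intervals of the two group means are disjoint at that day
    and at every later day — a persistent separation, which distinguishes
    true late divergence from a transient early fluctuation. Returns
    ``None`` if the intervals overlap at the final timepoint. Symmetric in
    the group order.
    """
    for g in (group_a, group_b):
        if g not in result.groups:
            raise ValueError(f"group {g!r} not present in the result")
    a = result.curve(group_a)
    b = result.curve(group_b)
    disjoint = [
        bool(ra["ci_lo"] > rb["ci_hi"] or rb["ci_lo"] > ra["ci_hi"])
        for (_, ra), (_, rb) in zip(a.iterrows(), b.iterrows())
    ]
    days = a["day"].tolist()
    for i in range(len(disjoint)):
        if all(disjoint[i:]):
            return float(days[i])
    return None


class TrajectoryModel:
    """Model wrapper: query expression + reference -> TrajectoryResult.

    ``fit(seed)`` standardizes the query cells, scores each timepoint
    signature with a randomized control, and returns the result object
    carrying curves, slopes and the divergence scan.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        ref: TimecourseReference,
        *,
        group_column: str = "group",
        scale: bool = True,
        n_control: int = 100,
        late_window: int | None = None,
    ) -> None:
        self.expr = expr
        self.ref = ref
        self.group_column = group_column
        self.scale = scale
        self.n_control = n_control
        self.late_window = late_window

    def fit(self, seed: int = 0) -> TrajectoryResult:
        labels = self.expr.cell_labels[self.group_column].to_numpy()
        return score_timecourse(
            self.expr, labels, self.ref,
            n_iter=self.n_control, seed=seed, scale=self.scale,
            late_window=self.late_window,
        )
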