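"""Normalization and Wilcoxon differential expression versus a reference.

Counts are scaled to a fixed per-cell total and log-transformed as
``log2(1 + scaled)`` — the UMI analogue of log2(TPM + 1), since gene length
carries no meaning for UMI counts. Differential expression of a cell group
against the naive reference uses the two-sided Wilcoxon rank-sum test with
tie-corrected normal approximation (the default of the mainstream
single-cell toolkits), Benjamini-Hochberg adjustment across all tested
genes, and log2 fold changes of scaled group means with pseudocount 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datasets import DropletDataset, ExpressionMatrix
from .signatures import GeneSignature

__all__ = [
    "DETable",
    "normalize_log",
    "differential_genes",
    "rank_sum_test",
    "top_de_geneset",
]

log = logging.getLogger(__name__)


def normalize_log(
    dataset: DropletDataset,
    total: float = 10_000.0,
    cell_labels: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Scale each cell to ``total`` counts and log2(1 + x)-transform.

    Raises if any cell has zero total counts (it cannot be scaled),
    listing the offending barcodes.
    """
    cell_totals = dataset.total_counts().astype(float)
    zero = np.flatnonzero(cell_totals == 0)
    if zero.size:
        bad = [dataset.barcode_ids[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} cell(s) have zero total counts and cannot be "
            f"normalized: {bad}"
        )
    dense = dataset.counts.toarray().astype(float)
    scaled = dense * (total / cell_totals)[None, :]
    labels = cell_labels if cell_labels is not None else dataset.droplet_meta
    return ExpressionMatrix(
        values=np.log2(1.0 + scaled),
        gene_names=list(dataset.gene_names),
        cell_labels=labels.reset_index(drop=True),
        normalization_total=total,
    )


@dataclass
class DETable:
    """Ranked per-gene differential-expression results."""

    table: pd.DataFrame  # gene, lfc, stat, p, p_adj, direction
    group: str
    reference: str

    def __post_init__(self) -> None:
        required = {"gene", "lfc", "stat", "p", "p_adj", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DETable missing columns {missing}")
        if self.table["gene"].duplicated().any():
            raise ValueError("DETable lists a gene twice")

    def __len__(self) -> int:
        return len(self.table)


def rank_sum_test(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum (Mann-Whitney U), rows = genes.

    Normal approximation with tie correction, no continuity correction.
    Returns ``(U statistic of x, two-sided p)``; genes with zero rank
    variance (constant across both groups) get p = 1.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    n1, n2 = x.shape[1], y.shape[1]
    n = n1 + n2
    both = np.concatenate([x, y], axis=1)
    ranks = scipy.stats.rankdata(both, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction: sum(t^3 - t) per gene over tied groups
    sorted_rows = np.sort(both, axis=1)
    changes = np.diff(sorted_rows, axis=1) != 0
    tie_term = np.empty(both.shape[0])
    for i in range(both.shape[0]):  # per-gene pass; tie runs via run lengths
        idx = np.flatnonzero(changes[i])
        sizes = np.diff(np.concatenate([[-1], idx, [n - 1]]))
        tie_term[i] = float((sizes**3 - sizes).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (u1 - mu) / np.where(sigma > 0, sigma, 1.0),
                     0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.where(sigma > 0, np.minimum(p, 1.0), 1.0)
    return u1, p


def differential_genes(
    expr: ExpressionMatrix,
    group: str,
    reference: str,
    *,
    label_column: str = "group",
    pseudocount: float = 1.0,
) -> DETable:
    """Per-gene DE of ``group`` versus ``reference`` cells.

    Both labels are taken from ``expr.cell_labels[label_column]``; each must
    mark at least 3 cells and the two sets must not overlap.
    """
    labels = expr.cell_labels[label_column].to_numpy()
    gi = np.flatnonzero(labels == group)
    ri = np.flatnonzero(labels == reference)
    if group == reference or np.intersect1d(gi, ri).size:
        raise ValueError("group and reference cells overlap")
    if gi.size < 3 or ri.size < 3:
        raise ValueError(
            f"need >= 3 cells per side; got {gi.size} ({group!r}) and "
            f"{ri.size} ({reference!r})"
        )
    xg = expr.values[:, gi]
    xr = expr.values[:, ri]
    u, p = rank_sum_test(xg, xr)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")

    # LFC on the scaled linear means with pseudocount
    lin_g = (np.exp2(xg) - 1.0).mean(axis=1)
    lin_r = (np.exp2(xr) - 1.0).mean(axis=1)
    lfc = np.log2(lin_g + pseudocount) - np.log2(lin_r + pseudocount)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat"))
    table = pd.DataFrame(
        {
            "gene": expr.gene_names,
            "lfc": lfc,
            "stat": u,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )
    return DETable(table=table, group=group, reference=reference)


def top_de_geneset(
    table: DETable,
    k: int = 100,
    direction: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """The ``k`` strongest genes in one direction, as an (up-set) signature.

    Ranked by adjusted p ascending, ties broken by |lfc| descending, then
    gene name; if fewer than ``k`` genes have the requested direction, all
    of them are returned with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not len(table):
        raise ValueError("empty DE table")
    sub = table.table[table.table["direction"] == direction].copy()
    if not len(sub):
        raise ValueError(f"no {direction}-regulated genes in the table")
    sub["_abs_lfc"] = sub["lfc"].abs()
    sub = sub.sort_values(
        ["p_adj", "_abs_lfc", "gene"], ascending=[True, False, True]
    )
    if len(sub) < k:
        msg = (
            f"only {len(sub)} {direction}-regulated genes available "
            f"(requested {k})"
        )
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    chosen = sub["gene"].head(k).tolist()
    sig_name = name or f"{table.group}_vs_{table.reference}_{direction}"
    return GeneSignature(sig_name, frozenset(chosen))
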