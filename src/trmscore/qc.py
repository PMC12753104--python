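"""Cell calling, hashtag demultiplexing, and droplet quality control.

The stage order mirrors a hashed-droplet experiment's preprocessing:

1. call cells from the barcode-rank curve (inflection below the knee);
2. demultiplex hashtags — assign each droplet to the sample whose tag
   dominates (>= 10 counts and more than double the runner-up), flagging
   droplets positive for two tags as doublets;
3. remove low-quality droplets: < 500 RNA counts, > 10% mitochondrial
   counts, < 500 total antibody-tag counts, or double isotype-control
   positivity (sticky droplets). Thresholds are exclusive on the removal
   side, so exactly-500-count and exactly-10%-mito droplets are retained;
4. optionally drop non-T cells by lineage module scores.

Each removal is attributed to the first failing rule in that order, making
the attrition report additive; the retained set itself does not depend on
rule order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import DropletDataset
from .signatures import GeneSignature

__all__ = [
    "DemuxResult",
    "QCReport",
    "call_cells_by_rank",
    "demultiplex_hashtags",
    "apply_qc_filters",
    "ucell_like_scores",
    "exclude_non_t",
]


class InflectionError(ValueError):
    """Raised when the barcode-rank curve has no detectable inflection."""


# ----------------------------------------------------------------------
# cell calling
# ----------------------------------------------------------------------

def call_cells_by_rank(
    total_counts: np.ndarray,
    *,
    smooth_window: int = 11,
    min_slope_magnitude: float = 2.0,
    edge_exclude: int = 3,
) -> tuple[int, np.ndarray]:
    """Call cell-containing droplets from the barcode-rank curve.

    Sorts per-droplet totals descending, smooths log10(total) versus
    log10(rank) with a running median, and places the threshold at the point
    of steepest negative slope (the inflection between the cell cliff and
    the ambient plateau), excluding the extreme ends of the curve. Droplets
    with total >= threshold are called cells.

    Returns ``(threshold, cell_mask)``.

    Raises
    ------
    InflectionError
        If fewer than 100 droplets, or the curve is flat/unimodal (steepest
        slope shallower than ``min_slope_magnitude`` decades per decade).
    """
    totals = np.asarray(total_counts)
    if totals.size < 100:
        raise InflectionError(
            f"need >= 100 droplets to locate an inflection, got {totals.size}"
        )
    if (totals < 0).any():
        raise ValueError("negative totals")
    order = np.argsort(totals)[::-1]
    sorted_tot = totals[order].astype(float)
    pos = sorted_tot > 0
    if pos.sum() < 10:
        raise InflectionError("almost all droplets have zero counts")

    # collapse ties: one point per distinct total, at its average rank
    vals_asc, counts_asc = np.unique(sorted_tot[pos], return_counts=True)
    vals = vals_asc[::-1]                               # descending totals
    tie_counts = counts_asc[::-1]
    ends = np.cumsum(tie_counts)                        # 1-based rank ends
    starts = ends - tie_counts
    avg_rank = (starts + 1 + ends) / 2.0

    if vals.size < 2 * edge_exclude + 3:
        raise InflectionError(
            "too few distinct totals to locate an inflection (flat curve)"
        )

    x = np.log10(avg_rank)
    y = np.log10(vals)
    if smooth_window > 1 and y.size > smooth_window:
        pad = smooth_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.array(
            [np.median(ypad[i:i + smooth_window]) for i in range(y.size)]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.diff(y) / np.diff(x)
    lo, hi = edge_exclude, slopes.size - edge_exclude
    imin = int(np.argmin(slopes[lo:hi])) + lo
    if slopes[imin] > -min_slope_magnitude:
        raise InflectionError(
            "no inflection: steepest log-log slope "
            f"{slopes[imin]:.2f} is shallower than -{min_slope_magnitude}"
        )
    # threshold at the geometric midpoint of the steepest drop
    threshold = int(round(10.0 ** ((y[imin] + y[imin + 1]) / 2.0)))
    return threshold, totals >= threshold


# ----------------------------------------------------------------------
# hashtag demultiplexing
# ----------------------------------------------------------------------

@dataclass
class DemuxResult:
    """Per-droplet hashtag assignment.

    ``assignment`` holds the winning tag index for singlets, -2 for
    doublets (two or more tags positive) and -1 for unassigned droplets.
    """

    assignment: np.ndarray
    max_tag_count: np.ndarray
    second_tag_count: np.ndarray
    positivity_thresholds: np.ndarray
    min_counts: int
    ratio: float

    DOUBLET = -2
    UNASSIGNED = -1

    def labels(self) -> np.ndarray:
        out = np.where(
            self.assignment == self.DOUBLET, "doublet",
            np.where(self.assignment == self.UNASSIGNED, "unassigned",
                     "singlet"),
        )
        return out

    @property
    def singlet_mask(self) -> np.ndarray:
        return self.assignment >= 0

    def summary(self) -> dict:
        lab = self.labels()
        return {
            "n_droplets": int(self.assignment.size),
            "n_singlet": int((lab == "singlet").sum()),
            "n_doublet": int((lab == "doublet").sum()),
            "n_unassigned": int((lab == "unassigned").sum()),
            "min_counts": self.min_counts,
            "ratio": self.ratio,
        }


def demultiplex_hashtags(
    hashtag_counts: np.ndarray,
    *,
    min_counts: int = 10,
    ratio: float = 2.0,
    positivity_quantile: float = 0.99,
) -> DemuxResult:
    """Assign droplets to samples from hashtag-oligo counts.

    A droplet is a *doublet* when two or more tags are positive, where a
    tag's positivity threshold is the ``positivity_quantile`` of its counts
    among droplets where it is not the maximal tag (its ambient
    background). Otherwise the droplet is a *singlet* of its top tag iff
    that tag has at least ``min_counts`` counts and more than ``ratio``
    times the second-highest tag; ties for the maximum, or failing either
    condition, leave it unassigned.
    """
    hto = np.asarray(hashtag_counts)
    if hto.ndim != 2 or hto.shape[0] < 2:
        raise ValueError("need a (tags >= 2) x droplets count matrix")
    n_tags, n_drop = hto.shape

    order = np.argsort(hto, axis=0)
    top = order[-1]
    maxc = hto[top, np.arange(n_drop)]
    second = hto[order[-2], np.arange(n_drop)]

    thresholds = np.empty(n_tags)
    for t in range(n_tags):
        background = hto[t, top != t]
        if background.size == 0:
            raise ValueError(
                f"hashtag {t} has no background droplets "
                "(it is maximal everywhere); cannot set a positivity "
                "threshold"
            )
        if hto[t].sum() == 0:
            raise ValueError(
                f"hashtag {t} has zero counts everywhere; cannot estimate "
                "its background"
            )
        thresholds[t] = np.quantile(background, positivity_quantile)

    n_positive = (hto > thresholds[:, None]).sum(axis=0)
    tie = (hto == maxc[None, :]).sum(axis=0) > 1

    assignment = np.full(n_drop, DemuxResult.UNASSIGNED, dtype=int)
    assignment[n_positive >= 2] = DemuxResult.DOUBLET
    singlet_ok = (
        (n_positive < 2)
        & ~tie
        & (maxc >= min_counts)
        & (maxc > ratio * second)
    )
    assignment[singlet_ok] = top[singlet_ok]
    return DemuxResult(
        assignment=assignment,
        max_tag_count=maxc,
        second_tag_count=second,
        positivity_thresholds=thresholds,
        min_counts=min_counts,
        ratio=ratio,
    )


# ----------------------------------------------------------------------
# QC filters
# ----------------------------------------------------------------------

@dataclass
class QCReport:
    """Attrition accounting: each removed droplet counted at its first
    failing rule, in the order low-RNA, high-mito, low-tag, isotype,
    non-T."""

    droplets_in: int
    removed_low_rna: int = 0
    removed_high_mito: int = 0
    removed_low_tag: int = 0
    removed_isotype: int = 0
    removed_non_t: int = 0
    droplets_out: int = 0

    def check(self) -> None:
        removed = (
            self.removed_low_rna + self.removed_high_mito
            + self.removed_low_tag + self.removed_isotype
            + self.removed_non_t
        )
        if self.droplets_out != self.droplets_in - removed:
            raise AssertionError("QCReport counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "droplets_in": self.droplets_in,
            "removed_low_rna": self.removed_low_rna,
            "removed_high_mito": self.removed_high_mito,
            "removed_low_tag": self.removed_low_tag,
            "removed_isotype": self.removed_isotype,
            "removed_non_t": self.removed_non_t,
            "droplets_out": self.droplets_out,
        }


def isotype_positivity(
    isotype_counts: np.ndarray, positivity_quantile: float = 0.99
) -> np.ndarray:
    """Boolean isotypes x droplets positivity matrix.

    Same construction as hashtag positivity: an isotype's threshold is the
    ``positivity_quantile`` of its counts among droplets where it is not
    the maximal isotype; positivity is count strictly above threshold.
    With a single isotype row the background is all droplets.
    """
    iso = np.asarray(isotype_counts)
    n_iso, n_drop = iso.shape
    thresholds = np.empty(n_iso)
    top = np.argmax(iso, axis=0)
    for t in range(n_iso):
        background = iso[t, top != t] if n_iso > 1 else iso[t]
        if background.size == 0:
            background = iso[t]
        thresholds[t] = np.quantile(background, positivity_quantile)
    return iso > thresholds[:, None]


def apply_qc_filters(
    dataset: DropletDataset,
    *,
    min_rna: int = 500,
    max_mito: float = 0.10,
    min_tag: int = 500,
    isotype_positivity_quantile: float = 0.99,
) -> tuple[DropletDataset, QCReport]:
    """Remove low-quality droplets and report per-rule attrition.

    A droplet is removed if its RNA total is below ``min_rna``, its
    mitochondrial fraction exceeds ``max_mito``, its combined antibody-tag
    (hashtag + isotype) total is below ``min_tag``, or at least two isotype
    controls are positive. Boundary droplets (exactly ``min_rna`` counts,
    exactly ``max_mito`` mito fraction, exactly ``min_tag`` tag counts) are
    retained.
    """
    if not dataset.mito_flags.any():
        raise ValueError("dataset has no mitochondrial gene flags")
    rna = dataset.total_counts()
    mito = dataset.mito_fraction()
    tags = dataset.tag_totals()
    iso_pos = isotype_positivity(
        dataset.isotype_counts, isotype_positivity_quantile
    ).sum(axis=0)

    fail_rna = rna < min_rna
    fail_mito = mito > max_mito
    fail_tag = tags < min_tag
    fail_iso = iso_pos >= 2

    keep = ~(fail_rna | fail_mito | fail_tag | fail_iso)
    # first-failing-rule attribution
    n_rna = int(fail_rna.sum())
    n_mito = int((~fail_rna & fail_mito).sum())
    n_tag = int((~fail_rna & ~fail_mito & fail_tag).sum())
    n_iso = int((~fail_rna & ~fail_mito & ~fail_tag & fail_iso).sum())
    report = QCReport(
        droplets_in=dataset.n_droplets,
        removed_low_rna=n_rna,
        removed_high_mito=n_mito,
        removed_low_tag=n_tag,
        removed_isotype=n_iso,
        droplets_out=int(keep.sum()),
    )
    report.check()
    return dataset.subset(keep), report


# ----------------------------------------------------------------------
# non-T exclusion by lineage module scores
# ----------------------------------------------------------------------

def ucell_like_scores(
    dataset: DropletDataset, signature: GeneSignature
) -> np.ndarray:
    """Per-cell rank-based module score in [0, 1].

    Within each cell, genes are ranked by expression (ties averaged,
    highest expression = highest rank); the score is the mean rank of the
    signature's up genes rescaled so that a signature containing every gene
    scores exactly 0.5. High values mean the program dominates the cell's
    transcriptome.
    """
    sig, _ = signature.restrict_to(dataset.gene_names)
    idx = [i for i, g in enumerate(dataset.gene_names) if g in sig.up_genes]
    dense = dataset.counts.toarray().astype(float)
    ranks = scipy.stats.rankdata(dense, axis=0)
    g = dataset.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes to rank")
    return (ranks[idx].mean(axis=0) - 1.0) / (g - 1.0)


def exclude_non_t(
    dataset: DropletDataset,
    lineage_signatures: list[GeneSignature],
    t_signature: GeneSignature,
    *,
    score_threshold: float = 0.6,
) -> tuple[DropletDataset, int]:
    """Drop cells expressing a non-T lineage program but not the T program.

    A cell is removed iff any lineage (e.g. myeloid, B, innate lymphoid)
    module score exceeds ``score_threshold`` while its T-cell score is
    below it. Returns ``(filtered dataset, number removed)``.
    """
    if not lineage_signatures:
        return dataset, 0
    for sig in lineage_signatures + [t_signature]:
        present = set(sig.up_genes) & set(dataset.gene_names)
        if not present:
            raise ValueError(
                f"signature {sig.name!r} has no genes in the dataset"
            )
    lineage = np.zeros(dataset.n_droplets, dtype=bool)
    for sig in lineage_signatures:
        lineage |= ucell_like_scores(dataset, sig) > score_threshold
    t_score = ucell_like_scores(dataset, t_signature)
    remove = lineage & (t_score < score_threshold)
    return dataset.subset(~remove), int(remove.sum())
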