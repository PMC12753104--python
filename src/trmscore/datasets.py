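"""In-memory containers for droplet-level count data and normalized expression.

The raw unit of data is the *droplet*: a GEM that may hold a real cell, two
cells (doublet), or only ambient RNA (empty). Gene counts are kept sparse
(genes x droplets); hashtag (HTO) and isotype-control antibody counts are
small dense matrices over the same droplet columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["DropletDataset", "ExpressionMatrix"]


@dataclass
class DropletDataset:
    """Raw counts for a set of droplets, plus antibody-tag counts and metadata.

    Parameters
    ----------
    counts
        genes x droplets sparse matrix of non-negative integer UMI counts.
    hashtag_counts
        tags x droplets dense array of hashtag-oligo counts.
    isotype_counts
        isotype-controls x droplets dense array of non-binding antibody counts.
    gene_names
        Unique gene identifiers, one per row of ``counts``.
    mito_flags
        Boolean per-gene flag marking mitochondrial genes.
    barcode_ids
        Droplet barcodes, one per column.
    droplet_meta
        Per-droplet key -> value table indexed like ``barcode_ids``.
    """

    counts: sp.spmatrix
    hashtag_counts: np.ndarray
    isotype_counts: np.ndarray
    gene_names: list[str]
    mito_flags: np.ndarray
    barcode_ids: list[str]
    droplet_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.hashtag_counts = np.asarray(self.hashtag_counts)
        self.isotype_counts = np.asarray(self.isotype_counts)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        g, n = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} rows")
        if len(set(self.gene_names)) != g:
            raise ValueError("gene names are not unique")
        if self.mito_flags.shape != (g,):
            raise ValueError("mito_flags length does not match gene count")
        if len(self.barcode_ids) != n:
            raise ValueError(f"{len(self.barcode_ids)} barcodes for {n} columns")
        for name, mat in (("hashtag", self.hashtag_counts),
                          ("isotype", self.isotype_counts)):
            if mat.ndim != 2 or mat.shape[1] != n:
                raise ValueError(
                    f"{name}_counts must be (tags, {n}); got {mat.shape}"
                )
        if self.droplet_meta.empty and len(self.droplet_meta.columns) == 0:
            self.droplet_meta = pd.DataFrame(index=pd.Index(self.barcode_ids))
        elif len(self.droplet_meta) != n:
            raise ValueError("droplet_meta length does not match droplet count")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-droplet total RNA counts."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-droplet fraction of counts mapping to mitochondrial genes.

        Droplets with zero total counts get fraction 0.
        """
        if not self.mito_flags.any():
            raise ValueError("dataset has no mitochondrial-flagged genes")
        tot = self.total_counts().astype(float)
        mito = np.asarray(self.counts[self.mito_flags].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1e-300), 0.0)
        return frac

    def tag_totals(self) -> np.ndarray:
        """Per-droplet total antibody-tag counts (hashtags + isotypes)."""
        return self.hashtag_counts.sum(axis=0) + self.isotype_counts.sum(axis=0)

    def subset(self, mask: np.ndarray) -> "DropletDataset":
        """Return a new dataset restricted to droplets where ``mask`` holds.

        ``mask`` may be boolean (length n_droplets) or integer indices.
        """
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return DropletDataset(
            counts=self.counts[:, idx],
            hashtag_counts=self.hashtag_counts[:, idx],
            isotype_counts=self.isotype_counts[:, idx],
            gene_names=list(self.gene_names),
            mito_flags=self.mito_flags.copy(),
            barcode_ids=[self.barcode_ids[i] for i in idx],
            droplet_meta=self.droplet_meta.iloc[idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression: ``log2(1 + count * total / cell_total)``.

    Attributes
    ----------
    values
        genes x cells dense float array, all >= 0.
    gene_names
        Row labels.
    cell_labels
        Per-cell annotation table (cluster / site / sample columns as
        available); index = barcodes.
    normalization_total
        The fixed per-cell total the counts were scaled to.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_labels: pd.DataFrame
    normalization_total: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if len(self.gene_names) != self.values.shape[0]:
            raise ValueError("gene_names length does not match rows")
        if len(self.cell_labels) != self.values.shape[1]:
            raise ValueError("cell_labels length does not match columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Indices of ``genes`` present in the matrix (absent ones skipped)."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def linear_values(self) -> np.ndarray:
        """Back-transform to the scaled (counts-per-total) linear scale."""
        return np.exp2(self.values) - 1.0
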