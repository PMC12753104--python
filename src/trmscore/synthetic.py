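"""Seeded simulator for hashed-droplet scRNA-seq experiments.

Emulates the statistical structure of a pooled two-flank skin T-cell
experiment: several transcriptional clusters (one a naive analogue, one
carrying a planted tissue-residency program), two skin "sites" with different
cluster mixtures, hashtag-oligo labels with ambient background, and the
droplet artifacts a QC stage must remove — empty droplets, cell doublets,
dying high-mitochondrial cells, and antibody-sticky droplets that light up
isotype controls.

Counts are negative binomial around gamma-distributed per-gene baseline
means scaled by a log-normal per-cell library size. Planted signature
programs multiply the up-gene means of a cluster by ``2**lfc_up`` and the
down-gene means by ``2**lfc_down``.

All randomness derives from one integer seed; each simulation concern draws
from its own named substream, so enabling an artifact never perturbs the
draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import DropletDataset
from .signatures import GeneSignature, TimecourseReference

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_signature_library",
    "generate_timecourse_populations",
    "generate_arrest_comparison",
]

# Fixed spawn keys: adding a new stream never shifts existing ones.
_STREAMS = {
    "base": 0,
    "cells": 1,
    "assign": 2,
    "doublets": 3,
    "empties": 4,
    "dying": 5,
    "hashtag": 6,
    "isotype": 7,
    "shuffle": 8,
    "timecourse": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimConfig:
    """Parameters of one simulated hashed-droplet experiment.

    Defaults describe the study conditions used throughout the test-suite:
    five clusters of 500 cells (cluster 0 the naive analogue), cluster 3
    carrying a 50-up/50-down-gene residency program at log2 fold change
    +1/-1, two sites with cluster mixtures that enrich cluster 3 at the
    antigen-bearing site, and ~2,000 empty droplets well separated from
    cells on the barcode-rank curve.
    """

    n_genes: int = 2000
    n_cells_per_cluster: list = field(default_factory=lambda: [500] * 5)
    n_empty_droplets: int = 2000
    doublet_fraction: float = 0.05
    dying_fraction: float = 0.05
    n_hashtags: int = 8
    hashtag_signal_mean: float = 800.0
    hashtag_ambient_mean: float = 2.0
    library_size_log_mean: float = math.log(5000.0)
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 0.3
    signature_effects: dict = field(
        default_factory=lambda: {3: [("TRM", 1.0, -1.0)]}
    )
    site_mixtures: dict = field(
        default_factory=lambda: {
            "VV": [0.10, 0.15, 0.20, 0.40, 0.15],
            "DNFB": [0.10, 0.35, 0.30, 0.10, 0.15],
        }
    )
    mito_gene_fraction: float = 0.05
    seed: int = 0

    # secondary knobs (defaults are part of the study conditions)
    signature_names: list = field(
        default_factory=lambda: ["TRM", "TACT", "TMEM", "TEX"]
    )
    signature_up_size: int = 50
    signature_down_size: int = 50
    naive_cluster: int = 0
    empty_library_fraction: float = 0.015
    mito_baseline_share: float = 0.03
    dying_mito_range: tuple = (0.15, 0.40)
    n_isotypes: int = 2
    isotype_ambient_mean: float = 3.0
    isotype_sticky_mean: float = 80.0
    sticky_fraction: float = 0.005
    gene_mean_shape: float = 0.5
    hashtag_dispersion: float = 0.02

    # ------------------------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_cluster))

    @property
    def sites(self) -> list:
        # sorted, so site indexing is stable under config serialization
        return sorted(self.site_mixtures)

    @property
    def n_mice(self) -> int:
        return self.n_hashtags // max(len(self.site_mixtures), 1)

    def effects_for(self, cluster: int) -> list:
        """Planted (signature, lfc_up, lfc_down) effects of one cluster."""
        eff = self.signature_effects.get(cluster, [])
        if eff and not isinstance(eff, (list, tuple)):
            raise ValueError("signature_effects values must be tuples/lists")
        if eff and isinstance(eff, tuple) and isinstance(eff[0], str):
            eff = [eff]
        return list(eff)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.n_cells_per_cluster or any(
            n <= 0 for n in self.n_cells_per_cluster
        ):
            raise ValueError("n_cells_per_cluster entries must be positive")
        if self.n_empty_droplets < 0:
            raise ValueError("n_empty_droplets must be >= 0")
        for name in ("doublet_fraction", "dying_fraction", "sticky_fraction",
                     "mito_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.doublet_fraction + self.dying_fraction >= 1.0:
            raise ValueError("doublet_fraction + dying_fraction must be < 1")
        if self.n_hashtags < 2:
            raise ValueError("need at least 2 hashtags")
        if self.n_hashtags % len(self.site_mixtures) != 0:
            raise ValueError(
                "n_hashtags must be a multiple of the number of sites "
                "(one tag per mouse x site)"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for site, mix in self.site_mixtures.items():
            mix = np.asarray(mix, dtype=float)
            if len(mix) != self.n_clusters:
                raise ValueError(
                    f"site {site!r}: mixture length {len(mix)} != "
                    f"{self.n_clusters} clusters"
                )
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ValueError(f"site {site!r}: mixture does not sum to 1")
            if (mix < 0).any():
                raise ValueError(f"site {site!r}: negative mixture entry")
        for c in self.signature_effects:
            if not 0 <= c < self.n_clusters:
                raise ValueError(f"signature_effects refers to cluster {c}")
            for eff in self.effects_for(c):
                if eff[0] not in self.signature_names:
                    raise ValueError(
                        f"planted signature {eff[0]!r} not in signature_names"
                    )
        blocks = self.signature_up_size + self.signature_down_size
        if blocks * len(self.signature_names) > self.n_genes - self._n_mito():
            raise ValueError(
                "signature gene blocks exceed the available gene pool"
            )
        # Empty droplets must sit clearly below cells on the rank curve,
        # otherwise the inflection point is undetectable.
        if self.n_empty_droplets > 0:
            sep = -math.log(self.empty_library_fraction)
            if sep < 6.0 * self.library_size_log_sd:
                raise ValueError(
                    "empty droplet library sizes overlap cell library sizes "
                    f"(need log-separation {6 * self.library_size_log_sd:.2f},"
                    f" have {sep:.2f}); the barcode-rank inflection would be "
                    "undetectable"
                )

    def _n_mito(self) -> int:
        return max(1, int(round(self.mito_gene_fraction * self.n_genes)))


@dataclass
class GroundTruth:
    """Planted labels of every emitted droplet, aligned with dataset columns."""

    droplet_class: np.ndarray          # "cell" | "empty" | "doublet"
    true_cluster: list                 # int, or (int, int) for doublets
    true_hashtag: list                 # int, or (int, int) for doublets
    true_site: list                    # site label ("" for empties)
    true_sample: list                  # mouse/sample label ("" for empties)
    is_dying: np.ndarray
    is_sticky: np.ndarray
    planted_effects: dict

    def __post_init__(self) -> None:
        n = len(self.droplet_class)
        for name in ("true_cluster", "true_hashtag", "true_site",
                     "true_sample", "is_dying", "is_sticky"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != droplet count {n}")
        for cls, tag in zip(self.droplet_class, self.true_hashtag):
            if cls == "doublet" and (not isinstance(tag, tuple)
                                     or len(tag) != 2):
                raise ValueError("doublets must carry exactly two tag ids")

    def __len__(self) -> int:
        return len(self.droplet_class)

    def to_frame(self) -> pd.DataFrame:
        """Flat table view (tuples joined with '+') for TSV export."""

        def flat(v):
            return "+".join(str(x) for x in v) if isinstance(v, tuple) else str(v)

        return pd.DataFrame(
            {
                "droplet_class": self.droplet_class,
                "true_cluster": [flat(v) for v in self.true_cluster],
                "true_hashtag": [flat(v) for v in self.true_hashtag],
                "true_site": self.true_site,
                "true_sample": self.true_sample,
                "is_dying": self.is_dying.astype(int),
                "is_sticky": self.is_sticky.astype(int),
            }
        )

    def subset(self, idx) -> "GroundTruth":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda xs: [xs[i] for i in idx]  # noqa: E731
        return GroundTruth(
            droplet_class=self.droplet_class[idx],
            true_cluster=take(self.true_cluster),
            true_hashtag=take(self.true_hashtag),
            true_site=take(self.true_site),
            true_sample=take(self.true_sample),
            is_dying=self.is_dying[idx],
            is_sticky=self.is_sticky[idx],
            planted_effects=self.planted_effects,
        )


# ----------------------------------------------------------------------
# gene layout helpers
# ----------------------------------------------------------------------

def gene_names_for(config: SimConfig) -> tuple[list, np.ndarray]:
    """Gene names and mitochondrial flags for a config."""
    m = config._n_mito()
    names = [f"mt-gene{i:04d}" for i in range(m)]
    names += [f"gene{i:04d}" for i in range(m, config.n_genes)]
    flags = np.zeros(config.n_genes, dtype=bool)
    flags[:m] = True
    return names, flags


def signature_blocks(config: SimConfig) -> dict:
    """Deterministic gene-index blocks per signature: name -> (up, down)."""
    m = config._n_mito()
    u, d = config.signature_up_size, config.signature_down_size
    blocks = {}
    pos = m
    for name in config.signature_names:
        if pos + u + d > config.n_genes:
            raise ValueError("signature gene blocks exceed the gene pool")
        blocks[name] = (np.arange(pos, pos + u), np.arange(pos + u, pos + u + d))
        pos += u + d
    return blocks


def _baseline_means(config: SimConfig) -> np.ndarray:
    """Relative per-gene expression (sums to 1) with a fixed mito share."""
    rng = _rng(config.seed, "base")
    p = rng.gamma(config.gene_mean_shape, 1.0, config.n_genes) + 1e-3
    m = config._n_mito()
    share = config.mito_baseline_share
    p[:m] *= share / p[:m].sum()
    p[m:] *= (1.0 - share) / p[m:].sum()
    return p


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean**2."""
    r = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(r, r / (r + mean)).astype(np.int64)


def _cluster_profiles(config: SimConfig, base: np.ndarray) -> np.ndarray:
    """clusters x genes matrix of relative expression with planted effects."""
    blocks = signature_blocks(config)
    prof = np.tile(base, (config.n_clusters, 1))
    for c in range(config.n_clusters):
        for name, lfc_up, lfc_down in config.effects_for(c):
            up, down = blocks[name]
            prof[c, up] *= 2.0 ** lfc_up
            prof[c, down] *= 2.0 ** lfc_down
    return prof


# ----------------------------------------------------------------------
# main generators
# ----------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> tuple[DropletDataset, GroundTruth]:
    """Simulate one hashed-droplet dataset with known ground truth.

    Returns the dataset (droplet order randomized) and the aligned truth.
    """
    config.validate()
    base = _baseline_means(config)
    profiles = _cluster_profiles(config, base)
    gene_names, mito_flags = gene_names_for(config)
    mu_lib, sd_lib = config.library_size_log_mean, config.library_size_log_sd
    n_sites = len(config.sites)

    rng_cells = _rng(config.seed, "cells")
    rng_assign = _rng(config.seed, "assign")
    rng_dbl = _rng(config.seed, "doublets")

    # --- real cells, cluster by cluster -------------------------------
    cluster_of = np.repeat(
        np.arange(config.n_clusters), config.n_cells_per_cluster
    )
    n_cells = config.n_cells
    libs = rng_cells.lognormal(mu_lib, sd_lib, n_cells)
    counts_cells = np.empty((config.n_genes, n_cells), dtype=np.int64)
    for c in range(config.n_clusters):
        cols = np.flatnonzero(cluster_of == c)
        mu = profiles[c][:, None] * libs[cols][None, :]
        counts_cells[:, cols] = _nb_draw(rng_cells, mu, config.nb_dispersion)

    # site ~ P(site | cluster) from the mixtures; mouse uniform
    mix = np.array(
        [config.site_mixtures[s] for s in config.sites], dtype=float
    )  # sites x clusters
    site_idx = np.empty(n_cells, dtype=int)
    for c in range(config.n_clusters):
        cols = np.flatnonzero(cluster_of == c)
        w = mix[:, c]
        w = w / w.sum() if w.sum() > 0 else np.full(n_sites, 1.0 / n_sites)
        site_idx[cols] = rng_assign.choice(n_sites, size=len(cols), p=w)
    mouse = rng_assign.integers(0, config.n_mice, n_cells)
    tag = mouse * n_sites + site_idx

    # artifact classes are mutually exclusive per droplet
    u = rng_assign.uniform(size=n_cells)
    is_doublet = u < config.doublet_fraction
    is_dying = (~is_doublet) & (
        u < config.doublet_fraction + config.dying_fraction
    )

    # --- doublets: add a second, independent cell ----------------------
    cluster2 = np.full(n_cells, -1)
    tag2 = np.full(n_cells, -1)
    dbl_cols = np.flatnonzero(is_doublet)
    if dbl_cols.size:
        props = np.asarray(config.n_cells_per_cluster, float)
        props /= props.sum()
        cluster2[dbl_cols] = rng_dbl.choice(
            config.n_clusters, size=dbl_cols.size, p=props
        )
        libs2 = rng_dbl.lognormal(mu_lib, sd_lib, dbl_cols.size)
        mu2 = profiles[cluster2[dbl_cols]].T * libs2[None, :]
        counts_cells[:, dbl_cols] += _nb_draw(
            rng_dbl, mu2, config.nb_dispersion
        )
        # second tag: any tag but the first
        t2 = rng_dbl.integers(0, config.n_hashtags - 1, dbl_cols.size)
        tag2[dbl_cols] = t2 + (t2 >= tag[dbl_cols])

    # --- dying cells: inflate the mitochondrial share ------------------
    rng_dying = _rng(config.seed, "dying")
    lo, hi = config.dying_mito_range
    for col in np.flatnonzero(is_dying):
        target = rng_dying.uniform(lo, hi)
        mcounts = counts_cells[mito_flags, col]
        other = counts_cells[~mito_flags, col].sum()
        msum = mcounts.sum()
        if msum == 0:
            counts_cells[0, col] = int(round(target / (1 - target) * other))
        else:
            f = target * other / (msum * (1.0 - target))
            counts_cells[mito_flags, col] = np.round(mcounts * f).astype(
                np.int64
            )

    # --- empty droplets -------------------------------------------------
    rng_emp = _rng(config.seed, "empties")
    n_empty = config.n_empty_droplets
    if n_empty:
        libs_e = rng_emp.lognormal(
            mu_lib + math.log(config.empty_library_fraction), sd_lib, n_empty
        )
        counts_empty = rng_emp.poisson(
            base[:, None] * libs_e[None, :]
        ).astype(np.int64)
    else:
        counts_empty = np.empty((config.n_genes, 0), dtype=np.int64)

    # --- hashtag and isotype counts ------------------------------------
    rng_hto = _rng(config.seed, "hashtag")
    n_total = n_cells + n_empty
    hto = rng_hto.poisson(
        config.hashtag_ambient_mean, (config.n_hashtags, n_total)
    ).astype(np.int64)
    own = _nb_draw(
        rng_hto,
        np.full(n_cells, config.hashtag_signal_mean),
        config.hashtag_dispersion,
    )
    hto[tag, np.arange(n_cells)] += own
    if dbl_cols.size:
        own2 = _nb_draw(
            rng_hto,
            np.full(dbl_cols.size, config.hashtag_signal_mean),
            config.hashtag_dispersion,
        )
        hto[tag2[dbl_cols], dbl_cols] += own2

    rng_iso = _rng(config.seed, "isotype")
    iso = rng_iso.poisson(
        config.isotype_ambient_mean, (config.n_isotypes, n_total)
    ).astype(np.int64)
    is_sticky = np.zeros(n_total, dtype=bool)
    is_sticky[:n_cells] = (
        rng_iso.uniform(size=n_cells) < config.sticky_fraction
    )
    sticky_cols = np.flatnonzero(is_sticky)
    if sticky_cols.size:
        iso[:, sticky_cols] += rng_iso.poisson(
            config.isotype_sticky_mean, (config.n_isotypes, sticky_cols.size)
        )

    # --- assemble, shuffle ---------------------------------------------
    counts = np.concatenate([counts_cells, counts_empty], axis=1)
    droplet_class = np.array(
        ["doublet" if d else "cell" for d in is_doublet]
        + ["empty"] * n_empty
    )
    sites = config.sites
    true_cluster: list = [
        (int(cluster_of[i]), int(cluster2[i])) if is_doublet[i]
        else int(cluster_of[i])
        for i in range(n_cells)
    ] + [-1] * n_empty
    true_hashtag: list = [
        (int(tag[i]), int(tag2[i])) if is_doublet[i] else int(tag[i])
        for i in range(n_cells)
    ] + [-1] * n_empty
    true_site = [sites[site_idx[i]] for i in range(n_cells)] + [""] * n_empty
    true_sample = [f"m{mouse[i]}" for i in range(n_cells)] + [""] * n_empty
    dying_all = np.concatenate([is_dying, np.zeros(n_empty, dtype=bool)])

    perm = _rng(config.seed, "shuffle").permutation(n_total)
    truth = GroundTruth(
        droplet_class=droplet_class[perm],
        true_cluster=[true_cluster[i] for i in perm],
        true_hashtag=[true_hashtag[i] for i in perm],
        true_site=[true_site[i] for i in perm],
        true_sample=[true_sample[i] for i in perm],
        is_dying=dying_all[perm],
        is_sticky=is_sticky[perm],
        planted_effects={
            c: config.effects_for(c) for c in config.signature_effects
        },
    )
    dataset = DropletDataset(
        counts=sp.csr_matrix(counts[:, perm]),
        hashtag_counts=hto[:, perm],
        isotype_counts=iso[:, perm],
        gene_names=gene_names,
        mito_flags=mito_flags,
        barcode_ids=[f"BC{i:06d}" for i in range(n_total)],
    )
    return dataset, truth


def generate_signature_library(config: SimConfig) -> list[GeneSignature]:
    """The named signatures the simulator can plant, as disjoint gene sets.

    Block layout is deterministic in the config, so the library is consistent
    with any dataset generated from the same config.
    """
    config.validate()
    names, _ = gene_names_for(config)
    out = []
    for sig_name, (up, down) in signature_blocks(config).items():
        out.append(
            GeneSignature(
                sig_name,
                frozenset(names[i] for i in up),
                frozenset(names[i] for i in down),
            )
        )
    return out


# ----------------------------------------------------------------------
# differentiation time-course
# ----------------------------------------------------------------------

def _timecourse_program(config: SimConfig, n_timepoints: int,
                        n_up: int, n_down: int, growth_len: float,
                        gradient_scale: float):
    """Per-gene onset/slope for a monotone differentiation program.

    Gene g switches on at ``onset[g]`` (timepoint units; negative = active
    from the start) and its |log2 FC| versus naive grows linearly with slope
    ``slope[g]`` per timepoint until it saturates after ``growth_len``
    timepoints. Down-program genes mirror with negative sign.
    """
    rng = _rng(config.seed, "timecourse")
    m = config._n_mito()
    blocks = signature_blocks(config)
    first_free = max((b[1][-1] for b in blocks.values()), default=m - 1) + 1
    if first_free + n_up + n_down > config.n_genes:
        raise ValueError("time-course program genes exceed the gene pool")
    up_idx = np.arange(config.n_genes - n_up - n_down, config.n_genes - n_down)
    down_idx = np.arange(config.n_genes - n_down, config.n_genes)
    if up_idx[0] < first_free:
        raise ValueError("time-course program overlaps signature blocks")
    onset_up = rng.uniform(-2.0, n_timepoints - 1.0, n_up)
    slope_up = rng.uniform(0.5, 2.0, n_up) * gradient_scale
    # down genes mirror up genes (same onsets and magnitudes, opposite
    # sign) so up- and down-program library shares cancel to first order
    # and normalization does not create spurious early group differences
    reps = int(np.ceil(n_down / max(n_up, 1)))
    onset_down = np.tile(onset_up, reps)[:n_down]
    slope_down = np.tile(slope_up, reps)[:n_down]

    def lfc_at(t: float) -> np.ndarray:
        lfc = np.zeros(config.n_genes)
        a = np.clip(t - onset_up + 1.0, 0.0, growth_len) / growth_len
        lfc[up_idx] = slope_up * a
        a = np.clip(t - onset_down + 1.0, 0.0, growth_len) / growth_len
        lfc[down_idx] = -slope_down * a
        return lfc

    return up_idx, down_idx, lfc_at


def _population_dataset(config: SimConfig, lfc: np.ndarray, n_cells: int,
                        rng: np.random.Generator, label: str,
                        barcode_prefix: str) -> DropletDataset:
    """One clean single-population dataset (no artifacts) at a given state."""
    base = _baseline_means(config)
    profile = base * np.exp2(lfc)
    libs = rng.lognormal(
        config.library_size_log_mean, config.library_size_log_sd, n_cells
    )
    counts = _nb_draw(
        rng, profile[:, None] * libs[None, :], config.nb_dispersion
    )
    gene_names, mito_flags = gene_names_for(config)
    hto = rng.poisson(
        config.hashtag_ambient_mean, (config.n_hashtags, n_cells)
    ).astype(np.int64)
    hto[0] += _nb_draw(
        rng, np.full(n_cells, config.hashtag_signal_mean),
        config.hashtag_dispersion,
    )
    iso = rng.poisson(
        config.isotype_ambient_mean, (config.n_isotypes, n_cells)
    ).astype(np.int64)
    meta = pd.DataFrame({"population": [label] * n_cells})
    return DropletDataset(
        counts=sp.csr_matrix(counts),
        hashtag_counts=hto,
        isotype_counts=iso,
        gene_names=gene_names,
        mito_flags=mito_flags,
        barcode_ids=[f"{barcode_prefix}{i:06d}" for i in range(n_cells)],
        droplet_meta=meta,
    )


def generate_timecourse_populations(
    config: SimConfig,
    n_timepoints: int,
    *,
    k: int = 100,
    day_step: float = 5.0,
    first_day: float = 5.0,
    n_cells_per_population: int = 400,
    n_program_up: int = 200,
    n_program_down: int = 200,
    growth_len: float = 1.0,
    gradient_scale: float = 1.0,
) -> tuple[list[DropletDataset], TimecourseReference]:
    """Populations along a differentiation gradient plus their reference.

    Simulates one cell population per timepoint whose program-gene log2 fold
    changes versus naive grow monotonically with time, then derives the
    reference the trajectory stage consumes: per timepoint, the top-``k``
    up- and down-regulated genes of that population versus a matched naive
    population (computed with the differential-expression stage).

    Returns ``(populations, reference)``; ``populations[t]`` is the dataset
    of timepoint ``t`` (its day is ``first_day + t * day_step``).
    """
    from .diffexpr import differential_genes, normalize_log, top_de_geneset

    config.validate()
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    _, _, lfc_at = _timecourse_program(
        config, n_timepoints, n_program_up, n_program_down,
        growth_len, gradient_scale,
    )
    # program parameters use the parent "timecourse" stream; population
    # counts use a child stream so both are independently reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed,
                               spawn_key=(_STREAMS["timecourse"], 1))
    )
    naive = _population_dataset(
        config, np.zeros(config.n_genes), n_cells_per_population, rng,
        "naive", "NV",
    )
    populations = []
    days = [first_day + t * day_step for t in range(n_timepoints)]
    for t in range(n_timepoints):
        populations.append(
            _population_dataset(
                config, lfc_at(float(t)), n_cells_per_population, rng,
                f"d{days[t]:g}", f"T{t:02d}",
            )
        )

    signatures = []
    for t, pop in enumerate(populations):
        merged = np.concatenate(
            [pop.counts.toarray(), naive.counts.toarray()], axis=1
        )
        labels = pd.DataFrame(
            {"group": ["pop"] * pop.n_droplets + ["naive"] * naive.n_droplets}
        )
        both = DropletDataset(
            counts=sp.csr_matrix(merged),
            hashtag_counts=np.zeros((1, merged.shape[1]), dtype=np.int64),
            isotype_counts=np.zeros((1, merged.shape[1]), dtype=np.int64),
            gene_names=list(pop.gene_names),
            mito_flags=pop.mito_flags.copy(),
            barcode_ids=[f"X{i:06d}" for i in range(merged.shape[1])],
            droplet_meta=labels,
        )
        expr = normalize_log(both)
        table = differential_genes(expr, "pop", "naive", label_column="group")
        up = top_de_geneset(table, k=k, direction="up",
                            name=f"TRM_d{days[t]:02g}")
        try:
            down = top_de_geneset(table, k=k, direction="down",
                                  name=f"TRM_d{days[t]:02g}")
            down_genes = down.up_genes
        except ValueError:
            down_genes = frozenset()
        signatures.append(
            GeneSignature(f"TRM_d{days[t]:02g}", up.up_genes, down_genes)
        )
    return populations, TimecourseReference(days=days, signatures=signatures)


def generate_arrest_comparison(
    config: SimConfig,
    n_timepoints: int = 6,
    truncate_at: int = 3,
    *,
    n_cells_per_group: int = 400,
    groups: tuple = ("naive", "early", "arrested", "full"),
    **timecourse_kwargs,
):
    """Query panel for trajectory analysis: naive, early, arrested, full.

    Builds the time-course reference plus a combined query dataset of four
    populations: naive (state 0), early (state 1), arrested (differentiation
    frozen at state ``truncate_at``) and full (final state). The dataset's
    ``droplet_meta['group']`` carries the group labels.

    Returns ``(query dataset, reference, truncation day)``.
    """
    if not 1 <= truncate_at < n_timepoints - 1:
        raise ValueError("truncate_at must lie strictly inside the course")
    pops, ref = generate_timecourse_populations(
        config, n_timepoints,
        n_cells_per_population=n_cells_per_group,
        **timecourse_kwargs,
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed,
                               spawn_key=(_STREAMS["timecourse"], 2))
    )
    state = {
        "naive": None,
        "early": pops[1],
        "arrested": pops[truncate_at],
        "full": pops[-1],
    }
    parts = []
    for g in groups:
        if state.get(g) is None:
            parts.append(
                _population_dataset(
                    config, np.zeros(config.n_genes), n_cells_per_group,
                    rng, g, "NQ",
                )
            )
        else:
            parts.append(state[g])
    merged = sp.hstack([p.counts for p in parts], format="csr")
    labels = [g for g, p in zip(groups, parts) for _ in range(p.n_droplets)]
    meta = pd.DataFrame({"group": labels})
    n = merged.shape[1]
    query = DropletDataset(
        counts=merged,
        hashtag_counts=np.zeros((1, n), dtype=np.int64),
        isotype_counts=np.zeros((1, n), dtype=np.int64),
        gene_names=list(parts[0].gene_names),
        mito_flags=parts[0].mito_flags.copy(),
        barcode_ids=[f"Q{i:06d}" for i in range(n)],
        droplet_meta=meta,
    )
    return query, ref, ref.days[truncate_at]


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
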