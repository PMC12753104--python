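"""Cell calling, hashtag demultiplexing and droplet filtering."""

import numpy as np
import pytest

from trmscore import generate_dataset, generate_signature_library
from trmscore.qc import (
    InflectionError,
    apply_qc_filters,
    call_cells_by_rank,
    demultiplex_hashtags,
    exclude_non_t,
    isotype_positivity,
    ucell_like_scores,
)

from conftest import clean_sim_config, small_sim_config, tiny_dataset


# ----------------------------------------------------------------------
# cell calling
# ----------------------------------------------------------------------

class TestCallCells:
    def test_bimodal_totals_split_perfectly(self):
        rng = np.random.default_rng(0)
        high = rng.normal(5000, 400, 400).clip(1000)
        low = rng.normal(50, 15, 600).clip(1)
        totals = np.concatenate([high, low]).round()
        threshold, mask = call_cells_by_rank(totals)
        assert mask[:400].all()
        assert not mask[400:].any()
        assert 100 < threshold < 1500

    def test_flat_curve_raises(self):
        with pytest.raises(InflectionError):
            call_cells_by_rank(np.full(500, 1000.0))

    def test_threshold_invariant_under_permutation(self):
        rng = np.random.default_rng(1)
        totals = np.concatenate(
            [rng.normal(4000, 300, 300), rng.normal(60, 20, 500).clip(1)]
        ).round()
        t1, m1 = call_cells_by_rank(totals)
        perm = rng.permutation(totals.size)
        t2, m2 = call_cells_by_rank(totals[perm])
        assert t1 == t2
        assert np.array_equal(m1[perm], m2)

    def test_too_few_droplets_raises(self):
        with pytest.raises(InflectionError, match="100"):
            call_cells_by_rank(np.arange(50))


# ----------------------------------------------------------------------
# demultiplexing
# ----------------------------------------------------------------------

def _with_background(*examples):
    """3-tag matrix: a structured ambient background plus example droplets.

    Background counts span 0..15, so per-tag positivity thresholds sit at
    ~15 and the appended example droplets are evaluated against the
    documented rule thresholds.
    """
    rng = np.random.default_rng(7)
    bg = rng.integers(0, 16, size=(3, 300))
    return np.concatenate([bg, np.array(examples).T], axis=1)


class TestDemux:
    def test_dominant_tag_with_weak_runnerup_is_singlet(self):
        # 30 counts, second tag 12: >= 10 and more than double the second
        hto = _with_background((30, 12, 0))
        res = demultiplex_hashtags(hto)
        assert res.assignment[-1] == 0

    def test_below_min_counts_unassigned(self):
        hto = _with_background((9, 0, 0))
        res = demultiplex_hashtags(hto)
        assert res.assignment[-1] == res.UNASSIGNED

    def test_ratio_rule_unassigned(self):
        # 20 <= 2 x 11: fails the more-than-double requirement
        hto = _with_background((20, 11, 0))
        res = demultiplex_hashtags(hto)
        assert res.assignment[-1] == res.UNASSIGNED

    def test_two_positive_tags_is_doublet(self):
        hto = _with_background((120, 90, 0))
        res = demultiplex_hashtags(hto)
        assert res.assignment[-1] == res.DOUBLET

    def test_tie_for_maximum_unassigned(self):
        # 12 >= min_counts but the two top tags tie: never a singlet
        hto = _with_background((12, 12, 0))
        res = demultiplex_hashtags(hto)
        assert res.assignment[-1] == res.UNASSIGNED

    def test_all_zero_tag_errors(self):
        hto = _with_background((30, 2, 0))
        hto[2] = 0
        with pytest.raises(ValueError, match="hashtag 2"):
            demultiplex_hashtags(hto)

    def test_droplet_order_invariance(self):
        rng = np.random.default_rng(3)
        hto = _with_background((30, 12, 0), (500, 2, 3), (40, 400, 1))
        res = demultiplex_hashtags(hto)
        perm = rng.permutation(hto.shape[1])
        res_p = demultiplex_hashtags(hto[:, perm])
        assert np.array_equal(res.assignment[perm], res_p.assignment)

    def test_synthetic_accuracy(self, small_dataset):
        """>= 95% of true single cells get their true tag; >= 90% of
        doublets are flagged."""
        _, ds, tr = small_dataset
        mask = np.asarray(tr.droplet_class) != "empty"
        res = demultiplex_hashtags(ds.hashtag_counts[:, mask])
        sub = tr.subset(mask)
        cells = np.asarray(sub.droplet_class) == "cell"
        correct = np.mean(
            [res.assignment[i] == sub.true_hashtag[i]
             for i in np.flatnonzero(cells)]
        )
        assert correct >= 0.95
        doublets = np.asarray(sub.droplet_class) == "doublet"
        flagged = np.mean(
            [res.assignment[i] == res.DOUBLET
             for i in np.flatnonzero(doublets)]
        )
        assert flagged >= 0.90


# ----------------------------------------------------------------------
# QC filters
# ----------------------------------------------------------------------

def _qc_oracle(ds, min_rna=500, max_mito=0.10, min_tag=500, q=0.99):
    """Independent per-droplet re-check of the four exclusion rules."""
    rna = np.asarray(ds.counts.sum(axis=0)).ravel()
    mito = np.asarray(ds.counts[ds.mito_flags].sum(axis=0)).ravel()
    tags = ds.hashtag_counts.sum(axis=0) + ds.isotype_counts.sum(axis=0)
    iso = ds.isotype_counts
    top = np.argmax(iso, axis=0)
    thresholds = []
    for t in range(iso.shape[0]):
        bg = iso[t, top != t] if iso.shape[0] > 1 else iso[t]
        if bg.size == 0:
            bg = iso[t]
        thresholds.append(np.quantile(bg, q))
    keep = []
    for j in range(ds.n_droplets):
        frac = mito[j] / rna[j] if rna[j] > 0 else 0.0
        n_pos = sum(iso[t, j] > thresholds[t] for t in range(iso.shape[0]))
        bad = (
            rna[j] < min_rna
            or frac > max_mito
            or tags[j] < min_tag
            or n_pos >= 2
        )
        keep.append(not bad)
    return np.array(keep)


class TestQCFilters:
    def test_boundary_droplets(self):
        # gene 0 is mitochondrial; droplets columns:
        #  0: 499 counts -> removed (low RNA)
        #  1: 500 counts, 11% mito -> removed (high mito)
        #  2: 500 counts, exactly 10% mito -> retained
        #  3: 600 counts, low tag total -> removed (low tag)
        counts = np.array(
            [
                [0, 55, 50, 10],
                [499, 445, 450, 590],
            ]
        )
        hashtags = np.array([[600, 600, 600, 100]])
        isotypes = np.array([[2, 2, 2, 2], [1, 1, 1, 1]])
        ds = tiny_dataset(counts, mito_rows=(0,), hashtags=hashtags,
                          isotypes=isotypes)
        filtered, report = apply_qc_filters(ds)
        assert filtered.barcode_ids == ["bc2"]
        assert report.removed_low_rna == 1
        assert report.removed_high_mito == 1
        assert report.removed_low_tag == 1
        assert report.removed_isotype == 0
        assert report.droplets_out == 1

    def test_double_isotype_positive_removed(self):
        rng = np.random.default_rng(5)
        n = 200
        counts = np.vstack([np.full(n, 10), np.full(n, 990)])
        iso = rng.integers(0, 4, size=(2, n))
        iso[:, 0] = 80  # sticky droplet: both isotypes high
        ds = tiny_dataset(counts, mito_rows=(0,),
                          hashtags=np.full((1, n), 600), isotypes=iso)
        filtered, report = apply_qc_filters(ds)
        assert report.removed_isotype == 1
        assert "bc0" not in filtered.barcode_ids

    def test_matches_bruteforce_oracle(self, small_dataset):
        _, ds, _ = small_dataset
        filtered, report = apply_qc_filters(ds)
        keep = _qc_oracle(ds)
        assert set(filtered.barcode_ids) == set(
            np.asarray(ds.barcode_ids)[keep]
        )
        report.check()

    def test_retained_set_independent_of_rule_order(self, small_dataset):
        """Attribution depends on rule order; the retained set does not."""
        _, ds, _ = small_dataset
        filtered, _ = apply_qc_filters(ds)
        rna = ds.total_counts()
        mito = ds.mito_fraction()
        tags = ds.tag_totals()
        iso_pos = isotype_positivity(ds.isotype_counts).sum(axis=0)
        # apply the same four rules in reverse order
        keep = ~(
            (iso_pos >= 2) | (tags < 500) | (mito > 0.10) | (rna < 500)
        )
        assert set(filtered.barcode_ids) == set(
            np.asarray(ds.barcode_ids)[keep]
        )

    def test_missing_mito_flags_errors(self):
        ds = tiny_dataset(np.ones((3, 120), dtype=int))
        ds.mito_flags[:] = False
        with pytest.raises(ValueError, match="mito"):
            apply_qc_filters(ds)


# ----------------------------------------------------------------------
# non-T exclusion
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def lineage_setup():
    cfg = clean_sim_config(
        seed=3,
        n_cells_per_cluster=[150, 150],
        signature_names=["TCELL", "MYELOID", "B", "ILC"],
        signature_effects={0: [("TCELL", 3.0, 0.0)],
                           1: [("MYELOID", 3.0, 0.0)]},
        site_mixtures={"VV": [0.5, 0.5], "DNFB": [0.5, 0.5]},
    )
    ds, tr = generate_dataset(cfg)
    sigs = {s.name: s for s in generate_signature_library(cfg)}
    return cfg, ds, tr, sigs


class TestExcludeNonT:
    def test_lineage_cells_removed_t_cells_kept(self, lineage_setup):
        _, ds, tr, sigs = lineage_setup
        filtered, n_removed = exclude_non_t(
            ds, [sigs["MYELOID"], sigs["B"], sigs["ILC"]], sigs["TCELL"]
        )
        kept = np.isin(ds.barcode_ids, filtered.barcode_ids)
        cl = np.asarray(tr.true_cluster)
        assert (~kept)[cl == 1].mean() >= 0.95  # myeloid removed
        assert kept[cl == 0].mean() >= 0.95     # T cells kept
        assert n_removed == (~kept).sum()

    def test_empty_lineage_list_removes_nothing(self, lineage_setup):
        _, ds, _, sigs = lineage_setup
        filtered, n_removed = exclude_non_t(ds, [], sigs["TCELL"])
        assert n_removed == 0
        assert filtered.n_droplets == ds.n_droplets

    def test_full_gene_set_scores_half(self, lineage_setup):
        from trmscore.signatures import GeneSignature

        _, ds, _, _ = lineage_setup
        sig = GeneSignature("all", frozenset(ds.gene_names))
        scores = ucell_like_scores(ds, sig)
        assert np.allclose(scores, 0.5, atol=1e-12)

    def test_absent_signature_errors(self, lineage_setup):
        from trmscore.signatures import GeneSignature

        _, ds, _, sigs = lineage_setup
        ghost = GeneSignature("ghost", frozenset(["nope1", "nope2"]))
        with pytest.raises(ValueError, match="ghost"):
            exclude_non_t(ds, [ghost], sigs["TCELL"])
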