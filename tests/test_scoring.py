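"""The core statistic: z-score signature scores with randomized controls."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from trmscore.datasets import ExpressionMatrix
from trmscore.diffexpr import normalize_log
from trmscore.scoring import (
    SignatureScoreModel,
    control_score,
    dunnett_compare,
    net_score,
    pseudobulk_scores,
    score_by_group,
    score_cells,
    standardize_genes,
)
from trmscore.signatures import GeneSignature
from trmscore import generate_dataset, generate_signature_library
from trmscore.pipeline import _truth_labels

from conftest import clean_sim_config


def _expr(values, labels=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    labels = labels if labels is not None else ["all"] * n
    return ExpressionMatrix(
        values=values,
        gene_names=[f"g{i}" for i in range(values.shape[0])],
        cell_labels=pd.DataFrame({"group": labels}),
        normalization_total=1e4,
    )


def _loop_score(z, gene_names, sig):
    """Per-cell double-loop oracle for the raw signature score."""
    idx = {g: i for i, g in enumerate(gene_names)}
    up = [idx[g] for g in sorted(sig.up_genes) if g in idx]
    down = [idx[g] for g in sorted(sig.down_genes) if g in idx]
    out = np.zeros(z.shape[1])
    for c in range(z.shape[1]):
        s_up = sum(z[g, c] for g in up) / len(up)
        s_down = sum(z[g, c] for g in down) / len(down) if down else 0.0
        out[c] = s_up - s_down
    return out


class TestStandardize:
    def test_centering_and_scaling(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(2, 3, size=(50, 40)))
        z = standardize_genes(expr)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.var(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_gene_maps_to_zeros(self):
        vals = np.vstack([np.full(20, 7.0), np.arange(20.0)])
        z = standardize_genes(_expr(vals))
        assert np.all(z[0] == 0.0)

    def test_center_only_keeps_variance(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(size=(10, 30)))
        z = standardize_genes(expr, scale=False)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        assert not np.allclose(z.var(axis=1, ddof=1), 1)


class TestScoreCells:
    def test_up_equals_down_scores_zero(self):
        # identical up and down sets cancel exactly (the GeneSignature type
        # itself forbids overlap, so feed score_cells a bare stand-in)
        import types

        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(size=(30, 25)))
        z = standardize_genes(expr)
        genes = frozenset(expr.gene_names[:10])
        sig = types.SimpleNamespace(name="s", up_genes=genes,
                                    down_genes=genes, size=20)
        scores = score_cells(z, expr.gene_names, sig)
        np.testing.assert_allclose(scores, 0, atol=1e-12)

    def test_grand_mean_exactly_zero(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(60, 80)))
        z = standardize_genes(expr)
        sig = GeneSignature("s", frozenset(expr.gene_names[:15]),
                            frozenset(expr.gene_names[20:30]))
        scores = score_cells(z, expr.gene_names, sig)
        assert abs(scores.mean()) < 1e-9

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_vectorized_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(8, 30)
        n = rng.integers(3, 25)
        expr = _expr(rng.normal(size=(g, n)))
        z = standardize_genes(expr)
        names = expr.gene_names
        k_up = int(rng.integers(1, max(2, g // 2)))
        k_down = int(rng.integers(0, g // 3 + 1))
        picks = rng.permutation(g)
        sig = GeneSignature(
            "s",
            frozenset(names[i] for i in picks[:k_up]),
            frozenset(names[i] for i in picks[k_up:k_up + k_down]),
        )
        np.testing.assert_allclose(
            score_cells(z, names, sig), _loop_score(z, names, sig),
            atol=1e-9,
        )

    def test_invariant_to_gene_and_cell_permutation(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(40, 30)))
        sig = GeneSignature("s", frozenset(expr.gene_names[5:20]))
        z = standardize_genes(expr)
        base = score_cells(z, expr.gene_names, sig)
        gp = rng.permutation(40)
        cp = rng.permutation(30)
        expr_p = _expr(expr.values[np.ix_(gp, cp)])
        expr_p.gene_names = [expr.gene_names[i] for i in gp]
        z_p = standardize_genes(expr_p)
        scores_p = score_cells(z_p, expr_p.gene_names, sig)
        np.testing.assert_allclose(scores_p, base[cp], atol=1e-9)

    def test_no_up_genes_errors(self):
        expr = _expr(np.ones((5, 10)))
        sig = GeneSignature("ghost", frozenset(["zz"]))
        z = standardize_genes(expr)
        with pytest.raises(ValueError, match="no up gene"):
            score_cells(z, expr.gene_names, sig)


@pytest.fixture(scope="module")
def z_setup():
    rng = np.random.default_rng(5)
    expr = _expr(rng.normal(size=(300, 150)))
    z = standardize_genes(expr)
    sig = GeneSignature("s", frozenset(expr.gene_names[:30]),
                        frozenset(expr.gene_names[30:50]))
    return expr, z, sig


class TestControlScore:

    def test_grand_mean_within_three_se(self, z_setup):
        expr, z, sig = z_setup
        mean, draws = control_score(z, expr.gene_names, sig, n_iter=100,
                                    seed=0, return_draws=True)
        grand = mean.mean()
        se = draws.mean(axis=1).std(ddof=1) / np.sqrt(draws.shape[0])
        assert abs(grand) <= 3 * se + 1e-12

    def test_variance_shrinks_with_iterations(self, z_setup):
        """Across-seed variance of the control mean drops ~n_iter-fold."""
        expr, z, sig = z_setup
        singles = np.array([
            control_score(z, expr.gene_names, sig, n_iter=1, seed=s)[0]
            for s in range(60)
        ])
        hundreds = np.array([
            control_score(z, expr.gene_names, sig, n_iter=100, seed=s)[0]
            for s in range(60)
        ])
        ratio = singles.var() / hundreds.var()
        assert 30 < ratio < 300

    def test_seed_determinism(self, z_setup):
        expr, z, sig = z_setup
        a = control_score(z, expr.gene_names, sig, n_iter=20, seed=9)
        b = control_score(z, expr.gene_names, sig, n_iter=20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_pool_too_small_errors(self):
        expr = _expr(np.random.default_rng(0).normal(size=(10, 12)))
        z = standardize_genes(expr)
        sig = GeneSignature("s", frozenset(expr.gene_names[:8]),
                            frozenset(f"ghost{i}" for i in range(4)))
        with pytest.raises(ValueError, match="pool"):
            control_score(z, expr.gene_names, sig)


class TestNetAndGroups:
    def test_net_identities(self):
        raw = np.array([1.0, -2.0, 0.5])
        assert np.array_equal(
            net_score(raw, np.zeros(3)).net, raw
        )
        assert np.array_equal(net_score(raw, raw).net, np.zeros(3))

    def test_single_group_mean_near_zero(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.normal(size=(200, 120)))
        z = standardize_genes(expr)
        sig = GeneSignature("s", frozenset(expr.gene_names[:25]))
        raw = score_cells(z, expr.gene_names, sig)
        ctl = control_score(z, expr.gene_names, sig, n_iter=100, seed=1)
        tab = score_by_group(raw - ctl, np.array(["all"] * 120))
        row = tab.iloc[0]
        assert row["ci_lo"] <= 0 <= row["ci_hi"]

    def test_bootstrap_ci_agrees_with_t(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0.3, 1.0, 400)
        labels = np.array(["a"] * 400)
        t_tab = score_by_group(scores, labels, ci_method="t")
        b_tab = score_by_group(scores, labels, ci_method="bootstrap",
                               n_boot=2000, seed=1)
        t_half = (t_tab["ci_hi"] - t_tab["ci_lo"]).iloc[0] / 2
        b_half = (b_tab["ci_hi"] - b_tab["ci_lo"]).iloc[0] / 2
        assert abs(t_half - b_half) / t_half < 0.15

    def test_random_split_means_mutually_covered(self):
        """Halves of a null group fall inside each other's CI at the
        analytic rate.

        Each mean lies in the other's 95% CI iff |mean_a - mean_b| is
        below the CI half-width; with equal halves that event has
        probability P(|Z| < 1.98/sqrt(2)) ~ 0.84, so the observed rate
        should sit near 0.84, not near 1.
        """
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            scores = rng.normal(size=200)
            labels = np.array(["a"] * 100 + ["b"] * 100)
            rng.shuffle(labels)
            tab = score_by_group(scores, labels).set_index("group")
            a, b = tab.loc["a"], tab.loc["b"]
            if (b["ci_lo"] <= a["mean"] <= b["ci_hi"]
                    and a["ci_lo"] <= b["mean"] <= a["ci_hi"]):
                hits += 1
        rate = hits / n_rep
        assert 0.84 - 3 * np.sqrt(0.84 * 0.16 / n_rep) <= rate <= 0.95

    def test_singleton_group_errors(self):
        with pytest.raises(ValueError, match="lonely"):
            score_by_group(np.arange(4.0),
                           np.array(["a", "a", "a", "lonely"]))


class TestDunnett:
    def test_two_groups_equals_plain_t(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(size=40),
                                 rng.normal(0.4, 1, 35)])
        labels = np.array(["ref"] * 40 + ["g"] * 35)
        d = dunnett_compare(scores, labels, "ref", seed=0)
        t_p = scipy.stats.ttest_ind(scores[40:], scores[:40]).pvalue
        assert d["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=200)
        labels = np.repeat(["ref", "a", "b", "c"], 50)
        d = dunnett_compare(scores, labels, "ref", seed=0).set_index("group")
        for g in ("a", "b", "c"):
            raw_p = scipy.stats.ttest_ind(
                scores[labels == g], scores[labels == "ref"]
            ).pvalue
            assert d.loc[g, "p_adj"] >= raw_p - 1e-9

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="absent"):
            dunnett_compare(np.arange(6.0),
                            np.array(["a"] * 3 + ["b"] * 3), "zz")


class TestPseudobulk:
    def test_single_pair_errors(self):
        cfg = clean_sim_config(seed=33, n_hashtags=2,
                               n_cells_per_cluster=[80, 80],
                               signature_effects={1: [("TRM", 1.0, -1.0)]},
                               site_mixtures={"VV": [0.5, 0.5],
                                              "DNFB": [0.5, 0.5]})
        ds, tr = generate_dataset(cfg)
        sig = generate_signature_library(cfg)[0]
        with pytest.raises(ValueError, match="2 samples"):
            pseudobulk_scores(
                ds,
                np.asarray(tr.true_site),
                np.asarray(tr.true_sample),
                sig,
            )

    def test_sign_matches_per_cell_means(self):
        """Pseudobulk site contrast agrees in sign with per-cell scores."""
        agree = 0
        for seed in range(5):
            cfg = clean_sim_config(seed=40 + seed)
            ds, tr = generate_dataset(cfg)
            sig = generate_signature_library(cfg)[0]
            labels = _truth_labels(tr)
            expr = normalize_log(ds, cell_labels=labels)
            model = SignatureScoreModel(expr, sig, group_column="site")
            res = model.fit(seed=seed)
            cells = res.group_means("TRM", by="site").set_index("group")
            cell_diff = cells.loc["VV", "mean"] - cells.loc["DNFB", "mean"]
            tab, _ = pseudobulk_scores(
                ds, labels["site"].to_numpy(), labels["sample"].to_numpy(),
                sig, seed=seed,
            )
            sites = tab.groupby("site")["net"].mean()
            agree += np.sign(sites["VV"] - sites["DNFB"]) == np.sign(cell_diff)
        assert agree >= 4


class TestModelResults:
    def test_summary_lists_groups_and_net_identity(self, clean_expr):
        cfg, _, _, expr = clean_expr
        sigs = generate_signature_library(cfg)
        res = SignatureScoreModel(expr, sigs).fit(seed=2)
        text = res.summary()
        assert "TRM" in text and "95% CI" in text
        for sig in sigs:
            r = res[sig.name]
            np.testing.assert_allclose(r.net, r.raw - r.control)
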