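"""Signature scoring with size-matched randomized gene-set controls.

The statistic: genes are centered (and by default scaled to unit variance)
across all cells; a cell's *raw* score for a signature is the mean z-score
of the signature's up genes minus the mean z-score of its down genes. A
*control* score repeats the computation on randomly drawn gene sets of the
same sizes, averaged over iterations; the reported *net* score is
raw - control. Because genes are centered across all cells, the raw score
has exactly zero grand mean over cells, and the control's expectation is
zero — the net score measures enrichment relative to both the cell
population and a size-matched random program.

Group-level summaries report the mean net score with a t-based (default)
or bootstrap 95% confidence interval; clusters are compared against a
reference group with Dunnett's many-to-one procedure, and paired site
conditions with a paired t-test on pseudobulk profiles.

``SignatureScoreModel`` / ``SignatureScoreResults`` wrap these operations
in a fit/results pair; the standalone functions remain the primitive API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import DropletDataset, ExpressionMatrix
from .signatures import GeneSignature

__all__ = [
    "ScoreResult",
    "standardize_genes",
    "score_cells",
    "control_score",
    "net_score",
    "score_by_group",
    "pseudobulk_scores",
    "dunnett_compare",
    "SignatureScoreModel",
    "SignatureScoreResults",
]


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def standardize_genes(expr: ExpressionMatrix, scale: bool = True) -> np.ndarray:
    """Center each gene across all cells; optionally scale to unit variance.

    Zero-variance genes map to all-zero rows. Returns a dense genes x cells
    array.
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells to standardize")
    x = expr.values
    centered = x - x.mean(axis=1, keepdims=True)
    if not scale:
        return centered
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def _gene_indices(gene_names: list, sig: GeneSignature) -> tuple[np.ndarray, np.ndarray, int]:
    lookup = {g: i for i, g in enumerate(gene_names)}
    up = np.array(sorted(lookup[g] for g in sig.up_genes if g in lookup),
                  dtype=int)
    down = np.array(sorted(lookup[g] for g in sig.down_genes if g in lookup),
                    dtype=int)
    dropped = sig.size - up.size - down.size
    if up.size == 0:
        raise ValueError(
            f"signature {sig.name!r}: no up gene present in the matrix"
        )
    return up, down, dropped


def score_cells(
    z: np.ndarray, gene_names: list, sig: GeneSignature
) -> np.ndarray:
    """Per-cell raw score: mean up-gene z minus mean down-gene z.

    Signature genes absent from the matrix are dropped; the down term is 0
    when the down set is empty (or entirely absent).
    """
    up, down, _ = _gene_indices(gene_names, sig)
    score = z[up].mean(axis=0)
    if down.size:
        score = score - z[down].mean(axis=0)
    return score


def control_score(
    z: np.ndarray,
    gene_names: list,
    sig: GeneSignature,
    n_iter: int = 100,
    seed: int = 0,
    return_draws: bool = False,
):
    """Average score of ``n_iter`` random same-size gene sets, per cell.

    Each iteration draws |up| + |down| genes uniformly without replacement
    from all genes in the matrix and scores them exactly like the real
    signature. Returns the per-cell mean over iterations (and the
    n_iter x cells draw matrix when ``return_draws``).
    """
    n_genes = z.shape[0]
    if sig.size > n_genes:
        raise ValueError(
            f"gene pool ({n_genes}) smaller than signature size ({sig.size})"
        )
    up, down, _ = _gene_indices(gene_names, sig)
    n_up, n_down = up.size, down.size
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, z.shape[1]))
    for it in range(n_iter):
        pick = rng.choice(n_genes, size=n_up + n_down, replace=False)
        s = z[pick[:n_up]].mean(axis=0)
        if n_down:
            s = s - z[pick[n_up:]].mean(axis=0)
        draws[it] = s
    mean = draws.mean(axis=0)
    return (mean, draws) if return_draws else mean


@dataclass
class ScoreResult:
    """Per-cell raw, control and net (= raw - control) signature scores."""

    signature_name: str
    raw: np.ndarray
    control: np.ndarray
    net: np.ndarray
    n_control_iterations: int
    seed: int
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_genes_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.raw)
        if len(self.control) != n or len(self.net) != n:
            raise ValueError("raw/control/net lengths differ")
        if not np.allclose(self.net, self.raw - self.control):
            raise ValueError("net must equal raw - control elementwise")

    def group_summary(self, by: str, ci_method: str = "t",
                      n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
        labels = self.labels[by].to_numpy()
        return score_by_group(self.net, labels, ci_method=ci_method,
                              n_boot=n_boot, seed=seed)

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.copy() if len(self.labels) else pd.DataFrame(
            index=range(len(self.raw))
        )
        out["raw"] = self.raw
        out["control"] = self.control
        out["net"] = self.net
        out.insert(0, "signature", self.signature_name)
        return out


def net_score(
    raw: np.ndarray,
    control: np.ndarray,
    *,
    signature_name: str = "",
    n_control_iterations: int = 0,
    seed: int = 0,
    labels: pd.DataFrame | None = None,
) -> ScoreResult:
    """Bundle raw and control scores into a ScoreResult (net = raw - control)."""
    raw = np.asarray(raw, dtype=float)
    control = np.asarray(control, dtype=float)
    if raw.shape != control.shape:
        raise ValueError("raw and control shapes differ")
    return ScoreResult(
        signature_name=signature_name,
        raw=raw,
        control=control,
        net=raw - control,
        n_control_iterations=n_control_iterations,
        seed=seed,
        labels=labels if labels is not None else pd.DataFrame(),
    )


def score_by_group(
    scores: np.ndarray,
    labels: np.ndarray,
    *,
    ci_method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean net score with 95% CI (t-based or bootstrap).

    Every group must contain at least 2 cells.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rows = []
    rng = np.random.default_rng(seed)
    for g in pd.unique(labels):
        s = scores[labels == g]
        n = s.size
        if n < 2:
            raise ValueError(f"group {g!r} has a single cell; no CI possible")
        m = s.mean()
        if ci_method == "t":
            se = s.std(ddof=1) / np.sqrt(n)
            half = scipy.stats.t.ppf(0.975, n - 1) * se
            lo, hi = m - half, m + half
        elif ci_method == "bootstrap":
            boots = rng.choice(s, size=(n_boot, n), replace=True).mean(axis=1)
            lo, hi = np.quantile(boots, [0.025, 0.975])
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append({"group": g, "mean": m, "ci_lo": lo, "ci_hi": hi, "n": n})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# group comparisons
# ----------------------------------------------------------------------

def dunnett_compare(
    scores: np.ndarray,
    labels: np.ndarray,
    reference: str,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of each group against ``reference``.

    Adjusted p-values come from the multivariate-t distribution of the
    simultaneous t statistics (seeded quasi-Monte-Carlo integration, so the
    result is deterministic for a fixed seed).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels) if g != reference]
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} absent")
    if len(groups) < 1:
        raise ValueError("need at least one non-reference group")
    control = scores[labels == reference]
    samples = [scores[labels == g] for g in groups]
    if len(samples) == 1:
        # a single comparison needs no multiplicity adjustment; the exact
        # pooled-variance t-test avoids quasi-Monte-Carlo integration error
        t, p = scipy.stats.ttest_ind(samples[0], control, equal_var=True)
        stat, pvals = np.array([t]), np.array([p])
    else:
        res = scipy.stats.dunnett(
            *samples, control=control,
            random_state=np.random.default_rng(seed),
        )
        stat, pvals = res.statistic, res.pvalue
    return pd.DataFrame(
        {
            "group": groups,
            "statistic": stat,
            "p_adj": pvals,
            "reference": reference,
        }
    )


def pseudobulk_scores(
    data: DropletDataset | ExpressionMatrix,
    site_labels: np.ndarray,
    sample_labels: np.ndarray,
    sig: GeneSignature,
    *,
    total: float = 10_000.0,
    scale: bool = True,
    n_iter: int = 100,
    seed: int = 0,
    paired: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Score (sample, site) pseudobulk units and compare sites pairwise.

    Counts are summed within each (sample, site) unit, the unit profiles
    renormalized to ``total`` and log2(1+x)-transformed, genes centered (and
    scaled) across units, and each unit scored like a cell, with the same
    randomized control. With two sites and ``paired=True``, samples present
    at both sites are compared by a paired t-test.

    Returns ``(unit table, comparison dict)``.
    """
    site_labels = np.asarray(site_labels)
    sample_labels = np.asarray(sample_labels)
    if isinstance(data, ExpressionMatrix):
        counts = data.linear_values()
        gene_names = data.gene_names
    else:
        counts = data.counts.toarray().astype(float)
        gene_names = data.gene_names
    units = sorted(set(zip(sample_labels, site_labels)))
    sites = sorted(set(site_labels))
    for s in sites:
        if sum(1 for u in units if u[1] == s) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 samples")
    profiles = np.stack(
        [
            counts[:, (sample_labels == smp) & (site_labels == st)].sum(axis=1)
            for smp, st in units
        ],
        axis=1,
    )
    unit_tot = profiles.sum(axis=0)
    if (unit_tot == 0).any():
        raise ValueError("a pseudobulk unit has zero counts")
    logv = np.log2(1.0 + profiles * (total / unit_tot)[None, :])
    expr = ExpressionMatrix(
        values=logv,
        gene_names=list(gene_names),
        cell_labels=pd.DataFrame(
            {"sample": [u[0] for u in units], "site": [u[1] for u in units]}
        ),
        normalization_total=total,
    )
    z = standardize_genes(expr, scale=scale)
    raw = score_cells(z, gene_names, sig)
    control = control_score(z, gene_names, sig, n_iter=n_iter, seed=seed)
    table = expr.cell_labels.copy()
    table["raw"] = raw
    table["control"] = control
    table["net"] = raw - control

    comparison: dict = {"signature": sig.name, "sites": sites}
    if paired:
        if len(sites) != 2:
            raise ValueError("paired comparison needs exactly 2 sites")
        a, b = sites
        wide = table.pivot(index="sample", columns="site", values="net")
        wide = wide.dropna()
        if len(wide) < 2:
            raise ValueError(
                "paired t-test needs >= 2 samples present at both sites"
            )
        t, p = scipy.stats.ttest_rel(wide[a], wide[b])
        comparison.update(
            {
                "test": "paired_t",
                "n_pairs": int(len(wide)),
                "mean_diff": float((wide[a] - wide[b]).mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return table, comparison


# ----------------------------------------------------------------------
# model / results pair
# ----------------------------------------------------------------------

class SignatureScoreModel:
    """Signature-score analysis of a normalized expression matrix.

    Parameters
    ----------
    expr
        Normalized log-scale expression with per-cell labels.
    signatures
        One or more gene signatures to score.
    group_column
        Column of ``expr.cell_labels`` used for group summaries.
    scale
        Standardize genes to unit variance (z-scores, default) or center
        only.
    n_control
        Iterations of the randomized gene-set control.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        signatures,
        *,
        group_column: str = "cluster",
        scale: bool = True,
        n_control: int = 100,
    ) -> None:
        if isinstance(signatures, GeneSignature):
            signatures = [signatures]
        if not signatures:
            raise ValueError("no signatures given")
        self.expr = expr
        self.signatures = list(signatures)
        self.group_column = group_column
        self.scale = scale
        self.n_control = n_control

    def fit(self, seed: int = 0) -> "SignatureScoreResults":
        """Compute raw/control/net scores for every signature."""
        z = standardize_genes(self.expr, scale=self.scale)
        names = self.expr.gene_names
        results = {}
        for i, sig in enumerate(self.signatures):
            raw = score_cells(z, names, sig)
            ctl = control_score(
                z, names, sig, n_iter=self.n_control, seed=seed + i
            )
            _, _, dropped = _gene_indices(names, sig)
            res = net_score(
                raw, ctl,
                signature_name=sig.name,
                n_control_iterations=self.n_control,
                seed=seed + i,
                labels=self.expr.cell_labels,
            )
            res.n_genes_dropped = dropped
            results[sig.name] = res
        return SignatureScoreResults(self, results, seed)


class SignatureScoreResults:
    """Fitted signature scores; summaries, comparisons, plots."""

    def __init__(self, model: SignatureScoreModel, scores: dict,
                 seed: int) -> None:
        self.model = model
        self.scores = scores
        self.seed = seed

    def __getitem__(self, name: str) -> ScoreResult:
        return self.scores[name]

    def group_means(self, signature: str, by: str | None = None,
                    ci_method: str = "t") -> pd.DataFrame:
        by = by or self.model.group_column
        return self.scores[signature].group_summary(by, ci_method=ci_method)

    def dunnett(self, reference, signature: str | None = None,
                by: str | None = None) -> pd.DataFrame:
        """Dunnett comparison of every group versus ``reference``."""
        by = by or self.model.group_column
        names = [signature] if signature else list(self.scores)
        frames = []
        for nm in names:
            res = self.scores[nm]
            labels = res.labels[by].to_numpy()
            d = dunnett_compare(res.net, labels, reference, seed=self.seed)
            d.insert(0, "signature", nm)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.to_frame() for r in self.scores.values()], ignore_index=True
        )

    def summary(self, by: str | None = None) -> str:
        """Plain-text summary: per-signature group means with 95% CIs."""
        by = by or self.model.group_column
        lines = [
            "Signature score results",
            f"  cells: {self.model.expr.n_cells}   genes: "
            f"{self.model.expr.n_genes}",
            f"  control iterations: {self.model.n_control}   seed: "
            f"{self.seed}   scaled: {self.model.scale}",
            "",
        ]
        for nm, res in self.scores.items():
            lines.append(f"[{nm}] (dropped genes: {res.n_genes_dropped})")
            tab = res.group_summary(by)
            for g, m, lo, hi, n in zip(tab["group"], tab["mean"],
                                       tab["ci_lo"], tab["ci_hi"],
                                       tab["n"]):
                lines.append(
                    f"  {str(g):>12}  mean {m:+.4f}  "
                    f"95% CI [{lo:+.4f}, {hi:+.4f}]  n={int(n)}"
                )
            lines.append("")
        return "\n".join(lines)

    def plot(self, signature: str, by: str | None = None, ax=None):
        """Group means with 95% CI error bars (requires matplotlib)."""
        import matplotlib.pyplot as plt

        by = by or self.model.group_column
        tab = self.group_means(signature, by)
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(tab))
        ax.errorbar(
            x, tab["mean"],
            yerr=[tab["mean"] - tab["ci_lo"], tab["ci_hi"] - tab["mean"]],
            fmt="o", capsize=3,
        )
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xticks(x, [str(g) for g in tab["group"]])
        ax.set_ylabel(f"net {signature} score")
        ax.set_xlabel(by)
        return ax
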