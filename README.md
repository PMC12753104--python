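# trmscore

Signature-score analysis for hashed-droplet single-cell RNA-seq of skin
CD8 tissue-resident memory T cells (T_RM), with a fully seeded synthetic
data generator so every stage is testable offline.

## Who this is for

Skin T_RM that encounter their cognate antigen in the epidermis during
development become transcriptionally more fully differentiated than
"bystander" T_RM recruited to an inflamed site without antigen. Showing
this from a pooled, cell-hashed droplet experiment takes a chain of steps:
call cells from the barcode-rank curve, demultiplex hashtag oligos back to
mouse-and-flank samples, remove low-quality droplets, compute differential
expression against a naive reference, and finally score each cell against
published T-cell state gene programs — per cluster, per site as
pseudobulk, and against an ordered differentiation time-course. `trmscore`
implements that chain as a library with a thin CLI, and ships a simulator
that plants known cluster programs, site mixtures and droplet artifacts so
every claim the pipeline makes can be checked against ground truth.

## The statistic

Expression is normalized to a fixed per-cell total and log-transformed,
`x = log2(1 + count · 10⁴ / cell_total)`, then standardized per gene
across all cells to z-scores `z_g` (centering-only is a flag). For a
signature with up-gene set *U* and down-gene set *D*, the raw score of
cell *c* is

```
raw(c) = mean_{g∈U} z_g(c) − mean_{g∈D} z_g(c)
```

A size-matched control repeats the computation on `n_iter = 100` random
gene sets of the same sizes (drawn uniformly without replacement, seeded)
and the reported **net score** is `raw − control`. Because genes are
centered across all cells, the raw score has exactly zero grand mean and
the control's expectation is zero: a group's mean net score measures
enrichment relative to both the cell population and a random program of
equal size. Groups are summarized as mean with 95% t-based (or bootstrap)
confidence intervals; clusters are compared to the naive reference with
Dunnett's many-to-one procedure, paired flank sites with a paired t-test
on pseudobulk profiles, and differentiation state by scoring against
per-timepoint top-k DE gene sets of a time-course reference.

## Worked example

```python
import numpy as np
import trmscore as tm
from trmscore.pipeline import _truth_labels

cfg = tm.SimConfig(seed=7)                       # 5 clusters x 500 cells,
dataset, truth = tm.generate_dataset(cfg)        # doublets, empties, ...

thr, cells = tm.call_cells_by_rank(dataset.total_counts())
called, truth = dataset.subset(cells), truth.subset(cells)

demux = tm.demultiplex_hashtags(called.hashtag_counts)
singlets = called.subset(demux.singlet_mask)
truth = truth.subset(demux.singlet_mask)

filtered, report = tm.apply_qc_filters(singlets)
keep = np.isin(singlets.barcode_ids, filtered.barcode_ids)
truth = truth.subset(keep)

expr = tm.normalize_log(filtered, cell_labels=_truth_labels(truth))
sigs = tm.generate_signature_library(cfg)
results = tm.SignatureScoreModel(expr, sigs, group_column="cluster").fit(seed=7)
print(results.summary())
print(results.dunnett(0, signature="TRM").to_string(index=False))
```

prints (abridged):

```
cell-calling threshold: 618 counts; 2500/4500 droplets called
{'n_droplets': 2500, 'n_singlet': 2359, 'n_doublet': 141, 'n_unassigned': 0, ...}
{'droplets_in': 2359, 'removed_low_rna': 0, 'removed_high_mito': 115,
 'removed_low_tag': 2, 'removed_isotype': 19, 'droplets_out': 2223}

Signature score results
  cells: 2223   genes: 2000
  control iterations: 100   seed: 7   scaled: True

[TRM] (dropped genes: 0)
             0  mean -0.2133  95% CI [-0.2314, -0.1952]  n=452
             4  mean -0.2128  95% CI [-0.2325, -0.1932]  n=438
             1  mean -0.2147  95% CI [-0.2323, -0.1970]  n=447
             2  mean -0.2151  95% CI [-0.2343, -0.1959]  n=433
             3  mean +0.8361  95% CI [+0.8185, +0.8537]  n=453

signature  group  statistic    p_adj  reference
      TRM      4   0.032703 0.999999          0
      TRM      1  -0.106433 0.999909          0
      TRM      2  -0.138955 0.999738          0
      TRM      3  79.829117 0.000000          0
```

Reading the output: the barcode-rank inflection recovered all 2,500
cell-containing droplets and no empties; demultiplexing flagged 141
hashtag doublets; QC removed the 115 dying (high-mitochondrial) cells and
19 antibody-sticky droplets. Cluster 3 — the cluster simulated with the
tissue-residency program — has a strongly positive net T_RM score while
all other clusters sit slightly negative (scores are relative to the
all-cell mean), and Dunnett's test rejects cluster 3 against the naive
reference (cluster 0) while no other cluster approaches significance.

The same stages are available from the shell:

```bash
trmscore simulate --seed 7 --outdir run/raw
trmscore qc --counts run/raw --outdir run/qc
trmscore score --counts run/qc/filtered --signatures run/raw/signatures.gmt \
               --reference-group 0 --n-iter 100 --seed 7 --out run/scores.tsv
trmscore run --seed 7 --outdir run/full   # whole pipeline, one manifest
```

All file formats are plain text: Matrix Market bundles for counts, GMT
for gene sets (paired `NAME_up` / `NAME_down` lines, time-course days
encoded as `TRM_d05`), TSV/JSON for results, YAML for run configs.

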