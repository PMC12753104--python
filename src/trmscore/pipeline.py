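"""One-command orchestration: simulate -> QC -> DE -> score -> trajectory.

A run is fully specified by a :class:`RunConfig` (YAML-serializable); its
single seed drives every random draw. Each stage writes flat-file outputs
(MTX/TSV/GMT/JSON) into the run directory, and a manifest records resolved
parameters, output hashes and library versions, so a rerun with the same
config and seed reproduces every numeric output bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import DropletDataset
from .diffexpr import differential_genes, normalize_log, top_de_geneset
from .io import (
    read_mtx_bundle,
    write_gmt,
    write_mtx_bundle,
    write_timecourse_gmt,
)
from .qc import apply_qc_filters, call_cells_by_rank, demultiplex_hashtags
from .scoring import SignatureScoreModel, pseudobulk_scores
from .synthetic import (
    GroundTruth,
    SimConfig,
    generate_dataset,
    generate_signature_library,
    generate_timecourse_populations,
)
from .trajectory import TrajectoryModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending entity."""


def _listify(obj):
    """Canonical YAML-safe form: tuples -> lists, numpy -> python scalars."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "trmscore_run"
    # stage toggles
    simulate: bool = True
    qc: bool = True
    de: bool = True
    score: bool = True
    trajectory: bool = True
    # inputs when simulation is off
    input_bundle: str | None = None
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)
    # qc stage
    min_rna: int = 500
    max_mito: float = 0.10
    min_tag: int = 500
    demux_min_counts: int = 10
    demux_ratio: float = 2.0
    positivity_quantile: float = 0.99
    # de stage
    de_top_k: int = 100
    reference_cluster: int = 0
    # score / trajectory stages
    n_control_iterations: int = 100
    scale_genes: bool = True
    n_timepoints: int = 6
    trajectory_top_k: int = 100
    late_window: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "signature_effects" in sim:
                sim["signature_effects"] = {
                    int(k): [tuple(e) for e in v] if v and isinstance(
                        v[0], (list, tuple)
                    ) else tuple(v)
                    for k, v in sim["signature_effects"].items()
                }
            if "dying_mito_range" in sim:
                sim["dying_mito_range"] = tuple(sim["dying_mito_range"])
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _truth_labels(truth: GroundTruth) -> pd.DataFrame:
    """Per-droplet cluster/site/sample labels (primary cell of doublets)."""
    prim = [
        c[0] if isinstance(c, tuple) else c for c in truth.true_cluster
    ]
    return pd.DataFrame(
        {
            "cluster": prim,
            "site": truth.true_site,
            "sample": truth.true_sample,
        }
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    rundir = Path(config.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yaml")
    notes: dict = {}

    sim = dataclasses.replace(config.sim, seed=config.seed)

    # --- simulate -------------------------------------------------------
    stage = "simulate"
    truth: GroundTruth | None = None
    try:
        if config.simulate:
            dataset, truth = generate_dataset(sim)
            write_mtx_bundle(dataset, rundir / "raw")
            truth.to_frame().to_csv(
                rundir / "raw" / "ground_truth.tsv", sep="\t", index=False
            )
            write_gmt(
                generate_signature_library(sim),
                rundir / "signatures.gmt",
            )
        elif config.input_bundle:
            dataset = read_mtx_bundle(config.input_bundle)
        else:
            raise ValueError(
                "simulation disabled and no input_bundle given"
            )
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    labels = (
        _truth_labels(truth)
        if truth is not None
        else dataset.droplet_meta.reset_index(drop=True)
    )

    # --- qc -------------------------------------------------------------
    stage = "qc"
    keep_truth = truth
    try:
        if config.qc:
            threshold, cell_mask = call_cells_by_rank(dataset.total_counts())
            called = dataset.subset(cell_mask)
            labels = labels.loc[cell_mask].reset_index(drop=True)
            if keep_truth is not None:
                keep_truth = keep_truth.subset(cell_mask)

            demux = demultiplex_hashtags(
                called.hashtag_counts,
                min_counts=config.demux_min_counts,
                ratio=config.demux_ratio,
                positivity_quantile=config.positivity_quantile,
            )
            pd.DataFrame(
                {
                    "barcode": called.barcode_ids,
                    "assignment": demux.labels(),
                    "tag": demux.assignment,
                    "max_tag_count": demux.max_tag_count,
                    "second_tag_count": demux.second_tag_count,
                }
            ).to_csv(rundir / "demux.tsv", sep="\t", index=False)
            singlets = demux.singlet_mask
            called = called.subset(singlets)
            labels = labels.loc[singlets].reset_index(drop=True)
            if keep_truth is not None:
                keep_truth = keep_truth.subset(singlets)

            filtered, report = apply_qc_filters(
                called,
                min_rna=config.min_rna,
                max_mito=config.max_mito,
                min_tag=config.min_tag,
                isotype_positivity_quantile=config.positivity_quantile,
            )
            keep = np.isin(called.barcode_ids, filtered.barcode_ids)
            labels = labels.loc[keep].reset_index(drop=True)
            if keep_truth is not None:
                keep_truth = keep_truth.subset(keep)
            dataset = filtered
            _write_json(
                {
                    "cell_calling_threshold": int(threshold),
                    "demux": demux.summary(),
                    "qc": report.to_dict(),
                },
                rundir / "qc_report.json",
            )
        labels.assign(barcode=dataset.barcode_ids).to_csv(
            rundir / "cells.tsv", sep="\t", index=False
        )
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    if not (config.de or config.score or config.trajectory):
        _finalize(rundir, notes)
        return rundir

    # --- normalization shared by de/score/trajectory ---------------------
    stage = "normalize"
    try:
        expr = normalize_log(dataset, cell_labels=labels)
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    clusters = sorted(set(labels["cluster"])) if "cluster" in labels else []
    ref_cluster = config.reference_cluster

    # --- differential expression -----------------------------------------
    stage = "de"
    try:
        if config.de:
            if ref_cluster not in clusters:
                raise ValueError(
                    f"reference cluster {ref_cluster} absent after QC"
                )
            de_dir = rundir / "de"
            de_dir.mkdir(exist_ok=True)
            top_sets = []
            for c in clusters:
                if c == ref_cluster:
                    continue
                n_c = int((labels["cluster"] == c).sum())
                if n_c < 3:
                    notes[f"de_skipped_cluster_{c}"] = n_c
                    continue
                table = differential_genes(
                    expr, c, ref_cluster, label_column="cluster"
                )
                table.table.to_csv(
                    de_dir / f"cluster{c}_vs_{ref_cluster}.tsv",
                    sep="\t", index=False,
                )
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    top_sets.append(
                        top_de_geneset(
                            table, k=config.de_top_k, direction="up",
                            name=f"cluster{c}_top{config.de_top_k}",
                        )
                    )
            write_gmt(top_sets, de_dir / "top_genes.gmt")
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    # --- signature scores -------------------------------------------------
    stage = "score"
    try:
        if config.score:
            sigs = generate_signature_library(sim)
            model = SignatureScoreModel(
                expr, sigs,
                group_column="cluster",
                scale=config.scale_genes,
                n_control=config.n_control_iterations,
            )
            results = model.fit(seed=config.seed)
            results.to_frame().to_csv(
                rundir / "scores.tsv", sep="\t", index=False
            )
            summary: dict = {}
            for sig in sigs:
                entry: dict = {
                    "groups": _listify(
                        results.group_means(sig.name).to_dict("records")
                    )
                }
                if ref_cluster in clusters and len(clusters) >= 2:
                    entry["dunnett"] = _listify(
                        results.dunnett(
                            ref_cluster, signature=sig.name
                        ).to_dict("records")
                    )
                sites = labels["site"].replace("", np.nan).dropna()
                if sites.nunique() == 2:
                    mask = (labels["site"] != "").to_numpy()
                    try:
                        _, comp = pseudobulk_scores(
                            expr_subset(expr, mask),
                            labels.loc[mask, "site"].to_numpy(),
                            labels.loc[mask, "sample"].to_numpy(),
                            sig,
                            scale=config.scale_genes,
                            n_iter=config.n_control_iterations,
                            seed=config.seed,
                        )
                        entry["pseudobulk"] = comp
                    except ValueError as err:
                        entry["pseudobulk_skipped"] = str(err)
                summary[sig.name] = entry
            _write_json(summary, rundir / "score_summary.json")
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    # --- trajectory --------------------------------------------------------
    stage = "trajectory"
    try:
        if config.trajectory:
            _, ref = generate_timecourse_populations(
                sim, config.n_timepoints, k=config.trajectory_top_k
            )
            write_timecourse_gmt(ref, rundir / "timecourse.gmt")
            model = TrajectoryModel(
                expr, ref,
                group_column="cluster",
                scale=config.scale_genes,
                n_control=config.n_control_iterations,
                late_window=config.late_window,
            )
            result = model.fit(seed=config.seed)
            result.table.to_csv(
                rundir / "trajectory.tsv", sep="\t", index=False
            )
            _write_json(
                {
                    "late_window": result.late_window,
                    "slopes": {
                        str(g): result.late_window_slope(g)
                        for g in result.groups
                    },
                },
                rundir / "trajectory_summary.json",
            )
    except Exception as err:
        raise PipelineError(f"stage {stage}: {err}") from err

    _finalize(rundir, notes)
    return rundir


def expr_subset(expr, mask: np.ndarray):
    """Column-subset of an ExpressionMatrix."""
    from .datasets import ExpressionMatrix

    idx = np.flatnonzero(np.asarray(mask))
    return ExpressionMatrix(
        values=expr.values[:, idx],
        gene_names=list(expr.gene_names),
        cell_labels=expr.cell_labels.iloc[idx].reset_index(drop=True),
        normalization_total=expr.normalization_total,
    )


def _finalize(rundir: Path, notes: dict) -> None:
    files = sorted(
        p for p in rundir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "trmscore_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "outputs": {
            str(p.relative_to(rundir)): _sha256(p) for p in files
        },
        "notes": notes,
    }
    _write_json(manifest, rundir / "manifest.json")
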