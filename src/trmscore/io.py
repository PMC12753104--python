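"""Flat-file formats: Matrix Market count bundles, GMT gene sets, TSV tables.

A *bundle* is a directory holding the three count matrices of a
hashed-droplet experiment in Matrix Market coordinate format (1-based
indices, integer values) plus companion TSVs for genes (id, name, mito
flag) and barcodes. GMT files carry one gene set per line (name,
description, then member genes, tab-separated); a signature's up and down
sets are stored as paired ``NAME_up`` / ``NAME_down`` lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import DropletDataset
from .signatures import GeneSignature, TimecourseReference

__all__ = [
    "write_mtx_bundle",
    "read_mtx_bundle",
    "write_gmt",
    "read_gmt",
    "write_timecourse_gmt",
    "read_timecourse_gmt",
]

_COUNTS = "counts.mtx"
_HASHTAGS = "hashtags.mtx"
_ISOTYPES = "isotypes.mtx"
_GENES = "genes.tsv"
_BARCODES = "barcodes.tsv"
_META = "droplet_meta.tsv"


def write_mtx_bundle(dataset: DropletDataset, path) -> Path:
    """Write a dataset as an MTX + TSV directory bundle; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / _COUNTS, sp.coo_matrix(dataset.counts))
    scipy.io.mmwrite(
        path / _HASHTAGS, sp.coo_matrix(dataset.hashtag_counts)
    )
    scipy.io.mmwrite(
        path / _ISOTYPES, sp.coo_matrix(dataset.isotype_counts)
    )
    genes = pd.DataFrame(
        {
            "gene_id": dataset.gene_names,
            "gene_name": dataset.gene_names,
            "mito": dataset.mito_flags.astype(int),
        }
    )
    genes.to_csv(path / _GENES, sep="\t", index=False)
    pd.DataFrame({"barcode": dataset.barcode_ids}).to_csv(
        path / _BARCODES, sep="\t", index=False
    )
    if len(dataset.droplet_meta.columns):
        dataset.droplet_meta.to_csv(path / _META, sep="\t", index=False)
    return path


def read_mtx_bundle(path) -> DropletDataset:
    """Read a bundle written by :func:`write_mtx_bundle`."""
    path = Path(path)
    for fname in (_COUNTS, _HASHTAGS, _ISOTYPES, _GENES, _BARCODES):
        if not (path / fname).exists():
            raise FileNotFoundError(f"bundle is missing {fname} in {path}")
    counts = sp.csr_matrix(scipy.io.mmread(path / _COUNTS)).astype(np.int64)
    hto = np.asarray(
        scipy.io.mmread(path / _HASHTAGS).todense()  # type: ignore[union-attr]
    ).astype(np.int64)
    iso = np.asarray(
        scipy.io.mmread(path / _ISOTYPES).todense()  # type: ignore[union-attr]
    ).astype(np.int64)
    genes = pd.read_csv(path / _GENES, sep="\t")
    barcodes = pd.read_csv(path / _BARCODES, sep="\t")
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"counts has {counts.shape[0]} rows but genes.tsv lists "
            f"{len(genes)} genes"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"counts has {counts.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} barcodes"
        )
    meta_path = path / _META
    meta = (
        pd.read_csv(meta_path, sep="\t")
        if meta_path.exists()
        else pd.DataFrame()
    )
    return DropletDataset(
        counts=counts,
        hashtag_counts=hto,
        isotype_counts=iso,
        gene_names=genes["gene_name"].astype(str).tolist(),
        mito_flags=genes["mito"].to_numpy().astype(bool),
        barcode_ids=barcodes["barcode"].astype(str).tolist(),
        droplet_meta=meta,
    )


# ----------------------------------------------------------------------
# GMT
# ----------------------------------------------------------------------

def write_gmt(signatures: list[GeneSignature], path,
              description: str = "trmscore") -> Path:
    """Write signatures as paired ``NAME_up`` / ``NAME_down`` GMT lines.

    Genes are written sorted, so equal signatures produce identical files.
    """
    path = Path(path)
    with path.open("w") as fh:
        for sig in signatures:
            fh.write(
                "\t".join([f"{sig.name}_up", description,
                           *sorted(sig.up_genes)]) + "\n"
            )
            if sig.down_genes:
                fh.write(
                    "\t".join([f"{sig.name}_down", description,
                               *sorted(sig.down_genes)]) + "\n"
                )
    return path


def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT file, pairing ``NAME_up`` / ``NAME_down`` lines.

    Lines whose set name carries neither suffix become up-only signatures.
    Malformed lines (fewer than 3 tab-separated fields) raise with the
    line number.
    """
    path = Path(path)
    ups: dict[str, frozenset] = {}
    downs: dict[str, frozenset] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(needs name, description and >= 1 gene)"
                )
            raw_name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set is empty")
            if raw_name.endswith("_up"):
                name, bucket = raw_name[:-3], ups
            elif raw_name.endswith("_down"):
                name, bucket = raw_name[:-5], downs
            else:
                name, bucket = raw_name, ups
            if name in bucket:
                raise ValueError(
                    f"{path}:{lineno}: duplicate set for {name!r}"
                )
            bucket[name] = genes
            if name not in order:
                order.append(name)
    out = []
    for name in order:
        if name not in ups:
            raise ValueError(
                f"{path}: {name!r} has a down set but no up set"
            )
        out.append(
            GeneSignature(name, ups[name], downs.get(name, frozenset()))
        )
    return out


def write_timecourse_gmt(ref: TimecourseReference, path) -> Path:
    """Write a time-course reference; the day is encoded in the set name
    (``TRM_d05_up``), so ordering survives the round trip."""
    return write_gmt(list(ref.signatures), path, description="timecourse")


def read_timecourse_gmt(path) -> TimecourseReference:
    """Read a reference written by :func:`write_timecourse_gmt`.

    The numeric day is parsed from the trailing ``_d<day>`` of each set
    name; signatures are ordered by day.
    """
    sigs = read_gmt(path)
    days = []
    for sig in sigs:
        tail = sig.name.rsplit("_d", 1)
        if len(tail) != 2:
            raise ValueError(
                f"set name {sig.name!r} does not encode a day (NAME_d<day>)"
            )
        try:
            days.append(float(tail[1]))
        except ValueError as err:
            raise ValueError(
                f"set name {sig.name!r}: day {tail[1]!r} is not numeric"
            ) from err
    order = np.argsort(days)
    return TimecourseReference(
        days=[days[i] for i in order],
        signatures=[sigs[i] for i in order],
    )
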