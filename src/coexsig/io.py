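"""Readers and writers for the pipeline's plain-text formats.

Counts TSV: header row of sample ids, first column gene ids, integer
cells.  Gene annotation TSV: gene_id, length_bp, gc_frac, chrom.  Sample
metadata TSV: sample_id, family_id, status, sex, batch.  All UTF-8,
tab-separated, one record per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .simulate import SimulationTruth


class ParseError(ValueError):
    pass


def read_counts_tsv(path) -> pd.DataFrame:
    """Integer genes × samples matrix; duplicate gene ids are rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids in {path}: {dupes[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr.astype(float)).all():
        bad = df.columns[[not np.issubdtype(df[c].dtype, np.number) for c in df.columns]]
        raise ParseError(f"non-numeric cells in {path} (columns {list(bad)[:5]})")
    if not np.allclose(arr.astype(float), np.round(arr.astype(float))):
        rows, cols = np.nonzero(~np.isclose(arr.astype(float), np.round(arr.astype(float))))
        raise ParseError(
            f"non-integer count at gene {df.index[rows[0]]!r}, sample {df.columns[cols[0]]!r}"
        )
    return df.astype(np.int64)


def read_gene_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        raise ParseError(f"duplicate gene ids in {path}")
    return df[["length_bp", "gc_frac", "chrom"]]


def read_sample_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        raise ParseError(f"duplicate sample ids in {path}")
    return df[["family_id", "status", "sex", "batch"]]


def read_dataset(counts_path, annotation_path, metadata_path) -> ExpressionDataset:
    counts = read_counts_tsv(counts_path)
    genes = read_gene_annotation_tsv(annotation_path)
    samples = read_sample_metadata_tsv(metadata_path)
    return ExpressionDataset(
        values=counts, genes=genes.loc[counts.index], samples=samples.loc[counts.columns]
    )


def write_dataset(ds: ExpressionDataset, outdir, prefix: str = "") -> dict:
    """Write counts/annotation/metadata TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "annotation": outdir / f"{prefix}gene_annotation.tsv",
        "metadata": outdir / f"{prefix}sample_metadata.tsv",
    }
    ds.values.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    ds.genes.rename_axis("gene_id").to_csv(paths["annotation"], sep="\t")
    ds.samples.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
    return paths


def write_truth_json(truth: SimulationTruth, path) -> None:
    payload = {
        "gene_modules": {g: int(m) for g, m in truth.gene_modules.items()},
        "loadings": {g: float(a) for g, a in truth.loadings.items()},
        "eigengenes": {
            str(m): truth.eigengenes[m].round(8).tolist() for m in truth.eigengenes.columns
        },
        "samples": list(truth.eigengenes.index),
        "disease_modules": list(truth.disease_modules),
        "families": {s: f for s, f in truth.families.items()},
        "seed": truth.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
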