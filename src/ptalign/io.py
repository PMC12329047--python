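"""Readers and writers for the matrix, table, and bundle formats.

Count matrices are accepted either as a CellRanger-style directory
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``, genes in rows) or as
a dense TSV/CSV of cells x genes with cell ids in the first column.  The
trained reference is persisted as a single joblib archive carrying the
binned reference, gene set, perceptron, and provenance metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import scipy.io as sio

from .align import PseudotimePredictor
from .matrix import ExpressionMatrix
from .reference import BinnedReference, StageBoundaries, TrajectoryGeneSet

__all__ = [
    "read_matrix",
    "read_pseudotime",
    "read_gene_list",
    "read_trajectory_genes",
    "write_trajectory_genes",
    "write_alignment",
    "save_bundle",
    "load_bundle",
]


def read_matrix(path) -> ExpressionMatrix:
    """Read counts from an MTX directory or a dense cells-x-genes TSV/CSV."""
    path = Path(path)
    if path.is_dir():
        mtx = sio.mmread(path / "matrix.mtx").tocsr()  # genes x cells, CellRanger dialect
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        gene_col = 1 if feats.shape[1] > 1 else 0
        return ExpressionMatrix(
            cell_ids=barcodes.to_numpy(dtype=object),
            gene_ids=feats[gene_col].to_numpy(dtype=object),
            counts=mtx.T,
        )
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        cell_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
        counts=df.to_numpy(),
    )


def write_matrix_mtx(matrix: ExpressionMatrix, outdir) -> None:
    """Write counts as an MTX directory (genes x cells, CellRanger dialect)."""
    import scipy.sparse as sp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(matrix.counts.T))
    pd.Series(matrix.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"id": matrix.gene_ids, "name": matrix.gene_ids}).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )


def read_pseudotime(path) -> pd.Series:
    """TSV of (cell_id, pseudotime); returns a Series indexed by cell id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("pseudotime table needs (cell_id, pseudotime) columns")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def read_gene_list(path) -> list:
    """Plain-text gene list, one symbol per line."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_trajectory_genes(path) -> TrajectoryGeneSet:
    df = pd.read_csv(path, sep="\t")
    return TrajectoryGeneSet(
        genes=df["gene"].to_numpy(dtype=object),
        stage=df["stage"].to_numpy(dtype=object),
        importance=df["importance"].to_numpy(dtype=float) if "importance" in df else None,
    )


def write_trajectory_genes(genes: TrajectoryGeneSet, path) -> None:
    pd.DataFrame(
        {
            "gene": genes.genes,
            "stage": genes.stage,
            "importance": genes.importance if genes.importance is not None else np.nan,
        }
    ).to_csv(path, sep="\t", index=False)


def write_alignment(result, out_tsv, composition_json=None, include_cycling=True) -> None:
    """Per-cell alignment TSV plus optional composition JSON."""
    from .align import stage_composition

    pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "aligned_pseudotime": result.pseudotime,
            "stage": [s if s is not None else "" for s in result.stage],
            "status": result.status,
        }
    ).to_csv(out_tsv, sep="\t", index=False)
    if composition_json is not None:
        comp = stage_composition(result, include_cycling=include_cycling)
        keys = ["Q", "A", "D"] + (["cycling"] if include_cycling else [])
        Path(composition_json).write_text(
            json.dumps(dict(zip(keys, map(float, comp))), indent=2) + "\n"
        )


def save_bundle(
    path,
    binned: BinnedReference,
    genes: TrajectoryGeneSet,
    model: PseudotimePredictor,
    reference=None,
    boundaries: StageBoundaries | None = None,
    meta: dict | None = None,
) -> None:
    """Persist the trained reference as one portable joblib archive.

    ``reference`` (the full ReferenceLineage) is optional but required later
    for permutation QC, which rebinds permuted gene sets on the reference.
    """
    joblib.dump(
        {
            "binned": binned,
            "genes": genes,
            "model": model,
            "reference": reference,
            "boundaries": boundaries or StageBoundaries(),
            "meta": {
                "n_bins": binned.n_bins,
                "n_genes": len(genes),
                "seed": model.seed,
                "best_params": model.best_params,
                **(meta or {}),
            },
        },
        path,
    )


def load_bundle(path) -> dict:
    return joblib.load(path)
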