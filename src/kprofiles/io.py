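"""Reading and writing expression matrices and clustering results.

The interchange format is plain TSV: header row of sample IDs, first
column of gene IDs, numeric body, UTF-8, '\\n' line endings, '.' decimal.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusteringResult, cluster_score
from .matrix import ExpressionMatrix
from .simdata import SimulatedDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_dataset",
    "write_result",
]


def read_matrix(path: str | os.PathLike, standardize: bool = True) -> ExpressionMatrix:
    """Read a genes x samples TSV; optionally row-standardize.

    Raises a descriptive error for missing or non-numeric cells, duplicate
    identifiers, or fewer than three sample columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 sample columns, found {df.shape[1]}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    matrix = ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        tuple(str(g) for g in df.index),
        tuple(str(s) for s in df.columns),
    )
    return matrix.standardized() if standardize else matrix


def write_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a matrix in the TSV dialect read_matrix accepts."""
    df = pd.DataFrame(
        matrix.values, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)
    )
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g", lineterminator="\n")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (gene_id, true_label) TSV as a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "true_label": int})
    return df.set_index("gene_id")["true_label"]


def write_dataset(
    dataset: SimulatedDataset,
    matrix_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> None:
    """Write a simulated dataset: expression TSV plus a gene/label TSV."""
    write_matrix(dataset.matrix, matrix_path)
    pd.DataFrame(
        {"gene_id": list(dataset.matrix.gene_ids), "true_label": dataset.labels}
    ).to_csv(labels_path, sep="\t", index=False, lineterminator="\n")


def write_result(
    result: ClusteringResult,
    matrix: ExpressionMatrix,
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Write assignments, profiles and a run summary under ``outdir``.

    Returns the paths written: ``assignments.tsv`` (gene_id, cluster,
    p_value; cluster 0 = unassigned), ``profiles.tsv`` (one line per
    cluster: cluster index then the ordered sample IDs) and ``summary.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": outdir / "assignments.tsv",
        "profiles": outdir / "profiles.tsv",
        "summary": outdir / "summary.txt",
    }
    with open(paths["assignments"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tcluster\tp_value\n")
        for gid, cl, p in zip(matrix.gene_ids, result.assignment, result.p_values):
            fh.write(f"{gid}\t{cl}\t{p:.6g}\n")
    with open(paths["profiles"], "w", encoding="utf-8", newline="\n") as fh:
        for k, prof in enumerate(result.profiles, start=1):
            ordered = "\t".join(matrix.sample_ids[j] for j in prof.order)
            fh.write(f"{k}\t{ordered}\n")
    with open(paths["summary"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"K\t{len(result.profiles)}\n")
        fh.write(f"n_iterations\t{result.n_iterations}\n")
        fh.write(f"converged\t{result.converged}\n")
        fh.write(f"n_assigned\t{int((result.assignment > 0).sum())}\n")
        fh.write(f"score\t{cluster_score(result):.6g}\n")
    return paths
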