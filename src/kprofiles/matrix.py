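"""Expression-matrix container.

The package works on a genes x samples matrix: rows are genes (features),
columns are samples.  Values are expression levels in arbitrary units;
clustering operates on row-standardized values so that the Euclidean
sample-sample distances and DCOL magnitudes are comparable across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ExpressionMatrix", "standardize_rows"]


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center each row to mean 0 and scale to sd 1.

    Rows with zero variance (flat probes) are centered only, yielding an
    all-zero row instead of NaNs, so degenerate genes survive loading and
    are later handled by the sigma=0 p-value policy.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (values - mean) / sd


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix with row/column identifiers.

    Parameters
    ----------
    values
        2-D float array, one row per gene, one column per sample.
        Missing values are disallowed.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        p, n = values.shape
        if p < 1:
            raise ValueError("matrix must contain at least one gene row")
        if n < 2:
            raise ValueError("matrix must contain at least two sample columns")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "ExpressionMatrix":
        """Return a copy with every gene row scaled to mean 0, sd 1."""
        return ExpressionMatrix(
            standardize_rows(self.values), self.gene_ids, self.sample_ids
        )

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Build a matrix, autogenerating ``gene_i`` / ``sample_j`` ids."""
        values = np.asarray(values, dtype=float)
        p, n = values.shape
        if gene_ids is None:
            gene_ids = [f"gene_{i + 1}" for i in range(p)]
        if sample_ids is None:
            sample_ids = [f"sample_{j + 1}" for j in range(n)]
        return cls(values, tuple(gene_ids), tuple(sample_ids))
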