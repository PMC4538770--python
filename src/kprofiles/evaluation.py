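"""Scoring clusterings against ground truth and benchmarking.

Provides a pair-counting Adjusted Rand Index, a confusion matrix laid out
with the unassigned/noise groups first, and a benchmark harness that races
K-profiles against a plain k-means baseline on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import KMeans

from .cluster import KProfilesConfig, fit
from .simdata import SimulationSpec, simulate

__all__ = [
    "ConfusionMatrix",
    "adjusted_rand_index",
    "confusion_matrix",
    "run_benchmark",
    "plot_benchmark",
]


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Hubert–Arabie adjusted Rand index between two label vectors.

    Computed from the pair-count contingency table; 1 iff the partitions
    are identical up to relabeling, ~0 for random agreement.  Degenerate
    pairs of partitions (both trivial) score 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    index = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((index - expected) / (max_index - expected))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Reported-vs-true cross-tabulation.

    Rows are reported clusters with the unassigned group (label 0) first;
    columns are true clusters with the pure-noise group (label 0) first.
    """

    counts: np.ndarray
    row_labels: tuple[int, ...]
    col_labels: tuple[int, ...]


def confusion_matrix(
    reported: Sequence[int], truth: Sequence[int]
) -> ConfusionMatrix:
    """Cross-tabulate reported labels (0 = unassigned) against truth (0 = noise)."""
    reported = np.asarray(reported, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if reported.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    n_rows = int(reported.max()) + 1
    n_cols = int(truth.max()) + 1
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    np.add.at(counts, (reported, truth), 1)
    return ConfusionMatrix(
        counts=counts,
        row_labels=tuple(range(n_rows)),
        col_labels=tuple(range(n_cols)),
    )


def _benchmark_ari(truth: np.ndarray, reported: np.ndarray) -> float:
    # score only the true-cluster genes; an unassigned gene keeps label 0,
    # which acts as its own (penalized) group among them
    mask = truth > 0
    return adjusted_rand_index(truth[mask], reported[mask])


def run_benchmark(
    specs: Iterable[SimulationSpec],
    methods: Sequence[str] = ("kprofiles", "kmeans"),
    reps: int = 20,
    seed: int = 0,
    config: KProfilesConfig | None = None,
) -> pd.DataFrame:
    """Race clustering methods over simulated designs.

    For every spec and replicate a fresh dataset is generated, every method
    is run with K equal to the true number of clusters, and the ARI over
    the true-cluster genes is recorded.  Returns a tidy frame with columns
    mechanism, M, noise_sd, method, rep, ari.  The k-means baseline is
    scikit-learn's, run on the row-standardized matrix with 10 restarts.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for m in methods:
        if m not in ("kprofiles", "kmeans"):
            raise ValueError(f"unknown method {m!r}")
    root = np.random.SeedSequence(seed)
    rows = []
    for spec in specs:
        for rep in range(reps):
            sim_s, kp_s, km_s = (
                int(s % (2**31))
                for s in root.spawn(1)[0].generate_state(3, dtype=np.uint64)
            )
            dataset = simulate(replace(spec, seed=sim_s))
            matrix = dataset.matrix.standardized()
            truth = dataset.labels
            for method in methods:
                if method == "kprofiles":
                    cfg = config or KProfilesConfig(K=spec.m_clusters)
                    result = fit(matrix, replace(cfg, K=spec.m_clusters, seed=kp_s))
                    reported = result.assignment
                else:
                    km = KMeans(
                        n_clusters=spec.m_clusters, n_init=10, random_state=km_s
                    )
                    reported = km.fit_predict(matrix.values) + 1
                rows.append(
                    {
                        "mechanism": spec.mechanism,
                        "M": spec.m_clusters,
                        "noise_sd": spec.noise_sd,
                        "method": method,
                        "rep": rep,
                        "ari": _benchmark_ari(truth, reported),
                    }
                )
    return pd.DataFrame(rows)


def plot_benchmark(results: pd.DataFrame, path: str) -> None:
    """Mean-ARI-vs-noise line plot per method (convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    summary = (
        results.groupby(["method", "noise_sd"])["ari"].mean().reset_index()
    )
    for method, grp in summary.groupby("method"):
        ax.plot(grp["noise_sd"], grp["ari"], marker="o", label=method)
    ax.set_xlabel("noise sd")
    ax.set_ylabel("mean ARI")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
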