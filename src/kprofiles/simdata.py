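"""Synthetic expression data with known nonlinear cluster structure.

Datasets mimic the benchmark design used throughout: M clusters of genes
over n samples, each cluster internally linked through one of four link
functions (linear, sine, box wave, absolute value), plus a block of pure
noise genes that belong to no cluster.  Three generation mechanisms:

hidden_factor
    every gene in a cluster is a (possibly nonlinear) function of one
    shared latent factor z ~ N(0,1), plus additive Gaussian noise;
dep1
    genes are generated sequentially, each a function of one randomly
    chosen earlier gene of the cluster;
dep2
    each new gene is a U(-1,1)-weighted sum of functions of two randomly
    chosen earlier genes.

Every transformed gene is standardized before noise is added, so
``noise_sd`` means the same thing for every link function.  True labels
(1..M for cluster genes, 0 for noise genes) ride along for ARI scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "LINKS",
    "MECHANISMS",
    "SimulationSpec",
    "SimulatedDataset",
    "apply_link",
    "simulate_hidden_factor",
    "simulate_dependent",
    "simulate",
]

LINKS = ("linear", "sine", "box", "abs")
MECHANISMS = ("hidden_factor", "dep1", "dep2")


def apply_link(name: str, x: np.ndarray) -> np.ndarray:
    """Apply one of the four link functions elementwise (raw, unstandardized).

    linear: f(z) = z; sine: f(z) = sin(pi z); box: square wave
    sign(sin(pi z)) with f = +1 at the zero crossings; abs: f(z) = |z|.
    """
    x = np.asarray(x, dtype=float)
    if name == "linear":
        return x.copy()
    if name == "sine":
        return np.sin(np.pi * x)
    if name == "box":
        return np.where(np.sin(np.pi * x) >= 0, 1.0, -1.0)
    if name == "abs":
        return np.abs(x)
    raise ValueError(f"unknown link function {name!r}")


def _standardize_vec(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class SimulationSpec:
    """Design of one synthetic dataset.

    Defaults follow the benchmark design: 100 genes per cluster, 100
    samples, 100 pure-noise genes, all four link functions, noise sd 0.4
    (the low-moderate point of the 0.2–2.0 sweep grid).
    """

    m_clusters: int
    genes_per_cluster: int = 100
    n_samples: int = 100
    n_noise_genes: int = 100
    mechanism: str = "hidden_factor"
    link_set: tuple[str, ...] = LINKS
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "link_set", tuple(self.link_set))
        if self.m_clusters < 1:
            raise ValueError("m_clusters must be >= 1")
        if self.genes_per_cluster < 1:
            raise ValueError("genes_per_cluster must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not self.link_set:
            raise ValueError("link_set must be nonempty")
        for name in self.link_set:
            if name not in LINKS:
                raise ValueError(f"unknown link function {name!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mechanism == "dep2" and self.genes_per_cluster < 2:
            raise ValueError("dep2 needs at least two genes per cluster")


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated matrix with its ground-truth labels (0 = noise gene)."""

    matrix: ExpressionMatrix
    labels: np.ndarray
    spec: SimulationSpec = field(repr=False)


def _assemble(
    spec: SimulationSpec, cluster_rows: list[np.ndarray], rng: np.random.Generator
) -> SimulatedDataset:
    noise = rng.standard_normal((spec.n_noise_genes, spec.n_samples))
    values = np.vstack([np.vstack(cluster_rows)] + ([noise] if spec.n_noise_genes else []))
    gene_ids = [
        f"c{c + 1}_g{g + 1}"
        for c in range(spec.m_clusters)
        for g in range(spec.genes_per_cluster)
    ] + [f"noise_g{g + 1}" for g in range(spec.n_noise_genes)]
    sample_ids = [f"s{j + 1}" for j in range(spec.n_samples)]
    labels = np.concatenate(
        [
            np.repeat(np.arange(1, spec.m_clusters + 1), spec.genes_per_cluster),
            np.zeros(spec.n_noise_genes, dtype=int),
        ]
    )
    matrix = ExpressionMatrix(values, tuple(gene_ids), tuple(sample_ids))
    return SimulatedDataset(matrix=matrix, labels=labels, spec=spec)


def simulate_hidden_factor(spec: SimulationSpec) -> SimulatedDataset:
    """Each cluster driven by one latent factor: gene = std(f(z)) + eps."""
    if spec.mechanism != "hidden_factor":
        raise ValueError("spec.mechanism must be 'hidden_factor'")
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for _ in range(spec.m_clusters):
        z = rng.standard_normal(spec.n_samples)
        rows = np.empty((spec.genes_per_cluster, spec.n_samples))
        for g in range(spec.genes_per_cluster):
            link = spec.link_set[rng.integers(len(spec.link_set))]
            rows[g] = _standardize_vec(apply_link(link, z))
        if spec.noise_sd > 0:
            rows += rng.normal(0.0, spec.noise_sd, rows.shape)
        blocks.append(rows)
    return _assemble(spec, blocks, rng)


def simulate_dependent(spec: SimulationSpec) -> SimulatedDataset:
    """Sequential within-cluster generation (dep1 / dep2 mechanisms).

    The first gene of a cluster is standard normal; each later gene is a
    link function of one earlier gene (dep1) or a beta-weighted sum of link
    functions of two earlier genes, betas ~ U(-1,1) (dep2).  Noise is added
    to the whole cluster only after all its genes exist.
    """
    if spec.mechanism not in ("dep1", "dep2"):
        raise ValueError("spec.mechanism must be 'dep1' or 'dep2'")
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for _ in range(spec.m_clusters):
        rows = np.empty((spec.genes_per_cluster, spec.n_samples))
        rows[0] = rng.standard_normal(spec.n_samples)
        for g in range(1, spec.genes_per_cluster):
            if spec.mechanism == "dep1":
                sel = rng.integers(g)
                link = spec.link_set[rng.integers(len(spec.link_set))]
                rows[g] = _standardize_vec(apply_link(link, rows[sel]))
            else:
                # with a single predecessor both selections draw gene 0
                sel1, sel2 = rng.integers(g), rng.integers(g)
                link1 = spec.link_set[rng.integers(len(spec.link_set))]
                link2 = spec.link_set[rng.integers(len(spec.link_set))]
                b1, b2 = rng.uniform(-1.0, 1.0, size=2)
                rows[g] = _standardize_vec(
                    b1 * apply_link(link1, rows[sel1])
                    + b2 * apply_link(link2, rows[sel2])
                )
        if spec.noise_sd > 0:
            rows += rng.normal(0.0, spec.noise_sd, rows.shape)
        blocks.append(rows)
    return _assemble(spec, blocks, rng)


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Dispatch on ``spec.mechanism``."""
    if spec.mechanism == "hidden_factor":
        return simulate_hidden_factor(spec)
    return simulate_dependent(spec)
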