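"""The K-profiles clustering loop.

The algorithm is the nonlinear counterpart of K-means: a cluster is
summarized not by a centroid but by a *profile* — an ordering of the
samples (a short Hamiltonian path through them in the cluster's gene
subspace).  Genes are attached to the cluster whose profile gives them the
smallest DCOL, but only when that DCOL is statistically significant against
the gene's own permutation null; insignificant genes stay unassigned and
never contaminate profile estimation.

One pass of the loop:

1. assign every gene to its minimum-DCOL cluster, gated by a p-value
   cutoff transformed for the implicit minimum over K tests,
2. recompute each cluster's profile with the TSP heuristic.

The nominal cutoff starts loose (random initial profiles deserve little
trust) and tightens linearly to its final value across the iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dcol import GeneNullParams, dcol_matrix, dcol_pvalue, estimate_null_params
from .matrix import ExpressionMatrix
from .profile_order import hamiltonian_order, sample_distances

__all__ = [
    "KProfilesConfig",
    "ClusterProfile",
    "ClusteringResult",
    "adjust_cutoff",
    "init_profiles",
    "assign_genes",
    "update_profiles",
    "fit",
    "cluster_score",
]

log = logging.getLogger("kprofiles.cluster")

P_FLOOR = 1e-300  # floor under p-values before taking logs


@dataclass(frozen=True)
class KProfilesConfig:
    """Settings for one K-profiles fit.

    Parameters
    ----------
    K
        Number of clusters.
    p_start, p_end
        Nominal p-value cutoff at the first and the last iteration; the
        cutoff decreases linearly between them.
    max_iter
        Iteration cap; the schedule reaches ``p_end`` at this iteration.
    B
        Number of column permutations for the per-gene DCOL null.
    init
        Profile initialization: ``"gene"`` seeds each profile with the
        sorted order of a well-supported data gene (the analog of seeding
        K-means centroids with data points); ``"random"`` draws K uniformly
        random sample orders.
    seed
        Root seed; all randomness in the fit flows from it.
    """

    K: int
    p_start: float = 0.2
    p_end: float = 0.05
    max_iter: int = 20
    B: int = 500
    init: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.p_end <= self.p_start <= 1):
            raise ValueError("need 0 < p_end <= p_start <= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.init not in ("gene", "random"):
            raise ValueError("init must be 'gene' or 'random'")


@dataclass
class ClusterProfile:
    """A cluster: its member gene indices and its sample order."""

    members: np.ndarray  # sorted gene indices, possibly empty
    order: np.ndarray  # permutation of sample indices


@dataclass
class ClusteringResult:
    """Outcome of a K-profiles fit.

    ``assignment[i]`` is the 1-based cluster index of gene i, or 0 when the
    gene failed the final significance gate.  ``p_values[i]`` is the gene's
    final minimum-over-clusters DCOL p-value.
    """

    assignment: np.ndarray
    p_values: np.ndarray
    profiles: list[ClusterProfile] = field(repr=False)
    n_iterations: int
    converged: bool


def adjust_cutoff(pi: float, K: int) -> float:
    """Per-comparison cutoff so that min of K independent uniforms < pi.

    Returns ``1 - (1 - pi)**(1/K)``; the identity at K=1, strictly
    decreasing in K.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must lie strictly in (0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    return 1.0 - (1.0 - pi) ** (1.0 / K)


def _transformed(cutoff: float, K: int) -> float:
    # config allows cutoff == 1 (assign everything); adjust_cutoff is strict
    return 1.0 if cutoff >= 1.0 else adjust_cutoff(cutoff, K)


def init_profiles(
    K: int, n_samples: int, seed: int | np.random.SeedSequence = 0
) -> list[ClusterProfile]:
    """K empty clusters with independent uniformly random sample orders."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    empty = np.empty(0, dtype=int)
    return [
        ClusterProfile(members=empty.copy(), order=rng.permutation(n_samples))
        for _ in range(K)
    ]


def seed_profiles_by_gene(
    matrix: ExpressionMatrix,
    null_params: GeneNullParams,
    K: int,
    seed: int | np.random.SeedSequence = 0,
    n_candidates: int = 10,
    support_cutoff: float = 1e-3,
    support_ratio: float = 0.75,
) -> list[ClusterProfile]:
    """Seed K profiles with the sorted orders of well-supported genes.

    A single gene's sorted order is itself a valid profile (the 1-D
    Hamiltonian path), so profiles can be seeded from data exactly the way
    K-means centroids are seeded from data points.  Seeds are picked
    sequentially by the greedy k-means++ rule with the normalized DCOL
    ``d_ik / mu_i`` as the distance: candidates are drawn with probability
    proportional to their squared distance to the profiles chosen so far,
    each candidate's sorted order is refined by one Hamiltonian-path pass
    over the genes it makes significant at ``support_cutoff`` (a single
    gene's order fits only genes monotonically linked to it; the refined
    path fits their shared underlying structure), and the refined order
    that most reduces the total potential ``sum_i min_k (d_ik / mu_i)**2``
    wins the slot.  Covered clusters offer no reduction and pure-noise
    genes reduce only themselves, so seeds land on distinct clusters.  The
    raw DCOL ratio, not the p-value, drives the selection: the permutation
    test is sensitive enough that profiles graze genes of foreign
    clusters, and masking by p-value would starve those clusters of seeds.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    tsp_seeds = ss.spawn(K)
    values = matrix.values
    p_genes = matrix.n_genes
    # normalized distance of each gene to the chosen profiles; constant
    # genes (mu = 0) get 0 so they are never drawn as seeds
    mu_safe = np.where(null_params.mu > 0, null_params.mu, np.inf)
    min_ratio = np.where(null_params.mu > 0, 1.0, 0.0)
    profiles: list[ClusterProfile] = []
    empty = np.empty(0, dtype=int)

    def supporters_of(order: np.ndarray) -> np.ndarray:
        # genes the order genuinely fits: significant against the
        # permutation null AND with a clearly reduced DCOL.  The second
        # condition matters: the test is sensitive enough to flag genes of
        # foreign clusters that the path merely grazes, and folding those
        # into a refinement would produce hybrid two-cluster profiles.
        d = dcol_matrix(values, order)
        pvals = np.asarray(dcol_pvalue(d, null_params.mu, null_params.sigma))
        return np.flatnonzero((pvals <= support_cutoff) & (d / mu_safe <= support_ratio))

    for k in range(K):
        d2 = min_ratio**2
        total = d2.sum()
        weights = d2 / total if total > 0 else np.full(p_genes, 1.0 / p_genes)
        n_cand = min(n_candidates, p_genes)
        candidates = rng.choice(p_genes, size=n_cand, replace=False, p=weights)
        best_potential = np.inf
        best_order = None
        best_ratio = None
        for g in np.sort(candidates):
            order = np.argsort(values[g], kind="stable")
            supporters = supporters_of(order)
            if supporters.size >= 2:
                order = hamiltonian_order(
                    sample_distances(matrix, supporters), seed=tsp_seeds[k]
                )
            ratio = dcol_matrix(values, order) / mu_safe
            potential = float((np.minimum(min_ratio, ratio) ** 2).sum())
            if potential < best_potential:
                best_potential, best_order, best_ratio = potential, order, ratio
        # one more pass on the winner: supporters of the refined path can
        # include link classes the seed gene's own order missed
        supporters = supporters_of(best_order)
        if supporters.size >= 2:
            best_order = hamiltonian_order(
                sample_distances(matrix, supporters), seed=tsp_seeds[k]
            )
            best_ratio = dcol_matrix(values, best_order) / mu_safe
        profiles.append(ClusterProfile(members=empty.copy(), order=best_order))
        min_ratio = np.minimum(min_ratio, best_ratio)
    return profiles


def assign_genes(
    matrix: ExpressionMatrix,
    profiles: list[ClusterProfile],
    null_params: GeneNullParams,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Significance-gated assignment of every gene to its closest profile.

    For each gene the DCOL against every profile's order is computed; the
    gene goes to the minimum-DCOL cluster (ties to the lowest index) iff the
    corresponding p-value is at or below the multiplicity-transformed
    cutoff, else it is left unassigned (label 0).  Returns the assignment
    vector and the per-gene minimum p-value.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    values = matrix.values
    if null_params.mu.shape[0] != matrix.n_genes:
        raise ValueError("null_params were estimated on a different matrix")
    K = len(profiles)
    dists = np.column_stack([dcol_matrix(values, prof.order) for prof in profiles])
    best = dists.argmin(axis=1)
    d_min = dists[np.arange(dists.shape[0]), best]
    p_min = np.asarray(dcol_pvalue(d_min, null_params.mu, null_params.sigma))
    threshold = _transformed(cutoff, K)
    assignment = np.where(p_min <= threshold, best + 1, 0)
    return assignment, p_min


def update_profiles(
    matrix: ExpressionMatrix,
    assignment: np.ndarray,
    K: int,
    seed: int | np.random.SeedSequence = 0,
) -> list[ClusterProfile]:
    """Recompute every cluster's profile from its current members.

    Nonempty clusters get the heuristic shortest Hamiltonian path through
    the samples in their gene subspace; clusters that lost all members are
    reseeded with a fresh random order so K stays fixed.
    """
    assignment = np.asarray(assignment, dtype=int)
    if assignment.min() < 0 or assignment.max() > K:
        raise ValueError("assignment labels must lie in 0..K")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(K)
    profiles = []
    for k in range(1, K + 1):
        members = np.flatnonzero(assignment == k)
        if members.size == 0:
            rng = np.random.default_rng(children[k - 1])
            order = rng.permutation(matrix.n_samples)
        else:
            order = hamiltonian_order(
                sample_distances(matrix, members), seed=children[k - 1]
            )
        profiles.append(ClusterProfile(members=members, order=order))
    return profiles


def _cutoff_schedule(config: KProfilesConfig) -> np.ndarray:
    if config.max_iter == 1:
        return np.array([config.p_end])
    t = np.arange(config.max_iter)
    return config.p_start + (config.p_end - config.p_start) * t / (config.max_iter - 1)


def fit(matrix: ExpressionMatrix, config: KProfilesConfig) -> ClusteringResult:
    """Run the full K-profiles clustering on an expression matrix.

    Estimates the permutation null once, initializes K random profiles,
    then alternates significance-gated assignment and profile updates while
    the nominal cutoff decays linearly from ``p_start`` to ``p_end``.
    Stops early when the cutoff has reached ``p_end`` and the assignment
    vector no longer changes; fully deterministic given ``config.seed``.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least three samples to cluster")
    ss = np.random.SeedSequence(config.seed)
    null_ss, init_ss, loop_ss = ss.spawn(3)
    null_params = estimate_null_params(matrix, B=config.B, seed=null_ss)
    if config.init == "gene":
        profiles = seed_profiles_by_gene(matrix, null_params, config.K, seed=init_ss)
    else:
        profiles = init_profiles(config.K, matrix.n_samples, seed=init_ss)
    iter_seeds = loop_ss.spawn(config.max_iter)
    schedule = _cutoff_schedule(config)

    assignment = np.zeros(matrix.n_genes, dtype=int)
    p_values = np.ones(matrix.n_genes)
    converged = False
    n_iterations = 0
    for t, cutoff in enumerate(schedule):
        prev = assignment
        assignment, p_values = assign_genes(matrix, profiles, null_params, cutoff)
        profiles = update_profiles(
            matrix, assignment, config.K, seed=iter_seeds[t]
        )
        n_iterations = t + 1
        log.debug(
            "iter %d: cutoff=%.4f assigned=%d changed=%d",
            n_iterations,
            cutoff,
            int((assignment > 0).sum()),
            int((assignment != prev).sum()),
        )
        at_end = cutoff <= config.p_end + 1e-15
        if at_end and t > 0 and np.array_equal(assignment, prev):
            converged = True
            break
    return ClusteringResult(
        assignment=assignment,
        p_values=p_values,
        profiles=profiles,
        n_iterations=n_iterations,
        converged=converged,
    )


def cluster_score(result: ClusteringResult) -> float:
    """Model-fit score: sum of negative log p-values over all genes.

    Plays the role the within-cluster variance plays for K-means when
    choosing the number of clusters.  p-values are floored at 1e-300 so a
    perfect fit cannot produce an infinity.
    """
    p = np.maximum(np.asarray(result.p_values, dtype=float), P_FLOOR)
    return float(-np.log(p).sum())
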