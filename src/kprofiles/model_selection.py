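"""Choosing the number of clusters K.

The within-cluster-variance curve of K-means is replaced by the sum of
negative log DCOL p-values over all genes: more recovered structure means
smaller p-values and a larger score.  K is chosen at the elbow of the
score-vs-K curve (operationalized as the interior point farthest from the
chord joining the curve's endpoints, after normalizing both axes), with an
optional gap-style comparison against row-permuted reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cluster import KProfilesConfig, cluster_score, fit
from .matrix import ExpressionMatrix

__all__ = ["ScoreCurve", "score_curve", "choose_k_elbow", "gap_score"]


@dataclass(frozen=True)
class ScoreCurve:
    """Cluster-score values over a grid of candidate K."""

    ks: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ks", tuple(int(k) for k in self.ks))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if len(self.ks) != len(self.scores):
            raise ValueError("ks and scores must have equal length")
        if any(b <= a for a, b in zip(self.ks, self.ks[1:])):
            raise ValueError("ks must be strictly increasing")


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def score_curve(
    matrix: ExpressionMatrix,
    ks: Sequence[int],
    config: KProfilesConfig,
    seed: int = 0,
) -> ScoreCurve:
    """Fit at every candidate K (seeded per K) and record the score.

    ``config`` supplies everything but K and the seed.
    """
    ks = [int(k) for k in ks]
    if not ks or any(k < 1 for k in ks):
        raise ValueError("ks must be nonempty with all K >= 1")
    seeds = _child_seeds(seed, len(ks))
    scores = []
    for k, s in zip(ks, seeds):
        result = fit(matrix, replace(config, K=k, seed=s))
        scores.append(cluster_score(result))
    return ScoreCurve(ks=tuple(ks), scores=tuple(scores))


def choose_k_elbow(curve: ScoreCurve) -> int:
    """K at the elbow: interior point farthest from the endpoint chord.

    Both axes are normalized to [0, 1] first, so the choice is invariant to
    affine rescaling of the score axis.  Ties (e.g. an exactly linear
    curve, where every distance is zero) go to the smallest interior K.
    """
    if len(curve.ks) < 3:
        raise ValueError("need at least three curve points")
    x = np.asarray(curve.ks, dtype=float)
    y = np.asarray(curve.scores, dtype=float)
    x = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    y = (y - y.min()) / span if span > 0 else np.zeros_like(y)
    # perpendicular distance from each point to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    interior = dist[1:-1]
    return curve.ks[1 + int(np.argmax(interior))]


def gap_score(
    matrix: ExpressionMatrix,
    K: int,
    n_ref: int,
    config: KProfilesConfig,
    seed: int = 0,
) -> float:
    """Observed cluster score minus its mean over row-permuted references.

    Each reference matrix permutes the entries within every gene row
    independently, destroying inter-gene dependence while preserving every
    gene's marginal distribution.  A clearly positive gap indicates more
    structure than chance at this K.
    """
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    seeds = _child_seeds(seed, 2 * n_ref + 1)
    observed = cluster_score(fit(matrix, replace(config, K=K, seed=seeds[0])))
    ref_scores = []
    for r in range(n_ref):
        rng = np.random.default_rng(seeds[1 + 2 * r])
        shuffled = np.array(
            [row[rng.permutation(row.size)] for row in matrix.values]
        )
        ref = ExpressionMatrix(shuffled, matrix.gene_ids, matrix.sample_ids)
        ref_scores.append(
            cluster_score(fit(ref, replace(config, K=K, seed=seeds[2 + 2 * r])))
        )
    return observed - float(np.mean(ref_scores))
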