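"""The K-profiles clustering loop."""

import numpy as np
import pytest

from kprofiles import (
    ExpressionMatrix,
    KProfilesConfig,
    adjust_cutoff,
    adjusted_rand_index,
    assign_genes,
    cluster_score,
    estimate_null_params,
    fit,
    init_profiles,
    orders_equivalent,
    update_profiles,
)
from kprofiles.cluster import _cutoff_schedule


class TestAdjustCutoff:
    def test_identity_at_k1(self):
        for pi in (0.05, 0.2, 0.7):
            assert adjust_cutoff(pi, 1) == pytest.approx(pi, abs=1e-12)

    def test_hand_algebra(self):
        # 1 - sqrt(1 - 0.19) = 1 - 0.9 = 0.1
        assert adjust_cutoff(0.19, 2) == pytest.approx(0.1, abs=1e-12)

    def test_closed_form_k10(self):
        assert adjust_cutoff(0.2, 10) == pytest.approx(0.022067231, abs=1e-6)

    def test_strictly_decreasing_in_k(self):
        vals = [adjust_cutoff(0.2, k) for k in range(1, 8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, pi):
        with pytest.raises(ValueError):
            adjust_cutoff(pi, 3)


class TestInitProfiles:
    def test_valid_permutations(self):
        profiles = init_profiles(3, 5, seed=9)
        assert len(profiles) == 3
        for prof in profiles:
            assert sorted(prof.order) == list(range(5))
            assert prof.members.size == 0

    def test_deterministic(self):
        a = init_profiles(4, 7, seed=2)
        b = init_profiles(4, 7, seed=2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.order, y.order)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            init_profiles(0, 5)


class TestAssignGenes:
    def test_constant_gene_unassigned(self, rng):
        values = np.vstack([np.full(20, 2.0), rng.normal(size=(3, 20))])
        m = ExpressionMatrix.from_arrays(values)
        null = estimate_null_params(m, B=100, seed=0)
        profiles = init_profiles(2, 20, seed=0)
        assignment, pvals = assign_genes(m, profiles, null, 0.2)
        assert assignment[0] == 0
        assert pvals[0] == 1.0

    def test_monotone_gene_assigned_to_matching_profile(self, rng):
        profiles = init_profiles(3, 30, seed=4)
        target = profiles[1].order
        signal = np.empty(30)
        signal[target] = np.linspace(0, 1, 30)  # strictly increasing along profile 1
        values = np.vstack([signal, rng.normal(size=(30, 30))])
        m = ExpressionMatrix.from_arrays(values)
        null = estimate_null_params(m, B=200, seed=1)
        assignment, pvals = assign_genes(m, profiles, null, 0.2)
        assert assignment[0] == 2  # 1-based index of profile 1
        assert pvals[0] < 1e-6

    def test_insignificant_gene_unassigned(self, rng):
        m = ExpressionMatrix.from_arrays(rng.normal(size=(50, 20)))
        null = estimate_null_params(m, B=200, seed=2)
        profiles = init_profiles(1, 20, seed=5)
        assignment, pvals = assign_genes(m, profiles, null, 0.01)
        threshold = 0.01
        assert np.all((assignment == 0) == (pvals > threshold))


class TestUpdateProfiles:
    def test_singleton_cluster_sorts_gene(self, rng):
        y = rng.normal(size=12)
        m = ExpressionMatrix.from_arrays(np.vstack([y, rng.normal(size=12)]))
        profiles = update_profiles(m, np.array([1, 0]), K=1, seed=0)
        assert orders_equivalent(profiles[0].order, np.argsort(y))

    def test_empty_cluster_reseeded_deterministically(self, tiny_matrix):
        a = update_profiles(tiny_matrix, np.zeros(3, dtype=int), K=2, seed=8)
        b = update_profiles(tiny_matrix, np.zeros(3, dtype=int), K=2, seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.order, y.order)
            assert sorted(x.order) == list(range(4))

    def test_duplicated_gene_same_order_as_singleton(self, rng):
        y = rng.normal(size=10)
        m = ExpressionMatrix.from_arrays(np.vstack([y, y]))
        double = update_profiles(m, np.array([1, 1]), K=1, seed=0)
        single = update_profiles(m, np.array([1, 0]), K=1, seed=0)
        assert orders_equivalent(double[0].order, single[0].order)

    def test_bad_labels_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            update_profiles(tiny_matrix, np.array([0, 1, 5]), K=2, seed=0)


class TestCutoffSchedule:
    def test_monotone_and_reaches_end(self):
        cfg = KProfilesConfig(K=2, p_start=0.2, p_end=0.05, max_iter=20)
        sched = _cutoff_schedule(cfg)
        assert len(sched) == 20
        assert sched[0] == pytest.approx(0.2)
        assert sched[-1] == pytest.approx(0.05)
        assert np.all(np.diff(sched) <= 0)

    def test_single_iteration(self):
        cfg = KProfilesConfig(K=1, p_start=0.2, p_end=0.05, max_iter=1)
        assert _cutoff_schedule(cfg).tolist() == [0.05]


class TestFit:
    def test_deterministic(self, small_structured):
        m = small_structured.matrix.standardized()
        cfg = KProfilesConfig(K=2, B=100, max_iter=8, seed=42)
        a = fit(m, cfg)
        b = fit(m, cfg)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        assert a.n_iterations == b.n_iterations
        assert a.converged == b.converged

    def test_recovers_zero_noise_clusters(self, small_structured):
        m = small_structured.matrix.standardized()
        result = fit(m, KProfilesConfig(K=2, B=200, seed=0))
        truth = small_structured.labels
        mask = truth > 0
        assert adjusted_rand_index(truth[mask], result.assignment[mask]) == 1.0

    def test_members_respect_significance_gate(self, small_structured):
        m = small_structured.matrix.standardized()
        cfg = KProfilesConfig(K=2, B=100, seed=3)
        result = fit(m, cfg)
        threshold = adjust_cutoff(cfg.p_end, cfg.K)
        assigned = result.assignment > 0
        assert np.all(result.p_values[assigned] <= threshold)
        # assigned genes partition across member sets
        all_members = np.concatenate([p.members for p in result.profiles])
        assert len(all_members) == len(set(all_members)) == assigned.sum()
        for k, prof in enumerate(result.profiles, start=1):
            np.testing.assert_array_equal(
                np.sort(prof.members), np.flatnonzero(result.assignment == k)
            )

    def test_random_init_supported(self, small_structured):
        m = small_structured.matrix.standardized()
        result = fit(m, KProfilesConfig(K=2, B=100, init="random", seed=1))
        assert result.assignment.shape == (m.n_genes,)

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix.from_arrays(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            fit(m, KProfilesConfig(K=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KProfilesConfig(K=0)
        with pytest.raises(ValueError):
            KProfilesConfig(K=2, p_start=0.05, p_end=0.2)
        with pytest.raises(ValueError):
            KProfilesConfig(K=2, init="bogus")


class TestClusterScore:
    def _result(self, pvals):
        from kprofiles.cluster import ClusteringResult

        return ClusteringResult(
            assignment=np.zeros(len(pvals), dtype=int),
            p_values=np.asarray(pvals),
            profiles=[],
            n_iterations=1,
            converged=True,
        )

    def test_all_ones_scores_zero(self):
        assert cluster_score(self._result([1.0, 1.0, 1.0])) == 0.0

    def test_hand_value(self):
        assert cluster_score(self._result([0.1, 0.01])) == pytest.approx(
            6.9078, abs=1e-3
        )

    def test_monotone_in_pvalues(self):
        base = cluster_score(self._result([0.5, 0.2]))
        assert cluster_score(self._result([0.5, 0.1])) > base

    def test_zero_pvalue_finite(self):
        assert np.isfinite(cluster_score(self._result([0.0, 1.0])))
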