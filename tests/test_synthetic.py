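import numpy as np
import pytest

from cycleconn.clustering import diametrical_fit
from cycleconn.graph_metrics import system_segregation
from cycleconn.leida import session_eigenvectors
from cycleconn.static_fc import FCMatrix, fisher_r2z, pearson_fc
from cycleconn.stats import acf, paired_diffs, paired_t
from cycleconn.synthetic import (
    DynamicSimParams,
    SimulationError,
    StaticSimParams,
    default_state_patterns,
    gen_ar1_series,
    gen_dynamic_cohort,
    gen_static_cohort,
    plant_block_fc,
    shifted_stationary,
    stationary_transition_matrix,
)


class TestAr1Series:
    def test_white_noise_limit(self):
        y = gen_ar1_series(0.0, 10000, 1.0, seed=0)
        assert abs(acf(y, 1)[0]) < 0.03

    def test_theoretical_lag1(self):
        y = gen_ar1_series(0.6, 10000, 1.0, seed=1)
        assert acf(y, 1)[0] == pytest.approx(0.6, abs=0.03)

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(
            gen_ar1_series(0.4, 50, 2.0, seed=9), gen_ar1_series(0.4, 50, 2.0, seed=9)
        )

    def test_parameter_errors(self):
        with pytest.raises(SimulationError):
            gen_ar1_series(1.0, 10)
        with pytest.raises(SimulationError):
            gen_ar1_series(0.5, 0)


class TestPlantBlockFC:
    def test_zero_couplings_give_identity(self):
        np.testing.assert_array_equal(plant_block_fc(4, [2, 2], 0.0, 0.0), np.eye(4))

    def test_exactly_three_distinct_values(self):
        m = plant_block_fc(4, [2, 2], 0.6, 0.2)
        assert set(np.round(m.ravel(), 12)) == {1.0, 0.6, 0.2}
        np.testing.assert_array_equal(m, m.T)

    def test_segregation_of_planted_matrix_is_exactly_one(self):
        # Fisher z of 0 between-network correlation is 0, so SS = 1
        m = plant_block_fc(10, [5, 5], 0.5, 0.0)
        z = fisher_r2z(FCMatrix(m))
        ss = system_segregation(z, [0] * 5 + [1] * 5)
        assert ss == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_definite_rejected_with_hint(self):
        with pytest.raises(SimulationError, match="positive"):
            plant_block_fc(6, [3, 3], -0.4, 0.9)


class TestStaticCohort:
    def test_structure_and_determinism(self):
        params = StaticSimParams(p=21, t=50, n_days=4, seed=3)
        a = gen_static_cohort(params)
        b = gen_static_cohort(StaticSimParams(p=21, t=50, n_days=4, seed=3))
        assert len(a.manifest.records) == 8
        assert a.manifest.paired_days() == [1, 2, 3, 4]
        for ra, rb in zip(a.manifest.records, b.manifest.records):
            np.testing.assert_array_equal(ra.data, rb.data)
        assert a.truth.r_between == b.truth.r_between

    def test_segregation_effect_direction_recovered(self, small_static_cohort):
        cohort = small_static_cohort
        part = cohort.atlas.partition_vector()
        values = {"natural": [], "oc": []}
        for rec in cohort.manifest.records:
            z = fisher_r2z(pearson_fc(rec))
            values[rec.condition].append(system_segregation(z, part))
        assert np.mean(values["natural"]) > np.mean(values["oc"])

    def test_day_effect_induces_positive_lag1_in_paired_diffs(self):
        # day-level AR(1) on between-network coupling must show up in the
        # lag-1 autocorrelation of daily paired segregation differences
        lag1 = []
        for seed in range(6):
            cohort = gen_static_cohort(
                StaticSimParams(p=42, t=300, n_days=30, day_ar1_phi=0.6,
                                day_sd=0.04, noise_sd=0.0, seed=seed)
            )
            part = cohort.atlas.partition_vector()
            by_cond = {"natural": {}, "oc": {}}
            for rec in cohort.manifest.records:
                z = fisher_r2z(pearson_fc(rec))
                by_cond[rec.condition][rec.day_index] = system_segregation(z, part)
            diffs = paired_diffs(by_cond["natural"], by_cond["oc"])
            lag1.append(acf(diffs, 1)[0])
        assert np.mean(lag1) > 0.15

    def test_null_cohort_type_one_error_near_alpha(self):
        # identical conditions, no day autocorrelation: paired t on
        # segregation should reject at close to the nominal 5% rate
        rejections = 0
        n_seeds = 80
        for seed in range(n_seeds):
            cohort = gen_static_cohort(
                StaticSimParams(p=28, partition_sizes=[7, 7, 7, 7],
                                r_between_natural=0.15, r_between_oc=0.15,
                                t=80, n_days=10, day_ar1_phi=0.0, seed=seed)
            )
            part = cohort.atlas.partition_vector()
            by_cond = {"natural": {}, "oc": {}}
            for rec in cohort.manifest.records:
                z = fisher_r2z(pearson_fc(rec))
                by_cond[rec.condition][rec.day_index] = system_segregation(z, part)
            p = paired_t(paired_diffs(by_cond["natural"], by_cond["oc"])).p
            rejections += p < 0.05
        # binomial(80, 0.05): observing more than 11 has probability < 1e-3
        assert rejections <= 11


class TestDynamicCohort:
    def test_single_coherent_state_gives_uniform_eigenvector(self):
        params = DynamicSimParams(
            p=12, k_true=1, state_patterns=np.ones((1, 12)),
            phase_noise_sd=0.0, t=120, n_days=1, seed=0,
        )
        cohort = gen_dynamic_cohort(params)
        out = session_eigenvectors(cohort.manifest.records[0])
        uniform = np.ones(12) / np.sqrt(12)
        assert np.abs(out.vectors @ uniform).min() >= 0.99

    def test_stationary_distribution_reached_for_long_t(self):
        params = DynamicSimParams(p=8, k_true=2, fo_shift=0.4, stay=0.5,
                                  t=20000, n_days=1, seed=2)
        cohort = gen_dynamic_cohort(params)
        fo = cohort.truth.fractional_occurrence["oc01"]
        np.testing.assert_allclose(fo, cohort.truth.stationary["oc"], atol=0.03)

    def test_truth_occurrences_match_label_counts_exactly(self):
        cohort = gen_dynamic_cohort(DynamicSimParams(p=8, t=50, n_days=2, seed=1))
        for sid, labels in cohort.truth.labels.items():
            np.testing.assert_array_equal(
                cohort.truth.fractional_occurrence[sid],
                np.bincount(labels, minlength=4) / labels.size,
            )

    def test_deterministic_under_seed(self):
        a = gen_dynamic_cohort(DynamicSimParams(p=8, t=40, n_days=2, seed=7))
        b = gen_dynamic_cohort(DynamicSimParams(p=8, t=40, n_days=2, seed=7))
        for ra, rb in zip(a.manifest.records, b.manifest.records):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_nyquist_guard(self):
        with pytest.raises(SimulationError, match="Nyquist"):
            DynamicSimParams(f0=0.3, tr=2.0)

    def test_planted_patterns_recovered_through_leida(self, small_dynamic_cohort):
        cohort = small_dynamic_cohort
        pooled = np.vstack([
            session_eigenvectors(rec).vectors for rec in cohort.manifest.records[:6]
        ])
        model = diametrical_fit(pooled, k=2, restarts=10, seed=0)
        patterns = cohort.truth.state_patterns
        patterns = patterns / np.linalg.norm(patterns, axis=1, keepdims=True)
        sims = np.abs(model.centroids @ patterns.T)
        assert sims.max(axis=0).min() >= 0.95


class TestMarkovHelpers:
    def test_transition_matrix_has_requested_stationary(self):
        pi = shifted_stationary(4, 0.08)
        t = stationary_transition_matrix(pi, stay=0.8)
        np.testing.assert_allclose(t.sum(axis=1), 1.0)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-12)
        assert pi[0] == pytest.approx(0.25 + 0.08)

    def test_patterns_distinct_and_orthogonal(self):
        pats = default_state_patterns(16, 4)
        gram = pats @ pats.T
        np.testing.assert_allclose(gram, 16 * np.eye(4), atol=1e-12)
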