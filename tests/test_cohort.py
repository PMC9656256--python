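"""Synthetic-cohort generator: planted effects, AR(1) simulation, determinism."""

import numpy as np
import pytest

from fconn.cohort import (
    CohortSpec,
    EffectBlock,
    build_group_covariances,
    generate_cohort,
    nearest_psd_correlation,
    plant_effects,
    simulate_subject,
)
from fconn.connectivity import pearson_connectivity
from fconn.edge_stats import stack_edges


def small_spec(**kwargs):
    base = dict(
        n_regions=12, n_timepoints=60, n_control=4, n_patient=4,
        effect_blocks=(), seed=5,
    )
    base.update(kwargs)
    return CohortSpec(**base)


class TestGroupCovariances:
    def test_zero_effect_gives_identical_groups(self):
        spec = small_spec(effect_blocks=((0, 6, "hypo", 0.0),))
        control, patient = build_group_covariances(spec)
        np.testing.assert_allclose(control, patient, atol=1e-12)

    def test_hypo_scaling_rule_and_psd_projection(self):
        # Equicorrelation baseline: r = 0.5 inside the block, 0.3 elsewhere
        # (positive definite by construction for these sizes).
        n = 12
        base = np.full((n, n), 0.3)
        base[:6, :6] = 0.5
        np.fill_diagonal(base, 1.0)
        assert np.linalg.eigvalsh(base)[0] > 0
        blocks = (EffectBlock(0, 6, "hypo", 0.8),)
        # pre-projection value by the stated rule: 0.5 * (1 - 0.8) = 0.1
        planted = plant_effects(base, blocks)
        off = ~np.eye(6, dtype=bool)
        assert np.all(np.abs(planted[:6, :6][off] - 0.1) < 0.05)
        # entries outside the block untouched by the rule, projection small
        assert np.all(np.abs(planted[6:, 6:][~np.eye(6, dtype=bool)] - 0.3) < 0.05)

    def test_hyper_moves_toward_capped_scale_up(self):
        n = 8
        base = np.full((n, n), 0.4)
        np.fill_diagonal(base, 1.0)
        planted = plant_effects(base, (EffectBlock(0, 4, "hyper", 0.5),))
        off = ~np.eye(4, dtype=bool)
        assert planted[:4, :4][off].mean() > 0.4

    def test_study_scale_shapes(self):
        spec = CohortSpec(seed=1)
        control, patient = build_group_covariances(spec)
        assert control.shape == patient.shape == (166, 166)

    def test_matrices_are_psd_correlations(self):
        control, patient = build_group_covariances(small_spec())
        for m in (control, patient):
            np.testing.assert_allclose(np.diag(m), 1.0)
            np.testing.assert_allclose(m, m.T)
            assert np.linalg.eigvalsh(m)[0] > -1e-10

    def test_patient_differs_only_inside_blocks(self):
        spec = small_spec(effect_blocks=((2, 5, "hypo", 0.5),))
        control, patient = build_group_covariances(spec)
        outside = np.ones((12, 12), dtype=bool)
        outside[2:5, 2:5] = False
        # PSD projection may nudge outside entries, but only slightly
        assert np.max(np.abs((patient - control)[outside])) < 0.02
        inside = control[2:5, 2:5][~np.eye(3, dtype=bool)]
        planted = patient[2:5, 2:5][~np.eye(3, dtype=bool)]
        assert np.all(planted < inside)

    def test_rejects_bad_blocks(self):
        with pytest.raises(ValueError, match="delta"):
            small_spec(effect_blocks=((0, 3, "hypo", 1.0),))
        with pytest.raises(ValueError, match="disjoint"):
            small_spec(effect_blocks=((0, 4, "hypo", 0.2), (3, 6, "hyper", 0.2)))
        with pytest.raises(ValueError, match="outside"):
            small_spec(effect_blocks=((8, 14, "hypo", 0.2),))

    def test_psd_projection_is_projection(self):
        m = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
        repaired = nearest_psd_correlation(m)
        assert np.linalg.eigvalsh(repaired)[0] >= -1e-12
        np.testing.assert_allclose(np.diag(repaired), 1.0)
        already = np.array([[1.0, 0.2], [0.2, 1.0]])
        np.testing.assert_allclose(nearest_psd_correlation(already), already, atol=1e-12)


class TestSimulateSubject:
    def test_identity_covariance_decorrelated(self):
        ts = simulate_subject(np.eye(10), 50_000, ar=0.0, seed=1)
        r = np.corrcoef(ts.data)
        off = np.abs(r[~np.eye(10, dtype=bool)])
        assert off.max() < 0.02

    def test_target_correlation_recovered(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.9
        ts = simulate_subject(cov, 20_000, ar=0.0, seed=2)
        r01 = np.corrcoef(ts.data[0], ts.data[1])[0, 1]
        assert 0.87 <= r01 <= 0.93

    def test_ar_smoothing_preserves_stationary_correlation(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.6
        ts = simulate_subject(cov, 20_000, ar=0.5, seed=3)
        r01 = np.corrcoef(ts.data[0], ts.data[1])[0, 1]
        assert abs(r01 - 0.6) < 0.05
        lag1 = np.corrcoef(ts.data[0, :-1], ts.data[0, 1:])[0, 1]
        assert abs(lag1 - 0.5) < 0.05

    def test_seed_determinism(self):
        cov = np.eye(5)
        a = simulate_subject(cov, 100, 0.3, seed=7)
        b = simulate_subject(cov, 100, 0.3, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_subject(bad, 50, 0.0, seed=0)


class TestGenerateCohort:
    def test_default_spec_is_the_study_cohort(self, default_cohort):
        assert len(default_cohort) == 90
        groups = [s.group for s in default_cohort.subjects]
        assert groups.count("control") == 49
        assert groups.count("depression") == 41
        diagnoses = [s.diagnosis for s in default_cohort.subjects if s.group == "depression"]
        assert diagnoses.count("mdd") == 35
        assert diagnoses.count("bipolar") == 6
        assert default_cohort.subjects[0].timeseries.data.shape == (166, 192)

    def test_patients_only_cohort_allowed(self):
        cohort = generate_cohort(small_spec(n_control=0))
        assert all(s.group == "depression" for s in cohort.subjects)

    def test_byte_identical_regeneration(self):
        a = generate_cohort(small_spec())
        b = generate_cohort(small_spec())
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.timeseries.data, sb.timeseries.data)

    def test_seed_isolation(self):
        a = generate_cohort(small_spec(seed=1))
        b = generate_cohort(small_spec(seed=2))
        assert not np.array_equal(a.subjects[0].timeseries.data, b.subjects[0].timeseries.data)
        assert a.ground_truth["effect_blocks"] == b.ground_truth["effect_blocks"]

    def test_ground_truth_edges_are_within_blocks(self):
        spec = small_spec(effect_blocks=((2, 5, "hypo", 0.5),))
        cohort = generate_cohort(spec)
        edges = cohort.ground_truth["planted_edges"]
        assert sorted((i, j) for i, j, _ in edges) == [(2, 3), (2, 4), (3, 4)]

    def test_null_cohort_t_statistics_centered(self):
        """With no planted effect the signed edge-wise t-statistics average ~0.

        The factor structure shared by all subjects correlates the edge-wise
        t-statistics, so a single cohort's mean t fluctuates with SD ~0.4;
        centering is therefore tested across replicate cohorts (whose mean
        t values are independent) with a one-sample t-test against zero.
        """
        from scipy import stats as sps

        cohort_means = []
        for rep in range(8):
            spec = CohortSpec(
                n_regions=20, n_timepoints=5000, n_control=40, n_patient=40,
                effect_blocks=(), subject_df=None, seed=17 + rep,
            )
            cohort = generate_cohort(spec)
            Y, _, _, _ = stack_edges(
                [pearson_connectivity(s.timeseries) for s in cohort.subjects]
            )
            t = sps.ttest_ind(Y[:40], Y[40:], axis=0, equal_var=True).statistic
            cohort_means.append(t.mean())
        res = sps.ttest_1samp(cohort_means, 0.0)
        assert res.pvalue > 0.01
        assert abs(np.mean(cohort_means)) < 0.5

    def test_hypo_blocks_recoverable_from_sample_correlations(
        self, default_cohort, default_connectivity
    ):
        """Planted hypo-connectivity shows up as negative patient-minus-control
        within-block sample correlation differences."""
        groups = np.array([s.group for s in default_cohort.subjects])
        R = np.stack([c.R for c in default_connectivity])
        mean_c = R[groups == "control"].mean(axis=0)
        mean_p = R[groups == "depression"].mean(axis=0)
        for blk in default_cohort.spec.effect_blocks:
            sl = slice(blk.start, blk.stop)
            off = ~np.eye(blk.stop - blk.start, dtype=bool)
            diff = (mean_p - mean_c)[sl, sl][off].mean()
            if blk.direction == "hypo":
                assert diff < 0
            else:
                assert diff > 0
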