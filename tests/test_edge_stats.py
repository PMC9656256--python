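"""Edge-wise permutation GLM, FDR behaviour, and the demographics tests."""

import numpy as np
import pandas as pd
import pytest

from fconn.edge_stats import (
    DesignMatrix,
    chi_square_test,
    edgewise_group_test,
    global_measure_test,
    ks_normality,
    ks_two_sample,
    make_design,
    stack_edges,
)
from fconn.io import validate_subject_table


def null_edge_matrices(rng, n_subjects, n_nodes, shift=None):
    """Symmetric 'connectivity-like' matrices with i.i.d. N(0,1) edges.

    ``shift``: optional (edge_index, per_subject_offsets) to plant an effect.
    """
    iu = np.triu_indices(n_nodes, 1)
    mats = []
    for s in range(n_subjects):
        vals = rng.normal(size=len(iu[0]))
        if shift is not None:
            edge, offsets = shift
            vals[edge] += offsets[s]
        m = np.eye(n_nodes)
        m[iu] = vals
        m = m + m.T - np.eye(n_nodes)
        mats.append(m)
    return mats


def two_group_design(n_a, n_b):
    X = np.column_stack([np.ones(n_a + n_b), np.r_[np.zeros(n_a), np.ones(n_b)]])
    return DesignMatrix(X=X, columns=["intercept", "group"])


class TestDesign:
    def test_dummy_pruning_keeps_full_rank(self):
        df = validate_subject_table(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(10)],
                    "group": ["control"] * 5 + ["depression"] * 5,
                    "diagnosis": ["none"] * 5 + ["mdd"] * 4 + ["bipolar"],
                }
            )
        )
        design = make_design(df)
        assert design.columns == ["intercept", "diagnosis_bipolar", "group"]
        assert np.linalg.matrix_rank(design.X) == 3

    def test_confounded_covariate_is_error(self):
        X = np.column_stack(
            [np.ones(6), [0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]]
        )
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(X=X)


class TestEdgewiseGroupTest:
    def test_strict_null_has_no_discoveries(self):
        rng = np.random.default_rng(0)
        mats = null_edge_matrices(rng, 30, 21)  # 210 edges, ~200 null edges
        res = edgewise_group_test(mats, two_group_design(15, 15), alpha=1e-4, n_perm=500, seed=1)
        assert res.n_significant_edges == 0
        assert res.n_involved_nodes == 0

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(1)
        offsets = np.r_[np.zeros(20), np.full(20, 5.0)]
        mats = null_edge_matrices(rng, 40, 6, shift=(0, offsets))
        res = edgewise_group_test(mats, two_group_design(20, 20), alpha=0.05, n_perm=400, seed=2)
        assert res.table["p_perm"].min() >= 1.0 / 401
        assert res.table["p_perm"].max() <= 1.0

    def test_t_antisymmetric_under_group_recoding(self):
        rng = np.random.default_rng(2)
        mats = null_edge_matrices(rng, 20, 5)
        d1 = two_group_design(10, 10)
        X2 = d1.X.copy()
        X2[:, 1] = 1.0 - X2[:, 1]
        d2 = DesignMatrix(X=X2, columns=d1.columns)
        t1 = edgewise_group_test(mats, d1, n_perm=10, seed=0).table["t"]
        t2 = edgewise_group_test(mats, d2, n_perm=10, seed=0).table["t"]
        np.testing.assert_allclose(t1, -t2, atol=1e-10)

    def test_orthogonal_covariate_changes_t_only_through_dof(self):
        """A covariate orthogonal to group, intercept AND the outcomes leaves
        the contrast estimate untouched; t rescales by the exact dof factor."""
        rng = np.random.default_rng(3)
        n, nodes = 24, 5
        mats = null_edge_matrices(rng, n, nodes)
        d1 = two_group_design(12, 12)
        Y, _, _, _ = stack_edges(mats)
        basis = np.column_stack([d1.X, Y])
        q, _ = np.linalg.qr(np.column_stack([basis, rng.normal(size=n)]))
        extra = q[:, -1]  # orthogonal to intercept, group and every edge column
        X2 = np.column_stack([d1.X[:, 0], extra, d1.X[:, 1]])
        d2 = DesignMatrix(X=X2, columns=["intercept", "extra", "group"])
        t1 = edgewise_group_test(mats, d1, n_perm=10, seed=0).table["t"].to_numpy()
        t2 = edgewise_group_test(mats, d2, n_perm=10, seed=0).table["t"].to_numpy()
        dof_factor = np.sqrt((n - 3) / (n - 2))  # s^2 uses n-p; p grows by 1
        np.testing.assert_allclose(t2, t1 * dof_factor, atol=1e-10)

    def test_groups_too_small_rejected(self):
        rng = np.random.default_rng(4)
        mats = null_edge_matrices(rng, 3, 4)
        X = np.column_stack([np.ones(3), [0, 0, 1.0]])
        with pytest.raises(ValueError, match="2 subjects per group"):
            edgewise_group_test(mats, DesignMatrix(X=X), n_perm=10)

    def test_fdr_false_discovery_proportion_controlled(self):
        """Mean realized FDP over seeded all-null cohorts stays within
        alpha + 2 binomial SE (30 nodes, 20+20 subjects)."""
        alpha, n_rep = 0.05, 100
        fdp = np.empty(n_rep)
        design = two_group_design(20, 20)
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            mats = null_edge_matrices(rng, 40, 30)
            res = edgewise_group_test(mats, design, alpha=alpha, n_perm=500, seed=r)
            fdp[r] = 1.0 if res.n_significant_edges > 0 else 0.0
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert fdp.mean() <= alpha + 2 * se

    def test_label_shuffling_matches_null_count_distribution(self):
        """Shuffling group labels before testing yields the same distribution
        of uncorrected-discovery counts as a genuinely null cohort."""
        design = two_group_design(15, 15)
        counts = {"null": [], "shuffled": []}
        for arm in counts:
            for r in range(60):
                rng = np.random.default_rng((7000 if arm == "null" else 9000) + r)
                mats = null_edge_matrices(rng, 30, 12)
                if arm == "shuffled":
                    mats = [mats[i] for i in rng.permutation(30)]
                res = edgewise_group_test(mats, design, alpha=0.05, n_perm=300, seed=r)
                counts[arm].append(int((res.table["p_perm"] <= 0.05).sum()))
        _, p = ks_two_sample(counts["null"], counts["shuffled"])
        assert p > 0.01


class TestGlobalMeasureTest:
    def test_identical_groups(self):
        t, p = global_measure_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="pooled variance"):
            global_measure_test([0.0] * 4, [1.0] * 4)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.2, size=9)
        t, _ = global_measure_test(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(expected, abs=1e-12)


class TestDemographics:
    def test_chi_square_matches_published_cohort_tables(self):
        """Sex (14/35 vs 14/27) and education (16/33 vs 20/21) contingency
        tables of the 49-control / 41-patient cohort."""
        chi2_sex, p_sex = chi_square_test([[14, 35], [14, 27]])
        assert chi2_sex == pytest.approx(0.324, abs=5e-4)
        assert p_sex > 0.05
        chi2_edu, p_edu = chi_square_test([[16, 33], [20, 21]])
        assert chi2_edu == pytest.approx(2.419, abs=5e-4)
        assert p_edu > 0.05

    def test_chi_square_equal_proportions_zero(self):
        chi2, p = chi_square_test([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0)

    def test_chi_square_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])

    def test_ks_two_sample_extremes_and_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=10)
        d_same, _ = ks_two_sample(a, a)
        assert d_same == pytest.approx(0.0)
        d_sep, _ = ks_two_sample(a, a + 100.0)
        assert d_sep == pytest.approx(1.0)
        # brute-force ECDF sweep oracle
        b = rng.normal(0.7, 1.0, size=10)
        grid = np.sort(np.concatenate([a, b]))
        gaps = [abs((a <= x).mean() - (b <= x).mean()) for x in grid]
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(max(gaps), abs=1e-12)

    def test_ks_normality_accepts_gaussian_samples(self):
        hits = 0
        for r in range(60):
            x = np.random.default_rng(100 + r).normal(size=10_000)
            _, p = ks_normality(x)
            hits += p > 0.05
        assert hits >= 57  # >= 95 % of replicates

    def test_ks_normality_rejects_exponential_samples(self):
        hits = 0
        for r in range(60):
            x = np.random.default_rng(200 + r).exponential(size=200)
            _, p = ks_normality(x)
            hits += p < 0.05
        assert hits >= 57

    def test_ks_normality_constant_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality([1.0] * 10)
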