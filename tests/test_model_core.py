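"""Unit tests for the design matrix and multinomial-probit machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from latentpop import (
    CoefficientSet,
    DesignMatrix,
    UtilityMatrix,
    build_design,
    latent_class_probs,
    membership_probs,
    sample_utilities,
    update_beta,
    utilities_to_label,
)
from latentpop.model_core import (
    _latent_probs_fast,
    sample_utilities_joint,
)

# ---------------------------------------------------------------------------
# build_design
# ---------------------------------------------------------------------------


class TestBuildDesign:
    def test_linear_trend_standardizes_and_errors_on_constant(self):
        table = pd.DataFrame(
            {"id": list("abc"), "latitude": [0.0, 1.0, 2.0], "longitude": [0.0, 0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="longitude"):
            build_design(table, geo_trend="linear")
        table["longitude"] = [0.0, 1.0, 3.0]
        design = build_design(table, geo_trend="linear")
        assert design.values.shape == (3, 3)
        lat = design.values[:, 1]
        assert lat.mean() == pytest.approx(0.0, abs=1e-12)
        assert lat.std() == pytest.approx(1.0, rel=1e-12)

    def test_effects_coding_rows(self):
        table = pd.DataFrame({"id": list("xyz"), "lang": ["A", "B", "C"]})
        design = build_design(table, geo_trend="none", factors=("lang",))
        np.testing.assert_allclose(
            design.values[:, 1:], [[1, 0], [0, 1], [-1, -1]]
        )

    def test_quadratic_trend_has_six_columns(self):
        r = np.random.default_rng(0)
        table = pd.DataFrame(
            {"id": range(5), "latitude": r.normal(size=5), "longitude": r.normal(size=5)}
        )
        design = build_design(table, geo_trend="quadratic")
        assert design.n_columns == 6
        # expansion applies to the standardized coordinates
        lat = design.values[:, 1]
        np.testing.assert_allclose(design.values[:, 3], lat**2)

    def test_single_level_factor_rejected(self):
        table = pd.DataFrame({"id": list("ab"), "lang": ["A", "A"]})
        with pytest.raises(ValueError, match="single observed level"):
            build_design(table, geo_trend="none", factors=("lang",))

    @given(st.lists(st.sampled_from("ABCDE"), min_size=4, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_effects_coding_sums_to_zero_over_levels(self, levels):
        table = pd.DataFrame({"id": range(len(levels)), "f": levels})
        if len(set(levels)) < 2:
            return
        design = build_design(table, geo_trend="none", factors=("f",))
        # each level's effect row, including the implied last level, sums to 0
        uniq = sorted(set(levels))
        rows = {}
        for lev in uniq:
            i = levels.index(lev)
            rows[lev] = design.values[i, 1:]
        np.testing.assert_allclose(sum(rows.values()), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# label rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "vec,expected",
    [
        ((0.1, 2.0, -1.0), 1),
        ((5.0, 5.0, 1.0), 0),
        ((3.0, 3.0, 3.0), 0),
    ],
)
def test_utilities_to_label_argmax_and_ties(vec, expected):
    assert utilities_to_label(np.array(vec)) == expected


def test_utilities_to_label_rejects_nan():
    with pytest.raises(ValueError):
        utilities_to_label(np.array([0.0, np.nan]))


# ---------------------------------------------------------------------------
# membership probabilities
# ---------------------------------------------------------------------------


class TestMembershipProbs:
    def test_zero_coefficients_give_uniform(self):
        beta = CoefficientSet(beta=np.zeros((4, 2)))
        pi = membership_probs(np.array([1.0, 0.3]), beta)
        np.testing.assert_allclose(pi, 0.25, atol=1e-8)

    def test_two_cluster_closed_form(self):
        # K=2 with mean difference m: pi_1 = Phi(m / sqrt(2))
        for m in (-1.3, 0.0, 0.7, 2.5):
            beta = np.array([[m], [0.0]])
            pi = membership_probs(np.array([1.0]), beta)
            assert pi[0] == pytest.approx(ndtr(m / np.sqrt(2)), abs=1e-6)
            assert pi.sum() == pytest.approx(1.0, abs=1e-8)

    def test_quadrature_matches_monte_carlo_oracle(self, rng):
        beta = np.array([[1.0], [0.5], [0.0]])
        x = np.array([1.0])
        quad = membership_probs(x, beta, method="quadrature")
        n = 10**6
        mc = membership_probs(x, beta, method="mc", n_mc=n, rng=rng)
        se = np.sqrt(quad * (1 - quad) / n)
        assert np.all(np.abs(quad - mc) < 3 * se + 1e-9)

    def test_mc_requires_positive_draws(self, rng):
        with pytest.raises(ValueError):
            membership_probs(np.array([1.0]), np.zeros((2, 1)), method="mc", n_mc=0)

    @given(st.integers(2, 6), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_probability_vector_for_any_beta(self, K, seed):
        r = np.random.default_rng(seed)
        beta = r.normal(scale=2.0, size=(K, 3))
        beta[0] = 0.0
        pi = membership_probs(r.normal(size=3), beta)
        assert np.all(pi >= 0)
        assert pi.sum() == pytest.approx(1.0, abs=1e-8)

    def test_fast_table_path_matches_quadrature(self, rng):
        means = rng.uniform(-5, 5, size=(50, 4))
        fast = _latent_probs_fast(means)
        exact = latent_class_probs(means, n_nodes=64)
        assert np.abs(fast - exact).max() < 5e-4


# ---------------------------------------------------------------------------
# truncated-normal utility updates
# ---------------------------------------------------------------------------


class TestSampleUtilities:
    def test_argmax_consistency_always_holds(self, rng):
        beta = CoefficientSet(beta=np.vstack([np.zeros(2), rng.normal(size=(2, 2))]))
        x = rng.normal(size=2)
        y = None
        for _ in range(200):
            z = int(rng.integers(3))
            y = sample_utilities(x, beta, z, None, rng)
            assert int(np.argmax(y)) == z
            assert y[0] > y[1] or z != 0  # K=2-style constraint on winner

    def test_truncation_raises_winner_mean(self, rng):
        beta = CoefficientSet(beta=np.array([[0.0], [0.0], [0.0]]))
        x = np.array([1.0])
        draws = [sample_utilities(x, beta, 0, None, rng)[0] for _ in range(3000)]
        assert np.mean(draws) > 0.2  # strictly above the untruncated mean 0

    def test_one_pass_kernel_matches_rejection_oracle(self, rng):
        # fixed label, 3 clusters: long-run law of the kernel equals direct
        # rejection sampling of N(m, I) | argmax = z
        m = np.array([0.3, -0.4, 0.0])
        beta = CoefficientSet(beta=m[:, None], reference_cluster=2)
        x = np.array([1.0])
        z = 1
        y = None
        kernel = []
        for i in range(20000):
            y = sample_utilities(x, beta, z, y, rng)
            if i >= 100:
                kernel.append(y.copy())
        kernel = np.array(kernel[::5])

        target = []
        while len(target) < 3000:
            cand = m + rng.standard_normal((4000, 3))
            target.extend(cand[cand.argmax(axis=1) == z])
        target = np.array(target[:3000])

        for j in range(3):
            se = np.sqrt(
                target[:, j].var() / len(target) + kernel[:, j].var() / len(kernel)
            )
            assert abs(kernel[:, j].mean() - target[:, j].mean()) < 5 * se

    def test_joint_redraw_matches_rejection_moments(self, rng):
        means = np.tile(np.array([0.5, -1.0, 0.2]), (4000, 1))
        labels = np.full(4000, 2)
        y = sample_utilities_joint(means, labels, rng)
        assert np.all(y.argmax(axis=1) == 2)
        target = []
        while len(target) < 4000:
            cand = means[0] + rng.standard_normal((8000, 3))
            target.extend(cand[cand.argmax(axis=1) == 2])
        target = np.array(target[:4000])
        for j in range(3):
            se = np.sqrt((target[:, j].var() + y[:, j].var()) / 4000)
            assert abs(y[:, j].mean() - target[:, j].mean()) < 5 * se


# ---------------------------------------------------------------------------
# conjugate coefficient update
# ---------------------------------------------------------------------------


class TestUpdateBeta:
    def test_intercept_only_conjugacy(self, rng):
        design = DesignMatrix(values=np.ones((3, 1)), column_meta=[("intercept",)])
        utilities = UtilityMatrix(y=np.array([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]]))
        draws = np.array(
            [
                update_beta(design, utilities, 0, rng).beta[1, 0]
                for _ in range(4000)
            ]
        )
        assert draws.mean() == pytest.approx(2.0, abs=4 * np.sqrt(1 / 3 / 4000) + 0.02)
        assert draws.var() == pytest.approx(1 / 3, rel=0.15)

    def test_posterior_mean_is_least_squares(self, rng):
        r = np.random.default_rng(3)
        D = np.column_stack([np.ones(40), r.normal(size=(40, 2))])
        meta = [("intercept",), ("continuous", "u"), ("continuous", "v")]
        design = DesignMatrix(values=D, column_meta=meta)
        Y = r.normal(size=(40, 2))
        draws = np.array(
            [update_beta(design, UtilityMatrix(y=Y), 0, rng).beta[1] for _ in range(6000)]
        )
        lstsq = np.linalg.lstsq(D, Y[:, 1], rcond=None)[0]
        se = np.sqrt(np.diag(np.linalg.inv(D.T @ D)) / 6000)
        assert np.all(np.abs(draws.mean(axis=0) - lstsq) < 5 * se + 1e-3)

    def test_draw_covariance_matches_gram_inverse(self):
        r = np.random.default_rng(5)
        D = np.column_stack([np.ones(30), r.normal(size=(30, 2))])
        meta = [("intercept",), ("continuous", "u"), ("continuous", "v")]
        design = DesignMatrix(values=D, column_meta=meta)
        # many clusters share the same design: pool their independent draws
        K = 5001
        Y = np.zeros((30, K))
        draws = []
        for seed in range(10):
            cs = update_beta(design, UtilityMatrix(y=Y), 0, np.random.default_rng(seed))
            draws.append(cs.beta[1:])
        draws = np.concatenate(draws, axis=0)
        cov = np.cov(draws.T)
        target = np.linalg.inv(D.T @ D)
        assert np.abs(cov - target).max() / np.abs(target).max() < 0.02

    def test_reference_row_untouched(self, rng):
        design = DesignMatrix(values=np.ones((5, 1)), column_meta=[("intercept",)])
        utilities = UtilityMatrix(y=rng.normal(size=(5, 3)))
        cs = update_beta(design, utilities, 1, rng)
        assert np.all(cs.beta[1] == 0.0)

    def test_singular_design_names_collinear_columns(self, rng):
        D = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        meta = [("intercept",), ("continuous", "lat"), ("continuous", "lat2")]
        design = DesignMatrix(values=D, column_meta=meta)
        utilities = UtilityMatrix(y=rng.normal(size=(6, 2)))
        with pytest.raises(np.linalg.LinAlgError, match="lat"):
            update_beta(design, utilities, 0, rng)


def test_coefficient_set_enforces_zero_reference():
    with pytest.raises(ValueError):
        CoefficientSet(beta=np.ones((2, 2)), reference_cluster=0)
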