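import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import comb

import raschval as rv
from raschval.errors import EstimationError, ValidationError
from raschval.rasch import _esf_brute_force, log_esf


class TestElementarySymmetric:
    def test_order_zero_is_one(self):
        assert rv.elementary_symmetric([0.3, 5.0, 1.2])[0] == pytest.approx(1.0)

    def test_hand_expanded_cubic(self):
        # (1+x)(1+2x)(1+3x) = 1 + 6x + 11x^2 + 6x^3
        np.testing.assert_allclose(
            rv.elementary_symmetric([1.0, 2.0, 3.0]), [1, 6, 11, 6], rtol=1e-12
        )

    def test_equal_terms_give_binomial_coefficients(self):
        e, k = 0.7, 8
        gamma = rv.elementary_symmetric([e] * k)
        expected = [comb(k, r) * e**r for r in range(k + 1)]
        np.testing.assert_allclose(gamma, expected, rtol=1e-10)

    def test_nonpositive_terms_rejected(self):
        with pytest.raises(ValidationError):
            rv.elementary_symmetric([1.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=20.0), min_size=2, max_size=9)
    )
    def test_matches_brute_force_subset_enumeration(self, eps):
        eps = np.array(eps)
        np.testing.assert_allclose(
            rv.elementary_symmetric(eps), _esf_brute_force(eps), rtol=1e-9
        )

    def test_log_space_recursion_stable_at_k50(self):
        rng = np.random.default_rng(0)
        log_eps = rng.normal(0, 3, 50)
        lg = log_esf(log_eps)
        assert np.all(np.isfinite(lg))
        # gamma_k = product of all terms
        assert lg[-1] == pytest.approx(log_eps.sum(), rel=1e-10)


class TestExpectedProb:
    def test_half_at_equal_location(self):
        assert rv.expected_prob(1.3, 1.3) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert rv.expected_prob(1.0, 0.0) == pytest.approx(0.73106, abs=1e-5)

    def test_saturates_in_the_limits(self):
        assert rv.expected_prob(40.0, 0.0) == pytest.approx(1.0)
        assert rv.expected_prob(-40.0, 0.0) == pytest.approx(0.0)


def _brute_force_cml(data):
    """Independent oracle: maximize the enumerated conditional likelihood.

    The conditional log-likelihood is written directly from the pattern
    probabilities P(x | r) = exp(-sum x_i beta_i) / gamma_r with gamma from
    subset enumeration, and maximized over the sum-to-zero subspace with
    Nelder-Mead.
    """
    x = data.responses
    k = x.shape[1]
    r = x.sum(axis=1)
    keep = (r > 0) & (r < k)
    xs, rs = x[keep], r[keep]

    def nll(free):
        beta = np.append(free, -free.sum())
        gamma = _esf_brute_force(np.exp(-beta))
        return float(np.sum(xs @ beta) + np.sum(np.log(gamma[rs])))

    best = None
    for start in (np.zeros(k - 1), np.full(k - 1, 0.3)):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return np.append(best.x, -best.x.sum())


class TestFitCml:
    def test_identical_columns_get_equal_difficulty(self):
        rng = np.random.default_rng(2)
        col = (rng.random(80) < 0.5).astype(int)
        other = (rng.random(80) < 0.4).astype(int)
        data = rv.ResponseMatrix(np.column_stack([col, col, other]), ["a", "b", "c"])
        items = rv.fit_cml(data)
        assert items.beta[0] == pytest.approx(items.beta[1], abs=1e-6)

    def test_sum_to_zero_constraint(self, default_fit):
        _, _, items, _ = default_fit
        assert abs(items.beta.sum()) < 1e-8
        assert np.all(items.se > 0)

    def test_matches_brute_force_conditional_likelihood(self, tiny_matrix):
        items = rv.fit_cml(tiny_matrix)
        oracle = _brute_force_cml(tiny_matrix)
        np.testing.assert_allclose(items.beta, oracle, atol=1e-4)

    def test_invariant_to_duplicating_every_person(self, tiny_matrix):
        stacked = rv.ResponseMatrix(
            np.vstack([tiny_matrix.responses] * 2), tiny_matrix.item_labels
        )
        a = rv.fit_cml(tiny_matrix)
        b = rv.fit_cml(stacked)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)

    def test_inestimable_item_raises_with_name(self):
        x = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        with pytest.raises(EstimationError, match="'a'"):
            rv.fit_cml(rv.ResponseMatrix(x, ["a", "b"]))

    def test_recovers_generating_difficulties(self, default_fit):
        data, truth, items, _ = default_fit
        centered = truth.beta - truth.beta.mean()
        assert np.sqrt(np.mean((items.beta - centered) ** 2)) < 0.2


class TestEstimateAbilities:
    def test_half_of_symmetric_items_maps_to_zero(self):
        beta = np.array([-1.0, -0.5, 0.5, 1.0])
        items = rv.ItemParameters(["a", "b", "c", "d"], beta, np.ones(4), True, 1)
        x = np.array([[1, 1, 0, 0]])
        persons = rv.estimate_abilities(rv.ResponseMatrix(x, items.labels), items)
        assert persons.theta[0] == pytest.approx(0.0, abs=0.05)

    def test_raw_score_sufficiency_and_monotonicity(self, default_fit):
        data, _, items, persons = default_fit
        for r in np.unique(persons.raw_score):
            assert len(set(persons.theta[persons.raw_score == r])) == 1
        order = np.argsort(persons.raw_score)
        assert np.all(np.diff(persons.theta[order]) >= 0)

    def test_extreme_scores_get_finite_estimates(self):
        beta = np.array([-0.5, 0.0, 0.5])
        items = rv.ItemParameters(["a", "b", "c"], beta, np.ones(3), True, 1)
        x = np.array([[0, 0, 0], [1, 1, 1]])
        persons = rv.estimate_abilities(rv.ResponseMatrix(x, items.labels), items)
        assert np.all(np.isfinite(persons.theta))
        assert np.all(np.isfinite(persons.se))
        assert persons.theta[0] < 0 < persons.theta[1]

    def test_recovers_latent_trait(self, default_fit):
        _, truth, _, persons = default_fit
        assert np.corrcoef(persons.theta, truth.theta)[0, 1] > 0.6


def test_item_and_person_measures_share_one_scale(default_fit):
    """Observed item endorsement ~ mean model probability at the estimates."""
    data, _, items, persons = default_fit
    observed = data.responses.mean(axis=0)
    modeled = rv.expected_prob(persons.theta[:, None], items.beta[None, :]).mean(axis=0)
    np.testing.assert_allclose(observed, modeled, atol=0.03)
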