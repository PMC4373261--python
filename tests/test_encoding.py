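"""Single-neuron encoding model: distributions, firing probability, MI,
inhibition.  Oracles: exhaustive enumeration over connectivity/spike
outcomes at small S, Monte-Carlo simulation, and a hand-built joint table
for the mutual information."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgpatsep.encoding import (
    EncodingParams,
    apply_inhibition,
    connected_count_pmf,
    firing_prob_given_m,
    firing_profile,
    inhibition_probability,
    input_count_pmf,
    mi_surface,
    mutual_information,
    optimal_alpha_mi,
    uniform_stimulus_prior,
)

# subnormal probabilities overflow scipy's regularized-beta pmf internals
probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False,
                  allow_subnormal=False)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exhaustive_firing_prob(m, r, p, theta, S):
    """Enumerate all connectivity subsets and spike outcomes (S small)."""
    activated = set(range(m))
    total = 0.0
    for conn in itertools.product((0, 1), repeat=S):
        w_conn = math.prod(r if c else 1 - r for c in conn)
        inputs = [i for i in range(S) if conn[i] and i in activated]
        fire = 0.0
        for spikes in itertools.product((0, 1), repeat=len(inputs)):
            w_sp = math.prod(p if s else 1 - p for s in spikes)
            if sum(spikes) >= theta:
                fire += w_sp
        total += w_conn * fire
    return total


def direct_joint_mi(per_m, prior):
    """MI from an explicitly assembled joint table P(m, t), plain loops."""
    pt1 = sum(pm * q for pm, q in zip(prior, per_m))
    mi = 0.0
    for pm, q in zip(prior, per_m):
        for cond, marg in ((q, pt1), (1 - q, 1 - pt1)):
            joint = pm * cond
            if joint > 0:
                mi += joint * math.log2(cond / marg)
    return mi


# ---------------------------------------------------------------------------
# count distributions
# ---------------------------------------------------------------------------

class TestCountDistributions:
    def test_connected_count_degenerate_rates(self):
        pmf0 = connected_count_pmf(0.0, 100)
        assert pmf0[0] == pytest.approx(1.0)
        pmf1 = connected_count_pmf(1.0, 100)
        assert pmf1[100] == pytest.approx(1.0)

    def test_connected_count_small_layer(self):
        assert connected_count_pmf(0.5, 2) == pytest.approx([0.25, 0.5, 0.25])

    def test_input_count_point_masses(self):
        all_active = input_count_pmf(100, 5, 100)
        assert all_active[5] == pytest.approx(1.0)
        none_connected = input_count_pmf(3, 0, 100)
        assert none_connected[0] == pytest.approx(1.0)

    def test_input_count_enumeration(self):
        # m=2 activated of S=4; all C(4,2)=6 connected pairs equally likely:
        # overlap 0 in 1 case, 1 in 4 cases, 2 in 1 case.
        pmf = input_count_pmf(2, 2, 4)
        assert pmf[:3] == pytest.approx([1 / 6, 4 / 6, 1 / 6])

    @given(r=probs, S=st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_connected_count_normalized(self, r, S):
        assert connected_count_pmf(r, S).sum() == pytest.approx(1.0, abs=1e-12)

    @given(data=st.data(), S=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_input_count_normalized_and_supported(self, data, S):
        m = data.draw(st.integers(0, S))
        n = data.draw(st.integers(0, S))
        pmf = input_count_pmf(m, n, S)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        support = np.nonzero(pmf > 1e-15)[0]
        if support.size:
            assert support.min() >= max(0, n + m - S)
            assert support.max() <= min(m, n)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            connected_count_pmf(1.5, 10)
        with pytest.raises(ValueError):
            input_count_pmf(11, 2, 10)


# ---------------------------------------------------------------------------
# firing probability
# ---------------------------------------------------------------------------

class TestFiringProbability:
    def test_silent_inputs_never_fire(self):
        params = EncodingParams(r=0.5, p=0.0, theta=2, S=20)
        assert firing_prob_given_m(10, params) == pytest.approx(0.0)

    def test_saturated_inputs_always_fire(self):
        params = EncodingParams(r=1.0, p=1.0, theta=5, S=20)
        assert firing_prob_given_m(20, params) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "S,m,r,p,theta",
        [(4, 2, 0.3, 0.6, 2), (5, 5, 0.5, 0.5, 2), (6, 3, 0.8, 0.4, 3),
         (6, 4, 0.25, 0.9, 4), (3, 2, 0.5, 0.5, 2)],
    )
    def test_matches_exhaustive_enumeration(self, S, m, r, p, theta):
        params = EncodingParams(r=r, p=p, theta=theta, S=S)
        expected = exhaustive_firing_prob(m, r, p, theta, S)
        assert firing_prob_given_m(m, params) == pytest.approx(expected, abs=1e-12)

    def test_matches_monte_carlo(self):
        S, m, r, p, theta = 3, 2, 0.5, 0.5, 2
        rng = np.random.default_rng(20240117)
        n_draws = 10**6
        conn = rng.random((n_draws, S)) < r
        spikes = rng.random((n_draws, S)) < p
        active = np.zeros(S, dtype=bool)
        active[:m] = True
        fired = ((conn & spikes & active).sum(axis=1) >= theta)
        estimate = fired.mean()
        se = math.sqrt(estimate * (1 - estimate) / n_draws)
        params = EncodingParams(r=r, p=p, theta=theta, S=S)
        assert abs(firing_prob_given_m(m, params) - estimate) < 3 * se

    def test_monotone_in_m_p_r_and_theta(self):
        base = dict(r=0.4, p=0.4, theta=3, S=30)
        q = [firing_prob_given_m(m, EncodingParams(**base)) for m in range(31)]
        assert all(b >= a - 1e-12 for a, b in zip(q, q[1:]))
        up_p = firing_prob_given_m(15, EncodingParams(**{**base, "p": 0.6}))
        up_r = firing_prob_given_m(15, EncodingParams(**{**base, "r": 0.6}))
        up_theta = firing_prob_given_m(15, EncodingParams(**{**base, "theta": 5}))
        mid = firing_prob_given_m(15, EncodingParams(**base))
        assert up_p >= mid and up_r >= mid and up_theta <= mid

    def test_theta_below_two_rejected(self):
        with pytest.raises(ValueError):
            EncodingParams(r=0.5, p=0.5, theta=1, S=10)

    def test_mixture_collapses_to_binomial(self):
        # sum_n Hyp(m'|m,n,S) Binom(n;S,r) = Binom(m'; m, r): each activated
        # neuron is independently connected, an analytic cross-check of the
        # mixture construction.
        from scipy import stats

        from dgpatsep.encoding import _input_count_matrix
        S, r = 30, 0.37
        M = _input_count_matrix(r, S)
        for m in (0, 7, 30):
            expected = stats.binom.pmf(np.arange(S + 1), m, r)
            assert M[m] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_zero_when_disconnected_or_silent(self):
        assert mutual_information(EncodingParams(r=0.0, p=0.7, theta=2, S=30)) == \
            pytest.approx(0.0, abs=1e-12)
        assert mutual_information(EncodingParams(r=0.6, p=0.0, theta=2, S=30)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_joint_table_oracle(self):
        params = EncodingParams(r=0.5, p=0.5, theta=2, S=4)
        prior = uniform_stimulus_prior(4)
        per_m = [firing_prob_given_m(m, params) for m in range(5)]
        assert mutual_information(params) == pytest.approx(
            direct_joint_mi(per_m, prior), abs=1e-12
        )

    @given(r=probs, p=probs, theta=st.integers(2, 6))
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_one_bit(self, r, p, theta):
        mi = mutual_information(EncodingParams(r=r, p=p, theta=theta, S=12))
        assert -1e-12 <= mi <= 1.0 + 1e-12

    def test_profile_consistency(self):
        params = EncodingParams(r=0.3, p=0.6, theta=2, S=25)
        prof = firing_profile(params)
        assert prof.stimulus_prior.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.marginal_firing_prob == pytest.approx(
            prof.stimulus_prior @ prof.per_m_firing_prob, abs=1e-12
        )
        assert np.all((prof.per_m_firing_prob >= 0)
                      & (prof.per_m_firing_prob <= 1))

    def test_bad_prior_rejected(self):
        params = EncodingParams(r=0.3, p=0.6, theta=2, S=10)
        with pytest.raises(ValueError):
            mutual_information(params, prior=np.ones(11))
        with pytest.raises(ValueError):
            mutual_information(params, prior=np.full(5, 0.2))


# ---------------------------------------------------------------------------
# feedback inhibition
# ---------------------------------------------------------------------------

class TestInhibition:
    def test_closed_form_value(self):
        assert inhibition_probability(0.7, 0.4) == pytest.approx(
            math.exp(-1.75), rel=1e-12
        )

    def test_zero_activity_gives_zero_inhibition(self):
        assert inhibition_probability(0.7, 0.0) == 0.0

    def test_monotonicity(self):
        # stronger for larger f, and for smaller alpha
        assert inhibition_probability(0.7, 0.5) > inhibition_probability(0.7, 0.3)
        assert inhibition_probability(0.2, 0.7) > inhibition_probability(0.7, 0.7)

    def test_apply_scaled_value(self):
        expected = 0.5 * (1 - math.exp(-1.75))
        assert apply_inhibition(0.5, 0.7, 0.4) == pytest.approx(expected, rel=1e-12)

    def test_apply_never_amplifies_and_vanishes_at_large_alpha(self):
        for mode in ("scaled", "subtractive", "scaled-const"):
            for q in (0.0, 0.3, 1.0):
                out = apply_inhibition(q, 0.5, 0.4, mode)
                assert out <= q + 1e-15
        assert apply_inhibition(0.5, 1e6, 0.4) == pytest.approx(0.5, rel=1e-9)
        assert apply_inhibition(0.0, 0.3, 0.4) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inhibition_probability(-0.1, 0.4)
        with pytest.raises(ValueError):
            apply_inhibition(1.5, 0.5, 0.4)
        with pytest.raises(ValueError):
            apply_inhibition(0.5, 0.5, 0.4, mode="bogus")


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

class TestSweeps:
    def test_surface_zero_rows_at_r_zero(self):
        table = mi_surface(r_values=[0.0, 0.3], p_values=[0.2, 0.5],
                           theta_values=[2], S=15)
        zero_rows = table[table["r"] == 0.0]
        assert (zero_rows["mi_bits"].abs() < 1e-12).all()

    def test_single_cell_matches_pointwise(self):
        table = mi_surface(r_values=[0.3], p_values=[0.5], theta_values=[3],
                           alpha_values=[0.4], S=15)
        assert len(table) == 1
        expected = mutual_information(
            EncodingParams(r=0.3, p=0.5, theta=3, S=15, alpha=0.4)
        )
        assert table["mi_bits"].iloc[0] == pytest.approx(expected, abs=1e-14)

    def test_surface_deterministic(self):
        kwargs = dict(r_values=[0.2, 0.6], p_values=[0.3, 0.7],
                      theta_values=[2, 3], alpha_values=[None, 0.5], S=12)
        a = mi_surface(**kwargs)
        b = mi_surface(**kwargs)
        assert a.equals(b)

    def test_optimal_alpha_single_and_tied_grids(self):
        # one candidate: returned as-is
        best = optimal_alpha_mi([0.3], alpha_grid=[0.4], S=12,
                                p_values=[0.3, 0.6])
        assert best[0.3] == 0.4
        # r = 0: MI identically zero, tie broken toward smallest alpha
        best = optimal_alpha_mi([0.0], alpha_grid=[0.2, 0.5, 0.9], S=12,
                                p_values=[0.3, 0.6])
        assert best[0.0] == 0.2

    def test_optimal_alpha_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            optimal_alpha_mi([0.2], alpha_grid=[])
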