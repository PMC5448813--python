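"""Unit and property tests of the per-overlap belief-update engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.model import (
    AMBIGUOUS,
    REPLAY,
    ModelParams,
    OverlapInput,
    PerceptualState,
    combine_prior,
    filter_responses,
    posterior_ccw,
    prediction_error,
    response_probability,
    step,
    update_state,
)
from bistablepc.cohort import build_session, simulate_subject


def mixture_posterior_ccw(mu_m, pi_m, mode_sd=0.005, n_grid=80001):
    """Numeric oracle: normalise joint-prior x two-Gaussian-mode likelihood.

    Integrates the explicit mixture posterior on a fine grid and returns the
    mass above theta = 0.5; independent of the closed form under test.
    """
    theta = np.linspace(-0.5, 1.5, n_grid)
    if pi_m > 0:
        prior = np.exp(-0.5 * pi_m * (theta - mu_m) ** 2)
    else:
        prior = np.ones_like(theta)
    lik = np.exp(-0.5 * ((theta - 0.0) / mode_sd) ** 2) + np.exp(
        -0.5 * ((theta - 1.0) / mode_sd) ** 2
    )
    post = prior * lik
    post /= np.trapezoid(post, theta)
    return float(np.trapezoid(post[theta > 0.5], theta[theta > 0.5]))


class TestCombinePrior:
    @pytest.mark.parametrize(
        "state, overlap, params, expected",
        [
            # stability factor alone
            (
                PerceptualState(1.0, 3.5),
                OverlapInput(0.5, AMBIGUOUS),
                ModelParams(3.5, 0.0),
                (1.0, 3.5),
            ),
            # symmetric precision-weighted mean
            (
                PerceptualState(1.0, 2.0),
                OverlapInput(0.0, REPLAY),
                ModelParams(2.0, 2.0),
                (0.5, 4.0),
            ),
            # asymmetric weights
            (
                PerceptualState(0.0, 3.0),
                OverlapInput(1.0, REPLAY),
                ModelParams(3.0, 1.0),
                (0.25, 4.0),
            ),
        ],
    )
    def test_gaussian_product(self, state, overlap, params, expected):
        mu_m, pi_m = combine_prior(state, overlap, params)
        assert mu_m == pytest.approx(expected[0])
        assert pi_m == pytest.approx(expected[1])

    def test_product_matches_numeric_gaussian_product(self):
        """Mean/precision agree with the mode of the numeric density product."""
        theta = np.linspace(-3, 4, 200001)
        state = PerceptualState(0.0, 3.0)
        params = ModelParams(3.0, 1.0)
        dens = np.exp(-0.5 * 3.0 * (theta - 0.0) ** 2) * np.exp(
            -0.5 * 1.0 * (theta - 1.0) ** 2
        )
        dens /= np.trapezoid(dens, theta)
        mu_num = np.trapezoid(theta * dens, theta)
        var_num = np.trapezoid((theta - mu_num) ** 2 * dens, theta)
        mu_m, pi_m = combine_prior(state, OverlapInput(1.0, REPLAY), params)
        assert mu_m == pytest.approx(mu_num, abs=1e-6)
        assert pi_m == pytest.approx(1 / var_num, rel=1e-4)

    def test_flat_prior_convention(self):
        mu_m, pi_m = combine_prior(
            PerceptualState(1.0, 0.0), OverlapInput(0.5, AMBIGUOUS), ModelParams(0.0, 0.0)
        )
        assert (mu_m, pi_m) == (0.5, 0.0)

    def test_negative_precision_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(-1.0, 0.0)


class TestPosterior:
    def test_symmetry_and_flat(self):
        assert posterior_ccw(0.5, 7.0) == 0.5
        assert posterior_ccw(0.9, 0.0) == 0.5

    def test_closed_form_value(self):
        assert posterior_ccw(1.0, 3.5) == pytest.approx(expit(1.75), abs=1e-12)

    @pytest.mark.parametrize("mu_m", [0.0, 0.25, 0.5, 0.8, 1.0])
    @pytest.mark.parametrize("pi_m", [0.0, 0.7, 2.0, 3.5, 6.0])
    def test_matches_mixture_integration_oracle(self, mu_m, pi_m):
        """Closed form agrees with numeric mixture normalisation to <1e-4."""
        assert posterior_ccw(mu_m, pi_m) == pytest.approx(
            mixture_posterior_ccw(mu_m, pi_m), abs=1e-4
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            posterior_ccw(float("nan"), 1.0)


class TestResponseModel:
    @pytest.mark.parametrize(
        "p, zeta, expected",
        [(0.73, 1.0, 0.73), (0.5, 7.3, 0.5), (0.8, 2.0, 0.64 / 0.68)],
    )
    def test_unit_square_sigmoid(self, p, zeta, expected):
        assert response_probability(p, zeta) == pytest.approx(expected)

    def test_bad_zeta(self):
        with pytest.raises(InvalidParameterError):
            response_probability(0.5, 0.0)

    @pytest.mark.parametrize(
        "y, p, expected", [(1, 0.8, 0.2), (0, 0.8, 0.8), (1, 1 - 1e-9, 1e-9)]
    )
    def test_prediction_error(self, y, p, expected):
        assert prediction_error(y, p) == pytest.approx(expected)


class TestUpdate:
    def test_transition_resets_to_pi_init(self):
        new = update_state(PerceptualState(0.0, 1.2), 1, 0.3, ModelParams(3.5))
        assert new == PerceptualState(1.0, 3.5)

    def test_zero_pe_noop(self):
        state = PerceptualState(1.0, 3.5)
        assert update_state(state, 1, 0.0, ModelParams(3.5)) == state

    def test_variance_accumulates(self):
        new = update_state(PerceptualState(1.0, 3.5), 1, 0.148, ModelParams(3.5))
        assert new.pi_stability == pytest.approx(1 / (1 / 3.5 + 0.148))


class TestStep:
    def test_fresh_state_posterior(self, rng):
        state = PerceptualState(1.0, 3.5)
        _, rec = step(state, OverlapInput(0.5, AMBIGUOUS), ModelParams(3.5), rng=rng)
        assert rec.p_ccw == pytest.approx(expit(3.5 / 2))
        assert rec.y_predicted == rec.p_ccw  # zeta = 1

    def test_huge_disparity_forces_transition(self, rng):
        params = ModelParams(pi_init=3.5, pi_stereo=1e4)
        state = PerceptualState(1.0, 3.5)
        _, rec = step(state, OverlapInput(0.0, REPLAY), params, rng=rng)
        assert rec.y_predicted < 1e-6  # transition to 0 nearly certain

    def test_observed_decision_grows_variance(self):
        state = PerceptualState(1.0, 3.5)
        new, rec = step(state, OverlapInput(0.5, AMBIGUOUS), ModelParams(3.5), decision=1)
        assert rec.pe > 0
        assert new.pi_stability < state.pi_stability

    def test_bad_observed_decision(self):
        with pytest.raises(DataError):
            step(
                PerceptualState(1.0, 3.5),
                OverlapInput(0.5, AMBIGUOUS),
                ModelParams(3.5),
                decision=2,
            )


@settings(max_examples=50, deadline=None)
@given(
    mu=st.sampled_from([0.0, 1.0]),
    pi=st.floats(0.01, 10.0),
    pi_stereo=st.floats(0.0, 10.0),
    mu_stereo=st.sampled_from([0.0, 0.5, 1.0]),
)
def test_label_symmetry(mu, pi, pi_stereo, mu_stereo):
    """Swapping percept labels maps p_ccw -> 1 - p_ccw and preserves PE."""
    params = ModelParams(pi_init=3.5, pi_stereo=pi_stereo)
    a = combine_prior(
        PerceptualState(mu, pi), OverlapInput(mu_stereo, REPLAY), params
    )
    b = combine_prior(
        PerceptualState(1 - mu, pi), OverlapInput(1 - mu_stereo, REPLAY), params
    )
    pa, pb = posterior_ccw(*a), posterior_ccw(*b)
    assert pa == pytest.approx(1 - pb, abs=1e-12)
    assert prediction_error(1, pa) == pytest.approx(prediction_error(0, pb), abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(pi_init=st.floats(0.5, 8.0), n=st.integers(3, 25))
def test_stay_path_monotonicity(pi_init, n):
    """Under ambiguity with a constant decision, precision falls and PE
    rises, bounded by 0.5."""
    params = ModelParams(pi_init=pi_init)
    state = PerceptualState(1.0, pi_init)
    pes, pis = [], []
    for _ in range(n):
        state, rec = step(state, OverlapInput(0.5, AMBIGUOUS), params, decision=1)
        pes.append(rec.pe)
        pis.append(state.pi_stability)
    assert all(np.diff(pes) > 0)
    assert all(np.diff(pis) < 0)
    assert pes[-1] < 0.5


class TestFilterResponses:
    def test_constant_reports_pe_increases(self, small_session):
        responses = small_session.overlaps[
            ["run", "block", "overlap_index", "time_s", "condition"]
        ].copy()
        responses["response"] = 1.0
        traj = filter_responses(responses, small_session, ModelParams(3.5))
        block1 = traj[traj["block"] == 1]
        assert np.all(np.diff(block1["pe"]) > 0)
        assert block1["pe"].iloc[-1] < 0.5

    def test_alternating_reports_pe_constant(self, small_session):
        responses = small_session.overlaps[
            ["run", "block", "overlap_index", "time_s", "condition"]
        ].copy()
        responses["response"] = (np.arange(len(responses)) % 2).astype(float)
        traj = filter_responses(responses, small_session, ModelParams(3.5))
        # from the third overlap of each block on, every step is a
        # transition against a freshly reset pi_init prior
        later = traj.groupby(["run", "block"]).apply(
            lambda f: f.iloc[2:], include_groups=False
        )
        assert np.allclose(later["pe"], expit(3.5 / 2))

    def test_replay_pe_below_ambiguous(self, small_subject):
        params, responses, session = small_subject
        traj = filter_responses(responses, session, params)
        pe_amb = traj.loc[traj["condition"] == AMBIGUOUS, "pe"].mean()
        pe_rep = traj.loc[traj["condition"] == REPLAY, "pe"].mean()
        assert pe_rep < pe_amb

    def test_missing_reports_carried_and_unscored(self, small_subject):
        params, responses, session = small_subject
        responses = responses.copy()
        hole = responses.index[5]
        responses.loc[hole, "response"] = np.nan
        traj = filter_responses(responses, session, params)
        assert not traj["scored"].iloc[5]
        # decision carried forward from the previous overlap
        assert traj["y"].iloc[5] == traj["y"].iloc[4]

    def test_first_overlap_of_block_unscored(self, small_subject):
        params, responses, session = small_subject
        traj = filter_responses(responses, session, params)
        firsts = traj.groupby(["run", "block"]).head(1)
        assert not firsts["scored"].any()

    def test_length_mismatch_raises(self, small_subject):
        params, responses, session = small_subject
        with pytest.raises(DataError):
            filter_responses(responses.iloc[:-3], session, params)

    def test_deterministic(self, small_subject):
        params, responses, session = small_subject
        a = filter_responses(responses, session, params)
        b = filter_responses(responses, session, params)
        pd.testing.assert_frame_equal(a, b)
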