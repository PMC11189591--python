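"""Grid-posterior ideal observer: priors, per-condition likelihoods,
sequential updating, and point estimates."""

import numpy as np
import pytest

from prefobs.bayes_optimal import (
    BayesOptimalObserver,
    init_grid,
    trial_log_likelihood,
    update_posterior,
)
from prefobs.choice import choice_prob_left
from prefobs.core import AllocationPair, Condition, Observation, ObserverSession
from prefobs.ddm import DDMParams, simulate_decisions
from prefobs.wfpt import wfpt_pdf

SMALL = {"preference": 13, "beta": 7, "boundary": 9, "drift_scale": 9, "ndt": 5}


@pytest.fixture(scope="module")
def small_grid():
    return init_grid(SMALL)


def _session_from_decisions(pairs, decisions, cond, slots=None):
    observations = [
        Observation(
            pair=p,
            condition=cond,
            choice=d.choice if cond.choice_visible else None,
            rt=d.rt if cond.rt_visible else None,
        )
        for p, d in zip(pairs, decisions)
    ]
    return ObserverSession(
        observer_id="o",
        dictator_id="d",
        condition=cond,
        observations=observations,
        estimation_slots=slots or (0, len(observations)),
    )


@pytest.fixture(scope="module")
def simulated_session_p02():
    rng = np.random.default_rng(31)
    params = DDMParams(boundary=2.0, ndt=0.3, drift_scale=6.0)
    pairs = []
    while len(pairs) < 12:
        l, r = rng.uniform(0, 1, 2)
        if l != r:
            pairs.append(AllocationPair(left=float(l), right=float(r)))
    decisions = simulate_decisions(pairs, 0.2, params, rng)
    return pairs, decisions


def test_grid_weights_normalised(small_grid):
    assert small_grid.weights.sum() == pytest.approx(1.0)
    assert np.all(small_grid.weights >= 0)


def test_prior_marginal_preference_mean_is_beta_mean():
    fine = init_grid(
        {"preference": 400, "beta": 3, "boundary": 3, "drift_scale": 3, "ndt": 2}
    )
    assert fine.marginal_mean("preference") == pytest.approx(3.5 / 6.5, abs=1e-3)


def test_ndt_marginal_uniform(small_grid):
    marg = small_grid.marginal("ndt")
    np.testing.assert_allclose(marg, np.full_like(marg, 1 / marg.size), atol=1e-12)


def test_resolution_must_be_at_least_two():
    with pytest.raises(ValueError):
        init_grid({**SMALL, "preference": 1})


def test_none_condition_leaves_posterior_unchanged(small_grid):
    grid = small_grid.copy()
    obs = Observation(
        pair=AllocationPair(left=0.2, right=0.8), condition=Condition.NONE
    )
    update_posterior(grid, obs)
    np.testing.assert_array_equal(grid.log_weights, small_grid.log_weights)


def test_choice_only_likelihood_matches_softmax(small_grid):
    pair = AllocationPair(left=0.25, right=0.65)
    obs = Observation(pair=pair, condition=Condition.CHOICE_ONLY, choice="left")
    ll = trial_log_likelihood(small_grid, obs)
    i, j = 4, 3
    p = small_grid.centers["preference"][i]
    beta = small_grid.centers["beta"][j]
    assert np.exp(ll[i, j, 0, 0, 0]) == pytest.approx(
        choice_prob_left(pair, p, beta), rel=1e-9
    )


def test_rt_only_likelihood_matches_marginal_wfpt(small_grid):
    pair = AllocationPair(left=0.15, right=0.85)
    obs = Observation(pair=pair, condition=Condition.RT_ONLY, rt=1.1)
    ll = trial_log_likelihood(small_grid, obs)
    i, k, m, n = 2, 4, 5, 1
    p = small_grid.centers["preference"][i]
    a = small_grid.centers["boundary"][k]
    scale = small_grid.centers["drift_scale"][m]
    tau = small_grid.centers["ndt"][n]
    v = scale * ((1 - (pair.left - p) ** 2) - (1 - (pair.right - p) ** 2))
    expected = wfpt_pdf(1.1, "upper", drift=v, boundary_sep=a, ndt=tau) + wfpt_pdf(
        1.1, "lower", drift=v, boundary_sep=a, ndt=tau
    )
    assert np.exp(ll[i, 0, k, m, n]) == pytest.approx(expected, rel=1e-9)


def test_update_keeps_normalisation_and_commutes(small_grid, simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(pairs[:4], decisions[:4], Condition.BOTH)
    grid_a = small_grid.copy()
    for obs in session.observations:
        update_posterior(grid_a, obs)
        assert np.exp(grid_a.log_weights).sum() == pytest.approx(1.0)
    grid_b = small_grid.copy()
    for obs in reversed(session.observations):
        update_posterior(grid_b, obs)
    np.testing.assert_allclose(
        grid_a.log_weights, grid_b.log_weights, atol=1e-10
    )


def test_posterior_moves_toward_generating_preference(simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(pairs, decisions, Condition.BOTH)
    bo = BayesOptimalObserver(resolution=SMALL).fit(session)
    prior_mean = 3.5 / 6.5
    assert bo.preference_estimate_ < prior_mean
    assert abs(bo.preference_estimate_ - 0.2) < abs(prior_mean - 0.2)
    assert 0.0 < bo.preference_estimate_ < 1.0
    # informative data should shrink the marginal SD relative to the prior
    assert bo.marginal_sd_ < init_grid(SMALL).marginal_sd("preference")


def test_choice_only_concentrates_near_deterministic_agent():
    rng = np.random.default_rng(8)
    pairs = []
    while len(pairs) < 40:
        l, r = rng.uniform(0, 1, 2)
        if l != r:
            pairs.append(AllocationPair(left=float(l), right=float(r)))
    p_true = 0.8
    observations = [
        Observation(
            pair=pair,
            condition=Condition.CHOICE_ONLY,
            choice="left"
            if (1 - (pair.left - p_true) ** 2) >= (1 - (pair.right - p_true) ** 2)
            else "right",
        )
        for pair in pairs
    ]
    session = ObserverSession(
        observer_id="o",
        dictator_id="d",
        condition=Condition.CHOICE_ONLY,
        observations=observations,
        estimation_slots=(0, len(observations)),
    )
    bo = BayesOptimalObserver(
        resolution={"preference": 41, "beta": 11, "boundary": 3, "drift_scale": 3, "ndt": 2}
    ).fit(session)
    assert bo.preference_estimate_ == pytest.approx(0.8, abs=0.05)


def test_estimate_resolution_stability(simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(pairs, decisions, Condition.BOTH)
    coarse = BayesOptimalObserver(resolution=SMALL).fit(session)
    doubled = BayesOptimalObserver(
        resolution={**SMALL, "preference": 2 * SMALL["preference"]}
    ).fit(session)
    assert abs(coarse.preference_estimate_ - doubled.preference_estimate_) < 0.01


def test_posterior_predictive_probabilities(small_grid, simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(pairs, decisions, Condition.BOTH)
    bo = BayesOptimalObserver(resolution=SMALL).fit(session)
    pair = AllocationPair(left=0.3, right=0.7)
    swapped = AllocationPair(left=0.7, right=0.3)
    p_left = bo.predict_proba_left(pair)
    assert 0.0 <= p_left <= 1.0
    assert p_left + bo.predict_proba_left(swapped) == pytest.approx(1.0)


def test_map_estimator_available(simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(pairs, decisions, Condition.BOTH)
    bo = BayesOptimalObserver(resolution=SMALL, estimator="map").fit(session)
    assert 0.0 < bo.preference_estimate_ < 1.0


def test_trajectory_recorded_at_slots(simulated_session_p02):
    pairs, decisions = simulated_session_p02
    session = _session_from_decisions(
        pairs, decisions, Condition.BOTH, slots=(0, 4, 8, 12)
    )
    bo = BayesOptimalObserver(resolution=SMALL).fit(session)
    assert len(bo.trajectory_) == 4
    assert bo.trajectory_[0] == pytest.approx(3.5 / 6.5, abs=0.01)
    assert bo.trajectory_[-1] == bo.preference_estimate_
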