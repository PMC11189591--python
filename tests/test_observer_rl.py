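"""Delta-rule observer: outcome rules, forward dynamics, likelihoods, and
maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefobs.core import AllocationPair, Condition, Observation, ObserverSession
from prefobs.observer_rl import (
    ObserverRLModel,
    RLParams,
    _CompiledSession,
    classify_speed,
    combined_outcome,
    estimation_negloglik,
    outcome_both,
    outcome_choice,
    outcome_none,
    outcome_rt,
    prediction_negloglik,
    rl_update,
    session_negloglik,
    simulate_observer,
    trajectory,
)


def _obs(l, r, cond=Condition.BOTH, choice=None, rt=None):
    return Observation(
        pair=AllocationPair(left=l, right=r), condition=cond, choice=choice, rt=rt
    )


@pytest.mark.parametrize(
    "p, o, alpha, expected",
    [(0.3, 1.0, 1.0, 1.0), (0.3, 1.0, 0.0, 0.3), (0.5, 1.0, 0.2, 0.6)],
)
def test_delta_rule_update(p, o, alpha, expected):
    assert rl_update(p, o, alpha) == pytest.approx(expected)


def test_classify_speed_running_mean_includes_current():
    assert classify_speed(1.0, [1.0]) == "fast"  # first trial: rt == mean
    assert classify_speed(2.0, [1.0, 1.0, 2.0]) == "slow"  # mean 4/3 < 2
    assert classify_speed(1.0, [2.0, 2.0, 1.0]) == "fast"


def test_outcome_choice_selfish_indicator():
    assert outcome_choice(_obs(0.8, 0.2, choice="left", rt=1.0)) == 1.0
    assert outcome_choice(_obs(0.8, 0.2, choice="right", rt=1.0)) == 0.0
    assert outcome_choice(_obs(0.4, 0.6, choice="right", rt=1.0)) == 1.0


def test_outcome_rt_rules():
    slow_obs = _obs(0.3, 0.7, Condition.RT_ONLY, rt=3.0)
    assert outcome_rt(slow_obs, 0.5, "slow") == pytest.approx(0.5)
    fast_obs = _obs(0.4, 0.6, Condition.RT_ONLY, rt=0.5)
    # P_prev = 0.8: higher-s option is 0.6, which is the larger one -> 1
    assert outcome_rt(fast_obs, 0.8, "fast") == 1.0
    # P_prev = 0.2: higher-s option is 0.4, not the larger one -> 0
    assert outcome_rt(fast_obs, 0.2, "fast") == 0.0


def test_outcome_both_and_none_and_combined():
    obs = _obs(0.2, 0.6, choice="right", rt=1.0)
    assert outcome_both(obs, "slow") == pytest.approx(0.4)
    assert outcome_both(obs, "fast") == 1.0
    assert outcome_none(_obs(0.3, 0.7, Condition.NONE)) == pytest.approx(0.5)
    assert outcome_none(_obs(0.1, 0.2, Condition.NONE)) == pytest.approx(0.15)
    assert combined_outcome(1.0, 0.5, 0.5) == pytest.approx(0.75)
    assert combined_outcome(1.0, 0.5, 0.0) == 1.0
    assert combined_outcome(1.0, 0.5, 1.0) == 0.5


def _random_session(rng, cond, n=12, observer="o", dictator="d"):
    observations = []
    for _ in range(n):
        l, r = rng.uniform(0, 1, 2)
        while l == r:
            l, r = rng.uniform(0, 1, 2)
        observations.append(
            Observation(
                pair=AllocationPair(left=float(l), right=float(r)),
                condition=cond,
                choice=("left" if rng.uniform() < 0.5 else "right")
                if cond.choice_visible
                else None,
                rt=float(rng.uniform(0.4, 3.0)) if cond.rt_visible else None,
            )
        )
    pairs = []
    for _ in range(4):
        l, r = rng.uniform(0, 1, 2)
        while l == r:
            l, r = rng.uniform(0, 1, 2)
        pairs.append(AllocationPair(left=float(l), right=float(r)))
    return ObserverSession(
        observer_id=observer,
        dictator_id=dictator,
        condition=cond,
        observations=observations,
        prediction_pairs=pairs,
    )


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    alpha=st.floats(0.0, 1.0),
    p0=st.floats(0.0, 1.0),
    omega=st.floats(0.0, 1.0),
    seed=st.integers(0, 1000),
    cond=st.sampled_from(list(Condition)),
)
def test_trajectory_stays_in_unit_interval(alpha, p0, omega, seed, cond):
    rng = np.random.default_rng(seed)
    session = _random_session(rng, cond)
    traj = trajectory(session, RLParams(alpha=alpha, p0=p0, omega=omega))
    assert np.all(traj >= 0.0) and np.all(traj <= 1.0)
    assert traj[0] == p0


def test_all_slow_observations_converge_to_mean_midpoint():
    """With only slow trials the delta rule's fixed point is the average
    midpoint of the observed pairs."""
    pairs = [AllocationPair(left=l, right=l + 0.2) for l in (0.1, 0.3, 0.5, 0.7)]
    observations = [
        Observation(pair=p, condition=Condition.RT_ONLY, rt=10.0 + i)
        for i, p in enumerate(pairs * 20)
    ]
    # increasing RTs keep every trial after the first above the running mean;
    # drop the first (it counts as fast by definition)
    session = ObserverSession(
        observer_id="o",
        dictator_id="d",
        condition=Condition.RT_ONLY,
        observations=observations,
        estimation_slots=(0, len(observations)),
    )
    # small learning rate: the exponentially weighted average approaches the
    # plain mean of the cycled midpoints
    traj = trajectory(session, RLParams(alpha=0.05, p0=0.0, omega=0.5))
    mean_mid = np.mean([p.midpoint for p in pairs])
    assert traj[-1] == pytest.approx(mean_mid, abs=0.05)


def test_simulate_observer_slot_zero_is_p0_and_bounded(rng):
    session = _random_session(rng, Condition.BOTH)
    params = RLParams(alpha=0.4, p0=0.37, omega=0.5, sigma=1e-9)
    estimates, predictions = simulate_observer(session, params, rng)
    assert estimates[0] == pytest.approx(0.37, abs=1e-6)
    assert all(0 <= e <= 1 for e in estimates)
    assert len(predictions) == 4
    assert set(predictions) <= {"left", "right"}


def test_selfish_dictator_pulls_estimate_up(rng):
    """Observing a consistently selfish chooser in the both condition moves
    the estimate above its starting point."""
    finals = []
    for _ in range(100):
        observations = []
        for _ in range(12):
            l, r = sorted(rng.uniform(0, 1, 2))
            if l == r:
                continue
            observations.append(
                Observation(
                    pair=AllocationPair(left=float(l), right=float(r)),
                    condition=Condition.BOTH,
                    choice="right",  # always the larger allocation
                    rt=float(rng.uniform(0.3, 0.8)),  # fast decisions
                )
            )
        session = ObserverSession(
            observer_id="o",
            dictator_id="d",
            condition=Condition.BOTH,
            observations=observations,
            estimation_slots=(0, len(observations)),
        )
        traj = trajectory(session, RLParams(alpha=0.4, p0=0.5, omega=0.5))
        finals.append(traj[-1])
    assert np.median(finals) > 0.5


def test_estimation_negloglik_properties():
    base = estimation_negloglik(0.5, 0.5, 0.1)
    assert base == pytest.approx(-math.log(1 / (0.1 * math.sqrt(2 * math.pi))))
    assert estimation_negloglik(0.6, 0.5, 0.1) == pytest.approx(
        estimation_negloglik(0.4, 0.5, 0.1)
    )
    assert (
        estimation_negloglik(0.9, 0.5, 0.1)
        > estimation_negloglik(0.7, 0.5, 0.1)
        > base
    )


def test_prediction_negloglik_matches_softmax():
    from prefobs.choice import choice_prob_left

    pair = AllocationPair(left=0.3, right=0.8)
    p, beta = 0.6, 7.0
    nll = prediction_negloglik("left", pair, p, beta)
    assert nll == pytest.approx(-math.log(choice_prob_left(pair, p, beta)))
    # equal subjective values -> -log 0.5
    sym = AllocationPair(left=0.3, right=0.7)
    assert prediction_negloglik("left", sym, 0.5, beta) == pytest.approx(math.log(2))
    # literal variant returns the negated probability itself
    assert prediction_negloglik("left", sym, 0.5, beta, literal_eq14=True) == (
        pytest.approx(-0.5)
    )


def test_compiled_session_matches_reference(rng):
    for cond in Condition:
        session = _random_session(rng, cond)
        params = RLParams(alpha=0.33, p0=0.6, omega=0.71, sigma=0.12, beta_p=4.0)
        est, pred = simulate_observer(session, params, rng)
        session.reported_estimates = est
        session.predicted_choices = pred
        ref = session_negloglik(session, params)
        fast = _CompiledSession(session).nll(0.33, 0.6, 0.71, 4.0, 0.12)
        assert fast == pytest.approx(ref, abs=1e-10)


@pytest.fixture(scope="module")
def fitted_observer():
    rng = np.random.default_rng(77)
    true = RLParams(alpha=0.45, p0=0.5, omega=0.5, sigma=0.1, beta_p=8.0)
    sessions = []
    for i, cond in enumerate(list(Condition) * 4):  # 16 sessions
        s = _random_session(rng, cond, dictator=f"d{i}")
        est, pred = simulate_observer(s, true, rng)
        s.reported_estimates = est
        s.predicted_choices = pred
        sessions.append(s)
    model = ObserverRLModel(n_starts=8, random_state=3).fit(sessions)
    return true, sessions, model


def test_fit_beats_generating_parameters(fitted_observer):
    true, sessions, model = fitted_observer
    nll_at_truth = sum(session_negloglik(s, true) for s in sessions)
    assert model.nll_ <= nll_at_truth + 1e-6


def test_fit_recovers_learning_rate(fitted_observer):
    true, _, model = fitted_observer
    assert abs(model.alpha_ - true.alpha) < 0.15


def test_fit_seeded_identical(fitted_observer):
    _, sessions, model = fitted_observer
    again = ObserverRLModel(n_starts=8, random_state=3).fit(sessions)
    assert again.alpha_ == model.alpha_ and again.nll_ == model.nll_


def test_fit_requires_behavior(rng):
    session = _random_session(rng, Condition.BOTH)
    with pytest.raises(ValueError, match="reported estimates"):
        ObserverRLModel(n_starts=1).fit([session])
    with pytest.raises(ValueError, match="no sessions"):
        ObserverRLModel(n_starts=1).fit([])


def test_rl_params_validation():
    with pytest.raises(ValueError):
        RLParams(alpha=1.2, p0=0.5, omega=0.5)
    with pytest.raises(ValueError):
        RLParams(alpha=0.5, p0=0.5, omega=0.5, sigma=-1.0)
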