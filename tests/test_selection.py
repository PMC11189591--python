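"""Informative-trial selection: RT regression, categorisation, filtering,
picks, and order search."""

import numpy as np
import pytest

from prefobs.core import AllocationPair, Decision
from prefobs.selection import (
    RTRegressionFit,
    categorize_trial,
    filter_inconsistent,
    fit_rt_regression,
    optimize_trial_order,
    rl_order_criterion,
    select_observation_trials,
    select_prediction_trials,
)


def _trial(l, r, choice, rt, idx=0):
    return (
        AllocationPair(left=l, right=r, trial_index=idx),
        Decision(choice=choice, rt=rt),
    )


@pytest.fixture(scope="module")
def simulated_trials(dictator_dataset):
    _, df = dictator_dataset
    return [
        _trial(r.left, r.right, r.choice, r.rt, int(r.trial)) for r in df.itertuples()
    ]


@pytest.fixture(scope="module")
def true_pref(dictator_dataset):
    return dictator_dataset[0].preference


def test_noiseless_regression_is_exact():
    # rt = 2 - 1 * difficulty, difficulty computed at P = 0.3
    p = 0.3
    trials = []
    for i, (l, r) in enumerate([(0.1, 0.9), (0.2, 0.6), (0.0, 0.4), (0.5, 0.9)]):
        d = abs((1 - (l - p) ** 2) - (1 - (r - p) ** 2))
        trials.append(_trial(l, r, "left", 2.0 - 1.0 * d, i))
    fit = fit_rt_regression(trials, p)
    assert fit.b0 == pytest.approx(2.0)
    assert fit.b1 == pytest.approx(-1.0)


def test_regression_requires_variance_and_enough_trials():
    trials = [_trial(0.2, 0.4, "left", 1.0, i) for i in range(5)]
    with pytest.raises(ValueError, match="zero variance"):
        fit_rt_regression(trials, 0.3)  # all difficulties equal
    with pytest.raises(ValueError, match="at least 3"):
        fit_rt_regression(trials[:2], 0.3)


def test_negative_slope_on_ddm_data(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    assert fit.b1 < 0


@pytest.mark.parametrize(
    "rt, expected",
    [(2.0, "slow"), (1.0, "fast"), (1.3, "uninformative")],
)
def test_categorization_thresholds(rt, expected):
    fit = RTRegressionFit(b0=1.5, b1=-1.0)
    trial = _trial(0.2, 0.8, "left", rt)  # |l - r| = 0.6, fast cut at 1.14
    assert categorize_trial(trial, fit) == expected


def test_categories_partition_when_slope_negative(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    labels = {categorize_trial(t, fit) for t in simulated_trials}
    assert labels <= {"fast", "slow", "uninformative"}
    # each trial gets exactly one label by construction; fast and slow are
    # disjoint because the fast cut lies below the slow cut for b1 <= 0
    for t in simulated_trials:
        assert isinstance(categorize_trial(t, fit), str)


def test_filter_inconsistent_rules():
    keep = _trial(0.2, 0.8, "left", 1.0, 0)  # chose 0.2, P=0.3 -> closer
    drop = _trial(0.2, 0.8, "right", 1.0, 1)  # chose 0.8 -> farther
    tie = _trial(0.2, 0.4, "left", 1.0, 2)  # equidistant from 0.3 -> kept
    kept = filter_inconsistent([keep, drop, tie], 0.3)
    assert [t[0].trial_index for t in kept] == [0, 2]


def test_observation_selection_structure(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    selected = select_observation_trials(simulated_trials, true_pref, fit)
    assert len(selected) == 12
    fast = selected[:6]
    slow = selected[6:]
    assert all(categorize_trial(t, fit) == "fast" for t in fast)
    assert all(categorize_trial(t, fit) == "slow" for t in slow)
    # every selected slow trial beats every unselected slow trial on
    # midpoint distance
    chosen_ids = {t[0].trial_index for t in selected}
    unselected_slow = [
        t
        for t in filter_inconsistent(simulated_trials, true_pref)
        if categorize_trial(t, fit) == "slow" and t[0].trial_index not in chosen_ids
    ]
    worst_chosen = max(abs(t[0].midpoint - true_pref) for t in slow)
    if unselected_slow:
        best_left = min(abs(t[0].midpoint - true_pref) for t in unselected_slow)
        assert worst_chosen <= best_left + 1e-12
    # no selected trial is inconsistent
    consistent_ids = {
        t[0].trial_index for t in filter_inconsistent(simulated_trials, true_pref)
    }
    assert chosen_ids <= consistent_ids


def test_selected_slow_trials_are_slower_than_fast(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    selected = select_observation_trials(simulated_trials, true_pref, fit)
    fast_rts = [t[1].rt for t in selected[:6]]
    slow_rts = [t[1].rt for t in selected[6:]]
    assert np.mean(slow_rts) > np.mean(fast_rts)


def test_selection_shortfall_raises():
    p = 0.5
    trials = [_trial(0.4, 0.6, "left", 1.0 + 0.01 * i, i) for i in range(10)]
    fit = RTRegressionFit(b0=0.5, b1=-0.5)  # everything slow
    with pytest.raises(ValueError, match="shortfall"):
        select_observation_trials(trials, p, fit)


def test_prediction_trials_disjoint_and_fast_first(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    observed = select_observation_trials(simulated_trials, true_pref, fit)
    preds = select_prediction_trials(
        simulated_trials, true_pref, fit, exclude=observed
    )
    assert len(preds) == 4
    obs_ids = {t[0].trial_index for t in observed}
    pred_ids = {t[0].trial_index for t in preds}
    assert not (obs_ids & pred_ids)
    # the 2 fast picks are the fastest remaining fast trials
    remaining = [t for t in simulated_trials if t[0].trial_index not in obs_ids]
    rem_fast = [
        t
        for t in filter_inconsistent(remaining, true_pref)
        if categorize_trial(t, fit) == "fast"
    ]
    fastest_two = sorted(rem_fast, key=lambda t: (t[1].rt, t[0].trial_index))[:2]
    assert {t[0].trial_index for t in preds[:2]} == {
        t[0].trial_index for t in fastest_two
    }


def test_order_search_budget_one_returns_input(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    selected = select_observation_trials(simulated_trials, true_pref, fit)
    out = optimize_trial_order(selected, true_pref, lambda o: 0.0, budget=1)
    assert [t[0].trial_index for t in out] == [t[0].trial_index for t in selected]


def test_order_search_minimises_over_its_candidates(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    selected = select_observation_trials(simulated_trials, true_pref, fit)
    criterion = rl_order_criterion(true_pref)
    best = optimize_trial_order(selected, true_pref, criterion, budget=30, seed=0)
    best_score = criterion(best)
    # regenerate the search's candidate set: the input order plus 29 seeded
    # permutations; the returned order must minimise the criterion over it
    rng = np.random.default_rng(0)
    candidates = [list(range(len(selected)))] + [
        list(rng.permutation(len(selected))) for _ in range(29)
    ]
    scores = [criterion([selected[i] for i in perm]) for perm in candidates]
    assert best_score <= min(scores) + 1e-12


def test_order_search_seeded_reproducible(simulated_trials, true_pref):
    fit = fit_rt_regression(simulated_trials, true_pref)
    selected = select_observation_trials(simulated_trials, true_pref, fit)
    criterion = rl_order_criterion(true_pref)
    a = optimize_trial_order(selected, true_pref, criterion, budget=15, seed=5)
    b = optimize_trial_order(selected, true_pref, criterion, budget=15, seed=5)
    assert [t[0].trial_index for t in a] == [t[0].trial_index for t in b]
    with pytest.raises(ValueError):
        optimize_trial_order(selected, true_pref, criterion, budget=0)


def test_exact_mode_on_tiny_input():
    trials = [_trial(0.1 * i, 0.1 * i + 0.5, "left", 1.0 + 0.1 * i, i) for i in range(4)]

    def criterion(ordered):
        # prefer ascending trial_index lexicographically
        return sum(
            k * t[0].trial_index for k, t in enumerate(ordered)
        )  # minimised by descending index

    out = optimize_trial_order(trials, 0.5, criterion, budget=2, exact_limit=100)
    assert [t[0].trial_index for t in out] == [3, 2, 1, 0]
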