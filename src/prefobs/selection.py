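"""Informative-trial selection for the observation phase.

From a dictator's full set of decisions, the pipeline picks the 12 trials an
observer will see (plus 4 held-out prediction trials) so that both the RTs
and the choices are maximally diagnostic of the preference:

1. regress RT on trial difficulty ``|s(left) - s(right)|`` (slope is
   negative on DDM-like data: easier trials are faster);
2. categorise trials — *slow* trials (RT above the regression intercept)
   indicate the preference sits near the options' midpoint, *fast* trials
   (RT below the line evaluated at the maximal difficulty the pair allows,
   ``b0 + b1 * (left - right)**2``) indicate it lies outside the option
   interval, everything else is uninformative;
3. drop inconsistent choices (the option farther from the preference);
4. keep the 6 fastest fast trials and the 6 slow trials whose midpoint is
   closest to the preference; order them to be learnable; reserve the next
   2 + 2 as prediction problems.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .core import AllocationPair, Decision, difficulty

__all__ = [
    "RTRegressionFit",
    "fit_rt_regression",
    "categorize_trial",
    "filter_inconsistent",
    "select_observation_trials",
    "select_prediction_trials",
    "optimize_trial_order",
    "rl_order_criterion",
]

Trial = tuple[AllocationPair, Decision]
TrialCategory = Literal["fast", "slow", "uninformative"]


@dataclass(frozen=True)
class RTRegressionFit:
    """OLS fit of RT (seconds) on trial difficulty: ``rt = b0 + b1 * d``."""

    b0: float
    b1: float


def fit_rt_regression(trials: Sequence[Trial], preference) -> RTRegressionFit:
    """Ordinary least squares of RT on ``|s(left) - s(right)|``."""
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for the RT regression")
    d = np.array([difficulty(pair, preference) for pair, _ in trials])
    rt = np.array([dec.rt for _, dec in trials])
    if np.ptp(d) == 0:
        raise ValueError("zero variance in trial difficulty; regression undefined")
    b1, b0 = np.polyfit(d, rt, 1)
    if b1 > 0:
        warnings.warn(
            "positive RT-difficulty slope: RTs do not behave like "
            "evidence-accumulation data",
            UserWarning,
            stacklevel=2,
        )
    return RTRegressionFit(b0=float(b0), b1=float(b1))


def categorize_trial(trial: Trial, fit: RTRegressionFit) -> TrialCategory:
    """Label a trial slow / fast / uninformative from the RT regression.

    Slow: RT above the intercept (slower than the hardest possible trial is
    predicted to be, so the preference is likely near the pair midpoint).
    Fast: RT below the line at the pair's maximal attainable difficulty
    ``(left - right)**2`` (faster than any midpoint-preference account
    allows, so the preference lies outside the option interval).
    """
    pair, dec = trial
    if dec.rt > fit.b0:
        return "slow"
    if dec.rt < fit.b0 + fit.b1 * (pair.left - pair.right) ** 2:
        return "fast"
    return "uninformative"


def filter_inconsistent(trials: Sequence[Trial], preference) -> list[Trial]:
    """Drop trials where the chosen allocation is strictly farther from the
    preference than the unchosen one (equidistant options survive)."""
    p = float(preference)
    kept = []
    for pair, dec in trials:
        d_chosen = abs(pair.allocation(dec.choice) - p)
        d_other = abs(pair.other(dec.choice) - p)
        if d_chosen <= d_other + 1e-9:  # equidistant options are kept
            kept.append((pair, dec))
    return kept


def _sorted_fast(trials: Sequence[Trial]) -> list[Trial]:
    # ties in RT broken by trial_index for reproducibility
    return sorted(trials, key=lambda t: (t[1].rt, t[0].trial_index))


def _sorted_slow(trials: Sequence[Trial], preference: float) -> list[Trial]:
    return sorted(
        trials, key=lambda t: (abs(t[0].midpoint - preference), t[0].trial_index)
    )


def _split_informative(
    trials: Sequence[Trial], preference, fit: RTRegressionFit
) -> tuple[list[Trial], list[Trial]]:
    consistent = filter_inconsistent(trials, preference)
    fast = [t for t in consistent if categorize_trial(t, fit) == "fast"]
    slow = [t for t in consistent if categorize_trial(t, fit) == "slow"]
    return fast, slow


def select_observation_trials(
    trials: Sequence[Trial],
    preference,
    fit: RTRegressionFit,
    *,
    n_fast: int = 6,
    n_slow: int = 6,
) -> list[Trial]:
    """The 6 fastest fast trials plus the 6 slow trials whose midpoint is
    closest to the preference (after consistency filtering)."""
    fast, slow = _split_informative(trials, preference, fit)
    if len(fast) < n_fast or len(slow) < n_slow:
        raise ValueError(
            f"selection shortfall: need {n_fast} fast and {n_slow} slow "
            f"informative consistent trials, have {len(fast)} fast / {len(slow)} slow"
        )
    p = float(preference)
    return _sorted_fast(fast)[:n_fast] + _sorted_slow(slow, p)[:n_slow]


def select_prediction_trials(
    trials: Sequence[Trial],
    preference,
    fit: RTRegressionFit,
    *,
    exclude: Sequence[Trial] = (),
    n_fast: int = 2,
    n_slow: int = 2,
) -> list[Trial]:
    """The next 2 fastest fast trials and next 2 midpoint-optimising slow
    trials among those not already used for observation."""
    used = {(t[0].trial_index) for t in exclude}
    remaining = [t for t in trials if t[0].trial_index not in used]
    fast, slow = _split_informative(remaining, preference, fit)
    if len(fast) < n_fast or len(slow) < n_slow:
        raise ValueError(
            f"prediction-trial shortfall: need {n_fast} fast / {n_slow} slow, "
            f"have {len(fast)} / {len(slow)}"
        )
    p = float(preference)
    return _sorted_fast(fast)[:n_fast] + _sorted_slow(slow, p)[:n_slow]


def optimize_trial_order(
    selected: Sequence[Trial],
    preference,
    estimator: Callable[[Sequence[Trial]], float],
    *,
    budget: int = 200,
    seed: int | None = None,
    exact_limit: int = 0,
) -> list[Trial]:
    """Order the selected trials so a learner recovers the preference best.

    ``estimator`` maps an ordered trial sequence to a summed estimation
    error across conditions (smaller is better); the search returns the
    ordering with the smallest criterion.  For ``budget <= 1`` the input
    order is returned unchanged.

    With ``exact_limit > 0`` and ``len(selected)! <= exact_limit`` every
    permutation is scored; otherwise ``budget`` random permutations (always
    including the input order) are scored under the given seed.
    """
    selected = list(selected)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if budget == 1:
        return selected

    n = len(selected)
    candidates: list[tuple] = [tuple(range(n))]
    n_perms = math.factorial(n) if n <= 20 else None
    if exact_limit and n_perms is not None and n_perms <= exact_limit:
        candidates = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(budget - 1):
            candidates.append(tuple(rng.permutation(n)))

    best_order, best_score = None, np.inf
    for perm in candidates:
        ordered = [selected[i] for i in perm]
        score = estimator(ordered)
        if score < best_score:
            best_order, best_score = ordered, score
    return best_order


def rl_order_criterion(preference, rl_params=None) -> Callable[[Sequence[Trial]], float]:
    """Build the default order-search criterion: run the RL forward model in
    every condition on the candidate order and sum |final estimate - P|."""
    from .core import Condition, Observation
    from .observer_rl import RLParams, trajectory
    from .core import ObserverSession

    params = rl_params or RLParams(alpha=0.4, p0=0.5, omega=0.5)
    p = float(preference)

    def criterion(ordered: Sequence[Trial]) -> float:
        total = 0.0
        for cond in Condition:
            obs = [
                Observation(
                    pair=pair,
                    condition=cond,
                    choice=dec.choice if cond.choice_visible else None,
                    rt=dec.rt if cond.rt_visible else None,
                )
                for pair, dec in ordered
            ]
            session = ObserverSession(
                observer_id="order-search",
                dictator_id="order-search",
                condition=cond,
                observations=obs,
                estimation_slots=(len(obs),),
            )
            total += abs(float(trajectory(session, params)[-1]) - p)
        return total

    return criterion
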