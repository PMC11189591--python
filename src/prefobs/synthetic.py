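"""Synthetic-study generator.

Builds complete artificial datasets with the statistical structure the
analysis assumes: a Dictator-Game design of 11 allocation levels in 10%
steps (55 distinct pairs, 3 repeats = 165 trials) with small truncated-
normal per-trial noise on each allocation; DDM-generated choices and RTs
for a cohort of dictators whose preferences span the unit interval; and
observer sessions for the 2x2 (choice x RT visibility) within-subject
design — 16 dictators per observer, 4 per condition, 12 observed trials,
estimation slots before observing and after trials 4 / 8 / 12, and 4
held-out prediction problems (2 fast, 2 slow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AllocationPair, Condition, Decision, Observation, ObserverSession
from .ddm import DDMParams, simulate_decisions

__all__ = [
    "StudyConfig",
    "SyntheticDictator",
    "make_design",
    "sample_dictators",
    "generate_dictator_dataset",
    "select_for_dictator",
    "build_observer_sessions",
    "simulate_observer_cohort",
]


@dataclass(frozen=True)
class StudyConfig:
    """Design constants of a synthetic study (defaults mirror the in-lab
    protocol the generator emulates)."""

    n_dictators: int = 16
    n_observers: int = 46
    allocation_step: float = 0.1
    repeats_per_pair: int = 3  # dictator task; the observer self-task uses 1
    noise_sd: float = 0.02
    noise_bound: float = 0.05
    n_observed: int = 12
    estimation_slots: tuple = (0, 4, 8, 12)
    n_prediction_fast: int = 2
    n_prediction_slow: int = 2

    def __post_init__(self) -> None:
        if self.n_dictators % 4 != 0:
            raise ValueError("n_dictators must be divisible by 4 (2x2 condition blocks)")
        if self.noise_bound < self.noise_sd:
            raise ValueError("noise_bound must be >= noise_sd")
        if min(self.n_dictators, self.n_observers, self.repeats_per_pair) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SyntheticDictator:
    """Ground-truth generative agent: preference plus DDM parameters (and a
    softmax temperature, for choice-rule variants)."""

    dictator_id: str
    preference: float
    ddm: DDMParams
    beta: float = 8.0


def _truncnorm_noise(rng: np.random.Generator, size: int, sd: float, bound: float):
    a, b = -bound / sd, bound / sd
    return stats.truncnorm.rvs(a, b, scale=sd, size=size, random_state=rng)


def make_design(config: StudyConfig, rng: np.random.Generator) -> list[AllocationPair]:
    """The full Dictator-Game design: all distinct pairs of the 11 base
    allocation levels, repeated, with per-trial truncated-normal noise on
    each allocation (clipped to [0, 1]) and balanced left/right assignment.

    Probability-zero post-noise ties are broken by resampling the noise.
    """
    levels = np.round(np.arange(0.0, 1.0 + 1e-9, config.allocation_step), 10)
    base_pairs = [
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    trials = []
    idx = 0
    for lo, hi in base_pairs:
        # balance which side carries the larger allocation across repeats
        orient = np.array([r % 2 == 0 for r in range(config.repeats_per_pair)])
        rng.shuffle(orient)
        for flip in orient:
            a, b = (hi, lo) if flip else (lo, hi)
            while True:
                na, nb = np.clip(
                    np.array([a, b])
                    + _truncnorm_noise(rng, 2, config.noise_sd, config.noise_bound),
                    0.0,
                    1.0,
                )
                if na != nb:
                    break
            trials.append(AllocationPair(left=float(na), right=float(nb), trial_index=idx))
            idx += 1
    return trials


def sample_dictators(
    config: StudyConfig, rng: np.random.Generator
) -> list[SyntheticDictator]:
    """A cohort whose preferences are stratified over [0.05, 0.95] (so every
    condition block can span the range) with DDM parameters in realistic
    mid-ranges of the observer's prior bounds."""
    n = config.n_dictators
    centers = np.linspace(0.05, 0.95, n)
    jitter_room = (centers[1] - centers[0]) / 2 if n > 1 else 0.0
    prefs = np.clip(centers + rng.uniform(-0.5, 0.5, n) * jitter_room, 0.0, 1.0)
    dictators = []
    for i, p in enumerate(prefs):
        ddm = DDMParams(
            boundary=float(rng.uniform(1.5, 2.5)),
            ndt=float(rng.uniform(0.2, 0.4)),
            drift_scale=float(rng.uniform(4.0, 8.0)),
        )
        dictators.append(
            SyntheticDictator(
                dictator_id=f"d{i:02d}",
                preference=float(p),
                ddm=ddm,
                beta=float(rng.uniform(6.0, 12.0)),
            )
        )
    return dictators


def generate_dictator_dataset(
    dictator: SyntheticDictator,
    design: list[AllocationPair],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one decision per design trial; returns the canonical
    dictator-trials table (dictator_id, trial, left, right, choice, rt)."""
    decisions = simulate_decisions(design, dictator.preference, dictator.ddm, rng)
    return pd.DataFrame(
        {
            "dictator_id": dictator.dictator_id,
            "trial": [p.trial_index for p in design],
            "left": [p.left for p in design],
            "right": [p.right for p in design],
            "choice": [d.choice for d in decisions],
            "rt": [d.rt for d in decisions],
        }
    )


def select_for_dictator(
    trials_df: pd.DataFrame,
    preference: float,
    *,
    order_budget: int = 50,
    seed: int | None = None,
):
    """Run the full trial-selection pipeline for one dictator.

    Returns ``(observation_trials, prediction_trials)`` — 12 ordered trials
    and 4 held-out ones — as (pair, decision) tuples.
    """
    from .selection import (
        fit_rt_regression,
        optimize_trial_order,
        rl_order_criterion,
        select_observation_trials,
        select_prediction_trials,
    )

    trials = [
        (
            AllocationPair(left=row.left, right=row.right, trial_index=int(row.trial)),
            Decision(choice=row.choice, rt=row.rt),
        )
        for row in trials_df.itertuples()
    ]
    fit = fit_rt_regression(trials, preference)
    observed = select_observation_trials(trials, preference, fit)
    observed = optimize_trial_order(
        observed, preference, rl_order_criterion(preference), budget=order_budget, seed=seed
    )
    predictions = select_prediction_trials(trials, preference, fit, exclude=observed)
    return observed, predictions


def build_observer_sessions(
    selections: dict,
    dictators: list[SyntheticDictator],
    config: StudyConfig,
    rng: np.random.Generator,
    observer_ids: list[str] | None = None,
) -> list[ObserverSession]:
    """Assemble sessions for each observer: 4 dictators per condition,
    stratified by preference, with choice/RT masked per condition.

    ``selections`` maps dictator_id to ``(observation_trials,
    prediction_trials)`` from :func:`select_for_dictator`.
    """
    if observer_ids is None:
        observer_ids = [f"o{i:02d}" for i in range(config.n_observers)]
    by_id = {d.dictator_id: d for d in dictators}
    ordered = sorted(dictators, key=lambda d: d.preference)
    conditions = list(Condition)
    sessions = []
    for obs_id in observer_ids:
        # deal sorted dictators round-robin into the 4 conditions with a
        # per-observer random rotation, so each condition spans the range
        assignment: dict[str, Condition] = {}
        for block_start in range(0, len(ordered), 4):
            block = ordered[block_start : block_start + 4]
            shift = rng.integers(4)
            for k, d in enumerate(block):
                assignment[d.dictator_id] = conditions[(k + int(shift)) % 4]
        for d_id, cond in assignment.items():
            observed, predictions = selections[d_id]
            observations = [
                Observation(
                    pair=pair,
                    condition=cond,
                    choice=dec.choice if cond.choice_visible else None,
                    rt=dec.rt if cond.rt_visible else None,
                )
                for pair, dec in observed
            ]
            sessions.append(
                ObserverSession(
                    observer_id=obs_id,
                    dictator_id=d_id,
                    condition=cond,
                    observations=observations,
                    estimation_slots=config.estimation_slots,
                    prediction_pairs=[pair for pair, _ in predictions],
                    dictator_prediction_choices=[dec.choice for _, dec in predictions],
                    true_preference=by_id[d_id].preference,
                )
            )
    return sessions


def simulate_observer_cohort(
    sessions: list[ObserverSession],
    agent: str = "rl",
    params=None,
    rng: np.random.Generator | None = None,
    *,
    bo_resolution: int | dict = 15,
) -> pd.DataFrame:
    """Forward-simulate a cohort of observers through their sessions.

    ``agent="rl"`` runs the observational RL model (stochastic slider noise
    and softmax predictions); ``agent="bo"`` runs the Bayes-optimal grid
    observer (deterministic per session; results are cached per dictator x
    condition).  Returns a tidy table with one row per estimate and per
    prediction.
    """
    rng = rng or np.random.default_rng()
    rows = []
    if agent == "rl":
        from .observer_rl import RLParams, simulate_observer

        params = params or RLParams(alpha=0.4, p0=0.5, omega=0.5)
        for s in sessions:
            estimates, predictions = simulate_observer(s, params, rng)
            rows.extend(_session_rows(s, estimates, predictions))
    elif agent == "bo":
        from .bayes_optimal import BayesOptimalObserver

        cache: dict[tuple, tuple] = {}
        for s in sessions:
            key = (s.dictator_id, s.condition)
            if key not in cache:
                bo = BayesOptimalObserver(resolution=bo_resolution).fit(s)
                preds = bo.predict(s.prediction_pairs)
                cache[key] = (list(bo.trajectory_), preds)
            estimates, predictions = cache[key]
            rows.extend(_session_rows(s, estimates, predictions))
    else:
        raise ValueError(f"agent must be 'rl' or 'bo', got {agent!r}")
    return pd.DataFrame(rows)


def _session_rows(s: ObserverSession, estimates, predictions):
    rows = []
    for slot, est in zip(s.estimation_slots, estimates):
        rows.append(
            {
                "observer_id": s.observer_id,
                "dictator_id": s.dictator_id,
                "condition": s.condition.value,
                "kind": "estimate",
                "index": slot,
                "value": est,
                "true_preference": s.true_preference,
                "correct": np.nan,
            }
        )
    for i, (pair, choice) in enumerate(zip(s.prediction_pairs, predictions)):
        truth = (
            s.dictator_prediction_choices[i]
            if s.dictator_prediction_choices is not None
            else None
        )
        rows.append(
            {
                "observer_id": s.observer_id,
                "dictator_id": s.dictator_id,
                "condition": s.condition.value,
                "kind": "prediction",
                "index": i,
                "value": np.nan,
                "true_preference": s.true_preference,
                "correct": float(choice == truth) if truth is not None else np.nan,
            }
        )
    return rows
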