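"""Observational reinforcement-learning model of preference inference.

The observer maintains a running estimate ``P_t`` of the dictator's social
preference and updates it after every observed trial with a delta rule,
``P_t = P_{t-1} + alpha * (O_t - P_{t-1})``.  The teaching signal ``O_t``
depends on what the condition reveals:

* choices visible — 1 if the chosen allocation was the more selfish one,
  0 otherwise;
* RTs visible — slow trials (RT above the running mean for this dictator)
  teach the options' midpoint (the preference probably lies between them);
  fast trials teach the selfishness of the option currently believed to
  have the higher subjective value;
* both visible — an ``omega``-weighted convex mix of the two signals above;
* nothing visible — the options' midpoint on every trial.

Since every outcome lies in [0, 1] and the delta rule is a convex
combination, ``P_t`` can never leave the unit interval.

Slider estimates are modelled as Gaussian reports around ``P_t`` (SD
``sigma``); predictions of the dictator's choices use a softmax with inverse
temperature ``beta_p`` on subjective values at the final estimate.
:class:`ObserverRLModel` fits (alpha, P0, omega, beta_p) per observer by
maximum likelihood with restarts drawn from Beta(1.1, 1.1) for alpha and
Gamma(1.2, 5) for beta_p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .core import (
    AllocationPair,
    Condition,
    Observation,
    ObserverSession,
    Side,
    subjective_value,
)

__all__ = [
    "RLParams",
    "rl_update",
    "classify_speed",
    "outcome_choice",
    "outcome_rt",
    "outcome_both",
    "outcome_none",
    "combined_outcome",
    "trial_outcome",
    "trajectory",
    "simulate_observer",
    "estimation_negloglik",
    "prediction_negloglik",
    "session_negloglik",
    "ObserverRLModel",
    "fit_rl",
]

_LOG_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class RLParams:
    """Free parameters of the observational RL model."""

    alpha: float  # learning rate in [0, 1]
    p0: float  # initial preference estimate in [0, 1]
    omega: float  # RT weight in the both-condition outcome mix, [0, 1]
    sigma: float = 0.1  # SD of the slider-report likelihood (> 0)
    beta_p: float = 8.0  # inverse temperature for predictions (> 0)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1 or not 0 <= self.p0 <= 1 or not 0 <= self.omega <= 1:
            raise ValueError("alpha, p0 and omega must lie in [0, 1]")
        if self.sigma <= 0 or self.beta_p <= 0:
            raise ValueError("sigma and beta_p must be positive")


def rl_update(p_prev: float, outcome: float, alpha: float) -> float:
    """Delta-rule update ``P_t = P_{t-1} + alpha * (O_t - P_{t-1})``."""
    if not 0 <= outcome <= 1:
        raise ValueError("outcome must lie in [0, 1]")
    return p_prev + alpha * (outcome - p_prev)


def classify_speed(rt: float, rt_history_including_current: Sequence[float]) -> str:
    """Label a trial ``"slow"`` iff its RT strictly exceeds the running mean
    of all RTs seen for this dictator *including the current one* — so the
    first trial is never slow."""
    mean_rt = float(np.mean(rt_history_including_current))
    return "slow" if rt > mean_rt else "fast"


def _selfish_indicator(chosen: float, other: float) -> float:
    return 1.0 if chosen > other else 0.0


def outcome_choice(obs: Observation) -> float:
    """Choice-based outcome: 1 iff the chosen allocation is the larger
    (more selfish) of the two."""
    if obs.choice is None:
        raise ValueError("choice not visible in this observation")
    return _selfish_indicator(obs.pair.allocation(obs.choice), obs.pair.other(obs.choice))


def outcome_rt(obs: Observation, p_prev: float, speed: str) -> float:
    """RT-based outcome.  Slow trials teach the midpoint; fast trials teach
    the selfishness of the option with the higher subjective value under the
    current estimate (the choice the dictator is presumed to have made)."""
    if obs.rt is None:
        raise ValueError("rt not visible in this observation")
    if speed == "slow":
        return obs.pair.midpoint
    s_left = subjective_value(obs.pair.left, p_prev)
    s_right = subjective_value(obs.pair.right, p_prev)
    presumed: Side = "left" if s_left >= s_right else "right"
    return _selfish_indicator(obs.pair.allocation(presumed), obs.pair.other(presumed))


def outcome_both(obs: Observation, speed: str) -> float:
    """Literal both-condition outcome: midpoint on slow trials, the choice
    indicator on fast trials (the unweighted variant of the model)."""
    if speed == "slow":
        return obs.pair.midpoint
    return outcome_choice(obs)


def outcome_none(obs: Observation) -> float:
    """No-information outcome: the options' midpoint."""
    return obs.pair.midpoint


def combined_outcome(o_choice: float, o_rt: float, omega: float) -> float:
    """Weighted both-condition outcome ``(1 - omega) * O_Ch + omega * O_RT``."""
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    return (1.0 - omega) * o_choice + omega * o_rt


def trial_outcome(
    obs: Observation,
    p_prev: float,
    rt_history: list[float],
    omega: float,
    *,
    weighted_both: bool = True,
) -> float:
    """Dispatch the per-condition teaching signal for one observation.

    ``rt_history`` is mutated: visible RTs are appended before the speed
    classification, so the running mean includes the current trial.
    """
    cond = obs.condition
    if cond is Condition.NONE:
        return outcome_none(obs)
    if cond is Condition.CHOICE_ONLY:
        return outcome_choice(obs)
    rt_history.append(obs.rt)
    speed = classify_speed(obs.rt, rt_history)
    if cond is Condition.RT_ONLY:
        return outcome_rt(obs, p_prev, speed)
    # both condition
    if weighted_both:
        return combined_outcome(outcome_choice(obs), outcome_rt(obs, p_prev, speed), omega)
    return outcome_both(obs, speed)


def trajectory(
    session: ObserverSession, params: RLParams, *, weighted_both: bool = True
) -> np.ndarray:
    """Deterministic forward pass: the preference estimate before each trial
    and after the last, as an array of length ``n_observations + 1``
    (``trajectory[k]`` is the estimate after ``k`` observations)."""
    p = params.p0
    traj = [p]
    rt_history: list[float] = []
    for obs in session.observations:
        o = trial_outcome(obs, p, rt_history, params.omega, weighted_both=weighted_both)
        p = rl_update(p, o, params.alpha)
        assert -1e-12 <= p <= 1 + 1e-12, "delta rule left the unit interval"
        traj.append(p)
    return np.asarray(traj)


def _predict_prob_left(pair: AllocationPair, p_final: float, beta_p: float) -> float:
    z = beta_p * (subjective_value(pair.left, p_final) - subjective_value(pair.right, p_final))
    return 1.0 / (1.0 + math.exp(-z))


def simulate_observer(
    session: ObserverSession,
    params: RLParams,
    rng: np.random.Generator,
    *,
    weighted_both: bool = True,
) -> tuple[list[float], list[Side]]:
    """Forward-simulate one session: noisy slider estimates at the session's
    estimation slots (Gaussian around the modelled estimate, clipped to
    [0, 1]) and softmax-sampled predictions at the final estimate."""
    traj = trajectory(session, params, weighted_both=weighted_both)
    estimates = [
        float(np.clip(traj[slot] + params.sigma * rng.standard_normal(), 0.0, 1.0))
        for slot in session.estimation_slots
    ]
    p_final = float(traj[-1])
    predictions: list[Side] = []
    for pair in session.prediction_pairs:
        prob_left = _predict_prob_left(pair, p_final, params.beta_p)
        predictions.append("left" if rng.uniform() < prob_left else "right")
    return estimates, predictions


def estimation_negloglik(reported: float, modeled: float, sigma: float) -> float:
    """Negative log of the Gaussian density of the slider report around the
    modelled estimate."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (reported - modeled) / sigma
    return 0.5 * z * z + math.log(sigma * math.sqrt(2.0 * math.pi))


def prediction_negloglik(
    chosen: Side,
    pair: AllocationPair,
    p_final: float,
    beta_p: float,
    *,
    literal_eq14: bool = False,
) -> float:
    """Negative log softmax probability of the predicted choice.

    ``literal_eq14=True`` instead returns the negated probability itself
    (the printed form of the prediction objective, which is a negated
    logistic rather than a log); the default treats the objective as a
    proper negative log-likelihood.
    """
    s_ch = subjective_value(pair.allocation(chosen), p_final)
    s_un = subjective_value(pair.other(chosen), p_final)
    prob = 1.0 / (1.0 + math.exp(beta_p * (s_un - s_ch)))
    if literal_eq14:
        return -prob
    return -math.log(max(prob, _LOG_PROB_FLOOR))


def session_negloglik(
    session: ObserverSession,
    params: RLParams,
    *,
    weighted_both: bool = True,
    literal_eq14: bool = False,
) -> float:
    """Summed estimation + prediction negative log-likelihood of one session
    (requires the observer's reported estimates and predicted choices)."""
    if session.reported_estimates is None:
        raise ValueError("session has no reported estimates to fit")
    traj = trajectory(session, params, weighted_both=weighted_both)
    nll = 0.0
    for slot, reported in zip(session.estimation_slots, session.reported_estimates):
        nll += estimation_negloglik(reported, float(traj[slot]), params.sigma)
    if session.predicted_choices:
        p_final = float(traj[-1])
        for pair, chosen in zip(session.prediction_pairs, session.predicted_choices):
            nll += prediction_negloglik(
                chosen, pair, p_final, params.beta_p, literal_eq14=literal_eq14
            )
    return nll


class _CompiledSession:
    """Parameter-independent precomputation of one session for fast fitting.

    Speed labels depend only on the RT stream, and the choice-based outcome
    only on the data, so both are computed once; the per-parameter forward
    pass then reduces to a handful of float operations per trial.  Produces
    nlls identical to :func:`session_negloglik` (asserted in the tests).
    """

    __slots__ = ("trials", "slots", "reported", "preds", "cond")

    def __init__(self, session: ObserverSession, weighted_both: bool = True):
        if session.reported_estimates is None:
            raise ValueError("session has no reported estimates to fit")
        self.cond = session.condition
        rt_history: list[float] = []
        trials = []
        for obs in session.observations:
            l, r = obs.pair.left, obs.pair.right
            mid = obs.pair.midpoint
            cond = obs.condition
            if cond is Condition.NONE:
                trials.append(("const", mid, l, r, False))
            elif cond is Condition.CHOICE_ONLY:
                trials.append(("const", outcome_choice(obs), l, r, False))
            else:
                rt_history.append(obs.rt)
                slow = classify_speed(obs.rt, rt_history) == "slow"
                if cond is Condition.RT_ONLY:
                    trials.append(("rt", mid, l, r, slow))
                elif weighted_both:
                    trials.append(("mix", outcome_choice(obs), l, r, slow))
                else:
                    o = mid if slow else outcome_choice(obs)
                    trials.append(("const", o, l, r, slow))
        self.trials = trials
        self.slots = tuple(session.estimation_slots)
        self.reported = tuple(session.reported_estimates)
        if session.predicted_choices:
            self.preds = tuple(
                (pair.allocation(ch), pair.other(ch))
                for pair, ch in zip(session.prediction_pairs, session.predicted_choices)
            )
        else:
            self.preds = ()

    @staticmethod
    def _rt_outcome(mid: float, l: float, r: float, slow: bool, p: float) -> float:
        if slow:
            return mid
        presumed_left = (l - p) ** 2 <= (r - p) ** 2
        return 1.0 if presumed_left == (l > r) else 0.0

    def nll(self, alpha, p0, omega, beta_p, sigma, literal_eq14=False) -> float:
        p = p0
        traj = {0: p} if 0 in self.slots else {}
        want = set(self.slots)
        for k, (kind, val, l, r, slow) in enumerate(self.trials, start=1):
            if kind == "const":
                o = val
            elif kind == "rt":
                o = self._rt_outcome(0.5 * (l + r), l, r, slow, p)
            else:  # mix: val is the choice outcome
                o_rt = self._rt_outcome(0.5 * (l + r), l, r, slow, p)
                o = (1.0 - omega) * val + omega * o_rt
            p = p + alpha * (o - p)
            if k in want:
                traj[k] = p
        log_norm = math.log(sigma * math.sqrt(2.0 * math.pi))
        nll = 0.0
        for slot, rep in zip(self.slots, self.reported):
            z = (rep - traj[slot]) / sigma
            nll += 0.5 * z * z + log_norm
        for chosen, unchosen in self.preds:
            z = beta_p * (
                (1.0 - (unchosen - p) ** 2) - (1.0 - (chosen - p) ** 2)
            )
            if literal_eq14:
                nll += -1.0 / (1.0 + math.exp(z))
            else:
                nll += float(np.logaddexp(0.0, z))
        return nll


class ObserverRLModel(BaseEstimator):
    """Maximum-likelihood fit of the observational RL model to one
    observer's sessions.

    Minimises the summed estimation + prediction negative log-likelihood
    over (alpha, P0, omega, beta_p), with the slider-noise SD fixed at
    ``sigma``.  Restart initial values are drawn from Beta(1.1, 1.1) for
    alpha, Gamma(1.2, 5) for beta_p, and uniforms for P0 and omega.

    Attributes
    ----------
    params_ : RLParams
        Best-fitting parameter bundle.
    alpha_, p0_, omega_, beta_p_ : float
        Individual fitted parameters (``sigma`` is fixed, not fitted).
    nll_ : float
        Total negative log-likelihood at the optimum.
    n_restarts_converged_ : int
    """

    def __init__(
        self,
        sigma: float = 0.1,
        n_starts: int = 50,
        random_state: int | None = None,
        beta_max: float = 100.0,
        weighted_both: bool = True,
        literal_eq14: bool = False,
    ):
        self.sigma = sigma
        self.n_starts = n_starts
        self.random_state = random_state
        self.beta_max = beta_max
        self.weighted_both = weighted_both
        self.literal_eq14 = literal_eq14

    def _nll(self, theta, sessions) -> float:
        alpha, p0, omega, beta_p = theta
        return sum(
            s.nll(
                alpha,
                p0,
                omega,
                max(beta_p, 1e-6),
                self.sigma,
                literal_eq14=self.literal_eq14,
            )
            for s in sessions
        )

    def fit(self, X: Sequence[ObserverSession], y=None):
        """Fit to a list of :class:`~prefobs.core.ObserverSession` with
        reported behavior."""
        sessions = [_CompiledSession(s, self.weighted_both) for s in X]
        if not sessions:
            raise ValueError("no sessions to fit")
        bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (1e-2, self.beta_max)]
        rng = np.random.default_rng(self.random_state)
        best = None
        n_ok = 0
        for _ in range(self.n_starts):
            x0 = np.array(
                [
                    rng.beta(1.1, 1.1),
                    rng.uniform(),
                    rng.uniform(),
                    min(rng.gamma(1.2, 5.0), self.beta_max),
                ]
            )
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(self._nll, x0, args=(sessions,), method="L-BFGS-B", bounds=bounds)
            n_ok += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        self.n_restarts_converged_ = n_ok
        self.converged_ = n_ok > 0
        alpha, p0, omega, beta_p = best.x
        self.alpha_ = float(alpha)
        self.p0_ = float(p0)
        self.omega_ = float(omega)
        self.beta_p_ = float(beta_p)
        self.params_ = RLParams(
            alpha=self.alpha_, p0=self.p0_, omega=self.omega_,
            sigma=self.sigma, beta_p=self.beta_p_,
        )
        self.nll_ = float(best.fun)
        return self

    def score(self, X, y=None) -> float:
        """Negative of the total nll on ``X`` (higher is better)."""
        compiled = [_CompiledSession(s, self.weighted_both) for s in X]
        return -self._nll([self.alpha_, self.p0_, self.omega_, self.beta_p_], compiled)


def fit_rl(
    sessions: Sequence[ObserverSession],
    sigma: float = 0.1,
    n_starts: int = 50,
    seed: int | None = None,
) -> tuple[RLParams, float]:
    """Functional wrapper over :class:`ObserverRLModel`; returns
    ``(RLParams, total nll)``."""
    model = ObserverRLModel(sigma=sigma, n_starts=n_starts, random_state=seed).fit(sessions)
    return model.params_, model.nll_
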