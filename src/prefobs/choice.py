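"""Softmax choice model and choice-only preference estimation.

The probability of choosing the left allocation is a logistic function of
the subjective-value difference, ``P(left) = 1 / (1 + exp(beta * (s(right)
- s(left))))``, with inverse temperature ``beta``: beta -> 0 makes choices
random, beta -> inf deterministic value maximisation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .core import AllocationPair, Side, subjective_value

__all__ = [
    "BETA_MAX",
    "choice_prob_left",
    "choice_loglik",
    "ChoicePreferenceSoftmax",
    "fit_preference_choices",
]

#: upper bound on the inverse temperature during fitting (matches the
#: Bayes-optimal observer's grid bound, keeping estimates comparable)
BETA_MAX = 100.0

_PROB_FLOOR = 1e-12


def _s(x, p):
    return 1.0 - (np.asarray(x, dtype=float) - p) ** 2


def choice_prob_left(pair: AllocationPair, preference, beta: float) -> float:
    """Softmax probability of choosing the left option."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    p = float(preference)
    return float(
        expit(beta * (subjective_value(pair.left, p) - subjective_value(pair.right, p)))
    )


def _loglik_arrays(left, right, is_left, p, beta):
    z = beta * (_s(left, p) - _s(right, p))
    prob_left = expit(z)
    prob = np.where(is_left, prob_left, 1.0 - prob_left)
    return float(np.log(np.maximum(prob, _PROB_FLOOR)).sum())


def choice_loglik(
    trials: Sequence[tuple[AllocationPair, Side]], preference, beta: float
) -> float:
    """Summed log-probability of the recorded choices."""
    if len(trials) == 0:
        raise ValueError("empty trial list")
    left = np.array([q.left for q, _ in trials])
    right = np.array([q.right for q, _ in trials])
    is_left = np.array([c == "left" for _, c in trials])
    return _loglik_arrays(left, right, is_left, float(preference), float(beta))


class ChoicePreferenceSoftmax(BaseEstimator):
    """Maximum-likelihood social-preference estimation from choices alone.

    Fits (preference, beta) to a table of binary allocation choices with
    seeded multi-start L-BFGS-B.

    Attributes
    ----------
    preference_ : float
        Fitted social preference in [0, 1].
    beta_ : float
        Fitted inverse temperature in (0, 100].
    loglik_ : float
        Log-likelihood at the optimum.
    at_beta_cap_ : bool
        True when the MLE hit the beta upper bound (near-deterministic data:
        any sufficiently large beta rationalises the choices equally well).
    """

    def __init__(
        self,
        n_starts: int = 10,
        random_state: int | None = None,
        beta_max: float = BETA_MAX,
        min_trials: int = 20,
    ):
        self.n_starts = n_starts
        self.random_state = random_state
        self.beta_max = beta_max
        self.min_trials = min_trials

    def fit(self, X, y=None):
        """Fit on a DataFrame with columns ``left``, ``right``, ``choice``."""
        left = X["left"].to_numpy(float)
        right = X["right"].to_numpy(float)
        is_left = X["choice"].to_numpy() == "left"
        if left.size == 0:
            raise ValueError("empty trial table")
        if left.size < self.min_trials:
            warnings.warn(
                f"only {left.size} trials; estimates may be unstable", UserWarning,
                stacklevel=2,
            )
        bounds = [(1e-3, 1 - 1e-3), (1e-2, self.beta_max)]
        rng = np.random.default_rng(self.random_state)

        def nll(theta):
            return -_loglik_arrays(left, right, is_left, theta[0], theta[1])

        best = None
        for _ in range(self.n_starts):
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        self.preference_ = float(best.x[0])
        self.beta_ = float(best.x[1])
        self.loglik_ = float(-best.fun)
        self.converged_ = bool(best.success)
        self.at_beta_cap_ = bool(self.beta_ >= self.beta_max * (1 - 1e-6))
        if self.at_beta_cap_:
            warnings.warn(
                "inverse temperature hit its upper bound (near-deterministic "
                "choices); preference is identified only up to the "
                "rationalising interval",
                UserWarning,
                stacklevel=2,
            )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probability of choosing left for each row of ``X``."""
        left = X["left"].to_numpy(float)
        right = X["right"].to_numpy(float)
        z = self.beta_ * (_s(left, self.preference_) - _s(right, self.preference_))
        return expit(z)

    def score(self, X, y=None) -> float:
        left = X["left"].to_numpy(float)
        right = X["right"].to_numpy(float)
        is_left = X["choice"].to_numpy() == "left"
        return _loglik_arrays(left, right, is_left, self.preference_, self.beta_)


def fit_preference_choices(
    trials: Sequence[tuple[AllocationPair, Side]],
    n_starts: int = 10,
    seed: int | None = None,
):
    """Functional wrapper over :class:`ChoicePreferenceSoftmax`.

    Returns ``(preference, beta, loglik)``.
    """
    import pandas as pd

    df = pd.DataFrame(
        {
            "left": [q.left for q, _ in trials],
            "right": [q.right for q, _ in trials],
            "choice": [c for _, c in trials],
        }
    )
    est = ChoicePreferenceSoftmax(n_starts=n_starts, random_state=seed).fit(df)
    return est.preference_, est.beta_, est.loglik_
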