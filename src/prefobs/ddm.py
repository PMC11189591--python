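"""Drift-diffusion model of Dictator-Game decisions and preference
estimation from response times.

The dictator's decision between two allocations is a Wiener process whose
per-trial drift is a linear function of the subjective-value difference,
``v_t = drift_scale * (s(left_t) - s(right_t))``; the upper boundary maps to
the left option.  Because hard trials (options equidistant from the
preferred allocation) have near-zero drift and hence long first-passage
times, the distribution of response times alone carries information about
the preference: :class:`RTPreferenceDDM` recovers it by maximising the RT
likelihood marginalised over both choice boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .core import AllocationPair, Decision, subjective_value
from .wfpt import prob_upper, simulate_first_passage, wfpt_pdf

__all__ = [
    "DDMParams",
    "trial_drift",
    "simulate_decision",
    "simulate_decisions",
    "rt_only_loglik",
    "joint_loglik",
    "RTPreferenceDDM",
    "fit_preference_rt",
]

#: density floor used during fitting so response times at or below the
#: candidate non-decision time contribute a large-but-finite penalty instead
#: of -inf, letting the optimiser traverse the ndt axis
DENSITY_FLOOR = 1e-10

PARAM_BOUNDS = {
    "preference": (1e-3, 1.0 - 1e-3),
    "boundary": (0.1, 10.1),
    "ndt": (0.0, 2.0),
    "drift_scale": (0.0, 20.0),
}


@dataclass(frozen=True)
class DDMParams:
    """Generative DDM parameters of one dictator."""

    boundary: float  # separation b > 0
    ndt: float  # non-decision time tau (s)
    drift_scale: float  # maps subjective-value difference to drift
    noise_sd: float = 1.0  # diffusion coefficient (conventionally fixed)
    start_bias: float = 0.5  # relative start point (unbiased)

    def __post_init__(self) -> None:
        if self.boundary <= 0 or self.ndt < 0 or self.drift_scale < 0:
            raise ValueError("boundary must be > 0, ndt >= 0, drift_scale >= 0")
        if self.noise_sd <= 0 or not 0 < self.start_bias < 1:
            raise ValueError("noise_sd must be > 0 and start_bias in (0, 1)")


def trial_drift(pair: AllocationPair, preference, drift_scale: float) -> float:
    """Per-trial drift ``drift_scale * (s(left) - s(right))``."""
    return float(
        drift_scale
        * (subjective_value(pair.left, preference) - subjective_value(pair.right, preference))
    )


def _drifts(left: np.ndarray, right: np.ndarray, p: float, scale: float) -> np.ndarray:
    return scale * ((1.0 - (left - p) ** 2) - (1.0 - (right - p) ** 2))


def simulate_decisions(
    pairs: Sequence[AllocationPair],
    preference,
    params: DDMParams,
    rng: np.random.Generator,
    *,
    dt: float = 1e-3,
) -> list[Decision]:
    """Sample one (choice, rt) per pair from the DDM (vectorised)."""
    p = float(preference)
    left = np.array([q.left for q in pairs])
    right = np.array([q.right for q in pairs])
    v = _drifts(left, right, p, params.drift_scale)
    upper, rt = simulate_first_passage(
        v,
        params.boundary,
        params.ndt,
        rng,
        start_bias=params.start_bias,
        noise_sd=params.noise_sd,
        dt=dt,
    )
    return [Decision("left" if u else "right", float(t)) for u, t in zip(upper, rt)]


def simulate_decision(
    pair: AllocationPair, preference, params: DDMParams, rng: np.random.Generator, **kw
) -> Decision:
    """Sample a single decision; see :func:`simulate_decisions`."""
    return simulate_decisions([pair], preference, params, rng, **kw)[0]


def _validate_arrays(left, right, rt):
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if left.size == 0:
        raise ValueError("empty trial list")
    if np.any(rt <= 0):
        raise ValueError("all response times must be positive")
    return left, right, rt


def _rt_only_loglik_arrays(left, right, rt, p, params: DDMParams, floor=DENSITY_FLOOR):
    v = _drifts(left, right, p, params.drift_scale)
    kw = dict(
        drift=v,
        boundary_sep=params.boundary,
        ndt=params.ndt,
        start_bias=params.start_bias,
        noise_sd=params.noise_sd,
    )
    dens = wfpt_pdf(rt, "upper", **kw) + wfpt_pdf(rt, "lower", **kw)
    return float(np.log(np.maximum(dens, floor)).sum())


def rt_only_loglik(
    trials: Sequence[tuple[AllocationPair, float]], preference, params: DDMParams
) -> float:
    """RT-only log-likelihood: per trial, the WFPT density marginalised over
    the unknown choice, ``sum_t log[f(rt_t, left) + f(rt_t, right)]``."""
    if len(trials) == 0:
        raise ValueError("empty trial list")
    left, right, rt = _validate_arrays(
        [p.left for p, _ in trials], [p.right for p, _ in trials], [r for _, r in trials]
    )
    return _rt_only_loglik_arrays(left, right, rt, float(preference), params)


def joint_loglik(
    trials: Sequence[tuple[AllocationPair, Decision]], preference, params: DDMParams
) -> float:
    """Joint choice+RT log-likelihood: ``sum_t log f(rt_t, choice_t)``."""
    if len(trials) == 0:
        raise ValueError("empty trial list")
    p = float(preference)
    left = np.array([q.left for q, _ in trials])
    right = np.array([q.right for q, _ in trials])
    rt = np.array([d.rt for _, d in trials])
    is_left = np.array([d.choice == "left" for _, d in trials])
    v = _drifts(left, right, p, params.drift_scale)
    kw = dict(
        boundary_sep=params.boundary,
        ndt=params.ndt,
        start_bias=params.start_bias,
        noise_sd=params.noise_sd,
    )
    up = wfpt_pdf(rt, "upper", drift=v, **kw)
    lo = wfpt_pdf(rt, "lower", drift=v, **kw)
    dens = np.where(is_left, up, lo)
    return float(np.log(np.maximum(dens, DENSITY_FLOOR)).sum())


def ddm_choice_prob_left(pair: AllocationPair, preference, params: DDMParams) -> float:
    """Closed-form probability that the DDM chooses the left option."""
    v = trial_drift(pair, preference, params.drift_scale)
    return float(
        prob_upper(v, params.boundary, start_bias=params.start_bias, noise_sd=params.noise_sd)
    )


class RTPreferenceDDM(BaseEstimator):
    """Maximum-likelihood social-preference estimation from response times
    alone (choices unobserved), or jointly from choices and response times.

    Fits (preference, boundary, non-decision time, drift scale) by maximising
    the RT likelihood marginalised over both choice boundaries
    (``mode="rt"``) or the joint choice+RT WFPT likelihood
    (``mode="joint"``), with seeded multi-start L-BFGS-B.

    Parameters
    ----------
    mode : {"rt", "joint"}
        Which likelihood to maximise.
    n_starts : int
        Number of random restarts (initial points drawn uniformly within the
        parameter bounds).
    random_state : int or None
        Seed for the restart draws; fits are reproducible given a seed.
    min_trials : int
        Below this many trials a warning is emitted (the RT-only likelihood
        surface is shallow at small n).

    Attributes
    ----------
    preference_ : float
        Fitted social preference in [0, 1].
    params_ : DDMParams
        Fitted boundary / ndt / drift-scale bundle.
    loglik_ : float
        Log-likelihood at the optimum.
    converged_ : bool
        Whether the best restart reported convergence.
    degenerate_ : bool
        True when the data carry no usable RT gradient (e.g. constant RTs).
    """

    def __init__(
        self,
        mode: str = "rt",
        n_starts: int = 10,
        random_state: int | None = None,
        min_trials: int = 20,
    ):
        self.mode = mode
        self.n_starts = n_starts
        self.random_state = random_state
        self.min_trials = min_trials

    def _objective(self, theta, left, right, rt, is_left):
        p, b, tau, scale = theta
        params = DDMParams(boundary=b, ndt=tau, drift_scale=scale)
        v = _drifts(left, right, p, scale)
        kw = dict(drift=v, boundary_sep=b, ndt=tau)
        if self.mode == "rt":
            dens = wfpt_pdf(rt, "upper", **kw) + wfpt_pdf(rt, "lower", **kw)
        else:
            up = wfpt_pdf(rt, "upper", **kw)
            lo = wfpt_pdf(rt, "lower", **kw)
            dens = np.where(is_left, up, lo)
        return -np.log(np.maximum(dens, DENSITY_FLOOR)).sum()

    def fit(self, X, y=None):
        """Fit on a trial table.

        ``X`` is a pandas DataFrame with columns ``left``, ``right``, ``rt``
        (and ``choice`` in {"left","right"} for ``mode="joint"``), or an
        (n, 3) array of the numeric columns for ``mode="rt"``.
        """
        if self.mode not in ("rt", "joint"):
            raise ValueError(f"mode must be 'rt' or 'joint', got {self.mode!r}")
        if hasattr(X, "columns"):
            left = X["left"].to_numpy(float)
            right = X["right"].to_numpy(float)
            rt = X["rt"].to_numpy(float)
            is_left = (
                (X["choice"].to_numpy() == "left") if "choice" in X.columns else None
            )
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("array input must have shape (n, 3): left, right, rt")
            left, right, rt = arr.T
            is_left = None
        left, right, rt = _validate_arrays(left, right, rt)
        if self.mode == "joint" and is_left is None:
            raise ValueError("mode='joint' requires a 'choice' column")
        n = rt.size
        if n < self.min_trials:
            warnings.warn(
                f"only {n} trials; preference estimates may be unstable below "
                f"{self.min_trials}",
                UserWarning,
                stacklevel=2,
            )

        self.degenerate_ = bool(np.ptp(rt) == 0)
        if self.degenerate_:
            warnings.warn(
                "constant response times: no RT gradient, fit is degenerate",
                UserWarning,
                stacklevel=2,
            )

        bounds = [
            PARAM_BOUNDS["preference"],
            PARAM_BOUNDS["boundary"],
            (0.0, float(rt.min())),
            PARAM_BOUNDS["drift_scale"],
        ]
        rng = np.random.default_rng(self.random_state)
        best = None
        n_ok = 0
        for _ in range(self.n_starts):
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            res = minimize(
                self._objective,
                x0,
                args=(left, right, rt, is_left),
                method="L-BFGS-B",
                bounds=bounds,
            )
            n_ok += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        self.n_restarts_converged_ = n_ok
        self.converged_ = bool(best.success) or n_ok > 0
        if not self.converged_:
            warnings.warn("no restart converged; returning best iterate", UserWarning)
        p, b, tau, scale = best.x
        self.preference_ = float(p)
        self.params_ = DDMParams(boundary=float(b), ndt=float(tau), drift_scale=float(scale))
        self.loglik_ = float(-best.fun)
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of ``X`` under the fitted parameters."""
        left = X["left"].to_numpy(float) if hasattr(X, "columns") else np.asarray(X, float)[:, 0]
        right = X["right"].to_numpy(float) if hasattr(X, "columns") else np.asarray(X, float)[:, 1]
        rt = X["rt"].to_numpy(float) if hasattr(X, "columns") else np.asarray(X, float)[:, 2]
        return _rt_only_loglik_arrays(left, right, rt, self.preference_, self.params_)


def fit_preference_rt(
    trials: Sequence[tuple[AllocationPair, float]],
    n_starts: int = 10,
    seed: int | None = None,
):
    """Functional wrapper over :class:`RTPreferenceDDM`.

    Returns ``(preference, DDMParams, loglik)``.
    """
    import pandas as pd

    df = pd.DataFrame(
        {
            "left": [p.left for p, _ in trials],
            "right": [p.right for p, _ in trials],
            "rt": [r for _, r in trials],
        }
    )
    est = RTPreferenceDDM(n_starts=n_starts, random_state=seed).fit(df)
    return est.preference_, est.params_, est.loglik_
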