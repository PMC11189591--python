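"""Bayes-optimal benchmark observer: sequential grid posterior over the
generative DDM.

The observer assumes the dictator's decisions come from the drift-diffusion
model used throughout the package (drift = drift_scale * subjective-value
difference) and maintains a discretised joint posterior over its five
parameters:

==============  =================  ======================================
parameter        support            prior
==============  =================  ======================================
preference P     (0, 1)             Beta(3.5, 3)
temperature b    (0, 100)           Gamma(shape 1.2, scale 5)
boundary a       (0.1, 10.1)        Gamma(shape 2, scale 2)
drift scale v    (0, 20)            Normal(0, 5) truncated, renormalised
non-dec. T_er    (0.1, 0.5)         uniform
==============  =================  ======================================

Each observed trial multiplies the grid weights by a condition-specific
likelihood — the WFPT density of the observed (choice, RT) when both are
visible, the softmax choice probability when only choices are visible, the
WFPT density summed over both boundaries when only RTs are visible, and a
constant when nothing is visible (the posterior then equals the prior).
Updates accumulate in log space and are renormalised after every trial.

The preference report is the mean of the marginal posterior over P by
default; the joint-MAP cell is available as an alternative point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .core import AllocationPair, Condition, Observation, ObserverSession
from .wfpt import wfpt_pdf

__all__ = [
    "GRID_BOUNDS",
    "PosteriorGrid",
    "init_grid",
    "trial_log_likelihood",
    "update_posterior",
    "BayesOptimalObserver",
]

GRID_BOUNDS = {
    "preference": (0.0, 1.0),
    "beta": (0.0, 100.0),
    "boundary": (0.1, 10.1),
    "drift_scale": (0.0, 20.0),
    "ndt": (0.1, 0.5),
}

_AXES = ("preference", "beta", "boundary", "drift_scale", "ndt")


def _prior_density(axis: str, x: np.ndarray) -> np.ndarray:
    if axis == "preference":
        return stats.beta.pdf(x, 3.5, 3.0)
    if axis == "beta":
        return stats.gamma.pdf(x, a=1.2, scale=5.0)
    if axis == "boundary":
        return stats.gamma.pdf(x, a=2.0, scale=2.0)
    if axis == "drift_scale":
        return stats.norm.pdf(x, 0.0, 5.0)  # truncation handled by the bounds
    if axis == "ndt":
        return np.ones_like(x)
    raise KeyError(axis)


@dataclass
class PosteriorGrid:
    """Discretised joint distribution over the five DDM parameters.

    ``log_weights`` has one axis per parameter in the order
    (preference, beta, boundary, drift_scale, ndt); weights are kept
    normalised (logsumexp == 0) after every update.
    """

    centers: dict = field(default_factory=dict)  # axis -> 1-D array of cell centers
    log_weights: np.ndarray = None

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def normalize(self) -> None:
        self.log_weights = self.log_weights - logsumexp(self.log_weights)

    def marginal(self, axis: str) -> np.ndarray:
        """Normalised marginal weights along one named axis."""
        i = _AXES.index(axis)
        other = tuple(j for j in range(5) if j != i)
        w = self.weights.sum(axis=other)
        return w / w.sum()

    def marginal_mean(self, axis: str) -> float:
        return float(np.dot(self.marginal(axis), self.centers[axis]))

    def marginal_sd(self, axis: str) -> float:
        w = self.marginal(axis)
        c = self.centers[axis]
        m = np.dot(w, c)
        return float(np.sqrt(np.dot(w, (c - m) ** 2)))

    def joint_map(self) -> dict:
        """Cell-center parameter tuple with the highest joint weight."""
        idx = np.unravel_index(int(np.argmax(self.log_weights)), self.log_weights.shape)
        return {axis: float(self.centers[axis][i]) for axis, i in zip(_AXES, idx)}

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(
            centers={k: v.copy() for k, v in self.centers.items()},
            log_weights=self.log_weights.copy(),
        )


def init_grid(resolution: int | dict = 15) -> PosteriorGrid:
    """Build the prior grid: equal-width bins per axis, cell centers at bin
    midpoints, weights proportional to the product of prior densities."""
    if isinstance(resolution, int):
        resolution = {axis: resolution for axis in _AXES}
    centers = {}
    log_marginals = []
    for axis in _AXES:
        n = int(resolution[axis])
        if n < 2:
            raise ValueError(f"resolution for {axis} must be >= 2")
        lo, hi = GRID_BOUNDS[axis]
        edges = np.linspace(lo, hi, n + 1)
        c = 0.5 * (edges[:-1] + edges[1:])
        centers[axis] = c
        dens = _prior_density(axis, c)
        dens = dens / dens.sum()
        log_marginals.append(np.log(dens))
    lw = (
        log_marginals[0][:, None, None, None, None]
        + log_marginals[1][None, :, None, None, None]
        + log_marginals[2][None, None, :, None, None]
        + log_marginals[3][None, None, None, :, None]
        + log_marginals[4][None, None, None, None, :]
    )
    grid = PosteriorGrid(centers=centers, log_weights=lw)
    grid.normalize()
    return grid


def _wfpt_log_terms(grid: PosteriorGrid, pair: AllocationPair, rt: float):
    """log WFPT densities at both boundaries on the (P, a, v, T) sub-grid,
    returned with a broadcastable beta axis inserted."""
    p = grid.centers["preference"]
    ds = (1.0 - (pair.left - p) ** 2) - (1.0 - (pair.right - p) ** 2)  # s(left)-s(right)
    drift = (
        ds[:, None, None, None] * grid.centers["drift_scale"][None, None, :, None]
    )
    a = grid.centers["boundary"][None, :, None, None]
    tau = grid.centers["ndt"][None, None, None, :]
    up = wfpt_pdf(rt, "upper", drift=drift, boundary_sep=a, ndt=tau)
    lo = wfpt_pdf(rt, "lower", drift=drift, boundary_sep=a, ndt=tau)
    return up[:, None], lo[:, None]  # -> (P, 1, a, v, T)


def trial_log_likelihood(grid: PosteriorGrid, obs: Observation) -> np.ndarray:
    """Per-cell log-likelihood of one observation, broadcastable against the
    grid's log-weights."""
    cond = obs.condition
    if cond is Condition.NONE:
        return np.zeros((1,) * 5)
    if cond is Condition.CHOICE_ONLY:
        p = grid.centers["preference"]
        s_diff = (1.0 - (obs.pair.left - p) ** 2) - (1.0 - (obs.pair.right - p) ** 2)
        z = s_diff[:, None] * grid.centers["beta"][None, :]
        prob_left = expit(z)
        prob = prob_left if obs.choice == "left" else 1.0 - prob_left
        out = np.log(np.maximum(prob, 1e-300))
        return out[:, :, None, None, None]
    up, lo = _wfpt_log_terms(grid, obs.pair, obs.rt)
    if cond is Condition.RT_ONLY:
        dens = up + lo
    else:  # BOTH: density at the observed boundary (upper = left)
        dens = up if obs.choice == "left" else lo
    return np.log(np.maximum(dens, 1e-300))


def update_posterior(grid: PosteriorGrid, obs: Observation) -> PosteriorGrid:
    """Multiply in one observation's likelihood and renormalise (in place)."""
    ll = trial_log_likelihood(grid, obs)
    lw = grid.log_weights + ll
    total = logsumexp(lw)
    if not np.isfinite(total):
        raise ValueError(
            f"all-zero likelihood updating on trial {obs.pair.trial_index} "
            f"(condition {obs.condition.value}, rt={obs.rt})"
        )
    grid.log_weights = lw - total
    return grid


class BayesOptimalObserver(BaseEstimator):
    """Sequential Bayes-optimal preference inference on a parameter grid.

    ``fit(session)`` replays the session's observation stream through
    :func:`update_posterior` and records the marginal-preference estimate at
    every estimation slot.

    Parameters
    ----------
    resolution : int or dict
        Grid points per axis (dict keys: preference, beta, boundary,
        drift_scale, ndt).
    estimator : {"mean", "map"}
        Point estimate: marginal posterior mean over preference (default) or
        the preference coordinate of the joint-MAP cell.

    Attributes
    ----------
    grid_ : PosteriorGrid
        Posterior after all observations.
    preference_estimate_ : float
    trajectory_ : list of float
        Estimate at each estimation slot of the fitted session.
    marginal_sd_ : float
        Posterior SD of the preference marginal.
    """

    def __init__(self, resolution: int | dict = 15, estimator: str = "mean"):
        self.resolution = resolution
        self.estimator = estimator

    def _point_estimate(self, grid: PosteriorGrid) -> float:
        if self.estimator == "mean":
            return grid.marginal_mean("preference")
        if self.estimator == "map":
            return grid.joint_map()["preference"]
        raise ValueError(f"estimator must be 'mean' or 'map', got {self.estimator!r}")

    def fit(self, X: ObserverSession, y=None):
        session = X
        grid = init_grid(self.resolution)
        slots = set(session.estimation_slots)
        trajectory = []
        if 0 in slots:
            trajectory.append(self._point_estimate(grid))
        for k, obs in enumerate(session.observations, start=1):
            update_posterior(grid, obs)
            if k in slots:
                trajectory.append(self._point_estimate(grid))
        self.grid_ = grid
        self.trajectory_ = trajectory
        self.preference_estimate_ = self._point_estimate(grid)
        self.marginal_sd_ = grid.marginal_sd("preference")
        return self

    def predict_proba_left(self, pair: AllocationPair) -> float:
        """Posterior-predictive probability of choosing the left option:
        the softmax probability averaged over the (P, beta) marginal."""
        grid = self.grid_
        w2 = grid.weights.sum(axis=(2, 3, 4))
        w2 = w2 / w2.sum()
        p = grid.centers["preference"]
        s_diff = (1.0 - (pair.left - p) ** 2) - (1.0 - (pair.right - p) ** 2)
        prob = expit(s_diff[:, None] * grid.centers["beta"][None, :])
        return float((w2 * prob).sum())

    def predict(self, pairs) -> list:
        """Most likely choice for each pair under the posterior predictive."""
        return [
            "left" if self.predict_proba_left(p) >= 0.5 else "right" for p in pairs
        ]
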