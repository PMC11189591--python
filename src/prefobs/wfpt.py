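"""Wiener first-passage-time (WFPT) primitives for the drift-diffusion model.

A decision is modelled as a Wiener process with drift ``v`` and unit diffusion
coefficient between two absorbing boundaries at 0 and ``a`` (the boundary
separation), starting at relative position ``w`` (0.5 = unbiased).  The time
of first absorption is the decision time; observed response time adds a
non-decision offset ``ndt``.

The density of absorption at a given boundary is evaluated with the standard
pair of series expansions — a small-time expansion (sum over image charges)
and a large-time expansion (sine series) — switching to whichever needs fewer
terms for a requested truncation error (default 1e-6).  All functions are
vectorised over numpy arrays.

Conventions used throughout the package: the *upper* boundary corresponds to
the *left* option, and the per-trial drift is
``drift_scale * (s(left) - s(right))``, so a positive subjective-value
advantage for the left option drives the process toward its boundary.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "wfpt_pdf",
    "prob_upper",
    "simulate_first_passage",
]

_MAX_TERMS = 120


def _fpt_density_unit(tt: np.ndarray, w: float, err: float) -> np.ndarray:
    """First-passage density at the lower boundary for a zero-drift unit
    process on normalised time ``tt = t / a**2``."""
    tt = np.asarray(tt, dtype=float)
    out = np.zeros_like(tt)
    pos = tt > 0
    if not np.any(pos):
        return out
    ttp = tt[pos]

    # term counts for the requested truncation error (standard bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * ttp) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * ttp * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(ttp) + 1.0)
        arg_l = np.pi * ttp * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * ttp)),
            1.0 / (np.pi * np.sqrt(ttp)),
        )
        kl = np.maximum(kl, 1.0)

    use_small = ks < kl
    dens = np.zeros_like(ttp)

    if np.any(use_small):
        t_s = ttp[use_small]
        K = int(min(np.ceil(ks[use_small].max()), _MAX_TERMS))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2 + 1
        k = np.arange(lo, hi, dtype=float)[:, None]
        terms = (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * t_s[None, :]))
        dens[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * t_s**3)

    if np.any(~use_small):
        t_l = ttp[~use_small]
        K = int(min(np.ceil(kl[~use_small].max()), _MAX_TERMS))
        k = np.arange(1, K + 1, dtype=float)[:, None]
        terms = k * np.exp(-(k**2) * np.pi**2 * t_l[None, :] / 2.0) * np.sin(k * np.pi * w)
        dens[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(dens, 0.0)
    return out


def wfpt_pdf(
    t,
    boundary: str,
    *,
    drift,
    boundary_sep,
    ndt=0.0,
    start_bias: float = 0.5,
    noise_sd: float = 1.0,
    err: float = 1e-6,
):
    """Density of first passage at the named boundary at response time ``t``.

    Parameters
    ----------
    t : float or array
        Response time(s) in seconds; times at or below ``ndt`` get density 0.
    boundary : {"upper", "lower"}
        Which absorbing boundary the process hit (upper = left option).
    drift, boundary_sep, ndt, start_bias, noise_sd :
        DDM parameters; broadcastable against ``t``.
    err :
        Series truncation tolerance.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t = np.asarray(t, dtype=float)
    v = np.asarray(drift, dtype=float)
    a = np.asarray(boundary_sep, dtype=float)
    tau = np.asarray(ndt, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(a)) and np.all(np.isfinite(tau))):
        raise ValueError("DDM parameters must be finite")
    if np.any(a <= 0) or np.any(tau < 0) or noise_sd <= 0:
        raise ValueError("boundary_sep must be > 0, ndt >= 0, noise_sd > 0")
    if not 0.0 < start_bias < 1.0:
        raise ValueError("start_bias must lie in (0, 1)")

    # rescale to unit diffusion coefficient
    v = v / noise_sd
    a = a / noise_sd
    w = start_bias
    if boundary == "upper":
        v, w = -v, 1.0 - w

    t, v, a, tau = np.broadcast_arrays(t, v, a, tau)
    td = t - tau  # decision time
    tt = np.where(td > 0, td / a**2, 0.0)
    dens_unit = _fpt_density_unit(tt, w, err)
    with np.errstate(over="ignore"):
        scale = np.exp(-v * a * w - v**2 * np.where(td > 0, td, 0.0) / 2.0) / a**2
    out = np.where(td > 0, dens_unit * scale, 0.0)
    return out if out.ndim else float(out)


def prob_upper(drift, boundary_sep, start_bias: float = 0.5, noise_sd: float = 1.0):
    """Closed-form probability that the process is absorbed at the upper
    boundary: ``expm1(-2 v w a) / expm1(-2 v a)`` (``w`` at zero drift).

    For an unbiased start this reduces to the logistic ``1/(1 + exp(-v a))``.
    """
    v = np.asarray(drift, dtype=float) / noise_sd
    a = np.asarray(boundary_sep, dtype=float) / noise_sd
    w = start_bias
    with np.errstate(over="ignore", invalid="ignore"):
        p = np.where(
            np.abs(v) < 1e-12,
            w,
            np.expm1(-2.0 * v * w * a) / np.expm1(-2.0 * v * a),
        )
    return p if p.ndim else float(p)


def simulate_first_passage(
    drift,
    boundary_sep,
    ndt,
    rng: np.random.Generator,
    *,
    n: int | None = None,
    start_bias: float = 0.5,
    noise_sd: float = 1.0,
    dt: float = 1e-3,
    max_time: float = 30.0,
    max_resample: int = 10,
    bridge: bool = True,
):
    """Euler–Maruyama simulation of the two-boundary diffusion.

    Returns ``(upper, rt)``: boolean array marking absorption at the upper
    boundary, and response times including ``ndt``.  ``drift`` may be an
    array (one value per simulated trial).  Paths that fail to absorb within
    ``max_time`` are resampled; persistent non-absorption raises after
    ``max_resample`` rounds with a warning on each round.

    With ``bridge=True`` (default), within-step boundary crossings are
    detected via the Brownian-bridge crossing probability
    ``exp(-2 d0 d1 / (sigma^2 dt))``, removing the leading-order
    discretisation bias of plain Euler–Maruyama.
    """
    v = np.atleast_1d(np.asarray(drift, dtype=float))
    if n is not None:
        v = np.broadcast_to(v, (n,)).copy() if v.size == 1 else v
        if v.size != n:
            raise ValueError("drift length incompatible with n")
    m = v.size
    a = float(boundary_sep)
    if a <= 0 or ndt < 0:
        raise ValueError("boundary_sep must be > 0 and ndt >= 0")

    rt = np.full(m, np.nan)
    upper = np.zeros(m, dtype=bool)
    pending = np.arange(m)
    sqrt_dt = np.sqrt(dt) * noise_sd
    n_steps = int(np.ceil(max_time / dt))

    for attempt in range(max_resample):
        if pending.size == 0:
            break
        x = np.full(pending.size, start_bias * a)
        alive = np.ones(pending.size, dtype=bool)
        t_abs = np.full(pending.size, np.nan)
        hit_up = np.zeros(pending.size, dtype=bool)
        vp = v[pending]
        var_dt = (noise_sd**2) * dt
        for step in range(1, n_steps + 1):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            x_old = x[idx].copy()
            x[idx] += vp[idx] * dt + sqrt_dt * rng.standard_normal(idx.size)
            hit_hi = x[idx] >= a
            hit_lo = x[idx] <= 0.0
            if bridge:
                inside = ~(hit_hi | hit_lo)
                if np.any(inside):
                    xi0, xi1 = x_old[inside], x[idx][inside]
                    p_hi = np.exp(-2.0 * (a - xi0) * (a - xi1) / var_dt)
                    p_lo = np.exp(-2.0 * xi0 * xi1 / var_dt)
                    u = rng.uniform(size=(2, xi0.size))
                    cross_hi = u[0] < p_hi
                    cross_lo = u[1] < p_lo
                    both = cross_hi & cross_lo
                    cross_hi[both] = p_hi[both] >= p_lo[both]
                    cross_lo[both] = ~cross_hi[both]
                    sub = np.zeros(idx.size, dtype=bool)
                    sub[inside] = cross_hi
                    hit_hi |= sub
                    sub = np.zeros(idx.size, dtype=bool)
                    sub[inside] = cross_lo
                    hit_lo |= sub
            done = hit_hi | hit_lo
            if np.any(done):
                d = idx[done]
                t_abs[d] = step * dt
                hit_up[d] = hit_hi[done]
                alive[d] = False
        finished = ~alive
        fin_idx = pending[finished]
        rt[fin_idx] = t_abs[finished] + ndt
        upper[fin_idx] = hit_up[finished]
        pending = pending[alive]
        if pending.size:
            warnings.warn(
                f"{pending.size} diffusion path(s) not absorbed within "
                f"{max_time}s; resampling (round {attempt + 1})",
                RuntimeWarning,
                stacklevel=2,
            )
    if pending.size:
        raise RuntimeError(f"{pending.size} path(s) never absorbed; check parameters")
    return upper, rt
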