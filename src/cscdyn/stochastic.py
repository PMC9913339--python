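"""Parameter white noise: Wiener-driven rates and trajectory bundles.

Environmental and intrinsic variability is modelled by letting one rate
parameter (typically the mitotic rate ``lambda_mitotic``, the DC death
rate ``d`` or the plasticity amplitude ``q0``) evolve as an unbiased
Wiener process around its base value::

    d theta_t = rho dW_t,      theta(0) = theta_0,

so the parameter's marginal distribution at time t is Normal(theta_0,
rho^2 t).  The noise is independent of the system state, so each
realization is an ordinary non-autonomous ODE driven by a pre-drawn
parameter path; the integrator exploits this by generating the Wiener path
on a fine fixed step grid and advancing the state with a Heun (2nd-order
Runge-Kutta) rule using the mid-step parameter value.

The response of the model is quantified on *bundles* of N independent
realizations: at each output time the spread of each variable across the
bundle is summarized by an unbinned Gaussian maximum-likelihood fit, whose
closed form is the sample mean and the (1/N) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    DIVERGENCE_CEILING,
    DEFAULT_INIT,
    ModelParams,
    State,
    Trajectory,
    _rhs_raw,
)

__all__ = [
    "NoiseSpec",
    "Bundle",
    "WidthSeries",
    "wiener_path",
    "simulate_stochastic",
    "simulate_bundle",
    "simulate_parameter_path_ode",
    "bundle_width",
    "width_growth_check",
]

NOISE_TARGETS = ("lambda_mitotic", "d", "q0", "eta", "psi", "alpha_a", "alpha_m")


@dataclass(frozen=True)
class NoiseSpec:
    """Which parameter fluctuates, and how strongly.

    ``rho`` is the Wiener amplitude: a fraction of the base parameter value
    in ``relative`` mode (the default; realistic amplitudes are 5-20%), or
    in the parameter's own units in ``absolute`` mode.
    """

    target: str = "lambda_mitotic"
    rho: float = 0.10
    amplitude_mode: str = "relative"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.target not in NOISE_TARGETS:
            raise ValueError(f"noise target must be one of {NOISE_TARGETS}, got {self.target!r}")
        if self.amplitude_mode not in ("relative", "absolute"):
            raise ValueError("amplitude_mode must be 'relative' or 'absolute'")
        if self.rho <= 0:
            raise ValueError("rho must be strictly positive")
        if self.amplitude_mode == "relative" and not (0.05 <= self.rho <= 0.20):
            warnings.warn(
                f"relative noise amplitude {self.rho} outside the realistic 5-20% range",
                stacklevel=2,
            )

    def rho_absolute(self, p: ModelParams) -> float:
        base = getattr(p, self.target)
        return self.rho * base if self.amplitude_mode == "relative" else self.rho


def wiener_path(t_grid, rho: float, seed=None) -> np.ndarray:
    """Sample a Wiener path W on ``t_grid`` with W(t_grid[0]) = 0.

    Increments over a step of length dt are Normal(0, rho^2 dt); the same
    seed always reproduces the same path.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    t = np.asarray(t_grid, dtype=float)
    dt = np.diff(t)
    if t.ndim != 1 or np.any(dt <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    incr = rng.standard_normal(dt.size) * (rho * np.sqrt(dt))
    return np.concatenate([[0.0], np.cumsum(incr)])


@dataclass
class WidthSeries:
    """Per-variable bundle width sigma(t) and fitted means mu(t)."""

    times: np.ndarray
    sigma: dict  # variable name -> array over times
    mu: dict
    n_used: int = 0

    def __post_init__(self) -> None:
        for v, s in self.sigma.items():
            if np.any(np.asarray(s) < 0):
                raise ValueError(f"sigma[{v}] must be non-negative")


@dataclass
class Bundle:
    """N stochastic realizations on a common output grid.

    ``states`` has shape (n, n_times, 4); ``param_paths`` (n, n_times)
    holds the noised parameter.  ``flags[i]`` is a set drawn from
    {"nonphysical_parameter", "divergence"}.
    """

    times: np.ndarray
    states: np.ndarray
    param_paths: np.ndarray
    noise: NoiseSpec
    base_params: ModelParams
    seeds: Sequence[int]
    flags: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            states=self.states[i],
            params_used=self.base_params,
            param_path={self.noise.target: self.param_paths[i]},
            metadata={"seed": self.seeds[i], "flags": sorted(self.flags[i])},
        )

    def mean_states(self, include_flagged: bool = True) -> np.ndarray:
        """Pointwise arithmetic mean trajectory across the bundle."""
        idx = self._usable(include_flagged)
        return self.states[idx].mean(axis=0)

    def _usable(self, include_flagged: bool) -> np.ndarray:
        if include_flagged:
            return np.arange(self.n)
        return np.array([i for i in range(self.n) if not self.flags[i]], dtype=int)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _em_bundle(
    p: ModelParams,
    noise: NoiseSpec,
    init: State,
    t_end: float,
    seeds: Sequence[int],
    dt: float,
    dt_out: float,
    divergence_ceiling: float,
) -> Bundle:
    """Fixed-step Heun integration of all realizations simultaneously."""
    n = len(seeds)
    steps_per_out = max(int(round(dt_out / dt)), 1)
    dt = dt_out / steps_per_out
    n_out = max(int(round(t_end / dt_out)), 1)
    t_out = np.linspace(0.0, n_out * dt_out, n_out + 1)
    n_steps = n_out * steps_per_out

    rho = noise.rho_absolute(p)
    base_value = getattr(p, noise.target)
    # parameter path on the step grid, one column per realization
    theta = np.empty((n_steps + 1, n))
    for j, s in enumerate(seeds):
        theta[:, j] = base_value + wiener_path(
            np.linspace(0.0, t_end, n_steps + 1), rho, seed=s
        )

    y = np.tile(init.as_array()[:, None], (1, n))  # (4, n)
    out = np.empty((n, n_out + 1, 4))
    out[:, 0, :] = y.T
    diverged = np.zeros(n, dtype=bool)

    base = {
        "lambda_mitotic": np.full(n, p.lambda_mitotic),
        "d": np.full(n, p.d),
        "q0": np.full(n, p.q0),
    }
    varied_core = noise.target in base

    def rhs(S, D, a, m, th):
        if varied_core:
            rates = dict(base)
            rates[noise.target] = th
            return np.array(
                _rhs_raw(S, D, a, m, rates["lambda_mitotic"], rates["d"], rates["q0"], p)
            )
        # structural parameters (eta, psi, alpha_a, alpha_m): loop per value
        out_ = np.empty((4, S.size))
        for j in range(S.size):
            pj = p.replace(**{noise.target: max(th[j], 1e-12)})
            out_[:, j] = _rhs_raw(S[j], D[j], a[j], m[j], pj.lambda_mitotic, pj.d, pj.q0, pj)
        return out_

    k = 0
    for o in range(1, n_out + 1):
        for _ in range(steps_per_out):
            th_mid = 0.5 * (theta[k] + theta[k + 1])
            S, D, a, m = y
            f1 = rhs(S, D, a, m, th_mid)
            yp = y + dt * f1
            np.maximum(yp, 0.0, out=yp)
            f2 = rhs(yp[0], yp[1], yp[2], yp[3], th_mid)
            ynew = y + 0.5 * dt * (f1 + f2)
            np.maximum(ynew, 0.0, out=ynew)
            tot = ynew[0] + ynew[1]
            over = tot > 1.0
            if np.any(over):
                ynew[0, over] /= tot[over]
                ynew[1, over] /= tot[over]
            newly_div = (~diverged) & (ynew[2] > divergence_ceiling)
            diverged |= newly_div
            ynew[:, diverged] = y[:, diverged]  # freeze divergent runs
            y = ynew
            k += 1
        out[:, o, :] = y.T

    param_out = theta[::steps_per_out].T.copy()  # (n, n_out+1)
    flags = []
    for i in range(n):
        fl = set()
        if np.any(theta[:, i] <= 0):
            fl.add("nonphysical_parameter")
        if diverged[i]:
            fl.add("divergence")
        flags.append(fl)

    return Bundle(
        times=t_out,
        states=out,
        param_paths=param_out,
        noise=noise,
        base_params=p,
        seeds=list(seeds),
        flags=flags,
        metadata={"dt": dt, "dt_out": dt_out, "scheme": "heun_midpoint_parameter"},
    )


def simulate_stochastic(
    p: ModelParams,
    noise: NoiseSpec,
    init: State = DEFAULT_INIT,
    t_end: float = 10.0,
    seed: Optional[int] = None,
    *,
    dt: float = 1e-3,
    dt_out: float = 0.05,
    divergence_ceiling: float = DIVERGENCE_CEILING,
) -> Trajectory:
    """One realization of the model with a Wiener-fluctuating parameter.

    The joint path of (S, D, a, m) and the noised parameter is returned as
    a :class:`Trajectory` with ``param_path``; realizations whose parameter
    leaves (0, inf) carry the flag ``nonphysical_parameter``.
    """
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    b = _em_bundle(p, noise, init, t_end, [seed], dt, dt_out, divergence_ceiling)
    traj = b.trajectory(0)
    if b.flags[0] & {"divergence"}:
        traj.events.append((float("nan"), "divergence"))
    return traj


def simulate_bundle(
    p: ModelParams,
    noise: NoiseSpec,
    init: State = DEFAULT_INIT,
    t_end: float = 10.0,
    n: int = 20,
    base_seed: int = 0,
    *,
    dt: float = 1e-3,
    dt_out: float = 0.05,
    divergence_ceiling: float = DIVERGENCE_CEILING,
) -> Bundle:
    """N independent realizations, seeded ``base_seed + index``."""
    if n < 2:
        raise ValueError("a bundle needs n >= 2 realizations")
    seeds = [base_seed + i for i in range(n)]
    return _em_bundle(p, noise, init, t_end, seeds, dt, dt_out, divergence_ceiling)


def simulate_parameter_path_ode(
    p: ModelParams,
    target: str,
    t_path: np.ndarray,
    theta_path: np.ndarray,
    init: State,
    t_end: float,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    t_eval: Optional[np.ndarray] = None,
) -> Trajectory:
    """Solve the non-autonomous ODE for a *given* parameter path.

    Because the noise is independent of the system state, a stochastic
    realization is exactly the solution of the deterministic system with
    the pre-drawn, linearly interpolated parameter path; this high-order
    adaptive route is the independent oracle for the fixed-step integrator.
    """
    t_path = np.asarray(t_path, float)
    theta_path = np.asarray(theta_path, float)

    def theta(t):
        return np.interp(t, t_path, theta_path)

    def rhs(t, y):
        S, D, a, m = np.maximum(y, 0.0)
        if S + D > 1.0:
            tot = S + D
            S, D = S / tot, D / tot
        th = theta(t)
        lam, d, q0 = p.lambda_mitotic, p.d, p.q0
        if target == "lambda_mitotic":
            lam = th
        elif target == "d":
            d = th
        elif target == "q0":
            q0 = th
        else:
            return _rhs_raw(S, D, a, m, lam, d, q0, p.replace(**{target: max(th, 1e-12)}))
        return _rhs_raw(S, D, a, m, lam, d, q0, p)

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(rhs, (0.0, t_end), init.as_array(), method="RK45", rtol=rtol, atol=atol, t_eval=t_eval, max_step=0.05)
    return Trajectory(
        times=sol.t,
        states=np.maximum(sol.y.T, 0.0),
        params_used=p,
        param_path={target: theta(sol.t)},
        metadata={"oracle": True},
    )


# ---------------------------------------------------------------------------
# Bundle width
# ---------------------------------------------------------------------------

def _gaussian_mle(x: np.ndarray):
    """Closed-form unbinned Gaussian MLE: mean and 1/N standard deviation."""
    if np.ptp(x) == 0.0:
        return float(x[0]), 0.0
    mu = float(np.mean(x))
    sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
    return mu, sigma


def bundle_width(
    b: Bundle,
    t: Optional[float] = None,
    variables: Sequence[str] = ("S", "D", "m"),
    include_flagged: bool = False,
    include_parameter: bool = False,
) -> WidthSeries:
    """Bundle width sigma(t) per variable via the unbinned Gaussian MLE.

    By default the activator ``a`` is excluded (it is a numerical zero in
    the fixed-point regimes of interest) and flagged realizations are
    dropped.  Pass ``t`` to restrict the series to the closest grid time.
    """
    idx = b._usable(include_flagged)
    if idx.size < 2:
        raise ValueError("need at least 2 usable realizations for a width fit")
    cols = {"S": 0, "D": 1, "a": 2, "m": 3}
    if t is None:
        times = b.times
        sel = np.arange(b.times.size)
    else:
        k = int(np.argmin(np.abs(b.times - t)))
        times = b.times[k : k + 1]
        sel = np.array([k])

    sigma, mu = {}, {}
    for v in variables:
        s_arr = np.empty(sel.size)
        m_arr = np.empty(sel.size)
        for j, k in enumerate(sel):
            m_arr[j], s_arr[j] = _gaussian_mle(b.states[idx, k, cols[v]])
        sigma[v], mu[v] = s_arr, m_arr
    if include_parameter:
        s_arr = np.empty(sel.size)
        m_arr = np.empty(sel.size)
        for j, k in enumerate(sel):
            m_arr[j], s_arr[j] = _gaussian_mle(b.param_paths[idx, k])
        sigma[b.noise.target], mu[b.noise.target] = s_arr, m_arr
    return WidthSeries(times=times, sigma=sigma, mu=mu, n_used=int(idx.size))


def width_growth_check(ws: WidthSeries, t_max: float, breakout_frac: float = 0.05) -> dict:
    """Least-squares linearity check of sigma(t) on (0, t_max].

    For each variable, fits sigma = slope * t + intercept and reports the
    slope, R^2 and any super-linear breakout times where sigma exceeds the
    fit by more than ``breakout_frac`` of the fitted range.
    """
    mask = (ws.times > 0) & (ws.times <= t_max)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points in (0, t_max] for a linear fit")
    t = ws.times[mask]
    report = {}
    for v, s_full in ws.sigma.items():
        s = np.asarray(s_full)[mask]
        A = np.vstack([t, np.ones_like(t)]).T
        (slope, intercept), *_ = np.linalg.lstsq(A, s, rcond=None)
        pred = slope * t + intercept
        ss_res = float(np.sum((s - pred) ** 2))
        ss_tot = float(np.sum((s - np.mean(s)) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
        scale = max(float(np.ptp(s)), 1e-300)
        breakout = t[(s - pred) > breakout_frac * scale]
        report[v] = {
            "slope": float(slope),
            "intercept": float(intercept),
            "r_squared": float(r2),
            "superlinear_breakout_times": breakout.tolist(),
        }
    return report
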