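"""Deterministic cancer stem-cell population model.

The tumor is described by four coupled variables:

* ``S`` — cancer stem cell (CSC) density, as a fraction of all cells,
* ``D`` — differentiated cancer cell (DC) density,
* ``a`` — concentration of the chemical activator steering the outcome of
  stem divisions (high ``a`` favors symmetric stem-stem division),
* ``m`` — concentration of the plasticity activator that lets DCs
  de-differentiate back to the stem state when stem density drops low.

Stem cells are the only dividing population.  A division produces on
average ``2p`` stem cells and ``2(1-p)`` differentiated cells, where the
division probability ``p(D, a)`` increases with the activator ``a`` and is
suppressed by crowding of differentiated cells.  DCs die at rate ``d`` and
de-differentiate at the plasticity rate ``q(m)``, a smooth step that
switches on once ``m`` exceeds the threshold ``m0``.  Mitosis is throttled
by the saturation factor ``Upsilon = tanh((1 - S - D)/sl)`` so that the
total cell fraction ``S + D`` cannot exceed one.

The governing equations are::

    dS/dt = (2 p(D,a) - 1) Upsilon lam S + q(m) D
    dD/dt = 2 (1 - p(D,a)) Upsilon lam S - (d + q(m)) D
    da/dt = a (beta S a / (1 + a) - alpha_a)
    dm/dt = gamma exp(-S/S0) - alpha_m m

with ``p = eta a / ((1 + eta a)(1 + psi D))``,
``q = (q0/2) (1 + tanh((m - m0)/sq))`` and the saturation factor above.
Time is measured in days; the mitotic rate ``lam = 1/day`` sets the unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "State",
    "Trajectory",
    "DomainError",
    "SolverError",
    "division_probability",
    "plasticity_rate",
    "saturation_factor",
    "vector_field",
    "simulate",
    "DEFAULT_INIT",
]


class DomainError(ValueError):
    """State or argument outside the physically meaningful region."""


class SolverError(RuntimeError):
    """Integration failure; carries the last valid state if available."""

    def __init__(self, message: str, last_state: Optional["State"] = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParams:
    """Rate and shape constants of the population model.

    All rates are per day.  ``lambda_mitotic`` is the CSC mitotic rate (the
    time unit is chosen so it defaults to 1), ``d`` the DC death rate,
    ``q0`` the plasticity amplitude, ``eta`` the activator gain in the
    division probability, ``psi`` the crowding-inhibition strength,
    ``alpha_a``/``alpha_m`` the activator decay rates, ``beta``/``gamma``
    the activator production gains.  ``S0`` is the stem density scale below
    which plasticity-signal production switches on, ``m0`` the plasticity
    threshold, and ``sq``/``sl`` the widths of the two smooth steps (they
    must remain small for the step approximation to hold).
    """

    d: float
    q0: float
    eta: float
    beta: float
    gamma: float
    alpha_a: float
    alpha_m: float
    lambda_mitotic: float = 1.0
    psi: float = 1.0
    S0: float = 0.038
    m0: float = 0.5
    sq: float = 0.01
    sl: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if not (0 < self.S0 < 1):
            raise ValueError(f"S0 must lie in (0, 1), got {self.S0}")
        for name in ("sq", "sl"):
            v = getattr(self, name)
            if v > 0.5:
                warnings.warn(
                    f"{name}={v} is large; the step-function approximation "
                    "assumes a small width",
                    stacklevel=2,
                )

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class State:
    """Instantaneous state (S, D, a, m).

    ``S`` and ``D`` are cell fractions with ``S + D <= 1`` (the remainder
    ``1 - S - D`` is the inert fraction); ``a`` and ``m`` are non-negative
    activator number densities.
    """

    S: float
    D: float
    a: float
    m: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise DomainError(f"cell densities must be non-negative: S={self.S}, D={self.D}")
        if self.S + self.D > 1 + 1e-12:
            raise DomainError(f"S + D = {self.S + self.D} exceeds 1")
        if self.a < 0 or self.m < 0:
            raise DomainError(f"activators must be non-negative: a={self.a}, m={self.m}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.D, self.a, self.m], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "State":
        return cls(*(float(v) for v in y))

    @classmethod
    def unchecked(cls, S: float, D: float, a: float, m: float) -> "State":
        """Construct without invariant checks.

        Used only for analysis artifacts that live outside the physical
        region, such as fixed points of the unsaturated (Upsilon = 1)
        approximation of the flow.
        """
        obj = object.__new__(cls)
        object.__setattr__(obj, "S", float(S))
        object.__setattr__(obj, "D", float(D))
        object.__setattr__(obj, "a", float(a))
        object.__setattr__(obj, "m", float(m))
        return obj


#: Documented default initial state: a small seeded tumor.
DEFAULT_INIT = State(S=0.01, D=0.1, a=0.5, m=0.1)


@dataclass
class Trajectory:
    """Time-indexed solution of the model.

    ``states`` has shape ``(len(times), 4)`` with columns S, D, a, m.
    ``events`` is a list of ``(time, kind)`` with kind one of
    ``divergence``, ``extinction``, ``bound_violation``.  When parameters
    were time-dependent (noise or therapy), ``param_path`` holds the value
    of the varied parameter(s) on the same grid.
    """

    times: np.ndarray
    states: np.ndarray
    events: list = field(default_factory=list)
    params_used: Optional[ModelParams] = None
    param_path: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d grid")
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have one (S, D, a, m) row per time point")

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def D(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def a(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def m(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def final_state(self) -> State:
        return State.from_array(np.clip(self.states[-1], 0.0, None))

    def has_event(self, kind: str) -> bool:
        return any(k == kind for _, k in self.events)

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns t, S, D, a, m."""
        import pandas as pd

        data = {"t": self.times, "S": self.S, "D": self.D, "a": self.a, "m": self.m}
        if self.param_path:
            for name, path in self.param_path.items():
                data[name] = np.asarray(path)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Auxiliary functions of the vector field
# ---------------------------------------------------------------------------

def division_probability(D, a, p: ModelParams):
    """Probability p(D, a) that a stem division yields two stem cells.

    ``p = eta a / ((1 + eta a)(1 + psi D))``: increasing in the activator
    ``a`` (saturating at 1), decreasing with DC crowding ``D``.
    """
    D = np.asarray(D, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(D < 0) or np.any(a < 0):
        raise DomainError("division_probability requires D >= 0 and a >= 0")
    ea = p.eta * a
    out = ea / ((1.0 + ea) * (1.0 + p.psi * D))
    return float(out) if out.ndim == 0 else out


def plasticity_rate(m, p: ModelParams):
    """De-differentiation rate q(m) = (q0/2)[1 + tanh((m - m0)/sq)].

    A smooth step: essentially 0 below the threshold ``m0`` and ``q0``
    above it, with transition width ``sq``.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise DomainError("plasticity_rate requires m >= 0")
    out = 0.5 * p.q0 * (1.0 + np.tanh((m - p.m0) / p.sq))
    return float(out) if out.ndim == 0 else out


def saturation_factor(S, D, p: ModelParams):
    """Mitosis saturation factor Upsilon = tanh((1 - S - D)/sl).

    Close to 1 while the tumor is far from confluence, dropping to 0 as
    ``S + D`` approaches 1; this enforces ``S + D <= 1`` dynamically.
    """
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    free = 1.0 - S - D
    if np.any(free < -1e-12):
        raise DomainError("saturation_factor requires S + D <= 1")
    out = np.tanh(np.maximum(free, 0.0) / p.sl)
    return float(out) if out.ndim == 0 else out


def _rhs_raw(S, D, a, m, lam, d, q0, p: ModelParams, q_offset=0.0):
    """Vector field with the rate parameters (lam, d, q0) passed explicitly.

    Accepts scalars or broadcastable arrays; used by the deterministic,
    stochastic and therapy integrators alike.  ``q_offset`` is subtracted
    from the plasticity rate q(m) (forced-differentiation therapy); the
    resulting net rate may be negative by design.  No domain checks here.
    """
    ea = p.eta * a
    prob = ea / ((1.0 + ea) * (1.0 + p.psi * D))
    q = 0.5 * q0 * (1.0 + np.tanh((m - p.m0) / p.sq)) - q_offset
    ups = np.tanh(np.maximum(1.0 - S - D, 0.0) / p.sl)
    mitosis = ups * lam * S
    dS = (2.0 * prob - 1.0) * mitosis + q * D
    dD = 2.0 * (1.0 - prob) * mitosis - (d + q) * D
    da = a * (p.beta * S * a / (1.0 + a) - p.alpha_a)
    dm = p.gamma * np.exp(-S / p.S0) - p.alpha_m * m
    return dS, dD, da, dm


def vector_field(state, p: ModelParams) -> np.ndarray:
    """Time derivatives (dS/dt, dD/dt, da/dt, dm/dt) at ``state``.

    The sum dS/dt + dD/dt always equals ``Upsilon lam S - d D``: each stem
    division adds exactly one net cell and DC death is the only loss.
    """
    if isinstance(state, State):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        State.from_array(y)  # validate
    S, D, a, m = y
    return np.array(_rhs_raw(S, D, a, m, p.lambda_mitotic, p.d, p.q0, p))


# ---------------------------------------------------------------------------
# Deterministic simulation
# ---------------------------------------------------------------------------

#: Guard below which slightly negative solver states are clipped to zero.
NEGATIVE_CLIP = 1e-9
#: Default ceiling on the activator a beyond which the run is declared divergent.
DIVERGENCE_CEILING = 1e6
#: Total cell fraction below which the tumor is recorded as extinct.
EXTINCTION_FLOOR = 1e-6


def _project_domain(y):
    """Project a solver trial state onto the physical domain.

    Adaptive solvers probe trial states that may violate the constraints;
    those stages are rejected by the step controller, so the RHS clips
    rather than raises.  Accepted output states are validated separately.
    """
    S, D, a, m = y
    S = max(S, 0.0)
    D = max(D, 0.0)
    a = max(a, 0.0)
    m = max(m, 0.0)
    if S + D > 1.0:
        # project onto the simplex boundary, preserving the S:D ratio
        tot = S + D
        S, D = S / tot, D / tot
    return S, D, a, m


def _make_solver_rhs(p: ModelParams):
    def rhs(t, y):
        S, D, a, m = _project_domain(y)
        return _rhs_raw(S, D, a, m, p.lambda_mitotic, p.d, p.q0, p)

    return rhs


def simulate(
    p: ModelParams,
    init: State = DEFAULT_INIT,
    t_end: float = 20.0,
    *,
    dt_out: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    divergence_ceiling: float = DIVERGENCE_CEILING,
    extinction_floor: float = EXTINCTION_FLOOR,
    rhs: Optional[Callable] = None,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the deterministic model from ``init`` to ``t_end``.

    Uses an adaptive explicit Runge-Kutta method (Dormand-Prince 5(4) by
    default).  Integration halts early with a ``divergence`` event when the
    activator ``a`` exceeds ``divergence_ceiling``; an ``extinction`` event
    is recorded (without halting) when ``S + D`` first falls below
    ``extinction_floor``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not isinstance(init, State):
        init = State.from_array(init)

    f = rhs if rhs is not None else _make_solver_rhs(p)

    def ev_divergence(t, y):
        return y[2] - divergence_ceiling

    ev_divergence.terminal = True
    ev_divergence.direction = 1

    def ev_extinction(t, y):
        return y[0] + y[1] - extinction_floor

    ev_extinction.terminal = False
    ev_extinction.direction = -1

    n_out = max(int(round(t_end / dt_out)), 2)
    t_eval = np.linspace(0.0, t_end, n_out + 1)

    try:
        sol = solve_ivp(
            f,
            (0.0, t_end),
            init.as_array(),
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            events=[ev_divergence, ev_extinction],
            dense_output=False,
            max_step=max_step,
        )
    except DomainError:
        raise
    if not sol.success and sol.status != 1:
        last = State.from_array(np.clip(sol.y[:, -1], 0, None)) if sol.y.size else None
        raise SolverError(f"integration failed: {sol.message}", last_state=last)

    events = []
    if sol.t_events[0].size:
        events.append((float(sol.t_events[0][0]), "divergence"))
    for te in sol.t_events[1]:
        events.append((float(te), "extinction"))

    states = sol.y.T.copy()
    # validate accepted states: solver-noise-level excursions are clipped,
    # anything materially outside the domain is recorded as an event
    tol = max(100 * atol, NEGATIVE_CLIP)
    bad = (states.min(axis=1) < -tol) | (states[:, 0] + states[:, 1] > 1 + tol)
    if bad.any():
        events.append((float(sol.t[np.argmax(bad)]), "bound_violation"))
    states = np.maximum(states, 0.0)
    over = states[:, 0] + states[:, 1]
    mask = over > 1.0
    if mask.any():
        states[mask, 0] /= over[mask]
        states[mask, 1] /= over[mask]
    traj = Trajectory(
        times=sol.t,
        states=states,
        events=sorted(events),
        params_used=p,
        metadata={
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "t_end": t_end,
            "n_rhs_evaluations": int(sol.nfev),
            "terminated_early": bool(sol.status == 1),
        },
    )
    return traj
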