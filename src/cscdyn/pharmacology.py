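"""Pharmacokinetics, pharmacodynamics and therapy wiring.

Kinetics (PK): a one-compartment model with periodic administration.  The
dimensionless drug level ``chi(t)`` obeys::

    dchi/dt = zeta - alpha_d chi     during dosing,   nT <= t < nT + tau
    dchi/dt =      - alpha_d chi     during rest,     nT + tau <= t < (n+1)T

where ``zeta`` is the administration rate, ``alpha_d`` the first-order
clearance rate (1/alpha_d of order minutes to hours), ``T`` the
administration period and ``tau`` the administration duration, all in
days.  The piecewise-linear equation is solved analytically, with exact
carry-over of the residual level across phase boundaries.  The rate needed
to reach a prescribed peak ``chi_max = chi(tau)`` on the first dose is
``zeta = chi_max alpha_d / (1 - exp(-alpha_d tau))``.

Dynamics (PD): the drug acts through the smooth-step action function::

    Omega(chi) = (Omega0 / 2) [tanh((chi - chi0)/s_chi) + 1]

which plateaus near 0 for negligible levels and near ``Omega0`` for
saturating levels, transitioning around ``chi0`` with width ``s_chi``.

Therapies make model rates time-dependent:

* cytotoxic            — kills DCs:            d(t)   = d~  + Omega(chi)
* cytostatic           — slows stem mitosis:   lam(t) = lam~ - Omega(chi)
* anti-plasticity      — blocks de-differentiation: q0(t) = q0~ - Omega(chi)
* differentiation+cytotoxic — forces stem differentiation while killing
  DCs: the plasticity term becomes q(m) - Omega_diff(chi) (allowed to go
  negative: the net effect is an induced stem death/differentiation rate)
  and d(t) = d~ + Omega_cyto(chi).

Subtractive therapies clamp the affected rate at zero by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    DIVERGENCE_CEILING,
    EXTINCTION_FLOOR,
    DEFAULT_INIT,
    DomainError,
    ModelParams,
    SolverError,
    State,
    Trajectory,
    _project_domain,
    _rhs_raw,
)

__all__ = [
    "DrugSchedule",
    "ActionParams",
    "TherapySpec",
    "THERAPY_TYPES",
    "dose_rate_for_peak",
    "drug_level",
    "drug_action",
    "effective_params",
    "simulate_with_therapy",
]

THERAPY_TYPES = (
    "cytotoxic",
    "cytostatic",
    "anti_plasticity",
    "differentiation_plus_cytotoxic",
)


def dose_rate_for_peak(chi_max: float, alpha_d: float, tau: float) -> float:
    """Administration rate zeta that attains peak chi(tau) = chi_max.

    From the dosing-phase solution chi(t) = zeta (1 - exp(-alpha_d t)) /
    alpha_d starting at chi(0) = 0.
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    if chi_max <= 0 or alpha_d <= 0:
        raise ValueError("chi_max and alpha_d must be strictly positive")
    return chi_max * alpha_d / (1.0 - math.exp(-alpha_d * tau))


@dataclass(frozen=True)
class DrugSchedule:
    """Periodic drug administration: dosing for ``tau`` out of every ``T`` days.

    Exactly one of ``zeta`` (administration rate) or ``chi_max`` (target
    first-dose peak, from which zeta is derived) must be given.  Dosing
    starts at ``t_start`` and, if ``n_periods`` is set, stops after that
    many administrations.
    """

    alpha_d: float
    T: float
    tau: float
    zeta: Optional[float] = None
    chi_max: Optional[float] = None
    t_start: float = 0.0
    n_periods: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.tau < self.T):
            raise ValueError(f"need 0 < tau < T, got tau={self.tau}, T={self.T}")
        if self.alpha_d <= 0:
            raise ValueError("alpha_d must be strictly positive")
        if (self.zeta is None) == (self.chi_max is None):
            raise ValueError("give exactly one of zeta or chi_max")
        if self.t_start < 0:
            raise ValueError("t_start must be non-negative")
        if self.n_periods is not None and self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if (self.T - self.tau) * self.alpha_d < 3.0:
            warnings.warn(
                "rest period T - tau is not much larger than the drug decay "
                "time 1/alpha_d; the drug will accumulate across periods",
                stacklevel=2,
            )

    @property
    def zeta_effective(self) -> float:
        if self.zeta is not None:
            return self.zeta
        return dose_rate_for_peak(self.chi_max, self.alpha_d, self.tau)

    def phase_boundaries(self, t_end: float) -> np.ndarray:
        """All dosing on/off switch times in [0, t_end]."""
        pts = []
        n = 0
        while True:
            on = self.t_start + n * self.T
            if on > t_end:
                break
            if self.n_periods is not None and n >= self.n_periods:
                break
            pts.append(on)
            off = on + self.tau
            if off <= t_end:
                pts.append(off)
            n += 1
        return np.array(pts)


def drug_level(t, schedule: DrugSchedule):
    """Analytic drug level chi(t) under the periodic schedule.

    chi = 0 before ``t_start``; within each period the dosing-phase and
    decay-phase exponentials are chained with exact carry-over, so chi is
    continuous everywhere.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    ad, T, tau = schedule.alpha_d, schedule.T, schedule.tau
    zeta = schedule.zeta_effective
    zss = zeta / ad  # dosing-phase asymptote

    s = t - schedule.t_start
    chi = np.zeros_like(s)
    active = s >= 0
    sa = s[active]

    n = np.floor(sa / T).astype(int)
    # start-of-period levels: chi_n = A (1 - r^n)/(1 - r), geometric build-up
    peak1 = zss * (1.0 - np.exp(-ad * tau))  # first-dose peak
    A = peak1 * np.exp(-ad * (T - tau))  # carry-over of one dose into the next period
    r = math.exp(-ad * T)
    if schedule.n_periods is not None:
        n_dosing = np.minimum(n, schedule.n_periods - 1)
    else:
        n_dosing = n
    chi_n = A * (1.0 - r ** n_dosing) / (1.0 - r)

    u = sa - n * T
    if schedule.n_periods is not None:
        # past the last administration: pure decay from the end of period n_p-1
        past = n >= schedule.n_periods
        u = np.where(past, sa - (schedule.n_periods - 1) * T, u)
    dosing = u < tau
    peak_n = zss + (chi_n - zss) * np.exp(-ad * tau)
    val = np.where(
        dosing,
        zss + (chi_n - zss) * np.exp(-ad * np.minimum(u, tau)),
        peak_n * np.exp(-ad * (u - tau)),
    )
    chi[active] = val
    return float(chi[0]) if scalar else chi


@dataclass(frozen=True)
class ActionParams:
    """Smooth-step drug action: magnitude ``omega0`` (units of the targeted
    rate), midpoint level ``chi0`` and transition width ``s_chi``."""

    omega0: float
    chi0: float
    s_chi: float

    def __post_init__(self) -> None:
        for name in ("omega0", "chi0", "s_chi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def drug_action(chi, a: ActionParams):
    """Action Omega(chi) = (omega0/2)[tanh((chi - chi0)/s_chi) + 1].

    Monotone in chi, plateauing at 0 (negligible drug) and omega0
    (saturation); note Omega(0) is small but never exactly zero.
    """
    chi_arr = np.asarray(chi, dtype=float)
    if np.any(chi_arr < 0):
        raise DomainError("drug level chi must be non-negative")
    out = 0.5 * a.omega0 * (np.tanh((chi_arr - a.chi0) / a.s_chi) + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TherapySpec:
    """A therapy: type, dosing schedule and action parameters.

    The combined ``differentiation_plus_cytotoxic`` type takes a pair of
    actions ``(action_diff, action_cyto)``; all others take a single
    :class:`ActionParams`.  ``clamp_at_zero`` floors subtractive rates
    (lam, q0) at zero; the combined therapy's ``q(m) - Omega_diff`` is
    never clamped (its negative excursion is the induced stem death rate).
    """

    therapy_type: str
    schedule: DrugSchedule
    action: Union[ActionParams, tuple]
    clamp_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.therapy_type not in THERAPY_TYPES:
            raise ValueError(
                f"unknown therapy type {self.therapy_type!r}; choose from {THERAPY_TYPES}"
            )
        if self.therapy_type == "differentiation_plus_cytotoxic":
            if not (isinstance(self.action, tuple) and len(self.action) == 2):
                raise ValueError("combined therapy needs a pair (action_diff, action_cyto)")
        elif not isinstance(self.action, ActionParams):
            raise ValueError("this therapy type takes a single ActionParams")


def effective_params(t, base: ModelParams, therapy: TherapySpec) -> dict:
    """Instantaneous rate record under the therapy at time ``t``.

    Returns a dict with keys ``lambda_mitotic``, ``d``, ``q0``,
    ``q_offset`` and ``chi``.  ``q_offset`` is nonzero only for the
    combined therapy and is subtracted from the plasticity rate q(m).
    """
    chi = drug_level(t, therapy.schedule)
    lam, d, q0 = base.lambda_mitotic, base.d, base.q0
    q_offset = 0.0
    kind = therapy.therapy_type
    if kind == "cytotoxic":
        d = d + drug_action(chi, therapy.action)
    elif kind == "cytostatic":
        lam = lam - drug_action(chi, therapy.action)
        if therapy.clamp_at_zero:
            lam = np.maximum(lam, 0.0)
    elif kind == "anti_plasticity":
        q0 = q0 - drug_action(chi, therapy.action)
        if therapy.clamp_at_zero:
            q0 = np.maximum(q0, 0.0)
    else:  # differentiation_plus_cytotoxic
        act_diff, act_cyto = therapy.action
        q_offset = drug_action(chi, act_diff)
        d = d + drug_action(chi, act_cyto)
    return {
        "lambda_mitotic": lam,
        "d": d,
        "q0": q0,
        "q_offset": q_offset,
        "chi": chi,
    }


def simulate_with_therapy(
    p: ModelParams,
    therapy: TherapySpec,
    init: State = DEFAULT_INIT,
    t_end: float = 20.0,
    *,
    dt_out: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    divergence_ceiling: float = DIVERGENCE_CEILING,
    extinction_floor: float = EXTINCTION_FLOOR,
) -> Trajectory:
    """Integrate the model with therapy-driven time-dependent rates.

    The integrator restarts at every dosing on/off switch so the adaptive
    Runge-Kutta method never steps across a discontinuity of the forcing.
    Events (``divergence``, ``extinction``) behave as in the untreated
    simulator.
    """
    if not isinstance(init, State):
        init = State.from_array(init)

    def rhs(t, y):
        S, D, a, m = _project_domain(y)
        eff = effective_params(t, p, therapy)
        return _rhs_raw(
            S, D, a, m,
            eff["lambda_mitotic"], eff["d"], eff["q0"], p,
            q_offset=eff["q_offset"],
        )

    def ev_divergence(t, y):
        return y[2] - divergence_ceiling

    ev_divergence.terminal = True
    ev_divergence.direction = 1

    def ev_extinction(t, y):
        return y[0] + y[1] - extinction_floor

    ev_extinction.terminal = False
    ev_extinction.direction = -1

    n_out = max(int(round(t_end / dt_out)), 2)
    t_grid = np.linspace(0.0, t_end, n_out + 1)
    boundaries = therapy.schedule.phase_boundaries(t_end)
    seg_edges = np.unique(np.concatenate([[0.0], boundaries, [t_end]]))
    seg_edges = seg_edges[(seg_edges >= 0) & (seg_edges <= t_end)]

    times = [np.array([0.0])]
    states = [init.as_array()[None, :]]
    events = []
    y0 = init.as_array()
    stopped = False
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        if stopped or t1 <= t0:
            break
        inner = t_grid[(t_grid > t0 + 1e-12) & (t_grid < t1 - 1e-12)]
        t_eval = np.unique(np.concatenate([inner, [t1]]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y0,
            method="RK45",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            events=[ev_divergence, ev_extinction],
        )
        if not sol.success and sol.status != 1:
            last = State.from_array(np.clip(y0, 0, None))
            raise SolverError(f"integration failed in [{t0}, {t1}]: {sol.message}", last)
        if sol.t.size:
            times.append(sol.t)
            states.append(sol.y.T)
        if sol.t_events[0].size:
            events.append((float(sol.t_events[0][0]), "divergence"))
            stopped = True
        for te in sol.t_events[1]:
            events.append((float(te), "extinction"))
        if not stopped:
            y0 = sol.y[:, -1] if sol.y.size else y0

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=0)
    t_all, keep = np.unique(np.round(t_all, 12), return_index=True)
    y_all = np.maximum(y_all[keep], 0.0)

    eff_path = {"chi": drug_level(t_all, therapy.schedule)}
    kind = therapy.therapy_type
    if kind == "cytotoxic":
        eff_path["d"] = p.d + drug_action(eff_path["chi"], therapy.action)
    elif kind == "cytostatic":
        lam = p.lambda_mitotic - drug_action(eff_path["chi"], therapy.action)
        eff_path["lambda_mitotic"] = np.maximum(lam, 0.0) if therapy.clamp_at_zero else lam
    elif kind == "anti_plasticity":
        q0 = p.q0 - drug_action(eff_path["chi"], therapy.action)
        eff_path["q0"] = np.maximum(q0, 0.0) if therapy.clamp_at_zero else q0
    else:
        act_diff, act_cyto = therapy.action
        eff_path["q_offset"] = drug_action(eff_path["chi"], act_diff)
        eff_path["d"] = p.d + drug_action(eff_path["chi"], act_cyto)

    return Trajectory(
        times=t_all,
        states=y_all,
        events=sorted(events),
        params_used=p,
        param_path=eff_path,
        metadata={
            "therapy_type": kind,
            "rtol": rtol,
            "atol": atol,
            "terminated_early": stopped,
        },
    )
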