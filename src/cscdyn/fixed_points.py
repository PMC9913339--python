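"""Fixed points of the stem-cell model and their linear stability.

The system admits up to three fixed points:

* ``F1 = (0, 0, 0, gamma/alpha_m)`` — tumor extinction; always exists.
* ``F2 = (S2, D2, 0, m2)`` — a dormant, self-sustained colony upheld by the
  mitosis-plasticity feedback loop, with ``a = 0`` and

  .. math::

     m_2 = m_0 + s_q\\,\\mathrm{artanh}(2d/q_0 - 1),\\qquad
     S_2 = -S_0 \\log(\\alpha_m m_2/\\gamma),\\qquad
     D_2 = \\lambda S_2 / d,

  existing iff ``0 < d < q0`` and ``m2 < gamma/alpha_m`` (equivalently
  ``S2 > 0``).  The closed form assumes the saturation factor is ~1, which
  holds since S2 + D2 is far from confluence for realistic parameters.
* ``F3`` — the only fixed point with ``a != 0``; no closed form (it solves
  a cubic), located here by multi-start root search.  Its existence is
  signalled by ``d > psi alpha_a / beta``; when present it is a saddle.

F3 is first located in the *unsaturated* field (saturation factor held at
1, the approximation under which the fixed-point analysis is tractable);
its total cell fraction ``S3 + D3`` can then exceed 1.  When the
unsaturated root continues to a genuine equilibrium of the full field
inside the physical simplex, that polished point is reported
(``inside_physical_simplex`` existence flag); otherwise the unsaturated
location is returned as the organizing saddle through which
high-activator trajectories escape to uncontrolled proliferation.

Stability is read off the eigenvalues of the Jacobian evaluated at the
point (with the saturation factor at 1, matching the fixed-point
analysis): all real parts negative means stable; any positive means
unstable, with mixed signs labelled a saddle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import root

from .model import ModelParams, State, vector_field

__all__ = [
    "FixedPoint",
    "NonHyperbolicError",
    "fixed_point_f1",
    "fixed_point_f2",
    "fixed_point_f3",
    "find_fixed_points",
    "jacobian",
    "classify_stability",
]


class NonHyperbolicError(ValueError):
    """An eigenvalue real part is numerically zero; no stability verdict."""


@dataclass
class FixedPoint:
    """A fixed point with its existence record and linear stability."""

    label: str  # F1 | F2 | F3
    location: Optional[State]
    exists: bool
    existence_conditions: dict = field(default_factory=dict)
    eigenvalues: Optional[np.ndarray] = None
    stability: Optional[str] = None  # stable | unstable | saddle

    @property
    def is_stable(self) -> bool:
        """True iff all eigenvalue real parts are negative (saddles count
        as unstable)."""
        if self.stability is None:
            raise ValueError("stability not yet classified")
        return self.stability == "stable"

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "exists": self.exists,
            "existence_conditions": self.existence_conditions,
        }
        if self.location is not None:
            d["location"] = {
                "S": self.location.S,
                "D": self.location.D,
                "a": self.location.a,
                "m": self.location.m,
            }
        if self.eigenvalues is not None:
            d["eigenvalues"] = [
                {"re": float(e.real), "im": float(e.imag)} for e in self.eigenvalues
            ]
        if self.stability is not None:
            d["stability"] = self.stability
        return d


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def jacobian(state, p: ModelParams, mode: str = "analytic_upsilon1") -> np.ndarray:
    """4x4 Jacobian of the vector field at ``state``.

    ``analytic_upsilon1`` uses the hand-derived partial derivatives with
    the saturation factor held at 1 (the approximation used for the
    eigenvalue analysis, valid well below confluence).
    ``finite_difference`` differentiates the full field by central
    differences and serves as the independent cross-check.
    """
    y = state.as_array() if isinstance(state, State) else np.asarray(state, float)
    if mode == "finite_difference":
        return _jacobian_fd(y, p)
    if mode != "analytic_upsilon1":
        raise ValueError(f"unknown jacobian mode {mode!r}")

    S, D, a, m = y
    lam, d, q0 = p.lambda_mitotic, p.d, p.q0
    ea = p.eta * a
    prob = ea / ((1.0 + ea) * (1.0 + p.psi * D))
    dprob_da = p.eta / ((1.0 + ea) ** 2 * (1.0 + p.psi * D))
    dprob_dD = -ea * p.psi / ((1.0 + ea) * (1.0 + p.psi * D) ** 2)
    x = (m - p.m0) / p.sq
    q = 0.5 * q0 * (1.0 + np.tanh(x))
    # sech^2 evaluated overflow-free for large |x|
    e = np.exp(-2.0 * abs(x))
    sech2 = 4.0 * e / (1.0 + e) ** 2
    dq_dm = 0.5 * q0 / p.sq * sech2

    J = np.zeros((4, 4))
    # dS/dt = (2p - 1) lam S + q D          (Upsilon = 1)
    J[0, 0] = (2.0 * prob - 1.0) * lam
    J[0, 1] = 2.0 * lam * S * dprob_dD + q
    J[0, 2] = 2.0 * lam * S * dprob_da
    J[0, 3] = dq_dm * D
    # dD/dt = 2 (1 - p) lam S - (d + q) D
    J[1, 0] = 2.0 * (1.0 - prob) * lam
    J[1, 1] = -2.0 * lam * S * dprob_dD - (d + q)
    J[1, 2] = -2.0 * lam * S * dprob_da
    J[1, 3] = -dq_dm * D
    # da/dt = beta S a^2/(1+a) - alpha_a a
    J[2, 0] = p.beta * a * a / (1.0 + a)
    J[2, 2] = p.beta * S * a * (a + 2.0) / (1.0 + a) ** 2 - p.alpha_a
    # dm/dt = gamma exp(-S/S0) - alpha_m m
    J[3, 0] = -(p.gamma / p.S0) * np.exp(-S / p.S0)
    J[3, 3] = -p.alpha_m
    return J


def _jacobian_fd(y: np.ndarray, p: ModelParams, h_rel: float = 1e-6) -> np.ndarray:
    J = np.zeros((4, 4))
    for j in range(4):
        h = h_rel * max(abs(y[j]), 1.0)
        if h < 1e-14:
            raise FloatingPointError("finite-difference step underflow")
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        ym[j] = max(ym[j], 0.0)  # stay in the domain at boundary points
        J[:, j] = (vector_field(yp, p) - vector_field(ym, p)) / (yp[j] - ym[j])
    return J


# ---------------------------------------------------------------------------
# Stability classification
# ---------------------------------------------------------------------------

def classify_stability(
    fp: FixedPoint, p: ModelParams, *, mode: str = "analytic_upsilon1", tol: float = 1e-10
) -> str:
    """Attach eigenvalues and a stability label to ``fp`` (in place).

    stable: all eigenvalue real parts < 0; saddle: mixed signs; unstable:
    all positive.  Real parts within ``tol`` of zero raise
    :class:`NonHyperbolicError` rather than silently guessing.
    """
    if not fp.exists or fp.location is None:
        raise ValueError(f"{fp.label} does not exist; nothing to classify")
    J = jacobian(fp.location, p, mode=mode)
    eig = np.linalg.eigvals(J)
    re = eig.real
    if np.any(np.abs(re) < tol):
        raise NonHyperbolicError(
            f"{fp.label} has an eigenvalue with |Re| < {tol}; non-hyperbolic"
        )
    if np.all(re < 0):
        label = "stable"
    elif np.any(re > 0) and np.any(re < 0):
        label = "saddle"
    else:
        label = "unstable"
    fp.eigenvalues = eig
    fp.stability = label
    return label


# ---------------------------------------------------------------------------
# The three fixed points
# ---------------------------------------------------------------------------

def fixed_point_f1(p: ModelParams, classify: bool = True) -> FixedPoint:
    """Tumor extinction point F1 = (0, 0, 0, gamma/alpha_m); always exists."""
    fp = FixedPoint(
        label="F1",
        location=State(0.0, 0.0, 0.0, p.gamma / p.alpha_m),
        exists=True,
    )
    if classify:
        classify_stability(fp, p)
    return fp


def fixed_point_f2(p: ModelParams, classify: bool = True) -> FixedPoint:
    """Plasticity-sustained colony F2 = (S2, D2, 0, m2), if it exists.

    Existence requires ``0 < d < q0`` (so the artanh argument is in
    (-1, 1)) and ``m2 < gamma/alpha_m`` (so that ``S2 > 0``); the
    conditions are evaluated in that order.
    """
    conds = {"d_lt_q0": 0.0 < p.d < p.q0}
    if not conds["d_lt_q0"]:
        conds["m2_lt_gamma_over_alpham"] = None
        return FixedPoint("F2", None, False, conds)
    m2 = p.m0 + p.sq * np.arctanh(2.0 * p.d / p.q0 - 1.0)
    conds["m2_lt_gamma_over_alpham"] = bool(m2 < p.gamma / p.alpha_m)
    if not conds["m2_lt_gamma_over_alpham"] or m2 <= 0:
        return FixedPoint("F2", None, False, conds)
    S2 = -p.S0 * np.log(p.alpha_m * m2 / p.gamma)
    D2 = p.lambda_mitotic * S2 / p.d
    if S2 <= 0 or S2 + D2 > 1:
        conds["in_physical_domain"] = False
        return FixedPoint("F2", None, False, conds)
    fp = FixedPoint("F2", State(float(S2), float(D2), 0.0, float(m2)), True, conds)
    if classify:
        classify_stability(fp, p)
    return fp


def vector_field_upsilon1(y, p: ModelParams) -> np.ndarray:
    """Vector field with the saturation factor held at 1.

    This is the field the fixed-point analysis is carried out on; unlike
    :func:`cscdyn.vector_field` it is defined for S + D > 1 and performs
    no domain checks.
    """
    S, D, a, m = np.asarray(y, dtype=float)
    ea = p.eta * a
    prob = ea / ((1.0 + ea) * (1.0 + p.psi * D))
    q = 0.5 * p.q0 * (1.0 + np.tanh((m - p.m0) / p.sq))
    lam = p.lambda_mitotic
    return np.array([
        (2.0 * prob - 1.0) * lam * S + q * D,
        2.0 * (1.0 - prob) * lam * S - (p.d + q) * D,
        a * (p.beta * S * a / (1.0 + a) - p.alpha_a),
        p.gamma * np.exp(-np.clip(S / p.S0, -700.0, 700.0)) - p.alpha_m * m,
    ])


def _f3_heuristic(p: ModelParams) -> bool:
    return p.d > p.psi * p.alpha_a / p.beta


def fixed_point_f3(
    p: ModelParams,
    n_starts: int = 64,
    tol: float = 1e-3,
    classify: bool = True,
    seed: int = 0,
) -> FixedPoint:
    """Search for the activator-driven fixed point F3 (a != 0).

    There is no closed form (the point solves a cubic), so a multi-start
    Newton-type root search of the Upsilon = 1 field is run with S, D, m
    non-negative and ``a > tol`` (S3 + D3 may exceed 1; see the module
    docstring).  The analytic existence condition ``d > psi alpha_a /
    beta`` is reported alongside; when it predicts a point but none is
    found, a warning is issued.
    """
    conds = {"d_gt_psi_alpha_over_beta": bool(_f3_heuristic(p))}
    rng = np.random.default_rng(seed)

    found = []
    for _ in range(n_starts):
        y0 = [
            rng.uniform(0.0, 1.5),
            rng.uniform(0.0, 1.5),
            rng.uniform(max(tol, 0.05), 15.0),
            rng.uniform(0.0, 2.0 * p.gamma / p.alpha_m),
        ]
        sol = root(lambda y: vector_field_upsilon1(y, p), y0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        y = sol.x
        if y[2] <= tol or y[0] < -1e-9 or y[1] < -1e-9 or y[3] < -1e-9:
            continue
        if np.linalg.norm(vector_field_upsilon1(y, p)) > 1e-10:
            continue
        if not any(np.linalg.norm(y - z) < 1e-5 for z in found):
            found.append(np.clip(y, 0.0, None))
    if not found:
        if conds["d_gt_psi_alpha_over_beta"]:
            warnings.warn(
                "existence condition d > psi*alpha_a/beta holds but no F3 root "
                "was found; try more starts",
                stacklevel=2,
            )
        return FixedPoint("F3", None, False, conds)
    best = min(found, key=lambda r: np.linalg.norm(vector_field_upsilon1(r, p)))

    # If the unsaturated root lies near the physical simplex, the true
    # (full-field) equilibrium usually persists inside it: polish against
    # the full field and report the genuine equilibrium when it exists.
    def f_full(y):
        y2 = np.clip(y, 0.0, None)
        if y2[0] + y2[1] > 1.0:
            y2[:2] /= y2[0] + y2[1]
        return vector_field(y2, p)

    polished = root(f_full, best, method="hybr", tol=1e-13)
    y = np.clip(polished.x, 0.0, None)
    interior = (
        polished.success
        and np.linalg.norm(f_full(polished.x)) < 1e-8
        and y[0] + y[1] < 1.0 - 1e-6
        and y[2] > tol
    )
    if interior:
        conds["inside_physical_simplex"] = True
        fp = FixedPoint("F3", State.from_array(y), True, conds)
        if classify:
            classify_stability(fp, p, mode="finite_difference")
    else:
        conds["inside_physical_simplex"] = False
        fp = FixedPoint("F3", State.unchecked(*best), True, conds)
        if classify:
            classify_stability(fp, p)
    return fp


def _root_search(
    p: ModelParams,
    n_starts: int = 64,
    seed: int = 0,
    a_min: float = 0.0,
    a_max: float = 20.0,
) -> list:
    """Multi-start root search of the full field inside the physical region.

    Returns deduplicated roots (as 4-arrays) with S, D in [0, 1], S+D <= 1,
    a >= a_min and m >= 0.
    """
    rng = np.random.default_rng(seed)

    def f(y):
        S, D, a, m = y
        S, D, a, m = max(S, 0.0), max(D, 0.0), max(a, 0.0), max(m, 0.0)
        if S + D > 1.0:
            tot = S + D
            S, D = S / tot, D / tot
        return vector_field([S, D, a, m], p)

    found = []
    for _ in range(n_starts):
        S0 = rng.uniform(0.0, 0.6)
        D0 = rng.uniform(0.0, min(0.6, 1.0 - S0))
        a0 = rng.uniform(max(a_min, 1e-3), a_max) if a_min >= 0 else rng.uniform(0, a_max)
        m0 = rng.uniform(0.0, 2.0 * p.gamma / p.alpha_m)
        sol = root(f, [S0, D0, a0, m0], method="hybr", tol=1e-12)
        if not sol.success:
            continue
        # the search field is the projection of the flow onto the physical
        # region, so a converged point represents its projected state
        y = np.clip(sol.x, 0.0, None)
        if y[0] + y[1] > 1.0:
            y[:2] /= y[0] + y[1]
        # exclude the saturation boundary: stationarity with S+D = 1 is an
        # artifact of the projection, not an equilibrium of the flow
        if y[0] + y[1] > 1 - 1e-6 or y[2] < a_min:
            continue
        if np.linalg.norm(vector_field(y, p)) > 1e-8:
            continue
        if not any(np.linalg.norm(y - z) < 1e-5 for z in found):
            found.append(y)
    return found


def find_fixed_points(p: ModelParams, classify: bool = True) -> list:
    """All fixed points (F1, and F2/F3 where they exist)."""
    out = [fixed_point_f1(p, classify=classify), fixed_point_f2(p, classify=classify)]
    out.append(fixed_point_f3(p, classify=classify))
    return out
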