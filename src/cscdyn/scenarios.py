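"""Named scenario fixtures: one runnable configuration per published regime.

Each scenario bundles the rate constants of one studied regime with a
documented default initial state, a horizon, and (where applicable) the
drug schedule, action parameters and noise specification.  The shared
constants are ``lambda_mitotic = 1.0`` (the time unit), ``psi = 1.0``,
``S0 = 0.038``, ``m0 = 0.5``, ``sq = 0.01`` and ``sl = 0.1``.

Initial states are repository choices (marked in ``notes``): the regimes
are defined by their attractors and parameter rows, not by particular
starting points, so defaults were picked to exhibit each catalogued
outcome class and are freely overridable.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, replace
from typing import Optional

from .model import ModelParams, State
from .pharmacology import ActionParams, DrugSchedule, TherapySpec
from .stochastic import NoiseSpec

__all__ = ["Scenario", "get_scenario", "list_scenarios", "scenario_names", "MODEL_ROWS"]

# (alpha_a, alpha_m, beta, gamma, eta, psi, d, q0) for each regime row.
# fig5a/fig5b/fig5c share the single "fig5" row and differ only in dose.
MODEL_ROWS = {
    "fig1a": (0.5, 1.0, 2.0, 1.0, 5.0, 1.0, 1.2, 0.5),
    "fig1b": (1.0, 1.0, 2.0, 1.0, 5.0, 1.0, 0.2, 1.0),
    "fig2a": (0.5, 1.0, 2.0, 1.0, 5.0, 1.0, 1.2, 0.5),
    "fig2b": (1.0, 1.0, 2.0, 1.0, 5.0, 1.0, 0.2, 1.0),
    "fig2c": (0.4, 0.4, 2.0, 1.0, 2.0, 1.0, 0.4, 1.0),
    "fig2d": (1.0, 1.0, 2.0, 1.0, 5.0, 1.0, 0.2, 1.0),
    "fig3a": (1.0, 1.0, 2.0, 1.0, 5.0, 1.0, 0.2, 1.0),
    "fig5a-c": (1.0, 1.0, 2.0, 4.0, 2.0, 1.0, 0.95, 1.0),
    "fig5d": (1.0, 1.0, 2.0, 1.0, 1.75, 1.0, 0.8, 1.0),
    "fig6a": (0.7, 1.0, 4.0, 1.0, 4.0, 1.0, 1.2, 1.0),
    "fig6b": (1.0, 1.0, 3.0, 1.0, 1.0, 1.0, 0.8, 1.0),
    "fig7a": (1.0, 0.5, 2.0, 3.0, 5.0, 1.0, 0.9, 1.0),
    "fig7b": (1.0, 1.0, 2.0, 1.0, 5.0, 1.0, 0.2, 1.0),
    "fig8a": (1.0, 0.5, 2.0, 3.0, 5.0, 1.0, 0.9, 1.0),
    "fig8b": (0.7, 1.0, 4.0, 1.0, 4.0, 1.0, 1.2, 1.0),
}

#: Reference drug parameter set: chi_max, alpha_d, T, tau, omega0, chi0, s_chi.
DRUG_DEFAULTS = dict(chi_max=1.0, alpha_d=10.0, T=1.0, tau=0.08, omega0=1.0, chi0=0.2, s_chi=0.05)


@dataclass(frozen=True)
class Scenario:
    """A fully specified runnable regime."""

    name: str
    model: ModelParams
    init: State
    t_end: float
    therapy: Optional[TherapySpec] = None
    noise: Optional[NoiseSpec] = None
    n_bundle: Optional[int] = None
    outcome: str = ""
    notes: str = ""

    def with_overrides(self, **model_changes) -> "Scenario":
        return replace(self, model=self.model.replace(**model_changes))


def _params(row: str) -> ModelParams:
    aa, am, b, g, eta, psi, d, q0 = MODEL_ROWS[row]
    return ModelParams(alpha_a=aa, alpha_m=am, beta=b, gamma=g, eta=eta, psi=psi, d=d, q0=q0)


def _drug(therapy_type: str, *, chi_max=None, omega0=None) -> TherapySpec:
    dd = DRUG_DEFAULTS
    sched = DrugSchedule(
        alpha_d=dd["alpha_d"],
        T=dd["T"],
        tau=dd["tau"],
        chi_max=chi_max if chi_max is not None else dd["chi_max"],
    )
    act = ActionParams(
        omega0=omega0 if omega0 is not None else dd["omega0"],
        chi0=dd["chi0"],
        s_chi=dd["s_chi"],
    )
    if therapy_type == "differentiation_plus_cytotoxic":
        # equal-magnitude differentiation and cytotoxic actions
        return TherapySpec(therapy_type, sched, (act, act))
    return TherapySpec(therapy_type, sched, act)


_SMALL_TUMOR = State(S=0.01, D=0.1, a=0.5, m=0.1)
INIT_NOTE = "initial state is a repository default (not part of the published parameter sets)"


def _build() -> dict:
    reg = {}

    def add(name, row, init, t_end, outcome, therapy=None, noise=None, n_bundle=None, extra=""):
        notes = f"model row '{row}'; {INIT_NOTE}"
        if extra:
            notes += "; " + extra
        reg[name] = Scenario(
            name=name,
            model=_params(row),
            init=init,
            t_end=t_end,
            therapy=therapy,
            noise=noise,
            n_bundle=n_bundle,
            outcome=outcome,
            notes=notes,
        )

    _OVERSHOOT = State(S=0.02, D=0.05, a=2.0, m=0.1)
    add(
        "fig1a", "fig1a", _OVERSHOOT, 20.0,
        "overshoot, then convergence on F1 (tumor extinction)",
        extra="start with elevated a(0) so the transient overshoot is visible",
    )
    add("fig1b", "fig1b", _SMALL_TUMOR, 20.0, "convergence on the plasticity-sustained colony F2")
    add(
        "fig2a", "fig2a", _OVERSHOOT, 10.0,
        "stochastic bundle around the F1-convergent regime",
        noise=NoiseSpec(target="lambda_mitotic", rho=0.10), n_bundle=20,
    )
    add(
        "fig2b", "fig2b", _SMALL_TUMOR, 10.0,
        "stochastic bundle around the F2-convergent regime",
        noise=NoiseSpec(target="lambda_mitotic", rho=0.10), n_bundle=20,
    )
    add(
        "fig2c", "fig2c", State(S=0.05, D=0.4, a=0.2, m=0.1), 20.0,
        "falling S and D, then a plasticity bump as m crosses m0, settling on F2",
        noise=NoiseSpec(target="lambda_mitotic", rho=0.10), n_bundle=20,
        extra="start chosen with falling S, D so the plasticity bump near m0 is visible",
    )
    add(
        "fig2d", "fig2d", _SMALL_TUMOR, 10.0,
        "noise on d: D trajectories spread wider than S",
        noise=NoiseSpec(target="d", rho=0.10), n_bundle=20,
    )
    add(
        "fig3a", "fig3a", _SMALL_TUMOR, 10.0,
        "bundle width growth around the stable fixed point F2",
        noise=NoiseSpec(target="lambda_mitotic", rho=0.10), n_bundle=100,
        extra="default initial state is replaced by the F2 location at access time",
    )
    add(
        "fig5a", "fig5a-c", _SMALL_TUMOR, 20.0,
        "cytotoxic therapy breaks the mitosis-plasticity loop: regression to F1",
        therapy=_drug("cytotoxic"),
    )
    add(
        "fig5b", "fig5a-c", _SMALL_TUMOR, 20.0,
        "cytotoxic therapy, higher dose: faster regression",
        therapy=_drug("cytotoxic", chi_max=2.0, omega0=1.5),
        extra="dose overrides chi_max=2.0, omega0=1.5",
    )
    add(
        "fig5c", "fig5a-c", _SMALL_TUMOR, 20.0,
        "cytotoxic therapy, highest dose: fastest regression",
        therapy=_drug("cytotoxic", chi_max=3.0, omega0=2.0),
        extra="dose overrides chi_max=3.0, omega0=2.0",
    )
    add(
        "fig5d", "fig5d", State(S=0.05, D=0.25, a=30.0, m=0.1), 20.0,
        "tumor growth paradox: untreated overshoot regresses, cytotoxic therapy diverges",
        therapy=_drug("cytotoxic"),
        extra="large a(0) puts the start near the unstable proliferative region",
    )
    add(
        "fig6a", "fig6a", State(S=0.2, D=0.1, a=1.0, m=0.1), 20.0,
        "cytostatic rescue: untreated run proliferates out of control, treated regresses",
        therapy=_drug("cytostatic"),
        extra="large a(0) and sizeable S(0) drive the untreated run to divergence",
    )
    add(
        "fig6b", "fig6b", State(S=0.05, D=0.02, a=3.0, m=0.1), 20.0,
        "cytostatic delay: spontaneous regression happens later under treatment",
        therapy=_drug("cytostatic"),
    )
    add(
        "fig7a", "fig7a", _SMALL_TUMOR, 30.0,
        "anti-plasticity therapy breaks the de-differentiation loop: slow regression",
        therapy=_drug("anti_plasticity"),
    )
    add(
        "fig7b", "fig7b", _SMALL_TUMOR, 20.0,
        "anti-plasticity action too weak (d << q0): colony relaxes back onto F2",
        therapy=_drug("anti_plasticity"),
    )
    add(
        "fig8a", "fig8a", _SMALL_TUMOR, 30.0,
        "combined differentiation + cytotoxic therapy: regression of the stable colony",
        therapy=_drug("differentiation_plus_cytotoxic"),
    )
    add(
        "fig8b", "fig8b", State(S=0.2, D=0.1, a=1.0, m=0.1), 20.0,
        "combined therapy tames an otherwise divergent proliferation",
        therapy=_drug("differentiation_plus_cytotoxic"),
    )
    return reg


_REGISTRY = _build()


def scenario_names() -> list:
    return sorted(_REGISTRY)


def get_scenario(name: str) -> Scenario:
    """Look up a scenario by name (e.g. ``"fig1b"``).

    Unknown names raise a ``KeyError`` listing close matches and the full
    catalogue.
    """
    key = name.lower().strip()
    if key not in _REGISTRY:
        close = difflib.get_close_matches(key, _REGISTRY, n=3)
        hint = f" Did you mean {', '.join(close)}?" if close else ""
        raise KeyError(
            f"unknown scenario {name!r}.{hint} Available: {', '.join(scenario_names())}"
        )
    sc = _REGISTRY[key]
    if key == "fig3a":
        # the width study starts on the stable colony itself
        from .fixed_points import fixed_point_f2

        f2 = fixed_point_f2(sc.model, classify=False)
        sc = replace(sc, init=f2.location)
    return sc


def list_scenarios() -> dict:
    """Catalogue: name -> one-line expected outcome."""
    return {name: _REGISTRY[name].outcome for name in scenario_names()}
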