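"""Configuration and output serialization shared by library and CLI.

Trajectories are written as CSV (columns ``t,S,D,a,m`` plus any
time-dependent parameter columns) with a JSON sidecar for events and
metadata.  Scenario configurations round-trip through YAML with field
names matching the parameter tables (``alpha_a``, ``alpha_m``, ``beta``,
``gamma``, ``eta``, ``psi``, ``d``, ``q0``; drug block ``chi_max``,
``alpha_d``, ``T``, ``tau``, ``omega0``, ``chi0``, ``s_chi``).

All floats are serialized with 17 significant digits so that re-imported
configurations reproduce runs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import yaml

from .model import ModelParams, State, Trajectory
from .pharmacology import ActionParams, DrugSchedule, TherapySpec
from .scenarios import Scenario
from .stochastic import Bundle, NoiseSpec, WidthSeries

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "export_scenario_yaml",
    "load_scenario_yaml",
    "write_trajectory_csv",
    "write_bundle_csv",
    "write_widths_csv",
    "fixed_points_to_json",
]

FLOAT_FMT = "%.17g"


def _clean(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None}


def scenario_to_dict(sc: Scenario) -> dict:
    out = {
        "name": sc.name,
        "model": sc.model.as_dict(),
        "init": {"S": sc.init.S, "D": sc.init.D, "a": sc.init.a, "m": sc.init.m},
        "t_end": sc.t_end,
        "outcome": sc.outcome,
        "notes": sc.notes,
    }
    if sc.therapy is not None:
        th = sc.therapy
        actions = th.action if isinstance(th.action, tuple) else (th.action,)
        out["therapy"] = {
            "therapy_type": th.therapy_type,
            "clamp_at_zero": th.clamp_at_zero,
            "schedule": _clean(dataclasses.asdict(th.schedule)),
            "actions": [dataclasses.asdict(a) for a in actions],
        }
    if sc.noise is not None:
        out["noise"] = _clean(dataclasses.asdict(sc.noise))
    if sc.n_bundle is not None:
        out["n_bundle"] = sc.n_bundle
    return out


def scenario_from_dict(d: dict) -> Scenario:
    therapy = None
    if "therapy" in d:
        th = d["therapy"]
        actions = tuple(ActionParams(**a) for a in th["actions"])
        action = actions if len(actions) == 2 else actions[0]
        therapy = TherapySpec(
            therapy_type=th["therapy_type"],
            schedule=DrugSchedule(**th["schedule"]),
            action=action,
            clamp_at_zero=th.get("clamp_at_zero", True),
        )
    noise = NoiseSpec(**d["noise"]) if "noise" in d else None
    return Scenario(
        name=d["name"],
        model=ModelParams(**d["model"]),
        init=State(**d["init"]),
        t_end=float(d["t_end"]),
        therapy=therapy,
        noise=noise,
        n_bundle=d.get("n_bundle"),
        outcome=d.get("outcome", ""),
        notes=d.get("notes", ""),
    )


def export_scenario_yaml(sc: Scenario, path=None) -> str:
    text = yaml.safe_dump(scenario_to_dict(sc), sort_keys=False, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_scenario_yaml(source) -> Scenario:
    """Load a scenario from a YAML string or file path."""
    text = str(source)
    if "\n" not in text and len(text) < 4096 and Path(text).exists():
        text = Path(text).read_text()
    return scenario_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path, sidecar: bool = True) -> None:
    """CSV with columns t,S,D,a,m (+ parameter columns); JSON sidecar for
    events and metadata next to it (``<path>.meta.json``)."""
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    if sidecar:
        meta = {
            "events": [[t, k] for t, k in traj.events],
            "metadata": _jsonable(traj.metadata),
        }
        if traj.params_used is not None:
            meta["params"] = traj.params_used.as_dict()
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def write_bundle_csv(b: Bundle, path) -> None:
    """Wide CSV: one column per realization per variable (S_0, S_1, ...)."""
    import pandas as pd

    data = {"t": b.times}
    for vi, v in enumerate(("S", "D", "a", "m")):
        for i in range(b.n):
            data[f"{v}_{i}"] = b.states[i, :, vi]
    for i in range(b.n):
        data[f"{b.noise.target}_{i}"] = b.param_paths[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "n": b.n,
        "seeds": list(map(int, b.seeds)),
        "flags": [sorted(f) for f in b.flags],
        "noise": _clean(dataclasses.asdict(b.noise)),
        "metadata": _jsonable(b.metadata),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def write_widths_csv(ws: WidthSeries, path) -> None:
    import pandas as pd

    data = {"t": ws.times}
    for v, s in ws.sigma.items():
        data[f"sigma_{v}"] = s
    for v, mu in ws.mu.items():
        data[f"mu_{v}"] = mu
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def fixed_points_to_json(fps, path=None) -> str:
    text = json.dumps([fp.as_dict() for fp in fps], indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
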