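"""Scenario/trajectory serialization, run manifests and synthetic fixtures.

Scenarios are stored as hand-editable YAML (flat keys plus an event
list); trajectories as CSV with header ``t,E,P,M,I,S,a,c,r,m`` and full
float precision.  Every run is paired with a manifest recording the
scenario hash, the seed, the software version and all declared modelling
conventions, so a run can be reproduced bit-exactly.

The synthetic generators emulate the inputs that real deployments would
supply: daily therapeutic-alliance trajectories (the b_t series) and
randomized whole scenarios for property testing.  No downloads, no
deposited data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import STATE_VARS, TRAIT_PARAMS, TraitVector
from .engine import (
    InterventionEvent,
    NoiseSpec,
    Scenario,
    Trajectory,
    run,
)
from .traits import FilterConfig, TraitUpdateConfig

log = logging.getLogger(__name__)

#: Declared modelling conventions, recorded in every run manifest/log.
CONVENTIONS = {
    "noise_model": "additive uniform on +/-(level/100 * half range width)",
    "intervention": "additive shift of magnitude/100 internal units",
    "decay_indexing": "sample age within window; newest weight 1",
    "delta": "pre-saturation raw increment w * base * driver",
    "alliance_mix": "mean of a_{t-1} and b_t on every trait update",
    "z_scores": "whole series, sample (n-1) SD",
    "smoothing_edges": "truncated windows",
    "warm_up": "traits frozen for the first n iterations",
}


class ScenarioFormatError(ValueError):
    """The scenario file is malformed or fails validation."""


# --------------------------------------------------------------------------
# Scenario YAML
# --------------------------------------------------------------------------

def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "T": int(sc.T),
        "seed": int(sc.seed),
        "initial_states": {v: sc.initial_states[v] for v in STATE_VARS},
        "initial_traits": {p: sc.initial_traits[p] for p in TRAIT_PARAMS},
        "filter": {
            "n": int(sc.filter_cfg.n),
            "tau": dict(sc.filter_cfg.tau),
            "lam": dict(sc.filter_cfg.lam),
            "d": dict(sc.filter_cfg.d),
        },
        "trait_update": {
            "w": dict(sc.update_cfg.w),
            "bounds": {p: list(b) for p, b in sc.update_cfg.bounds.items()},
            "gate_low": sc.update_cfg.gate_low,
            "gate_high": sc.update_cfg.gate_high,
            "literal_low_gate": sc.update_cfg.literal_low_gate,
        },
        "noise": {
            "distribution": sc.noise.distribution,
            "levels": dict(sc.noise.levels),
        },
        "interventions": [asdict(ev) for ev in sc.interventions],
        "alliance": list(sc.alliance) if sc.alliance is not None else None,
        "overrides": (
            {p: [list(pt) for pt in pts] for p, pts in sc.overrides.items()}
            if sc.overrides else None
        ),
        "ranges": {v: list(sc.ranges[v]) for v in STATE_VARS},
    }


def scenario_from_dict(data: dict) -> Scenario:
    try:
        filt = data.get("filter", {})
        upd = data.get("trait_update", {})
        noise = data.get("noise", {})
        return Scenario(
            T=data["T"],
            initial_states=data["initial_states"],
            initial_traits=TraitVector(**data.get(
                "initial_traits", {"a": 0.3, "c": 0.3, "r": 0.3, "m": 0.3})),
            filter_cfg=FilterConfig(
                n=filt.get("n", 14),
                tau=filt.get("tau", 7.0),
                d=filt.get("d", 0.535),
                lam=filt.get("lam"),
            ),
            update_cfg=TraitUpdateConfig(
                w=upd.get("w", 0.004167),
                bounds=(
                    upd["bounds"] if "bounds" in upd else (0.1, 0.8)
                ),
                gate_low=upd.get("gate_low", 0.2),
                gate_high=upd.get("gate_high", 0.8),
                literal_low_gate=upd.get("literal_low_gate", True),
            ),
            interventions=tuple(
                InterventionEvent(**ev) for ev in data.get("interventions", [])
            ),
            noise=NoiseSpec(
                levels=noise.get("levels", 0.0),
                distribution=noise.get("distribution", "uniform"),
            ),
            alliance=data.get("alliance"),
            overrides=data.get("overrides"),
            ranges=data.get("ranges"),
            seed=data.get("seed", 0),
            name=data.get("name", ""),
        )
    except KeyError as err:
        raise ScenarioFormatError(f"scenario is missing required key {err}") from err
    except (TypeError, ValueError) as err:
        raise ScenarioFormatError(f"invalid scenario: {err}") from err


def write_scenario(sc: Scenario, path) -> Path:
    path = Path(path)
    header = (
        "# Simulation scenario for the state-trait psychotherapy dynamics model.\n"
        "# Initial states use the empirical +/-100 scale; traits lie in [0, 1].\n"
        "# Intervention magnitudes are signed percent of the 100-point scale.\n"
    )
    path.write_text(header + yaml.safe_dump(scenario_to_dict(sc), sort_keys=False))
    return path


def read_scenario(path) -> Scenario:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ScenarioFormatError(f"cannot parse {path}: {err}") from err
    if not isinstance(data, dict):
        raise ScenarioFormatError(f"{path} does not contain a scenario mapping")
    return scenario_from_dict(data)


def scenario_hash(sc: Scenario) -> str:
    payload = json.dumps(scenario_to_dict(sc), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


# --------------------------------------------------------------------------
# Trajectory CSV
# --------------------------------------------------------------------------

TRAJECTORY_COLUMNS = ["t", *STATE_VARS, *TRAIT_PARAMS]


def write_trajectory(traj: Trajectory, path, audit: bool = False) -> Path:
    path = Path(path)
    traj.to_frame(audit=audit).to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ScenarioFormatError(
            f"trajectory file {path} is missing columns {missing}"
        )
    return df


def read_alliance(path) -> tuple[float, ...]:
    """Read a single-column b_t CSV; 0–100-scaled series are auto-detected
    (max > 1) and divided by 100, which is logged."""
    raw = pd.read_csv(path, header=None).iloc[:, 0]
    if raw.dtype == object:  # a header line was present
        raw = pd.to_numeric(raw.iloc[1:], errors="raise")
    values = raw.to_numpy(dtype=float)
    if len(values) and np.nanmax(values) > 1.0:
        log.info("alliance series %s detected on 0-100 scale; dividing by 100", path)
        values = values / 100.0
    return tuple(float(v) for v in values)


# --------------------------------------------------------------------------
# Run manifest
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    scenario_hash: str
    seed: int
    version: str
    conventions: dict
    created: str

    @classmethod
    def for_scenario(cls, sc: Scenario) -> "RunManifest":
        from . import __version__

        return cls(
            scenario_hash=scenario_hash(sc),
            seed=int(sc.seed),
            version=__version__,
            conventions=dict(CONVENTIONS),
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path


def read_manifest(path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))


def write_run(traj: Trajectory, outdir, audit: bool = False) -> dict[str, Path]:
    """Write trajectory.csv, scenario.yaml, manifest.json and run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = traj.scenario
    paths = {
        "trajectory": write_trajectory(traj, outdir / "trajectory.csv", audit=audit),
        "scenario": write_scenario(sc, outdir / "scenario.yaml"),
        "manifest": write_manifest(RunManifest.for_scenario(sc), outdir / "manifest.json"),
    }
    lines = [f"scenario={sc.name or 'unnamed'} T={sc.T} seed={sc.seed}"]
    lines += [f"convention.{k}={v}" for k, v in CONVENTIONS.items()]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
    paths["log"] = outdir / "run.log"
    return paths


# --------------------------------------------------------------------------
# Synthetic fixtures
# --------------------------------------------------------------------------

def synth_alliance(
    T: int,
    shape: str = "logistic",
    noise_sd: float = 0.0,
    seed: int = 0,
    start: float = 0.3,
    stop: float = 0.8,
    level: float = 0.5,
    rate: float = 0.15,
) -> tuple[float, ...]:
    """Synthetic daily therapeutic-alliance series b_t in [0, 1].

    Shapes: ``constant`` (flat at ``level``), ``linear`` (start→stop),
    ``logistic`` (sigmoidal alliance growth from start to stop, midpoint
    at T/2 — the typical build-up of a working alliance over a
    treatment episode).  Gaussian noise of SD ``noise_sd`` is added and
    the series is clipped to [0, 1].  Same seed, same series.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    t = np.arange(1, T + 1, dtype=float)
    if shape == "constant":
        base = np.full(T, float(level))
    elif shape == "linear":
        base = start + (stop - start) * (t - 1) / max(T - 1, 1)
    elif shape == "logistic":
        base = start + (stop - start) / (1.0 + np.exp(-rate * (t - T / 2.0)))
    else:
        raise ValueError(
            f"unknown shape {shape!r}; expected constant, linear or logistic"
        )
    if noise_sd:
        base = base + np.random.default_rng(seed).normal(0.0, noise_sd, T)
    return tuple(float(v) for v in np.clip(base, 0.0, 1.0))


def random_scenario(seed: int, T: int = 1000) -> Scenario:
    """A randomized but valid scenario for property testing.

    Draws initial states across their empirical ranges, traits across
    [0.05, 0.95], per-variable noise levels up to 30% and up to three
    random intervention events; everything is derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    init = {}
    for v in STATE_VARS:
        lo, hi = (-100.0, 100.0) if v in ("E", "S") else (0.0, 100.0)
        init[v] = float(rng.uniform(lo, hi))
    traits = TraitVector(*(float(x) for x in rng.uniform(0.05, 0.95, 4)))
    levels = {v: float(rng.uniform(0.0, 30.0)) for v in STATE_VARS}
    events = []
    for _ in range(rng.integers(0, 4)):
        t0 = int(rng.integers(1, max(T - 1, 2)))
        t1 = int(min(T, t0 + rng.integers(0, 50)))
        var = str(rng.choice(STATE_VARS))
        events.append(
            InterventionEvent(t0, t1, var, float(rng.uniform(-30.0, 30.0)))
        )
    return Scenario(
        T=T,
        initial_states=init,
        initial_traits=traits,
        noise=NoiseSpec(levels=levels),
        interventions=tuple(events),
        seed=int(rng.integers(0, 2**31 - 1)),
        name=f"random-{seed}",
    )


def run_preset(name: str, seed: int | None = None) -> Trajectory:
    """Materialize and run a preset scenario (optionally re-seeded)."""
    from .engine import preset_scenario

    sc = preset_scenario(name)
    if seed is not None:
        sc = sc.with_seed(seed)
    return run(sc)
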