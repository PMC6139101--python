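"""Scenario orchestration: the per-iteration update cycle and trajectory record.

A simulation run repeats, for t = 1..T:

1. one synchronous step of the five state equations under the current traits,
2. additive intervention shifts scheduled for this iteration,
3. additive dynamic noise (daily hassles and uplifts),
4. clamping of each state to its configured internal range,
5. from t = n on, one trait update from the trailing n-day state window —
   unless an override schedule pins a trait, in which case its scheduled
   value is used verbatim (the mechanism behind control-parameter ramp
   experiments).

Initial values arrive on the empirical ±100 questionnaire scale and are
mapped to the internal scale by division by 100.  Intervention
magnitudes are signed percent of the 100-point scale, i.e. additive
shifts of magnitude/100 internal units.  Noise is uniform (by default)
on ±(level/100 · half range width).  One master seed spawns independent
per-variable substreams, so adding an intervention or changing one
variable's noise level never shifts another variable's noise sequence.

Every applied noise and intervention increment is recorded, so a
trajectory can be replayed bit-exactly from its initial condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    STATE_VARS,
    TRAIT_PARAMS,
    DEFAULT_CONSTANTS,
    EquationConstants,
    StateVector,
    TraitVector,
    step_states,
)
from .traits import (
    FilterConfig,
    StateWindow,
    TraitUpdateConfig,
    update_traits,
)

#: Default internal ranges: bipolar variables span [-1, 1], unipolar [0, 1].
#: The sigmoid gains and offsets of the equations produce non-degenerate
#: responses on these spans; figure-caption initial values on the ±100
#: empirical scale map onto them by division by 100.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "E": (-1.0, 1.0),
    "P": (0.0, 1.0),
    "M": (0.0, 1.0),
    "I": (0.0, 1.0),
    "S": (-1.0, 1.0),
}

EMPIRICAL_SCALE = 100.0


@dataclass(frozen=True)
class InterventionEvent:
    """One additive intervention: ``magnitude`` percent of the 100-point
    scale applied to ``variable`` on every iteration of [t_start, t_end]."""

    t_start: int
    t_end: int
    variable: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.variable not in STATE_VARS:
            raise ValueError(
                f"unknown variable {self.variable!r}; expected one of {STATE_VARS}"
            )
        if self.t_start > self.t_end:
            raise ValueError(
                f"event start {self.t_start} is after its end {self.t_end}"
            )

    def active(self, t: int) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass(frozen=True)
class NoiseSpec:
    """Per-variable dynamic-noise levels in percent of half the range width."""

    levels: Mapping[str, float] | float = 0.0
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if isinstance(self.levels, Mapping):
            levels = {v: float(self.levels.get(v, 0.0)) for v in STATE_VARS}
        else:
            levels = {v: float(self.levels) for v in STATE_VARS}
        for v, lv in levels.items():
            if lv < 0:
                raise ValueError(f"noise level for {v} must be >= 0, got {lv}")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(
                f"unknown noise distribution {self.distribution!r}; "
                "expected 'uniform' or 'normal'"
            )
        object.__setattr__(self, "levels", levels)


def _normalize_overrides(overrides) -> dict[str, tuple[tuple[float, float], ...]]:
    out: dict[str, tuple[tuple[float, float], ...]] = {}
    for param, points in overrides.items():
        if param not in TRAIT_PARAMS:
            raise ValueError(
                f"unknown trait parameter {param!r} in override schedule"
            )
        pts = tuple((float(t), float(v)) for t, v in points)
        if not pts:
            raise ValueError(f"override schedule for {param} is empty")
        if any(b[0] < a[0] for a, b in zip(pts, pts[1:])):
            raise ValueError(f"override schedule for {param} must be sorted by t")
        for t, v in pts:
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"override value for {param} at t={t} must lie in [0, 1], got {v}"
                )
        out[param] = pts
    return out


def override_value(points: Sequence[tuple[float, float]], t: int) -> float:
    """Piecewise-linear override schedule value at iteration t (flat ends)."""
    ts = [p[0] for p in points]
    vs = [p[1] for p in points]
    return float(np.interp(t, ts, vs))


@dataclass(frozen=True)
class Scenario:
    """Full specification of one simulation run.

    Initial states are on the empirical scale (E, S in [-100, 100]; P, M,
    I in [0, 100]).  ``alliance`` is the optional daily b_t series in
    [0, 1] (length >= T); ``overrides`` maps trait names to
    piecewise-linear (t, value) schedules that disable the endogenous
    dynamics of that trait.  ``seed`` fixes every random draw.
    """

    T: int
    initial_states: Mapping[str, float]
    initial_traits: TraitVector = TraitVector(0.3, 0.3, 0.3, 0.3)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    update_cfg: TraitUpdateConfig = field(default_factory=TraitUpdateConfig)
    interventions: tuple[InterventionEvent, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    alliance: tuple[float, ...] | None = None
    overrides: Mapping[str, tuple[tuple[float, float], ...]] | None = None
    ranges: Mapping[str, tuple[float, float]] | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 1):
            raise ValueError(f"iteration count T must be an integer >= 1, got {self.T!r}")
        ranges = dict(DEFAULT_RANGES if self.ranges is None else self.ranges)
        missing = set(STATE_VARS) - set(ranges)
        if missing:
            raise ValueError(f"ranges missing entries for {sorted(missing)}")
        init = {v: float(self.initial_states[v]) for v in STATE_VARS}
        for v, x in init.items():
            lo, hi = ranges[v]
            if not lo * EMPIRICAL_SCALE <= x <= hi * EMPIRICAL_SCALE:
                raise ValueError(
                    f"initial value for {v} must lie in "
                    f"[{lo * EMPIRICAL_SCALE}, {hi * EMPIRICAL_SCALE}], got {x}"
                )
        if self.alliance is not None:
            alliance = tuple(float(b) for b in self.alliance)
            if len(alliance) < self.T:
                raise ValueError(
                    f"alliance series has {len(alliance)} values but the run "
                    f"needs at least T={self.T}"
                )
            for b in alliance:
                if not 0.0 <= b <= 1.0:
                    raise ValueError(f"alliance values must lie in [0, 1], got {b}")
            object.__setattr__(self, "alliance", alliance)
        object.__setattr__(self, "initial_states", init)
        object.__setattr__(self, "ranges", {v: tuple(ranges[v]) for v in STATE_VARS})
        object.__setattr__(self, "interventions", tuple(self.interventions))
        if self.overrides is not None:
            object.__setattr__(self, "overrides", _normalize_overrides(self.overrides))

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))


@dataclass
class Trajectory:
    """Per-iteration record of a run: states, traits and audit increments.

    All arrays share length T+1 (row 0 is the initial condition).  The
    recorded noise and intervention increments replay the raw states
    exactly when re-applied from the initial condition.
    """

    scenario: Scenario
    states: np.ndarray        # (T+1, 5) in STATE_VARS order
    traits: np.ndarray        # (T+1, 4) in TRAIT_PARAMS order
    noise_inc: np.ndarray     # (T+1, 5), row 0 all zero
    interv_inc: np.ndarray    # (T+1, 5), row 0 all zero

    @property
    def T(self) -> int:
        return len(self.states) - 1

    def series(self, name: str) -> np.ndarray:
        """The full time series of one state variable or trait parameter."""
        if name in STATE_VARS:
            return self.states[:, STATE_VARS.index(name)]
        if name in TRAIT_PARAMS:
            return self.traits[:, TRAIT_PARAMS.index(name)]
        raise KeyError(name)

    def to_frame(self, audit: bool = False):
        """The trajectory as a pandas DataFrame, header t,E,P,M,I,S,a,c,r,m."""
        import pandas as pd

        data = {"t": np.arange(len(self.states))}
        for i, v in enumerate(STATE_VARS):
            data[v] = self.states[:, i]
        for j, p in enumerate(TRAIT_PARAMS):
            data[p] = self.traits[:, j]
        if audit:
            for i, v in enumerate(STATE_VARS):
                data[f"noise_{v}"] = self.noise_inc[:, i]
            for i, v in enumerate(STATE_VARS):
                data[f"interv_{v}"] = self.interv_inc[:, i]
        return pd.DataFrame(data, columns=list(data))


def rescale_initial(
    empirical: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> StateVector:
    """Map empirical-scale initial values (±100) to the internal scale (/100)."""
    vals = {}
    for v in STATE_VARS:
        x = float(empirical[v])
        lo, hi = ranges[v]
        if not lo * EMPIRICAL_SCALE <= x <= hi * EMPIRICAL_SCALE:
            raise ValueError(
                f"initial value for {v} must lie in "
                f"[{lo * EMPIRICAL_SCALE}, {hi * EMPIRICAL_SCALE}], got {x}"
            )
        vals[v] = x / EMPIRICAL_SCALE
    return StateVector(**vals)


def intervention_shift(
    schedule: Sequence[InterventionEvent], t: int
) -> dict[str, float]:
    """Summed internal-scale shift per variable from all events active at t."""
    shift = dict.fromkeys(STATE_VARS, 0.0)
    for ev in schedule:
        if ev.active(t):
            shift[ev.variable] += ev.magnitude / EMPIRICAL_SCALE
    return shift


def apply_interventions(
    state: StateVector, schedule: Sequence[InterventionEvent], t: int
) -> StateVector:
    """Add every active event's magnitude/100 to its variable (effects add)."""
    shift = intervention_shift(schedule, t)
    if all(s == 0.0 for s in shift.values()):
        return state
    return StateVector(**{v: state[v] + shift[v] for v in STATE_VARS})


def noise_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-variable RNG substreams spawned from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(STATE_VARS))
    return {v: np.random.default_rng(ss) for v, ss in zip(STATE_VARS, children)}


def noise_draw(
    spec: NoiseSpec,
    streams: Mapping[str, np.random.Generator],
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> dict[str, float]:
    """One iteration's additive noise per variable.

    Uniform on ±(level/100 · R/2) where R is the variable's range width
    (or normal with that value as standard deviation).  A zero level
    draws nothing, so its variable's stream stays untouched and the
    perturbation is exactly 0.0.
    """
    out = dict.fromkeys(STATE_VARS, 0.0)
    for v in STATE_VARS:
        level = spec.levels[v]
        if level == 0.0:
            continue
        lo, hi = ranges[v]
        half = (hi - lo) / 2.0
        amp = level / 100.0 * half
        if spec.distribution == "uniform":
            out[v] = float(streams[v].uniform(-amp, amp))
        else:
            out[v] = float(streams[v].normal(0.0, amp))
    return out


def apply_noise(
    state: StateVector,
    spec: NoiseSpec,
    streams: Mapping[str, np.random.Generator],
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> StateVector:
    draw = noise_draw(spec, streams, ranges)
    if all(d == 0.0 for d in draw.values()):
        return state
    return StateVector(**{v: state[v] + draw[v] for v in STATE_VARS})


def clamp_states(
    state: StateVector,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> StateVector:
    """Clip each variable to its configured internal range (idempotent)."""
    vals = {}
    for v in STATE_VARS:
        lo, hi = ranges[v]
        vals[v] = min(hi, max(lo, state[v]))
    return StateVector(**vals)


def run(
    scenario: Scenario,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> Trajectory:
    """Execute a scenario and record the full trajectory.

    Identical scenarios (including the seed) yield bit-identical
    trajectories.  Traits are frozen during the warm-up period while the
    state window fills (the first n iterations), so no starting instant
    is privileged by the deviation filters.
    """
    ranges = scenario.ranges
    fcfg, ucfg = scenario.filter_cfg, scenario.update_cfg
    n = fcfg.n
    weights = {v: fcfg.weights(v) for v in STATE_VARS}
    overrides = scenario.overrides or {}
    all_pinned = set(overrides) == set(TRAIT_PARAMS)

    state = rescale_initial(scenario.initial_states, ranges)
    traits = scenario.initial_traits
    if overrides:
        pinned = {p: override_value(pts, 0) for p, pts in overrides.items()}
        traits = TraitVector(**{p: pinned.get(p, traits[p]) for p in TRAIT_PARAMS})

    T = scenario.T
    states = np.empty((T + 1, len(STATE_VARS)))
    traits_arr = np.empty((T + 1, len(TRAIT_PARAMS)))
    noise_inc = np.zeros((T + 1, len(STATE_VARS)))
    interv_inc = np.zeros((T + 1, len(STATE_VARS)))
    states[0] = state.as_tuple()
    traits_arr[0] = traits.as_tuple()

    window = StateWindow(n=n)
    window.append(state)
    streams = noise_streams(scenario.seed)

    for t in range(1, T + 1):
        try:
            stepped = step_states(state, traits, constants)
            iv = intervention_shift(scenario.interventions, t)
            nz = noise_draw(scenario.noise, streams, ranges)
            vals = {}
            for v in STATE_VARS:
                x = stepped[v]
                if iv[v] != 0.0:
                    x = x + iv[v]
                if nz[v] != 0.0:
                    x = x + nz[v]
                lo, hi = ranges[v]
                vals[v] = min(hi, max(lo, x))
            state = StateVector(**vals)
        except Exception as err:
            raise RuntimeError(f"simulation failed at iteration t={t}: {err}") from err
        window.append(state)

        if t >= n and not all_pinned:
            b_t = scenario.alliance[t - 1] if scenario.alliance is not None else None
            traits = update_traits(traits, window, fcfg, ucfg, b_t, weights)
        if overrides:
            pinned = {p: override_value(pts, t) for p, pts in overrides.items()}
            traits = TraitVector(
                **{p: pinned.get(p, traits[p]) for p in TRAIT_PARAMS}
            )

        states[t] = state.as_tuple()
        traits_arr[t] = traits.as_tuple()
        noise_inc[t] = [nz[v] for v in STATE_VARS]
        interv_inc[t] = [iv[v] for v in STATE_VARS]

    return Trajectory(
        scenario=scenario,
        states=states,
        traits=traits_arr,
        noise_inc=noise_inc,
        interv_inc=interv_inc,
    )


def replay_states(trajectory: Trajectory,
                  constants: EquationConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Rebuild the raw state array from the recorded audit increments.

    Applies the deterministic state step plus the recorded intervention
    and noise increments (in the original order) and re-clamps; the
    result must equal ``trajectory.states`` bit-exactly.
    """
    sc = trajectory.scenario
    ranges = sc.ranges
    out = np.empty_like(trajectory.states)
    out[0] = trajectory.states[0]
    state = StateVector(**dict(zip(STATE_VARS, trajectory.states[0])))
    for t in range(1, len(out)):
        traits = TraitVector(**dict(zip(TRAIT_PARAMS, trajectory.traits[t - 1])))
        stepped = step_states(state, traits, constants)
        vals = {}
        for i, v in enumerate(STATE_VARS):
            x = stepped[v]
            iv = trajectory.interv_inc[t, i]
            nz = trajectory.noise_inc[t, i]
            if iv != 0.0:
                x = x + iv
            if nz != 0.0:
                x = x + nz
            lo, hi = ranges[v]
            vals[v] = min(hi, max(lo, x))
        state = StateVector(**vals)
        out[t] = state.as_tuple()
    return out


# --------------------------------------------------------------------------
# Preset scenarios: the published simulation experiments
# --------------------------------------------------------------------------

#: The recurring default start: high dysphoric affect and problem load,
#: maximal insight pressure, little motivation, negative experienced success.
_BASELINE_START = {"E": 97.6, "P": 61.5, "M": 7.5, "I": 100.0, "S": -40.7}
_CRISIS_START = {"E": 100.0, "P": 79.0, "M": 32.5, "I": 50.0, "S": 33.5}


def _fig3() -> Scenario:
    # Control-parameter ramp: c pinned at 0.60, raised linearly to 1.00 over
    # iterations 100..200, constant afterwards; a, r, m pinned mid-range.
    # The endogenous trait dynamics is disabled for all four parameters.
    return Scenario(
        T=400,
        initial_states=dict(_BASELINE_START),
        initial_traits=TraitVector(0.5, 0.6, 0.5, 0.5),
        noise=NoiseSpec(levels=10.0),
        overrides={
            "a": ((0, 0.5),),
            "r": ((0, 0.5),),
            "m": ((0, 0.5),),
            "c": ((0, 0.60), (100, 0.60), (200, 1.00), (400, 1.00)),
        },
        name="fig3",
    )


def _fig5() -> Scenario:
    return Scenario(
        T=200,
        initial_states=dict(_BASELINE_START),
        initial_traits=TraitVector(0.30, 0.30, 0.30, 0.30),
        noise=NoiseSpec(levels=30.0),
        interventions=(
            InterventionEvent(50, 60, "M", +20.0),
            InterventionEvent(50, 60, "I", +20.0),
            InterventionEvent(50, 60, "S", +20.0),
            InterventionEvent(50, 60, "E", -20.0),
            InterventionEvent(50, 60, "P", -20.0),
        ),
        name="fig5",
    )


def _fig6a() -> Scenario:
    return Scenario(
        T=100,
        initial_states=dict(_CRISIS_START),
        initial_traits=TraitVector(a=0.10, c=0.35, r=0.35, m=0.10),
        noise=NoiseSpec(levels=10.0),
        interventions=tuple(
            InterventionEvent(t, t, "S", +38.0) for t in (17, 30, 50)
        ),
        name="fig6a",
    )


def _fig6b() -> Scenario:
    # The continuous-intervention window runs t = 17..25 (body text; the
    # figure caption's "27 to 25" is inconsistent with itself).
    return Scenario(
        T=100,
        initial_states=dict(_CRISIS_START),
        initial_traits=TraitVector(a=0.10, c=0.35, r=0.35, m=0.10),
        noise=NoiseSpec(levels=10.0),
        interventions=(InterventionEvent(17, 25, "S", +38.0),),
        name="fig6b",
    )


def _fig7() -> Scenario:
    return Scenario(
        T=150,
        initial_states=dict(_BASELINE_START),
        initial_traits=TraitVector(a=0.10, c=0.75, r=0.46, m=0.53),
        noise=NoiseSpec(levels={"E": 10.0, "P": 10.0, "M": 5.0, "I": 5.0, "S": 5.0}),
        name="fig7",
    )


def _fig8() -> Scenario:
    return Scenario(
        T=300,
        initial_states=dict(_BASELINE_START),
        initial_traits=TraitVector(0.20, 0.20, 0.20, 0.20),
        noise=NoiseSpec(levels=2.0),
        interventions=(
            InterventionEvent(20, 200, "E", -10.0),
            InterventionEvent(20, 100, "P", -10.0),
            InterventionEvent(20, 100, "M", +5.0),
            InterventionEvent(25, 100, "I", +10.0),
            InterventionEvent(25, 100, "S", +10.0),
        ),
        name="fig8",
    )


def _fig9() -> Scenario:
    return Scenario(
        T=108,
        initial_states={"E": 100.0, "P": 79.0, "M": 32.5, "I": 50.0, "S": 1.0},
        initial_traits=TraitVector(a=0.10, c=0.60, r=0.35, m=0.10),
        noise=NoiseSpec(levels={"E": 2.0, "P": 2.0, "M": 5.0, "I": 5.0, "S": 5.0}),
        interventions=(
            InterventionEvent(35, 100, "P", -10.0),
            InterventionEvent(35, 100, "M", +10.0),
            InterventionEvent(35, 100, "S", +10.0),
            InterventionEvent(35, 50, "E", -10.0),
            InterventionEvent(35, 50, "I", +10.0),
        ),
        name="fig9",
    )


_PRESETS = {
    "fig3": _fig3,
    "fig5": _fig5,
    "fig6a": _fig6a,
    "fig6b": _fig6b,
    "fig7": _fig7,
    "fig8": _fig8,
    "fig9": _fig9,
}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def preset_scenario(name: str) -> Scenario:
    """A ready-made scenario encoding one published simulation experiment."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(_PRESETS)}"
        ) from None
    return builder()
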