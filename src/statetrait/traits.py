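"""Slow trait (control-parameter) dynamics driven by recent state history.

Traits cannot be set from outside; they change only through what the
person actually experiences.  Each trait is nudged once per iteration by
exponentially weighted deviations of the recent states from their
running-window mean — so the *relative* rise or fall of a state matters,
never its absolute level — passed through a normalized combiner specific
to that trait, damped by a small sensitivity weight, and finally run
through a saturation/threshold stage that confines growth to a
predefined sub-range of [0, 1].  The window length (14 days) and the
half-life of the decay weighting (7 days) enforce the separation of time
scales between fast state dynamics and slow trait evolution.

Working-alliance disposition ``a`` is special: when an empirical
alliance series ``b_t`` (daily therapeutic-alliance ratings in [0, 1])
is available, its current value is averaged with ``a_{t-1}`` before the
update; without data the mix falls back to ``a_{t-1}`` alone.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import STATE_VARS, TRAIT_PARAMS, StateVector, TraitVector

LN2 = math.log(2.0)


class ShortWindowError(ValueError):
    """The state window does not yet hold the required n samples."""


def _per_variable(value, keys: Sequence[str], what: str) -> dict[str, float]:
    """Broadcast a scalar to a per-key dict, or validate a given mapping."""
    if isinstance(value, Mapping):
        missing = set(keys) - set(value)
        if missing:
            raise ValueError(f"{what} missing entries for {sorted(missing)}")
        return {k: float(value[k]) for k in keys}
    return {k: float(value) for k in keys}


def decay_constant(tau: float) -> float:
    """Decay constant λ = ln 2 / τ for a half-life of ``tau`` days."""
    if not tau > 0:
        raise ValueError(f"half-life must be positive, got {tau}")
    return LN2 / tau


def decay_weights(n: int, lam: float) -> np.ndarray:
    """Exponential age weights for the n window positions, oldest→newest.

    Position ``i = 1..n`` gets weight ``e^{-λ(n-i)}``: the newest sample
    has weight exactly 1 and the oldest ``e^{-λ(n-1)}``.  The weights
    depend only on the sample's age within the window, never on absolute
    time, which keeps the filter time-translation invariant.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"window length must be an integer >= 2, got {n!r}")
    if not lam > 0:
        raise ValueError(f"decay constant must be positive, got {lam}")
    return np.exp(-lam * np.arange(n - 1, -1, -1, dtype=float))


def filter_value(
    window: Sequence[float],
    d: float,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    """Decay-weighted sum of a variable's deviations from its window mean.

    Returns ``d · Σ_i (x_i − mean) · e^{-λ(n-i)}`` over the window
    (oldest→newest).  Mean-centering makes the value exactly zero for a
    constant window and invariant under adding a constant to every
    element; it scales linearly with the window values.  ``d`` corrects
    the mean shift introduced by weighting the centered values.
    """
    if not d > 0:
        raise ValueError(f"correction factor must be positive, got {d}")
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ShortWindowError(
            f"filter needs a full 1-d window of >= 2 values, got shape {x.shape}"
        )
    if weights is None:
        weights = decay_weights(len(x), lam)
    elif len(weights) != len(x):
        raise ShortWindowError(
            f"window has {len(x)} values but {len(weights)} weights were given"
        )
    # Anchor the mean at the first element: deviations of a constant window
    # are then identically 0.0 in floating point, not merely small.
    rel = x - x[0]
    dev = rel - rel.mean()
    return float(d * np.dot(dev, weights))


@dataclass(frozen=True)
class FilterConfig:
    """Window length, half-lives, decay constants and mean-shift corrections.

    ``lam`` is derived as ln2/τ per variable unless given explicitly.
    Defaults: n = 14 days, τ = 7 days (hence λ ≈ 0.099), d = 0.535 for
    every variable.  The correction factor d compensates the mean shift
    caused by decay-weighting centered deviations; it is a given model
    constant, not derived here.
    """

    n: int = 14
    tau: Mapping[str, float] | float = 7.0
    d: Mapping[str, float] | float = 0.535
    lam: Mapping[str, float] | float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ValueError(f"window length n must be an integer >= 2, got {self.n!r}")
        tau = _per_variable(self.tau, STATE_VARS, "tau")
        d = _per_variable(self.d, STATE_VARS, "d")
        for k, v in tau.items():
            if not v > 0:
                raise ValueError(f"tau[{k}] must be positive, got {v}")
        for k, v in d.items():
            if not v > 0:
                raise ValueError(f"d[{k}] must be positive, got {v}")
        if self.lam is None:
            lam = {k: decay_constant(v) for k, v in tau.items()}
        else:
            lam = _per_variable(self.lam, STATE_VARS, "lam")
            for k, v in lam.items():
                if not v > 0:
                    raise ValueError(f"lam[{k}] must be positive, got {v}")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "lam", lam)

    def weights(self, var: str) -> np.ndarray:
        return decay_weights(self.n, self.lam[var])


@dataclass(frozen=True)
class TraitUpdateConfig:
    """Sensitivity weights, windowed ranges, gain factors and gate thresholds.

    ``bounds[X] = (p_min, p_max)`` restricts trait X to the sub-range
    where the state dynamics stays complex; the gain factor
    ``k = p_max − p_min`` scales the saturation.  The threshold gate
    additionally damps growth above ``gate_high`` and decline below
    ``gate_low``.  ``literal_low_gate`` keeps the published ``(p − 1)``
    factor of the low branch, which reverses the increment's sign near
    the floor (a restoring force); set it False to use ``|p − 1|``
    instead for sensitivity analysis.
    """

    w: Mapping[str, float] | float = 0.004167
    bounds: Mapping[str, tuple[float, float]] | tuple[float, float] = (0.1, 0.8)
    gate_low: float = 0.2
    gate_high: float = 0.8
    literal_low_gate: bool = True

    def __post_init__(self) -> None:
        w = _per_variable(self.w, TRAIT_PARAMS, "w")
        for k, v in w.items():
            if not 0 < v < 1:
                raise ValueError(f"weight w[{k}] must lie in (0, 1), got {v}")
        if isinstance(self.bounds, Mapping):
            bounds = {k: (float(lo), float(hi)) for k, (lo, hi) in self.bounds.items()}
            missing = set(TRAIT_PARAMS) - set(bounds)
            if missing:
                raise ValueError(f"bounds missing entries for {sorted(missing)}")
        else:
            lo, hi = self.bounds
            bounds = {k: (float(lo), float(hi)) for k in TRAIT_PARAMS}
        for k, (lo, hi) in bounds.items():
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(
                    f"bounds[{k}] must satisfy 0 <= p_min < p_max <= 1, got ({lo}, {hi})"
                )
        if not self.gate_low < self.gate_high:
            raise ValueError(
                f"gate_low must be below gate_high, got {self.gate_low}, {self.gate_high}"
            )
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "bounds", bounds)

    def gain(self, param: str) -> float:
        lo, hi = self.bounds[param]
        return hi - lo


@dataclass
class StateWindow:
    """The trailing n state vectors, oldest→newest, plus the iteration index."""

    n: int
    t: int = 0
    _buf: deque = field(default_factory=deque, repr=False)

    def __post_init__(self) -> None:
        self._buf = deque(self._buf, maxlen=self.n)

    def append(self, state: StateVector) -> None:
        self._buf.append(state)

    def __len__(self) -> int:
        return len(self._buf)

    @property
    def full(self) -> bool:
        return len(self._buf) == self.n

    def values(self, var: str) -> list[float]:
        return [s[var] for s in self._buf]

    @classmethod
    def from_states(cls, states: Iterable[StateVector], n: int, t: int = 0
                    ) -> "StateWindow":
        w = cls(n=n, t=t)
        for s in states:
            w.append(s)
        return w


def combine_drivers(
    param_id: str,
    filters: Mapping[str, float],
    traits_prev: TraitVector,
) -> float:
    """Normalized driver of one trait from the five state filters.

    a: ½(f_S − f_E) — success minus dysphoric affect;
    c: ⅓(f_I + f_S + r_{t−1}) — insight, success and available resources;
    r: ½(f_S + c_{t−1}) — success and cognitive competencies;
    m: ¼(−f_E − f_P + f_M + f_S) — relief, motivation and success.
    The 1/2, 1/3, 1/4 constants normalize the sum of contributors to 1.
    """
    f = filters
    if param_id == "a":
        return (f["S"] - f["E"]) / 2.0
    if param_id == "c":
        return (f["I"] + f["S"] + traits_prev.r) / 3.0
    if param_id == "r":
        return (f["S"] + traits_prev.c) / 2.0
    if param_id == "m":
        return (-f["E"] - f["P"] + f["M"] + f["S"]) / 4.0
    raise KeyError(f"unknown trait parameter {param_id!r}; expected one of {TRAIT_PARAMS}")


def saturate(
    param_id: str,
    p_prev: float,
    raw_increment: float,
    cfg: TraitUpdateConfig,
) -> float:
    """Saturation and threshold gating of a raw trait increment.

    ``raw_increment`` is the pre-saturation change Δ = w·p·driver.  The
    sign-gated saturation scales Δ by the gain factor times the distance
    to the approached bound: ``s* = k·Δ·(p_max − p)`` for growth,
    ``k·Δ·(p − p_min)`` for decline.  Beyond the outer thresholds an
    extra factor damps the step: ``(1 − p)·s*`` when p > gate_high and Δ
    > 0, ``(p − 1)·s*`` when p < gate_low and Δ < 0 (the published low
    branch; it reverses the sign near the floor and acts as a restoring
    force — see ``literal_low_gate``).  Δ = 0 returns exactly 0.
    """
    if not math.isfinite(raw_increment):
        raise ValueError(f"raw increment must be finite, got {raw_increment!r}")
    if raw_increment == 0.0:
        return 0.0
    lo, hi = cfg.bounds[param_id]
    k = hi - lo
    if raw_increment > 0.0:
        s_star = k * raw_increment * (hi - p_prev)
        if p_prev > cfg.gate_high:
            return (1.0 - p_prev) * s_star
        return s_star
    s_star = k * raw_increment * (p_prev - lo)
    if p_prev < cfg.gate_low:
        factor = (p_prev - 1.0) if cfg.literal_low_gate else abs(p_prev - 1.0)
        return factor * s_star
    return s_star


def mix_alliance(a_prev: float, b_t: float | None = None) -> float:
    """Blend trait ``a`` with the day's empirical alliance rating.

    Returns ½(a_{t−1} + b_t); with no alliance information, b_t defaults
    to a_{t−1} and the mix reduces to a_{t−1} itself.
    """
    if b_t is None:
        return a_prev
    if not (math.isfinite(b_t) and 0.0 <= b_t <= 1.0):
        raise ValueError(f"alliance value b_t must lie in [0, 1], got {b_t!r}")
    return (a_prev + b_t) / 2.0


def state_filters(
    window: StateWindow,
    cfg: FilterConfig,
    weights: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """The five per-variable filter values for a full window."""
    if not window.full or window.n != cfg.n:
        raise ShortWindowError(
            f"trait update needs a full window of n={cfg.n} states, "
            f"got {len(window)} (window n={window.n})"
        )
    if weights is None:
        weights = {v: cfg.weights(v) for v in STATE_VARS}
    return {
        v: filter_value(window.values(v), cfg.d[v], cfg.lam[v], weights[v])
        for v in STATE_VARS
    }


def update_traits(
    traits_prev: TraitVector,
    window: StateWindow,
    filter_cfg: FilterConfig,
    update_cfg: TraitUpdateConfig,
    b_t: float | None = None,
    weights: Mapping[str, np.ndarray] | None = None,
) -> TraitVector:
    """One synchronous trait update from the trailing state window.

    All four parameters are updated from the same previous TraitVector.
    For parameter ``a`` the multiplicative base is the alliance mix
    (½(a_{t−1} + b_t) when b_t is given); the other parameters use their
    own previous value.  The applied increment is the saturated,
    threshold-gated version of Δ = w·base·driver, and the result is
    clamped to [0, 1] as a hard safety net.
    """
    filters = state_filters(window, filter_cfg, weights)
    new = {}
    for p in TRAIT_PARAMS:
        p_prev = traits_prev[p]
        base = mix_alliance(p_prev, b_t) if p == "a" else p_prev
        driver = combine_drivers(p, filters, traits_prev)
        delta = update_cfg.w[p] * base * driver
        s = saturate(p, p_prev, delta, update_cfg)
        new[p] = min(1.0, max(0.0, p_prev + s))
    return TraitVector(**new)
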