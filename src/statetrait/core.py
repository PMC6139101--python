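"""The five coupled nonlinear state equations.

This module evaluates the pure deterministic map that sends the state
vector at iteration *t−1* (under fixed trait parameters) to the state
vector at iteration *t*.  One iteration corresponds to one day, matching
the daily self-rating cadence of process monitoring in psychotherapy.

The five states are the order parameters of the system:

* ``E`` — emotions, bipolar: dysphoric affect at the positive end, joy /
  self-esteem at the negative end,
* ``P`` — problem and stress intensity, symptom severity,
* ``M`` — motivation to change (state aspect),
* ``I`` — insight, new perspectives on one's problems,
* ``S`` — therapeutic success and goal attainment (bipolar).

Four trait parameters modulate the interaction functions:

* ``a`` — working-alliance / attachment disposition,
* ``c`` — cognitive and emotion-regulation competencies,
* ``r`` — behavioral resources and skills,
* ``m`` — trait motivation, self-efficacy, hopefulness,

each confined to [0, 1].  Every variable-to-variable influence is a
logistic (sigmoid-shaped) function whose gain, offset and scale are
literal constants; the constants live in :class:`EquationConstants` so
they can be audited or replaced as a group, and the default table
reproduces the published equations verbatim.

The update is synchronous: every equation reads only the *t−1* state.
No clamping happens here; range enforcement is the engine's job, which
keeps this map directly comparable against an independent transcription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

STATE_VARS = ("E", "P", "M", "I", "S")
TRAIT_PARAMS = ("a", "c", "r", "m")


class NonFiniteError(ValueError):
    """An intermediate or input value is NaN or infinite."""


class UnknownEquationError(KeyError):
    """The requested equation id is not one of E, P, M, I, S."""


def sig(u: float) -> float:
    """Shared logistic building block ``1 / (1 + e^u)``.

    Strictly decreasing in ``u`` with range (0, 1).  Every printed term
    of the form ``1/(1+e^u)`` routes through this function.  Evaluated
    in the numerically stable branch form so large ``|u|`` saturates to
    0 or 1 instead of overflowing.
    """
    if not math.isfinite(u):
        raise NonFiniteError(f"sig() argument must be finite, got {u!r}")
    if u >= 0.0:
        eu = math.exp(-u)
        return eu / (1.0 + eu)
    return 1.0 / (1.0 + math.exp(u))


@dataclass(frozen=True)
class StateVector:
    """The five order-parameter values at one iteration (internal scale)."""

    E: float
    P: float
    M: float
    I: float
    S: float

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise NonFiniteError(f"state variable {name} is not finite: {v!r}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.E, self.P, self.M, self.I, self.S)

    def __getitem__(self, name: str) -> float:
        if name not in STATE_VARS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class TraitVector:
    """The four control-parameter values, each in [0, 1]."""

    a: float
    c: float
    r: float
    m: float

    def __post_init__(self) -> None:
        for name in TRAIT_PARAMS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise NonFiniteError(f"trait {name} is not finite: {v!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait {name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.c, self.r, self.m)

    def __getitem__(self, name: str) -> float:
        if name not in TRAIT_PARAMS:
            raise KeyError(name)
        return getattr(self, name)


# --------------------------------------------------------------------------
# Equation constants
# --------------------------------------------------------------------------

_DEFAULT_TABLE: dict[tuple[str, str], dict[str, float]] = {
    # E — emotions
    ("E", "from_E"): {"gain": 10.0},                       # 1/(1+e^{-10E}) - c
    ("E", "from_I"): {"gain": 20.0, "shift": 5.0},
    ("E", "from_P"): {
        "num_gain_base": 2.0, "num_gain_slope": 3.0,
        "num_offset": 0.5, "num_slope": 0.5,
        "den_gain": 25.0, "p_offset": 0.2, "p_slope": 0.75,
    },
    ("E", "from_S"): {"scale": 1.25, "gain": 5.0, "shift": 0.5,
                      "offset": 0.5, "m_coef": 0.5},
    # P — problem intensity
    ("P", "from_E"): {"gain": 10.0},
    ("P", "competencies"): {"coef": 1.0},                  # -c
    ("P", "from_S"): {"scale": 1.2, "gain": 5.0, "shift": 0.5},
    ("P", "offset"): {"value": 0.2},                       # -0.2
    ("P", "resources"): {"coef": 0.8},                     # -0.8 r
    # M — motivation to change (first two factors form one product group)
    ("M", "from_P"): {"scale": 1.261,
                      "offset1": 0.05, "m1": 0.85, "gain1": 10.1, "gain1_m": 19.9,
                      "offset2": 0.43, "m2": 0.03, "gain2": 7.0, "gain2_m": 3.0},
    ("M", "from_S"): {"gain": 5.0},                        # -1/(1+e^{5S})
    ("M", "resources"): {},                                # (r+m)/2
    # I — insight
    ("I", "from_E"): {"gain": 20.0, "shift": 5.0},
    ("I", "from_M"): {"gain": 20.0, "shift": 5.0},
    ("I", "from_S"): {"gain": 20.0, "shift": 5.0},
    # S — success
    ("S", "from_E"): {"scale": 1.3, "gain": 5.0, "shift": 0.5,
                      "offset": 0.65, "cm_coef": 0.35},
    ("S", "from_I"): {"gain": 20.0, "shift": 5.0},
    ("S", "from_M_up"): {"gain": 20.0, "shift": 5.0},
    ("S", "from_M_down"): {"gain": 20.0, "shift": 5.0},
    ("S", "from_P"): {"scale": 1.25, "gain": 5.0, "shift": 0.5,
                      "offset": 0.5, "cm_coef": 0.5},
    ("S", "from_S"): {"gain": 10.0},
    ("S", "resources"): {},                                # (m+r)/2 - 1
}


@dataclass(frozen=True)
class EquationConstants:
    """Immutable table of the literal numeric constants of the five equations.

    Keyed by ``(equation, term)``; the default table reproduces the
    published equations character for character (including the 1.261
    scale of M's product group, which is kept verbatim, not re-derived).
    """

    table: Mapping[tuple[str, str], Mapping[str, float]]

    @classmethod
    def default(cls) -> "EquationConstants":
        frozen = MappingProxyType(
            {k: MappingProxyType(dict(v)) for k, v in _DEFAULT_TABLE.items()}
        )
        return cls(table=frozen)

    def flat(self) -> dict[str, float]:
        """Dump every constant as a flat ``equation.term.name -> value`` map."""
        out: dict[str, float] = {}
        for (eq, term), consts in self.table.items():
            for name, value in consts.items():
                out[f"{eq}.{term}.{name}"] = value
        return out

    def __getitem__(self, key: tuple[str, str]) -> Mapping[str, float]:
        return self.table[key]


DEFAULT_CONSTANTS = EquationConstants.default()


# --------------------------------------------------------------------------
# The sixteen interaction terms, grouped per target equation
# --------------------------------------------------------------------------
# Each function evaluates one additive term (or, for M's product, the whole
# multiplicative group) of its equation; labels name the source interaction.

def _E_from_E(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.E) - t.c


def _E_from_I(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.I * (1.0 - (t.c + t.r) / 2.0) + k["shift"])


def _E_from_P(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    u = 1.0 - (t.c + t.m) / 2.0
    num = (-sig((k["num_gain_base"] + k["num_gain_slope"] * u) * s.P)
           + k["num_offset"] + k["num_slope"] * u)
    return num * sig(k["den_gain"] * u * (s.P - k["p_offset"] - k["p_slope"] * u))


def _E_from_S(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return (k["scale"] * sig(k["gain"] * s.S - k["shift"])
            - k["offset"] - k["m_coef"] * t.m)


def _P_from_E(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.E)


def _P_competencies(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return -k["coef"] * t.c


def _P_from_S(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return k["scale"] * sig(k["gain"] * s.S - k["shift"])


def _P_offset(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return -k["value"]


def _P_resources(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return -k["coef"] * t.r


def _M_from_P(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    # Product group: a rising and a falling logistic in P whose product forms
    # a motivation "window" — too few problems do not press for change, an
    # overwhelming problem load paralyses it.
    f1 = k["scale"] * sig((s.P - k["offset1"] - k["m1"] * t.m)
                          * (k["gain1"] + k["gain1_m"] * t.m))
    f2 = sig(-(s.P - k["offset2"] + k["m2"] * t.m) * (k["gain2"] - k["gain2_m"] * t.m))
    return f1 * f2


def _M_from_S(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return -sig(k["gain"] * s.S)


def _M_resources(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return (t.r + t.m) / 2.0


def _I_from_E(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.E * ((t.a + t.c) / 2.0) + k["shift"])


def _I_from_M(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.M * ((t.a + t.c) / 2.0) + k["shift"])


def _I_from_S(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * abs(s.S) * t.c + k["shift"])


def _S_from_E(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return (k["scale"] * sig(k["gain"] * s.E - k["shift"])
            - k["offset"] + k["cm_coef"] * (t.c + t.m - 1.0))


def _S_from_I(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.I * (t.a + t.m + t.r) / 3.0 + k["shift"])


def _S_from_M_up(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.M * (t.a + t.m + t.r) / 3.0 + k["shift"])


def _S_from_M_down(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return -sig(k["gain"] * s.M * (1.0 - (t.a + t.m + t.r) / 3.0) + k["shift"])


def _S_from_P(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return (k["scale"] * sig(k["gain"] * s.P - k["shift"])
            - k["offset"] - k["cm_coef"] * (1.0 - (t.c + t.m) / 2.0))


def _S_from_S(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return sig(-k["gain"] * s.S)


def _S_resources(s: StateVector, t: TraitVector, k: Mapping[str, float]) -> float:
    return (t.m + t.r) / 2.0 - 1.0


_TERMS: dict[str, tuple[tuple[str, object], ...]] = {
    "E": (("from_E", _E_from_E), ("from_I", _E_from_I),
          ("from_P", _E_from_P), ("from_S", _E_from_S)),
    "P": (("from_E", _P_from_E), ("competencies", _P_competencies),
          ("from_S", _P_from_S), ("offset", _P_offset),
          ("resources", _P_resources)),
    "M": (("from_P", _M_from_P), ("from_S", _M_from_S),
          ("resources", _M_resources)),
    "I": (("from_E", _I_from_E), ("from_M", _I_from_M), ("from_S", _I_from_S)),
    "S": (("from_E", _S_from_E), ("from_I", _S_from_I),
          ("from_M_up", _S_from_M_up), ("from_M_down", _S_from_M_down),
          ("from_P", _S_from_P), ("from_S", _S_from_S),
          ("resources", _S_resources)),
}


def eval_state_terms(
    equation_id: str,
    state: StateVector,
    traits: TraitVector,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Evaluate every term of one equation, labelled by source interaction.

    For ``M`` the first multiplicative group (the product of the two
    logistic factors in P) is returned as the single term ``from_P``, so
    the plain sum of the returned values always equals
    :func:`eval_state` on the same inputs.
    """
    if equation_id not in _TERMS:
        raise UnknownEquationError(
            f"unknown equation id {equation_id!r}; expected one of {STATE_VARS}"
        )
    return {
        name: fn(state, traits, constants[(equation_id, name)])
        for name, fn in _TERMS[equation_id]
    }


def eval_state(
    equation_id: str,
    state: StateVector,
    traits: TraitVector,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Full right-hand side of one equation at the given state and traits."""
    terms = eval_state_terms(equation_id, state, traits, constants)
    total = 0.0
    for v in terms.values():
        total += v
    return total


def step_states(
    state: StateVector,
    traits: TraitVector,
    constants: EquationConstants = DEFAULT_CONSTANTS,
) -> StateVector:
    """One synchronous step of the five-dimensional map.

    Every equation reads only the input (t−1) state — no equation sees
    another variable's freshly computed value — so permuting the
    evaluation order cannot change the result.  Deterministic: identical
    inputs give bit-identical outputs.
    """
    new = {}
    for eq in STATE_VARS:
        v = eval_state(eq, state, traits, constants)
        if not math.isfinite(v):
            raise NonFiniteError(
                f"equation {eq} produced a non-finite value at state {state}"
            )
        new[eq] = v
    return StateVector(**new)
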