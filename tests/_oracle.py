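"""Independent transcription oracles for the tests.

These re-derive the model update rules directly from their printed
closed forms using only the standard library — no code is shared with
the package — so agreement between the two routes is evidence that the
package implements the stated equations, not merely that it is
self-consistent.
"""

import math


def oracle_step(E, P, M, I, S, a, c, r, m):
    """One synchronous step of the five state equations, transcribed term
    by term with plain 1/(1+e^u) arithmetic."""
    En = (
        1 / (1 + math.exp(-10 * E)) - c
        + 1 / (1 + math.exp(-20 * I * (1 - (c + r) / 2) + 5))
        + (
            -1 / (1 + math.exp((2 + 3 * (1 - (c + m) / 2)) * P))
            + 0.5 + 0.5 * (1 - (c + m) / 2)
        ) / (1 + math.exp(25 * (1 - (c + m) / 2) * (P - 0.2 - 0.75 * (1 - (c + m) / 2))))
        + 1.25 / (1 + math.exp(5 * S - 0.5)) - 0.5 - 0.5 * m
    )
    In = (
        1 / (1 + math.exp(-20 * E * ((a + c) / 2) + 5))
        + 1 / (1 + math.exp(-20 * M * ((a + c) / 2) + 5))
        + 1 / (1 + math.exp(-20 * abs(S) * c + 5))
    )
    Mn = (
        1.261 / (1 + math.exp((P - 0.05 - 0.85 * m) * (10.1 + 19.9 * m)))
        * 1 / (1 + math.exp(-(P - 0.43 + 0.03 * m) * (7 - 3 * m)))
        - 1 / (1 + math.exp(5 * S))
        + (r + m) / 2
    )
    Pn = (
        1 / (1 + math.exp(-10 * E)) - c
        + 1.2 / (1 + math.exp(5 * S - 0.5)) - 0.2 - 0.8 * r
    )
    Sn = (
        1.3 / (1 + math.exp(5 * E - 0.5)) - 0.65 + 0.35 * (c + m - 1)
        + 1 / (1 + math.exp(-20 * I * (a + m + r) / 3 + 5))
        + 1 / (1 + math.exp(-20 * M * (a + m + r) / 3 + 5))
        - 1 / (1 + math.exp(20 * M * (1 - (a + m + r) / 3) + 5))
        + 1.25 / (1 + math.exp(5 * P - 0.5)) - 0.5 - 0.5 * (1 - (c + m) / 2)
        + 1 / (1 + math.exp(-10 * S)) + (m + r) / 2 - 1
    )
    return En, Pn, Mn, In, Sn


def oracle_filter(values, d, lam):
    """Decay-weighted deviation filter: d * sum_i (x_i - mean) e^{-lam (n-i)}."""
    n = len(values)
    mean = sum(values) / n
    return d * sum(
        (values[i - 1] - mean) * math.exp(-lam * (n - i)) for i in range(1, n + 1)
    )


def oracle_update_traits(
    a, c, r, m,
    windows,              # dict var -> list of n values, oldest -> newest
    w=0.004167,
    d=0.535,
    lam=math.log(2) / 7,
    p_min=0.1, p_max=0.8,
    gate_low=0.2, gate_high=0.8,
    b_t=None,
):
    """One trait update transcribed from the printed combiners, saturation
    and threshold gating, with the alliance mix for parameter a."""
    f = {v: oracle_filter(windows[v], d, lam) for v in "EPMIS"}

    def saturated(p_prev, delta):
        if delta == 0:
            return 0.0
        k = p_max - p_min
        sgn = 1.0 if delta > 0 else -1.0
        s_star = k * delta * ((1 + sgn) / 2 * (p_max - p_prev)
                              + (1 - sgn) / 2 * (p_prev - p_min))
        if p_prev > gate_high and delta > 0:
            return (1 - p_prev) * s_star
        if p_prev < gate_low and delta < 0:
            return (p_prev - 1) * s_star
        return s_star

    a_base = a if b_t is None else (a + b_t) / 2
    drivers = {
        "a": (f["S"] - f["E"]) / 2,
        "c": (f["I"] + f["S"] + r) / 3,
        "r": (f["S"] + c) / 2,
        "m": (-f["E"] - f["P"] + f["M"] + f["S"]) / 4,
    }
    prev = {"a": a, "c": c, "r": r, "m": m}
    base = {"a": a_base, "c": c, "r": r, "m": m}
    out = {}
    for p in ("a", "c", "r", "m"):
        delta = w * base[p] * drivers[p]
        out[p] = min(1.0, max(0.0, prev[p] + saturated(prev[p], delta)))
    return out
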