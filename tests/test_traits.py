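"""Trait dynamics: filters, combiners, saturation, gating, alliance mixing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from statetrait import (
    FilterConfig,
    ShortWindowError,
    StateVector,
    StateWindow,
    TraitUpdateConfig,
    TraitVector,
    combine_drivers,
    decay_constant,
    decay_weights,
    filter_value,
    mix_alliance,
    saturate,
    update_traits,
)

from _oracle import oracle_filter, oracle_update_traits
from conftest import random_state, random_traits


def make_window(states, n=None):
    n = n if n is not None else len(states)
    return StateWindow.from_states(states, n=n)


def constant_window(value=0.37, n=14):
    s = StateVector(value, value, value, value, value)
    return make_window([s] * n)


class TestDecayConstant:
    def test_published_half_life(self):
        assert round(decay_constant(7.0), 3) == 0.099

    def test_identity_case(self):
        assert decay_constant(math.log(2)) == pytest.approx(1.0, abs=1e-15)

    def test_golden_fourteen_days(self):
        # frozen from direct arithmetic: ln 2 / 14
        assert decay_constant(14.0) == pytest.approx(0.049510512897138946, abs=1e-15)

    def test_strictly_decreasing_in_tau(self):
        taus = np.linspace(0.5, 30, 50)
        lams = [decay_constant(t) for t in taus]
        assert all(b < a for a, b in zip(lams, lams[1:]))

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            decay_constant(bad)


class TestDecayWeights:
    def test_newest_weight_is_one(self):
        for n, lam in [(2, 0.5), (14, 0.099), (30, 2.0)]:
            assert decay_weights(n, lam)[-1] == 1.0

    def test_no_decay_limit(self):
        assert decay_weights(14, 1e-12) == pytest.approx(np.ones(14), abs=1e-9)

    def test_direct_arithmetic(self):
        w = decay_weights(14, 0.099)
        expected = [math.exp(-0.099 * (14 - i)) for i in range(1, 15)]
        assert w == pytest.approx(expected, abs=1e-15)
        assert np.all(np.diff(w) > 0)  # strictly increasing oldest -> newest

    @pytest.mark.parametrize("n,lam", [(1, 0.1), (0, 0.1), (14, 0.0), (14, -1.0)])
    def test_invalid_rejected(self, n, lam):
        with pytest.raises(ValueError):
            decay_weights(n, lam)


class TestFilterValue:
    @pytest.mark.parametrize("value", [0.0, 0.1, 1.0, -0.7, 97.6, 1e-3])
    def test_constant_window_exactly_zero(self, value):
        window = [value] * 14
        assert filter_value(window, d=0.535, lam=0.099) == 0.0

    def test_two_point_closed_form(self):
        # window [x, x+h] -> d * (h/2) * (1 - e^{-lam}); frozen for
        # d = 0.535, lam = 0.099, h = 1
        got = filter_value([0.3, 1.3], d=0.535, lam=0.099)
        assert got == pytest.approx(0.025213825603700776, abs=1e-15)

    def test_shift_invariance(self, rng):
        for _ in range(200):
            w = rng.uniform(-1, 1, 14)
            shift = float(rng.uniform(-100, 100))
            a = filter_value(w, 0.535, 0.099)
            b = filter_value(w + shift, 0.535, 0.099)
            assert b == pytest.approx(a, abs=1e-12)

    def test_linearity(self, rng):
        for _ in range(200):
            w = rng.uniform(-1, 1, 14)
            alpha = float(rng.uniform(-5, 5))
            assert filter_value(alpha * w, 0.535, 0.099) == pytest.approx(
                alpha * filter_value(w, 0.535, 0.099), abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(100):
            w = list(rng.uniform(-1, 1, 14))
            assert filter_value(w, 0.535, 0.099) == pytest.approx(
                oracle_filter(w, 0.535, 0.099), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        window=st_.lists(st_.floats(-10, 10), min_size=2, max_size=30),
        shift=st_.floats(-100, 100),
    )
    def test_shift_invariance_property(self, window, shift):
        w = np.asarray(window)
        base = filter_value(w, 0.535, 0.099)
        scale = max(1.0, abs(shift))
        assert filter_value(w + shift, 0.535, 0.099) == pytest.approx(
            base, abs=1e-10 * scale)

    @settings(derandomize=True, max_examples=100)
    @given(value=st_.floats(-1000, 1000), n=st_.integers(2, 40))
    def test_constant_null_property(self, value, n):
        assert filter_value([value] * n, 0.535, 0.099) == 0.0

    def test_short_window_error_distinct(self):
        with pytest.raises(ShortWindowError):
            filter_value([1.0], d=0.535, lam=0.099)
        with pytest.raises(ValueError) as err:
            filter_value([1.0, 2.0], d=-1.0, lam=0.099)
        assert not isinstance(err.value, ShortWindowError)


class TestCombineDrivers:
    def test_zero_filters(self):
        zero = dict.fromkeys("EPMIS", 0.0)
        t = TraitVector(0.5, 0.5, 0.3, 0.5)
        assert combine_drivers("a", zero, t) == 0.0
        assert combine_drivers("m", zero, t) == 0.0
        assert combine_drivers("c", zero, t) == pytest.approx(0.1, abs=1e-15)

    def test_matches_printed_combiners(self, rng):
        for _ in range(100):
            f = {v: float(rng.normal(0, 1)) for v in "EPMIS"}
            t = random_traits(rng)
            assert combine_drivers("a", f, t) == pytest.approx(
                (f["S"] - f["E"]) / 2, abs=1e-15)
            assert combine_drivers("c", f, t) == pytest.approx(
                (f["I"] + f["S"] + t.r) / 3, abs=1e-15)
            assert combine_drivers("r", f, t) == pytest.approx(
                (f["S"] + t.c) / 2, abs=1e-15)
            assert combine_drivers("m", f, t) == pytest.approx(
                (-f["E"] - f["P"] + f["M"] + f["S"]) / 4, abs=1e-15)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            combine_drivers("x", dict.fromkeys("EPMIS", 0.0),
                            TraitVector(0.5, 0.5, 0.5, 0.5))


class TestSaturate:
    CFG = TraitUpdateConfig()

    def test_zero_increment(self):
        assert saturate("c", 0.5, 0.0, self.CFG) == 0.0

    def test_interior_growth(self):
        # s* = k * delta * (p_max - p): 0.7 * 0.01 * 0.3
        got = saturate("c", 0.5, 0.01, self.CFG)
        assert got == pytest.approx(0.7 * 0.01 * (0.8 - 0.5), abs=1e-15)

    def test_above_ceiling_restores(self):
        # p = 0.9 > p_max: (p_max - p) < 0 makes s* negative, and the high
        # gate scales it by (1 - p); the applied increment is restoring.
        got = saturate("c", 0.9, 0.01, self.CFG)
        s_star = 0.7 * 0.01 * (0.8 - 0.9)
        assert got == pytest.approx((1 - 0.9) * s_star, abs=1e-15)
        assert got < 0

    def test_literal_low_gate_reverses_sign(self):
        literal = saturate("c", 0.15, -0.01, self.CFG)
        absed = saturate("c", 0.15, -0.01,
                         TraitUpdateConfig(literal_low_gate=False))
        # published (p - 1) factor flips the decline into a restoring push
        assert literal == pytest.approx(-absed, abs=1e-15)
        assert literal > 0 > absed

    def test_sign_preserved_between_gates(self, rng):
        cfg = self.CFG
        for _ in range(200):
            p = float(rng.uniform(cfg.gate_low + 1e-6, cfg.gate_high - 1e-6))
            delta = float(rng.uniform(-0.05, 0.05))
            s = saturate("c", p, delta, cfg)
            if p < cfg.bounds["c"][1] and delta != 0.0:
                assert math.copysign(1, s) == math.copysign(1, delta) or s == 0.0


class TestMixAlliance:
    def test_mean(self):
        assert mix_alliance(0.2, 0.4) == pytest.approx(0.3, abs=1e-15)

    def test_absent_falls_back(self):
        assert mix_alliance(0.73) == 0.73

    def test_idempotent(self, rng):
        for x in rng.uniform(0, 1, 20):
            assert mix_alliance(float(x), float(x)) == pytest.approx(x, abs=1e-15)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            mix_alliance(0.5, bad)


class TestUpdateTraits:
    FCFG = FilterConfig()
    UCFG = TraitUpdateConfig()

    def test_constant_window_freezes_a_and_m(self):
        t = TraitVector(0.5, 0.5, 0.3, 0.5)
        new = update_traits(t, constant_window(), self.FCFG, self.UCFG)
        assert new.a == t.a and new.m == t.m      # zero filters, zero drivers
        assert new.c != t.c and new.r != t.r      # cross-terms r_{t-1}, c_{t-1}

    def test_constant_window_c_increment_matches_oracle(self):
        t = TraitVector(0.5, 0.5, 0.3, 0.5)
        new = update_traits(t, constant_window(), self.FCFG, self.UCFG)
        expected = oracle_update_traits(
            0.5, 0.5, 0.3, 0.5, {v: [0.37] * 14 for v in "EPMIS"})
        assert new.c == pytest.approx(expected["c"], abs=1e-15)
        # and the increment is the saturated w_c * c * (r/3) step
        delta = 0.004167 * 0.5 * (0.3 / 3)
        assert new.c - t.c == pytest.approx(0.7 * delta * (0.8 - 0.5), abs=1e-15)

    def test_outputs_always_in_unit_interval(self, rng):
        for _ in range(50):
            states = [random_state(rng, span=1.0) for _ in range(14)]
            t = random_traits(rng)
            new = update_traits(t, make_window(states), self.FCFG, self.UCFG)
            assert all(0.0 <= new[p] <= 1.0 for p in "acrm")

    def test_short_window_rejected(self):
        t = TraitVector(0.5, 0.5, 0.5, 0.5)
        win = make_window([StateVector(0, 0, 0, 0, 0)] * 5, n=14)
        with pytest.raises(ShortWindowError):
            update_traits(t, win, self.FCFG, self.UCFG)

    @pytest.mark.parametrize("with_alliance", [False, True])
    def test_matches_transcription_oracle(self, rng, with_alliance):
        for _ in range(100):
            states = [random_state(rng, span=1.0) for _ in range(14)]
            t = random_traits(rng)
            b_t = float(rng.uniform(0, 1)) if with_alliance else None
            ours = update_traits(t, make_window(states), self.FCFG, self.UCFG, b_t)
            windows = {v: [s[v] for s in states] for v in "EPMIS"}
            exp = oracle_update_traits(t.a, t.c, t.r, t.m, windows, b_t=b_t)
            for p in "acrm":
                assert ours[p] == pytest.approx(exp[p], abs=1e-12)

    def test_bounded_under_extreme_driver_sequences(self, rng):
        """200 random 1000-step driver sequences keep every trait in [0, 1]."""
        cfg = self.UCFG
        for _ in range(200):
            p = float(rng.uniform(0, 1))
            param = str(rng.choice(list("acrm")))
            drivers = rng.uniform(-50, 50, 1000)
            w = cfg.w[param]
            for drv in drivers:
                p = min(1.0, max(0.0, p + saturate(param, p, w * p * drv, cfg)))
            assert 0.0 <= p <= 1.0


class TestConfigs:
    def test_filter_config_derives_lambda(self):
        cfg = FilterConfig(tau=7.0)
        assert cfg.lam["E"] == pytest.approx(math.log(2) / 7, abs=1e-15)

    def test_filter_config_validates(self):
        with pytest.raises(ValueError):
            FilterConfig(n=1)
        with pytest.raises(ValueError):
            FilterConfig(tau=-1.0)

    def test_update_config_gain_is_printed_value(self):
        assert TraitUpdateConfig().gain("c") == pytest.approx(0.7, abs=1e-15)

    def test_update_config_validates_bounds(self):
        with pytest.raises(ValueError):
            TraitUpdateConfig(bounds=(0.8, 0.1))
        with pytest.raises(ValueError):
            TraitUpdateConfig(gate_low=0.9, gate_high=0.1)
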