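"""Cell model: equilibrium, scaling, pacing, APD measurement, rate tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrialerp import courtemanche as c
from atrialerp import engine


def test_rest_state_is_equilibrium():
    """At the published resting state the membrane is quiescent."""
    dy, i_ion = c.ionic_rhs(c.rest_state())
    assert abs(dy[0]) < 0.01          # mV/ms
    assert abs(i_ion) < 0.01


def test_quiescent_resting_potential():
    """After long unstimulated integration V settles in the physiological
    atrial resting range."""
    y = c.rest_state().reshape(1, -1).copy()
    tbl = engine.get_tables(0.02)
    code = engine.run_single_cell(y, np.ones(9), 0.02, 3000.0, 1e9, 1.0,
                                  0.0, tbl)
    assert code == 0
    assert -85.0 <= y[0, 0] <= -75.0
    dy, _ = c.ionic_rhs(y[0])
    assert abs(dy[0]) < 0.01


def test_nonfinite_state_names_offender():
    y = c.rest_state()
    y[2] = np.nan
    with pytest.raises(ValueError, match="h"):
        c.ionic_rhs(y)


def _random_states(seed, n):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        y = c.rest_state()
        y[0] = rng.uniform(-90, 30)
        y[1:16] = rng.uniform(0.05, 0.95, 15)
        y[16] = rng.uniform(8, 15)
        y[17] = rng.uniform(120, 150)
        y[18] = rng.uniform(5e-5, 5e-4)
        y[19] = rng.uniform(0.5, 3)
        y[20] = rng.uniform(0.5, 3)
        out.append(y)
    return out


@pytest.mark.parametrize("idx", range(9))
def test_scaling_linearity_term_by_term(idx):
    """The total ionic current is affine in each multiplier: doubling a
    multiplier adds exactly the baseline contribution of that term."""
    for y in _random_states(42 + idx, 5):
        s0, s1, s2 = np.ones(9), np.ones(9), np.ones(9)
        s0[idx], s2[idx] = 0.0, 2.0
        i0 = c.ionic_rhs(y, s0)[1]
        i1 = c.ionic_rhs(y, s1)[1]
        i2 = c.ionic_rhs(y, s2)[1]
        assert i2 - i1 == pytest.approx(i1 - i0, rel=1e-9, abs=1e-12)


def test_zeroed_inward_rectifier_removes_its_current():
    """s_gK1 = 0 leaves a current identical to the model without I_K1: its
    K+ flux contribution vanishes exactly."""
    y = c.rest_state()
    y[0] = -60.0
    s = np.ones(9)
    s[1] = 0.0
    dy0, _ = c.ionic_rhs(y, s)
    s[1] = 1.0
    dy1, i1 = c.ionic_rhs(y, s)
    # I_K1 at -60 mV is substantial; removing it changes dKi and dV equally
    assert dy0[17] != pytest.approx(dy1[17])
    s[1] = 2.0
    dy2, i2 = c.ionic_rhs(y, s)
    assert dy2[17] - dy1[17] == pytest.approx(dy1[17] - dy0[17], rel=1e-9)


def test_rate_tables_match_exact_rates():
    """Tabulated gate curves and current factors agree with the exact
    expressions to interpolation accuracy."""
    tbl = engine.get_tables(0.02)
    rng = np.random.default_rng(0)
    V = rng.uniform(-95.0, 45.0, 200)
    inf, tau = c.gate_inf_tau(V)
    cf = c.current_factors(V)
    x = (V - tbl.V_MIN) * tbl.inv_dv
    i0 = np.clip(x.astype(int), 0, tbl.table.shape[0] - 2)
    fr = x - i0
    for g in range(12):
        approx = tbl.table[i0, g] + fr * (tbl.table[i0 + 1, g] - tbl.table[i0, g])
        np.testing.assert_allclose(approx, inf[g], atol=2e-5)
        decay = tbl.table[i0, g + 12] + fr * (tbl.table[i0 + 1, g + 12]
                                              - tbl.table[i0, g + 12])
        np.testing.assert_allclose(decay, np.exp(-0.02 / tau[g]), atol=2e-5)
    for k in range(6):
        approx = tbl.table[i0, 24 + k] + fr * (tbl.table[i0 + 1, 24 + k]
                                               - tbl.table[i0, 24 + k])
        np.testing.assert_allclose(approx, cf[k], rtol=1e-4, atol=1e-6)


def test_engine_step_matches_reference_rhs():
    """One engine step at tiny dt reproduces the reference derivative."""
    dt = 0.001
    tbl = engine.get_tables(dt)
    for y in _random_states(7, 5):
        dy, _ = c.ionic_rhs(y)
        ref = y + dt * dy
        stepped = y.reshape(1, -1).copy()
        engine.run_single_cell(stepped, np.ones(9), dt, dt, 1e9, 1.0, 0.0, tbl)
        # gates use Rush-Larsen (equals Euler to O(dt^2)); rest is Euler
        np.testing.assert_allclose(stepped[0], ref, rtol=5e-3, atol=5e-4)


class TestPacing:
    def test_limit_cycle_control(self):
        """100 beats at BCL 500 ms reach a limit cycle: consecutive APD90
        within 1 ms, and within the published model's range when paced with
        its native 2 nA / 2 ms stimulus."""
        res = c.pace_to_limit_cycle(stim_amp=20.0, stim_dur=2.0)
        assert res.repolarization_ok
        assert abs(res.apd90_last - res.apd90_prev) < 1.0
        assert 250.0 <= res.apd90_last <= 320.0

    def test_af_remodeling_shortens_apd(self):
        ctrl = c.pace_to_limit_cycle(n_beats=50)
        af = c.pace_to_limit_cycle(c.AF_DIRECTION, n_beats=50)
        assert af.apd90_last < ctrl.apd90_last
        assert abs(af.apd90_last - af.apd90_prev) < 1.0

    def test_single_beat_equals_one_paced_beat(self):
        a = c.pace_to_limit_cycle(n_beats=1)
        y = c.rest_state().reshape(1, -1).copy()
        tbl = engine.get_tables(0.02)
        engine.run_single_cell(y, np.ones(9), 0.02, 500.0, 500.0, 3.0, 30.0,
                               tbl)
        np.testing.assert_allclose(a.state, y[0], rtol=1e-12)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            c.pace_to_limit_cycle(bcl=0.0)
        with pytest.raises(ValueError):
            c.pace_to_limit_cycle(n_beats=0)

    def test_concentrations_bounded_over_100_beats(self):
        res = c.pace_to_limit_cycle(n_beats=100)
        nai, ki, cai = res.state[16], res.state[17], res.state[18]
        assert 5.0 < nai < 20.0
        assert 100.0 < ki < 160.0
        assert 0.0 < cai < 0.01
        gates = np.concatenate([res.state[1:16]])
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)


class TestApd90:
    @settings(deadline=None, max_examples=20)
    @given(width=st.floats(40.0, 200.0))
    def test_square_pulse(self, width):
        """A square pulse of given width has APD90 = width +- sample step."""
        t = np.arange(0, 400.0, 0.5)
        V = np.where((t >= 50.0) & (t < 50.0 + width), 20.0, -80.0)
        assert c.apd90(t, V) == pytest.approx(width, abs=1.0)

    def test_no_beat(self):
        t = np.arange(0, 300.0, 0.5)
        with pytest.raises(c.NoBeat):
            c.apd90(t, np.full_like(t, -80.0))

    def test_paced_beat_in_range(self):
        res = c.pace_to_limit_cycle(n_beats=2, stim_amp=20.0, stim_dur=2.0)
        assert 200.0 < res.apd90_last < 330.0


def test_presets():
    assert np.all(c.CONTROL.scale.as_array() == 1.0)
    infl = c.INFLAMMATION.scale
    assert infl.gCaL == 0.225 and infl.gNa == 0.60 and infl.gKur == 0.50
    assert infl.gto == 0.35 and infl.gKs == 2.0
    assert infl.IpCa == 1.5 and infl.INaCa == 1.6
    assert infl.gK1 == 1.0 and infl.gKr == 1.0
    with pytest.raises(ValueError):
        c.ConductanceScale(gNa=-0.1)


def test_scale_json_roundtrip_and_composition():
    s = c.ConductanceScale(gK1=1.5, gCaL=0.4)
    assert c.ConductanceScale.from_json(s.to_json()) == s
    a, b = c.INFLAMMATION.scale, s
    np.testing.assert_allclose(a.compose(b).as_array(),
                               b.compose(a).as_array())
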