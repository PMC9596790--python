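"""Single-cell physiology: gating updates, gap coupling, profile scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriasim import (CellParameters, MyocyteState, ProfileScaling,
                      StimulusProtocol, apply_profile_scaling,
                      baseline_parameters, gap_current, rush_larsen_update,
                      simulate_pair, simulate_single_fibroblast,
                      simulate_single_myocyte, step_fibroblast, step_myocyte)
from atriasim.biomarkers import analyze_trace
from atriasim.cell_models import FibroblastState


# ---------------------------------------------------------------------------
# Rush-Larsen
# ---------------------------------------------------------------------------

class TestRushLarsen:
    def test_exact_for_constant_rates(self):
        # analytic solution of dw/dt = a(1-w) - b w
        for w0, a, b, h in [(0.2, 1.0, 3.0, 0.7), (0.9, 0.05, 0.0, 10.0),
                            (0.0, 2.5, 0.5, 0.01)]:
            winf = a / (a + b)
            exact = winf + (w0 - winf) * math.exp(-(a + b) * h)
            assert rush_larsen_update(w0, a, b, h) == pytest.approx(
                exact, abs=1e-14)

    def test_zero_rates_identity(self):
        assert rush_larsen_update(0.37, 0.0, 0.0, 5.0) == 0.37

    def test_long_step_reaches_steady_state(self):
        assert rush_larsen_update(0.9, 1.0, 3.0, 1e9) == pytest.approx(0.25)

    def test_matches_forward_euler_at_small_h(self):
        w, a, b, h = 0.2, 1.0, 3.0, 1e-4
        euler = w + h * (a * (1 - w) - b * w)
        assert abs(rush_larsen_update(w, a, b, h) - euler) < 1e-7

    def test_euler_agreement_is_second_order(self):
        w, a, b = 0.2, 1.0, 3.0
        d = []
        for h in (1e-3, 5e-4):
            euler = w + h * (a * (1 - w) - b * w)
            d.append(abs(rush_larsen_update(w, a, b, h) - euler))
        assert d[0] / d[1] == pytest.approx(4.0, rel=0.05)

    @settings(max_examples=200, deadline=None)
    @given(w=st.floats(0.0, 1.0),
           a=st.floats(0.0, 50.0),
           b=st.floats(0.0, 50.0),
           h=st.floats(1e-6, 100.0))
    def test_stays_in_unit_interval(self, w, a, b, h):
        assert 0.0 <= rush_larsen_update(w, a, b, h) <= 1.0

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            rush_larsen_update(0.5, -1.0, 1.0, 0.1)


# ---------------------------------------------------------------------------
# Gap-junction current
# ---------------------------------------------------------------------------

class TestGapCurrent:
    def test_zero_at_equal_potentials(self):
        g = gap_current(-60.0, -60.0, baseline_parameters())
        assert g.i_na == 0.0 and g.i_k == 0.0

    def test_ohms_law_and_split(self):
        params = baseline_parameters()
        g = gap_current(50.0, -50.0, params)   # dV = 100 mV, G = 0.5 nS
        assert g.total == pytest.approx(50.0)  # pA
        assert g.i_na == pytest.approx(params.g_gap_na * 100.0)
        assert g.i_k == pytest.approx(params.g_gap_k * 100.0)

    def test_linear_in_voltage_difference(self):
        params = baseline_parameters()
        assert gap_current(-20.0, -70.0, params).total == pytest.approx(
            -gap_current(-70.0, -20.0, params).total)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            gap_current(float("nan"), -50.0, baseline_parameters())

    def test_coupling_pulls_pair_potentials_together(self):
        # myocyte rests below the fibroblast: gap current must raise the
        # myocyte's diastolic Vm and pull the fibroblast down
        t, vm, vf = simulate_pair(duration_ms=500.0)
        rest_myo = vm[0]
        assert vm[-1] > rest_myo + 0.1
        assert vf[-1] < -47.75
        assert vm[-1] < vf[-1]   # ordering preserved

    def test_two_cell_kernel_matches_stepwise_coupling(self):
        """The tissue kernel's pair coupling equals explicit per-step
        integration with equal-and-opposite gap currents."""
        params = baseline_parameters()
        sm = MyocyteState.rest()
        sf = FibroblastState.rest()
        dt = 0.01
        for _ in range(10000):   # 100 ms
            g = gap_current(sm.vm, sf.vm, params)
            sm_new = step_myocyte(sm, params, dt, i_gap_na=g.i_na,
                                  i_gap_k=g.i_k)
            sf = step_fibroblast(sf, params, dt, i_gap_total=g.total)
            sm = sm_new
        t, vm, vf = simulate_pair(duration_ms=100.0)
        assert sm.vm == pytest.approx(vm[-1], abs=0.05)
        assert sf.vm == pytest.approx(vf[-1], abs=0.05)


# ---------------------------------------------------------------------------
# Profile scaling
# ---------------------------------------------------------------------------

class TestProfileScaling:
    def test_zero_scaling_is_identity(self):
        base = baseline_parameters()
        assert apply_profile_scaling(base, ProfileScaling()) == base

    def test_gna_percent_scaling(self):
        base = baseline_parameters()
        out = apply_profile_scaling(base, ProfileScaling(gNa=73.13))
        assert out.myocyte.p_na == pytest.approx(1.7313 * base.myocyte.p_na)
        assert out.myocyte.g_cal == base.myocyte.g_cal

    def test_diffusion_only_scaling(self):
        base = baseline_parameters()
        out = apply_profile_scaling(base, ProfileScaling(D=-50.0))
        assert out.diffusion == pytest.approx(0.5 * base.diffusion)
        assert out.myocyte == base.myocyte

    def test_all_nine_targets_scale(self):
        base = baseline_parameters()
        s = ProfileScaling(gNa=10, INaK=20, gK1=30, gCaL=40, gKur=50,
                           IKCa=60, D=70, Ko=80, Nao=90)
        out = apply_profile_scaling(base, s)
        m, b = out.myocyte, base.myocyte
        assert m.p_na / b.p_na == pytest.approx(1.1)
        assert m.i_nak_max / b.i_nak_max == pytest.approx(1.2)
        assert m.g_k1 / b.g_k1 == pytest.approx(1.3)
        assert m.g_cal / b.g_cal == pytest.approx(1.4)
        assert m.g_kur / b.g_kur == pytest.approx(1.5)
        assert m.g_sk / b.g_sk == pytest.approx(1.6)
        assert out.diffusion / base.diffusion == pytest.approx(1.7)
        assert m.k_o / b.k_o == pytest.approx(1.8)
        assert m.na_o / b.na_o == pytest.approx(1.9)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            ProfileScaling.from_dict({"gNaL": 10.0})

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            apply_profile_scaling(baseline_parameters(),
                                  ProfileScaling(gNa=150.0))


# ---------------------------------------------------------------------------
# Myocyte dynamics
# ---------------------------------------------------------------------------

class TestMyocyte:
    def test_resting_stability_one_second(self):
        t, v, _ = simulate_single_myocyte(
            protocol=StimulusProtocol(n_pulses=0, stim_cols=2),
            duration_ms=1000.0)
        assert abs(v[-1] - v[0]) < 1.0

    def test_action_potential_shape(self, paced_cell_trace):
        t, v, _ = paced_cell_trace
        first = (t >= 0) & (t < 500.0)
        assert v[first].max() > 0.0               # overshoot
        assert v[first][-1] < -70.0               # repolarized within 500 ms

    def test_periodic_apd_by_beat_four(self, paced_cell_trace):
        t, v, _ = paced_cell_trace
        wins = [(k * 1000.0, (k + 1) * 1000.0) for k in range(4)]
        beats = analyze_trace(t, v, wins)
        apds = [b["apd90"] for b in beats]
        assert all(np.isfinite(apds))
        assert abs(apds[3] - apds[2]) < 2.0

    def test_step_halving_local_error_second_order(self):
        """Richardson check: one step of dt vs two of dt/2 differs O(dt^2)."""
        base = baseline_parameters()
        s0 = MyocyteState.rest()
        for _ in range(2500):   # drive into the upstroke at fine dt
            s0 = step_myocyte(s0, base, 0.001, i_stim=20.0)

        def vm_after(dt, n):
            s = s0.copy()
            for _ in range(n):
                s = step_myocyte(s, base, dt, i_stim=20.0)
            return s.vm

        d1 = abs(vm_after(0.01, 1) - vm_after(0.005, 2))
        d2 = abs(vm_after(0.005, 1) - vm_after(0.0025, 2))
        assert 2.5 < d1 / d2 < 6.0

    def test_nan_state_raises_named_failure(self):
        from atriasim import SimulationFailure
        base = baseline_parameters()
        s = MyocyteState.rest()
        with pytest.raises((SimulationFailure, ValueError)):
            for _ in range(200):
                s = step_myocyte(s, base, 5.0, i_stim=500.0)

    def test_gating_stays_in_bounds_when_paced(self, paced_cell_trace):
        _, _, res = paced_cell_trace
        S = res.final_states[0]
        gating = S[0, 1:13]
        assert np.all(gating >= 0.0) and np.all(gating <= 1.0)


# ---------------------------------------------------------------------------
# Fibroblast dynamics
# ---------------------------------------------------------------------------

class TestFibroblast:
    def test_rests_at_stated_potential(self):
        t, v = simulate_single_fibroblast(duration_ms=2000.0)
        assert abs(v[-1] - (-47.75)) < 2.0

    def test_basin_of_attraction(self):
        _, v_hi = simulate_single_fibroblast(duration_ms=6000.0, v0=-30.0)
        _, v_lo = simulate_single_fibroblast(duration_ms=6000.0, v0=-80.0)
        assert abs(v_hi[-1] - v_lo[-1]) < 1.0
        assert abs(v_hi[-1] - (-47.75)) < 2.0

    def test_non_excitable_under_sustained_drive(self):
        """A depolarizing gap current raises Vm toward a plateau without any
        regenerative upstroke: dV/dt never exceeds the passive rate the
        injected current alone can produce."""
        params = baseline_parameters()
        i_gap = 30.0   # pA
        passive_rate = i_gap / params.fibroblast.cm   # mV/ms upper bound
        s = FibroblastState.rest()
        dt = 0.01
        vs = []
        for k in range(50000):   # 500 ms
            s = step_fibroblast(s, params, dt, i_gap_total=i_gap)
            if k % 10 == 0:
                vs.append(s.vm)
        vs = np.array(vs)
        dvdt = np.diff(vs) / (10 * dt)
        assert vs[-1] > -40.0                        # depolarized plateau
        assert dvdt.max() <= passive_rate + 1e-9     # no inward amplification
        # rise is monotone up to its maximum, then relaxes to the plateau
        imax = int(np.argmax(vs))
        assert np.all(np.diff(vs[:imax + 1]) > -1e-9)
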