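"""Biomarker extraction, conduction classification and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from atriasim import (BiomarkerSet, StimulusProtocol, TissueGeometry,
                      analyze_trace, apd90, biomarker_delta,
                      classify_conduction, conduction_velocity, group_tests,
                      summarize_condition)
from atriasim.synthetic import SyntheticTraceSpec, synthetic_ap_trace
from atriasim.tissue import NumericsConfig, SimulationResult


def make_result(nx=200, ny=200, t_left=5.0, t_right=33.13,
                right_activates=True, right_repolarizes=True):
    """Minimal SimulationResult carrying one beat of activation data."""
    g = TissueGeometry(nx=nx, ny=ny, fibrosis_fraction=0.0)
    shape = (1, ny, nx)
    act = np.full(shape, np.nan)
    dep = np.zeros(shape, dtype=bool)
    rep = np.zeros(shape, dtype=bool)
    lx, lyy = g.probe_left
    rx, ry = g.probe_right
    act[0, lyy, lx] = t_left
    dep[0, lyy, lx] = rep[0, lyy, lx] = True
    if right_activates:
        act[0, ry, rx] = t_right
        dep[0, ry, rx] = True
        rep[0, ry, rx] = right_repolarizes
    return SimulationResult(
        time=np.arange(10.0), traces=np.zeros((10, 2)),
        probe_nodes=(g.node_index(lx, lyy), g.node_index(rx, ry)),
        act_times=act, rmp=np.full(shape, -79.0),
        v_peak=np.full(shape, 30.0), apd_end=act + 180.0,
        depolarized=dep, repolarized=rep,
        geometry=g, protocol=StimulusProtocol(n_pulses=1),
        numerics=NumericsConfig())


class TestApd90:
    def test_recovers_planted_value(self):
        spec = SyntheticTraceSpec(apd90=150.0, noise_sd=0.0)
        t, v = synthetic_ap_trace(spec)
        vals = apd90(t, v, spec.beat_windows)
        assert np.all(np.abs(vals - 150.0) < 0.5)

    def test_time_dilation_doubles_apd(self):
        spec = SyntheticTraceSpec(apd90=120.0, noise_sd=0.0, n_beats=1)
        t, v = synthetic_ap_trace(spec)
        a1 = apd90(t, v, spec.beat_windows)[0]
        a2 = apd90(2 * t, v, [(0.0, 2000.0)])[0]
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_no_upstroke_marks_no_ap(self):
        t = np.arange(0.0, 500.0, 0.1)
        v = np.full_like(t, -80.0)
        b = analyze_trace(t, v, [(0.0, 500.0)])[0]
        assert math.isnan(b["apd90"]) and not b["repolarized"]

    def test_sampling_stride_insensitive(self):
        fine = SyntheticTraceSpec(apd90=200.0, dt_ms=0.05, noise_sd=0.0)
        coarse = SyntheticTraceSpec(apd90=200.0, dt_ms=0.25, noise_sd=0.0)
        a_f = apd90(*synthetic_ap_trace(fine), fine.beat_windows)[0]
        a_c = apd90(*synthetic_ap_trace(coarse), coarse.beat_windows)[0]
        assert abs(a_f - a_c) / a_f < 0.005


class TestConductionVelocity:
    def test_probe_arithmetic_matches_convention(self):
        # 1.9 cm between probes, 28.13 ms delay -> ~67.5 cm/s
        res = make_result(t_left=5.0, t_right=33.13)
        assert res.geometry.probe_distance_cm == pytest.approx(1.9)
        assert conduction_velocity(res) == pytest.approx(67.54, abs=0.05)

    def test_silent_right_probe_means_absent(self):
        res = make_result(right_activates=False)
        assert not classify_conduction(res)
        assert conduction_velocity(res) is None

    def test_failure_to_repolarize_is_block(self):
        res = make_result(right_repolarizes=False)
        assert not classify_conduction(res)

    def test_reversed_order_is_an_error(self):
        res = make_result(t_left=40.0, t_right=10.0)
        with pytest.raises(ValueError, match="probe"):
            conduction_velocity(res)


class TestDeltasAndSummaries:
    def _set(self, cv, apd=180.0, rmp=-79.0, peak=100.0, conducted=True):
        return BiomarkerSet(apd90=apd, cv=cv, rmp=rmp, peak=peak,
                            conducted=conducted)

    def test_identical_sets_zero_delta(self):
        a = self._set(67.5)
        d = biomarker_delta(a, a)
        assert d.d_cv == d.d_apd90 == d.d_rmp == d.d_peak == 0.0

    def test_delta_arithmetic_and_antisymmetry(self):
        drug = self._set(64.0)
        basal = self._set(67.5)
        d = biomarker_delta(drug, basal)
        assert d.d_cv == pytest.approx(-3.5)
        r = biomarker_delta(basal, drug)
        assert r.d_cv == pytest.approx(-d.d_cv)
        assert r.d_apd90 == pytest.approx(-d.d_apd90)

    def test_delta_undefined_without_conduction(self):
        with pytest.raises(ValueError):
            biomarker_delta(self._set(None, conducted=False), self._set(67.5))

    def test_single_profile_summary(self):
        s = summarize_condition([self._set(67.5)])
        assert s["CV"]["mean"] == 67.5 and s["CV"]["sd"] == 0.0
        assert s["n_conducting"] == 1

    def test_planted_mean_and_sd(self):
        s = summarize_condition([self._set(60.0), self._set(70.0)])
        assert s["CV"]["mean"] == pytest.approx(65.0)
        assert s["CV"]["sd"] == pytest.approx(7.0711, abs=1e-3)

    def test_non_conducting_excluded(self):
        s = summarize_condition([self._set(60.0),
                                 self._set(None, conducted=False)])
        assert s["n_total"] == 2 and s["n_conducting"] == 1


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"CV": [60, 62, 64, 66, 68.0],
                           "conducted": [True] * 5})
        rep = group_tests({"a": df, "b": df.copy()}, continuous=("CV",))
        assert rep["pairwise"]["a vs b"]["CV"]["p"] > 0.99
        assert not rep["biomarkers"]["CV"]["anova"]["significant"]

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"CV": rng.normal(60, 2, 30), "conducted": True})
        b = pd.DataFrame({"CV": rng.normal(70, 2, 30), "conducted": True})
        rep = group_tests({"a": a, "b": b}, continuous=("CV",))
        assert rep["pairwise"]["a vs b"]["CV"]["p"] < 1e-3
        assert rep["biomarkers"]["CV"]["kruskal"]["significant"]

    def test_chi_square_on_conduction_proportions(self):
        a = pd.DataFrame({"conducted": [True] * 124 + [False] * 0})
        b = pd.DataFrame({"conducted": [True] * 5 + [False] * 11})
        rep = group_tests({"0%": a, "10%": b}, continuous=())
        assert rep["conduction_chi2"]["p"] < 0.05

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            group_tests({"a": pd.DataFrame({"CV": [1.0]})})

    def test_small_groups_flagged_not_computed(self):
        a = pd.DataFrame({"CV": [60.0], "conducted": [True]})
        b = pd.DataFrame({"CV": [61.0], "conducted": [True]})
        rep = group_tests({"a": a, "b": b}, continuous=("CV",))
        assert "flag" in rep["pairwise"]["a vs b"]["CV"]
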