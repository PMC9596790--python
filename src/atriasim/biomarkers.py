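"""Action-potential biomarker extraction and condition-level statistics.

Biomarkers follow the tissue-study conventions: activation at the time of
maximum dV/dt (validated by an upstroke threshold), APD90 from activation to
the crossing of RMP + 0.1*(peak - RMP) with linear interpolation, CV from
the activation-time difference of two probes 1.9 cm apart on the full-size
plane, plane-level values averaged over myocytes and the last two beats.
"Peak" is reported as the AP amplitude (V_max - RMP); the absolute maximum
is stored alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomarkerSet", "BiomarkerDelta", "analyze_trace", "apd90",
    "classify_conduction", "conduction_velocity", "biomarkers_from_result",
    "summarize_condition", "biomarker_delta", "group_tests",
]


# ---------------------------------------------------------------------------
# Trace-level analysis
# ---------------------------------------------------------------------------

def analyze_trace(time: np.ndarray, vm: np.ndarray,
                  beat_windows: Sequence[tuple],
                  dvdt_threshold: float = 1.0,
                  v_cross: float = -20.0) -> list:
    """Per-beat AP markers from a uniformly sampled voltage trace.

    ``beat_windows`` is a sequence of (t_start, t_end) pairs, one per beat.
    Returns a list of dicts with keys t_act, rmp, v_peak, amplitude, apd90,
    repolarized; beats without a validated upstroke carry apd90 = nan and
    t_act = nan (the no-AP marker feeding the conduction logic).
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if time.shape != vm.shape:
        raise ValueError("time and voltage must have the same shape")
    dt = time[1] - time[0]
    dvdt = np.diff(vm) / dt
    out = []
    for (t0, t1) in beat_windows:
        i0, i1 = np.searchsorted(time, [t0, t1])
        i1 = min(i1, len(vm))
        seg = vm[i0:i1]
        if len(seg) < 3:
            raise ValueError("beat window contains too few samples")
        dseg = dvdt[i0:min(i1, len(dvdt))]
        k = int(np.argmax(dseg))
        t_act = time[i0 + k]
        crossed = bool(np.any(seg > v_cross))
        activated = crossed and dseg[k] > dvdt_threshold
        if not activated:
            out.append({"t_act": np.nan, "rmp": float(seg.min()),
                        "v_peak": np.nan, "amplitude": np.nan,
                        "apd90": np.nan, "repolarized": False})
            continue
        rmp = float(seg[:k + 1].min()) if k > 0 else float(seg[0])
        pk = int(np.argmax(seg[k:])) + k
        v_peak = float(seg[pk])
        v90 = rmp + 0.1 * (v_peak - rmp)
        apd = np.nan
        repol = False
        # require two consecutive samples below the threshold so sample
        # noise near the crossing does not trigger early
        tail = seg[pk:] < v90
        below = np.nonzero(tail[:-1] & tail[1:])[0]
        if not below.size and tail.size and tail[-1]:
            below = np.nonzero(tail)[0][-1:]
        if below.size:
            i = pk + below[0]
            # linear interpolation between samples i-1 and i
            va, vb = seg[i - 1], seg[i]
            frac = (va - v90) / (va - vb) if va != vb else 0.0
            t90 = time[i0 + i - 1] + frac * dt
            apd = t90 - t_act
            repol = True
        out.append({"t_act": float(t_act), "rmp": rmp, "v_peak": v_peak,
                    "amplitude": v_peak - rmp, "apd90": float(apd),
                    "repolarized": repol})
    return out


def apd90(time: np.ndarray, vm: np.ndarray,
          beat_windows: Sequence[tuple], **kw) -> np.ndarray:
    """APD90 per beat (ms); nan marks beats without an action potential."""
    return np.array([b["apd90"]
                     for b in analyze_trace(time, vm, beat_windows, **kw)])


# ---------------------------------------------------------------------------
# Tissue-level biomarkers
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSet:
    """Plane-averaged biomarkers of one (profile, fibrosis, drug) run."""
    apd90: float = math.nan       # ms
    cv: Optional[float] = None    # cm/s; None when not conducted
    rmp: float = math.nan         # mV
    peak: float = math.nan        # mV, AP amplitude (V_max - RMP)
    v_max: float = math.nan       # mV, absolute peak potential
    conducted: bool = False
    beats_used: tuple = ()
    n_cells: int = 0
    profile_id: int = -1
    fibrosis_pct: float = 0.0
    drug: str = "none"

    def as_row(self) -> dict:
        return {"profile_id": self.profile_id,
                "fibrosis_pct": self.fibrosis_pct, "drug": self.drug,
                "APD90": self.apd90, "CV": math.nan if self.cv is None
                else self.cv, "RMP": self.rmp, "Peak": self.peak,
                "Vmax": self.v_max, "conducted": self.conducted}


@dataclass(frozen=True)
class BiomarkerDelta:
    """Drug-minus-basal biomarker differences (same units)."""
    d_cv: float
    d_apd90: float
    d_rmp: float
    d_peak: float


def classify_conduction(result) -> bool:
    """True iff after the final stimulus the right CV-probe cell both
    depolarizes and repolarizes before the record ends.

    Failure to be stimulated, to conduct, or to repolarize all yield False.
    """
    g = result.geometry
    ix, iy = g.probe_right
    last = result.act_times.shape[0] - 1
    return bool(result.depolarized[last, iy, ix]
                and result.repolarized[last, iy, ix])


def conduction_velocity(result, last_beats: int = 2) -> Optional[float]:
    """Probe-to-probe conduction velocity (cm/s), averaged over the last
    ``last_beats`` beats; None when the run did not conduct."""
    if not classify_conduction(result):
        return None
    g = result.geometry
    lx, ly = g.probe_left
    rx, ry = g.probe_right
    n_beats = result.act_times.shape[0]
    beats = range(max(0, n_beats - last_beats), n_beats)
    cvs = []
    for b in beats:
        t_l = result.act_times[b, ly, lx]
        t_r = result.act_times[b, ry, rx]
        if np.isnan(t_l) or np.isnan(t_r):
            continue
        if t_r <= t_l:
            raise ValueError(
                f"right probe activated before the left probe on beat {b}; "
                "check probe placement")
        cvs.append(g.probe_distance_cm / (t_r - t_l) * 1000.0)
    return float(np.mean(cvs)) if cvs else None


def biomarkers_from_result(result, last_beats: int = 2,
                           profile_id: int = -1,
                           drug: str = "none") -> BiomarkerSet:
    """Plane-averaged biomarker set: myocyte nodes only, last two beats."""
    g = result.geometry
    myo = ~g.fibrosis_mask
    n_beats = result.act_times.shape[0]
    beats = tuple(range(max(0, n_beats - last_beats), n_beats))

    apds, rmps, amps, vmaxs = [], [], [], []
    for b in beats:
        act = result.act_times[b][myo]
        end = result.apd_end[b][myo]
        rmp = result.rmp[b][myo]
        vpk = result.v_peak[b][myo]
        ok = np.isfinite(act) & np.isfinite(end)
        apds.append(end[ok] - act[ok])
        rmps.append(rmp[np.isfinite(rmp)])
        okp = np.isfinite(vpk) & np.isfinite(rmp)
        amps.append(vpk[okp] - rmp[okp])
        vmaxs.append(vpk[np.isfinite(vpk)])

    def _mean(parts):
        allv = np.concatenate(parts) if parts else np.array([])
        return float(allv.mean()) if allv.size else math.nan

    conducted = classify_conduction(result)
    return BiomarkerSet(
        apd90=_mean(apds),
        cv=conduction_velocity(result, last_beats) if conducted else None,
        rmp=_mean(rmps),
        peak=_mean(amps),
        v_max=_mean(vmaxs),
        conducted=conducted,
        beats_used=beats,
        n_cells=int(myo.sum()),
        profile_id=profile_id,
        fibrosis_pct=result.geometry.fibrosis_fraction * 100.0,
        drug=drug,
    )


# ---------------------------------------------------------------------------
# Condition summaries and deltas
# ---------------------------------------------------------------------------

def summarize_condition(sets: Sequence[BiomarkerSet]) -> dict:
    """Mean +/- SD of each biomarker across conducting profiles, plus
    conduction counts for one (fibrosis, drug) condition."""
    conducting = [s for s in sets if s.conducted]
    summary = {"n_total": len(sets), "n_conducting": len(conducting)}
    if not conducting:
        return summary
    for key, get in (("APD90", lambda s: s.apd90), ("CV", lambda s: s.cv),
                     ("RMP", lambda s: s.rmp), ("Peak", lambda s: s.peak)):
        vals = np.array([get(s) for s in conducting], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            summary[key] = {"mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)) if vals.size > 1
                            else 0.0,
                            "n": int(vals.size)}
    return summary


def biomarker_delta(drug_set: BiomarkerSet,
                    basal_set: BiomarkerSet) -> BiomarkerDelta:
    """Componentwise drug - basal difference; defined only when both
    conditions conducted."""
    if not (drug_set.conducted and basal_set.conducted):
        raise ValueError("biomarker delta is undefined unless both the drug "
                         "and basal runs conduct")
    return BiomarkerDelta(
        d_cv=drug_set.cv - basal_set.cv,
        d_apd90=drug_set.apd90 - basal_set.apd90,
        d_rmp=drug_set.rmp - basal_set.rmp,
        d_peak=drug_set.peak - basal_set.peak,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_tests(groups: dict, continuous: Sequence[str] = ("APD90", "CV",
                                                           "RMP", "Peak"),
                conducted_col: str = "conducted", paired: bool = False) -> dict:
    """Location and proportion tests across >= 2 condition groups.

    ``groups`` maps a group label to a DataFrame of biomarker rows.  For each
    continuous biomarker: pairwise two-sided t-tests, one-way ANOVA and
    Kruskal-Wallis; for the conducted flag: a chi-square test on the
    conducting/blocked contingency table.  Significance threshold p < 0.05.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    report = {"alpha": 0.05, "biomarkers": {}, "pairwise": {}}
    for bm in continuous:
        arrays = []
        for lab in labels:
            df = groups[lab]
            if bm not in df:
                arrays.append(np.array([]))
                continue
            v = np.asarray(df[bm], dtype=float)
            arrays.append(v[np.isfinite(v)])
        usable = [a for a in arrays if a.size >= 2]
        entry = {}
        if len(usable) >= 2:
            f, p_anova = stats.f_oneway(*usable)
            h, p_kw = stats.kruskal(*usable)
            entry["anova"] = {"stat": float(f), "p": float(p_anova),
                              "significant": bool(p_anova < 0.05)}
            entry["kruskal"] = {"stat": float(h), "p": float(p_kw),
                                "significant": bool(p_kw < 0.05)}
        else:
            entry["flag"] = "insufficient group sizes for variance tests"
        report["biomarkers"][bm] = entry
        # pairwise t-tests
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = arrays[i], arrays[j]
                key = f"{labels[i]} vs {labels[j]}"
                pair = report["pairwise"].setdefault(key, {})
                if a.size < 2 or b.size < 2:
                    pair[bm] = {"flag": "group size < 2"}
                    continue
                if paired and a.size == b.size:
                    t, p = stats.ttest_rel(a, b)
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=False)
                pair[bm] = {"t": float(t), "p": float(p),
                            "significant": bool(p < 0.05)}
    # chi-square on conduction proportions
    table = []
    for lab in labels:
        df = groups[lab]
        if conducted_col in df:
            c = np.asarray(df[conducted_col], dtype=bool)
            table.append([int(c.sum()), int((~c).sum())])
    table = [row for row in table if sum(row) > 0]
    if len(table) >= 2:
        arr = np.array(table)
        if np.all(arr.sum(axis=0) > 0):
            chi2, p, dof, _ = stats.chi2_contingency(arr)
            report["conduction_chi2"] = {"stat": float(chi2), "p": float(p),
                                         "dof": int(dof),
                                         "significant": bool(p < 0.05),
                                         "table": arr.tolist()}
    return report
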