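"""Population of models: Latin Hypercube sampling of electrophysiological
profiles and biomarker-range calibration on a thin tissue strip.

Nine parameters of the baseline myocyte/tissue model (gNa, INaK, gK1, gCaL,
gKur, IKCa, D, Ko, Nao) are varied as multiplicative percent modifiers in
[-50%, +100%].  Candidates are simulated on a calibration strip (8x256
nodes by default, no fibrosis, no drug) and kept only if all action
potential biomarkers fall inside the configured physiological acceptance
ranges, measured over the last two beats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .biomarkers import BiomarkerSet, biomarkers_from_result
from .cell_models import (PROFILE_PARAMETERS, SCALING_MAX, SCALING_MIN,
                          ProfileScaling, SimulationFailure,
                          baseline_parameters)
from .tissue import (NumericsConfig, StimulusProtocol, TissueGeometry,
                     run_simulation)

__all__ = ["BiomarkerRanges", "lhs_sample", "calibrate_population",
           "CalibrationResult", "default_ranges", "profiles_to_csv",
           "profiles_from_csv"]

DEFAULT_BOUNDS = {name: (SCALING_MIN, SCALING_MAX)
                  for name in PROFILE_PARAMETERS}


@dataclass(frozen=True)
class BiomarkerRanges:
    """Inclusive acceptance bounds (min, max) per biomarker.

    Keys: APD90 (ms), CV (cm/s), RMP (mV), Peak (mV, AP amplitude).
    """
    bounds: dict

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty acceptance range for {k}")

    def accepts(self, bm: BiomarkerSet) -> tuple:
        """(accepted, reasons) for a biomarker set; non-conducting
        candidates are always rejected."""
        if not bm.conducted:
            return False, ["no conduction"]
        values = {"APD90": bm.apd90, "CV": bm.cv, "RMP": bm.rmp,
                  "Peak": bm.peak}
        reasons = []
        for k, (lo, hi) in self.bounds.items():
            v = values.get(k)
            if v is None or not np.isfinite(v) or not lo <= v <= hi:
                reasons.append(f"{k}={v} outside [{lo}, {hi}]")
        return not reasons, reasons


def default_ranges() -> BiomarkerRanges:
    """The shipped acceptance ranges (editable data file)."""
    with resources.files("atriasim.data").joinpath(
            "biomarker_ranges.json").open() as fh:
        raw = json.load(fh)
    raw.pop("_meta", None)
    return BiomarkerRanges({k: tuple(v) for k, v in raw.items()})


def lhs_sample(n: int, bounds: Optional[dict] = None,
               seed: int = 0) -> list:
    """Latin Hypercube sample of ``n`` profiles over the nine parameters.

    Each parameter takes exactly one value in each of n equal-width strata
    of its range; deterministic under ``seed``.  Degenerate bounds
    (min == max) yield a constant column.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    unknown = set(bounds) - set(PROFILE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameters in bounds: {sorted(unknown)}")
    sampler = qmc.LatinHypercube(d=len(PROFILE_PARAMETERS), seed=seed)
    u = sampler.random(n)
    lo = np.array([bounds[p][0] for p in PROFILE_PARAMETERS])
    hi = np.array([bounds[p][1] for p in PROFILE_PARAMETERS])
    degenerate = lo == hi
    for p, flag in zip(PROFILE_PARAMETERS, degenerate):
        if flag:
            import warnings
            warnings.warn(f"degenerate bounds for {p}: column is constant")
    x = qmc.scale(u, lo, np.where(degenerate, lo + 1.0, hi))
    x[:, degenerate] = lo[degenerate]
    return [ProfileScaling(profile_id=i,
                           **dict(zip(PROFILE_PARAMETERS, row)))
            for i, row in enumerate(x)]


def calibration_geometry(nx: int = 256, ny: int = 8) -> TissueGeometry:
    """The default calibration strip: 8x256 nodes, no fibrosis."""
    return TissueGeometry(nx=nx, ny=ny, fibrosis_fraction=0.0)


@dataclass
class CalibrationResult:
    accepted: list                       # list of ProfileScaling
    provenance: pd.DataFrame             # one row per candidate

    @property
    def accepted_ids(self) -> list:
        return [p.profile_id for p in self.accepted]


def calibrate_population(candidates: Sequence[ProfileScaling],
                         ranges: Optional[BiomarkerRanges] = None,
                         geometry: Optional[TissueGeometry] = None,
                         protocol: Optional[StimulusProtocol] = None,
                         numerics: Optional[NumericsConfig] = None,
                         ) -> CalibrationResult:
    """Simulate every candidate on the calibration strip and keep those whose
    biomarkers all fall inside ``ranges``.

    Candidates whose simulation blows up are rejected with reason
    "numerical failure".  Deterministic given configuration; the provenance
    table records biomarkers and rejection reasons per candidate.
    """
    ranges = ranges or default_ranges()
    geometry = geometry or calibration_geometry()
    protocol = protocol or StimulusProtocol.scaled(geometry.nx)
    base = baseline_parameters()

    accepted, rows = [], []
    for cand in candidates:
        row = {"profile_id": cand.profile_id, **cand.as_dict()}
        # step size satisfying the stability bound for this candidate's D
        num = numerics or NumericsConfig.for_diffusion(
            base.diffusion * (1.0 + cand.D / 100.0), dx=geometry.dx)
        try:
            res = run_simulation(geometry, profile=cand, protocol=protocol,
                                 numerics=num)
            bm = biomarkers_from_result(res, profile_id=cand.profile_id)
            ok, reasons = ranges.accepts(bm)
            row.update(bm.as_row())
            row["accepted"] = ok
            row["reason"] = "; ".join(reasons)
            if ok:
                accepted.append(cand)
        except SimulationFailure as exc:
            row["accepted"] = False
            row["reason"] = f"numerical failure: {exc}"
        rows.append(row)
    return CalibrationResult(accepted=accepted,
                             provenance=pd.DataFrame(rows))


def profiles_to_csv(profiles: Sequence[ProfileScaling], path) -> None:
    """Write profiles with the canonical nine-column header."""
    df = pd.DataFrame([{**p.as_dict(), "profile_id": p.profile_id}
                       for p in profiles])
    df.to_csv(path, index=False,
              columns=list(PROFILE_PARAMETERS) + ["profile_id"])


def profiles_from_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(PROFILE_PARAMETERS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        pid = int(row["profile_id"]) if "profile_id" in df.columns else i
        out.append(ProfileScaling(profile_id=pid,
                                  **{p: float(row[p])
                                     for p in PROFILE_PARAMETERS}))
    return out
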