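"""Result persistence: HDF5 for traces/activation maps, CSV for biomarkers."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd


def save_result(result, path) -> None:
    """Write probe traces, per-beat activation/biomarker maps and the run
    configuration (as JSON attributes) to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=result.time)
        f.create_dataset("traces_mV", data=result.traces)
        f.create_dataset("activation_ms", data=result.act_times)
        f.create_dataset("rmp_mV", data=result.rmp)
        f.create_dataset("v_peak_mV", data=result.v_peak)
        f.create_dataset("apd_end_ms", data=result.apd_end)
        f.create_dataset("depolarized", data=result.depolarized)
        f.create_dataset("repolarized", data=result.repolarized)
        f.create_dataset("fibrosis_mask",
                         data=result.geometry.fibrosis_mask)
        g = result.geometry
        f.attrs["config"] = json.dumps({
            "nx": g.nx, "ny": g.ny, "dx_cm": g.dx,
            "fibrosis_fraction": g.fibrosis_fraction,
            "mask_seed": g.mask_seed,
            "probe_left": list(g.probe_left),
            "probe_right": list(g.probe_right),
            "probe_nodes": list(result.probe_nodes),
            "n_pulses": result.protocol.n_pulses,
            "amplitude_pApF": result.protocol.amplitude,
            "duration_ms": result.protocol.duration,
            "period_ms": result.protocol.period,
            "dt_us": result.numerics.dt_us,
            "record_stride": result.numerics.record_stride,
            "diffusion_cm2_ms": result.params.diffusion,
            "conducted": bool(result.conducted),
        })
        f.attrs["stimulus_log"] = json.dumps(result.stimulus_log)


def biomarker_table(sets) -> pd.DataFrame:
    """Flat CSV-ready table: one row per (profile, fibrosis, drug) run."""
    return pd.DataFrame([s.as_row() for s in sets])
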