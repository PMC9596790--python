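"""Seeded synthetic fixtures: ground-truth AP traces, surrogate ML datasets
with a known decision rule, and ready-to-run toy tissue bundles.

Every generator is a pure function of its specification and seed, and its
output passes the same validators and schemas as real pipeline data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_models import PROFILE_PARAMETERS, ProfileScaling, \
    baseline_parameters
from .classifier import DRUG_FACTOR_COLUMNS, FEATURE_COLUMNS, LABEL_COLUMN
from .pharmacology import load_drug_table
from .tissue import NumericsConfig, StimulusProtocol, TissueGeometry

__all__ = ["SyntheticTraceSpec", "synthetic_ap_trace",
           "surrogate_ml_dataset", "toy_plane", "ToyPlaneBundle"]


# ---------------------------------------------------------------------------
# AP-like traces with planted biomarkers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTraceSpec:
    """An AP-like waveform with analytically known biomarkers.

    The upstroke is a half-cosine ramp (maximum dV/dt exactly at its
    midpoint = the activation time); repolarization decays linearly to RMP
    so that the 90%-repolarization crossing falls exactly ``apd90`` after
    activation.
    """
    rmp: float = -78.63            # mV
    amplitude: float = 89.16       # mV above RMP
    apd90: float = 150.0           # ms
    upstroke_ms: float = 2.0
    period_ms: float = 1000.0
    n_beats: int = 2
    dt_ms: float = 0.1
    noise_sd: float = 0.0          # mV
    seed: int = 0

    def __post_init__(self):
        if not self.apd90 < self.period_ms:
            raise ValueError("APD90 must be below the beat period")
        if self.amplitude <= 0 or self.noise_sd < 0:
            raise ValueError("invalid amplitude or noise SD")

    @property
    def beat_windows(self) -> list:
        return [(k * self.period_ms, (k + 1) * self.period_ms)
                for k in range(self.n_beats)]


def synthetic_ap_trace(spec: SyntheticTraceSpec):
    """Generate (time, Vm) for the spec; planted APD90/RMP/amplitude are
    exact in the noiseless limit."""
    n = int(round(spec.n_beats * spec.period_ms / spec.dt_ms))
    t = np.arange(n) * spec.dt_ms
    v = np.full(n, spec.rmp)
    up = spec.upstroke_ms
    peak = spec.rmp + spec.amplitude
    # activation (max dV/dt of the half-cosine) is at t_on + up/2;
    # the linear decay reaches V90 = rmp + 0.1*amplitude at t_act + apd90
    t_end_rel = up + (spec.apd90 - up / 2.0) / 0.9
    for k in range(spec.n_beats):
        t0 = k * spec.period_ms
        tau = t - t0
        rising = (tau >= 0) & (tau < up)
        v[rising] = spec.rmp + spec.amplitude * \
            0.5 * (1.0 - np.cos(np.pi * tau[rising] / up))
        falling = (tau >= up) & (tau < t_end_rel)
        v[falling] = peak - (peak - spec.rmp) * (tau[falling] - up) \
            / (t_end_rel - up)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=n)
    return t, v


# ---------------------------------------------------------------------------
# Surrogate feature tables with a known labeling rule
# ---------------------------------------------------------------------------

def _bayes_rule(rule: str):
    if rule == "sodium_product":
        # conduction iff the drug's INa factor times the profile's relative
        # sodium conductance stays above threshold
        def f(row):
            return row["factor_INa"] * (1.0 + row["gNa"] / 100.0) >= 0.75

        def margin_of(row):
            return abs(row["factor_INa"] * (1.0 + row["gNa"] / 100.0) - 0.75)
    elif rule == "single_feature":
        def f(row):
            return row["gNa"] >= 25.0

        def margin_of(row):
            return abs(row["gNa"] - 25.0) / 75.0
    elif rule == "linear_sum":
        # linearly separable rule spanning all nine profile modifiers
        def score(row):
            return float(np.mean([(row[p] - 25.0) / 75.0
                                  for p in PROFILE_PARAMETERS]))

        def f(row):
            return score(row) >= 0.0

        margin_of = lambda row: abs(score(row))  # noqa: E731
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return f, margin_of


def surrogate_ml_dataset(n: int, rule: str = "sodium_product",
                         noise_rate: float = 0.0, seed: int = 0,
                         margin: float = 0.0) -> pd.DataFrame:
    """Feature rows with the study's exact schema and labels from a known
    rule, optionally flipped at ``noise_rate`` (Bayes accuracy is therefore
    1 - noise_rate).  Rows closer than ``margin`` (in the rule's own scale)
    to the decision boundary are rejected, guaranteeing separability.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    decide, margin_of = _bayes_rule(rule)
    drug_table = load_drug_table()
    drug_names = ["none"] + sorted(drug_table)
    rows = []
    while len(rows) < n:
        row = {p: rng.uniform(-50.0, 100.0) for p in PROFILE_PARAMETERS}
        drug = drug_names[rng.integers(len(drug_names))]
        factors = {c: 1.0 for c in DRUG_FACTOR_COLUMNS}
        if drug != "none":
            for ch, f in drug_table[drug].factors().items():
                factors[f"factor_{ch}"] = f
        row.update(factors)
        row["fibrosis_pct"] = float(rng.choice([0.0, 5.0, 10.0]))
        if margin > 0 and margin_of(row) < margin:
            continue
        label = decide(row)
        # the flip draw is consumed regardless of the rate so datasets with
        # different noise levels share features under the same seed
        if rng.random() < noise_rate:
            label = not label
        row[LABEL_COLUMN] = int(label)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + [LABEL_COLUMN])


# ---------------------------------------------------------------------------
# Toy tissue bundles
# ---------------------------------------------------------------------------

@dataclass
class ToyPlaneBundle:
    geometry: TissueGeometry
    protocol: StimulusProtocol
    numerics: NumericsConfig
    profile: ProfileScaling
    params: object = field(repr=False, default=None)


def toy_plane(nx: int = 20, ny: int = 20, fraction: float = 0.0,
              seed: int = 0, n_pulses: int = 2,
              dt_us: float = 10.0) -> ToyPlaneBundle:
    """A ready-to-run down-scaled plane with the baseline profile.

    Probes follow the proportional 2.5% / 97.5% x-extent convention (clamped
    outside the stimulated edge) and the stimulus amplitude is rescaled by
    nx/200 so the toy domain sees the same charge-per-area as the full-size
    protocol.
    """
    if nx < 10 or ny < 10:
        raise ValueError("toy planes need nx, ny >= 10")
    geometry = TissueGeometry(nx=nx, ny=ny, fibrosis_fraction=fraction,
                              mask_seed=seed)
    protocol = StimulusProtocol.scaled(nx, n_pulses=n_pulses)
    numerics = NumericsConfig(dt_us=dt_us)
    return ToyPlaneBundle(geometry=geometry, protocol=protocol,
                          numerics=numerics,
                          profile=ProfileScaling(profile_id=0),
                          params=baseline_parameters())
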