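"""Single-pore-channel antiarrhythmic drug block.

A drug at free concentration [C_d] reduces the conductance of each target
channel by the factor G_i/G_0 = 1 / (1 + [C_d]/IC50).  The shipped drug
table covers amiodarone, dofetilide and sotalol with IKr, ICaL and INa
targets; block acts on myocyte channels only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Optional

__all__ = ["DrugSpec", "block_factor", "apply_drug", "load_drug_table",
           "get_drug", "DRUG_CHANNELS"]

#: channels a drug may target, and the myocyte parameter each maps onto
DRUG_CHANNELS = {"IKr": "g_kr", "ICaL": "g_cal", "INa": "p_na"}


@dataclass(frozen=True)
class DrugSpec:
    """A drug: free concentration (uM) and per-channel IC50 values (uM)."""
    name: str
    concentration: float
    ic50: dict

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("drug concentration must be non-negative")
        unknown = set(self.ic50) - set(DRUG_CHANNELS)
        if unknown:
            raise ValueError(f"unknown drug target channels: {sorted(unknown)}")
        for ch, v in self.ic50.items():
            if v <= 0:
                raise ValueError(f"IC50 for {ch} must be positive")

    def factors(self) -> dict:
        """Conductance factor G_i/G_0 per target channel."""
        return {ch: block_factor(self.concentration, ic)
                for ch, ic in self.ic50.items()}


def block_factor(concentration: float, ic50: float) -> float:
    """Pore-block conductance factor 1/(1 + c/IC50), in (0, 1]."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return 1.0 / (1.0 + concentration / ic50)


def apply_drug(params, drug: Optional[DrugSpec]):
    """Scale the targeted myocyte channel conductances by the drug's block
    factors; fibroblast currents and every other parameter are untouched.

    Multiplicative, so it composes order-independently with population
    profile scaling.  ``drug=None`` is the identity.
    """
    if drug is None:
        return params
    changes = {DRUG_CHANNELS[ch]: getattr(params.myocyte, DRUG_CHANNELS[ch]) * f
               for ch, f in drug.factors().items()}
    return replace(params, myocyte=replace(params.myocyte, **changes))


@lru_cache(maxsize=1)
def load_drug_table() -> dict:
    """The shipped drug constants as {name: DrugSpec}."""
    with resources.files("atriasim.data").joinpath("drugs.json").open() as fh:
        raw = json.load(fh)
    raw.pop("_meta", None)
    return {name: DrugSpec(name=name, concentration=d["concentration"],
                           ic50=dict(d["ic50"]))
            for name, d in raw.items()}


def get_drug(name: Optional[str]) -> Optional[DrugSpec]:
    """Look a drug up by name; ``None`` or ``"none"`` mean no drug."""
    if name is None or name == "none":
        return None
    table = load_drug_table()
    if name not in table:
        raise KeyError(f"unknown drug {name!r}; have {sorted(table)}")
    return table[name]
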