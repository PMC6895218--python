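"""Stage-specific oocyte packing density and whole-ovary oocyte numbers.

The packing density (oocytes per gram of ovary) of a stage follows, in
log10 form, from its volume fraction, the prolate-spheroid shape factor,
the ovary's specific gravity and the shrinkage-corrected volume-based
diameter:

    log10(OPD) = log10[ Vv * (1/rho) * (1+k)^3 / (8k) ] + C - 3*log10(cODv)

with cODv in micrometres and rho in g/cm3.  The additive constant C is the
cm3-to-um3 conversion for a prolate spheroid, 12 + log10(6/pi) = 12.281;
the published form rounds it to 12.28.  Both variants are supported via
``constant_mode`` ("exact" / "printed", default printed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from opdpipe.errors import ModelDomainError
from opdpipe.stages import OocyteStage

__all__ = [
    "EXACT_CONSTANT",
    "PRINTED_CONSTANT",
    "RHO_PRIMARY",
    "RHO_SECONDARY",
    "specific_gravity",
    "opd",
    "oocyte_number",
    "StageDensityInput",
    "stage_table",
]

#: Exact additive constant: unit conversion for a prolate spheroid.
EXACT_CONSTANT = 12.0 + math.log10(6.0 / math.pi)

#: Two-decimal constant as published.
PRINTED_CONSTANT = 12.28

#: Ovary specific gravity (g/cm3) when the most advanced oocyte is
#: previtellogenic or migratory-nucleus stage ...
RHO_PRIMARY = 1.061
#: ... and when it is cortical-alveoli or vitellogenic.
RHO_SECONDARY = 1.072

_RHO_BY_MAO = {
    OocyteStage.PVO1: RHO_PRIMARY,
    OocyteStage.PVO2: RHO_PRIMARY,
    OocyteStage.PVO3: RHO_PRIMARY,
    OocyteStage.PVO4A: RHO_PRIMARY,
    OocyteStage.PVO4B: RHO_PRIMARY,
    OocyteStage.PVO4C: RHO_PRIMARY,
    OocyteStage.MNO: RHO_PRIMARY,
    OocyteStage.CAO: RHO_SECONDARY,
    OocyteStage.EVTO: RHO_SECONDARY,
    OocyteStage.VTO: RHO_SECONDARY,
}


def specific_gravity(mao: OocyteStage | str, hyo_policy: str = "warn") -> float:
    """Ovary specific gravity from the most advanced oocyte stage present.

    No value is defined for ovaries with hydrated oocytes as the most
    advanced stage (they are excluded from packing-density estimation);
    policy "warn" falls back to the vitellogenic value with a warning,
    "error" raises.
    """
    mao = OocyteStage(mao)
    if mao is OocyteStage.HYO:
        if hyo_policy == "error":
            raise ModelDomainError(
                "specific gravity undefined for HYO as most advanced stage"
            )
        warnings.warn(
            "specific gravity undefined for HYO as most advanced stage; "
            "using the vitellogenic value 1.072",
            stacklevel=2,
        )
        return RHO_SECONDARY
    return _RHO_BY_MAO[mao]


def opd(
    Vv: float,
    k: float,
    cODv_um: float,
    rho: float,
    constant_mode: str = "printed",
) -> float:
    """Stage-specific oocyte packing density in oocytes per gram of ovary.

    A volume fraction of zero short-circuits to zero density (the logarithm
    is bypassed).  ``constant_mode`` selects the published two-decimal
    constant or the analytically exact one.
    """
    if not 0.0 <= Vv <= 1.0:
        raise ModelDomainError(f"Vv must be in [0, 1], got {Vv}")
    if k < 1.0:
        raise ModelDomainError(f"shape factor must be >= 1, got {k}")
    if cODv_um <= 0:
        raise ModelDomainError(f"cODv must be positive, got {cODv_um}")
    if rho <= 0:
        raise ModelDomainError(f"specific gravity must be positive, got {rho}")
    if Vv == 0.0:
        return 0.0
    if constant_mode == "printed":
        c = PRINTED_CONSTANT
    elif constant_mode == "exact":
        c = EXACT_CONSTANT
    else:
        raise ValueError(f"unknown constant_mode {constant_mode!r}")
    shape_term = (1.0 + k) ** 3 / (8.0 * k)
    log_opd = math.log10(Vv * (1.0 / rho) * shape_term) + c - 3.0 * math.log10(cODv_um)
    return 10.0**log_opd


def oocyte_number(OPD: float, GWf_g: float) -> float:
    """Whole-ovary stage oocyte number: packing density times fixed gonad weight."""
    if OPD < 0:
        raise ModelDomainError("OPD must be non-negative")
    if GWf_g <= 0:
        raise ModelDomainError("fixed gonad weight must be positive")
    return OPD * GWf_g


@dataclass(frozen=True)
class StageDensityInput:
    """Inputs for one stage of one female."""

    stage: OocyteStage
    Vv: float
    k: float
    cODv_um: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.Vv <= 1.0:
            raise ModelDomainError("Vv must be in [0, 1]")


def stage_table(
    inputs,
    mao: OocyteStage | str,
    GWf_g: float,
    constant_mode: str = "printed",
    hyo_policy: str = "warn",
) -> pd.DataFrame:
    """Packing density and oocyte number for every stage of one female.

    ``inputs`` is an iterable of :class:`StageDensityInput` or a DataFrame
    with columns (stage, Vv, k, cODv_um).  Hydrated oocytes are carried
    through with missing density and a reason code rather than computed,
    since their embedded dimensions cannot be measured reliably.
    """
    if isinstance(inputs, pd.DataFrame):
        inputs = [
            StageDensityInput(
                stage=OocyteStage(str(r["stage"])),
                Vv=float(r["Vv"]),
                k=float(r["k"]),
                cODv_um=float(r["cODv_um"]),
            )
            for _, r in inputs.iterrows()
        ]
    inputs = list(inputs)
    if not inputs:
        return pd.DataFrame(
            columns=["stage", "Vv", "k", "cODv_um", "rho", "OPD", "NO", "reason"]
        )
    mao = OocyteStage(mao)
    rows = []
    for item in inputs:
        if item.stage is OocyteStage.HYO:
            rows.append(
                {
                    "stage": item.stage.value,
                    "Vv": item.Vv,
                    "k": float("nan"),
                    "cODv_um": float("nan"),
                    "rho": float("nan"),
                    "OPD": float("nan"),
                    "NO": float("nan"),
                    "reason": "HYO_excluded",
                }
            )
            continue
        rho = specific_gravity(mao, hyo_policy=hyo_policy)
        density = opd(item.Vv, item.k, item.cODv_um, rho, constant_mode=constant_mode)
        rows.append(
            {
                "stage": item.stage.value,
                "Vv": item.Vv,
                "k": item.k,
                "cODv_um": item.cODv_um,
                "rho": rho,
                "OPD": density,
                "NO": oocyte_number(density, GWf_g),
                "reason": "",
            }
        )
    out = pd.DataFrame(rows)
    out["stage_order"] = [OocyteStage(s).order for s in out["stage"]]
    out = out.sort_values("stage_order").drop(columns="stage_order")
    return out.reset_index(drop=True)
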