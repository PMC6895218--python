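"""Size standardization of stage oocyte numbers and supporting model fits.

Three standardized forms of the whole-ovary stage oocyte number NO:
  * length-class split (raw NO, analysed within length classes),
  * TL-based relative NO = NO / TL^3 (cube-length proxy for body weight,
    justified by an isometric length-weight power law),
  * EW-based relative NO = NO / eviscerated weight (cross-validation path).
A phase-dependent linear model of fixed gonad weight on total length gives
predicted gonad weights and hence predicted oocyte numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from opdpipe.errors import MissingDataError, ModelDomainError

__all__ = [
    "AllometryFit",
    "GwModelFit",
    "fit_length_weight_power",
    "tl_based_no",
    "ew_based_no",
    "fit_gw_model",
    "predicted_no",
    "length_class_split",
]


@dataclass(frozen=True)
class AllometryFit:
    """Power-law fit W = a * L^b by OLS on log10-transformed data."""

    a: float
    b: float
    se_b: float  # nan when only two points (exact interpolation)
    r2: float
    n: int


def fit_length_weight_power(tl_cm: Sequence[float], ew_g: Sequence[float]) -> AllometryFit:
    """Fit EW = a * TL^b by least squares on log10 scale.

    Requires positive lengths and weights.  With exactly two points the fit
    interpolates and the slope standard error is undefined (returned as nan).
    """
    tl = np.asarray(tl_cm, dtype=float)
    ew = np.asarray(ew_g, dtype=float)
    if tl.size != ew.size or tl.size < 2:
        raise MissingDataError("need >= 2 paired (TL, EW) observations")
    if np.any(tl <= 0) or np.any(ew <= 0):
        raise ModelDomainError("lengths and weights must be positive")
    x = np.log10(tl)
    y = np.log10(ew)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    if tl.size == 2:
        se_b = float("nan")
        r2 = 1.0
    else:
        se_b = float(model.bse[1])
        r2 = float(model.rsquared)
    return AllometryFit(a=10.0**intercept, b=float(slope), se_b=se_b, r2=r2, n=tl.size)


def tl_based_no(NO, TL_cm):
    """Length-standardized oocyte number NO / TL^3 (oocytes per cm^3)."""
    tl = np.asarray(TL_cm, dtype=float)
    if np.any(tl <= 0):
        raise ModelDomainError("TL must be positive")
    out = np.asarray(NO, dtype=float) / tl**3
    return float(out) if np.ndim(out) == 0 else out


def ew_based_no(NO, EW_g):
    """Weight-standardized oocyte number NO / EW (oocytes per gram of body).

    Missing eviscerated weights propagate as missing results.
    """
    ew = np.asarray(EW_g, dtype=float)
    no = np.asarray(NO, dtype=float)
    out = np.where(np.isnan(ew) | (ew <= 0), np.nan, no / ew)
    if np.ndim(out) == 0 or (np.ndim(NO) == 0 and np.ndim(EW_g) == 0):
        return float(np.asarray(out).reshape(()))
    return out


@dataclass
class GwModelFit:
    """Gonad weight ~ phase + TL + phase:TL linear model."""

    intercept_by_phase: dict
    slope_by_phase: dict
    adj_r2: float
    interaction_f: float
    interaction_p: float
    n: int
    response: str

    def predict(self, phase: str, TL_cm: float) -> float:
        phase = str(phase)
        if phase not in self.intercept_by_phase:
            raise ModelDomainError(f"phase {phase!r} was not in the fitted data")
        return self.intercept_by_phase[phase] + self.slope_by_phase[phase] * TL_cm


def fit_gw_model(
    records: pd.DataFrame,
    response: str = "GWf_g",
    min_per_phase: int = 3,
) -> GwModelFit:
    """Fit gonad weight on total length with phase-specific lines.

    Categorical phase encoding with a phase-by-length interaction; returns
    per-phase intercepts and slopes, adjusted r2 and the F statistic for
    slope homogeneity (interaction term).
    """
    needed = {response, "TL_cm", "MAT"}
    if not needed.issubset(records.columns):
        raise MissingDataError(f"records need columns {sorted(needed)}")
    data = records[[response, "TL_cm", "MAT"]].dropna().copy()
    data["MAT"] = data["MAT"].astype(str)
    counts = data["MAT"].value_counts()
    thin = counts[counts < min_per_phase]
    if len(thin):
        raise MissingDataError(
            "phases with too few females for a phase-specific line: "
            + ", ".join(f"{p} (n={c})" for p, c in thin.items())
        )
    phases = sorted(counts.index)
    if len(phases) < 2:
        # single phase: plain regression, no interaction test
        model = smf.ols(f"{response} ~ TL_cm", data=data).fit()
        phase = phases[0]
        return GwModelFit(
            intercept_by_phase={phase: float(model.params["Intercept"])},
            slope_by_phase={phase: float(model.params["TL_cm"])},
            adj_r2=float(model.rsquared_adj),
            interaction_f=float("nan"),
            interaction_p=float("nan"),
            n=len(data),
            response=response,
        )
    full = smf.ols(f"{response} ~ C(MAT) * TL_cm", data=data).fit()
    reduced = smf.ols(f"{response} ~ C(MAT) + TL_cm", data=data).fit()
    comparison = anova_lm(reduced, full)
    base = phases[0]
    intercepts = {base: float(full.params["Intercept"])}
    slopes = {base: float(full.params["TL_cm"])}
    for phase in phases[1:]:
        intercepts[phase] = intercepts[base] + float(
            full.params.get(f"C(MAT)[T.{phase}]", 0.0)
        )
        slopes[phase] = slopes[base] + float(
            full.params.get(f"C(MAT)[T.{phase}]:TL_cm", 0.0)
        )
    return GwModelFit(
        intercept_by_phase=intercepts,
        slope_by_phase=slopes,
        adj_r2=float(full.rsquared_adj),
        interaction_f=float(comparison["F"].iloc[1]),
        interaction_p=float(comparison["Pr(>F)"].iloc[1]),
        n=len(data),
        response=response,
    )


def predicted_no(OPD, predicted_GWf_g):
    """Predicted stage oocyte number from packing density and predicted GWf."""
    opd_arr = np.asarray(OPD, dtype=float)
    gwf = np.asarray(predicted_GWf_g, dtype=float)
    if np.any(opd_arr < 0):
        raise ModelDomainError("OPD must be non-negative")
    if np.any(gwf <= 0):
        raise ModelDomainError("predicted GWf must be positive")
    out = opd_arr * gwf
    return float(out) if np.ndim(out) == 0 else out


OUT_OF_RANGE = "OUT_OF_RANGE"


def length_class_split(
    records: pd.DataFrame,
    boundaries: Sequence[float],
    column: str = "TL_cm",
    label_column: str = "tl_class",
) -> pd.DataFrame:
    """Assign each female to a half-open length class [lo, hi).

    A female of 64.9 cm falls in a 45-65 class; one of exactly 65.0 cm
    falls in the next class.  Lengths outside the boundary span are flagged
    with ``OUT_OF_RANGE``.
    """
    bounds = list(boundaries)
    if len(bounds) < 2 or any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing, length >= 2")
    labels = [f"{_fmt(lo)}-{_fmt(hi)}" for lo, hi in zip(bounds, bounds[1:])]
    out = records.copy()
    tl = out[column].to_numpy(float)
    idx = np.searchsorted(bounds, tl, side="right") - 1
    cls = np.where(
        (idx >= 0) & (idx < len(labels)) & (tl >= bounds[0]) & (tl < bounds[-1]),
        np.array(labels + [OUT_OF_RANGE])[np.clip(idx, 0, len(labels))],
        OUT_OF_RANGE,
    )
    out[label_column] = cls
    return out


def _fmt(x: float) -> str:
    return f"{x:g}"
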