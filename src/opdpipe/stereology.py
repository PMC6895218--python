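"""Stereological estimators: volume fractions, shape factors, diameters.

Volume fractions follow the Delesse principle: on a uniformly random planar
section, the area fraction of a component is an unbiased estimator of its
volume fraction, and point-count fractions estimate area fractions.  Counts
are pooled across fields as a ratio of sums, which stays unbiased when the
number of valid points differs between fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from opdpipe.errors import (
    MissingDataError,
    ModelDomainError,
    UndefinedVolumeFractionError,
)
from opdpipe.stages import (
    ALL_COMPONENTS,
    EMPTY_SPACE,
    OUTSIDE_WALL,
    OocyteStage,
)

__all__ = [
    "GridSpec",
    "GRID_A",
    "GRID_B",
    "FieldCount",
    "ShrinkageModel",
    "StabilizationResult",
    "volume_fraction",
    "stabilization_curve",
    "shape_factor",
    "volume_based_diameter",
    "correct_shrinkage",
    "compare_correction_models",
    "select_grid",
    "summarize_by_female",
]


@dataclass(frozen=True)
class GridSpec:
    """Square point lattice overlaid on a micrograph field."""

    n_points: int = 370
    probe_line_length_um: float = 65.7
    arrangement: str = "square"
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("grid needs at least one point")
        if self.probe_line_length_um <= 0:
            raise ValueError("probe line length must be positive")


#: The two pilot grid set-ups.
GRID_A = GridSpec(n_points=240, probe_line_length_um=77.1, name="A")
GRID_B = GridSpec(n_points=370, probe_line_length_um=65.7, name="B")


@dataclass
class FieldCount:
    """Grid hits for one micrograph field, one count per component."""

    field_id: str
    n_points: int
    hits: dict = field(default_factory=dict)
    female_id: str = ""

    def __post_init__(self) -> None:
        for comp, c in self.hits.items():
            if comp not in ALL_COMPONENTS:
                raise ValueError(f"unknown component {comp!r}")
            if c < 0:
                raise ValueError(f"negative hit count for {comp!r}")
        total = sum(self.hits.values())
        if total != self.n_points:
            raise ValueError(
                f"hits sum to {total}, expected n_points={self.n_points}"
            )

    def get(self, component) -> int:
        return int(self.hits.get(_component_token(component), 0))

    @property
    def valid_points(self) -> int:
        """Points on sectioned tissue (excludes empty space / outside wall)."""
        return self.n_points - self.get(EMPTY_SPACE) - self.get(OUTSIDE_WALL)


def _component_token(component) -> str:
    if isinstance(component, OocyteStage):
        return component.value
    return str(component)


def volume_fraction(counts: Iterable[FieldCount], component) -> float:
    """Pooled volume fraction of ``component`` over one or more fields.

    Ratio of summed hits to summed valid points (points minus empty-space
    and outside-wall hits).
    """
    counts = list(counts)
    if not counts:
        raise MissingDataError("volume_fraction needs at least one field")
    token = _component_token(component)
    num = sum(fc.get(token) for fc in counts)
    den = sum(fc.valid_points for fc in counts)
    if den <= 0:
        raise UndefinedVolumeFractionError(
            "no valid (tissue) grid points across fields"
        )
    return num / den


def component_fractions(counts: Iterable[FieldCount], over_raw: bool = False) -> dict:
    """Fractions for every component present.

    With ``over_raw`` the denominator is the raw point total, so fractions of
    *all* components (including empty space and outside the wall) sum to 1;
    otherwise tissue components are expressed over valid points and sum to 1.
    """
    counts = list(counts)
    if not counts:
        raise MissingDataError("needs at least one field")
    raw = sum(fc.n_points for fc in counts)
    valid = sum(fc.valid_points for fc in counts)
    out: dict = {}
    for comp in ALL_COMPONENTS:
        total = sum(fc.get(comp) for fc in counts)
        if total == 0:
            continue
        if over_raw:
            out[comp] = total / raw
        elif comp not in (EMPTY_SPACE, OUTSIDE_WALL):
            if valid <= 0:
                raise UndefinedVolumeFractionError("no valid grid points")
            out[comp] = total / valid
    return out


@dataclass(frozen=True)
class StabilizationResult:
    """Cumulative-mean stabilization diagnostic for a per-field series."""

    deviations: np.ndarray  # d_n = |cummean_n - mean_N| / mean_N
    threshold: float
    stable_n: int  # least n with d_m <= threshold for every m >= n


def stabilization_curve(
    per_field_values: Sequence[float], threshold: float = 0.05
) -> StabilizationResult:
    """Deviation of running means from the all-field mean.

    Used to decide how many fields must be counted: the curve ends at zero
    by construction, and ``stable_n`` is the first sample size from which
    the normalized deviation stays within ``threshold``.
    """
    values = np.asarray(per_field_values, dtype=float)
    if values.size < 1:
        raise MissingDataError("stabilization_curve needs at least one value")
    mean_all = values.mean()
    if mean_all == 0:
        raise ModelDomainError("series mean is zero; deviation undefined")
    cummeans = np.cumsum(values) / np.arange(1, values.size + 1)
    dev = np.abs(cummeans - mean_all) / abs(mean_all)
    ok = dev <= threshold
    # least n such that all m >= n satisfy the threshold
    stable = values.size
    for n in range(values.size, 0, -1):
        if ok[n - 1]:
            stable = n
        else:
            break
    return StabilizationResult(deviations=dev, threshold=threshold, stable_n=stable)


def _eligible(measurements: pd.DataFrame, stage, female_id) -> pd.DataFrame:
    token = _component_token(stage)
    m = measurements
    mask = (m["stage"].astype(str) == token) & m["through_nucleus"].astype(bool)
    if female_id is not None and "female_id" in m.columns:
        mask &= m["female_id"].astype(str) == str(female_id)
    return m.loc[mask]


def shape_factor(measurements: pd.DataFrame, stage, female_id=None) -> float:
    """Mean long/short axis ratio over through-nucleus oocytes of one stage."""
    sel = _eligible(measurements, stage, female_id)
    if sel.empty:
        warnings.warn(
            f"no through-nucleus oocytes for stage {stage} (female {female_id})",
            stacklevel=2,
        )
        return float("nan")
    k = sel["L_um"].to_numpy(float) / sel["S_um"].to_numpy(float)
    return float(k.mean())


def volume_based_diameter(measurements: pd.DataFrame, stage, female_id=None) -> float:
    """Cube root of the mean cubed arithmetic diameter (L+S)/2.

    Always at least the arithmetic mean diameter (power-mean inequality).
    """
    sel = _eligible(measurements, stage, female_id)
    if sel.empty:
        warnings.warn(
            f"no through-nucleus oocytes for stage {stage} (female {female_id})",
            stacklevel=2,
        )
        return float("nan")
    od = (sel["L_um"].to_numpy(float) + sel["S_um"].to_numpy(float)) / 2.0
    return float(np.cbrt(np.mean(od**3)))


@dataclass(frozen=True)
class ShrinkageModel:
    """Diameter rescaling between embedded and formalin-fixed dimensions.

    ``apply`` maps a diameter through the model.  The same class serves both
    directions: a shrink model (factor < 1) for simulation and a correction
    model (factor > 1) for analysis; ``inverse()`` swaps between the two.

    kinds:
      identity        -- returns input
      multiplicative  -- coefficients = (factor,)
      linear          -- coefficients = (intercept, slope)
    """

    kind: str = "identity"
    coefficients: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "multiplicative", "linear"):
            raise ValueError(f"unknown shrinkage model kind {self.kind!r}")
        if self.kind == "multiplicative" and len(self.coefficients) != 1:
            raise ValueError("multiplicative model needs one coefficient")
        if self.kind == "linear" and len(self.coefficients) != 2:
            raise ValueError("linear model needs (intercept, slope)")

    def apply(self, diameter_um: float):
        d = np.asarray(diameter_um, dtype=float)
        if np.any(d <= 0):
            raise ModelDomainError("diameter must be positive")
        if self.kind == "identity":
            out = d
        elif self.kind == "multiplicative":
            out = d * self.coefficients[0]
        else:
            a, b = self.coefficients
            out = a + b * d
        if np.any(out <= 0):
            raise ModelDomainError(
                f"shrinkage model {self.name or self.kind} produced a "
                "non-positive diameter"
            )
        return float(out) if np.isscalar(diameter_um) else out

    def inverse(self) -> "ShrinkageModel":
        if self.kind == "identity":
            return self
        if self.kind == "multiplicative":
            (f,) = self.coefficients
            return ShrinkageModel("multiplicative", (1.0 / f,), name=f"inv({self.name})")
        a, b = self.coefficients
        if b == 0:
            raise ModelDomainError("linear model with zero slope has no inverse")
        return ShrinkageModel("linear", (-a / b, 1.0 / b), name=f"inv({self.name})")


IDENTITY_SHRINKAGE = ShrinkageModel("identity", name="identity")


def correct_shrinkage(odv_um: float, model: ShrinkageModel) -> float:
    """Apply a shrinkage-correction model to a volume-based diameter."""
    if odv_um <= 0:
        raise ModelDomainError("ODv must be positive")
    return model.apply(odv_um)


def compare_correction_models(
    models: Sequence[ShrinkageModel],
    vto_inputs: pd.DataFrame,
    reference_bf: Mapping,
) -> pd.DataFrame:
    """Rank candidate shrinkage corrections against reference batch fecundity.

    ``vto_inputs`` holds one row per female with columns
    (female_id, Vv, k, ODv_um, rho, GWf_g) for the medium-late vitellogenic
    stage; ``reference_bf`` maps female_id to an independently observed batch
    fecundity.  For each model the corrected oocyte number is computed and the
    mean absolute relative deviation from the reference reported; the first
    row is the best model (ties keep input order).
    """
    from opdpipe.opd_engine import oocyte_number, opd

    if not models:
        raise MissingDataError("need at least one candidate model")
    ids = [fid for fid in vto_inputs["female_id"].astype(str) if fid in
           {str(k) for k in reference_bf}]
    if not ids:
        raise MissingDataError("no females with both corrected NO and reference BF")
    rows = []
    for rank_in, model in enumerate(models):
        devs = []
        for _, r in vto_inputs.iterrows():
            fid = str(r["female_id"])
            ref = {str(k): v for k, v in dict(reference_bf).items()}.get(fid)
            if ref is None:
                continue
            codv = correct_shrinkage(float(r["ODv_um"]), model)
            no = oocyte_number(
                opd(float(r["Vv"]), float(r["k"]), codv, float(r["rho"])),
                float(r["GWf_g"]),
            )
            devs.append(abs(no - ref) / ref)
        rows.append(
            {
                "model": model.name or model.kind,
                "input_order": rank_in,
                "mean_abs_rel_dev": float(np.mean(devs)),
                "n_females": len(devs),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_abs_rel_dev", "input_order"], kind="stable"
    )
    return out.reset_index(drop=True)


def select_grid(
    grid_sparse: GridSpec,
    grid_dense: GridSpec,
    estimates_sparse: Sequence[float],
    estimates_dense: Sequence[float],
    tolerance: float = 0.05,
) -> GridSpec:
    """Choose a grid from paired pilot estimates.

    If the mean absolute paired difference (relative to the dense-grid mean)
    exceeds ``tolerance``, the grids genuinely disagree and the denser,
    conservative option wins; otherwise the cheaper (sparser) grid is kept.
    """
    a = np.asarray(estimates_sparse, dtype=float)
    b = np.asarray(estimates_dense, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise MissingDataError("pilot estimates must be paired and non-empty")
    denser, sparser = (
        (grid_dense, grid_sparse)
        if grid_dense.n_points >= grid_sparse.n_points
        else (grid_sparse, grid_dense)
    )
    ref = np.abs(b).mean()
    if ref == 0:
        raise ModelDomainError("dense-grid estimates are all zero")
    rel_diff = np.abs(a - b).mean() / ref
    return denser if rel_diff > tolerance else sparser


def summarize_by_female(
    grid_counts: Sequence[FieldCount] | pd.DataFrame,
    measurements: pd.DataFrame,
    correction: ShrinkageModel = IDENTITY_SHRINKAGE,
    warn_identity: bool = True,
) -> pd.DataFrame:
    """Per female x stage stereology summary: Vv, k, ODv and corrected ODv.

    Grid counts may be FieldCount objects (carrying female_id) or the long
    table produced by :mod:`opdpipe.io_tables`.
    """
    if warn_identity and correction.kind == "identity":
        warnings.warn(
            "identity shrinkage correction in use: corrected diameters equal "
            "embedded diameters; supply measured correction coefficients for "
            "real data",
            stacklevel=2,
        )
    if isinstance(grid_counts, pd.DataFrame):
        from opdpipe.io_tables import field_counts_from_frame

        grid_counts = field_counts_from_frame(grid_counts)
    by_female: dict = {}
    for fc in grid_counts:
        by_female.setdefault(str(fc.female_id), []).append(fc)
    rows = []
    for fid, counts in by_female.items():
        stages_measured = set(
            measurements.loc[
                measurements["female_id"].astype(str) == fid, "stage"
            ].astype(str)
        )
        stages_counted = {
            comp for fc in counts for comp in fc.hits if comp in OocyteStage._value2member_map_
        }
        for stage in sorted(stages_measured | stages_counted, key=lambda s: OocyteStage(s).order):
            vv = volume_fraction(counts, stage)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k = shape_factor(measurements, stage, fid)
                odv = volume_based_diameter(measurements, stage, fid)
            codv = correct_shrinkage(odv, correction) if np.isfinite(odv) else float("nan")
            rows.append(
                {
                    "female_id": fid,
                    "stage": stage,
                    "Vv": vv,
                    "k": k,
                    "ODv_um": odv,
                    "cODv_um": codv,
                }
            )
    return pd.DataFrame(rows)
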