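"""Spawning phenology and batch/potential-fecundity accounting.

Phenology: monthly spawning fraction (actively spawning over mature
females) and assignment of each female to one of three spawning seasons,
with edge-of-season overrides for regenerating/regressing and
early-developing females.

Fecundity accounting: batch fecundity as the mean of the early- and
medium-late vitellogenic oocyte numbers; the potential batch count of a
stage as twice its oocyte number over batch fecundity (the factor two
encodes the mid-season assumption that half the batches are already shed);
batches accumulated backwards from the most advanced yolked stage; and
spawning duration from accumulated batches at a fixed spawning interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from opdpipe.errors import MissingDataError, ModelDomainError
from opdpipe.stages import (
    ACCUMULATION_ORDER,
    CUMULATIVE_LABELS,
    MATURE_PHASES,
    POOLED_PVO_LABEL,
    PVO_POOL,
    REPORT_PHASES,
    MaturityPhase,
    OocyteStage,
)

__all__ = [
    "SeasonCalendar",
    "DEFAULT_CALENDAR",
    "FecundityRow",
    "spawning_fraction",
    "assign_spawning_season",
    "batch_fecundity",
    "potential_batches",
    "accumulated_batches",
    "accumulate",
    "spawning_duration",
    "build_table1",
    "size_ratio_summary",
    "fecundity_vs_length",
    "pool_pvo123",
    "round_half_up",
]

#: Spawning-fraction plotting bands (percent): high, medium, low activity.
SPAWNING_FRACTION_BANDS = ((30.0, 50.0), (10.0, 30.0), (0.0, 10.0))

DEFAULT_INTERVAL_DAYS = 4.0
DEFAULT_MONTH_DAYS = 30.0
DEFAULT_TL_CLASSES = (40.0, 50.0, 60.0, 70.0, 80.0)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SeasonCalendar:
    """Month -> spawning-season mapping with cyclic-contiguous seasons."""

    month_to_season: Mapping[int, str]

    def __post_init__(self) -> None:
        mapping = dict(self.month_to_season)
        if set(mapping) != set(range(1, 13)):
            raise ValueError("calendar must map every month 1-12")
        object.__setattr__(self, "month_to_season", mapping)
        for season in self.seasons:
            months = [m for m in range(1, 13) if mapping[m] == season]
            if _cyclic_block(months) is None:
                raise ValueError(f"season {season} is not contiguous in cyclic order")

    @property
    def seasons(self) -> tuple:
        seen = []
        for m in range(1, 13):
            s = self.month_to_season[m]
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def season_of(self, month: int) -> str:
        return self.month_to_season[int(month)]

    def first_month(self, season: str) -> int:
        return _cyclic_block(
            [m for m in range(1, 13) if self.month_to_season[m] == season]
        )[0]

    def last_month(self, season: str) -> int:
        return _cyclic_block(
            [m for m in range(1, 13) if self.month_to_season[m] == season]
        )[-1]

    def preceding(self, season: str) -> str:
        order = self._cyclic_season_order()
        return order[(order.index(season) - 1) % len(order)]

    def following(self, season: str) -> str:
        order = self._cyclic_season_order()
        return order[(order.index(season) + 1) % len(order)]

    def _cyclic_season_order(self) -> list:
        order = []
        m = 1
        for _ in range(12):
            s = self.month_to_season[m]
            if s not in order:
                order.append(s)
            m = m % 12 + 1
        # rotate so order follows actual cyclic adjacency starting anywhere
        return order


def _cyclic_block(months: list[int]) -> list[int] | None:
    """Return months ordered first-to-last if cyclically contiguous, else None."""
    if not months:
        return None
    if len(months) == 12:
        return list(range(1, 13))
    month_set = set(months)
    starts = [m for m in months if (m - 2) % 12 + 1 not in month_set]
    if len(starts) != 1:
        return None
    out, m = [], starts[0]
    for _ in range(len(months)):
        if m not in month_set:
            return None
        out.append(m)
        m = m % 12 + 1
    return out


#: Default three-season calendar: winter-spring, summer, autumn.
DEFAULT_CALENDAR = SeasonCalendar(
    {12: "SS1", 1: "SS1", 2: "SS1", 3: "SS1", 4: "SS1", 5: "SS1",
     6: "SS2", 7: "SS2", 8: "SS2", 9: "SS3", 10: "SS3", 11: "SS3"}
)


def spawning_fraction(records: pd.DataFrame, month: int) -> float:
    """Proportion of actively spawning among sexually mature females in a month.

    Mature = every phase except immature.  Returns nan (with a warning) if
    the month has no mature females.
    """
    sel = records[records["month"].astype(int) == int(month)]
    mature = sel[sel["MAT"].astype(str) != MaturityPhase.IM.value]
    if mature.empty:
        warnings.warn(f"no mature females in month {month}", stacklevel=2)
        return float("nan")
    n_as = (mature["MAT"].astype(str) == MaturityPhase.AS.value).sum()
    return float(n_as / len(mature))


def assign_spawning_season(
    month: int,
    mat: str | MaturityPhase,
    has_spawning_markers: bool,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
) -> str:
    """Season label for one female, with edge-of-season overrides.

    Default is the capture month's season.  A regenerating or regressing
    female caught in the first month of a season is assumed to have spawned
    earlier and is assigned to the preceding season; a developing female
    without spawning markers caught in the last month of a season is assumed
    to spawn later and is assigned to the following season.  Both overrides
    wrap across the year boundary.
    """
    month = int(month)
    mat = MaturityPhase(str(mat))
    season = calendar.season_of(month)
    if mat in (MaturityPhase.RT, MaturityPhase.RS) and month == calendar.first_month(season):
        return calendar.preceding(season)
    if (
        mat is MaturityPhase.DV
        and not has_spawning_markers
        and month == calendar.last_month(season)
    ):
        return calendar.following(season)
    return season


def batch_fecundity(NO_EVTO: float, NO_VTO: float) -> float:
    """Batch fecundity: mean of early- and medium-late vitellogenic numbers."""
    if NO_EVTO < 0 or NO_VTO < 0:
        raise ModelDomainError("oocyte numbers must be non-negative")
    if NO_EVTO == 0 and NO_VTO == 0:
        raise ModelDomainError(
            "batch fecundity undefined: both vitellogenic numbers are zero"
        )
    return (NO_EVTO + NO_VTO) / 2.0


def potential_batches(NO_i: float, BF: float) -> float:
    """Unrounded potential batch count of one stage: 2 * NO_i / BF.

    The factor two assumes the typical female is mid-season and has already
    released half of her batches.
    """
    if BF <= 0:
        raise ModelDomainError("batch fecundity must be positive")
    if NO_i < 0:
        raise ModelDomainError("stage oocyte number must be non-negative")
    return 2.0 * NO_i / BF


def accumulated_batches(PF: float, BF: float) -> int:
    """Accumulated batch count from cumulative potential fecundity: round(PF/BF)."""
    if BF <= 0:
        raise ModelDomainError("batch fecundity must be positive")
    return round_half_up(PF / BF)


def spawning_duration(
    batches: float,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    month_days: float = DEFAULT_MONTH_DAYS,
    rounded: bool = True,
) -> float:
    """Spawning duration in months implied by a batch count.

    Duration is batches * interval / month length.  Report rounding: one
    decimal below ten months, nearest whole month from 9.95 upwards.
    """
    if batches < 0:
        raise ModelDomainError("batch count must be non-negative")
    months = batches * interval_days / month_days
    if not rounded:
        return months
    if months >= 9.95:
        return float(round_half_up(months))
    return float(f"{months:.1f}")


@dataclass(frozen=True)
class FecundityRow:
    """One cumulative-stage row of the fecundity report."""

    cumulative_label: str
    stage_token: str
    NO: float
    potential_fecundity: float  # 2 * cumulative NO, unrounded oocytes
    accumulated_batches: int
    duration_months: float
    duration_unrounded: float


def pool_pvo123(stage_nos: Mapping[str, float]) -> dict:
    """Pool PVO1, PVO2 and PVO3 numbers into a single PVO1-3 entry."""
    out = {}
    pooled = 0.0
    pool_tokens = {s.value for s in PVO_POOL}
    seen_pool = False
    for tok, value in stage_nos.items():
        tok = str(tok)
        if tok in pool_tokens:
            pooled += float(value)
            seen_pool = True
        else:
            out[tok] = float(value)
    if seen_pool:
        out[POOLED_PVO_LABEL] = out.get(POOLED_PVO_LABEL, 0.0) + pooled
    return out


def accumulate(
    stage_NOs: Mapping[str, float],
    BF: float,
    order: Sequence[str] = ACCUMULATION_ORDER,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    month_days: float = DEFAULT_MONTH_DAYS,
) -> list[FecundityRow]:
    """Cumulative fecundity rows from the most advanced yolked stage backwards.

    ``stage_NOs`` maps stage tokens (with PVO1-3 already pooled, or the raw
    PVO1/2/3 which are pooled here) to oocyte numbers.  Potential fecundity
    at row m is twice the cumulative oocyte number; the accumulated batch
    count is rounded once at the cumulative level.  Migratory-nucleus and
    hydrated oocytes never enter the accumulation.
    """
    if BF <= 0:
        raise ModelDomainError("batch fecundity must be positive")
    nos = pool_pvo123({str(k): float(v) for k, v in stage_NOs.items()})
    excluded = {OocyteStage.MNO.value, OocyteStage.HYO.value}
    ignored = set(nos) - set(order) - excluded
    if ignored:
        warnings.warn(
            f"stages not in accumulation order ignored: {sorted(ignored)}",
            stacklevel=2,
        )
    rows = []
    cum_no = 0.0
    labels = dict(zip(ACCUMULATION_ORDER, CUMULATIVE_LABELS))
    for tok in order:
        if tok in excluded:
            continue
        if tok not in nos:
            warnings.warn(f"stage {tok} missing; treated as 0", stacklevel=2)
        no_i = nos.get(tok, 0.0)
        cum_no += no_i
        pf = 2.0 * cum_no
        batches = accumulated_batches(pf, BF)
        rows.append(
            FecundityRow(
                cumulative_label=labels.get(tok, f"+{tok}"),
                stage_token=tok,
                NO=no_i,
                potential_fecundity=pf,
                accumulated_batches=batches,
                duration_months=spawning_duration(batches, interval_days, month_days),
                duration_unrounded=spawning_duration(
                    batches, interval_days, month_days, rounded=False
                ),
            )
        )
    return rows


def build_table1(
    records: pd.DataFrame,
    calendar: SeasonCalendar = DEFAULT_CALENDAR,
    tl_class_boundaries: Sequence[float] = DEFAULT_TL_CLASSES,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    month_days: float = DEFAULT_MONTH_DAYS,
) -> pd.DataFrame:
    """Fecundity report per length class x season x cumulative stage.

    ``records`` holds one row per female with columns month, MAT, TL_cm,
    POF_present and per-stage oocyte numbers ``NO_<STAGE>`` (unpooled PVO1/2/3
    allowed).  Only developing, spawning-capable and actively-spawning
    females enter.  Cells without data are emitted as missing (dashes on
    write).  Potential fecundity is reported in thousands of oocytes.
    """
    from opdpipe.standardization import length_class_split

    needed = {"month", "MAT", "TL_cm"}
    if not needed.issubset(records.columns):
        raise MissingDataError(f"records need columns {sorted(needed)}")
    no_cols = [c for c in records.columns if c.startswith("NO_")]
    if not no_cols:
        raise MissingDataError("records need per-stage NO_<STAGE> columns")
    data = records[records["MAT"].astype(str).isin({p.value for p in REPORT_PHASES})].copy()
    pof = data["POF_present"] if "POF_present" in data.columns else False
    data["season"] = [
        assign_spawning_season(m, mat, bool(p), calendar)
        for m, mat, p in zip(
            data["month"], data["MAT"], pof if hasattr(pof, "__iter__") else [False] * len(data)
        )
    ]
    data = length_class_split(data, tl_class_boundaries)
    data = data[data["tl_class"] != "OUT_OF_RANGE"]
    classes = [
        f"{b1:g}-{b2:g}"
        for b1, b2 in zip(tl_class_boundaries, tl_class_boundaries[1:])
    ]
    out_rows = []
    for tl_class in classes:
        for season in calendar.seasons:
            cell = data[(data["tl_class"] == tl_class) & (data["season"] == season)]
            if cell.empty:
                for label in CUMULATIVE_LABELS:
                    out_rows.append(
                        {
                            "tl_class": tl_class,
                            "season": season,
                            "cumulative_stage": label,
                            "n_females": 0,
                            "BF_thousands": np.nan,
                            "PF_thousands": np.nan,
                            "accumulated_batches": np.nan,
                            "duration_months": np.nan,
                        }
                    )
                continue
            mean_no = {c.removeprefix("NO_"): float(cell[c].mean()) for c in no_cols}
            bf = batch_fecundity(
                mean_no.get(OocyteStage.EVTO.value, 0.0),
                mean_no.get(OocyteStage.VTO.value, 0.0),
            )
            rows = accumulate(
                mean_no, bf, interval_days=interval_days, month_days=month_days
            )
            for row in rows:
                out_rows.append(
                    {
                        "tl_class": tl_class,
                        "season": season,
                        "cumulative_stage": row.cumulative_label,
                        "n_females": len(cell),
                        "BF_thousands": bf / 1e3,
                        "PF_thousands": row.potential_fecundity / 1e3,
                        "accumulated_batches": float(row.accumulated_batches),
                        "duration_months": row.duration_months,
                    }
                )
    return pd.DataFrame(out_rows)


def size_ratio_summary(
    report: pd.DataFrame, class_a: str, class_b: str, cumulative_stage: str
) -> float:
    """Ratio of season-averaged potential fecundity, class_a over class_b."""
    sel = report[report["cumulative_stage"] == cumulative_stage]
    a = sel[sel["tl_class"] == class_a]["PF_thousands"].dropna()
    b = sel[sel["tl_class"] == class_b]["PF_thousands"].dropna()
    if a.empty or b.empty:
        raise MissingDataError(
            f"class {class_a if a.empty else class_b} has no data at "
            f"{cumulative_stage}"
        )
    return float(a.mean() / b.mean())


def fecundity_vs_length(
    per_female: pd.DataFrame,
    no_column: str = "NO_sum",
) -> dict:
    """Regress a per-female oocyte-number sum on total length with a season factor.

    Returns slope, its p-value and the season-factor F test.  Needs columns
    (TL_cm, season, ``no_column``).
    """
    needed = {no_column, "TL_cm", "season"}
    if not needed.issubset(per_female.columns):
        raise MissingDataError(f"need columns {sorted(needed)}")
    data = per_female[[no_column, "TL_cm", "season"]].dropna()
    if data["TL_cm"].nunique() < 3:
        raise MissingDataError("need at least three distinct lengths")
    data = data.rename(columns={no_column: "NO"})
    full = smf.ols("NO ~ TL_cm + C(season)", data=data).fit()
    no_season = smf.ols("NO ~ TL_cm", data=data).fit()
    from statsmodels.stats.anova import anova_lm

    if data["season"].nunique() > 1:
        cmp_tbl = anova_lm(no_season, full)
        season_f = float(cmp_tbl["F"].iloc[1])
        season_p = float(cmp_tbl["Pr(>F)"].iloc[1])
    else:
        season_f, season_p = float("nan"), float("nan")
    return {
        "slope": float(full.params["TL_cm"]),
        "slope_p": float(full.pvalues["TL_cm"]),
        "season_f": season_f,
        "season_p": season_p,
        "n": len(data),
    }
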