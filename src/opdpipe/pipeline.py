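"""End-to-end pipeline orchestration and run manifests.

A :class:`PipelineConfig` fixes every tunable (grid, shrinkage correction,
formula constant mode, season calendar, spawning interval, length classes,
sample-size minima, master seed).  :func:`run_pipeline` generates synthetic
input tables (or consumes user-supplied ones), runs stereology, packing
density, standardization and the fecundity report, and writes a manifest
sufficient to reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from opdpipe import __version__
from opdpipe.dynamics import (
    DEFAULT_CALENDAR,
    SeasonCalendar,
    build_table1,
    spawning_fraction,
)
from opdpipe.errors import MissingDataError
from opdpipe.io_tables import (
    file_digest,
    frame_from_field_counts,
    read_females,
    read_grid_counts,
    read_measurements,
    write_females,
    write_grid_counts,
    write_measurements,
)
from opdpipe.opd_engine import StageDensityInput, stage_table
from opdpipe.stages import OocyteStage, REPORT_PHASES
from opdpipe.stereology import (
    GRID_A,
    GRID_B,
    GridSpec,
    ShrinkageModel,
    summarize_by_female,
)
from opdpipe.standardization import (
    ew_based_no,
    fit_gw_model,
    fit_length_weight_power,
    tl_based_no,
)
from opdpipe.synthetic import (
    SectionFieldSpec,
    child_seeds,
    count_grid_hits,
    default_stage_specs,
    render_fields,
    simulate_cohort,
    simulate_measurements,
    simulate_population,
    CohortSpec,
    allometry_noise_for_r2,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_tables"]

_GRIDS = {"A": GRID_A, "B": GRID_B}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run depends on, serializable to YAML."""

    master_seed: int = 0
    n_females: int = 157
    n_opd_females: int = 8
    grid: str = "B"
    n_fields: int = 7
    field_width_um: float = 600.0
    field_height_um: float = 600.0
    slab_thickness_um: float = 4.0
    field_heterogeneity_cv: float = 0.05
    shrinkage_kind: str = "identity"  # correction model (analysis direction)
    shrinkage_coefficients: tuple = ()
    constant_mode: str = "printed"
    season_calendar: dict = field(
        default_factory=lambda: dict(DEFAULT_CALENDAR.month_to_season)
    )
    interval_days: float = 4.0
    month_days: float = 30.0
    tl_classes: tuple = (40.0, 50.0, 60.0, 70.0, 80.0)
    min_oocytes_per_stage: int = 10
    min_fields: int = 7
    n_measure_per_stage: int = 10
    population_sample_mass_g: float = 0.02

    def correction_model(self) -> ShrinkageModel:
        return ShrinkageModel(
            self.shrinkage_kind, tuple(self.shrinkage_coefficients), name="correction"
        )

    def grid_spec(self) -> GridSpec:
        return _GRIDS[self.grid]

    def calendar(self) -> SeasonCalendar:
        return SeasonCalendar({int(k): v for k, v in self.season_calendar.items()})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self._as_plain_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("shrinkage_coefficients", "tl_classes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def _as_plain_dict(self) -> dict:
        d = asdict(self)
        d["shrinkage_coefficients"] = list(d["shrinkage_coefficients"])
        d["tl_classes"] = list(d["tl_classes"])
        return d

    def digest(self) -> str:
        canon = json.dumps(self._as_plain_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def simulate_tables(config: PipelineConfig, outdir) -> dict:
    """Generate the three synthetic input tables and write them as CSV.

    Seed fan-out (documented order): child 0 -> cohort, child 1 -> per-female
    simulation streams for the packing-density subsample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.master_seed, 2)
    cohort_seed = int(seeds[0].generate_state(1)[0])
    cohort = simulate_cohort(
        CohortSpec(
            n_females=config.n_females,
            allometry_noise_sd=allometry_noise_for_r2((34.0, 84.0), 3.01, 0.96),
            season_calendar=config.season_calendar,
            seed=cohort_seed,
        )
    )
    # packing-density subsample: analysable phases, no hydrated-only ovaries
    eligible = cohort[
        cohort["MAT"].isin({p.value for p in REPORT_PHASES})
        & (cohort["MAO"] != OocyteStage.HYO.value)
    ].sort_values("female_id")
    subsample = eligible.head(config.n_opd_females)
    if len(subsample) < config.n_opd_females:
        warnings.warn(
            f"only {len(subsample)} eligible females for the packing-density "
            f"subsample (requested {config.n_opd_females})"
        )
    field_spec = SectionFieldSpec(
        field_width_um=config.field_width_um,
        field_height_um=config.field_height_um,
        slab_thickness_um=config.slab_thickness_um,
        n_fields=config.n_fields,
        field_heterogeneity_cv=config.field_heterogeneity_cv,
    )
    shrink_model = config.correction_model().inverse()  # simulation direction
    grid = config.grid_spec()
    all_counts, all_measurements = [], []
    per_female_seeds = seeds[1].spawn(len(subsample))
    from opdpipe.opd_engine import specific_gravity

    for (_, female), fseed in zip(subsample.iterrows(), per_female_seeds):
        opds = {
            c.removeprefix("opd_"): float(female[c])
            for c in cohort.columns
            if c.startswith("opd_") and float(female[c]) > 0
        }
        specs = default_stage_specs(opds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = specific_gravity(female["MAO"])
        s_pop, s_fields, s_grid, s_meas = (
            int(s.generate_state(1)[0]) for s in fseed.spawn(4)
        )
        population = simulate_population(
            specs, config.population_sample_mass_g, rho, seed=s_pop
        )
        fields = render_fields(population, field_spec, seed=s_fields)
        for i, fld in enumerate(fields):
            all_counts.append(
                count_grid_hits(
                    fld, grid, seed=s_grid + i, female_id=str(female["female_id"])
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meas = simulate_measurements(
                population,
                n_per_stage=config.n_measure_per_stage,
                shrinkage_model=shrink_model,
                seed=s_meas,
                female_id=str(female["female_id"]),
            )
        all_measurements.append(meas)
    measurements = (
        pd.concat(all_measurements, ignore_index=True)
        if all_measurements
        else pd.DataFrame(columns=["female_id", "stage", "L_um", "S_um", "through_nucleus"])
    )
    paths = {
        "females": write_females(cohort, outdir / "females.csv"),
        "grid_counts": write_grid_counts(
            frame_from_field_counts(all_counts), outdir / "grid_counts.csv"
        ),
        "measurements": write_measurements(measurements, outdir / "measurements.csv"),
    }
    return paths


def run_pipeline(config: PipelineConfig, outdir, input_dir=None) -> dict:
    """Run the full pipeline; synthetic inputs are generated unless given.

    Outputs (all CSV unless noted): females.csv, grid_counts.csv,
    measurements.csv, stage_densities.csv, standardized.csv,
    spawning_fraction.csv, report_table1.csv, report_unrounded.csv and
    manifest.txt (key=value).  Deterministic under a fixed master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if input_dir is None:
        paths = simulate_tables(config, outdir)
    else:
        input_dir = Path(input_dir)
        paths = {
            "females": input_dir / "females.csv",
            "grid_counts": input_dir / "grid_counts.csv",
            "measurements": input_dir / "measurements.csv",
        }
    females = read_females(paths["females"]).frame
    grid_counts = read_grid_counts(paths["grid_counts"]).frame
    measurements = read_measurements(paths["measurements"]).frame

    # stereology ------------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = summarize_by_female(
            grid_counts, measurements, correction=config.correction_model(),
            warn_identity=False,
        )
    if summary.empty:
        raise MissingDataError("no grid counts to summarize")

    # packing density and oocyte numbers ------------------------------------
    meta = females.set_index(females["female_id"].astype(str))
    density_frames = []
    for fid, grp in summary.groupby("female_id"):
        if fid not in meta.index:
            raise MissingDataError(f"grid counts for unknown female {fid}")
        rec = meta.loc[fid]
        usable = grp[np.isfinite(grp["k"]) | (grp["stage"] == OocyteStage.HYO.value)]
        inputs = [
            StageDensityInput(
                stage=OocyteStage(str(r["stage"])),
                Vv=float(r["Vv"]),
                k=float(r["k"]) if np.isfinite(r["k"]) else 1.0,
                cODv_um=float(r["cODv_um"]) if np.isfinite(r["cODv_um"]) else 1.0,
            )
            for _, r in usable.iterrows()
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl = stage_table(
                inputs, rec["MAO"], float(rec["GWf_g"]),
                constant_mode=config.constant_mode,
            )
        tbl.insert(0, "female_id", fid)
        density_frames.append(tbl)
    densities = pd.concat(density_frames, ignore_index=True)
    densities.to_csv(outdir / "stage_densities.csv", index=False)

    # standardization -------------------------------------------------------
    has_ew = females["EW_g"].notna()
    allometry = None
    if has_ew.sum() >= 3:
        allometry = fit_length_weight_power(
            females.loc[has_ew, "TL_cm"], females.loc[has_ew, "EW_g"]
        )
    gw_fit = None
    try:
        gw_fit = fit_gw_model(females)
    except MissingDataError:
        pass
    std = densities.merge(
        females[["female_id", "month", "TL_cm", "EW_g", "GWf_g", "MAT", "POF_present"]],
        on="female_id",
    )
    std["NO_tl_based"] = tl_based_no(std["NO"], std["TL_cm"])
    std["NO_ew_based"] = ew_based_no(std["NO"], std["EW_g"])
    if gw_fit is not None:
        pgwf = np.array(
            [gw_fit.predict(m, t) for m, t in zip(std["MAT"], std["TL_cm"])]
        )
        valid = pgwf > 0
        std["pNO"] = np.where(valid, std["OPD"].to_numpy() * pgwf, np.nan)
    std.to_csv(outdir / "standardized.csv", index=False)

    # phenology -------------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sf = pd.DataFrame(
            {
                "month": range(1, 13),
                "spawning_fraction": [
                    spawning_fraction(females, m) for m in range(1, 13)
                ],
            }
        )
    sf.to_csv(outdir / "spawning_fraction.csv", index=False)

    # fecundity report ------------------------------------------------------
    wide = (
        std.pivot_table(index="female_id", columns="stage", values="NO", aggfunc="first")
        .rename(columns=lambda s: f"NO_{s}")
        .reset_index()
    )
    wide = wide.merge(
        females[["female_id", "month", "TL_cm", "MAT", "POF_present"]], on="female_id"
    )
    no_cols = [c for c in wide.columns if c.startswith("NO_")]
    wide[no_cols] = wide[no_cols].fillna(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = build_table1(
            wide,
            calendar=config.calendar(),
            tl_class_boundaries=config.tl_classes,
            interval_days=config.interval_days,
            month_days=config.month_days,
        )
    rounded = report.copy()
    rounded["BF_thousands"] = rounded["BF_thousands"].round(0)
    rounded["PF_thousands"] = rounded["PF_thousands"].round(0)
    rounded.to_csv(outdir / "report_table1.csv", index=False)
    report.to_csv(outdir / "report_unrounded.csv", index=False)

    # manifest --------------------------------------------------------------
    outputs = [
        "females.csv", "grid_counts.csv", "measurements.csv",
        "stage_densities.csv", "standardized.csv", "spawning_fraction.csv",
        "report_table1.csv", "report_unrounded.csv",
    ]
    lines = [
        f"opdpipe_version={__version__}",
        f"master_seed={config.master_seed}",
        f"config_sha256={config.digest()}",
        f"constant_mode={config.constant_mode}",
    ]
    if allometry is not None:
        lines.append(f"allometry_b={allometry.b:.6f}")
        lines.append(f"allometry_r2={allometry.r2:.6f}")
    if gw_fit is not None:
        lines.append(f"gw_model_adj_r2={gw_fit.adj_r2:.6f}")
    for name in outputs:
        p = outdir / name
        if p.exists():
            lines.append(f"sha256:{name}={file_digest(p)}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return {
        "outdir": outdir,
        "densities": densities,
        "standardized": std,
        "report": report,
        "allometry": allometry,
        "gw_fit": gw_fit,
        "manifest": outdir / "manifest.txt",
    }
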