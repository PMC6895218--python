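"""Seeded synthetic ovaries: populations, sectioned fields, cohorts.

Ground truth for every downstream estimator.  Oocytes are generated with
known per-stage packing density, diameter and shape-factor distributions;
virtual histological fields are produced by packing volume-equivalent
spheres without overlap (random sequential adsorption) into a slab around
the section plane and cutting them, so the expected per-field area fraction
of each stage equals its true volume fraction.  Shape factors enter the
emitted axis measurements analytically (L = k*S), not the 3D placement.

Every stochastic operation takes an explicit integer seed; a master seed
fans out to per-operation seeds through :func:`child_seeds`
(numpy ``SeedSequence.spawn`` in documented call order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from opdpipe.errors import InfeasiblePackingError
from opdpipe.stages import TISSUE, MaturityPhase, OocyteStage
from opdpipe.stereology import (
    FieldCount,
    GridSpec,
    IDENTITY_SHRINKAGE,
    ShrinkageModel,
)

__all__ = [
    "MAX_PACKING_FRACTION",
    "StagePopulationSpec",
    "SectionFieldSpec",
    "CohortSpec",
    "Population",
    "Field",
    "child_seeds",
    "simulate_population",
    "render_fields",
    "count_grid_hits",
    "simulate_measurements",
    "simulate_cohort",
    "default_stage_specs",
    "default_cohort_spec",
    "allometry_noise_for_r2",
]

#: Hard cap on the total oocyte volume fraction the generator accepts.
#: Above this the non-overlap placement cannot succeed.
MAX_PACKING_FRACTION = 0.55


def child_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Documented seed-splitting rule: ``SeedSequence(master).spawn(n)``."""
    return np.random.SeedSequence(master_seed).spawn(n)


@dataclass(frozen=True)
class StagePopulationSpec:
    """True parameters of one oocyte stage in a synthetic ovary."""

    stage: OocyteStage
    true_opd: float  # oocytes per gram of ovary
    diameter_mean_um: float
    diameter_cv: float = 0.0
    shape_factor_mean: float = 1.0
    shape_factor_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.true_opd <= 0:
            raise ValueError("true_opd must be positive")
        if self.diameter_mean_um <= 0:
            raise ValueError("diameter_mean_um must be positive")
        if self.diameter_cv < 0 or self.shape_factor_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.shape_factor_mean < 1.0:
            raise ValueError("shape_factor_mean must be >= 1")


@dataclass(frozen=True)
class SectionFieldSpec:
    """Geometry of the virtual micrograph fields."""

    field_width_um: float = 600.0
    field_height_um: float = 600.0
    slab_thickness_um: float = 4.0
    n_fields: int = 10
    field_heterogeneity_cv: float = 0.0

    def __post_init__(self) -> None:
        if min(self.field_width_um, self.field_height_um, self.slab_thickness_um) <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_fields < 1:
            raise ValueError("need at least one field")
        if self.field_heterogeneity_cv < 0:
            raise ValueError("field_heterogeneity_cv must be >= 0")


@dataclass
class Population:
    """A generated oocyte population with exact ground truth."""

    oocytes: pd.DataFrame  # stage, od_um, k, s_um, l_um, volume_um3, radius_um
    counts: dict  # stage token -> exact count
    vv: dict  # stage token -> exact volume fraction
    ovary_mass_g: float
    specific_gravity: float

    @property
    def ovary_volume_um3(self) -> float:
        return self.ovary_mass_g / self.specific_gravity * 1e12

    @property
    def total_packing_fraction(self) -> float:
        return float(sum(self.vv.values()))

    def number_density_per_um3(self, stage_token: str) -> float:
        return self.counts[stage_token] / self.ovary_volume_um3


@dataclass
class Field:
    """One planar section field with its elliptical (circular) profiles."""

    field_id: str
    width_um: float
    height_um: float
    profiles: pd.DataFrame  # x_um, y_um, r_um, parent_r_um, stage


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _draw_diameters(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    mu, sigma = _lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size=n)


def _draw_shape_factors(rng, mean: float, cv: float, n: int) -> np.ndarray:
    """k >= 1 via a shifted gamma on the excess over 1."""
    excess = mean - 1.0
    if excess <= 0 or cv == 0:
        return np.full(n, max(mean, 1.0))
    sd = cv * mean
    shape = (excess / sd) ** 2
    scale = sd * sd / excess
    return 1.0 + rng.gamma(shape, scale, size=n)


def simulate_population(
    specs: Sequence[StagePopulationSpec],
    ovary_mass_g: float,
    specific_gravity: float,
    seed: int,
) -> Population:
    """Generate an oocyte population with exact per-stage counts and Vv.

    Per-stage count is ``round(true_opd * ovary_mass)`` exactly; the exact
    volume fraction is the summed oocyte volume (prolate spheroid,
    V = pi/6 * k * S^3) over the ovary volume.  Raises
    :class:`InfeasiblePackingError` when the total packing fraction exceeds
    ``MAX_PACKING_FRACTION``.
    """
    if ovary_mass_g <= 0 or specific_gravity <= 0:
        raise ValueError("ovary mass and specific gravity must be positive")
    seen = set()
    for spec in specs:
        if spec.stage in seen:
            raise ValueError(f"duplicate spec for stage {spec.stage}")
        seen.add(spec.stage)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ovary_volume_um3 = ovary_mass_g / specific_gravity * 1e12
    frames, counts, vv = [], {}, {}
    for spec in specs:
        n = int(round(spec.true_opd * ovary_mass_g))
        counts[spec.stage.value] = n
        if n == 0:
            vv[spec.stage.value] = 0.0
            continue
        od = _draw_diameters(rng, spec.diameter_mean_um, spec.diameter_cv, n)
        k = _draw_shape_factors(rng, spec.shape_factor_mean, spec.shape_factor_cv, n)
        s = 2.0 * od / (1.0 + k)
        volume = np.pi / 6.0 * k * s**3
        frames.append(
            pd.DataFrame(
                {
                    "stage": spec.stage.value,
                    "od_um": od,
                    "k": k,
                    "s_um": s,
                    "l_um": k * s,
                    "volume_um3": volume,
                    "radius_um": np.cbrt(3.0 * volume / (4.0 * np.pi)),
                }
            )
        )
        vv[spec.stage.value] = float(volume.sum() / ovary_volume_um3)
    oocytes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["stage", "od_um", "k", "s_um", "l_um", "volume_um3", "radius_um"]
        )
    )
    pop = Population(
        oocytes=oocytes,
        counts=counts,
        vv=vv,
        ovary_mass_g=ovary_mass_g,
        specific_gravity=specific_gravity,
    )
    if pop.total_packing_fraction > MAX_PACKING_FRACTION:
        raise InfeasiblePackingError(
            f"total packing fraction {pop.total_packing_fraction:.3f} exceeds "
            f"the geometric cap {MAX_PACKING_FRACTION}"
        )
    return pop


def _pbc_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement a - b under periodic boundaries."""
    d = a - b
    return d - box * np.round(d / box)


def _conflicts_dense(
    cand: np.ndarray,
    cand_r: np.ndarray,
    placed_pos: np.ndarray,
    placed_r: np.ndarray,
    box: np.ndarray,
    chunk_cells: int = 4_000_000,
) -> np.ndarray:
    """Boolean mask: candidate overlaps any placed sphere (minimum image)."""
    m = len(cand)
    p = len(placed_r)
    if p == 0 or m == 0:
        return np.zeros(m, dtype=bool)
    out = np.empty(m, dtype=bool)
    step = max(1, chunk_cells // p)
    for start in range(0, m, step):
        sl = slice(start, min(start + step, m))
        d = cand[sl, None, :] - placed_pos[None, :, :]
        d -= box * np.round(d / box)
        d2 = np.einsum("ijk,ijk->ij", d, d)
        lim = (cand_r[sl, None] + placed_r[None, :]) ** 2
        out[sl] = (d2 < lim).any(axis=1)
    return out


def _conflicts(
    cand: np.ndarray,
    cand_r: np.ndarray,
    placed_pos: np.ndarray,
    placed_r: np.ndarray,
    box: np.ndarray,
    tree: cKDTree | None = None,
    k_neighbors: int = 12,
) -> np.ndarray:
    """Conflict mask, choosing dense or k-nearest-neighbour strategy.

    The KNN path checks each candidate only against its nearest placed
    centres; whenever the k-th neighbour could still conflict (rare), those
    rows fall back to the dense check.
    """
    m = len(cand)
    p = len(placed_r)
    if p == 0 or m == 0:
        return np.zeros(m, dtype=bool)
    if p <= 32 or m * p <= 250_000:
        return _conflicts_dense(cand, cand_r, placed_pos, placed_r, box)
    if tree is None:
        tree = cKDTree(placed_pos, boxsize=box)
    k = min(k_neighbors, p)
    dist, idx = tree.query(cand, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    conflict = (dist < cand_r[:, None] + placed_r[idx]).any(axis=1)
    if k < p:
        unsure = (~conflict) & (dist[:, -1] <= cand_r + placed_r.max())
        if unsure.any():
            rows = np.flatnonzero(unsure)
            conflict[rows] = _conflicts_dense(
                cand[rows], cand_r[rows], placed_pos, placed_r, box
            )
    return conflict


def _rsa_pack(
    radii: np.ndarray,
    box: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 4000,
) -> np.ndarray:
    """Random sequential adsorption of hard spheres in a periodic box.

    Periodic boundaries keep the ensemble exactly translation invariant, so
    any cut plane sees the global volume fraction in expectation (a walled
    box develops boundary layers that deplete its interior at moderate
    packing).  Spheres are placed strictly largest-first in blocks of
    similar size: filling small spheres before large ones would block the
    large ones entirely in polydisperse mixtures.  Within a block, each
    round proposes one uniform candidate per unplaced sphere and rejects
    overlaps; stragglers get large candidate batches one at a time.
    """
    n = radii.size
    if n == 0:
        return np.empty((0, 3))
    if np.any(4.0 * radii.max() >= box.min()):
        raise InfeasiblePackingError(
            "box too small relative to the largest sphere for periodic packing"
        )
    order = np.argsort(radii)[::-1]
    radii_sorted = radii[order]
    pos_sorted = np.full((n, 3), np.nan)
    placed_pos = np.empty((0, 3))
    placed_r = np.empty(0)
    block_size = 64
    for start in range(0, n, block_size):
        remaining = np.arange(start, min(start + block_size, n))
        stalled = 0
        for _ in range(max_rounds):
            if remaining.size == 0:
                break
            if remaining.size <= 8 or stalled >= 4:
                placed_pos, placed_r, failed = _rsa_finish(
                    radii_sorted, remaining, pos_sorted, placed_pos, placed_r,
                    box, rng,
                )
                remaining = failed
                break
            rr = radii_sorted[remaining]
            cand = rng.uniform(0.0, box, size=(remaining.size, 3))
            bad = _conflicts(cand, rr, placed_pos, placed_r, box)
            surv = np.flatnonzero(~bad)
            if surv.size:
                csub = cand[surv]
                rsub = rr[surv]
                keep_local = _greedy_mutual(csub, rsub, box)
                accepted_idx = remaining[surv[keep_local]]
                pos_sorted[accepted_idx] = csub[keep_local]
                placed_pos = np.vstack([placed_pos, csub[keep_local]])
                placed_r = np.concatenate([placed_r, rsub[keep_local]])
                mask = np.ones(remaining.size, dtype=bool)
                mask[surv[keep_local]] = False
                remaining = remaining[mask]
                stalled = 0 if keep_local.size else stalled + 1
            else:
                stalled += 1
        if remaining.size:
            raise InfeasiblePackingError(
                f"could not place {remaining.size} of {n} spheres; "
                "packing too dense for non-overlap placement"
            )
    out = np.empty_like(pos_sorted)
    out[order] = pos_sorted
    return out


def _greedy_mutual(cand: np.ndarray, cand_r: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Indices of a greedy non-overlapping subset (first come, first kept)."""
    m = len(cand)
    if m == 1:
        return np.array([0])
    if m > 1200:  # dense m x m matrix too large; use a periodic KD-tree
        tree = cKDTree(cand, boxsize=box)
        pairs = tree.query_pairs(r=2.0 * cand_r.max(), output_type="ndarray")
        kept = np.ones(m, dtype=bool)
        if pairs.size:
            delta = _pbc_delta(cand[pairs[:, 0]], cand[pairs[:, 1]], box)
            d2p = np.einsum("ij,ij->i", delta, delta)
            conflicted = pairs[d2p < (cand_r[pairs[:, 0]] + cand_r[pairs[:, 1]]) ** 2]
            order = np.lexsort((conflicted[:, 1], conflicted[:, 0]))
            for i, j in conflicted[order]:
                a, b = (i, j) if i < j else (j, i)
                if kept[a]:
                    kept[b] = False
        return np.flatnonzero(kept)
    d = cand[:, None, :] - cand[None, :, :]
    d -= box * np.round(d / box)
    d2 = np.einsum("ijk,ijk->ij", d, d)
    conflict = d2 < (cand_r[:, None] + cand_r[None, :]) ** 2
    np.fill_diagonal(conflict, False)
    kept = np.zeros(m, dtype=bool)
    for i in range(m):
        if not conflict[i, kept].any():
            kept[i] = True
    return np.flatnonzero(kept)


def _rsa_finish(
    radii_sorted, remaining, pos_sorted, placed_pos, placed_r, box, rng,
    chunk: int = 256, max_chunks: int = 24,
):
    """Place the last spheres one at a time with growing candidate batches."""
    failed = []
    for idx in remaining:
        r_i = radii_sorted[idx]
        placed_here = False
        tree = cKDTree(placed_pos, boxsize=box) if len(placed_r) else None
        size = chunk
        for _ in range(max_chunks):
            cand = rng.uniform(0.0, box, size=(size, 3))
            bad = _conflicts(
                cand, np.full(size, r_i), placed_pos, placed_r, box, tree=tree
            )
            good = np.flatnonzero(~bad)
            if good.size:
                choice = cand[good[0]]
                pos_sorted[idx] = choice
                placed_pos = np.vstack([placed_pos, choice[None, :]])
                placed_r = np.concatenate([placed_r, [r_i]])
                placed_here = True
                break
            size = min(size * 2, 32768)
        if not placed_here:
            failed.append(idx)
    return placed_pos, placed_r, np.asarray(failed, dtype=int)


def render_fields(
    population: Population,
    field_spec: SectionFieldSpec,
    seed: int,
    max_rounds: int = 4000,
) -> list[Field]:
    """Planar section fields cut through non-overlapping sphere packings.

    Each field gets its own slab; local stage densities match the
    population's global number densities, optionally modulated by a
    lognormal between-field heterogeneity factor.  A sphere of radius R cut
    at distance d from its centre yields a circular profile of radius
    sqrt(R^2 - d^2).
    """
    if population.oocytes.empty:
        return [
            Field(
                field_id=f"F{i + 1}",
                width_um=field_spec.field_width_um,
                height_um=field_spec.field_height_um,
                profiles=_empty_profiles(),
            )
            for i in range(field_spec.n_fields)
        ]
    rngs = [np.random.default_rng(s) for s in child_seeds(seed, field_spec.n_fields)]
    w, h = field_spec.field_width_um, field_spec.field_height_um
    r_max = float(population.oocytes["radius_um"].max())
    # Periodic box: must exceed four largest radii in every dimension for
    # minimum-image overlap checks; the xy margin lets profiles overhang the
    # field edges naturally via wrapped images.
    box = np.array(
        [
            max(w + 2.0 * r_max, 4.2 * r_max),
            max(h + 2.0 * r_max, 4.2 * r_max),
            4.2 * r_max + field_spec.slab_thickness_um,
        ]
    )
    box_volume = float(np.prod(box))
    stage_groups = {
        tok: grp for tok, grp in population.oocytes.groupby("stage", observed=True)
    }
    fields = []
    for i, rng in enumerate(rngs):
        het = 1.0
        if field_spec.field_heterogeneity_cv > 0:
            mu, sigma = _lognormal_params(1.0, field_spec.field_heterogeneity_cv)
            het = rng.lognormal(mu, sigma)
        radii_parts, stage_parts = [], []
        for tok, grp in stage_groups.items():
            lam = population.number_density_per_um3(tok) * box_volume * het
            n_s = rng.poisson(lam)
            if n_s == 0:
                continue
            take = rng.integers(0, len(grp), size=n_s)
            radii_parts.append(grp["radius_um"].to_numpy()[take])
            stage_parts.append(np.repeat(tok, n_s))
        if not radii_parts:
            fields.append(Field(f"F{i + 1}", w, h, _empty_profiles()))
            continue
        radii = np.concatenate(radii_parts)
        stages = np.concatenate(stage_parts)
        pos = _rsa_pack(radii, box, rng, max_rounds=max_rounds)
        # section plane at z = 0 (equivalently z = Lz under wrap)
        dz = np.minimum(pos[:, 2], box[2] - pos[:, 2])
        cut = dz < radii
        r_prof = np.sqrt(np.maximum(radii[cut] ** 2 - dz[cut] ** 2, 0.0))
        x, y = pos[cut, 0], pos[cut, 1]
        parent = radii[cut]
        stage_cut = stages[cut]
        # wrapped xy images so profiles can overhang every field edge
        xs, ys, rs, ps, ss = [], [], [], [], []
        for sx_shift in (-box[0], 0.0, box[0]):
            for sy_shift in (-box[1], 0.0, box[1]):
                xi = x + sx_shift
                yi = y + sy_shift
                inside = (
                    (xi + r_prof > 0)
                    & (xi - r_prof < w)
                    & (yi + r_prof > 0)
                    & (yi - r_prof < h)
                )
                xs.append(xi[inside])
                ys.append(yi[inside])
                rs.append(r_prof[inside])
                ps.append(parent[inside])
                ss.append(stage_cut[inside])
        profiles = pd.DataFrame(
            {
                "x_um": np.concatenate(xs),
                "y_um": np.concatenate(ys),
                "r_um": np.concatenate(rs),
                "parent_r_um": np.concatenate(ps),
                "stage": np.concatenate(ss),
            }
        )
        fields.append(Field(f"F{i + 1}", w, h, profiles))
    return fields


def _empty_profiles() -> pd.DataFrame:
    return pd.DataFrame(columns=["x_um", "y_um", "r_um", "parent_r_um", "stage"])


def count_grid_hits(
    field: Field, grid: GridSpec, seed: int, female_id: str = ""
) -> FieldCount:
    """Overlay a square point lattice at a random offset and classify points.

    Each point hits exactly one component: the profile covering it (nearest
    centre wins on overlap ties, which cannot happen with hard spheres but
    is handled for robustness) or sectioned-tissue background.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w, h = field.width_um, field.height_um
    n = grid.n_points
    nx = max(1, int(round(np.sqrt(n * w / h))))
    ny = int(np.ceil(n / nx))
    sx, sy = w / nx, h / ny
    off_x = rng.uniform(0.0, sx)
    off_y = rng.uniform(0.0, sy)
    idx = np.arange(n)
    px = off_x + (idx % nx) * sx
    py = off_y + (idx // nx) * sy
    py = np.mod(py, h)  # guard: ny*sy == h, offsets keep points inside
    hits: dict = {}
    assigned = np.full(n, TISSUE, dtype=object)
    prof = field.profiles
    if len(prof):
        centers = prof[["x_um", "y_um"]].to_numpy(float)
        radii = prof["r_um"].to_numpy(float)
        stages = prof["stage"].to_numpy()
        tree = cKDTree(centers)
        groups = tree.query_ball_point(np.column_stack([px, py]), r=float(radii.max()))
        for i, group in enumerate(groups):
            if not group:
                continue
            group = np.asarray(group)
            d2 = (centers[group, 0] - px[i]) ** 2 + (centers[group, 1] - py[i]) ** 2
            covering = group[d2 <= radii[group] ** 2]
            if covering.size == 0:
                continue
            if covering.size == 1:
                assigned[i] = stages[covering[0]]
            else:
                dcov = d2[np.isin(group, covering)]
                assigned[i] = stages[covering[np.argmin(dcov)]]
    tokens, counts = np.unique(assigned, return_counts=True)
    hits = {str(t): int(c) for t, c in zip(tokens, counts)}
    return FieldCount(
        field_id=field.field_id, n_points=n, hits=hits, female_id=female_id
    )


def simulate_measurements(
    population: Population,
    n_per_stage: int = 10,
    shrinkage_model: ShrinkageModel = IDENTITY_SHRINKAGE,
    seed: int = 0,
    female_id: str = "",
) -> pd.DataFrame:
    """Axis measurements (L, S) in embedded (shrunken) coordinates.

    Samples ``n_per_stage`` oocytes per stage, emits the equatorial
    ("through-nucleus", maximal) axes with the shrinkage model applied, so a
    downstream correction with the inverse model recovers true dimensions.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for tok, count in population.counts.items():
        grp = population.oocytes[population.oocytes["stage"] == tok]
        if count == 0 or grp.empty:
            warnings.warn(f"stage {tok} absent from population; skipped", stacklevel=2)
            continue
        n_take = min(n_per_stage, len(grp))
        if n_take < n_per_stage:
            warnings.warn(
                f"stage {tok}: only {n_take} oocytes available "
                f"(requested {n_per_stage})",
                stacklevel=2,
            )
        take = rng.choice(len(grp), size=n_take, replace=False)
        sub = grp.iloc[take]
        rows.append(
            pd.DataFrame(
                {
                    "female_id": female_id,
                    "stage": tok,
                    "L_um": shrinkage_model.apply(sub["l_um"].to_numpy()),
                    "S_um": shrinkage_model.apply(sub["s_um"].to_numpy()),
                    "through_nucleus": True,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["female_id", "stage", "L_um", "S_um", "through_nucleus"]
        )
    return pd.concat(rows, ignore_index=True)


# --- cohort generation -----------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic fish cohort spanning a full year."""

    n_females: int
    tl_range_cm: tuple = (34.0, 84.0)
    allometry_a: float = 0.0065
    allometry_b: float = 3.01
    allometry_noise_sd: float = 0.15  # natural-log scale
    gw_by_phase: Mapping | None = None  # phase -> (intercept, slope, resid_sd)
    season_calendar: Mapping | None = None  # month -> season label
    phase_frequencies_by_month: Mapping | None = None
    opd_by_phase: Mapping | None = None  # phase -> {stage token -> opd per g}
    opd_noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.allometry_b <= 0:
            raise ValueError("allometry_b must be positive")
        if self.tl_range_cm[0] <= 0 or self.tl_range_cm[1] <= self.tl_range_cm[0]:
            raise ValueError("tl_range_cm must be a positive increasing interval")
        if self.phase_frequencies_by_month is not None:
            for month, freqs in self.phase_frequencies_by_month.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"phase probabilities for month {month} sum to {total}"
                    )


#: Default month -> season mapping (winter-spring, summer, autumn).
DEFAULT_SEASON_CALENDAR = {
    12: "SS1", 1: "SS1", 2: "SS1", 3: "SS1", 4: "SS1", 5: "SS1",
    6: "SS2", 7: "SS2", 8: "SS2",
    9: "SS3", 10: "SS3", 11: "SS3",
}

DEFAULT_GW_BY_PHASE = {
    "IM": (-3.0, 0.12, 0.8),
    "DV": (-40.0, 1.2, 6.0),
    "SC": (-80.0, 2.2, 10.0),
    "AS": (-80.0, 2.2, 10.0),
    "RS": (-30.0, 0.9, 5.0),
    "RT": (-12.0, 0.45, 2.5),
}

#: Synthetic per-gram packing densities by ovarian phase.  These are NOT
#: measured values; they are chosen so that total packing stays well below
#: the geometric cap with the default diameters.
DEFAULT_OPD_BY_PHASE = {
    "IM": {"PVO1": 6e5, "PVO2": 4e5, "PVO3": 2e5, "PVO4A": 5e4},
    "DV": {
        "PVO1": 3.5e5, "PVO2": 2.5e5, "PVO3": 1.2e5, "PVO4A": 5e4,
        "PVO4B": 3e4, "PVO4C": 1.8e4, "CAO": 9e3, "EVTO": 3e3, "VTO": 1.5e3,
    },
    "SC": {
        "PVO1": 3e5, "PVO2": 2e5, "PVO3": 1e5, "PVO4A": 4e4,
        "PVO4B": 2.5e4, "PVO4C": 1.5e4, "CAO": 8e3, "EVTO": 4e3, "VTO": 4e3,
        "MNO": 300.0,
    },
    "AS": {
        "PVO1": 3e5, "PVO2": 2e5, "PVO3": 1e5, "PVO4A": 4e4,
        "PVO4B": 2.2e4, "PVO4C": 1.3e4, "CAO": 7e3, "EVTO": 3.5e3, "VTO": 3.5e3,
        "MNO": 500.0, "HYO": 200.0,
    },
    "RS": {
        "PVO1": 3e5, "PVO2": 2e5, "PVO3": 1.2e5, "PVO4A": 3e4,
        "PVO4B": 1.5e4, "PVO4C": 8e3, "CAO": 2e3, "EVTO": 500.0, "VTO": 300.0,
    },
    "RT": {
        "PVO1": 4e5, "PVO2": 3e5, "PVO3": 1.5e5, "PVO4A": 3e4,
        "PVO4B": 1e4, "PVO4C": 3e3,
    },
}

#: Synthetic stage geometry defaults: (diameter mean um, diameter cv,
#: shape-factor mean, shape-factor cv).  Configurable, declared synthetic.
DEFAULT_STAGE_GEOMETRY = {
    "PVO1": (15.0, 0.08, 1.05, 0.02),
    "PVO2": (22.0, 0.08, 1.05, 0.02),
    "PVO3": (35.0, 0.08, 1.05, 0.02),
    "PVO4A": (55.0, 0.08, 1.05, 0.02),
    "PVO4B": (75.0, 0.08, 1.05, 0.02),
    "PVO4C": (95.0, 0.08, 1.05, 0.02),
    "CAO": (140.0, 0.08, 1.08, 0.02),
    "EVTO": (230.0, 0.08, 1.08, 0.02),
    "VTO": (300.0, 0.08, 1.08, 0.02),
    "MNO": (320.0, 0.06, 1.08, 0.02),
    "HYO": (400.0, 0.10, 1.20, 0.05),
}

_MAO_BY_PHASE = {
    "IM": ("PVO3", "PVO4A"),
    "DV": ("CAO", "EVTO"),
    "SC": ("VTO",),
    "AS": ("VTO",),
    "RS": ("VTO",),
    "RT": ("PVO4B", "PVO4C"),
}


def default_stage_specs(
    opd_by_stage: Mapping[str, float],
    geometry: Mapping | None = None,
) -> list[StagePopulationSpec]:
    """Stage population specs from per-gram densities and geometry defaults."""
    geometry = geometry or DEFAULT_STAGE_GEOMETRY
    specs = []
    for tok, density in opd_by_stage.items():
        if density <= 0:
            continue
        d_mean, d_cv, k_mean, k_cv = geometry[tok]
        specs.append(
            StagePopulationSpec(
                stage=OocyteStage(tok),
                true_opd=density,
                diameter_mean_um=d_mean,
                diameter_cv=d_cv,
                shape_factor_mean=k_mean,
                shape_factor_cv=k_cv,
            )
        )
    return specs


def _default_phase_frequencies(calendar: Mapping[int, str]) -> dict:
    by_season: dict = {}
    for month, season in calendar.items():
        by_season.setdefault(season, []).append(month)
    freqs = {}
    for month in range(1, 13):
        season = calendar[month]
        months = _cyclic_sort(by_season[season])
        if month == months[0]:
            freqs[month] = {"IM": 0.10, "DV": 0.30, "SC": 0.20, "AS": 0.10,
                            "RS": 0.10, "RT": 0.20}
        elif month == months[-1]:
            freqs[month] = {"IM": 0.10, "DV": 0.25, "SC": 0.25, "AS": 0.20,
                            "RS": 0.15, "RT": 0.05}
        else:
            freqs[month] = {"IM": 0.10, "DV": 0.20, "SC": 0.30, "AS": 0.25,
                            "RS": 0.10, "RT": 0.05}
    return freqs


def _cyclic_sort(months: list[int]) -> list[int]:
    """Order a contiguous cyclic month block from its first to last month."""
    months = sorted(months)
    if len(months) == 12:
        return months
    # find the gap: the month after the gap is the block start
    month_set = set(months)
    start = next(m for m in months if (m - 2) % 12 + 1 not in month_set)
    out = []
    m = start
    while len(out) < len(months):
        out.append(m)
        m = m % 12 + 1
    return out


def allometry_noise_for_r2(
    tl_range_cm: tuple, b: float, r2: float, n_grid: int = 10001
) -> float:
    """Natural-log noise sd making a log-log length-weight fit attain ~r2."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    tl = np.linspace(tl_range_cm[0], tl_range_cm[1], n_grid)
    signal_sd = b * np.std(np.log10(tl))
    noise_sd_log10 = signal_sd * np.sqrt((1.0 - r2) / r2)
    return float(noise_sd_log10 * np.log(10.0))


def default_cohort_spec(
    n_females: int = 157, seed: int = 0, r2_allometry: float = 0.96
) -> CohortSpec:
    """Cohort spec mirroring the documented sampling design."""
    return CohortSpec(
        n_females=n_females,
        tl_range_cm=(34.0, 84.0),
        allometry_a=0.0065,
        allometry_b=3.01,
        allometry_noise_sd=allometry_noise_for_r2((34.0, 84.0), 3.01, r2_allometry),
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a year-spanning cohort of female records.

    Eviscerated weight follows the allometric power law with multiplicative
    lognormal noise; fixed gonad weight follows a phase-dependent linear
    model in total length; ovarian phases are drawn from monthly frequency
    tables tied to the season calendar.  True per-stage packing densities
    (columns ``opd_<STAGE>``) are attached for recovery tests.
    """
    calendar = dict(spec.season_calendar or DEFAULT_SEASON_CALENDAR)
    gw_by_phase = dict(spec.gw_by_phase or DEFAULT_GW_BY_PHASE)
    freqs = dict(spec.phase_frequencies_by_month or _default_phase_frequencies(calendar))
    opd_by_phase = dict(spec.opd_by_phase or DEFAULT_OPD_BY_PHASE)
    for month, f in freqs.items():
        total = sum(f.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase probabilities for month {month} sum to {total}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_females
    months = np.tile(np.arange(1, 13), int(np.ceil(n / 12)))[:n]
    rng.shuffle(months)
    tl = rng.uniform(spec.tl_range_cm[0], spec.tl_range_cm[1], size=n)
    ew = spec.allometry_a * tl**spec.allometry_b
    if spec.allometry_noise_sd > 0:
        ew = ew * np.exp(rng.normal(0.0, spec.allometry_noise_sd, size=n))
    phase_tokens = list(MaturityPhase.__members__)
    rows = []
    stage_tokens = [s.value for s in OocyteStage]
    for i in range(n):
        month = int(months[i])
        probs = [freqs[month].get(tok, 0.0) for tok in phase_tokens]
        phase = str(rng.choice(phase_tokens, p=probs))
        intercept, slope, resid_sd = gw_by_phase[phase]
        gwf = max(0.5, intercept + slope * tl[i] + rng.normal(0.0, resid_sd))
        mao = str(rng.choice(_MAO_BY_PHASE[phase]))
        pof = phase == "AS" or (phase == "RS" and rng.random() < 0.7)
        row = {
            "female_id": f"SYN{i + 1:04d}",
            "month": month,
            "TL_cm": round(float(tl[i]), 1),
            "WW_g": round(float(ew[i] * 1.08 + gwf), 2),
            "EW_g": round(float(ew[i]), 2),
            "GW_g": round(float(gwf), 2),
            "GWf_g": round(float(gwf), 2),
            "MAT": phase,
            "MAO": mao,
            "POF_present": bool(pof),
        }
        base = opd_by_phase.get(phase, {})
        for tok in stage_tokens:
            density = base.get(tok, 0.0)
            if density > 0 and spec.opd_noise_cv > 0:
                mu, sigma = _lognormal_params(1.0, spec.opd_noise_cv)
                density = density * rng.lognormal(mu, sigma)
            row[f"opd_{tok}"] = float(density)
        rows.append(row)
    return pd.DataFrame(rows)
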