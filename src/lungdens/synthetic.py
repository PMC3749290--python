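"""Synthetic CT phantoms and synthetic cohorts with ground truth.

Phantoms: two lung ellipsoids inside a soft-tissue body ellipsoid surrounded
by air at -1000 HU, an optional airway tube (trachea plus two main-bronchus
branches) carved at lumen density, spherical emphysema lesions placed with a
pattern-specific spatial prior until a designed voxel fraction is met exactly
on the ground-truth mask, optional thin-walled cysts, and additive Gaussian
HU noise applied last.  Ground-truth masks are constructed before noise, so
segmentation and densitometry accuracy are checkable exactly.

Cohorts: per-group ages, an emphysema-index-versus-age line per group
(floored at 0), pulmonary function generated through monotone links with the
sign structure of the clinical tables (FEV1% decreasing in EI, RV/TLC and RV
increasing, perc15 decreasing, LW increasing in RV, LV tracking TLC), and
group sizes 41 CF / 21 control by default.  The CF intercept is solved so
that the *expected* 95% confidence bands of the two EI-age regressions
separate at a designed onset age (default 13 years); the FEV1% noise SD is
calibrated by an internal Monte-Carlo so the realized Spearman correlation
between EI and FEV1% in CF is near its target (default -0.66).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ct_io import CTVolume, LabelVolume
from .errors import GenerationError
from . import cohort as _cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phantoms


@dataclass
class CystSpec:
    """A thin-walled air-filled cyst: lumen at air density inside a
    soft-tissue wall, the kind of lesion excluded manually from density masks."""

    center_frac: tuple[float, float, float]  # fractional (slice,row,col) position
    radius_mm: float
    wall_hu: float = 40.0
    lumen_hu: float = -1000.0
    wall_thickness_mm: float = 2.0


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (56, 72, 72)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_hu: float = 40.0
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 0.0
    emphysema_hu_mean: float = -980.0
    emphysema_fraction: float = 0.10
    emphysema_pattern: str = "subpleural"  # subpleural|bronchovascular|centrilobular|diffuse
    airway: bool = True
    airway_radius_mm: float = 8.0
    airway_wall_hu: float = 0.0
    airway_wall_thickness_mm: float = 2.0
    cysts: tuple[CystSpec, ...] = ()
    noise_sd: float = 3.0
    exterior_hu: float = -1000.0
    seed: int = 0
    # geometry (fractions of the grid); right lung sits at lower columns
    body_semiaxes: tuple[float, float, float] = (0.45, 0.38, 0.42)
    lung_semiaxes: tuple[float, float, float] = (0.33, 0.26, 0.15)
    lung_center_cols: tuple[float, float] = (0.30, 0.70)

    def __post_init__(self) -> None:
        if not (self.emphysema_hu_mean < -950.0 < self.parenchyma_hu_mean):
            raise GenerationError(
                "need emphysema_hu_mean < -950 < parenchyma_hu_mean"
            )
        if not 0.0 <= self.emphysema_fraction <= 0.5:
            raise GenerationError("emphysema_fraction must be in [0, 0.5]")
        if self.emphysema_pattern not in (
            "subpleural",
            "bronchovascular",
            "centrilobular",
            "diffuse",
        ):
            raise GenerationError(f"unknown pattern {self.emphysema_pattern!r}")


@dataclass
class PhantomTruth:
    """Noise-free ground-truth masks paired with a generated phantom."""

    body: LabelVolume
    lung: LabelVolume  # 1 = right, 2 = left
    airway: LabelVolume
    emphysema: LabelVolume
    cysts: LabelVolume
    achieved_fraction: float
    n_lung_voxels: int
    spec: PhantomSpec


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((z - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((x - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _stamp_sphere(mask: np.ndarray, center_vox, radius_mm, spacing) -> None:
    """Set mask voxels within radius_mm of center (physical distance)."""
    rz, ry, rx = (max(1, int(math.ceil(radius_mm / s))) for s in spacing)
    cz, cy, cx = (int(round(c)) for c in center_vox)
    z0, z1 = max(cz - rz, 0), min(cz + rz + 1, mask.shape[0])
    y0, y1 = max(cy - ry, 0), min(cy + ry + 1, mask.shape[1])
    x0, x1 = max(cx - rx, 0), min(cx + rx + 1, mask.shape[2])
    z, y, x = np.ogrid[z0:z1, y0:y1, x0:x1]
    d2 = (
        ((z - cz) * spacing[0]) ** 2
        + ((y - cy) * spacing[1]) ** 2
        + ((x - cx) * spacing[2]) ** 2
    )
    mask[z0:z1, y0:y1, x0:x1] |= d2 <= radius_mm**2


def _carve_tube(mask: np.ndarray, p0, p1, radius_mm, spacing) -> None:
    """Mark a cylinder of given radius along the segment p0->p1 (voxel coords)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = np.linalg.norm((p1 - p0) * np.asarray(spacing))
    n_steps = max(2, int(length / (min(spacing) * 0.5)))
    for t in np.linspace(0.0, 1.0, n_steps):
        _stamp_sphere(mask, p0 + t * (p1 - p0), radius_mm, spacing)


def _pattern_weights(
    pattern: str,
    lung: np.ndarray,
    airway: np.ndarray,
    spacing,
) -> np.ndarray:
    d_pleura = ndimage.distance_transform_edt(lung, sampling=spacing)
    if pattern == "subpleural":
        w = np.exp(-d_pleura / 5.0)
    elif pattern == "bronchovascular":
        if airway.any():
            d_aw = ndimage.distance_transform_edt(~airway, sampling=spacing)
            w = np.exp(-d_aw / 10.0)
        else:
            logger.warning("no airway for bronchovascular prior; using diffuse")
            w = np.ones_like(d_pleura)
    elif pattern == "centrilobular":
        w = np.where(d_pleura > 8.0, 1.0, 0.05)
    else:  # diffuse
        w = np.ones_like(d_pleura)
    w = np.where(lung, w, 0.0)
    return w


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a CT phantom and its noise-free ground-truth masks.

    Deterministic given ``spec.seed``.  The emphysema ground-truth mask is
    trimmed voxel-exactly to ``round(fraction * n_lung_voxels)`` voxels;
    the achieved fraction (count / n_lung) is recorded in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    sp = spec.spacing
    nz, ny, nx = shape
    center = (nz / 2.0, ny / 2.0, nx / 2.0)

    body = _ellipsoid(
        shape, center, tuple(a * s for a, s in zip(spec.body_semiaxes, shape))
    )
    lung_axes = tuple(a * s for a, s in zip(spec.lung_semiaxes, shape))
    lung_r = _ellipsoid(shape, (nz / 2, ny / 2, spec.lung_center_cols[0] * nx), lung_axes)
    lung_l = _ellipsoid(shape, (nz / 2, ny / 2, spec.lung_center_cols[1] * nx), lung_axes)
    lung_r &= body
    lung_l &= body
    overlap = lung_r & lung_l
    if overlap.any():
        # touching lungs: assign overlap voxels to the nearer centre, ties right
        z, y, x = np.nonzero(overlap)
        cr = np.array([nz / 2, ny / 2, spec.lung_center_cols[0] * nx])
        cl = np.array([nz / 2, ny / 2, spec.lung_center_cols[1] * nx])
        pts = np.column_stack([z, y, x]).astype(float)
        dr = ((pts - cr) * sp).__pow__(2).sum(1)
        dl = ((pts - cl) * sp).__pow__(2).sum(1)
        to_left = dl < dr
        lung_r[z[to_left], y[to_left], x[to_left]] = False
        lung_l[z[~to_left], y[~to_left], x[~to_left]] = False

    # airway lumen plus a soft-tissue wall: real airway walls separate lumen
    # air from parenchyma, which is what keeps seeded region growing confined
    airway = np.zeros(shape, dtype=bool)
    airway_wall = np.zeros(shape, dtype=bool)
    if spec.airway:
        top = (0.0, ny / 2.0, nx / 2.0)
        branch_pt = (0.42 * nz, ny / 2.0, nx / 2.0)
        segments = [(top, branch_pt, spec.airway_radius_mm)]
        for cx_frac in spec.lung_center_cols:
            segments.append(
                (branch_pt, (nz / 2.0, ny / 2.0, cx_frac * nx), 0.6 * spec.airway_radius_mm)
            )
        for p0, p1, radius in segments:
            _carve_tube(airway_wall, p0, p1, radius + spec.airway_wall_thickness_mm, sp)
        for p0, p1, radius in segments:
            _carve_tube(airway, p0, p1, radius, sp)
        # wall must be at least one voxel thick everywhere (26-connectivity),
        # whatever the grid spacing, or region growing escapes the lumen
        airway_wall |= ndimage.binary_dilation(airway, structure=np.ones((3, 3, 3), bool))
        airway_wall &= ~airway
    lung_r &= ~(airway | airway_wall)
    lung_l &= ~(airway | airway_wall)
    lung_any = lung_r | lung_l
    n_lung = int(lung_any.sum())

    # --- emphysema lesions, exact voxel fraction on the truth mask
    emph = np.zeros(shape, dtype=bool)
    target = int(round(spec.emphysema_fraction * n_lung))
    if target > 0:
        w = _pattern_weights(spec.emphysema_pattern, lung_any, airway, sp)
        flat_idx = np.flatnonzero(w > 0)
        p = w.ravel()[flat_idx]
        p = p / p.sum()
        count = 0
        for _ in range(6000):
            if count >= target:
                break
            c = np.unravel_index(rng.choice(flat_idx, p=p), shape)
            radius = rng.uniform(2.0, 8.0)
            blob = np.zeros(shape, dtype=bool)
            _stamp_sphere(blob, c, radius, sp)
            emph |= blob & lung_any
            count = int(emph.sum())
        if count < target:
            raise GenerationError(
                f"emphysema fraction {spec.emphysema_fraction} unreachable with "
                f"pattern {spec.emphysema_pattern!r}; achieved {count / n_lung:.4f}"
            )
        excess = count - target
        if excess > 0:
            drop = rng.choice(np.flatnonzero(emph), size=excess, replace=False)
            emph.ravel()[drop] = False

    # --- assemble HU values
    vals = np.full(shape, spec.exterior_hu, dtype=np.float64)
    vals[body] = spec.body_hu
    vals[lung_any] = spec.parenchyma_hu_mean
    if spec.parenchyma_hu_sd > 0:
        vals[lung_any] += rng.normal(0.0, spec.parenchyma_hu_sd, int(lung_any.sum()))
    vals[airway_wall] = spec.airway_wall_hu
    vals[airway] = -1000.0
    vals[emph] = spec.emphysema_hu_mean

    cyst_mask = np.zeros(shape, dtype=bool)
    for cy in spec.cysts:
        c_vox = tuple(f * s for f, s in zip(cy.center_frac, shape))
        lumen = np.zeros(shape, dtype=bool)
        _stamp_sphere(lumen, c_vox, cy.radius_mm, sp)
        shell = np.zeros(shape, dtype=bool)
        _stamp_sphere(shell, c_vox, cy.radius_mm + cy.wall_thickness_mm, sp)
        shell &= ~lumen
        vals[shell] = cy.wall_hu
        vals[lumen] = cy.lumen_hu
        cyst_mask |= lumen | shell
    emph &= ~cyst_mask  # cyst air is a lesion, not emphysema

    if spec.noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd, shape)

    lung_labels = np.zeros(shape, dtype=np.uint8)
    lung_labels[lung_r] = 1
    lung_labels[lung_l] = 2
    mk = lambda a: LabelVolume(np.asarray(a, dtype=np.uint8), sp)
    truth = PhantomTruth(
        body=mk(body),
        lung=LabelVolume(lung_labels, sp),
        airway=mk(airway),
        emphysema=mk(emph),
        cysts=mk(cyst_mask),
        achieved_fraction=float(emph.sum()) / n_lung if n_lung else 0.0,
        n_lung_voxels=n_lung,
        spec=spec,
    )
    return CTVolume(vals, sp), truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class Fev1Link:
    """Bounded, monotone decreasing logistic link from EI (%) to FEV1%."""

    lo: float = 25.0
    hi: float = 102.0
    midpoint_ei: float = 8.0
    scale_ei: float = 4.0

    def __call__(self, ei_pct):
        ei_pct = np.asarray(ei_pct, float)
        return self.lo + (self.hi - self.lo) / (
            1.0 + np.exp((ei_pct - self.midpoint_ei) / self.scale_ei)
        )


@dataclass
class CohortSpec:
    """Parameters of the synthetic CF-vs-control cohort generator.

    EI-related quantities are in percent; slopes in % per year.
    """

    n_cf: int = 41
    n_control: int = 21
    n_pft_cf: int = 39
    n_pft_control: int = 15
    age_range_cf: tuple[float, float] = (7.0, 66.0)
    age_range_control: tuple[float, float] = (4.0, 68.0)
    age_median_cf: float = 20.1
    age_median_control: float = 30.4
    age_log_sd_cf: float = 0.55
    age_log_sd_control: float = 0.60
    ei_slope_cf: float = 0.35
    ei_slope_control: float = 0.04
    ei_noise_sd_cf: float = 2.0
    ei_noise_sd_control: float = 0.7
    ei_intercept_control: float = 0.3
    onset_age: float = 13.0  # designed age of 95% CI band separation
    target_spearman_ei_fev1: float = -0.66
    fev1_link: Fev1Link = field(default_factory=Fev1Link)
    lv_tlc_offset_ml: float = 400.0
    lv_noise_ml: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cf, self.n_control) <= 0:
            raise GenerationError("group sizes must be positive")
        if not abs(self.target_spearman_ei_fev1) < 1:
            raise GenerationError("|target correlation| must be < 1")
        if self.n_pft_cf > self.n_cf or self.n_pft_control > self.n_control:
            raise GenerationError("PFT subset cannot exceed group size")


@dataclass
class CohortTruth:
    """Generator parameters realized for one cohort draw."""

    ei_slope_cf: float
    ei_slope_control: float
    ei_intercept_cf: float
    ei_intercept_control: float
    ei_noise_sd_cf: float
    ei_noise_sd_control: float
    designed_onset_age: float
    mean_line_crossing_age: float
    fev1_noise_sd: float
    target_spearman_ei_fev1: float
    lv_tlc_offset_ml: float
    seed: int


def _draw_ages(rng, n, median, log_sd, lo, hi) -> np.ndarray:
    ages = rng.lognormal(math.log(median), log_sd, n)
    return np.clip(ages, lo, hi)


def _expected_halfwidth(ages: np.ndarray, sigma: float, at_age: float, ci=0.95) -> float:
    """Expected mean-response CI half-width at one age for true noise sigma."""
    n = len(ages)
    tcrit = stats.t.ppf(0.5 + ci / 2.0, n - 2)
    ssx = float(((ages - ages.mean()) ** 2).sum())
    return float(tcrit * sigma * math.sqrt(1.0 / n + (at_age - ages.mean()) ** 2 / ssx))


def _solve_cf_intercept(
    spec: CohortSpec, ages_cf: np.ndarray, ages_ctrl: np.ndarray
) -> float:
    """CF intercept such that the expected CI bands separate at onset_age."""
    a = spec.onset_age
    hw = _expected_halfwidth(ages_cf, spec.ei_noise_sd_cf, a) + _expected_halfwidth(
        ages_ctrl, spec.ei_noise_sd_control, a
    )
    return (
        spec.ei_slope_control * a
        + spec.ei_intercept_control
        + hw
        - spec.ei_slope_cf * a
    )


def _ei_line(ages, slope, intercept, rng, noise_sd) -> np.ndarray:
    noise = rng.normal(0.0, noise_sd, len(ages)) if noise_sd > 0 else 0.0
    return np.maximum(0.0, slope * ages + intercept + noise)


_SIGMA_F_CACHE: dict[tuple, float] = {}


def calibrate_fev1_noise(spec: CohortSpec, n_reps: int = 150) -> float:
    """Monte-Carlo calibration of the FEV1% noise SD.

    Finds sigma such that the mean Spearman correlation between EI and
    FEV1% over fresh CF draws equals the target.  Uses a fixed internal RNG
    so the result depends only on the spec parameters, not on ``spec.seed``;
    cached per parameter set.
    """
    key = (
        spec.n_pft_cf,
        spec.age_range_cf,
        spec.age_median_cf,
        spec.age_log_sd_cf,
        spec.ei_slope_cf,
        spec.ei_noise_sd_cf,
        spec.ei_intercept_control,
        spec.ei_slope_control,
        spec.onset_age,
        spec.ei_noise_sd_control,
        spec.target_spearman_ei_fev1,
        (spec.fev1_link.lo, spec.fev1_link.hi, spec.fev1_link.midpoint_ei, spec.fev1_link.scale_ei),
        n_reps,
    )
    if key in _SIGMA_F_CACHE:
        return _SIGMA_F_CACHE[key]
    rng = np.random.default_rng(777)
    # pre-draw replicate material once; reuse across candidate sigmas so the
    # objective is monotone and bisection converges cleanly
    reps = []
    for _ in range(n_reps):
        ages_cf = _draw_ages(
            rng, spec.n_pft_cf, spec.age_median_cf, spec.age_log_sd_cf, *spec.age_range_cf
        )
        ages_ct = _draw_ages(
            rng,
            spec.n_pft_control,
            spec.age_median_control,
            spec.age_log_sd_control,
            *spec.age_range_control,
        )
        b_cf = _solve_cf_intercept(spec, ages_cf, ages_ct)
        ei = _ei_line(ages_cf, spec.ei_slope_cf, b_cf, rng, spec.ei_noise_sd_cf)
        base = spec.fev1_link(ei)
        eps = rng.normal(0.0, 1.0, spec.n_pft_cf)
        reps.append((ei, base, eps))

    def mean_rs(sigma: float) -> float:
        vals = [
            stats.spearmanr(ei, np.clip(base + sigma * eps, 5.0, 160.0)).statistic
            for ei, base, eps in reps
        ]
        return float(np.mean(vals))

    target = spec.target_spearman_ei_fev1
    lo, hi = 0.1, 120.0
    if mean_rs(hi) < target:  # even huge noise keeps |rs| above target
        sigma = hi
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if mean_rs(mid) < target:
                lo = mid
            else:
                hi = mid
        sigma = 0.5 * (lo + hi)
    _SIGMA_F_CACHE[key] = sigma
    logger.debug("calibrated FEV1%% noise SD = %.2f", sigma)
    return sigma


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a synthetic cohort table and its ground-truth parameters.

    Deterministic given ``spec.seed``.  Output columns follow
    :data:`lungdens.cohort.SUBJECT_FIELDS`; EI is a fraction of 1; subjects
    without pulmonary function testing have empty PFT cells.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_f = calibrate_fev1_noise(spec)

    rows = []
    groups = (
        ("CF", spec.n_cf, spec.age_median_cf, spec.age_log_sd_cf, spec.age_range_cf),
        (
            "control",
            spec.n_control,
            spec.age_median_control,
            spec.age_log_sd_control,
            spec.age_range_control,
        ),
    )
    ages_by_group = {}
    for name, n, med, lsd, rng_a in groups:
        ages_by_group[name] = _draw_ages(rng, n, med, lsd, *rng_a)
    b_cf = _solve_cf_intercept(spec, ages_by_group["CF"], ages_by_group["control"])
    intercepts = {"CF": b_cf, "control": spec.ei_intercept_control}
    slopes = {"CF": spec.ei_slope_cf, "control": spec.ei_slope_control}
    noise_sds = {"CF": spec.ei_noise_sd_cf, "control": spec.ei_noise_sd_control}

    link = spec.fev1_link
    for gname, n, *_ in groups:
        ages = ages_by_group[gname]
        ei_pct = _ei_line(ages, slopes[gname], intercepts[gname], rng, noise_sds[gname])
        fev1pct = np.clip(link(ei_pct) + rng.normal(0.0, sigma_f, n), 5.0, 160.0)
        size = np.clip(ages, 3.0, 20.0) / 20.0  # crude body-size growth factor
        tlc = np.maximum(0.5, size * rng.normal(6.0, 0.7, n))
        is_cf = 1.0 if gname == "CF" else 0.0
        rv_tlc = np.clip(
            0.30 + 0.012 * ei_pct + 0.10 * is_cf + rng.normal(0.0, 0.05, n),
            0.12,
            0.85,
        )
        rv = rv_tlc * tlc
        vc = tlc - rv
        fev1 = np.minimum(fev1pct / 100.0 * size * 3.6, 0.95 * vc)
        lv = np.maximum(
            300.0,
            tlc * 1000.0 - spec.lv_tlc_offset_ml + rng.normal(0.0, spec.lv_noise_ml, n),
        )
        ev = ei_pct / 100.0 * lv
        perc15 = -856.0 - 5.0 * ei_pct + rng.normal(0.0, 10.0, n)
        mld = -822.0 - 3.0 * ei_pct + 12.0 * is_cf + rng.normal(0.0, 18.0, n)
        lw = np.maximum(100.0, 350.0 + 190.0 * rv + 120.0 * is_cf + rng.normal(0.0, 70.0, n))
        sex = rng.choice(["M", "F"], n)
        gap = rng.integers(0, 60, n)
        for i in range(n):
            rows.append(
                dict(
                    id=f"{gname[:2].upper()}{i + 1:03d}",
                    group=gname,
                    age=float(ages[i]),
                    sex=str(sex[i]),
                    FEV1=float(fev1[i]),
                    FEV1pct=float(fev1pct[i]),
                    VC=float(vc[i]),
                    VCpct=float(100.0 * vc[i] / (size[i] * 4.2)),
                    FEV1_VC=float(fev1[i] / vc[i]),
                    RV=float(rv[i]),
                    RVpct=float(100.0 * rv[i] / (size[i] * 1.8)),
                    TLC=float(tlc[i]),
                    TLCpct=float(100.0 * tlc[i] / (size[i] * 6.0)),
                    RV_TLC=float(rv_tlc[i]),
                    LV=float(lv[i]),
                    EV=float(ev[i]),
                    EI=float(ei_pct[i] / 100.0),
                    MLD=float(mld[i]),
                    LW=float(lw[i]),
                    perc15=float(perc15[i]),
                    pft_mdct_gap_days=int(gap[i]),
                )
            )
    df = pd.DataFrame(rows, columns=_cohort.SUBJECT_FIELDS)

    # subjects without PFT (MDCT n exceeds PFT n, as in the study design)
    pft_cols = ["FEV1", "FEV1pct", "VC", "VCpct", "FEV1_VC", "RV", "RVpct", "TLC", "TLCpct", "RV_TLC"]
    for gname, n_total, n_pft in (
        ("CF", spec.n_cf, spec.n_pft_cf),
        ("control", spec.n_control, spec.n_pft_control),
    ):
        idx = df.index[df["group"] == gname].to_numpy()
        n_missing = n_total - n_pft
        if n_missing > 0:
            drop = rng.choice(idx, size=n_missing, replace=False)
            df.loc[drop, pft_cols] = np.nan

    _cohort.validate_cohort(df)
    crossing = (intercepts["control"] - b_cf) / (spec.ei_slope_cf - spec.ei_slope_control)
    truth = CohortTruth(
        ei_slope_cf=spec.ei_slope_cf,
        ei_slope_control=spec.ei_slope_control,
        ei_intercept_cf=b_cf,
        ei_intercept_control=spec.ei_intercept_control,
        ei_noise_sd_cf=spec.ei_noise_sd_cf,
        ei_noise_sd_control=spec.ei_noise_sd_control,
        designed_onset_age=spec.onset_age,
        mean_line_crossing_age=float(crossing),
        fev1_noise_sd=sigma_f,
        target_spearman_ei_fev1=spec.target_spearman_ei_fev1,
        lv_tlc_offset_ml=spec.lv_tlc_offset_ml,
        seed=spec.seed,
    )
    return df, truth
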