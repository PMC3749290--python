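"""Lung and airway segmentation from chest CT.

A classical, fully deterministic threshold pipeline:

1. body extraction (largest component above -200 HU, in-plane hole fill),
2. airway extraction by seeded 3D region growing from a trachea seed with
   stepwise threshold relaxation and volume-jump leak detection,
3. lung extraction as air-like voxels inside the body minus the airway tree,
   component filtering, per-lung morphological closing (to reincorporate
   vessels and septa), and a deterministic erosion/nearest-core split when
   the two lungs touch across the midline.

Every parameter is recorded in the returned :class:`SegmentationResult` so a
run can be reproduced exactly.  Label convention: right lung = 1, left
lung = 2, assigned by centre-of-mass column (in the supine patient
orientation the right lung appears at lower column indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .ct_io import CalibrationReport, CTVolume, LabelVolume, check_same_grid
from .errors import DegenerateInputError, SeedNotFoundError, SegmentationError

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

BODY_THRESHOLD_HU = -200.0
_TRACHEA_SCAN_HU = -900.0  # seed-candidate threshold for tracheal lumen air


@dataclass
class SegmentationParams:
    """Tunable parameters of the threshold/region-growing pipeline.

    air_threshold:
        HU below which voxels are lung-candidate air (default -500).
    trachea_seed:
        ``None`` for automatic seed detection, or manual (slice, row, col).
    airway_leak_volume_step_ml:
        Volume jump between successive growing thresholds that signals a leak
        into parenchyma (default 20 ml).
    closing_radius_mm:
        Radius of the per-lung morphological closing (default 2 mm).
    min_lung_volume_ml:
        Minimum component volume retained as lung (default 50 ml).
    """

    air_threshold: float = -500.0
    trachea_seed: Optional[tuple[int, int, int]] = None
    airway_leak_volume_step_ml: float = 20.0
    closing_radius_mm: float = 2.0
    min_lung_volume_ml: float = 50.0
    airway_threshold_step_hu: float = 10.0

    def __post_init__(self) -> None:
        if self.air_threshold >= 0:
            raise ValueError("air_threshold must be negative (HU)")
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")


@dataclass
class SegmentationResult:
    """Lung labels (1=right, 2=left), airway lumen mask, and the params used."""

    lung_mask: LabelVolume
    airway_mask: LabelVolume
    params_used: SegmentationParams = field(default_factory=SegmentationParams)

    def lung_voxel_count(self) -> int:
        return int(np.count_nonzero(self.lung_mask.labels))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        raise DegenerateInputError("no foreground voxels")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(sizes.argmax())


def segment_body(volume: CTVolume) -> LabelVolume:
    """Extract the body as the largest component above -200 HU, holes filled in-plane."""
    mask = volume.values > BODY_THRESHOLD_HU
    if not mask.any():
        raise DegenerateInputError("no voxel above -200 HU; volume contains no body")
    body = _largest_component(mask)
    filled = np.empty_like(body)
    for z in range(body.shape[0]):
        filled[z] = ndimage.binary_fill_holes(body[z])
    return LabelVolume(
        filled.astype(np.uint8), volume.spacing, volume.origin, volume.direction
    )


def find_trachea_seed(volume: CTVolume, body: LabelVolume) -> tuple[int, int, int]:
    """Locate a trachea seed: a round air component of 50-500 mm^2 inside the
    body on the top third of slices, scanned from the first slice down."""
    nz = volume.shape[0]
    area_per_px = volume.spacing[1] * volume.spacing[2]
    for z in range(max(1, nz // 3)):
        cand = (volume.values[z] < _TRACHEA_SCAN_HU) & (body.labels[z] > 0)
        if not cand.any():
            continue
        lab, n = ndimage.label(cand)
        for i in range(1, n + 1):
            comp = lab == i
            area = comp.sum() * area_per_px
            if not (50.0 <= area <= 500.0):
                continue
            ys, xs = np.nonzero(comp)
            extent_y = ys.max() - ys.min() + 1
            extent_x = xs.max() - xs.min() + 1
            # roundness: bounding box close to square and well filled
            if max(extent_y, extent_x) > 2.5 * min(extent_y, extent_x):
                continue
            if comp.sum() < 0.5 * extent_y * extent_x:
                continue
            return (z, int(round(ys.mean())), int(round(xs.mean())))
    raise SeedNotFoundError(
        "no round 50-500 mm^2 air component found in the top third of slices"
    )


def segment_airways(
    volume: CTVolume,
    params: SegmentationParams | None = None,
    body: LabelVolume | None = None,
    seed: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Grow the airway tree from the trachea with leak detection.

    Region growing runs over voxels ``<= t`` inside the body, with ``t``
    relaxed stepwise from -1000 HU up to ``params.air_threshold``.  When the
    grown volume jumps by more than ``airway_leak_volume_step_ml`` between
    consecutive thresholds, growth has leaked into parenchyma and the last
    pre-leak mask is returned.
    """
    params = params or SegmentationParams()
    if body is None:
        body = segment_body(volume)
    if seed is None:
        seed = params.trachea_seed
    if seed is None:
        seed = find_trachea_seed(volume, body)
    seed = tuple(int(v) for v in seed)  # type: ignore[assignment]

    vv = volume.voxel_volume_ml
    inside = body.labels > 0
    step = params.airway_threshold_step_hu
    thresholds = np.arange(-1000.0, params.air_threshold + 0.5 * step, step)
    prev_mask: np.ndarray | None = None
    prev_vol = 0.0
    for t in thresholds:
        cand = (volume.values <= t) & inside
        if not cand[seed]:
            continue
        lab, _ = ndimage.label(cand, structure=_CONN26)
        mask = lab == lab[seed]
        vol = float(mask.sum()) * vv
        if prev_mask is not None and vol - prev_vol > params.airway_leak_volume_step_ml:
            logger.debug(
                "airway leak at %.0f HU: %.1f ml -> %.1f ml; keeping pre-leak tree",
                t,
                prev_vol,
                vol,
            )
            break
        prev_mask, prev_vol = mask, vol
    if prev_mask is None:
        raise SeedNotFoundError(
            f"seed voxel {seed} never fell below the airway threshold"
        )
    return LabelVolume(
        prev_mask.astype(np.uint8), volume.spacing, volume.origin, volume.direction
    )


def _ellipsoid_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray | None:
    radii = [int(round(radius_mm / s)) for s in spacing]
    if all(r == 0 for r in radii):
        return None
    rz, ry, rx = (max(r, 0) for r in radii)
    z, y, x = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    se = (
        (z / max(rz, 1e-9)) ** 2 + (y / max(ry, 1e-9)) ** 2 + (x / max(rx, 1e-9)) ** 2
    ) <= 1.0 + 1e-9
    return se


def _split_touching_lungs(
    comp: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Split one merged lung component into two by iterative erosion; assign
    every voxel to the nearest eroded core (ties toward the lower-column core)."""
    eroded = comp
    erode_se = ndimage.generate_binary_structure(3, 1)  # gentle, 6-connected
    for _ in range(40):
        eroded = ndimage.binary_erosion(eroded, structure=erode_se)
        if not eroded.any():
            return None
        lab, n = ndimage.label(eroded, structure=_CONN26)
        if n >= 2:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            order = np.argsort(sizes)[::-1][:2]
            core_a, core_b = (lab == order[0]), (lab == order[1])
            da = ndimage.distance_transform_edt(~core_a, sampling=spacing)
            db = ndimage.distance_transform_edt(~core_b, sampling=spacing)
            # ties go to the core with the lower column centre (right lung)
            com_a = ndimage.center_of_mass(core_a)[2]
            com_b = ndimage.center_of_mass(core_b)[2]
            if com_b < com_a:
                core_a, core_b, da, db = core_b, core_a, db, da
            a = comp & (da <= db)
            b = comp & ~a
            if a.any() and b.any():
                return a, b
            return None
    return None


def segment_lungs(
    volume: CTVolume,
    params: SegmentationParams | None = None,
    calibration: CalibrationReport | None = None,
) -> SegmentationResult:
    """Segment both lungs and the central airways from a chest CT.

    Raises :class:`SegmentationError` if no component of at least
    ``min_lung_volume_ml`` survives filtering.  A failed calibration report is
    logged as a warning but does not abort the run.
    """
    params = params or SegmentationParams()
    if calibration is not None and not calibration.passed:
        logger.warning(
            "air calibration failed (mean %.1f HU, tolerance %.1f HU); proceeding",
            calibration.extracorporal_air_mean,
            calibration.tolerance,
        )
    body = segment_body(volume)
    try:
        airway = segment_airways(volume, params, body=body)
    except SeedNotFoundError:
        logger.warning("no trachea seed found; proceeding without airway exclusion")
        airway = LabelVolume(
            np.zeros(volume.shape, dtype=np.uint8),
            volume.spacing,
            volume.origin,
            volume.direction,
        )

    cand = (
        (volume.values <= params.air_threshold)
        & (body.labels > 0)
        & (airway.labels == 0)
    )
    lab, n = ndimage.label(cand, structure=_CONN26)
    if n == 0:
        raise SegmentationError("no air-like voxels inside the body")
    vv = volume.voxel_volume_ml
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = [i for i in range(1, n + 1) if sizes[i] * vv >= params.min_lung_volume_ml]
    keep.sort(key=lambda i: sizes[i], reverse=True)
    keep = keep[:2]
    if not keep:
        raise SegmentationError(
            f"no candidate component reaches {params.min_lung_volume_ml} ml"
        )

    if len(keep) == 1:
        comp = lab == keep[0]
        split = _split_touching_lungs(comp, volume.spacing)
        lungs = list(split) if split is not None else [comp]
    else:
        lungs = [lab == i for i in keep]

    # per-lung closing to reincorporate vessels/septa, constrained to the body
    se = _ellipsoid_structure(params.closing_radius_mm, volume.spacing)
    closed = []
    for m in lungs:
        if se is not None:
            m = ndimage.binary_closing(m, structure=se)
        m = m & (body.labels > 0) & (airway.labels == 0)
        closed.append(m)
    if len(closed) == 2:
        overlap = closed[0] & closed[1]
        if overlap.any():
            d0 = ndimage.distance_transform_edt(~lungs[0], sampling=volume.spacing)
            d1 = ndimage.distance_transform_edt(~lungs[1], sampling=volume.spacing)
            closed[0] = closed[0] & ~(overlap & (d1 < d0))
            closed[1] = closed[1] & ~(overlap & (d0 <= d1))

    # right lung (label 1) has the smaller centre-of-mass column
    coms = [ndimage.center_of_mass(m)[2] for m in closed]
    order = np.argsort(coms)
    lung_labels = np.zeros(volume.shape, dtype=np.uint8)
    if len(closed) == 2:
        lung_labels[closed[order[0]]] = 1
        lung_labels[closed[order[1]]] = 2
    else:
        label = 1 if coms[0] < volume.shape[2] / 2 else 2
        lung_labels[closed[0]] = label

    return SegmentationResult(
        LabelVolume(lung_labels, volume.spacing, volume.origin, volume.direction),
        airway,
        params,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
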