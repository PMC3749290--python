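"""Density-mask metrics for emphysema quantification.

Given a lung segmentation, a voxel is assigned to emphysema when its density
is *equal to or below* -950 HU (the comparison is inclusive; implementations
in the literature differ, so this is stated explicitly).  From the lung and
emphysema masks the module computes:

LV    segmented lung volume (ml)
EV    emphysema volume (ml), the LAA-950 density mask
EI    emphysema (pixel) index, EV/LV, stored as a fraction of 1
MLD   mean lung density (HU)
LW    lung weight (g) under the linear water-air density model
      rho(HU) = max(0, (HU + 1000)/1000) g/ml
15th  the HU value below which 15% of lung voxels fall (inverse empirical
      CDF without interpolation: the smallest observed value h for which
      the fraction of lung voxels strictly below h is >= 0.15)

Exclusion masks (manually delineated cysts, sacculations, bronchiectases)
are subtracted from the emphysema mask only; MLD and the 15th percentile are
computed over the uncorrected lung mask, so an exclusion can only lower EI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, LabelVolume, check_same_grid
from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

#: Inspiratory emphysema threshold in HU (inclusive).
EMPHYSEMA_THRESHOLD_HU = -950.0

#: Default histogram range and bin width (HU).
HISTOGRAM_RANGE_HU = (-1024.0, 200.0)
HISTOGRAM_BIN_WIDTH_HU = 1.0

Scope = Literal["whole", "right", "left"]
_SCOPE_LABELS = {"whole": (1, 2), "right": (1,), "left": (2,)}


@dataclass
class DensityHistogram:
    """Histogram of lung HU values on uniform bins."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExclusionSet:
    """Voxels to exclude from the emphysema mask (nonzero = excluded)."""

    mask: LabelVolume
    source: str = "manual"
    note: str = ""


@dataclass
class DensitometryReport:
    """All density-mask metrics for one lung scope."""

    threshold: float
    LV: float  # ml
    EV: float  # ml
    EI: float  # fraction of 1
    MLD: float  # HU
    LW: float  # g
    perc15: float  # HU
    histogram: DensityHistogram
    scope: Scope = "whole"
    exclusions_applied: bool = False

    @property
    def EI_percent(self) -> float:
        return 100.0 * self.EI

    def to_dict(self) -> dict:
        return {
            "threshold_hu": self.threshold,
            "LV_ml": self.LV,
            "EV_ml": self.EV,
            "EI": self.EI,
            "EI_percent": self.EI_percent,
            "MLD_hu": self.MLD,
            "LW_g": self.LW,
            "perc15_hu": self.perc15,
            "scope": self.scope,
            "exclusions_applied": self.exclusions_applied,
        }


def _scope_mask(lung_mask: LabelVolume, scope: Scope) -> np.ndarray:
    if scope not in _SCOPE_LABELS:
        raise ParameterError(f"unknown scope {scope!r}")
    return np.isin(lung_mask.labels, _SCOPE_LABELS[scope]) & (lung_mask.labels > 0)


def compute_density_mask(
    volume: CTVolume,
    lung_mask: LabelVolume,
    threshold: float = EMPHYSEMA_THRESHOLD_HU,
) -> LabelVolume:
    """Binary emphysema mask: lung voxels with HU <= threshold (inclusive)."""
    check_same_grid(volume, lung_mask)
    lung = lung_mask.labels > 0
    if not lung.any():
        raise DegenerateInputError("empty lung mask")
    emph = lung & (volume.values <= threshold)
    return LabelVolume(
        emph.astype(np.uint8), volume.spacing, volume.origin, volume.direction
    )


def apply_exclusions(
    emphysema_mask: LabelVolume, exclusions: ExclusionSet
) -> LabelVolume:
    """Subtract excluded lesion voxels from the emphysema mask."""
    check_same_grid(emphysema_mask, exclusions.mask)
    out = emphysema_mask.labels.astype(np.uint8).copy()
    out[exclusions.mask.labels > 0] = 0
    return LabelVolume(
        out, emphysema_mask.spacing, emphysema_mask.origin, emphysema_mask.direction
    )


def percentile15(values: np.ndarray, fraction: float = 0.15) -> float:
    """Inverse empirical CDF without interpolation.

    Returns the smallest observed HU value ``h`` such that the fraction of
    values strictly below ``h`` is at least ``fraction``.  If no observed
    value satisfies this (e.g. all values equal), the maximum is returned so
    the result stays inside the observed range.
    """
    a = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = a.size
    if n == 0:
        raise DegenerateInputError("no values for percentile computation")
    # smallest integer m with m/n >= fraction, in exact rational arithmetic
    # for the default fraction 3/20
    if abs(fraction - 0.15) < 1e-12:
        m = -((-3 * n) // 20)
    else:
        m = int(math.ceil(fraction * n - 1e-9))
    m = max(m, 1)
    if m > n:
        return float(a[-1])
    # need count(values < h) >= m, i.e. h strictly greater than the m-th
    # smallest value; pick the smallest observed such value
    t = a[m - 1]
    idx = int(np.searchsorted(a, t, side="right"))
    if idx >= n:
        return float(a[-1])
    return float(a[idx])


def density_histogram(
    volume: CTVolume,
    lung_mask: LabelVolume,
    bin_width: float = HISTOGRAM_BIN_WIDTH_HU,
    hist_range: tuple[float, float] = HISTOGRAM_RANGE_HU,
) -> DensityHistogram:
    """Histogram of lung HU values; out-of-range values clip into edge bins."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    check_same_grid(volume, lung_mask)
    vals = volume.values[lung_mask.labels > 0]
    if vals.size == 0:
        raise DegenerateInputError("empty lung mask")
    lo, hi = hist_range
    n_out = int(np.count_nonzero((vals < lo) | (vals > hi)))
    if n_out:
        logger.warning("%d lung voxels outside [%g, %g] HU clipped into edge bins", n_out, lo, hi)
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    clipped = np.clip(vals, lo, np.nextafter(hi, -np.inf))
    counts, edges = np.histogram(clipped, bins=edges)
    return DensityHistogram(edges, counts.astype(np.int64))


def compute_report(
    volume: CTVolume,
    lung_mask: LabelVolume,
    emphysema_mask: LabelVolume,
    scope: Scope = "whole",
    threshold: float = EMPHYSEMA_THRESHOLD_HU,
    exclusions_applied: bool = False,
    bin_width: float = HISTOGRAM_BIN_WIDTH_HU,
) -> DensitometryReport:
    """Compute LV, EV, EI, MLD, LW, 15th percentile and histogram for a scope.

    ``emphysema_mask`` is typically the output of :func:`compute_density_mask`
    optionally corrected by :func:`apply_exclusions`; MLD/perc15 always use
    the full (uncorrected) lung mask.
    """
    check_same_grid(volume, lung_mask)
    check_same_grid(volume, emphysema_mask)
    lung = _scope_mask(lung_mask, scope)
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise DegenerateInputError(f"no lung voxels in scope {scope!r}")
    vv = volume.voxel_volume_ml
    vals = volume.values[lung]
    emph = (emphysema_mask.labels > 0) & lung
    lv = n_lung * vv
    ev = int(emph.sum()) * vv
    mld = float(vals.mean())
    lw = float(np.maximum(0.0, (vals + 1000.0) / 1000.0).sum()) * vv
    p15 = percentile15(vals)
    scoped = LabelVolume(lung.astype(np.uint8), volume.spacing, volume.origin, volume.direction)
    hist = density_histogram(volume, scoped, bin_width=bin_width)
    return DensitometryReport(
        threshold=float(threshold),
        LV=lv,
        EV=ev,
        EI=ev / lv,
        MLD=mld,
        LW=lw,
        perc15=p15,
        histogram=hist,
        scope=scope,
        exclusions_applied=exclusions_applied,
    )


def render_minip(
    volume: CTVolume, slab_thickness_mm: float = 5.0, axis: int = 0
) -> np.ndarray:
    """Sliding-slab minimum intensity projection along one axis.

    Accentuates low-attenuation (emphysematous) regions.  The output grid
    matches the input; a slab of one voxel is the identity, a slab spanning
    the whole axis yields the global per-column minimum.
    """
    if axis not in (0, 1, 2):
        raise ParameterError("axis must be 0, 1 or 2")
    sp = volume.spacing[axis]
    if slab_thickness_mm < sp:
        raise ParameterError(
            f"slab ({slab_thickness_mm} mm) thinner than one voxel ({sp} mm)"
        )
    size = max(1, int(round(slab_thickness_mm / sp)))
    size = min(size, volume.shape[axis])
    return ndimage.minimum_filter1d(volume.values, size=size, axis=axis, mode="nearest")


def run_densitometry(
    volume: CTVolume,
    lung_mask: LabelVolume,
    threshold: float = EMPHYSEMA_THRESHOLD_HU,
    exclusions: ExclusionSet | None = None,
) -> dict[str, DensitometryReport]:
    """Convenience wrapper: density mask -> optional exclusions -> reports for
    whole/right/left scopes (per-lung scopes only where voxels exist)."""
    emph = compute_density_mask(volume, lung_mask, threshold)
    applied = False
    if exclusions is not None:
        emph = apply_exclusions(emph, exclusions)
        applied = True
    reports: dict[str, DensitometryReport] = {}
    for scope in ("whole", "right", "left"):
        if not _scope_mask(lung_mask, scope).any():  # type: ignore[arg-type]
            continue
        reports[scope] = compute_report(
            volume,
            lung_mask,
            emph,
            scope=scope,  # type: ignore[arg-type]
            threshold=threshold,
            exclusions_applied=applied,
        )
    return reports
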