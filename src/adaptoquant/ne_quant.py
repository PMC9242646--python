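"""Nuclear-envelope enrichment quantification for multichannel cell images.

Per cell, the perinuclear signal is the mean gray value in a band of
``band_halfwidth`` µm (default 1 µm) on either side of the nuclear ROI
boundary; the cytoplasmic signal is the mean over the cell mask minus the
nuclear ROI expanded by the same margin; the enrichment score is their
ratio.  Cells failing the condition-specific raw-gray-value inclusion
filters are excluded with a machine-readable reason.

Thresholds are applied to raw gray values without normalization, so the
scores are invariant to multiplicative gain but not to additive offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "CellImage",
    "CellMeasurement",
    "project_stack",
    "segment_nucleus",
    "ne_band",
    "cytoplasm_region",
    "measure_cell",
    "apply_inclusion_filters",
    "INCLUSION_CONDITIONS",
]

#: Recognized experimental-condition tags for the inclusion filters.
INCLUSION_CONDITIONS = ("untransfected", "SUN1-only", "KASH5-dTM", "KASH5-FL")


@dataclass
class CellImage:
    """One cell: named channel planes (max projections) plus masks."""

    channels: dict
    pixel_size: float
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(p).shape for p in self.channels.values()}
        shapes |= {np.asarray(self.nucleus_mask).shape, np.asarray(self.cell_mask).shape}
        if len(shapes) != 1:
            raise ValueError("all channel planes and masks must share one shape")
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise ValueError("nucleus mask must lie inside the cell mask")


@dataclass
class CellMeasurement:
    """Per-cell region means, enrichment ratios and inclusion verdict."""

    ne_mean: dict
    cyto_mean: dict
    whole_cell_mean: dict
    ne_cyto_ratio: dict
    condition: str
    included: bool = True
    reason: str = ""


def project_stack(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (Z, H, W) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("z-stack must be (Z, H, W) with at least one plane")
    return zstack.max(axis=0)


def segment_nucleus(
    dapi_plane: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 25,
) -> list[np.ndarray]:
    """Segment nuclei from the nuclei channel.

    Thresholds the plane (Otsu by default, overridable), labels connected
    components, fills holes, and returns one boolean mask per nucleus,
    largest first.  Raises when no component exceeds ``min_area_px``.
    """
    plane = np.asarray(dapi_plane, dtype=float)
    if plane.max() == plane.min():
        raise ValueError("no nucleus: plane is constant")
    thr = threshold_otsu(plane) if threshold is None else threshold
    binary = plane > thr
    labels, n = ndimage.label(binary)
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() >= min_area_px:
            masks.append(ndimage.binary_fill_holes(mask))
    if not masks:
        raise ValueError("no nucleus: no component above threshold")
    masks.sort(key=lambda m: m.sum(), reverse=True)
    return masks


def _dilate_um(mask: np.ndarray, radius_um: float, pixel_size: float) -> np.ndarray:
    """Euclidean dilation by a true (possibly fractional) pixel radius."""
    r = radius_um / pixel_size
    if r <= 0:
        return mask.copy()
    return mask | (ndimage.distance_transform_edt(~mask) <= r)


def ne_band(
    nucleus_mask: np.ndarray,
    band_halfwidth: float,
    pixel_size: float,
) -> np.ndarray:
    """Perinuclear band: ``band_halfwidth`` µm on either side of the ROI edge.

    Equivalent to ``dilate(nucleus, r) XOR erode(nucleus, r)`` with a
    Euclidean disk of radius ``r = band_halfwidth / pixel_size`` pixels, and
    computed as the set of pixels within ``r`` of the ROI boundary contour.
    Measuring from the contour (rather than from foreground/background pixel
    centers separately) keeps the band symmetric about the edge and free of
    the half-pixel bias of grid dilation/erosion.  Raises when the nucleus
    erodes away entirely.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    if band_halfwidth <= 0:
        return np.zeros_like(nucleus_mask)
    r = band_halfwidth / pixel_size
    boundary = nucleus_mask & ~ndimage.binary_erosion(nucleus_mask)
    band = ndimage.distance_transform_edt(~boundary) <= r
    if not (nucleus_mask & ~band).any():
        raise ValueError("nucleus is smaller than the band erosion radius")
    return band


def cytoplasm_region(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    margin: float,
    pixel_size: float,
) -> np.ndarray:
    """Cytoplasm: cell mask minus the nucleus expanded by ``margin`` µm."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("masks must be aligned")
    expanded = _dilate_um(nucleus_mask, margin, pixel_size)
    cyto = cell_mask & ~expanded
    if not cyto.any():
        raise ValueError("cytoplasm region is empty after subtraction")
    return cyto


def measure_cell(
    image: CellImage,
    condition: str,
    band_halfwidth: float = 1.0,
    margin: float = 1.0,
) -> CellMeasurement:
    """Region means and enrichment ratios for one cell, with inclusion verdict.

    Per channel, computes the mean gray value over the perinuclear band, the
    cytoplasm region and the whole cell mask, attaches band/cytoplasm
    ratios, and applies the condition's inclusion filters.
    """
    band = ne_band(image.nucleus_mask, band_halfwidth, image.pixel_size)
    cyto = cytoplasm_region(image.cell_mask, image.nucleus_mask, margin, image.pixel_size)
    ne_mean, cyto_mean, whole_mean, ratio = {}, {}, {}, {}
    for name, plane in image.channels.items():
        plane = np.asarray(plane, dtype=float)
        ne_mean[name] = float(plane[band].mean())
        cyto_mean[name] = float(plane[cyto].mean())
        whole_mean[name] = float(plane[image.cell_mask].mean())
        ratio[name] = ne_mean[name] / cyto_mean[name]
    meas = CellMeasurement(
        ne_mean=ne_mean,
        cyto_mean=cyto_mean,
        whole_cell_mean=whole_mean,
        ne_cyto_ratio=ratio,
        condition=condition,
    )
    return apply_inclusion_filters(meas, condition)


def apply_inclusion_filters(meas: CellMeasurement, condition: str) -> CellMeasurement:
    """Apply the condition-specific raw-gray-value inclusion filters.

    * ``KASH5-FL`` (full-length or point mutants, nuclear-targeted): exclude
      if the KASH5 whole-cell mean gray value is below 250.
    * ``SUN1-only``: exclude if the SUN1 whole-cell mean is below 200.
    * ``KASH5-dTM``: exclude if the SUN1 whole-cell mean is below 200, or if
      the KASH5 whole-cell mean is below 220.
    * ``untransfected``: no filter.

    Thresholds are strict "less than": a cell exactly at a threshold is
    included.  The verdict records the first failed rule.
    """
    if condition not in INCLUSION_CONDITIONS:
        raise ValueError(f"unknown condition tag: {condition!r}")

    def get(channel: str) -> float:
        if channel not in meas.whole_cell_mean:
            raise ValueError(f"condition {condition!r} requires channel {channel!r}")
        return meas.whole_cell_mean[channel]

    included, reason = True, ""
    if condition == "KASH5-FL":
        if get("KASH5") < 250:
            included, reason = False, "KASH5<250"
    elif condition == "SUN1-only":
        if get("SUN1") < 200:
            included, reason = False, "SUN1<200"
    elif condition == "KASH5-dTM":
        if get("SUN1") < 200:
            included, reason = False, "SUN1<200"
        elif get("KASH5") < 220:
            included, reason = False, "KASH5 whole-cell<220"
    meas.included = included
    meas.reason = reason
    return meas
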