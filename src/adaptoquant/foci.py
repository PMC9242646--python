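"""Telomeric focus quantification on chromosome spreads, and blot ratios.

Telomeric regions are the ends of the synaptonemal-complex axis (SYCP3)
signals.  Each focus is measured in a disk aperture with its local
background taken from a neighboring annulus (excluding pixels claimed by
other foci) and subtracted; corrected intensities are normalized to the
mean of a reference set (e.g. GFP-negative cells, or wild type).

Negative corrected intensities are retained, not clipped, so that group
means stay unbiased in low-signal conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "AxisTrace",
    "EndpointResult",
    "FocusMeasurement",
    "detect_axis_endpoints",
    "measure_focus",
    "normalize_foci",
    "blot_ratio",
]


@dataclass
class AxisTrace:
    """A traced synaptonemal-complex axis (polyline in pixel coordinates)."""

    id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValueError("an axis trace needs at least two vertices")

    @property
    def endpoints(self) -> np.ndarray:
        """The two telomeric points: first and last vertex, shape (2, 2)."""
        return np.stack([self.vertices[0], self.vertices[-1]])


@dataclass
class EndpointResult:
    """Detected telomeric points plus any closed-loop axes found."""

    points: np.ndarray  # (N, 2) x,y pixel coordinates
    n_closed_loops: int = 0


@dataclass
class FocusMeasurement:
    position: tuple[float, float]
    raw: float  # mean intensity in the aperture disk
    background: float  # mean intensity in the neighboring annulus
    corrected: float  # raw - background (may be negative)
    normalized: float | None = None  # corrected / reference mean


def _skeleton_endpoints(skel: np.ndarray):
    """Endpoint pixels (exactly one 8-neighbor) per skeleton component."""
    kernel = np.ones((3, 3))
    neighbor_count = ndimage.convolve(skel.astype(int), kernel, mode="constant") - skel
    endpoints = skel & (neighbor_count == 1)
    return endpoints


def _refine_endpoint(
    plane: np.ndarray, binary: np.ndarray, skel: np.ndarray, x: int, y: int, thr: float
) -> tuple[float, float]:
    """March a skeleton endpoint outward along the ridge to the signal edge.

    Skeletonization retracts line ends by up to the ridge half-width and can
    jog laterally off the ridge midline.  This estimates the local axis
    direction from the nearby skeleton pixels (principal component), walks
    outward while the thresholded signal persists, and re-centers the final
    point on the perpendicular intensity centroid.
    """
    h, w = binary.shape
    r = 5
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    ys, xs = np.nonzero(skel[y0:y1, x0:x1])
    if len(xs) < 2:
        return float(x), float(y)
    pts = np.stack([xs + x0, ys + y0], axis=1).astype(float)
    centroid = pts.mean(axis=0)
    u, _s, _vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = _vt[0]
    outward = np.array([x, y]) - centroid
    if np.dot(direction, outward) < 0:
        direction = -direction
    ux, uy = direction
    best = np.array([float(x), float(y)])
    for step in np.arange(0.25, 8.0, 0.25):
        px, py = x + ux * step, y + uy * step
        xi, yi = int(round(px)), int(round(py))
        if not (0 <= xi < w and 0 <= yi < h) or not binary[yi, xi]:
            break
        best = np.array([px, py])
    # lateral re-centering on the perpendicular intensity profile
    nx, ny = -uy, ux
    offsets = np.linspace(-2.0, 2.0, 17)
    sx = np.clip(best[0] + offsets * nx, 0, w - 1)
    sy = np.clip(best[1] + offsets * ny, 0, h - 1)
    vals = ndimage.map_coordinates(plane, np.stack([sy, sx]), order=1)
    wts = np.clip(vals - thr, 0.0, None)
    if wts.sum() > 0:
        shift = float(np.sum(offsets * wts) / wts.sum())
        best = best + shift * np.array([nx, ny])
    return float(best[0]), float(best[1])


def detect_axis_endpoints(
    source: np.ndarray | list,
    threshold: float | None = None,
) -> EndpointResult:
    """Locate telomeric points as the ends of the axis signals.

    With a list of :class:`AxisTrace` inputs, returns both endpoints of each
    trace.  With an image input, thresholds the plane (Otsu by default),
    skeletonizes the above-threshold axes, and returns the endpoints of each
    skeleton branch-free component; components without endpoints (closed
    loops) are counted in ``n_closed_loops`` rather than silently dropped.
    """
    if isinstance(source, (list, tuple)):
        if not source:
            return EndpointResult(points=np.empty((0, 2)))
        pts = np.concatenate([t.endpoints for t in source])
        return EndpointResult(points=pts)

    plane = np.asarray(source, dtype=float)
    thr = threshold_otsu(plane) if threshold is None else threshold
    binary = plane > thr
    skel = skeletonize(binary)
    endpoint_mask = _skeleton_endpoints(skel)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    points = []
    n_loops = 0
    for lab in range(1, n + 1):
        comp_eps = endpoint_mask & (labels == lab)
        ys, xs = np.nonzero(comp_eps)
        if len(xs) == 0:
            n_loops += 1
            continue
        for x, y in zip(xs, ys):
            points.append(_refine_endpoint(plane, binary, skel, int(x), int(y), thr))
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return EndpointResult(points=pts, n_closed_loops=n_loops)


def _distance_grid(shape, point):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - point[0], yy - point[1])


def measure_focus(
    plane: np.ndarray,
    point,
    pixel_size: float,
    aperture_radius: float = 0.4,
    bg_annulus: tuple[float, float] = (0.5, 0.8),
    other_points=None,
) -> FocusMeasurement:
    """Aperture intensity of one focus with local background subtraction.

    ``raw`` is the mean intensity in a disk of ``aperture_radius`` µm around
    ``point``; ``background`` is the mean over the ``bg_annulus`` (inner,
    outer) µm annulus excluding pixels inside any other focus's aperture;
    ``corrected = raw - background``.
    """
    plane = np.asarray(plane, dtype=float)
    inner, outer = bg_annulus
    if not (outer > inner >= aperture_radius):
        raise ValueError("annulus must satisfy outer > inner >= aperture_radius")
    r_ap = aperture_radius / pixel_size
    r_out = outer / pixel_size
    x, y = float(point[0]), float(point[1])
    if (x - r_ap < -0.5 or x + r_ap > plane.shape[1] - 0.5
            or y - r_ap < -0.5 or y + r_ap > plane.shape[0] - 0.5):
        raise ValueError("aperture out of bounds")
    d = _distance_grid(plane.shape, (x, y))
    aperture = d <= r_ap
    annulus = (d >= inner / pixel_size) & (d <= r_out)
    if other_points is not None:
        for other in other_points:
            if np.allclose(other, (x, y)):
                continue
            annulus &= _distance_grid(plane.shape, other) > r_ap
    if not aperture.any():
        raise ValueError("aperture contains no pixels")
    if not annulus.any():
        raise ValueError("background annulus fully occluded")
    raw = float(plane[aperture].mean())
    background = float(plane[annulus].mean())
    return FocusMeasurement(
        position=(x, y), raw=raw, background=background, corrected=raw - background
    )


def normalize_foci(
    measurements: list[FocusMeasurement],
    reference_measurements: list[FocusMeasurement],
) -> list[FocusMeasurement]:
    """Normalize corrected intensities to the reference mean.

    Each measurement's ``normalized`` field is its corrected intensity
    divided by the mean corrected intensity of the reference set (so the
    reference set itself normalizes to mean 1).  Measurements are updated in
    place and returned.
    """
    if not reference_measurements:
        raise ValueError("reference set is empty")
    ref_mean = float(np.mean([m.corrected for m in reference_measurements]))
    if ref_mean <= 0:
        raise ValueError("reference mean corrected intensity must be positive")
    for m in measurements:
        m.normalized = m.corrected / ref_mean
    return measurements


def blot_ratio(target_band, loading_band):
    """Densitometry ratio of a target band to its in-lane loading band.

    Scalars return the plain ratio.  Sequences are treated as replicates and
    return ``(ratios, mean, sem)`` with the standard error computed with the
    n-1 denominator.
    """
    target = np.atleast_1d(np.asarray(target_band, dtype=float))
    loading = np.atleast_1d(np.asarray(loading_band, dtype=float))
    if (loading <= 0).any():
        raise ValueError("loading band intensities must be positive")
    ratios = target / loading
    if ratios.size == 1:
        return float(ratios[0])
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
    return ratios, mean, sem
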