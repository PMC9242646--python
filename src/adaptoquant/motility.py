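"""Single-molecule TIRF motility analysis.

The pipeline mirrors standard kymograph-based practice for dynein-dynactin-
adaptor assays: a movie plus a microtubule polyline gives a kymograph
(space-time image); bright traces in the kymograph are segmented and linked
into per-particle events; events are classified as processive, diffusive, or
immotile; short events and bright aggregates are filtered; per-event velocity
and run length and per-field landing rate / percent-processive statistics are
reported.

Conventions
-----------
* Arclength bins are one pixel wide (bin size = pixel size in µm); frames and
  bins are 0-based; event frame spans are inclusive.
* Run length is the magnitude of the net arclength displacement; velocity is
  run length divided by event duration (pauses are not excised).
* Events that touch the first or last movie frame are flagged censored: they
  count toward landing rate and class fractions but are excluded from
  velocity / run-length statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from adaptoquant.core import MicrotubulePath, MovieStack

__all__ = [
    "Kymograph",
    "MotilityEvent",
    "EventMetrics",
    "FovSummary",
    "DetectionParams",
    "ClassifyParams",
    "build_kymograph",
    "trace_events",
    "classify_event",
    "filter_events",
    "event_metrics",
    "summarize_fov",
    "analyze_movie",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Kymograph:
    """Space-time image: rows are frames, columns are arclength bins."""

    matrix: np.ndarray
    bin_size: float  # µm per column
    path_id: str
    sampling_width: int  # pixels sampled perpendicular to the path
    frame_interval: float  # s per row

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D")

    @property
    def n_frames(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class MotilityEvent:
    """One particle trajectory on a microtubule path.

    ``positions`` holds the arclength (µm) of the intensity-weighted centroid
    at each frame from ``start_frame`` to ``end_frame`` inclusive.
    """

    path_id: str
    start_frame: int
    end_frame: int
    positions: np.ndarray  # µm, one entry per frame in the span
    mean_spot_intensity: float
    classification: str | None = None  # processive | diffusive | immotile
    aggregate_flag: bool = False
    censored: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if len(self.positions) != self.n_frames:
            raise ValueError("positions length must equal the frame span")

    @property
    def n_frames(self) -> int:
        """Number of frames in the (inclusive) span."""
        return self.end_frame - self.start_frame + 1

    @property
    def net_displacement(self) -> float:
        """Signed net arclength displacement in µm."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def excursion(self) -> float:
        """Total arclength excursion (max - min position) in µm."""
        return float(self.positions.max() - self.positions.min())


@dataclass
class EventMetrics:
    duration: float  # s
    run_length: float  # µm (net displacement magnitude)
    velocity: float  # µm/s


@dataclass
class FovSummary:
    """Per-field-of-view motility summary."""

    n_processive: int
    n_diffusive: int
    n_immotile: int
    total_mt_length: float  # µm
    movie_duration: float  # minutes
    motor_concentration: float | None  # pM, optional
    landing_rate: float  # events / (µm · min [· pM])
    percent_processive: float

    @property
    def n_total(self) -> int:
        return self.n_processive + self.n_diffusive + self.n_immotile


@dataclass
class DetectionParams:
    """Parameters for kymograph trace detection and linking."""

    threshold_sigma: float = 4.0  # spot threshold above background, in robust SDs
    max_jump_bins: float = 5.0  # max per-frame centroid jump when linking
    max_gap_frames: int = 1  # frames a track may go undetected before closing
    min_event_frames: int = 2  # discard fragments shorter than this


@dataclass
class ClassifyParams:
    """Thresholds for the processive/diffusive/immotile decision.

    The numeric criteria are a declared convention (typical for ~0.16 µm
    pixels with sub-pixel centroiding); all are exposed here.
    """

    min_net_displacement: float = 0.4  # µm
    min_consistency: float = 0.7  # fraction of steps sharing the net sign
    immobile_radius: float = 0.2  # µm total excursion


# ---------------------------------------------------------------------------
# kymograph construction
# ---------------------------------------------------------------------------


def build_kymograph(movie: MovieStack, path: MicrotubulePath, width: int = 5) -> Kymograph:
    """Build a kymograph by sampling a transect perpendicular to the path.

    Each (frame, arclength-bin) cell is the maximum bilinearly-interpolated
    intensity over a ``width``-pixel transect centred on the path at that
    arclength.  The maximum (rather than the mean) preserves dim moving
    spots against the flat transect background.

    Parameters
    ----------
    movie
        Calibrated movie stack.
    path
        Microtubule polyline in pixel coordinates; must lie inside the frame.
    width
        Odd transect width in pixels.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    n_bins = math.ceil(path.length_px)  # bin size = 1 px = pixel_size µm
    if n_bins < 1:
        raise ValueError("path too short to bin")

    h, w = movie.frames.shape[1:]
    # bins anchored at integer arclengths: a spot at arclength s (px) is
    # brightest in column floor(s)
    centers = np.arange(n_bins, dtype=float)
    pts = path.point_at(centers)  # (n_bins, 2) x,y
    normals = path.normal_at(centers)
    offsets = np.arange(width) - (width - 1) / 2.0
    # sample coordinates: (n_bins, width, 2)
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    if (coords[..., 0].min() < -0.5 or coords[..., 0].max() > w - 0.5
            or coords[..., 1].min() < -0.5 or coords[..., 1].max() > h - 0.5):
        raise ValueError("path (with transect width) exits the image bounds")
    # map_coordinates wants (row, col) = (y, x)
    sample = np.stack([coords[..., 1].ravel(), coords[..., 0].ravel()])

    kymo = np.empty((movie.n_frames, n_bins), dtype=float)
    for t in range(movie.n_frames):
        vals = ndimage.map_coordinates(
            movie.frames[t].astype(float), sample, order=1, mode="nearest"
        ).reshape(n_bins, width)
        kymo[t] = vals.max(axis=1)
    return Kymograph(
        matrix=kymo,
        bin_size=movie.pixel_size,
        path_id=path.id,
        sampling_width=width,
        frame_interval=movie.frame_interval,
    )


# ---------------------------------------------------------------------------
# event tracing
# ---------------------------------------------------------------------------


def _detect_spots(row: np.ndarray, background: float, threshold: float):
    """Segment one kymograph row into spot candidates.

    Returns a list of (centroid_bin, peak_intensity) for each contiguous run
    of above-threshold bins, with background-subtracted intensity weighting.
    """
    above = row > threshold
    if not above.any():
        return []
    labels, n = ndimage.label(above)
    out = []
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)[0]
        wts = row[idx] - background
        wts = np.clip(wts, 1e-12, None)
        centroid = float(np.sum(idx * wts) / np.sum(wts))
        out.append((centroid, float(row[idx].max())))
    return out


def trace_events(kymo: Kymograph, detection: DetectionParams | None = None) -> list[MotilityEvent]:
    """Trace per-particle events in a kymograph.

    Spots are segmented per frame (row) by thresholding above a robust
    background estimate; spots in consecutive frames are linked greedily by
    nearest-centroid distance, allowing short detection gaps.  Each event's
    per-frame positions are intensity-weighted centroids (gap frames are
    linearly interpolated).  Events touching the first or last frame are
    flagged censored.
    """
    detection = detection or DetectionParams()
    m = kymo.matrix
    background = float(np.median(m))
    mad = float(np.median(np.abs(m - background)))
    noise = 1.4826 * mad if mad > 0 else float(m.std())
    if noise == 0:
        return []  # featureless (constant) kymograph
    threshold = background + detection.threshold_sigma * noise

    # active tracks: dict id -> dict(frames=[], positions=[], peaks=[], last_frame)
    active: list[dict] = []
    finished: list[dict] = []
    for t in range(kymo.n_frames):
        cands = _detect_spots(m[t], background, threshold)
        unmatched = set(range(len(cands)))
        # candidate-track pairs sorted by distance, greedy assignment
        pairs = []
        for ti, tr in enumerate(active):
            for ci in unmatched:
                d = abs(cands[ci][0] - tr["positions"][-1])
                if d <= detection.max_jump_bins:
                    pairs.append((d, ti, ci))
        pairs.sort(key=lambda p: p[0])
        used_tracks: set[int] = set()
        used_cands: set[int] = set()
        for d, ti, ci in pairs:
            if ti in used_tracks or ci in used_cands:
                continue
            tr = active[ti]
            tr["frames"].append(t)
            tr["positions"].append(cands[ci][0])
            tr["peaks"].append(cands[ci][1])
            used_tracks.add(ti)
            used_cands.add(ci)
        # retire tracks that exceeded the allowed gap
        still = []
        for tr in active:
            if t - tr["frames"][-1] > detection.max_gap_frames:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        # new tracks from unmatched candidates
        for ci in range(len(cands)):
            if ci not in used_cands:
                active.append({"frames": [t], "positions": [cands[ci][0]], "peaks": [cands[ci][1]]})
    finished.extend(active)

    events = []
    for tr in finished:
        frames = np.asarray(tr["frames"])
        if frames[-1] - frames[0] + 1 < detection.min_event_frames:
            continue
        full = np.arange(frames[0], frames[-1] + 1)
        pos_bins = np.interp(full, frames, tr["positions"])  # fill gap frames
        events.append(
            MotilityEvent(
                path_id=kymo.path_id,
                start_frame=int(frames[0]),
                end_frame=int(frames[-1]),
                positions=pos_bins * kymo.bin_size,
                mean_spot_intensity=float(np.mean(tr["peaks"])),
                censored=(frames[0] == 0 or frames[-1] == kymo.n_frames - 1),
            )
        )
    events.sort(key=lambda e: (e.start_frame, e.positions[0]))
    return events


# ---------------------------------------------------------------------------
# classification, filtering, metrics
# ---------------------------------------------------------------------------


def classify_event(
    event: MotilityEvent,
    criteria: ClassifyParams | None = None,
) -> str:
    """Assign an event to processive / diffusive / immotile.

    Processive: net displacement magnitude at least ``min_net_displacement``
    and at least ``min_consistency`` of frame-to-frame steps share the sign
    of the net displacement.  Immotile: total excursion at most
    ``immobile_radius``.  Everything else is diffusive.
    """
    criteria = criteria or ClassifyParams()
    if event.n_frames < 2:
        raise ValueError("cannot classify a single-frame event")
    net = event.net_displacement
    steps = np.diff(event.positions)
    if abs(net) >= criteria.min_net_displacement and len(steps) > 0:
        consistency = float(np.mean(np.sign(steps) == np.sign(net)))
        if consistency >= criteria.min_consistency:
            return "processive"
    if event.excursion <= criteria.immobile_radius:
        return "immotile"
    return "diffusive"


def filter_events(
    events: list[MotilityEvent],
    min_frames: int = 4,
    aggregate_multiplier: float = 3.0,
) -> tuple[list[MotilityEvent], list[tuple[MotilityEvent, str]]]:
    """Apply the run-length and aggregate exclusion rules.

    Events spanning ``min_frames`` or fewer frames are rejected (only runs
    *longer* than the threshold are analyzed; at a 300 ms frame interval the
    default of four frames corresponds to a 1.2 s duration cut).  Events whose
    mean spot intensity exceeds ``aggregate_multiplier`` times the median
    event intensity in the field are rejected as bright aggregates and also
    flagged on the event.

    Returns ``(kept, rejected)`` where each rejection carries a
    machine-readable reason (``"too_short"`` or ``"aggregate"``); the two
    lists partition the input.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if not events:
        return [], []
    median_intensity = float(np.median([e.mean_spot_intensity for e in events]))
    kept: list[MotilityEvent] = []
    rejected: list[tuple[MotilityEvent, str]] = []
    for e in events:
        if e.n_frames <= min_frames:
            rejected.append((e, "too_short"))
        elif median_intensity > 0 and e.mean_spot_intensity > aggregate_multiplier * median_intensity:
            e.aggregate_flag = True
            rejected.append((e, "aggregate"))
        else:
            kept.append(e)
    return kept, rejected


def event_metrics(event: MotilityEvent, frame_interval: float) -> EventMetrics:
    """Duration, run length and velocity of a processive event.

    Duration is the frame span times the frame interval; run length is the
    magnitude of the net arclength displacement; velocity is run length over
    duration (net-displacement convention, pauses included).
    """
    if event.classification != "processive":
        raise ValueError("metrics are defined for processive events only")
    duration = (event.end_frame - event.start_frame) * frame_interval
    run_length = abs(event.net_displacement)
    return EventMetrics(duration=duration, run_length=run_length, velocity=run_length / duration)


def summarize_fov(
    events: list[MotilityEvent],
    paths: list[MicrotubulePath],
    movie: MovieStack,
    concentration: float | None = None,
) -> FovSummary:
    """Per-field landing rate and percent-processive summary.

    Landing rate divides the total number of analyzed events by the summed
    microtubule length (µm) times the movie duration (min), and additionally
    by the motor concentration (pM) when given.  Percent processive is the
    processive share of all classified events.
    """
    if not paths:
        raise ValueError("at least one microtubule path is required")
    total_len = sum(p.length_um(movie.pixel_size) for p in paths)
    if total_len <= 0:
        raise ValueError("total path length must be positive")
    counts = {"processive": 0, "diffusive": 0, "immotile": 0}
    for e in events:
        if e.classification not in counts:
            raise ValueError(f"event has no valid classification: {e.classification!r}")
        counts[e.classification] += 1
    n_total = sum(counts.values())
    duration_min = movie.duration_min
    rate = n_total / (total_len * duration_min)
    if concentration is not None:
        rate /= concentration
    pct = 100.0 * counts["processive"] / n_total if n_total else 0.0
    return FovSummary(
        n_processive=counts["processive"],
        n_diffusive=counts["diffusive"],
        n_immotile=counts["immotile"],
        total_mt_length=total_len,
        movie_duration=duration_min,
        motor_concentration=concentration,
        landing_rate=rate,
        percent_processive=pct,
    )


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------


def analyze_movie(
    movie: MovieStack,
    paths: list[MicrotubulePath],
    width: int = 5,
    detection: DetectionParams | None = None,
    criteria: ClassifyParams | None = None,
    min_frames: int = 4,
    aggregate_multiplier: float = 3.0,
    concentration: float | None = None,
):
    """Run the full kymograph pipeline on one field of view.

    Returns ``(kept_events, rejected, metrics, summary)`` where ``metrics``
    holds an :class:`EventMetrics` for every kept, uncensored processive
    event.
    """
    all_events: list[MotilityEvent] = []
    for p in paths:
        kymo = build_kymograph(movie, p, width=width)
        all_events.extend(trace_events(kymo, detection))
    kept, rejected = filter_events(all_events, min_frames, aggregate_multiplier)
    for e in kept:
        e.classification = classify_event(e, criteria)
    metrics = [
        event_metrics(e, movie.frame_interval)
        for e in kept
        if e.classification == "processive" and not e.censored
    ]
    summary = summarize_fov(kept, paths, movie, concentration)
    return kept, rejected, metrics, summary
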