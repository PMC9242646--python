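"""Synthetic single-molecule TIRF motility movies.

Particles land on microtubule paths as a Poisson process, draw a motility
class (processive / diffusive / immotile), and are rendered frame by frame
as 2-D Gaussian spots over Gaussian camera background.  Every simulated
event is recorded in the exported ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from adaptoquant.core import MicrotubulePath, MovieStack
from adaptoquant.synthetic.config import GroundTruth, SimulationConfig

__all__ = ["simulate_tirf_movie", "straight_paths"]


def straight_paths(
    n: int,
    field_size: tuple[int, int],
    margin: int = 12,
) -> list[MicrotubulePath]:
    """Evenly spaced horizontal microtubule paths spanning the field."""
    h, w = field_size
    ys = np.linspace(margin, h - 1 - margin, n)
    return [
        MicrotubulePath(f"mt{i}", np.array([[margin, y], [w - 1 - margin, y]], dtype=float))
        for i, y in enumerate(ys)
    ]


def _draw_speed(rng: np.random.Generator, dist: tuple[str, float, float]) -> float:
    # normal truncated at zero by redraw
    _, loc, scale = dist
    for _ in range(1000):
        v = rng.normal(loc, scale)
        if v > 0:
            return float(v)
    raise RuntimeError("could not draw a positive speed")


def _simulate_path_events(
    rng: np.random.Generator, config: SimulationConfig, path: MicrotubulePath
) -> list[dict]:
    """Draw all events landing on one path over the movie."""
    L = path.length_um(config.pixel_size)
    dt = config.frame_interval
    duration_min = config.movie_duration / 60.0
    n_events = rng.poisson(config.landing_rate_true * L * duration_min)
    classes = np.array(["processive", "diffusive", "immotile"])
    events = []
    for _ in range(n_events):
        birth = rng.uniform(0.0, config.movie_duration)
        cls = str(rng.choice(classes, p=np.asarray(config.state_fractions)))
        aggregate = bool(rng.random() < config.aggregate_fraction)
        start = rng.uniform(0.0, L)
        speed = _draw_speed(rng, config.speed_distribution)
        run_length = rng.exponential(config.run_length_mean)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        bleach = (
            rng.exponential(1.0 / config.bleach_rate) if config.bleach_rate > 0 else np.inf
        )

        birth_frame = int(np.ceil(birth / dt))
        if birth_frame >= config.n_frames:
            continue
        if cls == "processive":
            dist_to_end = (L - start) if direction > 0 else start
            lifetime = min(run_length, dist_to_end) / speed
        else:
            lifetime = rng.exponential(config.dwell_mean)
        lifetime = min(lifetime, bleach)
        death_frame = int(np.floor(min(birth + lifetime, config.movie_duration - dt) / dt))
        death_frame = min(death_frame, config.n_frames - 1)
        if death_frame < birth_frame:
            continue
        n_fr = death_frame - birth_frame + 1
        times = np.arange(birth_frame, death_frame + 1) * dt - birth
        if cls == "processive":
            pos = start + direction * speed * times
            pos = np.clip(pos, 0.0, L)
        elif cls == "immotile":
            pos = np.full(n_fr, start)
        else:  # diffusive: reflecting 1-D random walk along the path
            steps = rng.normal(0.0, config.diffusion_step_sd, n_fr)
            steps[0] = 0.0
            pos = start + np.cumsum(steps)
            # reflect at the path ends
            pos = np.abs(pos)
            pos = L - np.abs(L - pos)
        events.append(
            {
                "path_id": path.id,
                "birth_frame": birth_frame,
                "death_frame": death_frame,
                "class": cls,
                "speed_um_s": speed if cls == "processive" else np.nan,
                "run_length_um": float(abs(pos[-1] - pos[0])) if cls == "processive" else np.nan,
                "aggregate": aggregate,
                "positions_um": pos,
            }
        )
    return events


def simulate_tirf_movie(
    config: SimulationConfig, paths: list[MicrotubulePath]
) -> tuple[MovieStack, GroundTruth]:
    """Simulate a TIRF motility movie on the given microtubule paths.

    Landing is a Poisson process at ``landing_rate_true`` events per µm per
    minute on each path; each particle draws its class from
    ``state_fractions``.  Processive particles advance at their drawn speed
    until their exponential run length (or the path end, the movie end, or
    photobleaching) terminates the run; diffusive particles perform a
    reflecting 1-D random walk along the path; immotile particles hold
    position for an exponential dwell.  Spots are rendered as 2-D Gaussians
    of width ``psf_sigma`` over Gaussian background noise; aggregates carry
    ``aggregate_amplitude_multiplier`` times the spot amplitude.

    Returns the calibrated :class:`MovieStack` and a :class:`GroundTruth`
    whose ``events`` table lists every simulated event.
    """
    if not paths:
        raise ValueError("at least one microtubule path is required")
    h, w = config.field_size
    for p in paths:
        v = p.vertices
        if v[:, 0].min() < 0 or v[:, 0].max() > w - 1 or v[:, 1].min() < 0 or v[:, 1].max() > h - 1:
            raise ValueError(f"path {p.id} lies outside the field")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(paths) + 1)
    bg_rng = np.random.default_rng(children[0])

    all_events: list[dict] = []
    for p, child in zip(paths, children[1:]):
        all_events.extend(_simulate_path_events(np.random.default_rng(child), config, p))

    # per-frame render lists: frame -> [(x_px, y_px, amplitude), ...]
    path_by_id = {p.id: p for p in paths}
    per_frame: dict[int, list[tuple[float, float, float]]] = {}
    for ev in all_events:
        p = path_by_id[ev["path_id"]]
        amp = config.spot_amplitude * (
            config.aggregate_amplitude_multiplier if ev["aggregate"] else 1.0
        )
        s_px = np.asarray(ev["positions_um"]) / config.pixel_size
        pts = p.point_at(s_px)
        for k, f in enumerate(range(ev["birth_frame"], ev["death_frame"] + 1)):
            per_frame.setdefault(f, []).append((pts[k, 0], pts[k, 1], amp))

    sigma_px = config.psf_sigma / config.pixel_size
    win = max(2, int(np.ceil(4 * sigma_px)))
    frames = np.empty((config.n_frames, h, w), dtype=np.float32)
    for t in range(config.n_frames):
        frame = bg_rng.normal(config.background_mean, config.background_sd, (h, w))
        for x, y, amp in per_frame.get(t, ()):
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(0, xi - win), min(w, xi + win + 1)
            y0, y1 = max(0, yi - win), min(h, yi + win + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1) - x
            ys = np.arange(y0, y1) - y
            g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
            frame[y0:y1, x0:x1] += amp * g
        frames[t] = frame

    truth_rows = [{k: v for k, v in ev.items() if k != "positions_um"} for ev in all_events]
    truth = GroundTruth(
        events=pd.DataFrame(
            truth_rows,
            columns=[
                "path_id", "birth_frame", "death_frame", "class",
                "speed_um_s", "run_length_um", "aggregate",
            ],
        ),
        config={"seed": config.seed, "kind": "tirf_movie"},
    )
    movie = MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        label=f"synthetic TIRF (seed {config.seed})",
    )
    return movie, truth
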