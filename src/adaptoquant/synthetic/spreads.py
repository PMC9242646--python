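"""Synthetic spermatocyte spread images with telomeric foci.

Each simulated cell carries curvilinear synaptonemal-complex axes (the
SYCP3 channel); the p150 (dynactin) and GFP channels carry Gaussian foci at
the axis endpoints over a spatially varying background.  Mutant-expressing
(GFP-positive) cells render p150 foci at a configurable fraction of the
reference amplitude; GFP-negative reference cells carry the full reference
amplitude and no GFP signal.  Ground truth records every focus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from adaptoquant.foci import AxisTrace
from adaptoquant.synthetic.config import GroundTruth, SimulationConfig

__all__ = ["CellSpread", "simulate_spermatocyte_spread"]


@dataclass
class CellSpread:
    """One spread cell: channel planes, axis traces, and GFP status."""

    cell_id: str
    channels: dict  # 'SYCP3', 'p150', 'GFP' -> 2-D plane
    pixel_size: float
    axes: list  # list[AxisTrace]
    gfp_positive: bool


def _random_axis(
    rng: np.random.Generator, shape, margin: float, length_px: tuple[float, float]
) -> np.ndarray:
    """A gently curved quadratic Bezier polyline inside the image."""
    h, w = shape
    for _ in range(200):
        p0 = rng.uniform([margin, margin], [w - margin, h - margin])
        theta = rng.uniform(0, 2 * np.pi)
        L = rng.uniform(*length_px)
        p2 = p0 + L * np.array([np.cos(theta), np.sin(theta)])
        if not (margin <= p2[0] <= w - margin and margin <= p2[1] <= h - margin):
            continue
        normal = np.array([-np.sin(theta), np.cos(theta)])
        p1 = (p0 + p2) / 2 + rng.normal(0, L / 8) * normal
        t = np.linspace(0, 1, 40)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        if (pts[:, 0].min() >= margin / 2 and pts[:, 0].max() <= w - margin / 2
                and pts[:, 1].min() >= margin / 2 and pts[:, 1].max() <= h - margin / 2):
            return pts
    raise RuntimeError("could not place an axis inside the field")


def _render_axes(shape, axes, amplitude: float, sigma_px: float) -> np.ndarray:
    plane = np.zeros(shape)
    for ax in axes:
        # densely resample the polyline and accumulate, then blur to a ridge
        seg = np.diff(ax.vertices, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        n_samples = max(2, int(seglen.sum() * 2))
        t = np.linspace(0, 1, n_samples)
        cum = np.concatenate([[0], np.cumsum(seglen)]) / seglen.sum()
        xs = np.interp(t, cum, ax.vertices[:, 0])
        ys = np.interp(t, cum, ax.vertices[:, 1])
        ix = np.clip(np.round(xs).astype(int), 0, shape[1] - 1)
        iy = np.clip(np.round(ys).astype(int), 0, shape[0] - 1)
        np.add.at(plane, (iy, ix), 1.0)
    plane = ndimage.gaussian_filter(plane, sigma_px)
    if plane.max() > 0:
        plane *= amplitude / plane.max()
    return plane


def _add_gaussian_spots(plane, points, amplitudes, sigma_px):
    h, w = plane.shape
    win = max(2, int(np.ceil(4 * sigma_px)))
    for (x, y), amp in zip(points, amplitudes):
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(0, xi - win), min(w, xi + win + 1)
        y0, y1 = max(0, yi - win), min(h, yi + win + 1)
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        plane[y0:y1, x0:x1] += amp * np.exp(
            -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2)
        )


def simulate_spermatocyte_spread(
    config: SimulationConfig,
    n_cells: int,
    n_foci_per_cell: int,
    focus_fraction_of_reference: float,
    n_reference_cells: int | None = None,
    reference_amplitude: float = 600.0,
    gfp_amplitude: float = 400.0,
    amplitude_cv: float = 0.1,
    field_px: int = 192,
    aperture_radius: float = 0.4,
    min_separation_um: float = 2.0,
    axis_amplitude: float = 350.0,
) -> tuple[list[CellSpread], GroundTruth]:
    """Simulate spread cells with telomeric foci of known relative intensity.

    ``n_cells`` GFP-positive cells carry p150 foci at
    ``focus_fraction_of_reference`` times the reference amplitude (with
    per-focus lognormal-free Gaussian jitter of ``amplitude_cv`` relative
    sigma) at the endpoints of ``n_foci_per_cell / 2`` axes; matched
    GFP-negative cells (``n_reference_cells``, default equal) carry the
    reference amplitude and no GFP.  Backgrounds vary smoothly across each
    field.  Axes are rejected and resampled if any two foci would fall
    closer than one aperture diameter (and by default a more conservative
    ``min_separation_um``).

    Returns the cell list and ground truth with one row per focus.
    """
    if n_foci_per_cell % 2 != 0:
        raise ValueError("n_foci_per_cell must be even (two ends per axis)")
    if focus_fraction_of_reference < 0:
        raise ValueError("focus fraction must be >= 0")
    if n_reference_cells is None:
        n_reference_cells = n_cells
    rng = np.random.default_rng(config.seed)
    n_axes = n_foci_per_cell // 2
    sigma_px = config.psf_sigma / config.pixel_size
    min_sep_px = max(2 * aperture_radius, min_separation_um) / config.pixel_size
    shape = (field_px, field_px)

    cells: list[CellSpread] = []
    rows = []
    statuses = [True] * n_cells + [False] * n_reference_cells
    axis_clearance_px = 6.0  # axes must not cross or touch (spreads resolve them)
    for idx, gfp_positive in enumerate(statuses):
        # place axes one by one, keeping bodies and endpoints separated
        axes: list[AxisTrace] = []
        placed_pts: list[np.ndarray] = []
        attempts = 0
        while len(axes) < n_axes:
            attempts += 1
            if attempts > 2000:
                raise RuntimeError("could not place axes with separated endpoints")
            pts = _random_axis(rng, shape, 18, (35, 60))
            if placed_pts:
                prev = np.concatenate(placed_pts)
                d_body = np.linalg.norm(pts[:, None, :] - prev[None, :, :], axis=-1)
                if d_body.min() < axis_clearance_px:
                    continue
                prev_eps = np.concatenate([ax.endpoints for ax in axes])
                new_eps = np.stack([pts[0], pts[-1]])
                d_ep = np.linalg.norm(new_eps[:, None, :] - prev_eps[None, :, :], axis=-1)
                if d_ep.min() < min_sep_px:
                    continue
            if np.linalg.norm(pts[0] - pts[-1]) < min_sep_px:
                continue
            axes.append(AxisTrace(f"cell{idx}_ax{len(axes)}", pts))
            placed_pts.append(pts)

        # smoothly varying background per channel
        def background():
            gx, gy = rng.normal(0, 0.05, 2)
            base = config.background_mean * (
                1.0
                + gx * (np.arange(shape[1]) - shape[1] / 2)[None, :] / shape[1]
                + gy * (np.arange(shape[0]) - shape[0] / 2)[:, None] / shape[0]
            )
            return base + rng.normal(0.0, config.background_sd, shape)

        sycp3 = background() + _render_axes(shape, axes, axis_amplitude, sigma_px)
        p150 = background()
        gfp = background()

        base_amp = reference_amplitude * (
            focus_fraction_of_reference if gfp_positive else 1.0
        )
        for ax in axes:
            for end in ax.endpoints:
                amp = base_amp * max(0.0, 1.0 + rng.normal(0.0, amplitude_cv)) if base_amp > 0 else 0.0
                _add_gaussian_spots(p150, [end], [amp], sigma_px)
                g_amp = 0.0
                if gfp_positive:
                    g_amp = gfp_amplitude * max(0.0, 1.0 + rng.normal(0.0, amplitude_cv))
                    _add_gaussian_spots(gfp, [end], [g_amp], sigma_px)
                rows.append(
                    {
                        "cell_id": f"cell{idx}",
                        "axis_id": ax.id,
                        "x_px": float(end[0]),
                        "y_px": float(end[1]),
                        "p150_amplitude": amp,
                        "gfp_amplitude": g_amp,
                        "background_mean": config.background_mean,
                        "is_reference": not gfp_positive,
                    }
                )
        cells.append(
            CellSpread(
                cell_id=f"cell{idx}",
                channels={"SYCP3": sycp3, "p150": p150, "GFP": gfp},
                pixel_size=config.pixel_size,
                axes=axes,
                gfp_positive=gfp_positive,
            )
        )
    truth = GroundTruth(
        foci=pd.DataFrame(rows), config={"seed": config.seed, "kind": "spermatocyte_spread"}
    )
    return cells, truth
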