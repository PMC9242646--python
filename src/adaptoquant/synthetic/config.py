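"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SimulationConfig:
    """Conditions for the synthetic acquisitions.

    Defaults emulate the single-molecule TIRF assay conditions used for
    purified dynein-dynactin-adaptor reconstitutions: 300 ms frame interval,
    3 min movies, sub-pM motor concentrations on an EMCCD at 100x (0.16
    µm/pixel, diffraction-limited PSF of sigma 0.13 µm).  The IP-TIRF variant
    uses a 500 ms interval.

    Parameters
    ----------
    seed
        Top-level random seed; fully determines every output.
    pixel_size
        µm per pixel.
    frame_interval
        s per frame.
    movie_duration
        Total movie length in s.
    field_size
        (height, width) in pixels.
    motor_concentration
        Motor concentration in pM, or None when not applicable.
    landing_rate_true
        New events per µm of microtubule per minute.
    state_fractions
        (processive, diffusive, immotile) proportions; must sum to 1.
    speed_distribution
        ("normal", loc, scale) in µm/s for processive speeds (truncated at 0).
    run_length_mean
        Mean exponential run length in µm for processive events.
    psf_sigma
        Gaussian PSF sigma in µm.
    background_mean, background_sd, spot_amplitude
        Camera background statistics and single-spot peak amplitude
        (arbitrary intensity units).
    aggregate_fraction
        Fraction of landed particles rendered as bright aggregates.
    aggregate_amplitude_multiplier
        Amplitude multiplier applied to aggregates.
    dwell_mean
        Mean exponential dwell (s) of diffusive and immotile events.
    diffusion_step_sd
        Per-frame 1-D random-walk step sigma (µm) for diffusive events.
    bleach_rate
        Photobleaching rate per second (exponential survival); 0 disables.
    """

    seed: int = 0
    pixel_size: float = 0.16
    frame_interval: float = 0.3
    movie_duration: float = 180.0
    field_size: tuple[int, int] = (256, 256)
    motor_concentration: float | None = None
    landing_rate_true: float = 0.1
    state_fractions: tuple[float, float, float] = (0.6, 0.25, 0.15)
    speed_distribution: tuple[str, float, float] = ("normal", 0.5, 0.1)
    run_length_mean: float = 3.0
    psf_sigma: float = 0.13
    background_mean: float = 100.0
    background_sd: float = 8.0
    spot_amplitude: float = 300.0
    aggregate_fraction: float = 0.0
    aggregate_amplitude_multiplier: float = 10.0
    dwell_mean: float = 5.0
    diffusion_step_sd: float = 0.08
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        if any(f < 0 for f in self.state_fractions):
            raise ValueError("state_fractions must be nonnegative")
        for name in ("pixel_size", "frame_interval", "movie_duration",
                     "psf_sigma", "spot_amplitude", "run_length_mean", "dwell_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("landing_rate_true", "background_mean", "background_sd",
                     "aggregate_fraction", "bleach_rate", "diffusion_step_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.aggregate_fraction > 1:
            raise ValueError("aggregate_fraction must be <= 1")
        if min(self.field_size) < 8:
            raise ValueError("field too small")
        if self.speed_distribution[0] != "normal":
            raise ValueError("only a normal speed distribution family is supported")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_duration / self.frame_interval))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=2)


@dataclass
class GroundTruth:
    """Ground-truth records exported alongside each synthetic dataset.

    Only the tables relevant to the generator that produced the object are
    populated: ``events`` (one row per simulated motility event), ``cells``
    (one row per simulated cell), ``foci`` (one row per simulated telomeric
    focus), ``binding_params`` (the binding model used) and
    ``species_masses`` (kDa per species).  ``config`` echoes the generating
    configuration.
    """

    events: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    foci: pd.DataFrame | None = None
    binding_params: dict | None = None
    species_masses: dict | None = None
    config: dict = field(default_factory=dict)

    def save(self, directory: str | Path, stem: str = "truth") -> None:
        """Write populated tables as CSV and the config echo as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("events", "cells", "foci"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(directory / f"{stem}_{name}.csv", index=False)
        meta = {"config": self.config}
        if self.binding_params is not None:
            meta["binding_params"] = self.binding_params
        if self.species_masses is not None:
            meta["species_masses"] = self.species_masses
        (directory / f"{stem}_meta.json").write_text(
            json.dumps(meta, default=_json_default, indent=2)
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (tuple, np.ndarray)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
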