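"""Readers and writers for the standard on-disk formats.

Movies and kymographs travel as multi-page TIFF with the physical
calibration embedded as JSON in the image description; polylines (paths and
axis traces), events, measurements and titration tables travel as CSV with
unit-annotated headers; protocols as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from adaptoquant.binding import ITCExperiment, ITCProtocol, MalsTrace
from adaptoquant.core import MicrotubulePath, MovieStack
from adaptoquant.foci import AxisTrace, FocusMeasurement
from adaptoquant.motility import EventMetrics, Kymograph, MotilityEvent

__all__ = [
    "write_movie", "read_movie",
    "write_kymograph",
    "write_paths", "read_paths",
    "write_events", "write_metrics",
    "write_itc", "read_itc",
    "write_mals", "read_mals",
    "write_foci",
]


# -- TIFF -------------------------------------------------------------------


def write_movie(path: str | Path, movie: MovieStack) -> None:
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "label": movie.label,
    }
    tifffile.imwrite(
        path, movie.frames, description=json.dumps(meta), photometric="minisblack"
    )


def read_movie(path: str | Path) -> MovieStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    return MovieStack(
        frames=frames,
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        label=meta.get("label", ""),
    )


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    meta = {
        "bin_size_um": kymo.bin_size,
        "frame_interval_s": kymo.frame_interval,
        "path_id": kymo.path_id,
        "sampling_width_px": kymo.sampling_width,
    }
    tifffile.imwrite(
        path, kymo.matrix.astype(np.float32), description=json.dumps(meta),
        photometric="minisblack",
    )


# -- polylines --------------------------------------------------------------


def write_paths(path: str | Path, paths: list[MicrotubulePath]) -> None:
    rows = []
    for p in paths:
        for i, (x, y) in enumerate(p.vertices):
            rows.append({"path_id": p.id, "vertex_index": i, "x_px": x, "y_px": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths(path: str | Path) -> list[MicrotubulePath]:
    df = pd.read_csv(path)
    out = []
    for pid, sub in df.groupby("path_id", sort=False):
        sub = sub.sort_values("vertex_index")
        out.append(MicrotubulePath(str(pid), sub[["x_px", "y_px"]].to_numpy()))
    return out


# -- motility tables --------------------------------------------------------


def write_events(path: str | Path, events: list[MotilityEvent]) -> None:
    rows = [
        {
            "path_id": e.path_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "class": e.classification,
            "net_displacement_um": e.net_displacement,
            "mean_spot_intensity": e.mean_spot_intensity,
            "aggregate": e.aggregate_flag,
            "censored": e.censored,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metrics(path: str | Path, metrics: list[EventMetrics]) -> None:
    pd.DataFrame(
        [
            {"duration_s": m.duration, "run_length_um": m.run_length,
             "velocity_um_s": m.velocity}
            for m in metrics
        ]
    ).to_csv(path, index=False)


# -- ITC --------------------------------------------------------------------


def write_itc(csv_path: str | Path, experiment: ITCExperiment,
              protocol_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {
            "injection_index": np.arange(1, experiment.protocol.n_injections + 1),
            "volume_ul": experiment.protocol.injection_volumes,
            "heat_ucal": experiment.heats,
        }
    ).to_csv(csv_path, index=False)
    if protocol_path is not None:
        p = experiment.protocol
        Path(protocol_path).write_text(json.dumps({
            "cell_concentration_uM": p.cell_concentration,
            "syringe_concentration_uM": p.syringe_concentration,
            "cell_volume_ul": p.cell_volume,
            "temperature_C": p.temperature,
        }, indent=2))


def read_itc(csv_path: str | Path, protocol_path: str | Path) -> ITCExperiment:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(protocol_path).read_text())
    protocol = ITCProtocol(
        cell_concentration=meta["cell_concentration_uM"],
        syringe_concentration=meta["syringe_concentration_uM"],
        cell_volume=meta["cell_volume_ul"],
        injection_volumes=df["volume_ul"].to_numpy(),
        temperature=meta.get("temperature_C", 20.0),
    )
    return ITCExperiment(protocol=protocol, heats=df["heat_ucal"].to_numpy())


# -- MALS -------------------------------------------------------------------


def write_mals(path: str | Path, trace: MalsTrace) -> None:
    pd.DataFrame(
        {
            "volume_ml": trace.volume,
            "concentration_mg_per_ml": trace.concentration,
            "scattering": trace.scattering,
        }
    ).to_csv(path, index=False)


def read_mals(path: str | Path, dn_dc: float = 0.185, calibration: float = 1.0) -> MalsTrace:
    df = pd.read_csv(path)
    return MalsTrace(
        volume=df["volume_ml"].to_numpy(),
        concentration=df["concentration_mg_per_ml"].to_numpy(),
        scattering=df["scattering"].to_numpy(),
        dn_dc=dn_dc,
        calibration=calibration,
    )


# -- foci -------------------------------------------------------------------


def write_foci(path: str | Path, measurements: list[FocusMeasurement],
               cell_ids: list[str] | None = None, channel: str = "") -> None:
    rows = []
    for i, m in enumerate(measurements):
        rows.append(
            {
                "cell_id": cell_ids[i] if cell_ids else "",
                "channel": channel,
                "x_px": m.position[0],
                "y_px": m.position[1],
                "raw": m.raw,
                "background": m.background,
                "corrected": m.corrected,
                "normalized": m.normalized,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
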