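"""Core containers shared across the pipelines.

A :class:`MovieStack` is a time-ordered stack of 2-D intensity frames with
physical calibration (µm/pixel and s/frame); a :class:`MicrotubulePath` is an
ordered polyline in pixel coordinates along which kymographs are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MovieStack:
    """Time-ordered 2-D intensity frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` of non-negative intensities.
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Time between frames in seconds.
    label
        Free-text description of the acquisition.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        """Total movie length in seconds (frames x interval)."""
        return self.n_frames * self.frame_interval

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass
class MicrotubulePath:
    """Ordered polyline along a microtubule, in pixel coordinates.

    ``vertices`` is an ``(N, 2)`` array of ``(x, y)`` pixel positions with
    ``N >= 2``.  Physical length is derived from the vertex chain and the
    movie's pixel size.
    """

    id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array with N >= 2")

    # -- geometry -----------------------------------------------------------
    @property
    def segment_lengths_px(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def length_px(self) -> float:
        return float(self.segment_lengths_px.sum())

    def length_um(self, pixel_size: float) -> float:
        """Path length in µm: sum of segment lengths times the pixel size."""
        return self.length_px * pixel_size

    def _cumlen(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths_px)])

    def point_at(self, s_px: float | np.ndarray) -> np.ndarray:
        """Interpolate (x, y) at arclength ``s_px`` (pixels) along the path.

        Values outside ``[0, length_px]`` are clamped to the ends.
        """
        s = np.atleast_1d(np.clip(s_px, 0.0, self.length_px))
        cum = self._cumlen()
        x = np.interp(s, cum, self.vertices[:, 0])
        y = np.interp(s, cum, self.vertices[:, 1])
        out = np.stack([x, y], axis=-1)
        return out[0] if np.isscalar(s_px) else out

    def tangent_at(self, s_px: float | np.ndarray) -> np.ndarray:
        """Unit tangent vector(s) of the segment containing arclength s."""
        s = np.atleast_1d(np.clip(s_px, 0.0, self.length_px))
        cum = self._cumlen()
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
        seg = np.diff(self.vertices, axis=0)[idx]
        norm = np.linalg.norm(seg, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        t = seg / norm
        return t[0] if np.isscalar(s_px) else t

    def normal_at(self, s_px: float | np.ndarray) -> np.ndarray:
        """Unit normal (tangent rotated 90 degrees)."""
        t = np.atleast_2d(self.tangent_at(s_px))
        n = np.stack([-t[:, 1], t[:, 0]], axis=-1)
        return n[0] if np.isscalar(s_px) else n

    def reversed(self) -> "MicrotubulePath":
        return MicrotubulePath(self.id, self.vertices[::-1].copy())
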