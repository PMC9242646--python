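import numpy as np
import pytest

from adaptoquant.core import MicrotubulePath, MovieStack


@pytest.fixture
def single_spot_movie():
    """Noiseless movie with one static emitter at arclength 3.2 µm.

    Pixel size 0.16 µm, so the emitter sits 20 px along a straight
    horizontal path starting at x=4.
    """
    h, w = 32, 96
    frames = np.zeros((10, h, w), dtype=float)
    path = MicrotubulePath("p0", np.array([[4.0, 16.0], [90.0, 16.0]]))
    s_px = 3.2 / 0.16  # 20 px along the path
    x0, y0 = 4.0 + s_px, 16.0
    yy, xx = np.mgrid[0:h, 0:w]
    spot = 100.0 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 0.8**2))
    frames += spot
    movie = MovieStack(frames, pixel_size=0.16, frame_interval=0.3)
    return movie, path


def make_moving_spot_movie(speed_um_s=0.5, n_frames=40, frame_interval=0.3,
                           pixel_size=0.16, start_um=1.0, amplitude=100.0):
    """Noiseless movie with one emitter moving at constant speed along x."""
    h, w = 32, 128
    path = MicrotubulePath("p0", np.array([[4.0, 16.0], [124.0, 16.0]]))
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((n_frames, h, w))
    for t in range(n_frames):
        s_um = start_um + speed_um_s * t * frame_interval
        x = 4.0 + s_um / pixel_size
        frames[t] = amplitude * np.exp(-((xx - x) ** 2 + (yy - 16.0) ** 2) / (2 * 0.8**2))
    return MovieStack(frames, pixel_size=pixel_size, frame_interval=frame_interval), path
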