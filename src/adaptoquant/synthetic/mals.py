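"""Synthetic SEC-MALS elution traces."""

from __future__ import annotations

import numpy as np

from adaptoquant.binding import MalsTrace

__all__ = ["simulate_mals_trace"]


def simulate_mals_trace(
    mass: float,
    peak_concentration: float = 0.5,
    dn_dc: float = 0.185,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_center: float = 12.0,
    peak_sigma: float = 0.25,
    volume_range: tuple[float, float] = (10.0, 14.0),
    n_points: int = 400,
    calibration: float = 1.0,
) -> MalsTrace:
    """Simulate co-sampled concentration and light-scattering elution traces.

    The concentration channel is a Gaussian elution peak (mg/ml); the
    scattering channel is ``calibration * dn_dc^2 * c * mass`` pointwise (the
    dilute low-angle light-scattering relation), with optional multiplicative
    Gaussian noise of relative sigma ``noise_sd`` on both channels.
    """
    if mass <= 0 or peak_concentration <= 0 or dn_dc <= 0:
        raise ValueError("mass, peak concentration and dn/dc must be positive")
    v = np.linspace(*volume_range, n_points)
    conc = peak_concentration * np.exp(-((v - peak_center) ** 2) / (2 * peak_sigma**2))
    scat = calibration * dn_dc**2 * conc * mass
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc * (1.0 + rng.normal(0.0, noise_sd, n_points))
        scat = scat * (1.0 + rng.normal(0.0, noise_sd, n_points))
    return MalsTrace(volume=v, concentration=conc, scattering=scat,
                     dn_dc=dn_dc, calibration=calibration)
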