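"""Synthetic ITC titrations from the single-site isotherm."""

from __future__ import annotations

import numpy as np

from adaptoquant.binding import BindingModel, ITCExperiment, ITCProtocol, isotherm_heats

__all__ = ["simulate_itc"]


def simulate_itc(
    model: BindingModel,
    protocol: ITCProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ITCExperiment:
    """Simulate per-injection heats for a single-site titration.

    Heats follow :func:`adaptoquant.binding.isotherm_heats` (single-site
    isotherm with displacement-volume bookkeeping and the model's heat
    baseline) plus additive Gaussian noise of ``noise_sd`` µcal per
    injection.  A fixed seed reproduces the heat table exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    heats = isotherm_heats(model, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, len(heats))
    return ITCExperiment(protocol=protocol, heats=heats)
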