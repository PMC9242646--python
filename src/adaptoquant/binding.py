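"""Binding analysis: single-site ITC isotherms and SEC-MALS masses.

ITC: per-injection heats follow the independent single-site binding
isotherm.  With macromolecule M at total concentration ``Mt`` (sites
``N*Mt``) and ligand at total ``Xt`` in the active cell volume ``V0``, the
bound-ligand concentration solves the quadratic

    [MX] = (St + Xt + Kd - sqrt((St + Xt + Kd)^2 - 4*St*Xt)) / 2,
    St = N * Mt.

Perfusion-cell instruments (e.g. the iTC200) displace cell contents on each
injection; total concentrations follow the standard displacement
bookkeeping, and each injection's heat includes half of the heat content of
the displaced volume.

SEC-MALS: in the dilute low-angle limit the excess Rayleigh scattering is
proportional to ``(dn/dc)^2 * c * M``, so the per-point molar mass is
scattering / (calibration * dn_dc^2 * concentration) and the peak mass is
the concentration-weighted mean across the elution window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ITCProtocol",
    "ITCExperiment",
    "BindingModel",
    "MalsTrace",
    "StoichiometryCall",
    "FitResult",
    "UnidentifiableFitError",
    "isotherm_heats",
    "fit_isotherm",
    "mals_mass",
    "infer_stoichiometry",
    "SEQUENCE_MASSES_KDA",
]


#: Sequence-derived monomer masses (kDa) of the purified constructs used in
#: the stoichiometry analysis, computed from the public protein records:
#: the KASH5 N-terminal + coiled-coil construct (residues 1-349 of human
#: KASH5, UniProt Q8N6L0) and full-length human dynein light intermediate
#: chain 1 (DYNC1LI1, UniProt Q9Y6G9).
SEQUENCE_MASSES_KDA = {"KASH5-NCC": 38.45, "LIC1": 56.6}


class UnidentifiableFitError(RuntimeError):
    """Raised when the titration data cannot constrain the binding model."""


@dataclass
class ITCProtocol:
    """Titration protocol for a perfusion-cell calorimeter.

    Concentrations in µM, volumes in µl, temperature in °C.
    """

    cell_concentration: float
    syringe_concentration: float
    cell_volume: float = 200.0
    injection_volumes: np.ndarray = field(default_factory=lambda: np.full(19, 10.0))
    temperature: float = 20.0
    max_injected_fraction: float = 1.5  # sum of injections / cell volume cap

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if (self.cell_concentration <= 0 or self.syringe_concentration <= 0
                or self.cell_volume <= 0):
            raise ValueError("concentrations and cell volume must be positive")
        if (self.injection_volumes <= 0).any():
            raise ValueError("injection volumes must be positive")
        if self.injection_volumes.sum() > self.max_injected_fraction * self.cell_volume:
            raise ValueError("total injected volume exceeds the configured cell-volume cap")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCExperiment:
    protocol: ITCProtocol
    heats: np.ndarray  # µcal per injection

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.protocol.n_injections:
            raise ValueError("one heat per injection required")


@dataclass
class BindingModel:
    """Single-site binding parameters.

    N is sites per macromolecule (dimensionless), K_d in µM, ΔH in kcal/mol,
    baseline in µcal per injection.
    """

    n_sites: float
    kd: float
    dh: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_d must be positive")


@dataclass
class FitResult:
    model: BindingModel
    stderr: dict
    converged: bool
    c_value: float
    residuals: np.ndarray


@dataclass
class MalsTrace:
    """Co-sampled SEC-MALS elution traces.

    ``volume`` in ml, ``concentration`` in mg/ml (already converted from the
    refractive-index signal with dn/dc), ``scattering`` in calibrated
    proportional units: scattering = calibration * dn_dc^2 * c * M.
    """

    volume: np.ndarray
    concentration: np.ndarray
    scattering: np.ndarray
    dn_dc: float = 0.185
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.scattering = np.asarray(self.scattering, dtype=float)
        if not (len(self.volume) == len(self.concentration) == len(self.scattering)):
            raise ValueError("traces must be co-sampled")
        if self.dn_dc <= 0:
            raise ValueError("dn/dc must be positive")


@dataclass
class StoichiometryCall:
    copies: dict  # species name -> nonnegative integer copy number
    theoretical_mass: float  # kDa
    measured_mass: float  # kDa
    relative_residual: float
    consistent: bool


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------


def _bound_ligand(sites: np.ndarray, xt: np.ndarray, kd: float) -> np.ndarray:
    b = sites + xt + kd
    disc = b * b - 4.0 * sites * xt
    assert (disc >= -1e-9).all(), "negative discriminant in single-site quadratic"
    return 0.5 * (b - np.sqrt(np.clip(disc, 0.0, None)))


def _total_concentrations(protocol: ITCProtocol):
    """Running cell totals after each injection (displacement convention)."""
    dv = np.cumsum(protocol.injection_volumes)
    v0 = protocol.cell_volume
    f = dv / v0
    mt = protocol.cell_concentration * (1.0 - f / 2.0) / (1.0 + f / 2.0)
    xt = protocol.syringe_concentration * f / (1.0 + f / 2.0)
    return mt, xt


def isotherm_heats(model: BindingModel, protocol: ITCProtocol) -> np.ndarray:
    """Per-injection heats (µcal) of the single-site isotherm.

    The heat content of the cell after injection i is
    ``Q_i = ΔH * V0 * [MX]_i`` (µcal, with ΔH in kcal/mol, V0 in µl and
    concentrations in µM).  Each injection's measured heat is the change in
    cell heat content plus half of the heat content carried by the volume
    displaced during that injection, plus the instrument baseline.
    """
    mt, xt = _total_concentrations(protocol)
    mx = _bound_ligand(model.n_sites * mt, xt, model.kd)
    # kcal/mol * µM * µl = 1e-12 kcal = 1e-3 µcal
    q = model.dh * protocol.cell_volume * mx * 1e-3
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = protocol.injection_volumes
    heats = q - q_prev + (dv / protocol.cell_volume) * (q + q_prev) / 2.0
    return heats + model.baseline


def _heats_for_fit(protocol: ITCProtocol):
    def f(_x, n_sites, kd, dh, baseline):
        return isotherm_heats(BindingModel(n_sites, kd, dh, baseline), protocol)
    return f


def fit_isotherm(
    experiment: ITCExperiment,
    init: BindingModel | None = None,
    skip_first: bool = False,
) -> FitResult:
    """Nonlinear least-squares fit of the single-site model to an ITC run.

    Parameters are (N, K_d, ΔH, baseline).  Degenerate flat titrations (no
    heat signal above the injection-to-injection scatter) raise
    :class:`UnidentifiableFitError` rather than returning a spurious K_d.
    ``skip_first`` drops injection 1 from the residuals (a common practice
    for the first-injection artifact); the default keeps it.

    Returns the fitted model with per-parameter standard errors and the
    Wiseman c-value ``N*[cell]/K_d`` of the fit.  A c-value outside the
    classically fittable 1-1000 window triggers a warning flag via
    ``converged`` diagnostics rather than an error.
    """
    protocol = experiment.protocol
    heats = experiment.heats
    n_inj = len(heats)
    if n_inj < 5:
        raise ValueError("at least 5 injections are required for a fit")
    # flat-titration guard: for pure white noise var(heats) equals
    # var(diff)/2, while any binding signal inflates var(heats) far above it
    signal_var = float(np.var(heats))
    noise_var = float(np.var(np.diff(heats)) / 2.0)
    if signal_var == 0.0 or signal_var < 4.0 * noise_var:
        raise UnidentifiableFitError(
            "titration heats are flat: enthalpy (and hence K_d) is unidentifiable"
        )
    if init is None:
        dh_guess = (heats[0] - heats[-1])
        # crude scale guesses; curve_fit refines
        init = BindingModel(
            n_sites=1.0,
            kd=protocol.cell_concentration / 10.0,
            dh=dh_guess / (protocol.cell_concentration * protocol.cell_volume * 1e-3) or -1.0,
            baseline=float(heats[-1]),
        )
    weights = np.ones(n_inj)
    if skip_first:
        weights[0] = 0.0
    f = _heats_for_fit(protocol)

    def resid_model(x, n_sites, kd, dh, baseline):
        return f(x, n_sites, kd, dh, baseline) * weights

    x = np.arange(n_inj)
    p0 = [init.n_sites, init.kd, init.dh, init.baseline]
    bounds = ([1e-6, 1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            resid_model, x, heats * weights, p0=p0, bounds=bounds,
            maxfev=20000, xtol=1e-12, ftol=1e-12,
        )
        converged = np.all(np.isfinite(popt))
    except RuntimeError as err:
        raise UnidentifiableFitError(f"fit did not converge: {err}") from err
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    model = BindingModel(*popt)
    c_value = model.n_sites * protocol.cell_concentration / model.kd
    return FitResult(
        model=model,
        stderr={"n_sites": perr[0], "kd": perr[1], "dh": perr[2], "baseline": perr[3]},
        converged=bool(converged),
        c_value=float(c_value),
        residuals=heats - f(x, *popt),
    )


# ---------------------------------------------------------------------------
# SEC-MALS
# ---------------------------------------------------------------------------


def mals_mass(
    trace: MalsTrace,
    peak_window: tuple[float, float] | None = None,
    noise_floor_fraction: float = 0.02,
) -> float:
    """Concentration-weighted mean molar mass (kDa) across an elution window.

    ``peak_window`` is a (start, stop) volume interval in ml; the default
    uses the full trace.  Points whose concentration is below
    ``noise_floor_fraction`` of the window maximum are excluded from the
    per-point mass ratio (the ratio diverges at zero concentration).
    """
    if peak_window is None:
        sel = np.ones(len(trace.volume), dtype=bool)
    else:
        lo, hi = peak_window
        if lo >= hi or lo < trace.volume.min() or hi > trace.volume.max():
            raise ValueError("peak window must be a nonempty interval inside the trace")
        sel = (trace.volume >= lo) & (trace.volume <= hi)
    conc = trace.concentration[sel]
    scat = trace.scattering[sel]
    if len(conc) == 0 or conc.max() <= 0:
        raise ValueError("window contains no concentration signal")
    ok = conc > noise_floor_fraction * conc.max()
    if not ok.any():
        raise ValueError("window concentration is below the noise floor everywhere")
    mass_per_point = scat[ok] / (trace.calibration * trace.dn_dc**2 * conc[ok])
    return float(np.sum(conc[ok] * mass_per_point) / np.sum(conc[ok]))


def infer_stoichiometry(
    measured_mass: float,
    monomer_masses: dict,
    max_copies: int = 4,
    tolerance: float = 0.05,
) -> list[StoichiometryCall]:
    """Rank integer copy-number combinations against a measured mass.

    Enumerates every copy-number vector with 0..``max_copies`` copies per
    species (excluding all-zero), ranks by relative residual
    ``|theoretical - measured| / measured`` ascending with ties broken by
    fewer total copies, and flags calls within ``tolerance`` as consistent.
    """
    if not monomer_masses:
        raise ValueError("at least one species is required")
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    if measured_mass <= 0 or any(m <= 0 for m in monomer_masses.values()):
        raise ValueError("masses must be positive")
    names = list(monomer_masses)
    calls = []
    for combo in itertools.product(range(max_copies + 1), repeat=len(names)):
        if sum(combo) == 0:
            continue
        theo = sum(c * monomer_masses[n] for c, n in zip(combo, names))
        resid = abs(theo - measured_mass) / measured_mass
        calls.append(
            StoichiometryCall(
                copies=dict(zip(names, combo)),
                theoretical_mass=float(theo),
                measured_mass=float(measured_mass),
                relative_residual=float(resid),
                consistent=resid <= tolerance,
            )
        )
    calls.sort(key=lambda c: (c.relative_residual, sum(c.copies.values())))
    return calls
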