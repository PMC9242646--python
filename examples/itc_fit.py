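"""ITC: simulate a titration and fit the single-site binding model.

Simulates a perfusion-cell titration of a LIC1 peptide into KASH5-NCC at
the half-site stoichiometry (N = 0.5, one peptide per NCC dimer) and
recovers N, K_d and ΔH by nonlinear least squares.
"""

import numpy as np

from adaptoquant.binding import BindingModel, ITCProtocol, fit_isotherm
from adaptoquant.synthetic import simulate_itc

true_model = BindingModel(n_sites=0.5, kd=4.3, dh=-8.0, baseline=-0.05)
protocol = ITCProtocol(
    cell_concentration=50.0,       # µM KASH5-NCC in the cell
    syringe_concentration=550.0,   # µM LIC peptide in the syringe
    cell_volume=200.0,             # µl
    injection_volumes=np.full(30, 1.3),
)

experiment = simulate_itc(true_model, protocol, noise_sd=0.05, seed=7)
fit = fit_isotherm(experiment)

m, e = fit.model, fit.stderr
print(f"N        = {m.n_sites:.3f} ± {e['n_sites']:.3f}  (true 0.5)")
print(f"K_d      = {m.kd:.2f} ± {e['kd']:.2f} µM          (true 4.3)")
print(f"ΔH       = {m.dh:.2f} ± {e['dh']:.2f} kcal/mol    (true -8.0)")
print(f"c-value  = {fit.c_value:.1f}")
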