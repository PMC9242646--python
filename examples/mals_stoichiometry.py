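"""SEC-MALS: measure a complex mass and call its subunit stoichiometry.

Simulates an elution peak for the KASH5-NCC:LIC1 complex, recovers its
weight-averaged molar mass, and ranks integer copy-number combinations of
the two sequence-derived monomer masses against it.
"""

from adaptoquant.binding import SEQUENCE_MASSES_KDA, infer_stoichiometry, mals_mass
from adaptoquant.synthetic import simulate_mals_trace

trace = simulate_mals_trace(139.0, noise_sd=0.005, seed=1)
mass = mals_mass(trace)
print(f"measured molar mass: {mass:.1f} kDa")
print(f"monomer masses     : {SEQUENCE_MASSES_KDA}")

calls = infer_stoichiometry(mass, SEQUENCE_MASSES_KDA)
print("top stoichiometry calls:")
for call in calls[:3]:
    tag = "consistent" if call.consistent else "inconsistent"
    print(f"  {call.copies}  theoretical {call.theoretical_mass:.1f} kDa  "
          f"residual {100 * call.relative_residual:.1f}%  ({tag})")
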