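"""Nuclear-envelope enrichment: simulate transfected cells and score them.

Simulates a field of cells whose dynein channel is enriched 2-fold in a
1 µm perinuclear band, measures each cell's band/cytoplasm ratio, and shows
the condition-specific raw-intensity inclusion filters in action.
"""

import numpy as np

from adaptoquant.ne_quant import measure_cell
from adaptoquant.synthetic import SimulationConfig, simulate_cell_field

config = SimulationConfig(seed=5)
field, truth = simulate_cell_field(
    config,
    n_cells=20,
    enrichment_factors={"dynein": 2.0, "KASH5": 3.0},
    channel_means={"dynein": 300.0, "KASH5": (80.0, 350.0)},
    noise_sd=5.0,
)

ratios, n_excluded = [], 0
for i in range(field.n_cells):
    m = measure_cell(field.cell_image(i), condition="KASH5-FL")
    if not m.included:
        n_excluded += 1
        continue
    ratios.append(m.ne_cyto_ratio["dynein"])

print(f"measured {field.n_cells} cells; {n_excluded} excluded (KASH5 mean < 250)")
print(f"mean NE/cytoplasm dynein ratio: {np.mean(ratios):.3f} (true 2.0)")
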