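# adaptoquant

Quantification toolkit for dynein activating-adaptor biology, built around
the KASH5–dynein experimental program: single-molecule TIRF motility,
nuclear-envelope (NE) recruitment imaging, telomeric-focus intensity on
meiotic chromosome spreads, and in-vitro binding (ITC and SEC-MALS) — plus
matched synthetic-data generators with exact ground truth, so every analysis
routine can be validated by parameter recovery.

## The scientific problem

Cytoplasmic dynein-1 is autoinhibited on its own; *activating adaptors* such
as KASH5 link it to dynactin and cargo and convert it into a processive
motor. Establishing that a candidate protein is a genuine adaptor combines
several quantitative readouts:

- **Motility**: on kymographs from TIRF movies, does the adaptor produce
  processive runs, and with what velocity, run length and landing rate?
- **Cell biology**: does the adaptor recruit dynein/dynactin to its cargo
  site — here, a 1 µm perinuclear band around the nuclear envelope — and do
  point mutants abolish recruitment?
- **In vivo foci**: on spermatocyte spreads, how bright are dynactin (p150)
  foci at telomeres (the ends of SYCP3 axes) in mutant versus control cells?
- **Biochemistry**: what are the binding constants (ITC) and the complex
  stoichiometry (SEC-MALS plus sequence-derived masses)?

The package implements each readout as an importable, deterministic,
unit-tested pipeline, and pairs it with a generator producing realistic
synthetic data with known ground truth.

## Layout

| Module | Contents |
| --- | --- |
| `adaptoquant.core` | `MovieStack`, `MicrotubulePath` primitives |
| `adaptoquant.motility` | kymograph build/trace/classify/filter, event metrics, field summaries, `analyze_movie` |
| `adaptoquant.ne_quant` | nucleus segmentation, perinuclear band / cytoplasm masks, enrichment ratios, inclusion filters |
| `adaptoquant.foci` | SYCP3 axis-endpoint detection, aperture photometry with local background, normalization, blot ratios |
| `adaptoquant.binding` | single-site ITC isotherm + fit, SEC-MALS mass, stoichiometry inference |
| `adaptoquant.report_stats` | Kruskal–Wallis+Dunn and Welch+Dunnett-T3 comparisons, significance tiers, summary tables |
| `adaptoquant.synthetic` | generators: TIRF movies, cell fields, spermatocyte spreads, ITC titrations, MALS traces |
| `adaptoquant.io` | TIFF/CSV/JSON readers and writers |

## Worked example

`examples/tirf_motility.py` simulates a TIRF field and runs the full
kymograph pipeline:

```python
from adaptoquant.motility import analyze_movie
from adaptoquant.synthetic import SimulationConfig, simulate_tirf_movie, straight_paths

config = SimulationConfig(
    seed=1, frame_interval=0.5, movie_duration=180.0, field_size=(256, 256),
    landing_rate_true=0.2, state_fractions=(0.6, 0.25, 0.15),
    speed_distribution=("normal", 0.538, 0.054), run_length_mean=3.0,
)
paths = straight_paths(10, config.field_size)
movie, truth = simulate_tirf_movie(config, paths)
kept, rejected, metrics, summary = analyze_movie(movie, paths)
```

Output:

```text
simulated 198 ground-truth events on 10 microtubules
traced 183 candidate events; 51 rejected by the run filters
analyzed 81 uncensored processive events
median velocity   : 0.533 µm/s
median run length : 3.01 µm
landing rate      : 0.119 events / (µm · min)
percent processive: 62.1%
```

The other scripts in `examples/` cover NE enrichment (`ne_enrichment.py`),
telomeric foci (`telomere_foci.py`), ITC fitting (`itc_fit.py`), SEC-MALS
stoichiometry (`mals_stoichiometry.py`) and group statistics
(`group_stats.py`); each runs in seconds and prints the recovered versus
true values.

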