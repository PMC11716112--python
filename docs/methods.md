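# Methods

This note documents the models, conventions and default parameters behind
each analysis module, what the synthetic-data generators do and do not
emulate, and the design choices made where the underlying measurement
procedures leave room for interpretation.

## Genome model and occupancy accounting

Per-megabase occupancies divide absolute chromatin-bound copy numbers by the
total DNA content they are spread over. The default `GenomeModel` describes
a hypotriploid HeLa Kyoto genome of 7.9 Gb with a compartment factor of 2:
both the replicated mitotic chromatin mass and the summed content of two
daughter nuclei carry 2 × 7.9 Gb = 15,800 Mb. Occupancies assume equal
coverage of the mappable genome.

Chromatin-bound copies are the product of the nuclear copy number (from
FCS-calibrated imaging) and the chromatin-bound fraction (from FRAP).
Printed-table reproduction uses half-up rounding to the printed precision
(integers for copies, two decimals for per-Mb values); all internal
arithmetic is full precision. Two long-term ("immobile") conventions
coexist and are exposed explicitly via a `convention` parameter rather than
auto-detected: `table1_nuclear` applies the immobile fraction to the nuclear
pool (the early-G1 table's arithmetic) and `table2_bound` applies it to the
bound pool (the G1 table's arithmetic). `validate_tables` recomputes every
derivable cell of the packaged table and flags the four cells that are not
arithmetically consistent with their own row's inputs at printed precision
(two long-term densities that appear truncated rather than rounded, and two
bound-copy cells, one of which implies a bound fraction of 0.72 where the
table prints 71.0%); flagged cells are excluded from exact-match tests
rather than silently matched.

`loop_size` is the product of residence time and extrusion rate (default
1 kb/s). `encounter_probability` quantifies how likely ≥2 loops of a given
size overlap within 1 Mb under independent uniform placement of loop start
positions on [0, 1000 − L] kb — a deliberate, minimal placement model (no
loading-site bias, no exclusion). It is Monte-Carlo with a mandatory seed;
the classical uniform-spacings closed form
`P(no overlap) = ((M − (n−1)L)/M)ⁿ` serves as an independent oracle in the
tests.

## FCS calibration

The correlator computes `g(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩²` on uniformly sampled
traces with lags snapped to sample multiples. Fits use the one-component
free 3D-diffusion model without a triplet term. The axial structure
parameter κ defaults to 5 and is fixed during fitting (standard confocal
geometry; κ is poorly identifiable on noisy curves) but can be freed within
[1, 20]. Initialization: N₀ from the first-lag amplitude, τ_D₀ from the
half-amplitude lag. The calibration dye's diffusion coefficient is a
required configuration input, not a package constant — the effective volume
depends on which dye was measured.

The calibration line is an ordinary least-squares fit of concentration on
intensity, reported in x-intercept form `C = slope · (I − background)` so
that zero concentration maps to the background intensity; it is not forced
through a separately measured background point. Voxel conversion clamps
negative background-subtracted intensities to zero before multiplying by
the slope, avoiding negative concentrations at the cost of a small positive
bias in near-empty voxels; total copies integrate `C · V_voxel · N_A` over
the mask.

## FRAP

Intensities inside the chromatin mask are aggregated along the mask's
principal 2D axis; the boundary between bleached and unbleached regions is
the midpoint of the two region centroids' axis projections, and a 14-pixel
gap centered on that boundary is excluded from both region means to avoid
bleach-boundary gradients. Region means are weighted by the DNA-channel
intensity per position (plain intensity weights; the weighting scheme is an
exposed option since alternatives are defensible). No photobleaching
correction is applied during acquisition (acquisition bleaching is assumed
<10%), and background subtraction before the normalized difference is
optional — `d(t)` is invariant to affine rescaling of both channels, which
removes gain/offset differences by construction.

The fit is unweighted nonlinear least squares of `a + (1−a)e^(−k_off t)`
with `a ∈ [0, 1]`, `k_off > 0`, `t = 0` at the first post-bleach frame. A
flat curve at 1 flags `k_off` as unidentifiable rather than failing; a
fitted residence time longer than the observation span triggers an
identifiability warning rather than rejection. Because bleach-to-read lag
and total observation window bound which molecules count as "bound" vs
"immobile", fitted fractions are operational quantities tied to the
measurement protocol, not thermodynamic constants.

The total bound fraction after complete soluble-pool bleaching is the
background-corrected remaining unbleached-region intensity relative to
pre-bleach, clamped to [0, 1]; it is only meaningful once repeated bleach
steps have exhausted the soluble pool.

## Spot-bleach

The raw statistic is `100 × (mean_first − mean_last)/mean_first` over the
first and last 0.5-s windows of the 30-s depletion trace (first window
starts at t = 0 inclusive, last window ends at the final sample inclusive).
Calibration maps the free-mEGFP reference to 0% and the H2B reference to
100% and clamps to [0, 100], since noise produces raw values outside the
reference span. Replicates are averaged after calibration. Timecourse
interpolation is piecewise linear with the asynchronous-interphase anchor
conventionally placed at 300 min past anaphase onset; extrapolation raises.

## STED spot analysis

Nuclear masks: mild Gaussian blur, global triangle threshold (Otsu
optional), connected components, removal of small and border-touching
objects. Spot segmentation inside the mask: Gaussian blur (σ = 1 px), Otsu
threshold over masked pixels, one binary erosion with a 3×3 cross, removal
of objects below 4 px, one dilation, per-cluster local maxima (minimum
separation 3 px on the blurred image) seeding a watershed split; per-spot
mean intensities are measured on the unblurred (optionally rolling-ball
background-subtracted, radius 50 px) image. The erosion/dilation iteration
counts and the 4-px size cutoff are choices — the measurement procedure
names the steps but not their parameters — and are exposed in
`SpotSegmentationParams`.

Densities are detected spots divided by (2D mask area × an assumed 0.5 µm
optical depth); there is no 3D spot detection. Labeling efficiency
multiplies the detected density by 1.67 (the inverse of the ~40%
undercount the pipeline itself exhibits in the relevant density regime) and
divides by the expected bound density from FCS+FRAP.

The simulated benchmark fields place N single-pixel spots uniformly at
random, blur with σ = 2.6 px, scale so an isolated spot peaks at 6× the
unit-uniform random background, and add the background. One unit conversion
deserves emphasis: simulation conditions quoted as thousands of
"spots/µm³" elsewhere are per-field counts of the full 200 µm² / 100 µm³
field — 2,500 spots per field is 25 spots/µm³. Treating them as literal
per-µm³ densities would put a spot on nearly half of all pixels, which no
segmentation could resolve and which contradicts the expected bound-protein
densities (tens per µm³) the benchmark is compared against. The background
amplitude and distribution are unspecified upstream; the detection fraction
at a given density shifts with this choice, which is why the benchmark's
hard property is the monotone undercounting with density rather than any
single percentage.

## Trace geometry

Bins are 0-based 12-kb intervals (100 bins per 1.2 Mb by default);
distances are in nm; missing or QC-failing positions are NaN and never
imputed. Traces with fewer than 20 present positions are removed. "Contact"
uses strict inequality; ensemble maps default to 120 nm and per-trace
counts to 100 nm because both conventions are in active use. Adjacent bins
(|i−j| ≤ 1) are excluded from per-trace contact counts as trivial polymer
neighbors; loop calls additionally require j > i + 2. Ensemble contact
frequencies normalize per pair by the traces in which both positions are
present (not by all traces). Nested/stacked loops are counted as unordered
pairs of loop calls sharing exactly one anchor index, normalized by the
number of loop calls — one concrete reading of "two base loops with a
common anchor", validated against the synthetic generator only. The k-NN
statistic is implemented both as mean distance to the k spatially nearest
present positions (default) and as mean count within a radius, since the
phrase "mean number of k nearest neighbors" admits both readings.

## Synthetic generators

Every generator is byte-deterministic under a fixed seed, and each one's
output fed through its consuming module recovers the generative parameters
— that round trip is the package's core test matrix.

- FRAP: exact `a + (1−a)e^(−k_off t)` plus i.i.d. Gaussian noise (the t = 0
  point stays at 1, as the normalization enforces); the emitted
  bleached/unbleached pair is constructed around a conserved total.
- Spot-bleach: bound pool decays at 0.2/s (>99.7% depleted at 30 s),
  soluble pool constant — re-equilibration kinetics during illumination are
  not modeled beyond this.
- FCS: exact model curve with multiplicative Gaussian noise; a separate
  immigration-death count-trace generator (Poisson-stationary, geometric
  autocorrelation `g(k) = ρᵏ/N`) provides an analytic oracle for the
  correlator.
- STED fields: as described above; no camera noise model beyond the uniform
  background.
- Traces: Gaussian-chain backbone (RMS step 100 nm over a 12-kb bin,
  per-axis σ = step/√3, giving the exact 0.5 log-log scaling exponent used
  as an oracle), loops planted by pulling the downstream anchor to the
  target distance and rigidly translating the rest of the chain — orders of
  magnitude cheaper than loop-extrusion polymer dynamics and sufficient for
  testing the geometry statistics, but not a physical folding model.
  Localization noise is isotropic Gaussian (default σ = 20 nm per axis,
  matching the tracing precision scale) and positions drop out
  independently at the missing fraction (default 5%). The STAG2-depletion
  emulation removes nested sub-loops and enlarges steps by 10%; it encodes
  the expected qualitative contrast (fewer contacts, less nesting, longer
  distances), so tests against it validate the statistics' sensitivity, not
  any biological effect size.

What passing tests show, and do not show: the generators emulate the noise
magnitude and missingness of the real assays but none of their structured
artifacts (detector afterpulsing, imaging bleaching, chromatic offsets,
segmentation errors upstream of tracing). Parameter-recovery results
therefore bound the estimators' statistical behavior, not the full
experimental error budget.

## Problem sizes and numerical choices

Seeded study sizes used by the test suite and the acceptance script: 100
replicate curves for FRAP and spot-bleach recovery, a 3 × 3 parameter grid
× 12 replicates for FCS, 300–500 traces per ensemble condition, and five
50-µm² fields per STED density — sizes at which the checked medians and
frequencies are stable to well within their tolerances. Monte-Carlo
encounter probabilities default to 10⁵ draws. Curve fits use
`scipy.optimize.curve_fit`/`lmfit` least squares with the initializations
noted above; ties in printed-value reproduction round half-up.

## Known limitations

No multi-component or anomalous diffusion FCS models, no photon dead-time
or afterpulsing corrections; no reaction–diffusion FRAP models or 3D bleach
profiles; no modeling of soluble-pool re-equilibration during spot-bleach;
no 3D STED spot detection or PSF fitting; trace analysis consumes fitted
coordinates only (no drift correction, deconvolution or super-localization);
uncertainty propagation beyond optional linear propagation of printed
standard deviations is out of scope.
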