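# Methods

## Signal model and preprocessing

A measured spectrum is a wavenumber grid (cm⁻¹, canonically 1 cm⁻¹ spacing,
ascending) with dimensionless absorbance. The water association band (WAB)
is analyzed in the 2000–2500 cm⁻¹ window; the abutting 2400–2600 cm⁻¹
interval is band-free (the highest sub-band window ends at 2270 cm⁻¹, and
sub-band widths keep the band's wing well below 2400) and serves as the
anchor for background estimation.

The background is a constant offset plus a single Gaussian tail whose center
is constrained to 2700–3100 cm⁻¹, representing the low-frequency wing of the
strong CH-stretch bands. Offset and tail (center, FWHM, amplitude) are
fitted jointly by bounded least squares **over the anchor window only**. The
tail's curvature inside 2400–2600 cm⁻¹ separates it from the constant, so
the fit is well-posed; on noiseless synthetic data the planted background is
recovered to ≲1e−6 absolute (offset) and ≲1e−4 relative (tail). An option to
extend the support with the lowest-wavenumber points of the WAB window
exists (`n_edge_points`) but is off by default: when a populated W0a
sub-band sits at the 2000 cm⁻¹ edge, those points contain band signal and
bias the offset, which then corrupts every fitted population downstream.

Background-subtracted values are kept signed (no clipping); normalization
divides by the trapezoidal area over the WAB window and raises an error if
that area is non-positive. Normalization is idempotent and scale-invariant,
which is what makes fractional populations comparable across samples of
different thickness. All quadrature is trapezoidal — on a 1 cm⁻¹ grid the
trapezoid area of a Gaussian with FWHM ≥ 20 cm⁻¹ agrees with the closed form
a·σ·√(2π) to better than 0.1%, so the population denominators are exact to
state.

Sample drying is monitored through the area of the ν₂+ν₃ water combination
band near 5200 cm⁻¹ above a straight baseline through the integration-region
endpoints; hydration is declared stable when the relative area change
between successive scans is below 0.5% (`stabilization_tol`).

## Constrained decomposition

The normalized band is a sum of amplitude-parameterized Gaussians, one per
admitted sub-band class, fitted with `scipy.optimize.least_squares` (trust
region reflective, analytic Jacobian) under box constraints: centers inside
the class windows (upper edges open by 1e−9 cm⁻¹ except W4, so the shared
2120 cm⁻¹ boundary belongs to W2a), FWHM in (20, 200) cm⁻¹, amplitudes ≥ 0.
Widths are free per component. Initialization is deterministic: centers at
window midpoints, FWHM 60 cm⁻¹, amplitudes from the spectrum value at the
initial center (floored at 0); an optional seeded multistart perturbs the
initials but is off by default, so a fit is a pure function of (spectrum,
classes, config).

Convergence is declared when the relative RSS change falls below 1e−12 or
the parameter step below 1e−10 (at most 2000 function evaluations per solver
run). Overlapping Gaussians produce long "sloppy" valleys in which a single
trust-region descent can stall with a shrunken radius, so the solver is
restarted from its own solution (up to 8 rounds) until the RSS stops
improving or reaches the double-precision floor of the data norm; with this
scheme noiseless planted truths are recovered to machine precision
(populations ≲1e−10 for components separated by ≥ 40 cm⁻¹) and each noisy
fit costs a few tens of milliseconds.

Fractional populations are analytic component areas a·(FWHM/2.3548)·√(2π)
divided by their sum; they always total 1 to 1e−9. Warm-starting a superset
fit from a subset solution (extra amplitudes 0) guarantees nested-model RSS
monotonicity.

## Minimal-model selection

Five classes are always fitted (W0b, W1, W2a, W3, W4). The duplication
bands W0a and W2b are admitted by exhaustive comparison of the four
candidate class sets — mandatory, +W0a, +W2b, +both — using the Gaussian
BIC `n·ln(RSS/n) + k·ln n` with k = 3 parameters per component. An addition
is accepted only when it improves the BIC of the best accepted smaller
model by at least `selection_threshold` (default 10, a strong-evidence
margin); among BIC-equivalent candidates the smaller model wins. With four
candidates the exhaustive scan and a greedy scan coincide. At the default
threshold the spurious-addition rate on five-band truth at 0.3% noise is
0/100 seeds, while genuinely present duplication bands (populations ≥ 0.05)
are found in 100/100.

## Replicate aggregation and trends

Populations and peak frequencies are averaged per sample over 3–8
replicates; SDs are sample (n−1) statistics, 0 for a single replicate, and
the ≈0.3 cm⁻¹ instrumental-resolution uncertainty is *not* folded in. A
class absent from a replicate contributes population 0 but no center
observation.

Cross-composition analyses operate on finite S/P values only (∞ marks
protein-free references):

* **Two-family clustering** — profiles are area-normalized, ordered by S/P,
  and split at the largest L2 gap between consecutive profiles; the
  transition S/P labels the low side of the gap. The separation score
  (largest gap over the mean of the others) must reach 2.0 for the split to
  be called reliable; identical profiles give score 1 and an unreliable
  flag.
* **Population trends** — Spearman ρ of population against log₂(S/P)
  (the designs double S/P between levels); |ρ| ≥ 0.7 calls a direction,
  constant input is defined as ρ = 0/flat. The ±0.7 convention
  operationalizes qualitative increase/decrease statements.
* **Peak shifts** — endpoint comparison across the S/P range; a shift is
  declared only when |Δν| exceeds √(sd₁² + sd₂²); red = down-shift with
  S/P, blue = up-shift. Missing SDs are treated as 0 with a warning flag.

## Synthetic-data generator

The generator is the forward model of the decomposition and defines the
study conditions for all recovery tests:

* grid 2000–2600 cm⁻¹ at 1 cm⁻¹ (band window + background anchor);
* per-class Gaussians with areas proportional to planted populations
  (total band area 60 absorbance·cm⁻¹, peak absorbance ≈ 0.5), centers at
  window midpoints, FWHMs 22–36 cm⁻¹;
* background offset 0.05 plus a tail at 2900 cm⁻¹ (FWHM 300, amplitude 1)
  whose wing is a few percent of the band inside the anchor window;
* additive i.i.d. Gaussian noise, SD 0.3% of the spectrum maximum by
  default (the scale of a well-averaged FTIR measurement);
* composition response per sugar: logistic interpolation in log₂(S/P)
  between a protein-dominated and a sugar-dominated population vector,
  midpoint at S/P = 110 (between the 80 and 160 design levels, so the
  labeled transition of a clustered design is 80), steepness from 1.5
  (trehalose, smooth) to 6 (sucrose, abrupt); the protein-free limit is the
  sugar vector with W0a (protein-surface water) forced to 0;
* replicate structure: Dirichlet population jitter (concentration 400,
  population SDs of a few percent, matching the scale of real replicate
  error bars), truncated-normal center jitter (SD 2 cm⁻¹, clipped to the
  windows), 3–8 replicates per sample;
* reproducibility: one integer seed; per-(sugar, S/P, replicate) substreams
  derived via crc32 hashing into a `SeedSequence`, so extending a design
  never changes existing draws.

The planted widths deserve comment, since they shape what recovery tests
can show. Sub-band widths much above ~45 cm⁻¹ make neighboring classes
(especially the W0a/W0b and W2a/W2b pairs, whose windows nearly touch)
statistically unidentifiable at realistic noise: a five-band fit then
reaches the noise floor on seven-band truth and no estimator could
distinguish them. The defaults (22–36 cm⁻¹) encode the decomposition's own
premise — that the seven classes are resolvable features of the band — while
the composite envelope still spans the ~250–300 cm⁻¹ full-band scale because
the centers spread over 2000–2270 cm⁻¹. Real per-sub-band widths are not
published; if measured spectra become available the defaults should be
revisited, and recovery claims re-checked at the observed widths.

What the generator does **not** emulate: physically derived line shapes
(anharmonic coupling, librational combination structure), correlated or
multiplicative instrument noise, water-vapor/CO₂ interference lines,
crystallization artifacts (peak duplication), and temperature dependence.
Passing recovery tests therefore demonstrates the estimator's correctness
under the stated statistical model, not robustness to every artifact of
measured spectra.

## Formulation arithmetic

Monosaccharide-unit bookkeeping uses units-per-molecule 2 for the
disaccharides and 3 for raffinose; S/P = sugar molarity × units / protein
molarity, with ∞ for protein-free samples. Constants: water 18.015 g/mol;
trehalose, sucrose, maltose, lactose 342.30 g/mol (anhydrous isomers);
raffinose 504.42 g/mol; horse myoglobin 16 950 g/mol where a protein mass
is needed (configurable — reference sources for the matrices analyzed here
do not state the value they assumed). Reported-value comparisons round
half-even to the printed precision (2 decimals for molarities and g/g
ratios). The reference raffinose formulation rows are kept under their
nominal S/P labels; the computed ratios (e.g. 78 for the row labeled 80)
are reported alongside without reconciliation. The residual-water reference
table ties break toward the smaller S/P, and protein-free entries are
excluded from the minimum.

## Problem sizes and determinism

Recovery and selection studies use 100 seeded replicates of single spectra
(601 grid points); the full test suite and the acceptance script each run
in about a minute on one CPU. Every stochastic path (generator, multistart)
is driven by explicit integer seeds; identical inputs and config produce
bit-identical decompositions, and the pipeline writes a config hash and
library versions into its run log.

## Known limitations

* Fractional populations of strongly overlapping components are intrinsically
  ill-conditioned; at 0.3% noise the per-class population SD is ~0.5–1.5
  percentage points with the default widths and grows rapidly with width.
* The BIC threshold of 10 is a convention; data with strong baseline
  artifacts may need a higher threshold to avoid spurious duplication bands.
* The two-family split assumes exactly one transition; designs with two
  comparable gaps are reported with the larger one and a lower separation
  score, not as a multi-way split.
* JCAMP support covers single-block XYDATA tables only ((XY..XY) and
  (X++(Y..Y)) forms).
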