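# Methods

This note documents the models, numerical choices and deliberate limitations
behind `evftir`, in the order data flows through the pipeline.

## Data model

Spectra live on a shared, strictly monotonic, *uniform* wavenumber grid,
stored in descending order (4000 → 600 cm⁻¹, the plotting convention).
Uniformity is enforced at load (all consecutive spacings within 1e-6 relative
of the median) because Savitzky–Golay convolution weights assume equal
spacing; resampling non-uniform data is out of scope. Ascending input is
re-sorted and the reordering logged. The grid spacing is read from the data,
not assumed from the acquisition resolution: an instrument acquiring at
8 cm⁻¹ resolution typically exports a finer, zero-filled grid (the synthetic
default uses 4 cm⁻¹).

On-disk format is a wide CSV (first column wavenumber, one column per
spectrum) plus a metadata CSV keyed by `sample_id`. Floats are written with
Python's shortest round-tripping representation, so write→read reproduces the
matrix exactly; this is also what makes run bundles byte-reproducible.
Vendor binary formats (OPUS, JCAMP-DX) are deliberately not parsed.

## Preprocessing chain

Fixed order: crop → baseline → area normalization → SG second derivative →
inversion. The order question (baseline before or after cropping) is
resolved as *within the cropped region*, which makes the endpoint-anchored
baseline well defined.

**Baseline.** Default is the straight line through the region's two endpoint
samples (deterministic, endpoint-anchored; both endpoints become exactly 0).
A rubber-band correction (lower convex hull of the spectrum, computed by a
monotone-chain scan and interpolated on the grid) and a plain offset
(subtract the minimum) are provided; no method is canonical for this kind of
analysis, so the simplest deterministic one is the default.

**Area normalization.** Each spectrum is divided by the trapezoidal integral
of |A| over the region (computed on the ascending axis). |A| rather than A
keeps the integral positive in the presence of small negative post-baseline
values. The operation is idempotent and scale-invariant, which is exactly
its purpose: removing multiplicative differences (deposited film mass, ATR
contact) between replicates. One consequence worth knowing: normalized
intensities are *relative* quantities, so a genuine decrease of several
strong bands mechanically inflates every other band's share. How visible
that coupling is depends on how much constant "background" area the region
carries (see the generator's envelope below).

**Savitzky–Golay second derivative.** Weights are built from the
least-squares polynomial fit on a centered window (Vandermonde pseudoinverse
row times k!/h^k) — exact for polynomials up to the fit order, and verified
against an independent implementation in the tests. The default window is
quadratic with 3 points *per side* (7 points): "3 smoothing points" in
chemometrics software denotes the per-side count, and a 3-point total window
would smooth nothing. The minimal 3-point window remains available
(`sg_side_points=1`).

Two documented accuracy properties of the derivative at a Gaussian band
center (true value −H/σ²):

* the 3-point window's only error is the h²f⁗/12 truncation term — below 2%
  relative once σ ≥ 4 grid steps;
* the 7-point window additionally *smooths*, attenuating the center value
  (≈14% at σ = 4 grid steps, falling as 1/σ²). This bias is immaterial for
  the pipeline's comparative statistics (all spectra share it) but matters
  if absolute curvatures are wanted.

Edges are trimmed, never padded: `side_points` grid points are dropped from
each end, so the 96-point 1280–900 cm⁻¹ region yields a 90-point derivative
spanning 1268–912 cm⁻¹. Padding fabricates band-like artifacts exactly where
reported peaks sit near region edges. The cost is real and stated: a target
at 903 cm⁻¹ lies outside the derivative axis and is always reported
unmatched, and a band at 915 cm⁻¹ sits one grid point from the edge, which
constrains its detection (see peak detection). Because the axis is stored
descending, rows are reversed before convolution and reversed back, keeping
odd derivative orders correctly signed with respect to wavenumber.

Inversion (× −1) is applied only on the peak-reading branch; the PLS input
is the non-inverted second derivative, so β signs must always be read
together with the class coding.

## PLS-1 discrimination

NIPALS for a single response: per factor, w ∝ Xᵀy (unit norm), t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then rank-one deflation of X and y;
β = W(PᵀW)⁻¹q. Choices:

* response coding 0/1 (control/Aβ); direction-dependent statements are
  reported relative to the coding;
* factor signs fixed by forcing each weight vector's largest-magnitude
  element positive (NIPALS sign indeterminacy); class separation is judged
  by "all treated scores on one side of zero", not by a particular side;
* RMSE uses 1/n denominators (common chemometrics convention);
* one factor is the reporting default; models can be fit deeper and RMSEC is
  non-increasing in the factor count (checked against a least-squares oracle
  at full rank);
* deflation stopping: if ‖Xᵀy‖ or tᵀt falls below 1e-14 the model is
  returned with fewer factors and a warning.

Cross-validation default is leave-one-spectrum-out. This leaks class
information across technical replicates of the same biological sample — the
validated metrics are optimistic in exactly the way the original software's
full cross-validation is. `loo_bio_rep` (leave out all technical replicates
of one biological replicate together) is the honest alternative; both are
exposed and logged.

β-coefficient peak attribution finds strict local extrema of the β trace and
matches requested wavenumbers within a tolerance; the extremum's sign
assigns the band to the positively or negatively coded class.

## Peak reading and the shift rule

Detection operates on the inverted second derivative: strict local maxima
(plateaus take their highest-wavenumber point), filtered by **classic
topographic prominence** — each side of a peak is walked until strictly
higher terrain; the key saddle is the higher per-side minimum over sides
that reach higher terrain, and a side that runs off the signal end defines
no saddle. The distinction from window-bounded conventions matters at
region edges: a band truncated by the 912 cm⁻¹ edge keeps its full
prominence instead of being erased by the high boundary value. Two guards
precede the prominence filter: apexes with non-positive inverted value are
side-lobe artifacts (an absorption band must have negative second
derivative), and apexes below 1e-9 × max|trace| are numerical dust on flat
tails (which classic prominence would otherwise rank highly).

The default prominence threshold is 3× the median absolute deviation of the
trace's negative part — a per-spectrum scale that tracks the side-lobe/noise
floor without a tunable absolute unit.

Matching: each spectrum × target pair takes the nearest detected peak within
6 cm⁻¹ (the scale of both the doublet splittings in the assignment table and
the grid step); distance ties break toward the higher intensity. Intensity
is the apex grid value (no interpolation by default; 3-point parabolic
position refinement is available). A recompute invariant is tested: every
reported intensity equals the trace value at the reported position.

Peak-shift exclusion: per (target, condition), if matched positions spread
more than `max_spread` (default one grid step), the target is flagged and
excluded from group statistics — reported, never silently dropped. This
reconstructs the practice of refusing to quantify a band that does not sit
at one position across replicates of a condition.

Targets with no matched spectra in one group are still emitted in the
comparison table (with no test), so reports always carry one row per target
— including the 903 cm⁻¹ target that the edge trim makes unreadable.

The bundled assignment table maps each fingerprint wavenumber to its
vibrational-mode assignment and the sample type(s) it is observed in. Two
targets (903, 1102 cm⁻¹) have no direct literature row; their entries carry
the nearest listed band's text and a note marking the interpolation.

## Group comparison

Two-sided Mann–Whitney U from joint mid-ranks. The exact mode computes the
permutation distribution of U over all C(n₁+n₂, n₁) labelings via a dynamic
program over doubled mid-ranks (integral under ties), verified against
itertools enumeration; `auto` uses it for pooled samples up to 20
observations (12 under ties, falling back to the tie-corrected,
continuity-corrected normal approximation otherwise). Two-sided
p = min(1, 2 × smaller tail), which gives p = 1 for identical samples and
p = 0.1 for fully separated 3-vs-3 samples.

That last number is a designed-in caveat: with 3 biological replicates per
group and technical replicates averaged (`bio_means`), p < 0.05 is
*unreachable* — significance tiers below 0.01 necessarily come from treating
each spectrum as a unit. The default policy is therefore `all_spectra`
(faithful to how such data are evidently analyzed), with `bio_means` as the
statistically conservative option; both are logged. Technical replicates are
pseudoreplicates under `all_spectra`; read those p-values accordingly.

Direction is the comparison of group means; tiers are fixed thresholds
(ns ≥ 0.05 > \* > 0.01 > \*\* … \*\*\*\* < 0.0001). No multiple-testing
correction by default (per-peak testing at 0.05); Benjamini–Hochberg can be
applied downstream on the exported table. Exact-test conservatism is
quantified by the achievable size (e.g. 0.0400 at 9 vs 9 for nominal 0.05),
which is what the type-I validation checks against.

## Synthetic data generator

What it emulates: a 2-condition × 3-biological × 3-technical campaign on a
4000–600 cm⁻¹ grid (4 cm⁻¹ spacing); Gaussian absorption bands at the
fingerprint wavenumbers observed for each sample type; a broad matrix
envelope (center 1090 cm⁻¹, σ = 160 cm⁻¹, amplitude 2.5) under the narrow
bands; treatment effects as amplitude multipliers (defaults ×0.7 for
decreases at 1240/1085 in both types plus 1056/969/915 in EVs, ×1.4 for the
991 cm⁻¹ increase in EVs; directions mirror the studied phenotype, the
magnitudes are generator choices); lognormal per-biological-replicate scale
(σ = 0.15) × lognormal per-spectrum scatter (σ = 0.1); a fixed quadratic
baseline drift; additive white noise (σ = 0.02 A.U.).

Calibration rationale, decided once:

* **Band width σ = 5 cm⁻¹** (FWHM ≈ 12 cm⁻¹, plausible for condensed-phase
  fingerprint bands): the 7-point SG window smooths over ±12 cm⁻¹, and
  measured resolution shows 14 cm⁻¹ doublets (1053/1039, 929/915) separate
  only near this width; broader bands merge and the generator could not
  reproduce distinct target peaks.
* **Amplitudes** make each *quantified* band dominate its close unobserved
  doublet partner (1172 over 1158, 1121 over 1110), consistent with which
  partner the assignment table marks as observed: equal partners make the
  second-derivative apex flip-flop between them across replicates, and
  neither reads as one stable peak. The 915 cm⁻¹ band is strong (0.70) so
  its apex at 916 cm⁻¹ clears the trimmed 912 cm⁻¹ edge reliably.
* **The envelope** exists because real fingerprint spectra sit on a broad
  overlapping-band background. It also controls how strongly area
  normalization couples injected decreases into null bands (~2% here);
  without any envelope the coupling reaches ~9% and every null band would
  show a spurious "increase" — a property of share-based normalization, not
  of the test.
* **Noise level** gives ~3–6% replicate CV of normalized second-derivative
  peak intensities, the scale typical of dried-film ATR technical
  replicates.

Randomness: one integer seed; every spectrum draws from a counter-derived
substream keyed by (seed, condition, biological replicate, technical
replicate), so extending the design never perturbs existing spectra and
output is bit-reproducible.

The shift scenario jitters the 1053 cm⁻¹ band center per spectrum
(σ = 5 cm⁻¹). With the default matching tolerance the matched apex can only
land on {1048, 1052, 1056} cm⁻¹, and a flag requires both extremes within
one condition; jitter 5 maximizes the flag probability (~96% per seed —
smaller jitter rounds within one grid step, larger jitter loses matches to
the tolerance).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: Lorentzian/Voigt band shapes, wavelength-dependent ATR
penetration depth, atmospheric CO₂/H₂O lines, correlated (pink) detector
noise, batch effects beyond a global replicate scale, and any claim that the
injected effect magnitudes match the real biological effect sizes. Recovery
results validate the *machinery*, not the biology.

## Validation problem sizes

The shipped validation suite uses: 50 random quadratics and 10 wide
Gaussians (SG), 100 random small instances (NIPALS vs least squares), 20
instances (cross-validation loop), 200 random samples with n ≤ 8 (exact
Mann–Whitney vs enumeration), 20 seeded campaigns (end-to-end recovery), 50
seeds × 2 (shift reconstruction), 100 seeds (type-I error, checked per
target against simultaneous exact binomial bands around the achievable
size), and a duplicate run pair (byte determinism). These sizes make the
whole suite run in well under a minute while keeping every Monte-Carlo
margin comfortable.

## Known limitations

* The derivative axis cannot reach targets within `side_points` grid steps
  of the region edge (903 cm⁻¹); widening the analysis region is the only
  remedy under trim-only edge handling.
* Leave-one-spectrum-out CV is optimistic under technical replication (use
  `loo_bio_rep` for honest validation).
* `all_spectra` testing treats pseudoreplicates as units; `bio_means` with
  n = 3 cannot reach significance — the package exposes the dilemma rather
  than hiding it.
* Calibration/validation metrics from real studies are not reproducible
  without the original raw spectra; the package validates properties, not
  published table values.
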