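# Methods

This note documents the models, parameters and numerical choices behind
`ttmdyn`, in the spirit of the model documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and
what the synthetic validation does and does not establish.

## 1. The analysis model

### Phase-synchrony connectivity

Parcel timeseries are band-passed with a second-order zero-phase
Butterworth filter (forward–backward `filtfilt`; order configurable).
Zero-phase filtering is required because the next stage extracts
*phase*: any phase distortion would bias connectivity. The filter's DC
zero holds only in steady state, so the small residual offset left by
edge transients is removed explicitly after filtering. The default band
is 0.03–0.07 Hz, the narrowband regime in which an instantaneous phase
of BOLD is interpretable; with TR = 2 s the Nyquist frequency is 0.25 Hz
and band edges are validated against it.

Phases come from the analytic signal (Hilbert transform) per parcel,
wrapped to (−π, π]. Connectivity at timepoint t between parcels i and j
is `cos(φ_i(t) − φ_j(t))`: +1 in phase, 0 in quadrature, −1 in
anti-phase. The cosine variant is the minimal phase-difference map that
retains anti-phase information; the anti-phase-blind alternative
`1 − |sin(Δφ)|` is kept as a config option (`ips_variant`) for
comparison. Because the map is pointwise in time, computing phases on
all parcels once and subsetting to a network afterwards is exactly
equivalent to computing per network; we do the former. Wrapping
convention is immaterial since differences are taken before the cosine.

### Time-by-time similarity matrices

The neural TTM correlates (Pearson) the vectorised upper triangles of
the connectivity tensor's time slices across time. It is symmetric with
unit diagonal and positive semidefinite up to floating error (it is a
correlation Gram matrix); the test suite asserts an eigenvalue floor of
−1e−8. At least 3 parcels (3 edges) are required for a non-degenerate
edge vector, and a zero-variance edge vector at any timepoint is an
error naming the timepoint.

The behavioural TTM for a scalar rating series is `10 − |r_t − r_s|`
(Euclidean distance of 1-D points is the absolute difference), diagonal
10, range [2, 10] for ratings in [1, 9]. Group matrices are the cellwise
mean and the cellwise coefficient of variation; the CV uses the sample
(n−1) standard deviation, the conventional unbiased scaling at small n
(16 subjects / 25 raters).

Edge trimming removes the first and last 3 timepoints of every TTM: the
first and last connectivity frames of a run are artifactually similar
(filter and analytic-transform edge effects), and leaving them in
distorts long-range similarity statistics. Timepoint identifiers carry
original TR indices through trimming and alignment, so all masks are
defined on acquisition time. Indexing is 0-based internally; TR
timestamps are index × TR seconds.

The usable common timeline of a story run is
`acquired − dummies − surplus_ratings`: with 156 acquired volumes, 5
discarded equilibration scans and one surplus final rating, the matched
length is 150, and rest runs are truncated to their first 150
timepoints.

### Haemodynamic alignment

Neural BOLD lags the stimulus by the haemodynamic response. The package
implements lag-shift alignment: the sampled canonical double-gamma HRF
(peak delay 6 s, undershoot delay 16 s, undershoot ratio 1/6, length
32 s; each lobe a unit-scale gamma density whose mode sits at the stated
delay) peaks at 3 TRs for TR = 2 s, so `lag_align` drops the first 3
rows/columns of the neural TTM and the last 3 of the behavioural TTM,
pairing neural timepoint t with behavioural timepoint t − 3. Rows *and*
columns are removed (column-only removal would break matrix symmetry);
what matters is the pairing. A subject- and region-specific blind
deconvolution would be a refinement; the alignment function is the
pluggable hook for it.

### Correspondence statistics

Kendall's Tau-A, `(C − D) / (n(n−1)/2)`, keeps tied pairs in the
denominator. This matters because behavioural TTMs built from a 9-point
scale are saturated with ties: tie-rescaling coefficients (Tau-B/C,
Spearman) can reward degenerate near-constant predictions, Tau-A cannot.
Implementation: the O(n log n) Tau-B statistic is un-normalised back to
the integer concordant-minus-discordant count (exactly recovered by
rounding) and divided by the full pair count; tests verify exact
agreement with an exhaustive O(n²) enumeration.

The permutation null relabels the behavioural TTM's timepoints jointly
over rows and columns — the natural exchangeability null that preserves
matrix validity (permuting columns alone would destroy symmetry) — and
re-masks with the *original* |i−j| ≤ k band, since proximity is a
property of acquisition time, not of permuted labels. p-values use the
exact-test convention p = (1 + #{null ≥ obs}) / (1 + n_perm), one-sided
for positive correspondence by default (the hypothesis is isomorphic,
positive mapping; a two-sided flag exists).

The autocorrelation mask exists because any TTM has trivially high
similarity near its diagonal while the permutation destroys that
structure, which would otherwise inflate significance. The test is
*exact* when the behavioural series' timepoints are exchangeable; for
temporally smooth data the mask makes it approximately valid, and the
calibration experiment therefore generates its null from exchangeable
(iid) series — the regime with a defensible nominal level. The
stabilisation curve (mean Tau-A as a function of k) is the diagnostic
for choosing k: it falls while autocorrelated cells are being stripped
and flattens once they are gone; defaults k = 10 with sensitivity at
k = 24, both always computed. Tau on the *unmasked* triangle is reported
alongside, since near-diagonal similarity can carry real signal (state
lingering vs rapid transitions). BH-FDR is applied across networks
within one parcellation granularity.

### Intersubject similarity and contrasts

IntSS Fisher-z transforms each subject's TTM lower triangle (arctanh,
inputs clamped to ±(1 − 1e−12)) and Pearson-correlates subject pairs:
16 subjects give 120 unique pair values. Pair values are not independent
(each subject sits in 15 pairs); the pairs are nevertheless the test
units, replicating the convention of this analysis family — a
subject-level jackknife would be the conservative alternative and the
pair table retains subject identities to support it.

Contrasts use the Wilcoxon signed-rank test on paired pair differences:
zeros discarded, mid-ranks for tied magnitudes, tie-corrected normal
variance, z signed positive when the first condition is larger. For
n ≤ 12 non-zero differences the p comes from exact enumeration of all
2ⁿ sign patterns (two-sided, deviation-from-mean tail). The SEM of the
mean difference is a seeded bootstrap over pair differences (n = 1000).

The level × network ANOVA fits `value ~ level_lin * C(network)` with the
awareness level as a continuous 1..3 predictor — the question is whether
IntSS *scales* with awareness differently across networks — using type-II
sums of squares (equivalent to other types in this balanced design). The
per-network level × task ANOVA is the analogous
`value ~ level_lin * C(task)` interaction, Bonferroni-corrected across
networks.

### TTM entropy

Shannon entropy of the histogram of all TTM cells, 256 bins (mirroring
8-bit image-entropy routines), diagonal included by default. Cells are
min-max scaled to [0, 1] before binning: this is information-preserving,
whereas the classical image-entropy convention clips negative values to
0 and merges all anti-correlated cells into one bin — that behaviour is
available as `scaling="clip"` for comparability, and a fixed [−1, 1]
mapping as `scaling="fixed"`. A constant matrix yields 0 bits with a
warning; the upper bound is log2(n_bins). Refining bins never decreases
the entropy of the partition, which the tests assert.

Per network, awake-minus-deep deltas of entropy (within subject, then
averaged) and of mean IntSS are Spearman-correlated across networks.

## 2. The synthetic cohort

The generator emulates the study design: 16 subjects × {awake, moderate,
deep} × {story, rest}, 25 raters, 150 timepoints at TR = 2 s. No real
generative model of these data exists, so the package plants exactly the
two kinds of structure the analyses claim to detect:

* **Latent drive.** Smoothed uniform noise rescaled to span [0, 1]
  (window 8 TRs ≈ 16 s, the timescale of suspense arcs), degenerate
  draws resolved to 0.5. Raters see `round(1 + 8·clip(drive + ε, 0, 1))`
  with ε ~ N(0, 0.08) — mild inter-rater disagreement (observed max
  cell CV across raters ≈ 0.3).
* **Oscillators.** Each network carries a *shared* narrowband phase
  trajectory (frequency 0.04 + 0.02·drive Hz, common to all subjects,
  story only) and an *idiosyncratic* one per subject (driven by a
  subject-specific smooth modulator). Parcel signals are cosines of
  these phases offset by parcel-specific angles that shrink as the
  coupling κ(t) rises: κ_shared = gain·(0.15 + 0.85·drive),
  κ_idio = gain·(0.15 + 0.85·modulator). High drive → tight within-
  network locking → the connectivity pattern, and hence the TTM, tracks
  the drive. Network amplitudes (shared vs idiosyncratic) are the
  planted ground truth.
* **Sedation analog.** `coupling_gain` (awake 1.0, moderate 0.5, deep
  0.12) multiplies both oscillator amplitudes and the coupling, and
  additive scanner-like white noise rises with depth (SD 0.4 / 0.6 /
  0.8). This makes no pharmacological claim; it reproduces the
  qualitative signature of interest — under deep sedation planted
  dynamics collapse toward band-limited noise, whose TTM retains only
  the generic near-diagonal band that all subjects share.
* **Haemodynamics.** Activity is convolved with the canonical
  double-gamma HRF and cropped so that output timepoint 0 carries a
  fully formed response; the BOLD consequently lags the ratings by the
  HRF peak (≈3 TRs), which `lag_align` undoes.
* **Seeding.** All randomness derives from one master seed through keyed
  `numpy` generator streams (per subject, condition, network, rater), so
  identical specs are bit-identical and partial regeneration is
  reproducible.

Why the planted signatures emerge: awake, a shared-dominant network's
TTM is dominated by drive-locked structure common to all subjects (high
IntSS, concentrated similarity histogram → lower entropy), while an
idiosyncratic-dominant network's TTM is dominated by subject-specific
structure (low IntSS, broad histogram → higher entropy). Deeply sedated,
both collapse to the generic noise TTM (intermediate IntSS driven by the
shared autocorrelation band). Hence IntSS falls with sedation for shared
networks and *rises* for idiosyncratic ones, and the entropy deltas move
opposite to the IntSS deltas — the negative cross-network rank
correlation the complexity analysis measures.

What the generator does **not** emulate: spatially structured
physiological noise, motion, subject-specific HRF variability,
non-stationary sedation depth, heavy-tailed rating behaviour, or any
content structure of a real story beyond one scalar drive. Passing tests
therefore establish internal validity of the statistics (calibration,
recovery of planted effects, exactness of identities), not that real
data would show these effects.

## 3. Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at deliberately
chosen scales: permutation calibration uses 500 (tests) / 300 (script)
replicates of 199 permutations at T = 30; planted-structure recovery
uses 40 / 30 seeds of full 16-subject cohorts; the entropy association
uses 30 / 20 seeds of 8-network gradient cohorts; the full-scale
analysis drivers use 2000 permutations per network. These sizes give
stable rates (binomial SE ≲ 2 percentage points) at interactive
runtimes.

Other numerics: Fisher-z clamp 1 − 1e−12; zero-variance vectors detected
with a relative tolerance (1e−10, catching cancellation noise in
constant arctanh vectors); TTM symmetry validated at 1e−10; the PSD
floor −1e−8; Tau-A's concordant-minus-discordant count recovered by
integer rounding, making the statistic exact; Wilcoxon exact/normal
switch at n = 12; plateau detection on the stabilisation curve uses a
successive-difference threshold (default 0.005 in tau units).

## 4. Known limitations

* The pair-level inference convention for IntSS understates dependence
  between pairs; treat p-values as descriptive within that convention.
* The permutation test's nominal level is exact only under timepoint
  exchangeability; for strongly autocorrelated data the masked test is
  approximate, and the stabilisation curve should guide k.
* Lag-shift HRF correction assumes one global lag; blind deconvolution
  per region/subject is left as a hook.
* The edge-artifact reproduction (first/last frame similarity) seen in
  real acquisitions is not simulated; trimming is applied regardless.
* Entropy depends on the binning convention; cross-study comparisons
  must fix `n_bins` and `scaling`.
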