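# Methods

`flickerfit` simulates and analyzes a flicker fMRI experiment that measures
the temporal sensitivity of human visual cortex to modulations targeting the
three post-receptoral channels: achromatic light flux (LMS), red-green
(L−M), and blue-yellow (S). This note describes the models the package
implements, the choices made where the design was genuinely open, and what
the synthetic data do and do not establish about real recordings.

## Experimental design

Each 336 s acquisition presents 28 trials of 12 s, each flickering at one of
seven log-spaced frequencies (0, 2, 4, 8, 16, 32, 64 Hz). Trial order comes
from a first-order counterbalanced master sequence over the seven
conditions: 50 elements in which every ordered pair of conditions,
including repeats, occurs exactly once as consecutive elements. The
sequence is constructed as a seeded randomized Eulerian circuit on the
complete directed graph with self-loops over seven nodes (every such graph
has an Eulerian circuit, so construction always succeeds); opening the
circuit yields the 50-element path. The master sequence splits into halves
"A" (elements 1–25) and "B" (elements 26–50), each padded with three 0 Hz
trials. A block is the six acquisitions LMS_A, L−M_A, S_A, S_B, L−M_B,
LMS_B; six blocks make the 36-acquisition study (12,096 volumes at
TR = 1 s). Attention events (250 ms darkenings, probability 0.33 per trial,
never within 2 s of a trial boundary) keep the observer engaged and are
modeled as impulses.

One consequence of the A/B split worth knowing: the ordered pair that
straddles elements 25→26 of the master sequence appears in neither half, so
one of the 49 prior×subsequent frequency pairs can lack support within a
stimulus class. The carry-over fit reports such cells as undefined (NaN)
rather than zero, and summaries average over defined cells.

## Hemodynamic model

The BOLD impulse response is a weighted combination of three orthonormal
kernels (support 0–28 s at 1 s resolution) obtained by SVD of 512
double-gamma responses sampled over plausible peak delays (4–7 s),
dispersions (0.7–1.3), and undershoot ratios (0.1–0.5). The basis is a
fixture of this package: any three-component orthonormal basis spanning
plausible HRFs serves, and no test depends on exact basis values. The first
component correlates > 0.95 with the family mean, and three weights
reconstruct any family member with R² > 0.9.

## Time-series model

Per vertex, the model jointly estimates the three HRF weights (shared
across acquisitions) and one amplitude per frequency per acquisition plus
one attention amplitude per acquisition (8 × 36 = 288 covariates).
Frequency covariates are 12 s step functions, attention covariates unit
impulses; all are convolved with the candidate kernel per acquisition with
truncation at acquisition boundaries. Both model and data pass through a
0.0387 Hz high-pass filter, realized as the residual of projection onto an
orthonormal discrete-cosine basis (constant plus DCT-II terms below the
cutoff) per acquisition. The fit minimizes the L2 norm of the filtered
residual; it is separable, so for fixed kernel the amplitudes solve
independent per-acquisition ordinary least squares, and a
Levenberg–Marquardt search over the three weights (initialized at the
projection of the canonical double-gamma, tolerances 1e-14) handles the
nonlinear part.

Two numerical points matter. First, the model is scale-unidentified —
scaling the kernel by c and all amplitudes by 1/c changes nothing — so the
kernel is normalized to unit sum inside the fit and the simulator. With a
unit-sum kernel the plateau of a sustained response equals its amplitude,
so amplitudes read directly in percent signal change. Second, the seven
frequency covariates of an acquisition tile the entire acquisition, so
after convolution and high-pass their sum is nearly constant and the
absolute amplitude level is weakly determined. All downstream analyses
therefore reference amplitudes to the same-acquisition 0 Hz condition,
which cancels this common mode; recovery properties are stated for relative
amplitudes (and, where averaging applies, for the 12-acquisition mean per
direction × frequency crossing, the quantity the analyses consume).

Zero-variance vertices return zero amplitudes and R² = 0 rather than
raising. R² is computed on attention-cleaned averaged data: the fitted
attention component is subtracted, the six A-ordered and six B-ordered
acquisitions per direction are averaged and concatenated, and R² =
1 − SSE/SST of the stimulus model against this average after high-pass.
Vertices with R² strictly above 0.1 enter region and band summaries.

## Temporal sensitivity model

Amplitude versus frequency is fit with a difference-of-exponentials
frequency response: a fast center filter (i2πωτ_c + 1)^(−9) minus a slow
surround G_s (i2πωτ_s + 1)^(−10) with τ_s = r·τ_c, scaled by a gain G; the
response amplitude is the complex modulus. Filter orders 9 and 10 are held
fixed. The linear constraints are realized as bounds: τ_c ∈ [1e-4, 0.1] s,
r ∈ [1, 20], G_s ∈ [0, 1], G ≥ 0. Unimodality of |H| is checked on the
dense grid (sign pattern of first differences collapses to at most one
rise–fall) and enforced as a feasibility condition on candidate solutions.
Fitting profiles the gain out analytically (for fixed shape the optimal
G is a clipped one-dimensional least squares) and runs multi-start
trust-region least squares over (log10 τ_c, r, G_s) on a fixed lattice of
20 starts. The model is over-parameterized for six-frequency data, so fits
are summarized only by the interpolated peak: the maximum of |H| on a
log-spaced grid from 0.5 to 100 Hz with 0.01 log10 spacing. Fits use the
six non-zero frequencies with amplitudes referenced to 0 Hz; negative
amplitudes are fit as-is against the non-negative model. When the true peak
lies below the lowest stimulated frequency the data constrain only the
sampled points, and the extrapolated peak amplitude is not identified;
recovery statements therefore apply to responses peaking within the
stimulated range, as the cortical data do.

Uncertainty comes from a bootstrap across acquisitions: 1,000 replicates by
default, each resampling the 12 acquisitions of a direction with
replacement, averaging relative amplitudes, refitting (warm-started at the
full-sample solution with lattice fallback), and extracting the peak;
per-frequency and peak medians and interquartile ranges are reported.

## Carry-over analysis

The residual after the full time-series fit (stimulus plus attention,
high-passed), averaged over a region, is regressed on 49 covariates, one
per ordered (prior, subsequent) frequency pair: a 12 s boxcar over every
trial whose own frequency is the subsequent member and whose immediately
preceding trial in the same acquisition had the prior frequency. First
trials have no prior and are excluded; covariates are built separately for
achromatic (LMS) trials and for chromatic (L−M and S pooled) trials,
convolved with the region-average fitted HRF, and high-pass filtered like
the residual. Coefficients are arranged into the 7×7 carry-over matrix.
Across participants, cells whose mean magnitude exceeds twice the standard
error of the mean are flagged.

Because the main model absorbs each acquisition's mean response per
frequency, an injected multiplicative adaptation appears in the residual as
a contrast between trials that do and do not follow the adapting frequency;
recovered matrices are therefore interpretable relative to one another (an
injected 0.7× suppression after 64 Hz yields a negative 64 Hz row and a
compensating positive shift elsewhere).

## Pattern analyses

Per acquisition, the 0 Hz-referenced amplitudes across vertices for each
non-zero frequency are standardized to zero mean and unit SD. Split-half
similarity averages, over all 462 unordered partitions of the 12
acquisitions of a direction into halves, the Pearson correlation of every
frequency pair
between half-averaged patterns; each partition's matrix is symmetrized with
its complement, so the average is diagonally symmetric. Decoding asks, per
partition and probe direction, whether the held-out pattern most correlated
with the 64 Hz probe pattern is the 64 Hz pattern; ties count as incorrect.
When the two chromatic directions are pooled (24 acquisitions, over a
million possible partitions), a seeded random subset of 462 distinct
partitions replaces exhaustive enumeration; the 12-acquisition case is
always exact.
With six candidate frequencies chance is 1/6 ≈ 0.167. The 0 Hz condition
cannot participate: its 0 Hz-referenced pattern is identically zero and has
no across-vertex variance to standardize, so matrices and decoding use the
six non-zero frequencies.

## Retinal output model

Per-class temporal gain tables (spikes/s per % contrast) at eccentricity
centers 5, 25, and 40 degrees drive the prediction; the packaged table is a
synthetic stand-in with the qualitative structure of macaque recordings
(midget achromatic and chromatic, parasol achromatic, small bistratified S;
bistratified only at 5 and 25 degrees; on/off averaging applied upstream)
and is replaceable input. Responses are gain × contrast (nominal contrasts
90% LMS, 8% L−M, 50% S) with parasol cells saturating at 25% contrast.
LMS output sums midget and parasol achromatic responses; L−M is the midget
chromatic response; S the bistratified response. Population integration
weights each class by an exponentially declining total RGC receptive-field
density (e-fold 20 degrees, arbitrary units), class proportions shifting
from midget-dominated centrally toward parasol peripherally (config
values), and annular area 2πe in squared degrees per unit ring width. Each
direction × eccentricity frequency series is summarized by its peak via
log-quadratic interpolation around the tabulated maximum, with amplitudes
normalized to the across-eccentricity average LMS peak.

## Synthetic data

The generator's defaults define the test conditions: Watson-shaped neural
amplitudes peaking near 16 Hz (LMS, 3 %BOLD at peak), 12 Hz (L−M, 1.5) and
8 Hz (S, 1.0), with the peak frequency drifting upward by 5% per
eccentricity band; fixed per-vertex, per-frequency pattern perturbations
(SD 0.25 %BOLD); attention impulse amplitude 1 %BOLD; white Gaussian noise
(SD 0.5 %BOLD per volume); sinusoidal drift (amplitude 1 %BOLD at 0.01 Hz,
below the high-pass cutoff); multiplicative first-order carry-over gains
(all ones by default). Carry-over is injected on neural amplitude, matching
a habituation mechanism recoverable by residual regression. Everything is
reproducible from a seed, and configuration flags reproduce the degenerate
cases used in tests (zero noise, zero drift, patterns off, flat gains).

The simulator emulates the statistical structure the analysis assumes —
linear superposition, a common HRF per vertex, white noise — and omits
temporal autocorrelation, physiological noise spectra, motion, and scanner
drift nonstationarity. Passing recovery tests therefore demonstrates the
correctness and self-consistency of the estimation chain under its own
assumptions, not performance on real recordings.

## Problem sizes used in tests

Recovery tests run the full 36-acquisition design with 2–100 vertices
depending on the property (exact noiseless recovery at 100 vertices; noisy
amplitude-correlation at 16; carry-over sign recovery across 50 seeded
studies at 2), bootstrap comparisons at 10^3 versus 10^4 replicates, and
null decoding at 10^5 Monte-Carlo draws. These sizes were chosen so each
property is measured with comfortable statistical margin.

## Known limitations

- The absolute amplitude common mode is weakly identified by design;
  only 0 Hz-referenced amplitudes are meaningful.
- Peak summaries, not Watson parameters, are the supported output; raw
  parameter values are not unique.
- The carry-over matrix estimates contrasts between serial contexts, with
  one possibly undefined cell per class (see above).
- The retinal gain table is synthetic; quantitative retinal predictions
  should be recomputed with measured gains when available.
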