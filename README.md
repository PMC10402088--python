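# flickerfit

Analysis and simulation of an fMRI experiment measuring the temporal
sensitivity of human visual cortex to spectral flicker along the three
post-receptoral channels: achromatic light flux (LMS), red-green (L−M), and
blue-yellow (S). The package is for vision scientists and fMRI
methodologists who want a tested, reusable implementation of this analysis
chain — or a simulation testbed for it — without access to raw recordings.

## What it implements

**Experimental design.** 336 s acquisitions of 28 twelve-second trials
flickering at 0, 2, 4, 8, 16, 32, or 64 Hz, ordered by a 50-element
first-order counterbalanced sequence (every ordered pair of the seven
conditions occurs exactly once as consecutive elements), split into "A"/"B"
halves and arranged into six blocks of six acquisitions — 36 acquisitions,
12,096 volumes at TR = 1 s.

**Time-series model.** Per vertex, a nonlinear fit jointly estimates the
HRF — three weights w on an orthonormal temporal basis, kernel normalized to
unit sum — and the amplitude β of response to each frequency in each
acquisition (8 × 36 = 288 covariates), minimizing

‖ F(y) − F(X(w) β) ‖₂

where F is a 0.0387 Hz discrete-cosine high-pass projection applied per
acquisition. The fit is separable: amplitudes solve per-acquisition OLS
inside a Levenberg–Marquardt search over w.

**Temporal sensitivity.** Amplitude versus frequency is fit with the Watson
difference-of-exponentials model

H(ω) = G [ (i2πωτ_c + 1)^(−9) − G_s (i2πω·rτ_c + 1)^(−10) ]

with unimodality of |H| enforced and the fit summarized by its interpolated
peak on a dense log-frequency grid; medians and IQRs come from 1,000
bootstrap resamples across acquisitions.

**Downstream analyses.** First-order carry-over (adaptation) estimation by
regressing fit residuals on the 49 prior×subsequent frequency covariates;
split-half multi-vertex pattern similarity and 64 Hz best-match decoding
(chance 1/6 = 0.167) by eccentricity band; eccentricity-band averaging,
z-scored relative peak-frequency maps, and visual-field projection; and an
eccentricity-integrated retinal ganglion cell output model (midget, parasol
with 25 %-contrast saturation, small bistratified) predicting retinal
temporal sensitivity peaks.

A synthetic-data generator produces BOLD datasets with the full generative
structure (Watson-shaped amplitudes, carry-over, spatial patterns,
attention events, drift, noise), so every stage is testable end to end.
See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from flickerfit import (FlickerGLM, GroundTruth, WatsonTSFModel,
                        build_orthonormal_basis, build_study_schedule,
                        make_vertex_geometry, simulate_bold)

schedules = build_study_schedule(seed=0)      # 36 acquisitions, 12,096 volumes
geometry = make_vertex_geometry(6, seed=1)    # synthetic retinotopy table
basis = build_orthonormal_basis(seed=0)       # 3-component orthonormal HRF basis
truth = GroundTruth.default()                 # Watson TSFs, noise 0.5 %BOLD
data = simulate_bold(schedules, truth, basis, geometry, seed=2)

result = FlickerGLM(data, basis).fit()
print(result.summary())

tsf = WatsonTSFModel.from_amplitude_table(result.amplitudes, "LMS").fit()
print(tsf.summary())
summary = tsf.bootstrap(n_boot=1000, seed=3)
print(f"bootstrap peak frequency: {summary.peak_freq_hz_median:.1f} Hz "
      f"(IQR {summary.peak_freq_hz_iqr[0]:.1f}-{summary.peak_freq_hz_iqr[1]:.1f})")
```

prints

```
Flicker time-series GLM fit
------------------------------------------
vertices fitted               6
acquisitions                 36
time points               12096
covariates                  288
median R^2                0.789
vertices with R^2>0.1         6
mean HRF weights       [ 0.5577 -0.0253 -0.034 ]

Watson temporal sensitivity fit
---------------------------------------
gain G                   3.0047
tau_center (s)          0.00193
tau_ratio                1.7230
surround gain G_s        0.7517
filter orders        nc=9, ns=10 (fixed)
peak frequency (Hz)       17.34
peak amplitude           2.8004

bootstrap peak frequency: 17.3 Hz (IQR 16.9-17.3)
```

The GLM block reports the fit dimensions, the goodness of fit on
attention-cleaned averaged data (all six simulated vertices clear the
R² > 0.1 selection threshold), and the average HRF basis loadings. The
Watson block shows the fitted temporal sensitivity of the achromatic
channel: the simulation's ground-truth LMS response peaks near 16 Hz
(slightly higher at peripheral eccentricities), and the fit recovers an
interpolated peak of 17.3 Hz with a tight bootstrap interquartile range.
Raw Watson parameters are shown for completeness but are not uniquely
identified; the peak summary is the supported output.

A command-line interface mirrors the library (`flickerfit simulate | fit |
tsf | carryover | patterns | retina | aggregate | run-all`); `run-all`
executes the whole pipeline from a YAML config and writes a manifest with
file hashes for reproducibility.

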