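"""Synthetic BOLD data with the statistical structure the analysis assumes.

The generator produces ground-truth neural amplitudes from direction- and
eccentricity-dependent Watson temporal sensitivity functions, applies
first-order multiplicative carry-over modulation, adds reproducible
multi-vertex spatial patterns per frequency, attention-event impulse
responses, slow sinusoidal drift and white Gaussian noise, and convolves
with the HRF per acquisition.  Every draw is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as dsn
from .design import StimulusSchedule, FREQUENCIES_HZ, TR_S
from .hrf import HRFBasis, kernel_from_params
from .maps import assign_band, N_BANDS
from .watson import WatsonParams, watson_amplitude, params_for_peak


@dataclass(frozen=True)
class DriftSpec:
    """Slow sinusoidal drift below the analysis high-pass cutoff."""

    amplitude: float = 1.0
    frequency_hz: float = 0.01


#: ground-truth TSF peak targets (Hz) and peak amplitudes (%BOLD) by direction
DEFAULT_PEAKS_HZ = {"LMS": 16.0, "L-M": 12.0, "S": 8.0}
DEFAULT_PEAK_AMPS = {"LMS": 3.0, "L-M": 1.5, "S": 1.0}
#: multiplicative shift of the peak frequency per eccentricity band
DEFAULT_BAND_PEAK_FACTORS = tuple(1.0 + 0.05 * b for b in range(N_BANDS))


@dataclass
class GroundTruth:
    """True generative parameters of a simulated study.

    ``watson_params[direction][band]`` gives the TSF of each direction in
    each of the six eccentricity bands.  ``carryover_gain[i, j]`` multiplies
    the neural amplitude of a trial of frequency j when the immediately
    preceding trial had frequency i (all ones = no adaptation).
    ``pattern_scale`` is the SD in %BOLD of the fixed per-vertex,
    per-frequency spatial pattern perturbations.
    """

    watson_params: dict[str, list[WatsonParams]]
    carryover_gain: np.ndarray = field(
        default_factory=lambda: np.ones((len(FREQUENCIES_HZ), len(FREQUENCIES_HZ)))
    )
    pattern_scale: float = 0.25
    attention_amplitude: float = 1.0
    noise_sd: float = 0.5
    drift: DriftSpec = field(default_factory=DriftSpec)

    @classmethod
    def default(
        cls,
        pattern_scale: float = 0.25,
        noise_sd: float = 0.5,
        attention_amplitude: float = 1.0,
        drift: DriftSpec | None = None,
        carryover_gain: np.ndarray | None = None,
        peaks_hz: dict[str, float] | None = None,
        peak_amps: dict[str, float] | None = None,
    ) -> "GroundTruth":
        """Study-default conditions: Watson TSFs peaking near 16 Hz (LMS),
        12 Hz (L-M) and 8 Hz (S) with chromatic amplitude scaling, peak
        frequency drifting slightly upward with eccentricity band."""
        peaks = peaks_hz or DEFAULT_PEAKS_HZ
        amps = peak_amps or DEFAULT_PEAK_AMPS
        watson = {
            d: [
                params_for_peak(peaks[d] * DEFAULT_BAND_PEAK_FACTORS[b], amps[d])
                for b in range(N_BANDS)
            ]
            for d in peaks
        }
        kwargs = {}
        if carryover_gain is not None:
            kwargs["carryover_gain"] = np.asarray(carryover_gain, dtype=float)
        if drift is not None:
            kwargs["drift"] = drift
        return cls(
            watson_params=watson,
            pattern_scale=pattern_scale,
            noise_sd=noise_sd,
            attention_amplitude=attention_amplitude,
            **kwargs,
        )

    @classmethod
    def noiseless(cls, **kwargs) -> "GroundTruth":
        """Deterministic configuration: no noise, drift, patterns or carry-over."""
        kwargs.setdefault("pattern_scale", 0.0)
        kwargs.setdefault("noise_sd", 0.0)
        kwargs.setdefault("drift", DriftSpec(amplitude=0.0))
        return cls.default(**kwargs)


@dataclass
class BOLDDataset:
    """Vertices x time BOLD matrix in percent-signal-change units."""

    data: np.ndarray
    schedules: list[StimulusSchedule]
    geometry: pd.DataFrame
    acquisition_n_samples: int = dsn.ACQUISITION_N_SAMPLES

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_acquisitions(self) -> int:
        return len(self.schedules)

    def validate(self) -> None:
        if self.data.shape[1] != self.acquisition_n_samples * self.n_acquisitions:
            raise ValueError("time length does not match acquisitions")
        ecc = self.geometry["eccentricity_deg"].to_numpy()
        if np.any(ecc < 0) or np.any(ecc > 90):
            raise ValueError("eccentricities must lie in [0, 90]")


def make_vertex_geometry(
    n_vertices: int, seed: int, areas: tuple[str, ...] = ("V1",)
) -> pd.DataFrame:
    """Synthetic vertex geometry table standing in for a retinotopy template.

    Eccentricity is log-uniform on [0.5, 90] degrees, polar angle uniform,
    and pRF width grows linearly with eccentricity with multiplicative
    lognormal scatter (the standard cortical magnification trend).
    """
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    rng = np.random.default_rng(seed)
    ecc = 10.0 ** rng.uniform(np.log10(0.5), np.log10(90.0), size=n_vertices)
    angle = rng.uniform(0.0, 360.0, size=n_vertices)
    width = (0.5 + 0.15 * ecc) * np.exp(rng.normal(0.0, 0.2, size=n_vertices))
    return pd.DataFrame(
        {
            "eccentricity_deg": ecc,
            "polar_angle_deg": angle,
            "prf_width_deg": width,
            "area": rng.choice(np.asarray(areas, dtype=object), size=n_vertices),
        }
    )


def neural_amplitude(
    truth: GroundTruth,
    direction: str,
    frequency_hz: float,
    eccentricity_deg: float,
    prior_frequency_hz: float | None = None,
) -> float:
    """Ground-truth neural amplitude (%BOLD) of one trial.

    The Watson amplitude of the band containing the eccentricity, multiplied
    by the carry-over gain for the (prior, current) frequency pair.  The
    0 Hz condition yields 0 by convention.
    """
    if frequency_hz not in FREQUENCIES_HZ:
        raise ValueError(f"frequency {frequency_hz} not in the stimulus set")
    if frequency_hz == 0.0:
        return 0.0
    band = int(assign_band(eccentricity_deg))
    amp = float(watson_amplitude(frequency_hz, truth.watson_params[direction][band]))
    if prior_frequency_hz is not None:
        i = FREQUENCIES_HZ.index(prior_frequency_hz)
        j = FREQUENCIES_HZ.index(frequency_hz)
        amp *= float(truth.carryover_gain[i, j])
    return amp


def _pattern_templates(
    truth: GroundTruth, n_vertices: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fixed per-direction vertex x frequency perturbations (index 0 = 0 Hz row of zeros)."""
    templates = {}
    for d in truth.watson_params:
        t = np.zeros((n_vertices, len(FREQUENCIES_HZ)))
        if truth.pattern_scale > 0:
            t[:, 1:] = rng.normal(0.0, truth.pattern_scale, size=(n_vertices, 6))
        templates[d] = t
    return templates


def true_amplitude_table(
    schedules: list[StimulusSchedule],
    truth: GroundTruth,
    geometry: pd.DataFrame,
    templates: dict[str, np.ndarray] | None = None,
):
    """Expected per-acquisition amplitude table under the generative model.

    Exact for the no-carry-over configuration, in which all trials of one
    frequency within an acquisition share the same amplitude (band Watson
    amplitude plus the vertex's pattern perturbation).
    """
    from .glm import AmplitudeTable

    ecc = geometry["eccentricity_deg"].to_numpy()
    bands = assign_band(ecc)
    rows = []
    for a, sched in enumerate(schedules):
        for f in FREQUENCIES_HZ:
            for v in range(len(ecc)):
                if f == 0.0:
                    amp = 0.0
                else:
                    amp = float(
                        watson_amplitude(f, truth.watson_params[sched.direction][bands[v]])
                    )
                    if templates is not None:
                        amp += float(templates[sched.direction][v, FREQUENCIES_HZ.index(f)])
                rows.append(
                    (v, a, sched.direction, sched.sequence_label, f, amp)
                )
    df = pd.DataFrame(
        rows,
        columns=["vertex", "acquisition", "direction", "sequence_label", "frequency_hz", "amplitude"],
    )
    return AmplitudeTable(df)


def simulate_bold(
    schedules: list[StimulusSchedule],
    truth: GroundTruth,
    basis: HRFBasis,
    geometry: pd.DataFrame,
    seed: int,
    hrf_params: np.ndarray | None = None,
    return_templates: bool = False,
):
    """Forward-simulate a BOLD dataset for the given schedules and geometry.

    Per vertex and acquisition: trial boxcars weighted by ground-truth neural
    amplitudes (Watson TSF x carry-over gain + spatial pattern perturbation)
    plus attention impulses, convolved with the HRF, plus slow drift and
    white noise.  Linear in the neural amplitudes; reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    weights = basis.canonical_weights() if hrf_params is None else np.asarray(hrf_params, float)
    kernel = kernel_from_params(basis, weights)
    s = float(kernel.sum())
    if abs(s) < 1e-8:
        raise ValueError("HRF kernel has (near-)zero integral")
    kernel = kernel / s  # unit-sum kernel: amplitudes are plateau %BOLD
    n_vert = len(geometry)
    ecc = geometry["eccentricity_deg"].to_numpy()
    bands = assign_band(ecc)
    templates = _pattern_templates(truth, n_vert, rng)

    n_samp = schedules[0].n_samples
    segments = []
    t_axis = np.arange(n_samp) * TR_S
    for sched in schedules:
        if sched.n_samples != n_samp:
            raise ValueError("acquisitions must share a common duration")
        n_trials = len(sched.trials)
        # boxcars: time x trials
        boxcars = np.zeros((n_samp, n_trials))
        amps = np.zeros((n_vert, n_trials))
        prior = None
        for k, trial in enumerate(sched.trials):
            i0 = int(round(trial.onset_s / TR_S))
            i1 = int(round((trial.onset_s + trial.duration_s) / TR_S))
            boxcars[i0:i1, k] = 1.0
            if trial.frequency_hz > 0:
                j = FREQUENCIES_HZ.index(trial.frequency_hz)
                base = np.array(
                    [
                        watson_amplitude(
                            trial.frequency_hz,
                            truth.watson_params[sched.direction][b],
                        )
                        for b in range(N_BANDS)
                    ]
                )[bands]
                gain = 1.0
                if prior is not None:
                    gain = float(
                        truth.carryover_gain[FREQUENCIES_HZ.index(prior), j]
                    )
                amps[:, k] = gain * (base + templates[sched.direction][:, j])
            prior = trial.frequency_hz
        neural = (boxcars @ amps.T).T  # vertices x time
        impulses = np.zeros(n_samp)
        for a in sched.attention_onsets:
            impulses[min(int(a // TR_S), n_samp - 1)] += truth.attention_amplitude
        neural += impulses[None, :]
        bold = dsn.convolve_columns(neural.T, kernel).T
        if truth.drift.amplitude > 0:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_vert)
            bold += truth.drift.amplitude * np.sin(
                2.0 * np.pi * truth.drift.frequency_hz * t_axis[None, :] + phases[:, None]
            )
        if truth.noise_sd > 0:
            bold += rng.normal(0.0, truth.noise_sd, size=bold.shape)
        segments.append(bold)
    data = np.concatenate(segments, axis=1)
    ds = BOLDDataset(data=data, schedules=list(schedules), geometry=geometry)
    ds.validate()
    if return_templates:
        return ds, templates
    return ds
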