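"""Watson difference-of-exponentials temporal sensitivity model.

The frequency response is the difference of a fast center filter and a slow
surround filter, each a cascade of exponential low-pass stages:

    H_center(w)   = (i 2 pi w tau_c + 1)^(-nc)
    H_surround(w) = G_s (i 2 pi w tau_s + 1)^(-ns),  tau_s = r tau_c
    H(w)          = G (H_center - H_surround)

with filter orders nc = 9 and ns = 10 held fixed.  Free parameters are the
overall gain G, the center time constant tau_c, the surround/center time
constant ratio r >= 1, and the relative surround gain 0 <= G_s <= 1.  The
response amplitude is the complex modulus |H|.  The model is deliberately
summarized by its interpolated peak (amplitude and frequency on a dense
log-spaced grid) rather than by the raw parameters, which are not uniquely
identified by six-frequency data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

N_CENTER = 9
N_SURROUND = 10

#: bounds realizing the model's linear constraints
TAU_CENTER_BOUNDS_S = (1e-4, 0.1)
TAU_RATIO_BOUNDS = (1.0, 20.0)
SURROUND_GAIN_BOUNDS = (0.0, 1.0)

#: log-spaced interpolation grid for peak extraction: 0.5-100 Hz, 0.01 log10 step
PEAK_GRID_HZ = 10.0 ** np.arange(np.log10(0.5), 2.0 + 1e-12, 0.01)


@dataclass(frozen=True)
class WatsonParams:
    """Difference-of-exponentials parameters; gain in response units (%BOLD)."""

    gain: float
    tau_center_s: float
    tau_ratio: float
    surround_gain: float
    n_center: int = N_CENTER
    n_surround: int = N_SURROUND

    def validate(self) -> None:
        if not (self.tau_center_s > 0):
            raise ValueError("tau_center_s must be positive")
        if self.tau_ratio < 1.0:
            raise ValueError("tau_ratio must be >= 1")
        if not (0.0 <= self.surround_gain <= 1.0):
            raise ValueError("surround_gain must lie in [0, 1]")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


def watson_response(freq_hz, params: WatsonParams):
    """Complex frequency response H(w)."""
    w = np.asarray(freq_hz, dtype=float)
    jw = 1j * 2.0 * np.pi * w
    h_center = (jw * params.tau_center_s + 1.0) ** (-params.n_center)
    tau_s = params.tau_ratio * params.tau_center_s
    h_surround = params.surround_gain * (jw * tau_s + 1.0) ** (-params.n_surround)
    return params.gain * (h_center - h_surround)


def watson_amplitude(freq_hz, params: WatsonParams):
    """Response amplitude |H(w)| (modulus taken after the complex subtraction)."""
    return np.abs(watson_response(freq_hz, params))


def peak_of_fit(
    params: WatsonParams, grid_hz: np.ndarray | None = None
) -> tuple[float, float]:
    """Interpolated peak: (frequency, amplitude) of the dense-grid maximum."""
    grid = PEAK_GRID_HZ if grid_hz is None else grid_hz
    amp = watson_amplitude(grid, params)
    i = int(np.argmax(amp))
    return float(grid[i]), float(amp[i])


def is_unimodal(params: WatsonParams, grid_hz: np.ndarray | None = None) -> bool:
    """Check |H| has no local maximum other than the global one on the grid.

    First differences are signed with a relative tolerance; after dropping
    zeros and collapsing runs, the sign pattern must be one of
    [], [+], [-], [+, -].
    """
    grid = PEAK_GRID_HZ if grid_hz is None else grid_hz
    amp = watson_amplitude(grid, params)
    d = np.diff(amp)
    tol = 1e-12 * max(1.0, float(np.max(amp)))
    signs = np.sign(np.where(np.abs(d) < tol, 0.0, d))
    collapsed: list[float] = []
    for s in signs:
        if s != 0 and (not collapsed or collapsed[-1] != s):
            collapsed.append(s)
    return collapsed in ([], [1.0], [-1.0], [1.0, -1.0])


class TSFFitError(RuntimeError):
    """Raised when no feasible (unimodal, in-bounds) fit is found."""


def _shape_amplitude(freqs: np.ndarray, log_tau: float, ratio: float, gs: float):
    p = WatsonParams(1.0, 10.0 ** log_tau, ratio, gs)
    return watson_amplitude(freqs, p)


def _default_starts() -> list[tuple[float, float, float]]:
    # (log10 tau_center, tau_ratio, surround_gain) lattice
    return [
        (lt, r, g)
        for lt in (-3.2, -2.6, -2.2, -1.8, -1.3)
        for r in (1.5, 3.0)
        for g in (0.3, 0.9)
    ]


def fit_tsf(
    frequencies_hz,
    amplitudes,
    starts: list[tuple[float, float, float]] | None = None,
    require_unimodal: bool = True,
) -> WatsonParams:
    """Constrained least-squares fit of the Watson amplitude model.

    Multi-start trust-region fits over (gain, log10 tau_center, tau_ratio,
    surround_gain) within the parameter bounds; the unimodality of |H| on the
    dense peak grid is enforced as a feasibility check on candidate solutions.
    Negative data values are fit as-is against the non-negative model (they
    simply penalize the residual).
    """
    freqs = np.asarray(frequencies_hz, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if freqs.shape != amps.shape or freqs.size < 4:
        raise ValueError("need >= 4 matching (frequency, amplitude) pairs")

    if float(np.max(np.abs(amps))) == 0.0:
        return WatsonParams(0.0, 0.01, 2.0, 0.5)

    lo = [np.log10(TAU_CENTER_BOUNDS_S[0]), TAU_RATIO_BOUNDS[0], SURROUND_GAIN_BOUNDS[0]]
    hi = [np.log10(TAU_CENTER_BOUNDS_S[1]), TAU_RATIO_BOUNDS[1], SURROUND_GAIN_BOUNDS[1]]

    def best_gain(shape: np.ndarray) -> float:
        # gain solves a 1-D linear least squares, clipped at the G >= 0 bound
        denom = float(shape @ shape)
        return max(0.0, float(shape @ amps) / denom) if denom > 0 else 0.0

    def residual(x):
        shape = _shape_amplitude(freqs, *x)
        return best_gain(shape) * shape - amps

    best: WatsonParams | None = None
    best_sse = np.inf
    for start in starts if starts is not None else _default_starts():
        try:
            sol = least_squares(
                residual,
                x0=np.clip(start, lo, hi),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
                max_nfev=200,
            )
        except Exception:
            continue
        sse = float(sol.fun @ sol.fun)
        cand = WatsonParams(
            gain=best_gain(_shape_amplitude(freqs, *sol.x)),
            tau_center_s=float(10.0 ** sol.x[0]),
            tau_ratio=float(sol.x[1]),
            surround_gain=float(sol.x[2]),
        )
        if sse < best_sse - 1e-15 and (not require_unimodal or is_unimodal(cand)):
            best, best_sse = cand, sse
    if best is None:
        raise TSFFitError(
            "no feasible unimodal Watson fit found; "
            f"data range [{amps.min():.3g}, {amps.max():.3g}] over "
            f"{freqs.size} frequencies"
        )
    return best


def params_for_peak(
    peak_hz: float,
    peak_amplitude: float = 1.0,
    tau_ratio: float = 1.5,
    surround_gain: float = 0.8,
) -> WatsonParams:
    """Watson parameters whose dense-grid peak sits at the requested point.

    The peak frequency is monotone decreasing in tau_center for fixed shape
    parameters, so tau_center is found by bisection on the grid peak; the
    gain is then rescaled to hit the requested peak amplitude.
    """
    lo, hi = np.log10(TAU_CENTER_BOUNDS_S[0]), np.log10(TAU_CENTER_BOUNDS_S[1])

    def grid_peak(log_tau: float) -> float:
        p = WatsonParams(1.0, 10.0 ** log_tau, tau_ratio, surround_gain)
        return peak_of_fit(p)[0]

    if not (grid_peak(hi) <= peak_hz <= grid_peak(lo)):
        raise ValueError(f"peak {peak_hz} Hz unreachable within tau_center bounds")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if grid_peak(mid) > peak_hz:
            lo = mid
        else:
            hi = mid
    p = WatsonParams(1.0, 10.0 ** (0.5 * (lo + hi)), tau_ratio, surround_gain)
    _, amp = peak_of_fit(p)
    return replace(p, gain=peak_amplitude / amp)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class TSFSummary:
    """Bootstrap summary of a temporal sensitivity function."""

    frequencies_hz: np.ndarray
    amplitude_median: np.ndarray
    amplitude_iqr_low: np.ndarray
    amplitude_iqr_high: np.ndarray
    peak_freq_hz_median: float
    peak_freq_hz_iqr: tuple[float, float]
    peak_amp_median: float
    peak_amp_iqr: tuple[float, float]
    n_boot: int
    peak_freq_replicates: np.ndarray | None = None
    peak_amp_replicates: np.ndarray | None = None


class WatsonTSFModel:
    """Temporal sensitivity model for amplitude-vs-frequency data.

    ``acquisition_amplitudes`` is an (n_acquisitions x n_frequencies) matrix
    of relative response amplitudes (already referenced to the 0 Hz
    condition); the model is fit to the across-acquisition mean and
    uncertainty is obtained by resampling acquisitions with replacement.
    """

    def __init__(self, frequencies_hz, acquisition_amplitudes):
        self.frequencies_hz = np.asarray(frequencies_hz, dtype=float)
        amps = np.atleast_2d(np.asarray(acquisition_amplitudes, dtype=float))
        if amps.shape[1] != self.frequencies_hz.size:
            raise ValueError("amplitude matrix does not match frequency count")
        self.acquisition_amplitudes = amps

    @classmethod
    def from_amplitude_table(cls, table, direction: str, vertex=None):
        """Build from a fitted :class:`~flickerfit.glm.AmplitudeTable`.

        Uses relative (0 Hz-referenced) amplitudes at the six non-zero
        stimulus frequencies for the requested direction, optionally for a
        single vertex (otherwise averaged across vertices).
        """
        from .design import NONZERO_FREQUENCIES_HZ

        rel = table.relative().table
        rel = rel[(rel["direction"] == direction) & (rel["frequency_hz"] > 0)]
        if vertex is not None:
            rel = rel[rel["vertex"] == vertex]
        else:
            rel = (
                rel.groupby(["acquisition", "frequency_hz"], as_index=False)["amplitude"]
                .mean()
            )
        pivot = rel.pivot_table(
            index="acquisition", columns="frequency_hz", values="amplitude"
        )
        pivot = pivot.reindex(columns=list(NONZERO_FREQUENCIES_HZ))
        return cls(np.array(NONZERO_FREQUENCIES_HZ), pivot.to_numpy())

    def fit(self, **kwargs) -> "WatsonTSFResults":
        mean_amps = self.acquisition_amplitudes.mean(axis=0)
        params = fit_tsf(self.frequencies_hz, mean_amps, **kwargs)
        return WatsonTSFResults(self, params)


@dataclass
class WatsonTSFResults:
    """Fitted Watson model: parameters, interpolated peak, bootstrap summary."""

    model: WatsonTSFModel
    params: WatsonParams
    _bootstrap: TSFSummary | None = field(default=None, repr=False)

    @property
    def peak_freq_hz(self) -> float:
        return peak_of_fit(self.params)[0]

    @property
    def peak_amp(self) -> float:
        return peak_of_fit(self.params)[1]

    def predict(self, freq_hz):
        return watson_amplitude(freq_hz, self.params)

    def bootstrap(
        self, n_boot: int = 1000, seed: int = 0, keep_replicates: bool = False
    ) -> TSFSummary:
        """Bootstrap across acquisitions: per replicate, resample the
        acquisitions with replacement, average, refit (warm-started at the
        full-sample solution), and extract the interpolated peak; report
        medians and interquartile ranges."""
        rng = np.random.default_rng(seed)
        amps = self.model.acquisition_amplitudes
        n_acq = amps.shape[0]
        if n_acq < 2:
            raise ValueError("need >= 2 acquisitions to bootstrap")
        warm = (
            np.log10(self.params.tau_center_s),
            self.params.tau_ratio,
            self.params.surround_gain,
        )
        fallback = [(-2.6, 1.5, 0.9), (-2.0, 3.0, 0.3)]
        peak_f = np.empty(n_boot)
        peak_a = np.empty(n_boot)
        rep_amps = np.empty((n_boot, amps.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n_acq, size=n_acq)
            mean_b = amps[idx].mean(axis=0)
            rep_amps[b] = mean_b
            try:
                p = fit_tsf(self.model.frequencies_hz, mean_b, starts=[warm])
            except TSFFitError:
                p = fit_tsf(self.model.frequencies_hz, mean_b, starts=fallback)
            peak_f[b], peak_a[b] = peak_of_fit(p)
        q = lambda a, p: np.percentile(a, p, axis=0)
        return TSFSummary(
            frequencies_hz=self.model.frequencies_hz.copy(),
            amplitude_median=np.median(rep_amps, axis=0),
            amplitude_iqr_low=q(rep_amps, 25),
            amplitude_iqr_high=q(rep_amps, 75),
            peak_freq_hz_median=float(np.median(peak_f)),
            peak_freq_hz_iqr=(float(q(peak_f, 25)), float(q(peak_f, 75))),
            peak_amp_median=float(np.median(peak_a)),
            peak_amp_iqr=(float(q(peak_a, 25)), float(q(peak_a, 75))),
            n_boot=n_boot,
            peak_freq_replicates=peak_f if keep_replicates else None,
            peak_amp_replicates=peak_a if keep_replicates else None,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Watson temporal sensitivity fit",
            "-" * 39,
            f"gain G               {p.gain:10.4f}",
            f"tau_center (s)       {p.tau_center_s:10.5f}",
            f"tau_ratio            {p.tau_ratio:10.4f}",
            f"surround gain G_s    {p.surround_gain:10.4f}",
            f"filter orders        nc={p.n_center}, ns={p.n_surround} (fixed)",
            f"peak frequency (Hz)  {self.peak_freq_hz:10.2f}",
            f"peak amplitude       {self.peak_amp:10.4f}",
        ]
        return "\n".join(lines)


def bootstrap_tsf(table, direction: str, n_boot: int = 1000, seed: int = 0) -> TSFSummary:
    """Bootstrap TSF summary for one stimulus direction of an AmplitudeTable."""
    model = WatsonTSFModel.from_amplitude_table(table, direction)
    return model.fit().bootstrap(n_boot=n_boot, seed=seed)
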