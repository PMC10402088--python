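"""First-order carry-over (adaptation) analysis.

After the time-series model has absorbed the mean response to each stimulus
frequency, the region-averaged residual is regressed on a prior x subsequent
design: one covariate per ordered pair of stimulus frequencies, a 12 s
boxcar over every trial whose own frequency is the "subsequent" member and
whose immediately preceding trial within the same acquisition had the
"prior" frequency.  With seven frequencies this gives 49 covariates,
constructed separately for achromatic (LMS) trials and for chromatic (L-M
and S pooled) trials, convolved with the fitted regional HRF and high-pass
filtered identically to the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import design as dsn
from .design import FREQUENCIES_HZ, TR_S, StimulusSchedule

N_FREQ = len(FREQUENCIES_HZ)

STIMULUS_CLASSES = {
    "achromatic": ("LMS",),
    "chromatic": ("L-M", "S"),
}


@dataclass
class CarryoverMatrix:
    """7x7 modulation estimates: rows = prior frequency, cols = subsequent.

    Cells for (prior, subsequent) pairs absent from the class's schedule are
    NaN (undefined), not zero.
    """

    values: np.ndarray
    stimulus_class: str
    frequencies_hz: tuple[float, ...] = FREQUENCIES_HZ
    flags: np.ndarray | None = None


def residual_signal(results, mask=None) -> np.ndarray:
    """Region-averaged high-passed residual of the full fitted model.

    ``mask`` selects positions within the fitted vertex set (default: all
    fitted vertices); residuals are averaged across the region, consistent
    with obtaining the residual signal from one visual area.
    """
    idx = range(len(results.model.vertex_indices)) if mask is None else np.atleast_1d(mask)
    res = [results.filtered_residual(int(i)) for i in idx]
    return np.mean(res, axis=0)


def build_carryover_covariates(
    schedules: list[StimulusSchedule],
    stimulus_class: str,
    hrf_kernel: np.ndarray,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """49 prior x subsequent covariates on the full concatenated time axis.

    The first trial of each acquisition has no prior and is excluded.  Only
    acquisitions of the requested stimulus class contribute support; the
    covariates are convolved with ``hrf_kernel`` per acquisition.

    Returns (matrix: time x 49, labels: ordered (prior_hz, subsequent_hz)).
    """
    if stimulus_class not in STIMULUS_CLASSES:
        raise ValueError(f"unknown stimulus class {stimulus_class!r}")
    directions = STIMULUS_CLASSES[stimulus_class]
    n_samp = schedules[0].n_samples
    n_time = sum(s.n_samples for s in schedules)
    cov = np.zeros((n_time, N_FREQ * N_FREQ))
    labels = [(fi, fj) for fi in FREQUENCIES_HZ for fj in FREQUENCIES_HZ]
    offset = 0
    for sched in schedules:
        if sched.direction in directions:
            block = np.zeros((sched.n_samples, N_FREQ * N_FREQ))
            prior = None
            for trial in sched.trials:
                if prior is not None:
                    i = FREQUENCIES_HZ.index(prior)
                    j = FREQUENCIES_HZ.index(trial.frequency_hz)
                    i0 = int(round(trial.onset_s / TR_S))
                    i1 = int(round((trial.onset_s + trial.duration_s) / TR_S))
                    block[i0:i1, i * N_FREQ + j] = 1.0
                prior = trial.frequency_hz
            block = fftconvolve(block, hrf_kernel[:, None], axes=0)[: sched.n_samples]
            cov[offset : offset + sched.n_samples] = block
        offset += sched.n_samples
    return cov, labels


def fit_carryover(
    residual: np.ndarray,
    covariates: np.ndarray,
    stimulus_class: str,
    segment_length: int = dsn.ACQUISITION_N_SAMPLES,
    cutoff_hz: float = dsn.HIGHPASS_CUTOFF_HZ,
) -> CarryoverMatrix:
    """OLS of the residual on the carry-over covariates, arranged 7x7.

    Covariates are high-pass filtered per acquisition to match the residual.
    Pairs with no supporting trial yield NaN cells; collinearity among
    supported covariates raises.
    """
    residual = np.asarray(residual, dtype=float)
    covf = dsn.highpass_project(
        covariates.T, cutoff_hz=cutoff_hz, segment_length=segment_length
    ).T
    support = np.linalg.norm(covf, axis=0) > 1e-10
    x = covf[:, support]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError(
            "carry-over design is rank deficient among supported pairs"
        )
    beta, *_ = np.linalg.lstsq(x, residual, rcond=None)
    values = np.full(N_FREQ * N_FREQ, np.nan)
    values[support] = beta
    return CarryoverMatrix(values.reshape(N_FREQ, N_FREQ), stimulus_class)


def estimate_carryover(
    results,
    stimulus_class: str,
    mask=None,
) -> CarryoverMatrix:
    """Full carry-over pipeline for a fitted time-series model.

    Uses the region-average fitted HRF kernel for convolution and the
    region-averaged residual signal.
    """
    idx = (
        np.arange(len(results.model.vertex_indices)) if mask is None else np.atleast_1d(mask)
    )
    kernel = np.mean([results.kernel(int(i)) for i in idx], axis=0)
    resid = residual_signal(results, mask=idx)
    cov, _ = build_carryover_covariates(
        results.model.data.schedules, stimulus_class, kernel
    )
    return fit_carryover(
        resid, cov, stimulus_class, segment_length=results.model.n_samp
    )


def flag_cells(matrices: list[CarryoverMatrix | np.ndarray]) -> np.ndarray:
    """Reliability flags across participants: |mean| > 2 x SEM per cell.

    SEM uses the n-1 denominator; a cell whose values agree exactly across
    participants (SEM 0) is flagged whenever its mean is nonzero.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 participant matrices")
    stack = np.stack(
        [m.values if isinstance(m, CarryoverMatrix) else np.asarray(m) for m in matrices]
    )
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return np.abs(mean) > 2.0 * sem
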