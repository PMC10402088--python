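"""Stimulus sequences, trial timing, and regression design for the flicker study.

The experiment presents 12 s trials of spectral flicker at one of seven
log-spaced temporal frequencies (0, 2, 4, 8, 16, 32, 64 Hz), each acquisition
targeting one post-receptoral direction (achromatic LMS, red-green L-M, or
blue-yellow S).  A first-order counterbalanced master ordering of the seven
frequencies (every ordered pair of conditions, including repeats, appears
exactly once as consecutive elements) is split into two half-sequences "A"
and "B", each padded with three 0 Hz trials, giving 28 trials / 336 s per
acquisition.  Six blocks of six acquisitions (LMS_A, L-M_A, S_A, S_B, L-M_B,
LMS_B) make up the 36-acquisition study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

TR_S = 1.0
TRIAL_DURATION_S = 12.0
TRIALS_PER_ACQUISITION = 28
ACQUISITION_DURATION_S = 336.0
ACQUISITION_N_SAMPLES = int(round(ACQUISITION_DURATION_S / TR_S))

FREQUENCIES_HZ = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
NONZERO_FREQUENCIES_HZ = FREQUENCIES_HZ[1:]
DIRECTIONS = ("LMS", "L-M", "S")

#: within-block acquisition order: (direction, sequence label)
BLOCK_ORDER = (
    ("LMS", "A"), ("L-M", "A"), ("S", "A"),
    ("S", "B"), ("L-M", "B"), ("LMS", "B"),
)
N_BLOCKS = 6
N_ACQUISITIONS = N_BLOCKS * len(BLOCK_ORDER)

HIGHPASS_CUTOFF_HZ = 0.0387

ATTENTION_PROBABILITY = 0.33
ATTENTION_DURATION_S = 0.25
ATTENTION_GUARD_S = 2.0


# ---------------------------------------------------------------------------
# counterbalanced sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CounterbalancedSequence:
    """First-order (type-1 index-1) counterbalanced condition ordering.

    ``elements`` holds condition indices in 1..K.  The sequence has K**2 + 1
    elements and every ordered pair of conditions (i, j), including i == j,
    occurs exactly once among consecutive element pairs.
    """

    elements: tuple[int, ...]
    n_conditions: int

    def pair_counts(self) -> np.ndarray:
        """K x K matrix counting occurrences of each consecutive ordered pair."""
        counts = np.zeros((self.n_conditions, self.n_conditions), dtype=int)
        for a, b in zip(self.elements[:-1], self.elements[1:]):
            counts[a - 1, b - 1] += 1
        return counts

    def validate(self) -> None:
        k = self.n_conditions
        if len(self.elements) != k * k + 1:
            raise ValueError(
                f"sequence has {len(self.elements)} elements, expected {k * k + 1}"
            )
        if not all(1 <= e <= k for e in self.elements):
            raise ValueError("element out of range 1..K")
        if not np.array_equal(self.pair_counts(), np.ones((k, k), dtype=int)):
            raise ValueError("consecutive-pair counts are not all exactly one")


def make_counterbalanced_sequence(
    n_conditions: int, seed: int, max_restarts: int = 50
) -> CounterbalancedSequence:
    """Build a first-order counterbalanced sequence over ``n_conditions``.

    Uses a seeded randomized Hierholzer walk on the complete directed graph
    with self-loops over K nodes: every ordered pair of conditions is an edge,
    all in/out degrees equal K, so an Eulerian circuit exists; opening the
    circuit yields the K**2 + 1 element sequence.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    k = n_conditions
    for _ in range(max_restarts):
        out_edges = {
            u: list(rng.permutation(np.arange(1, k + 1))) for u in range(1, k + 1)
        }
        start = int(rng.integers(1, k + 1))
        stack = [start]
        circuit: list[int] = []
        while stack:
            v = stack[-1]
            if out_edges[v]:
                stack.append(int(out_edges[v].pop()))
            else:
                circuit.append(stack.pop())
        circuit.reverse()
        seq = CounterbalancedSequence(tuple(circuit), k)
        try:
            seq.validate()
        except ValueError:
            continue
        return seq
    raise RuntimeError(
        f"no counterbalanced sequence found for K={k} in {max_restarts} restarts"
    )


def frequency_of_condition(condition: int) -> float:
    """Map condition index 1..7 to its flicker frequency in Hz."""
    return FREQUENCIES_HZ[condition - 1]


def split_and_pad(seq: CounterbalancedSequence) -> tuple[list[float], list[float]]:
    """Split the 50-element master sequence into the A/B trial frequency lists.

    A takes elements 1-25, B elements 26-50; each is padded with three 0 Hz
    trials at the end, giving two 28-trial lists.
    """
    if len(seq.elements) != 50:
        raise ValueError(f"expected a 50-element sequence, got {len(seq.elements)}")
    freqs = [frequency_of_condition(c) for c in seq.elements]
    pad = [0.0, 0.0, 0.0]
    return freqs[:25] + pad, freqs[25:] + pad


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    onset_s: float
    duration_s: float
    frequency_hz: float


@dataclass
class StimulusSchedule:
    """Trial timing for one 336 s acquisition.

    ``attention_onsets`` are onsets of the 250 ms attention events (a brief
    darkening of the field), which never fall in the first or last 2 s of a
    trial.  Half-cosine windowing of trial on/offsets is stimulus metadata
    only and does not alter the 12 s step covariates.
    """

    direction: str
    sequence_label: str
    trials: list[Trial]
    attention_onsets: list[float] = field(default_factory=list)
    acquisition_duration_s: float = ACQUISITION_DURATION_S

    @property
    def n_samples(self) -> int:
        return int(round(self.acquisition_duration_s / TR_S))

    def validate(self) -> None:
        if len(self.trials) != TRIALS_PER_ACQUISITION:
            raise ValueError(f"expected 28 trials, got {len(self.trials)}")
        for t in self.trials[-3:]:
            if t.frequency_hz != 0.0:
                raise ValueError("last three trials must be 0 Hz padding")
        for a in self.attention_onsets:
            trial = self.trials[int(a // TRIAL_DURATION_S)]
            if not (
                trial.onset_s + ATTENTION_GUARD_S
                <= a
                <= trial.onset_s + TRIAL_DURATION_S - ATTENTION_GUARD_S - ATTENTION_DURATION_S
            ):
                raise ValueError(f"attention event at {a} s violates the 2 s guard")


def _schedule_from_freqs(
    direction: str, label: str, freqs: list[float], rng: np.random.Generator
) -> StimulusSchedule:
    trials = [
        Trial(onset_s=i * TRIAL_DURATION_S, duration_s=TRIAL_DURATION_S, frequency_hz=f)
        for i, f in enumerate(freqs)
    ]
    attention = []
    lo = ATTENTION_GUARD_S
    hi = TRIAL_DURATION_S - ATTENTION_GUARD_S - ATTENTION_DURATION_S
    for t in trials:
        if rng.random() < ATTENTION_PROBABILITY:
            attention.append(float(t.onset_s + rng.uniform(lo, hi)))
    return StimulusSchedule(direction, label, trials, attention)


def build_study_schedule(seed: int) -> list[StimulusSchedule]:
    """Build the 36 acquisitions of the full study from a single seed.

    One counterbalanced master ordering is drawn and shared by all blocks;
    attention events are drawn independently per trial (probability 0.33,
    onset uniform within the allowed window).
    """
    rng = np.random.default_rng(seed)
    master = make_counterbalanced_sequence(7, seed=int(rng.integers(2**31)))
    freqs_a, freqs_b = split_and_pad(master)
    schedules = []
    for _ in range(N_BLOCKS):
        for direction, label in BLOCK_ORDER:
            freqs = freqs_a if label == "A" else freqs_b
            schedules.append(_schedule_from_freqs(direction, label, freqs, rng))
    return schedules


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Stimulus/attention regressors for one or more concatenated acquisitions.

    ``matrix`` is time points x covariates.  Each acquisition contributes one
    0/1 step-function covariate per stimulus frequency (all trials of that
    frequency share the column) and one unit-impulse attention covariate.
    Convolution, when applied, is per acquisition with truncation at the
    acquisition boundary (acquisitions are separated by rest on the
    background, so responses do not bleed across them).
    """

    matrix: np.ndarray
    labels: list[tuple[int, str]]
    convolved: bool

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]


def _acquisition_design(schedule: StimulusSchedule) -> np.ndarray:
    """Unconvolved 336 x 8 design block for one acquisition."""
    n = schedule.n_samples
    x = np.zeros((n, len(FREQUENCIES_HZ) + 1))
    for t in schedule.trials:
        if t.frequency_hz not in FREQUENCIES_HZ:
            raise ValueError(f"unknown stimulus frequency {t.frequency_hz} Hz")
        j = FREQUENCIES_HZ.index(t.frequency_hz)
        i0 = int(round(t.onset_s / TR_S))
        i1 = int(round((t.onset_s + t.duration_s) / TR_S))
        x[i0:i1, j] = 1.0
    for a in schedule.attention_onsets:
        x[min(int(a // TR_S), n - 1), -1] += 1.0
    return x


def convolve_columns(block: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each column with ``kernel`` and truncate to the block length."""
    n = block.shape[0]
    return fftconvolve(block, kernel[:, None], axes=0)[:n]


def build_design_matrix(
    schedules: list[StimulusSchedule], hrf_kernel: np.ndarray | None = None
) -> DesignMatrix:
    """Assemble the concatenated design for a list of acquisitions.

    For the full 36-acquisition study this yields 8 x 36 = 288 columns
    (7 frequency covariates + 1 attention covariate per acquisition).
    """
    labels: list[tuple[int, str]] = []
    n_total = sum(s.n_samples for s in schedules)
    offset = 0
    col = 0
    matrix = np.zeros((n_total, 8 * len(schedules)))
    for a, sched in enumerate(schedules):
        x = _acquisition_design(sched)
        if hrf_kernel is not None:
            x = convolve_columns(x, hrf_kernel)
        matrix[offset:offset + sched.n_samples, col:col + 8] = x
        labels.extend((a, f"{f:g}Hz") for f in FREQUENCIES_HZ)
        labels.append((a, "attention"))
        offset += sched.n_samples
        col += 8
    return DesignMatrix(matrix=matrix, labels=labels, convolved=hrf_kernel is not None)


# ---------------------------------------------------------------------------
# high-pass filtering
# ---------------------------------------------------------------------------

def dct_highpass_basis(
    n_samples: int, cutoff_hz: float = HIGHPASS_CUTOFF_HZ, tr_s: float = TR_S
) -> np.ndarray:
    """Orthonormal basis of slow regressors: constant + DCT-II terms below cutoff."""
    t = np.arange(n_samples)
    cols = [np.full(n_samples, 1.0 / np.sqrt(n_samples))]
    k = 1
    while k / (2.0 * n_samples * tr_s) < cutoff_hz:
        c = np.cos(np.pi * k * (t + 0.5) / n_samples)
        cols.append(c / np.linalg.norm(c))
        k += 1
    return np.column_stack(cols)


def highpass_project(
    signal: np.ndarray,
    cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
    tr_s: float = TR_S,
    segment_length: int | None = None,
) -> np.ndarray:
    """Residual after projecting out slow drift, applied per acquisition.

    ``signal`` has time on its last axis; ``segment_length`` (default: the
    whole signal as one segment) splits the time axis into equal acquisitions
    that are filtered independently.  Idempotent (the DCT set is a fixed
    subspace and this is an orthogonal projection residual).
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n == 0:
        raise ValueError("empty signal")
    seg = n if segment_length is None else int(segment_length)
    if n % seg != 0:
        raise ValueError(f"signal length {n} is not a multiple of segment {seg}")
    out = np.empty_like(signal)
    basis = dct_highpass_basis(seg, cutoff_hz, tr_s)
    for i in range(n // seg):
        sl = slice(i * seg, (i + 1) * seg)
        x = signal[..., sl]
        out[..., sl] = x - (x @ basis) @ basis.T
    return out
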