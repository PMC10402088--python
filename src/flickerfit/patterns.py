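"""Multi-vertex pattern standardization, split-half similarity, and decoding.

Per acquisition, the set of 0 Hz-referenced response amplitudes across
vertices for each non-zero stimulus frequency is standardized to zero mean
and unit SD across vertices.  Split-half similarity correlates the
frequency patterns averaged within one half of the acquisitions against
those of the complementary half, averaged over all unordered half
partitions (462 for 12 acquisitions).  Best-match decoding asks whether the
held-out pattern most correlated with a probe frequency's pattern is that
same frequency; with six candidate frequencies chance performance is
1/6 = 0.167.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .design import NONZERO_FREQUENCIES_HZ


@dataclass
class PatternSimilarityMatrix:
    """Split-half Pearson correlations over the non-zero frequencies."""

    values: np.ndarray
    frequencies_hz: tuple[float, ...]
    label: str
    n_partitions: int


def pattern_array(table, directions) -> np.ndarray:
    """(n_acquisitions x 6 x n_vertices) relative-amplitude patterns.

    ``directions`` may be a single direction or a list to pool (e.g. the two
    chromatic directions); pooled acquisitions are stacked along the first
    axis.  Amplitudes are referenced to the 0 Hz condition per acquisition.
    """
    if isinstance(directions, str):
        directions = [directions]
    rel = table.relative().table
    rel = rel[rel["direction"].isin(directions) & (rel["frequency_hz"] > 0)]
    out = []
    for acq, group in rel.groupby("acquisition"):
        pivot = group.pivot_table(
            index="frequency_hz", columns="vertex", values="amplitude"
        ).reindex(index=list(NONZERO_FREQUENCIES_HZ))
        out.append(pivot.to_numpy())
    return np.stack(out)


def standardize_patterns(patterns: np.ndarray) -> np.ndarray:
    """Z-score each (acquisition x frequency) pattern across vertices."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[-1] < 2:
        raise ValueError("need >= 2 vertices to standardize a pattern")
    sd = patterns.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero across-vertex variance: degenerate pattern")
    return (patterns - patterns.mean(axis=-1, keepdims=True)) / sd


def _half_partitions(n_acq: int, max_partitions: int | None = None, seed: int = 0):
    """Unordered partitions of range(n_acq) into equal halves (each once).

    When the full count exceeds ``max_partitions``, a seeded random subset of
    distinct partitions is drawn instead (useful when pooling many
    acquisitions; 12 acquisitions give the exact 462)."""
    if n_acq % 2 != 0:
        raise ValueError("need an even number of acquisitions")
    from math import comb

    total = comb(n_acq - 1, n_acq // 2 - 1)
    if max_partitions is not None and total > max_partitions:
        rng = np.random.default_rng(seed)
        seen = set()
        while len(seen) < max_partitions:
            half = (0,) + tuple(
                sorted(rng.choice(np.arange(1, n_acq), n_acq // 2 - 1, replace=False))
            )
            seen.add(half)
        halves = sorted(seen)
    else:
        halves = [(0,) + c for c in combinations(range(1, n_acq), n_acq // 2 - 1)]
    for half in halves:
        other = tuple(i for i in range(n_acq) if i not in half)
        yield half, other


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of a with every row of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1, keepdims=True)
    bn = np.linalg.norm(bz, axis=1, keepdims=True)
    # constant rows have undefined correlation; report 0 rather than NaN
    az = np.divide(az, an, out=np.zeros_like(az), where=an > 0)
    bz = np.divide(bz, bn, out=np.zeros_like(bz), where=bn > 0)
    return az @ bz.T


def split_half_similarity(
    patterns: np.ndarray,
    label: str = "",
    max_partitions: int | None = None,
    seed: int = 0,
) -> PatternSimilarityMatrix:
    """Average split-half similarity matrix over all half partitions.

    Per partition the two half-averaged pattern sets are correlated for
    every frequency pair and the matrix is symmetrized with its complement
    partition (swapping halves transposes the matrix), making the average
    diagonally symmetric.
    """
    patterns = standardize_patterns(np.asarray(patterns, dtype=float))
    n_acq = patterns.shape[0]
    total = None
    count = 0
    for half, other in _half_partitions(n_acq, max_partitions, seed):
        m = _corr_rows(
            patterns[list(half)].mean(axis=0), patterns[list(other)].mean(axis=0)
        )
        m = 0.5 * (m + m.T)
        total = m if total is None else total + m
        count += 1
    return PatternSimilarityMatrix(
        values=total / count,
        frequencies_hz=NONZERO_FREQUENCIES_HZ,
        label=label,
        n_partitions=count,
    )


def _best_match_correct(probe: np.ndarray, candidates: np.ndarray, target: int) -> bool:
    """True when the probe's best-correlated candidate is the target, with a
    strict, unique winner (ties count as incorrect)."""
    r = _corr_rows(probe[None, :], candidates)[0]
    top = r.max()
    return bool(r[target] == top and np.sum(r == top) == 1)


def decode_target(
    patterns: np.ndarray,
    target_freq_hz: float = 64.0,
    vertex_subset=None,
    max_partitions: int | None = None,
    seed: int = 0,
) -> float:
    """Proportion of split-half cases decoding the target frequency.

    For each unordered half partition (both probe directions), the
    half-averaged pattern of the target frequency is correlated with the six
    held-out frequency patterns; a case is correct when the target wins.
    Evaluable on a vertex subset (e.g. one eccentricity band).
    """
    patterns = np.asarray(patterns, dtype=float)
    if vertex_subset is not None:
        vertex_subset = np.atleast_1d(vertex_subset)
        if vertex_subset.size == 0:
            raise ValueError("empty vertex subset")
        patterns = patterns[..., vertex_subset]
    patterns = standardize_patterns(patterns)
    if patterns.shape[1] < 2:
        raise ValueError("need >= 2 candidate frequencies")
    target = NONZERO_FREQUENCIES_HZ.index(target_freq_hz)
    n_correct = 0
    n_cases = 0
    for half, other in _half_partitions(patterns.shape[0], max_partitions, seed):
        pa = patterns[list(half)].mean(axis=0)
        pb = patterns[list(other)].mean(axis=0)
        n_correct += _best_match_correct(pa[target], pb, target)
        n_correct += _best_match_correct(pb[target], pa, target)
        n_cases += 2
    return n_correct / n_cases


def null_decoding_rate(
    n_draws: int,
    n_vertices: int = 50,
    n_candidates: int = 6,
    seed: int = 0,
    chunk: int = 20000,
) -> float:
    """Monte-Carlo chance level of best-match decoding with i.i.d. noise
    patterns: the probe and all candidate patterns are independent Gaussian
    vectors, and a draw is correct when the designated candidate is the
    strict best match."""
    rng = np.random.default_rng(seed)
    correct = 0
    done = 0
    while done < n_draws:
        n = min(chunk, n_draws - done)
        probe = rng.standard_normal((n, n_vertices))
        cand = rng.standard_normal((n, n_candidates, n_vertices))
        pz = probe - probe.mean(axis=1, keepdims=True)
        pz /= np.linalg.norm(pz, axis=1, keepdims=True)
        cz = cand - cand.mean(axis=2, keepdims=True)
        cz /= np.linalg.norm(cz, axis=2, keepdims=True)
        r = np.einsum("nv,nkv->nk", pz, cz)
        top = r.max(axis=1)
        wins = (r[:, 0] == top) & (np.sum(r == top[:, None], axis=1) == 1)
        correct += int(wins.sum())
        done += n
    return correct / n_draws
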