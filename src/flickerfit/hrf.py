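"""Three-parameter orthonormal-basis hemodynamic response model.

The BOLD impulse response is modeled as a weighted combination of three
orthonormal temporal kernels.  The basis is derived by singular value
decomposition of a family of double-gamma impulse responses spanning
plausible peak delays, dispersions, and undershoot ratios (a FLOBS-style
construction); the weights are the three free HRF parameters of the
time-series model.  Kernel support is 0-28 s at 1 s resolution, covering the
canonical response and its undershoot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import gamma as gamma_dist

HRF_SUPPORT_S = 28


@dataclass(frozen=True)
class HRFFamilySpec:
    """Parameter ranges of the double-gamma family the basis is built from."""

    peak_delay_range: tuple[float, float] = (4.0, 7.0)
    peak_dispersion_range: tuple[float, float] = (0.7, 1.3)
    undershoot_delay_range: tuple[float, float] = (12.0, 18.0)
    undershoot_ratio_range: tuple[float, float] = (0.1, 0.5)
    n_samples: int = 512


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 5.5,
    peak_dispersion: float = 1.0,
    undershoot_delay: float = 15.0,
    undershoot_ratio: float = 0.3,
    undershoot_dispersion: float = 1.6,
) -> np.ndarray:
    """Double-gamma impulse response, normalized to unit sum.

    Unit sum makes the plateau of a long convolved boxcar equal the boxcar
    amplitude, so stimulus amplitudes are expressed directly in %BOLD.
    """
    pos = gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    neg = gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = pos - undershoot_ratio * neg
    s = h.sum()
    if abs(s) < 1e-12:
        raise ValueError("degenerate HRF: zero integral")
    return h / s


@dataclass
class HRFBasis:
    """Orthonormal temporal basis (support x 3) with provenance metadata."""

    kernels: np.ndarray
    family_spec: HRFFamilySpec
    seed: int
    singular_values: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.kernels.shape[1]

    @property
    def support_s(self) -> int:
        return self.kernels.shape[0]

    def canonical_weights(self) -> np.ndarray:
        """Projection of the mid-range (canonical) family member onto the basis."""
        spec = self.family_spec
        t = np.arange(self.support_s, dtype=float)
        canonical = double_gamma_hrf(
            t,
            peak_delay=float(np.mean(spec.peak_delay_range)),
            peak_dispersion=float(np.mean(spec.peak_dispersion_range)),
            undershoot_delay=float(np.mean(spec.undershoot_delay_range)),
            undershoot_ratio=float(np.mean(spec.undershoot_ratio_range)),
        )
        return self.kernels.T @ canonical

    def save(self, matrix_path, sidecar_path) -> None:
        np.savetxt(matrix_path, self.kernels, delimiter="\t")
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"family_spec": asdict(self.family_spec), "seed": self.seed}, fh
            )

    @classmethod
    def load(cls, matrix_path, sidecar_path) -> "HRFBasis":
        kernels = np.loadtxt(matrix_path, delimiter="\t")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        spec_dict = meta["family_spec"]
        spec_dict = {
            k: tuple(v) if isinstance(v, list) else v for k, v in spec_dict.items()
        }
        return cls(kernels=kernels, family_spec=HRFFamilySpec(**spec_dict), seed=meta["seed"])


def sample_hrf_family(spec: HRFFamilySpec, seed: int) -> np.ndarray:
    """Sample the double-gamma family: n_samples x support matrix."""
    rng = np.random.default_rng(seed)
    t = np.arange(HRF_SUPPORT_S, dtype=float)
    rows = np.empty((spec.n_samples, HRF_SUPPORT_S))
    for i in range(spec.n_samples):
        rows[i] = double_gamma_hrf(
            t,
            peak_delay=rng.uniform(*spec.peak_delay_range),
            peak_dispersion=rng.uniform(*spec.peak_dispersion_range),
            undershoot_delay=rng.uniform(*spec.undershoot_delay_range),
            undershoot_ratio=rng.uniform(*spec.undershoot_ratio_range),
        )
    return rows


def build_orthonormal_basis(
    family_spec: HRFFamilySpec | None = None,
    n_components: int = 3,
    seed: int = 0,
) -> HRFBasis:
    """Derive the orthonormal HRF basis from the sampled double-gamma family.

    The top ``n_components`` right singular vectors of the sampled family are
    the basis kernels; signs are fixed so the first component correlates
    positively with the family mean.  Deterministic given the spec and seed.
    """
    spec = family_spec or HRFFamilySpec()
    family = sample_hrf_family(spec, seed)
    if np.ptp(family, axis=0).max() < 1e-12:
        raise ValueError("degenerate HRF family: all sampled members identical")
    _, svals, vt = np.linalg.svd(family, full_matrices=False)
    kernels = vt[:n_components].T.copy()
    mean_hrf = family.mean(axis=0)
    for j in range(n_components):
        ref = mean_hrf if j == 0 else kernels[:, j]
        anchor = float(kernels[:, j] @ mean_hrf) if j == 0 else ref[np.argmax(np.abs(ref))]
        if anchor < 0:
            kernels[:, j] *= -1.0
    return HRFBasis(
        kernels=kernels,
        family_spec=spec,
        seed=seed,
        singular_values=svals[:n_components],
    )


def kernel_from_params(basis: HRFBasis, weights: np.ndarray) -> np.ndarray:
    """HRF kernel from its three basis loadings (linear in the weights)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (basis.n_components,):
        raise ValueError(
            f"expected {basis.n_components} weights, got shape {weights.shape}"
        )
    if not np.all(np.isfinite(weights)):
        raise ValueError("HRF weights must be finite")
    return basis.kernels @ weights
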