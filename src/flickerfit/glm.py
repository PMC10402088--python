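"""Joint HRF + amplitude modeling of concatenated BOLD time series.

For each vertex, a nonlinear model simultaneously estimates the shape of the
hemodynamic response (three loadings on an orthonormal basis, held in common
across acquisitions) and the amplitude of response to each stimulus
frequency in each acquisition (plus an attention-event amplitude per
acquisition).  The fit is separable: for candidate HRF weights the design is
convolved, both design and data are passed through the 0.0387 Hz high-pass
projection per acquisition, and the amplitudes solve an ordinary
least-squares problem; the outer search over the three HRF weights minimizes
the L2 norm of the filtered residual.  Because covariates never bleed across
acquisition boundaries, the inner OLS decomposes into independent
per-acquisition solves.

The seven frequency covariates of an acquisition sum to a step-free constant
except for the onset transient of the convolution, so the absolute amplitude
level is weakly determined; downstream analyses always reference amplitudes
to the same-acquisition 0 Hz condition, which cancels this common mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from . import design as dsn
from .design import DIRECTIONS, FREQUENCIES_HZ, StimulusSchedule
from .hrf import HRFBasis, kernel_from_params
from .simulate import BOLDDataset

N_FREQ = len(FREQUENCIES_HZ)
N_COLS = N_FREQ + 1  # 7 frequency covariates + 1 attention covariate


@dataclass
class AmplitudeTable:
    """Long-format table of response amplitudes (%BOLD).

    Columns: vertex, acquisition, direction, sequence_label, frequency_hz,
    amplitude.  For the full 36-acquisition study each (direction x
    frequency) crossing is measured in 12 acquisitions.
    """

    table: pd.DataFrame

    def n_measures(self) -> pd.Series:
        """Number of acquisitions measuring each (direction x frequency)."""
        return self.table.groupby(["direction", "frequency_hz"])["acquisition"].nunique()

    def relative(self) -> "AmplitudeTable":
        """Amplitudes referenced to the same-acquisition 0 Hz condition."""
        df = self.table.copy()
        zero = (
            df[df["frequency_hz"] == 0.0]
            .set_index(["vertex", "acquisition"])["amplitude"]
        )
        key = pd.MultiIndex.from_frame(df[["vertex", "acquisition"]])
        df["amplitude"] = df["amplitude"].to_numpy() - zero.reindex(key).to_numpy()
        return AmplitudeTable(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AmplitudeTable":
        return cls(pd.read_csv(path, sep="\t"))


def relative_amplitudes(table: AmplitudeTable) -> AmplitudeTable:
    """Subtract the same-acquisition 0 Hz amplitude from every frequency."""
    return table.relative()


class RankDeficientDesignError(ValueError):
    pass


class FlickerGLM:
    """Time-series model for a (vertices x time) BOLD dataset.

    Parameters
    ----------
    data : BOLDDataset
        Percent-signal-change data with schedules and geometry attached.
    basis : HRFBasis
        Orthonormal HRF basis; the three loadings are the nonlinear
        parameters of the fit.
    mask : array of bool or int indices, optional
        Vertices to fit (mirrors restricting the analysis to posterior
        cortex); others are skipped.
    """

    def __init__(
        self,
        data: BOLDDataset,
        basis: HRFBasis,
        mask=None,
        cutoff_hz: float = dsn.HIGHPASS_CUTOFF_HZ,
    ):
        self.data = data
        self.basis = basis
        self.cutoff_hz = cutoff_hz
        n_vert = data.n_vertices
        if mask is None:
            self.vertex_indices = np.arange(n_vert)
        else:
            mask = np.asarray(mask)
            self.vertex_indices = (
                np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
            )
        self.n_acq = data.n_acquisitions
        self.n_samp = data.acquisition_n_samples
        # unconvolved per-acquisition design blocks: (n_acq, n_samp, 8)
        self._blocks = np.stack(
            [dsn._acquisition_design(s) for s in data.schedules]
        )
        self._dct = dsn.dct_highpass_basis(self.n_samp, cutoff_hz)
        # filtered data per acquisition: (n_vert, n_acq, n_samp)
        y = data.data.reshape(n_vert, self.n_acq, self.n_samp)
        self._y = y
        self._yf = y - (y @ self._dct) @ self._dct.T

    # -- forward pieces ---------------------------------------------------

    def _convolved_blocks(self, kernel: np.ndarray) -> np.ndarray:
        """Convolve every design column with the kernel, per acquisition."""
        full = fftconvolve(self._blocks, kernel[None, :, None], axes=1)
        return full[:, : self.n_samp, :]

    def _filtered_design(self, kernel: np.ndarray) -> np.ndarray:
        xc = self._convolved_blocks(kernel)
        proj = np.einsum("ts,atk->ask", self._dct, xc)
        return xc - np.einsum("us,ask->auk", self._dct, proj)

    def check_design_rank(self, kernel: np.ndarray) -> None:
        """Raise if the filtered design of any acquisition is rank deficient
        (ignoring structurally empty columns such as an acquisition with no
        attention events)."""
        xf = self._filtered_design(kernel)
        for a in range(self.n_acq):
            cols = np.linalg.norm(xf[a], axis=0) > 1e-10
            if np.linalg.matrix_rank(xf[a][:, cols]) < int(cols.sum()):
                raise RankDeficientDesignError(
                    f"filtered design is rank deficient in acquisition {a}"
                )

    def _solve_amplitudes(self, xf: np.ndarray, yf_v: np.ndarray):
        """Per-acquisition OLS of filtered data on the filtered design.

        Returns (betas: n_acq x 8, residual: n_acq x n_samp)."""
        betas = np.zeros((self.n_acq, N_COLS))
        resid = np.empty((self.n_acq, self.n_samp))
        for a in range(self.n_acq):
            x = xf[a]
            cols = np.linalg.norm(x, axis=0) > 1e-10
            sol, *_ = np.linalg.lstsq(x[:, cols], yf_v[a], rcond=None)
            betas[a, cols] = sol
            resid[a] = yf_v[a] - x[:, cols] @ sol
        return betas, resid

    # -- fitting ----------------------------------------------------------

    def _normalize_weights(self, w: np.ndarray) -> np.ndarray:
        """Rescale weights so the kernel has unit sum.

        The model is invariant to scaling the kernel by c and the amplitudes
        by 1/c; fixing the kernel integral at one identifies the scale and
        keeps amplitudes in percent-signal-change units (the plateau of a
        sustained response equals its amplitude).
        """
        s = float(np.sum(self.basis.kernels @ w))
        if abs(s) < 1e-8:
            raise ValueError("HRF kernel has (near-)zero integral; cannot normalize")
        return np.asarray(w, dtype=float) / s

    def fit(
        self,
        optimize_hrf: bool = True,
        init_weights: np.ndarray | None = None,
        xtol: float = 1e-12,
        max_nfev: int = 120,
    ) -> "FlickerGLMResults":
        """Fit every masked vertex and return a results object.

        ``optimize_hrf=False`` holds the HRF at ``init_weights`` (default:
        the canonical projection) and performs the amplitude OLS only.
        """
        init = (
            self.basis.canonical_weights()
            if init_weights is None
            else np.asarray(init_weights, dtype=float)
        )
        init = self._normalize_weights(init)
        self.check_design_rank(kernel_from_params(self.basis, init))

        n_fit = len(self.vertex_indices)
        weights = np.tile(init, (n_fit, 1))
        betas = np.zeros((n_fit, self.n_acq, N_COLS))
        sse = np.zeros(n_fit)
        n_evals = np.zeros(n_fit, dtype=int)

        for i, v in enumerate(self.vertex_indices):
            yf_v = self._yf[v]
            if np.ptp(self.data.data[v]) == 0.0:
                continue  # zero-variance vertex: amplitudes 0 by convention
            sst = float(np.sum(yf_v**2))

            def residual_vec(w):
                s = float(np.sum(self.basis.kernels @ w))
                if abs(s) < 1e-8:
                    return np.full(self.n_acq * self.n_samp, 1e6)
                xf = self._filtered_design(kernel_from_params(self.basis, w / s))
                _, resid = self._solve_amplitudes(xf, yf_v)
                return resid.ravel()

            r0 = residual_vec(init)
            sse0 = float(r0 @ r0)
            w_hat = init
            if optimize_hrf and sse0 > 1e-16 * max(sst, 1e-30):
                sol = least_squares(
                    residual_vec,
                    x0=init,
                    method="lm",
                    xtol=xtol,
                    ftol=xtol,
                    gtol=xtol,
                    max_nfev=max_nfev,
                )
                w_hat = self._normalize_weights(sol.x)
                n_evals[i] = sol.nfev
            xf = self._filtered_design(kernel_from_params(self.basis, w_hat))
            b, resid = self._solve_amplitudes(xf, yf_v)
            weights[i] = w_hat
            betas[i] = b
            sse[i] = float(np.sum(resid**2))
        return FlickerGLMResults(
            model=self,
            hrf_weights=weights,
            betas=betas,
            sse=sse,
            n_evals=n_evals,
        )


@dataclass
class FlickerGLMResults:
    """Estimates from :class:`FlickerGLM`: per-vertex HRF weights, the
    amplitude table, attention amplitudes, and the R^2 of the model on
    attention-cleaned averaged data."""

    model: FlickerGLM
    hrf_weights: np.ndarray  # n_fit x 3
    betas: np.ndarray  # n_fit x n_acq x 8
    sse: np.ndarray
    n_evals: np.ndarray
    _r2: np.ndarray | None = field(default=None, repr=False)
    _averaged: dict | None = field(default=None, repr=False)

    # -- tables -----------------------------------------------------------

    @property
    def amplitudes(self) -> AmplitudeTable:
        rows = []
        scheds = self.model.data.schedules
        for i, v in enumerate(self.model.vertex_indices):
            for a, sched in enumerate(scheds):
                for j, f in enumerate(FREQUENCIES_HZ):
                    rows.append(
                        (int(v), a, sched.direction, sched.sequence_label, f, self.betas[i, a, j])
                    )
        return AmplitudeTable(
            pd.DataFrame(
                rows,
                columns=[
                    "vertex", "acquisition", "direction", "sequence_label",
                    "frequency_hz", "amplitude",
                ],
            )
        )

    @property
    def attention_amplitudes(self) -> pd.DataFrame:
        rows = [
            (int(v), a, self.betas[i, a, -1])
            for i, v in enumerate(self.model.vertex_indices)
            for a in range(self.model.n_acq)
        ]
        return pd.DataFrame(rows, columns=["vertex", "acquisition", "amplitude"])

    def kernel(self, i: int = 0) -> np.ndarray:
        """Fitted HRF kernel of the i-th fitted vertex."""
        return kernel_from_params(self.model.basis, self.hrf_weights[i])

    # -- attention-cleaned averaging and R^2 -------------------------------

    def clean_and_average(self):
        """Attention-cleaned, A/B-averaged data, matching model, and R^2.

        The fitted attention effect is subtracted from the raw data; for each
        stimulus direction the six "A"-ordered and six "B"-ordered
        acquisitions are averaged and the averages concatenated (direction
        order LMS, L-M, S; label order A, B).  R^2 of the stimulus model
        against these averages, after high-pass filtering, is retained per
        vertex; attention variance is excluded by construction.
        """
        if self._averaged is not None:
            return self._averaged
        m = self.model
        scheds = m.data.schedules
        combos = [
            (d, lab)
            for d in DIRECTIONS
            for lab in ("A", "B")
            if any(s.direction == d and s.sequence_label == lab for s in scheds)
        ]
        if not combos:
            raise ValueError("no (direction, sequence label) groups in the schedules")
        n_fit = len(m.vertex_indices)
        n_seg = len(combos)
        data_avg = np.zeros((n_fit, n_seg, m.n_samp))
        model_avg = np.zeros((n_fit, n_seg, m.n_samp))
        for i, v in enumerate(m.vertex_indices):
            xc = m._convolved_blocks(kernel_from_params(m.basis, self.hrf_weights[i]))
            stim = np.einsum("atk,ak->at", xc[:, :, :N_FREQ], self.betas[i, :, :N_FREQ])
            att = xc[:, :, -1] * self.betas[i, :, -1:]
            clean = m._y[v] - att
            for s, (d, lab) in enumerate(combos):
                idx = [
                    a
                    for a, sc in enumerate(scheds)
                    if sc.direction == d and sc.sequence_label == lab
                ]
                data_avg[i, s] = clean[idx].mean(axis=0)
                model_avg[i, s] = stim[idx].mean(axis=0)
        dctb = m._dct
        data_f = data_avg - (data_avg @ dctb) @ dctb.T
        model_f = model_avg - (model_avg @ dctb) @ dctb.T
        sse = np.sum((data_f - model_f) ** 2, axis=(1, 2))
        sst = np.sum(data_f**2, axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
        self._averaged = {
            "combos": combos,
            "data": data_f,
            "model": model_f,
            "r2": r2,
        }
        self._r2 = r2
        return self._averaged

    @property
    def r2(self) -> np.ndarray:
        if self._r2 is None:
            self.clean_and_average()
        return self._r2

    def select_vertices(self, threshold: float = 0.1) -> np.ndarray:
        """Vertex indices with R^2 strictly above threshold (may be empty)."""
        return self.model.vertex_indices[self.r2 > threshold]

    # -- residuals (for the carry-over analysis) --------------------------

    def filtered_residual(self, i: int) -> np.ndarray:
        """High-passed residual time series (full model) of fitted vertex i."""
        m = self.model
        xf = m._filtered_design(kernel_from_params(m.basis, self.hrf_weights[i]))
        _, resid = m._solve_amplitudes(xf, m._yf[m.vertex_indices[i]])
        return resid.ravel()

    def summary(self) -> str:
        r2 = self.r2
        lines = [
            "Flicker time-series GLM fit",
            "-" * 42,
            f"vertices fitted        {len(self.model.vertex_indices):8d}",
            f"acquisitions           {self.model.n_acq:8d}",
            f"time points            {self.model.n_acq * self.model.n_samp:8d}",
            f"covariates             {self.model.n_acq * N_COLS:8d}",
            f"median R^2             {np.median(r2):8.3f}",
            f"vertices with R^2>0.1  {int(np.sum(r2 > 0.1)):8d}",
            f"mean HRF weights       {np.array2string(self.hrf_weights.mean(axis=0), precision=4)}",
        ]
        return "\n".join(lines)


def select_vertices(results: FlickerGLMResults, threshold: float = 0.1) -> np.ndarray:
    """Vertices whose attention-cleaned averaged-data R^2 exceeds threshold."""
    return results.select_vertices(threshold)


def fit_timeseries(
    data: BOLDDataset, basis: HRFBasis, mask=None, **fit_kwargs
) -> FlickerGLMResults:
    """Convenience wrapper: build a FlickerGLM and fit it."""
    return FlickerGLM(data, basis, mask=mask).fit(**fit_kwargs)
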