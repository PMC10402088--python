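"""Eccentricity banding, band summaries, relative peak maps, and the
visual-field projection of per-vertex values.

V1 is divided into six log-spaced eccentricity bands with edges at 0, 2.8,
5.6, 11.25, 22.5, 45 and 90 degrees.  Band intervals are half-open
[lo, hi); the 90 degree edge is included in the last band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import zscore

BAND_EDGES_DEG = (0.0, 2.8, 5.6, 11.25, 22.5, 45.0, 90.0)
N_BANDS = len(BAND_EDGES_DEG) - 1


def assign_band(
    eccentricity_deg, edges: tuple[float, ...] = BAND_EDGES_DEG
) -> np.ndarray:
    """0-based band index for each eccentricity; [lo, hi) with 90 in band 6."""
    ecc = np.asarray(eccentricity_deg, dtype=float)
    edges_arr = np.asarray(edges)
    if np.any(ecc < edges_arr[0]) or np.any(ecc > edges_arr[-1]):
        raise ValueError("eccentricity outside the banded range")
    idx = np.searchsorted(edges_arr, ecc, side="right") - 1
    return np.minimum(idx, len(edges_arr) - 2)


def band_average(
    amplitudes,
    geometry: pd.DataFrame,
    r2: np.ndarray,
    threshold: float = 0.1,
    edges: tuple[float, ...] = BAND_EDGES_DEG,
) -> pd.DataFrame:
    """Average amplitudes over selected vertices within each eccentricity band.

    Vertices with time-series fit R^2 strictly above ``threshold`` are
    selected; their amplitudes are averaged per band x direction x frequency
    x acquisition.  Empty bands appear with NaN amplitude and n_vertices 0.
    """
    from .glm import AmplitudeTable

    table = amplitudes.table if isinstance(amplitudes, AmplitudeTable) else amplitudes
    r2 = np.asarray(r2, dtype=float)
    bands = assign_band(geometry["eccentricity_deg"].to_numpy(), edges)
    keep = r2 > threshold
    vert_band = pd.DataFrame(
        {"vertex": np.arange(len(bands)), "band": bands, "keep": keep}
    )
    merged = table.merge(vert_band, on="vertex")
    merged = merged[merged["keep"]]
    grouped = (
        merged.groupby(["band", "direction", "frequency_hz", "acquisition"], as_index=False)
        .agg(amplitude=("amplitude", "mean"), n_vertices=("vertex", "nunique"))
    )
    # materialize empty bands explicitly
    cells = table[["direction", "frequency_hz", "acquisition"]].drop_duplicates()
    full = pd.concat(
        [cells.assign(band=b) for b in range(len(edges) - 1)], ignore_index=True
    )
    out = full.merge(grouped, on=["band", "direction", "frequency_hz", "acquisition"], how="left")
    out["n_vertices"] = out["n_vertices"].fillna(0).astype(int)
    return out


@dataclass
class RelativePeakMap:
    """Across-direction average of per-direction z-scored log peak frequency."""

    values: np.ndarray
    per_direction_z: dict[str, np.ndarray]


def relative_peak_map(peak_freqs_hz: dict[str, np.ndarray]) -> RelativePeakMap:
    """Relative peak temporal sensitivity map.

    For each stimulus direction, the per-vertex interpolated peak frequency
    is expressed in log10 Hz and z-scored across vertices (subtract the
    across-vertex mean, divide by the SD); the per-direction z-maps are then
    averaged per vertex.
    """
    z_maps = {}
    for direction, freqs in peak_freqs_hz.items():
        f = np.asarray(freqs, dtype=float)
        if f.size < 2:
            raise ValueError("need >= 2 vertices per direction")
        logf = np.log10(f)
        if np.std(logf) == 0:
            raise ValueError(f"zero variance of log peak frequency for {direction}")
        z_maps[direction] = zscore(logf)
    stacked = np.stack(list(z_maps.values()))
    return RelativePeakMap(values=stacked.mean(axis=0), per_direction_z=z_maps)


@dataclass
class FieldImage:
    """Visual-field projection on a square grid; NaN marks uncovered pixels."""

    image: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    weight: np.ndarray


def project_to_visual_field(
    values,
    geometry: pd.DataFrame,
    half_width_deg: float = 90.0,
    n_grid: int = 181,
    weight_floor: float = 1e-6,
) -> FieldImage:
    """Project per-vertex values into the visual field.

    Each vertex deposits a 2-D isotropic Gaussian (sigma = its pRF width) at
    its (eccentricity, polar angle) field location; the image is the
    weight-normalized sum, with pixels whose total weight falls below
    ``weight_floor`` flagged empty (NaN).
    """
    values = np.asarray(values, dtype=float)
    ecc = geometry["eccentricity_deg"].to_numpy()
    ang = np.deg2rad(geometry["polar_angle_deg"].to_numpy())
    sigma = geometry["prf_width_deg"].to_numpy()
    x0, y0 = ecc * np.cos(ang), ecc * np.sin(ang)
    axis = np.linspace(-half_width_deg, half_width_deg, n_grid)
    gx, gy = np.meshgrid(axis, axis)
    num = np.zeros_like(gx)
    den = np.zeros_like(gx)
    for v in range(len(values)):
        w = np.exp(-((gx - x0[v]) ** 2 + (gy - y0[v]) ** 2) / (2.0 * sigma[v] ** 2))
        num += w * values[v]
        den += w
    image = np.where(den >= weight_floor, num / np.maximum(den, weight_floor), np.nan)
    return FieldImage(image=image, x_deg=axis, y_deg=axis, weight=den)
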