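"""Eccentricity-integrated model of retinal ganglion cell output.

Temporal frequency tuning of three RGC classes (midget, parasol, small
bistratified) is taken from a per-class gain table (spikes/s per % contrast)
tabulated at three eccentricity centers (5, 25, 40 degrees; the bistratified
class only at 5 and 25).  The response of a cell class to a stimulus is
gain x effective contrast, with parasol cells saturating at 25% contrast.
Channel responses map post-receptoral directions onto classes: LMS is the
sum of the midget and parasol achromatic responses, L-M the midget
chromatic response, S the bistratified response.  Population integration
scales each class's response by the total RGC receptive-field density at
that eccentricity, the class proportion, and the annular area of the
eccentricity ring, and summarizes each direction x eccentricity series by
its interpolated peak, normalized to the across-eccentricity average LMS
peak response.

The packaged gain table is a synthetic, documented stand-in with the
qualitative structure of macaque recordings (it is replaceable input, not a
measurement); see ``data/rgc_gains_synthetic.tsv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

ECCENTRICITY_CENTERS_DEG = (5.0, 25.0, 40.0)
PARASOL_SATURATION_CONTRAST_PCT = 25.0

#: nominal maximum stimulus contrast (%) per post-receptoral direction
DEFAULT_CONTRASTS_PCT = {"LMS": 90.0, "L-M": 8.0, "S": 50.0}

#: (cell class, channel) pairs contributing to each stimulus direction
CHANNEL_CLASSES = {
    "LMS": (("midget", "achromatic"), ("parasol", "achromatic")),
    "L-M": (("midget", "chromatic"),),
    "S": (("bistratified", "S"),),
}

CELL_CLASSES = ("midget", "parasol", "bistratified")


@dataclass
class RGCGainTable:
    """Per-class, per-eccentricity, per-frequency gains (spikes/s per %contrast)."""

    table: pd.DataFrame  # columns: cell_class, channel, ecc_deg, freq_hz, gain
    on_off_averaged: bool = True
    provenance: str = ""

    def validate(self) -> None:
        if (self.table["gain"] < 0).any():
            raise ValueError("gains must be non-negative")
        bi = self.table[self.table["cell_class"] == "bistratified"]
        if not set(bi["ecc_deg"]).issubset({5.0, 25.0}):
            raise ValueError("bistratified gains exist only at 5 and 25 degrees")

    def frequencies(self) -> np.ndarray:
        return np.sort(self.table["freq_hz"].unique())

    def gains(self, cell_class: str, channel: str, ecc_deg: float) -> np.ndarray | None:
        sub = self.table[
            (self.table["cell_class"] == cell_class)
            & (self.table["channel"] == channel)
            & (self.table["ecc_deg"] == ecc_deg)
        ].sort_values("freq_hz")
        if sub.empty:
            return None
        return sub["gain"].to_numpy()

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "RGCGainTable":
        t = cls(pd.read_csv(path, sep="\t"), **kwargs)
        t.validate()
        return t

    @classmethod
    def packaged(cls) -> "RGCGainTable":
        """The synthetic gain table shipped with the package."""
        ref = resources.files("flickerfit") / "data" / "rgc_gains_synthetic.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(
                path,
                provenance="synthetic fixture emulating macaque RGC temporal tuning",
            )


@dataclass
class RetinaConfig:
    """Density and class-proportion model at the three eccentricity centers.

    Total RGC receptive-field density declines exponentially with
    eccentricity (density_scale x exp(-ecc / density_efold_deg), arbitrary
    units); class proportions shift peripherally from midget-dominated
    toward parasol.  Annular area is computed in squared degrees (2 pi e per
    unit ring width).
    """

    density_scale: float = 1.0
    density_efold_deg: float = 20.0
    class_proportions: dict = field(
        default_factory=lambda: {
            "midget": (0.80, 0.60, 0.45),
            "parasol": (0.10, 0.28, 0.42),
            "bistratified": (0.06, 0.08, 0.08),
        }
    )
    contrasts_pct: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS_PCT))

    def density(self, ecc_deg: float) -> float:
        return self.density_scale * float(np.exp(-ecc_deg / self.density_efold_deg))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RetinaConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["class_proportions"] = {k: tuple(v) for k, v in d["class_proportions"].items()}
        return cls(**d)


def cell_response(gain, stimulus_contrast_pct: float, cell_class: str):
    """Spikes/s response of a cell class: gain x effective contrast.

    Effective contrast is capped at 25% for parasol cells and linear for the
    other classes.
    """
    if cell_class not in CELL_CLASSES:
        raise ValueError(f"unknown cell class {cell_class!r}")
    if stimulus_contrast_pct < 0:
        raise ValueError("contrast must be >= 0")
    eff = (
        min(stimulus_contrast_pct, PARASOL_SATURATION_CONTRAST_PCT)
        if cell_class == "parasol"
        else stimulus_contrast_pct
    )
    return np.asarray(gain, dtype=float) * eff


@dataclass
class ChannelResponse:
    """Per-class spikes/s responses of one direction at one eccentricity."""

    direction: str
    ecc_deg: float
    frequencies_hz: np.ndarray
    by_class: dict  # cell_class -> spikes/s array over frequencies
    available: bool = True

    def total(self) -> np.ndarray:
        return np.sum(list(self.by_class.values()), axis=0)


def channel_response(
    table: RGCGainTable,
    direction: str,
    ecc_deg: float,
    contrasts_pct: dict | None = None,
) -> ChannelResponse:
    """Response of one post-receptoral direction at one eccentricity.

    The S direction is unavailable at 40 degrees (no bistratified gains
    there); this returns an explicit unavailable result rather than raising.
    """
    if direction not in CHANNEL_CLASSES:
        raise ValueError(f"unknown direction {direction!r}")
    contrasts = contrasts_pct or DEFAULT_CONTRASTS_PCT
    freqs = table.frequencies()
    by_class = {}
    for cell_class, channel in CHANNEL_CLASSES[direction]:
        gains = table.gains(cell_class, channel, ecc_deg)
        if gains is None:
            return ChannelResponse(direction, ecc_deg, freqs, {}, available=False)
        by_class[cell_class] = cell_response(gains, contrasts[direction], cell_class)
    return ChannelResponse(direction, ecc_deg, freqs, by_class)


def _log_quadratic_peak(freqs: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Peak via log-quadratic interpolation around the tabulated maximum."""
    i = int(np.argmax(resp))
    if i == 0 or i == len(freqs) - 1:
        return float(freqs[i]), float(resp[i])
    x = np.log10(freqs[i - 1 : i + 2])
    y = resp[i - 1 : i + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        return float(freqs[i]), float(resp[i])
    xv = -b / (2.0 * a)
    xv = float(np.clip(xv, x[0], x[2]))
    return 10.0 ** xv, float(np.polyval([a, b, c], xv))


@dataclass
class RetinalPrediction:
    """Integrated retinal output per direction x eccentricity.

    ``responses`` is a long DataFrame (direction, ecc_deg, freq_hz,
    response); ``peaks`` holds the interpolated peak frequency and the peak
    amplitude normalized to the across-eccentricity average LMS peak.
    S-direction rows are absent at 40 degrees.
    """

    responses: pd.DataFrame
    peaks: pd.DataFrame


def integrate_population(
    table: RGCGainTable,
    config: RetinaConfig | None = None,
    eccentricities_deg: tuple[float, ...] = ECCENTRICITY_CENTERS_DEG,
) -> RetinalPrediction:
    """Population-integrated predicted retinal response and its peaks.

    Each class's spikes/s response is weighted by total RGC RF density x
    class proportion x annular area (2 pi e deg^2 per unit ring width) and
    summed within direction.
    """
    config = config or RetinaConfig()
    rows = []
    peak_rows = []
    for direction in CHANNEL_CLASSES:
        for k, ecc in enumerate(eccentricities_deg):
            resp = channel_response(table, direction, ecc, config.contrasts_pct)
            if not resp.available:
                continue
            area = 2.0 * np.pi * ecc
            weighted = np.zeros_like(resp.frequencies_hz, dtype=float)
            for cell_class, spikes in resp.by_class.items():
                prop = config.class_proportions[cell_class][k]
                weighted = weighted + spikes * config.density(ecc) * prop * area
            for f, r in zip(resp.frequencies_hz, weighted):
                rows.append((direction, ecc, f, r))
            pf, pa = _log_quadratic_peak(resp.frequencies_hz, weighted)
            peak_rows.append((direction, ecc, pf, pa))
    responses = pd.DataFrame(rows, columns=["direction", "ecc_deg", "freq_hz", "response"])
    peaks = pd.DataFrame(peak_rows, columns=["direction", "ecc_deg", "peak_freq_hz", "peak_amp"])
    lms_mean = peaks.loc[peaks["direction"] == "LMS", "peak_amp"].mean()
    peaks["peak_amp_norm"] = peaks["peak_amp"] / lms_mean
    return RetinalPrediction(responses=responses, peaks=peaks)
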