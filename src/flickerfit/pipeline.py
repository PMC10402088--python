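"""End-to-end orchestration: simulate, fit, TSF, carry-over, patterns,
retina, aggregate — reproducible from a single serializable config."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .carryover import STIMULUS_CLASSES, estimate_carryover
from .design import DIRECTIONS, build_study_schedule
from .glm import FlickerGLM
from .hrf import build_orthonormal_basis
from .maps import assign_band, band_average, relative_peak_map, project_to_visual_field
from .patterns import decode_target, pattern_array, split_half_similarity
from .retina import RetinaConfig, RGCGainTable, integrate_population
from .simulate import GroundTruth, make_vertex_geometry, simulate_bold
from .watson import WatsonTSFModel

log = logging.getLogger("flickerfit")

STAGES = ("simulate", "fit", "tsf", "carryover", "patterns", "retina", "aggregate")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_vertices: int = 40
    noise_sd: float = 0.5
    pattern_scale: float = 0.25
    n_boot: int = 1000
    r2_threshold: float = 0.1
    optimize_hrf: bool = True
    field_grid: int = 61

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, writing every intermediate artifact and a
    manifest (stage outputs, seeds, file hashes).  Deterministic: rerunning
    with the same config reproduces identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, *paths) -> None:
        manifest["stages"][stage] = {
            str(p.relative_to(out)): fio.sha256_of(p) for p in paths
        }
        log.info("stage %s complete (%d files)", stage, len(paths))

    try:
        # -- simulate -----------------------------------------------------
        schedules = build_study_schedule(config.seed)
        geometry = make_vertex_geometry(config.n_vertices, seed=config.seed + 1)
        basis = build_orthonormal_basis(seed=0)
        truth = GroundTruth.default(
            noise_sd=config.noise_sd, pattern_scale=config.pattern_scale
        )
        dataset = simulate_bold(schedules, truth, basis, geometry, seed=config.seed + 2)
        fio.write_events_tsv(schedules, out / "events.tsv")
        fio.write_geometry(geometry, out / "geometry.tsv")
        fio.write_bold(dataset, out / "bold.tsv", out / "bold.json", seed=config.seed + 2)
        basis.save(out / "hrf_basis.tsv", out / "hrf_basis.json")
        record("simulate", out / "events.tsv", out / "geometry.tsv",
               out / "bold.tsv", out / "bold.json",
               out / "hrf_basis.tsv", out / "hrf_basis.json")

        # -- fit ----------------------------------------------------------
        result = FlickerGLM(dataset, basis).fit(optimize_hrf=config.optimize_hrf)
        table = result.amplitudes
        table.to_tsv(out / "amplitudes.tsv")
        np.savetxt(out / "hrf_weights.tsv", result.hrf_weights, delimiter="\t")
        pd.DataFrame({"vertex": result.model.vertex_indices, "r2": result.r2}).to_csv(
            out / "r2.tsv", sep="\t", index=False
        )
        record("fit", out / "amplitudes.tsv", out / "hrf_weights.tsv", out / "r2.tsv")

        # -- tsf ----------------------------------------------------------
        tsf_rows = []
        for d in DIRECTIONS:
            res = WatsonTSFModel.from_amplitude_table(table, d).fit()
            summ = res.bootstrap(n_boot=config.n_boot, seed=config.seed + 3)
            for f, med, lo_, hi_ in zip(
                summ.frequencies_hz, summ.amplitude_median,
                summ.amplitude_iqr_low, summ.amplitude_iqr_high,
            ):
                tsf_rows.append((d, "frequency", f, med, lo_, hi_))
            tsf_rows.append((d, "peak_freq_hz", np.nan, summ.peak_freq_hz_median, *summ.peak_freq_hz_iqr))
            tsf_rows.append((d, "peak_amp", np.nan, summ.peak_amp_median, *summ.peak_amp_iqr))
        pd.DataFrame(
            tsf_rows,
            columns=["direction", "kind", "frequency_hz", "median", "iqr_lo", "iqr_hi"],
        ).to_csv(out / "tsf.tsv", sep="\t", index=False)
        record("tsf", out / "tsf.tsv")

        # -- carryover ----------------------------------------------------
        co_paths = []
        for cls in STIMULUS_CLASSES:
            mat = estimate_carryover(result, cls)
            p = out / f"carryover_{cls}.tsv"
            fio.write_matrix_tsv(mat.values, p)
            co_paths.append(p)
        record("carryover", *co_paths)

        # -- patterns -----------------------------------------------------
        pat_paths = []
        bands = assign_band(geometry["eccentricity_deg"].to_numpy())
        decode_rows = []
        for label, dirs in (("achromatic", "LMS"), ("chromatic", ["L-M", "S"])):
            pats = pattern_array(table, dirs)
            # pooled chromatic trials give 24 acquisitions; cap the partition
            # enumeration at the 462 of the 12-acquisition case
            sim = split_half_similarity(pats, label=label, max_partitions=462, seed=config.seed)
            p = out / f"similarity_{label}.tsv"
            fio.write_matrix_tsv(sim.values, p)
            pat_paths.append(p)
            for b in range(6):
                subset = np.flatnonzero(bands == b)
                if subset.size < 2:
                    continue
                decode_rows.append(
                    (label, b,
                     decode_target(pats, 64.0, subset, max_partitions=462, seed=config.seed))
                )
        pd.DataFrame(
            decode_rows, columns=["class", "band", "proportion_correct"]
        ).to_csv(out / "decoding_by_band.tsv", sep="\t", index=False)
        record("patterns", *pat_paths, out / "decoding_by_band.tsv")

        # -- retina -------------------------------------------------------
        pred = integrate_population(RGCGainTable.packaged(), RetinaConfig())
        pred.peaks.to_csv(out / "retina_peaks.tsv", sep="\t", index=False)
        pred.responses.to_csv(out / "retina_responses.tsv", sep="\t", index=False)
        record("retina", out / "retina_peaks.tsv", out / "retina_responses.tsv")

        # -- aggregate ----------------------------------------------------
        band_tbl = band_average(table, geometry, result.r2, threshold=config.r2_threshold)
        band_tbl.to_csv(out / "band_amplitudes.tsv", sep="\t", index=False)
        sel = result.r2 > config.r2_threshold
        peak_freqs = {}
        if sel.sum() >= 2:
            for d in DIRECTIONS:
                pf = []
                for i in np.flatnonzero(sel):
                    res = WatsonTSFModel.from_amplitude_table(
                        table, d, vertex=int(result.model.vertex_indices[i])
                    ).fit()
                    pf.append(res.peak_freq_hz)
                peak_freqs[d] = np.array(pf)
            rmap = relative_peak_map(peak_freqs)
            sub_geom = geometry.iloc[np.flatnonzero(sel)].reset_index(drop=True)
            img = project_to_visual_field(rmap.values, sub_geom, n_grid=config.field_grid)
            fio.write_matrix_tsv(np.nan_to_num(img.image, nan=np.nan), out / "field_map.tsv")
            pd.DataFrame(
                {"vertex": result.model.vertex_indices[sel], "relative_peak_z": rmap.values}
            ).to_csv(out / "relative_peak_map.tsv", sep="\t", index=False)
            record("aggregate", out / "band_amplitudes.tsv",
                   out / "relative_peak_map.tsv", out / "field_map.tsv")
        else:
            record("aggregate", out / "band_amplitudes.tsv")
    except Exception as exc:  # persist partial manifest before propagating
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages"]), "unknown"
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed in stage {manifest['failed_stage']}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
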