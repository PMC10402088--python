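"""Delimited-text readers and writers for schedules, BOLD data, and results.

Events use a BIDS-style TSV with one row per trial (columns: acquisition,
onset, duration, frequency_hz, direction, sequence_label, attention_onsets);
attention onsets are attached, semicolon-delimited, to the trial row during
which they occur.  BOLD matrices are written as TSV with a JSON sidecar
recording dimensions, TR and the generating seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusSchedule, Trial, TRIAL_DURATION_S
from .simulate import BOLDDataset


def schedules_to_events(schedules: list[StimulusSchedule]) -> pd.DataFrame:
    rows = []
    for a, sched in enumerate(schedules):
        for t in sched.trials:
            atts = [
                x
                for x in sched.attention_onsets
                if t.onset_s <= x < t.onset_s + t.duration_s
            ]
            rows.append(
                {
                    "acquisition": a,
                    "onset": t.onset_s,
                    "duration": t.duration_s,
                    "frequency_hz": t.frequency_hz,
                    "direction": sched.direction,
                    "sequence_label": sched.sequence_label,
                    "attention_onsets": ";".join(f"{x:.3f}" for x in atts),
                }
            )
    return pd.DataFrame(rows)


def write_events_tsv(schedules: list[StimulusSchedule], path) -> None:
    schedules_to_events(schedules).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[StimulusSchedule]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    schedules = []
    for _, group in df.groupby("acquisition", sort=True):
        trials = [
            Trial(float(r.onset), float(r.duration), float(r.frequency_hz))
            for r in group.itertuples()
        ]
        attention: list[float] = []
        for r in group.itertuples():
            if r.attention_onsets:
                attention.extend(float(x) for x in str(r.attention_onsets).split(";"))
        schedules.append(
            StimulusSchedule(
                direction=group["direction"].iloc[0],
                sequence_label=group["sequence_label"].iloc[0],
                trials=trials,
                attention_onsets=sorted(attention),
                acquisition_duration_s=trials[-1].onset_s + trials[-1].duration_s,
            )
        )
    return schedules


def write_bold(dataset: BOLDDataset, data_path, sidecar_path, seed=None) -> None:
    np.savetxt(data_path, dataset.data, delimiter="\t", fmt="%.6f")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "n_vertices": int(dataset.n_vertices),
                "n_acquisitions": int(dataset.n_acquisitions),
                "acquisition_n_samples": int(dataset.acquisition_n_samples),
                "tr_s": 1.0,
                "units": "percent signal change",
                "seed": seed,
            },
            fh,
        )


def read_bold(data_path, events_path, geometry_path) -> BOLDDataset:
    data = np.loadtxt(data_path, delimiter="\t", ndmin=2)
    schedules = read_events_tsv(events_path)
    geometry = pd.read_csv(geometry_path, sep="\t")
    ds = BOLDDataset(data=data, schedules=schedules, geometry=geometry)
    ds.validate()
    return ds


def write_geometry(geometry: pd.DataFrame, path) -> None:
    geometry.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: np.ndarray, path, row_labels=None, col_labels=None) -> None:
    df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
    df.to_csv(path, sep="\t", index=row_labels is not None)


def sha256_of(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
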