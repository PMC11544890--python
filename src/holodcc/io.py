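"""Disk formats: multi-page TIFF recordings with JSON sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._util import stable_json
from .evaluate import CompositionSeries
from .simulate import CellTruth, Recording


def write_recording(path, recording: Recording, scene=None, seed=None) -> Path:
    """32-bit float multi-page TIFF (one page per frame) + .json sidecar."""
    path = Path(path)
    tifffile.imwrite(path, recording.frames.astype(np.float32))
    sidecar = {
        "sample_id": recording.sample_id,
        "subject_id": recording.subject_id,
        "matrix": recording.matrix,
        "day": recording.day,
        "scene": dataclasses.asdict(scene) if scene is not None else None,
        "seed": seed,
        "truths": [t.to_dict() for t in recording.truths],
    }
    path.with_suffix(".json").write_text(stable_json(sidecar))
    return path


def read_recording(path) -> Recording:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    truths = [CellTruth(**t) for t in meta.get("truths", [])]
    return Recording(sample_id=meta.get("sample_id", path.stem),
                     subject_id=meta.get("subject_id", ""),
                     matrix=meta.get("matrix", ""),
                     frames=frames, truths=truths, day=meta.get("day"))


def write_series_csv(path, series: list[CompositionSeries]) -> Path:
    path = Path(path)
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_series_csv(path) -> list[CompositionSeries]:
    df = pd.read_csv(path)
    out = []
    for (subject, matrix, source), grp in df.groupby(["subject", "matrix", "source"],
                                                     sort=True):
        days = sorted(grp["day"].unique())
        classes = sorted(grp["class"].unique())
        pivot = grp.pivot_table(index="day", columns="class",
                                values="proportion").loc[days, classes]
        out.append(CompositionSeries(subject_id=str(subject), matrix=str(matrix),
                                     days=[int(d) for d in days], classes=classes,
                                     proportions=pivot.to_numpy(), source=str(source)))
    return out


def write_table_csv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table_csv(path) -> pd.DataFrame:
    from .features import schema_fingerprint

    table = pd.read_csv(path)
    table.attrs["schema_fingerprint"] = schema_fingerprint()
    return table
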