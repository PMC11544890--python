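"""Shared fixtures: small synthetic recordings and feature-space blobs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from holodcc.features import FEATURE_NAMES, schema_fingerprint
from holodcc.preprocess import CellPatch, SegmentationParams, preprocess_recording
from holodcc.simulate import SceneConfig, blood_phenotypes, synthesize_recording


@pytest.fixture(scope="session")
def params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def phenotypes():
    return blood_phenotypes()


@pytest.fixture(scope="session")
def small_recording(phenotypes):
    """40-frame blood recording, interior placements, with ground truth."""
    scene = SceneConfig(frame_shape=(256, 320), cells_per_frame_mean=8,
                        noise_sd=0.05, placement_margin=50, seed=7)
    rec = synthesize_recording(phenotypes, [0.5, 0.3, 0.2], scene, 40,
                               np.random.default_rng(7), sample_id="fix")
    return rec


@pytest.fixture(scope="session")
def small_patches(small_recording, params):
    patches, summary = preprocess_recording(small_recording.frames, params,
                                            sample_id="fix")
    return patches, summary


def make_patch(values: np.ndarray, mask: np.ndarray, size: int = 0) -> CellPatch:
    """Embed a small (values, mask) pair into a CellPatch, optionally padded
    into a larger square patch with the shape centred."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if size and size > values.shape[0]:
        big_v = np.zeros((size, size))
        big_m = np.zeros((size, size), dtype=bool)
        r0 = (size - values.shape[0]) // 2
        c0 = (size - values.shape[1]) // 2
        big_v[r0:r0 + values.shape[0], c0:c0 + values.shape[1]] = values
        big_m[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = mask
        values, mask = big_v, big_m
    return CellPatch(values=values, mask=mask)


def disc_mask(radius: int, size: int) -> np.ndarray:
    """Digital disc x^2 + y^2 <= r^2 centred in a size x size grid."""
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def gaussian_blob_table(rng: np.random.Generator,
                        n_per_class: int = 200,
                        separation: float = 4.0,
                        classes=("granulocyte", "lymphocyte", "monocyte"),
                        subjects=("cow1",),
                        subject_shift: float = 0.0) -> pd.DataFrame:
    """Labeled feature table of Gaussian blobs in 24-D feature space.

    Class means differ by ``separation`` (in units of the unit within-class
    SD) along the first four features; the rest are noise.  Optionally each
    subject's blob centres are shifted by ``subject_shift`` SDs to emulate
    inter-animal variation.
    """
    rows = []
    for si, subj in enumerate(subjects):
        srng = np.random.default_rng(rng.integers(2**31))
        shift = subject_shift * srng.standard_normal(len(FEATURE_NAMES))
        for ci, cls in enumerate(classes):
            mu = np.zeros(len(FEATURE_NAMES))
            mu[:4] = ci * separation
            X = rng.standard_normal((n_per_class, len(FEATURE_NAMES))) + mu + shift
            for x in X:
                row = dict(zip(FEATURE_NAMES, x))
                row.update(label=cls, subject_id=subj, sample_id=f"s{si}",
                           matrix="blood", day=-1, frame_index=0,
                           component_index=0, synthetic=False)
                rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["schema_fingerprint"] = schema_fingerprint()
    return table
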