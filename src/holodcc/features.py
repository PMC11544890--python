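"""24 hand-crafted morphological features per cell patch.

The catalog covers the four property families that separate leukocyte
classes in quantitative phase images — size, shape, optical height/volume,
and texture — using only the patch's phase values ``P`` and its segmentation
mask ``M`` (no re-thresholding, so description stays consistent with
detection).

Conventions chosen once and kept fixed:

* physical units use ``pixel_area_um2`` from the segmentation parameters;
  the linear pixel pitch is its square root;
* perimeter is the outer pixel-edge count times the pitch
  (digitization-exact, hence oracle-friendly);
* phase statistics are computed over the masked values; a constant patch has
  zero skewness/kurtosis by convention; entropy uses a 32-bin histogram over
  the masked value range with natural log and empty bins contributing 0;
* the gradient is a central difference in pixel units (rad/px);
* local maxima are counted after a 1-px Gaussian smoothing, strict
  8-neighbour maxima only (plateaus count zero).
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.spatial import ConvexHull, QhullError

from .preprocess import CellPatch, SegmentationParams

#: Ordered feature catalog: (name, unit). Order defines the schema.
FEATURE_CATALOG: list[tuple[str, str]] = [
    ("area_um2", "um^2"),
    ("equivalent_diameter_um", "um"),
    ("perimeter_um", "um"),
    ("circularity", "1"),
    ("eccentricity", "1"),
    ("major_axis_um", "um"),
    ("minor_axis_um", "um"),
    ("aspect_ratio", "1"),
    ("solidity", "1"),
    ("extent", "1"),
    ("mean_phase", "rad"),
    ("median_phase", "rad"),
    ("max_phase", "rad"),
    ("min_phase", "rad"),
    ("phase_range", "rad"),
    ("std_phase", "rad"),
    ("phase_skewness", "1"),
    ("phase_kurtosis", "1"),
    ("phase_entropy", "nat"),
    ("optical_volume", "rad.um^2"),
    ("mass_displacement_um", "um"),
    ("mean_gradient_magnitude", "rad/px"),
    ("radial_contrast", "rad"),
    ("local_maxima_count", "count"),
]

FEATURE_NAMES: list[str] = [n for n, _ in FEATURE_CATALOG]

METADATA_COLUMNS = ["label", "subject_id", "sample_id", "matrix", "day",
                    "frame_index", "component_index", "synthetic"]

_CROP_MARGIN = 4  # >= Gaussian kernel radius (sigma 1, truncate 3) + 1


def schema_fingerprint(names: Sequence[str] = FEATURE_NAMES) -> str:
    """Short digest of the ordered feature schema.

    Stored with every trained model and recomputed from table columns at
    prediction time, so a model can never be silently applied to features it
    was not trained on.
    """
    units = dict(FEATURE_CATALOG)
    payload = ";".join(f"{n}:{units.get(n, '?')}" for n in names)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_features(patch: CellPatch, params: SegmentationParams) -> dict[str, float]:
    """Compute the 24-feature vector for one cell patch."""
    values = np.asarray(patch.values, dtype=np.float64)
    mask = np.asarray(patch.mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("patch values and mask shapes differ")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask")
    if n_px < 4:
        raise ValueError("mask too small for moment features (< 4 px)")

    pa = params.pixel_area_um2
    pitch = float(np.sqrt(pa))

    # crop to the mask bbox plus a margin wide enough that smoothing and
    # gradients at mask pixels see exactly the same neighbourhood as in the
    # full patch -> features are exactly translation invariant
    rr, cc = np.nonzero(mask)
    r0 = max(rr.min() - _CROP_MARGIN, 0)
    r1 = min(rr.max() + _CROP_MARGIN + 1, mask.shape[0])
    c0 = max(cc.min() - _CROP_MARGIN, 0)
    c1 = min(cc.max() + _CROP_MARGIN + 1, mask.shape[1])
    V = values[r0:r1, c0:c1]
    M = mask[r0:r1, c0:c1]

    out: dict[str, float] = {}
    area_um2 = n_px * pa
    out["area_um2"] = area_um2
    out["equivalent_diameter_um"] = 2.0 * np.sqrt(area_um2 / np.pi)

    # outer pixel-edge perimeter: mask/non-mask edges incl. the array border
    pad = np.pad(M, 1, constant_values=False)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((pad & ~np.roll(pad, shift, axis=ax)).sum())
    perimeter_um = edges * pitch
    out["perimeter_um"] = perimeter_um
    out["circularity"] = 4.0 * np.pi * area_um2 / perimeter_um**2

    # second-moment ellipse of the mask (per-pixel point masses, the
    # classical image-moment formulation: axis length = 4 sqrt(eigenvalue))
    mrr, mcc = np.nonzero(M)
    dr = mrr - mrr.mean()
    dc = mcc - mcc.mean()
    mu20 = float((dr * dr).mean())
    mu02 = float((dc * dc).mean())
    mu11 = float((dr * dc).mean())
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam1 = (mu20 + mu02) / 2.0 + common   # major eigenvalue
    lam2 = (mu20 + mu02) / 2.0 - common
    lam2 = max(lam2, 0.0)
    out["eccentricity"] = float(np.sqrt(1.0 - lam2 / lam1)) if lam1 > 0 else 0.0
    major = 4.0 * np.sqrt(lam1) * pitch
    minor = 4.0 * np.sqrt(lam2) * pitch
    out["major_axis_um"] = major
    out["minor_axis_um"] = minor
    # collinear masks have a zero second moment across the line; floor the
    # minor axis at one pixel so the ratio stays finite
    out["aspect_ratio"] = major / max(minor, pitch)

    # solidity against the convex hull of the pixel *corner* points, so any
    # convex digital shape scores close to 1 and none exceeds it
    corners = np.concatenate([
        np.stack([mrr + d, mcc + e], axis=1)
        for d in (-0.5, 0.5) for e in (-0.5, 0.5)])
    try:
        hull_area = ConvexHull(corners).volume
    except QhullError:
        hull_area = float(n_px)
    out["solidity"] = n_px / hull_area
    bbox_px = (mrr.max() - mrr.min() + 1) * (mcc.max() - mcc.min() + 1)
    out["extent"] = n_px / bbox_px

    vals = V[M]
    mean = float(vals.mean())
    vmax, vmin = float(vals.max()), float(vals.min())
    d = vals - mean
    m2 = float((d * d).mean())
    sd = float(np.sqrt(m2))
    out["mean_phase"] = mean
    out["median_phase"] = float(np.median(vals))
    out["max_phase"] = vmax
    out["min_phase"] = vmin
    out["phase_range"] = vmax - vmin
    out["std_phase"] = sd
    if sd > 0:
        out["phase_skewness"] = float((d**3).mean()) / m2**1.5
        out["phase_kurtosis"] = float((d**4).mean()) / m2**2 - 3.0
    else:
        out["phase_skewness"] = 0.0
        out["phase_kurtosis"] = 0.0
    if vmax > vmin:
        hist, _ = np.histogram(vals, bins=32, range=(vmin, vmax))
        p = hist[hist > 0] / n_px
        out["phase_entropy"] = float(-(p * np.log(p)).sum())
    else:
        out["phase_entropy"] = 0.0

    out["optical_volume"] = float(vals.sum()) * pa

    bin_cen = np.array([mrr.mean(), mcc.mean()])
    wsum = float(vals.sum())
    if wsum > 0:
        w_cen = np.array([(mrr * vals).sum(), (mcc * vals).sum()]) / wsum
        out["mass_displacement_um"] = float(np.linalg.norm(w_cen - bin_cen)) * pitch
    else:
        out["mass_displacement_um"] = 0.0

    gy, gx = np.gradient(V)
    out["mean_gradient_magnitude"] = float(np.sqrt(gy[M]**2 + gx[M]**2).mean())

    r = np.sqrt((mrr - bin_cen[0])**2 + (mcc - bin_cen[1])**2)
    rmax = r.max()
    if rmax > 0:
        ring = np.minimum((r / rmax * 4).astype(int), 3)
        means = [vals[ring == k].mean() for k in range(4) if (ring == k).any()]
        out["radial_contrast"] = float(np.std(means))
    else:
        out["radial_contrast"] = 0.0

    sm = gaussian_filter(V, sigma=1.0, mode="constant", truncate=3.0)
    neigh = maximum_filter(sm, footprint=np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]],
                                                  dtype=bool), mode="constant",
                           cval=-np.inf)
    out["local_maxima_count"] = float(((sm > neigh) & M).sum())

    return out


def build_feature_table(patches: Sequence[CellPatch],
                        params: SegmentationParams,
                        labels: Sequence[str] | None = None,
                        subject_id: str = "",
                        matrix: str = "",
                        day: int | None = None) -> pd.DataFrame:
    """One row per patch: 24 features plus provenance metadata.

    Row order follows the patch list (deterministic).  ``labels``, if given,
    must align 1:1 with the patches.  The returned frame carries the schema
    fingerprint in ``attrs`` and a ``synthetic`` flag column (False for every
    measured row; SMOTE marks its interpolated rows True).
    """
    if labels is not None and len(labels) != len(patches):
        raise ValueError("labels must align 1:1 with patches")
    rows = []
    for i, patch in enumerate(patches):
        row = compute_features(patch, params)
        if labels is not None:
            row["label"] = labels[i]
        row["subject_id"] = subject_id
        row["sample_id"] = patch.sample_id
        row["matrix"] = matrix
        row["day"] = day if day is not None else -1
        row["frame_index"] = patch.frame_index
        row["component_index"] = patch.component_index
        row["synthetic"] = False
        rows.append(row)
    cols = FEATURE_NAMES + [c for c in METADATA_COLUMNS
                            if labels is not None or c != "label"]
    table = pd.DataFrame(rows, columns=cols)
    table.attrs["schema_fingerprint"] = schema_fingerprint()
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 24) feature block in schema order."""
    missing = [n for n in FEATURE_NAMES if n not in table.columns]
    if missing:
        raise ValueError(f"table is missing feature columns: {missing}")
    return table[FEATURE_NAMES].to_numpy(dtype=np.float64)


def table_fingerprint(table: pd.DataFrame) -> str:
    """Fingerprint of the feature columns actually present, in table order."""
    names = [c for c in table.columns if c in set(FEATURE_NAMES)]
    return schema_fingerprint(names)
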