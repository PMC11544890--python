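"""Synthetic quantitative-phase recordings with ground-truth annotations.

Real flow-through phase-microscopy measurements of bovine leukocytes are not
publicly deposited, so every downstream stage (segmentation, feature
extraction, classification, composition recovery) is exercised against
synthetic recordings generated here.  A recording is a stack of phase frames
(radians): a static channel-artifact pattern, plus Gaussian background noise,
plus non-overlapping cell phantoms drawn from class-specific phenotypes.

The phantom model is a raised-cosine phase bump on an elliptical footprint,
optionally decorated with internal lobes (a proxy for nuclear lobation) and
multiplicative speckle texture.  These knobs control exactly the properties
the classifiers later exploit: projected size, peak optical height, optical
volume, contrast and texture.

Everything is driven by ``numpy.random.Generator`` instances; identical
(config, seed) pairs produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from ._util import derive_seed, truncated_normal

_MAX_SAMPLE_RETRIES = 50
_MAX_PLACE_RETRIES = 200


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassPhenotype:
    """Morphological recipe for one leukocyte class.

    Parameters
    ----------
    class_name:
        Label attached to every phantom rendered from this phenotype.
    radius_mean, radius_sd:
        Cell radius in pixels (mean and jitter SD; draws are clipped at
        ±2.5 SD so a phantom cannot collapse or explode).
    peak_phase_mean, peak_phase_sd:
        Maximum phase shift of the cell in radians.
    lobe_count:
        Number of internal phase lobes (0 = smooth profile).
    granularity_sd:
        Relative amplitude of multiplicative intra-cell speckle texture.
    eccentricity_mean:
        Target elongation of the footprint ellipse, in [0, 1).
    debris:
        Marks sub-resolution junk phantoms (milk isolation remnants) that are
        *meant* to fall below the segmentation area filter; these skip the
        detectability floors on radius and peak phase.
    """

    class_name: str
    radius_mean: float
    radius_sd: float
    peak_phase_mean: float
    peak_phase_sd: float
    lobe_count: int = 0
    granularity_sd: float = 0.0
    eccentricity_mean: float = 0.0
    debris: bool = False

    def __post_init__(self) -> None:
        if not self.debris:
            if self.radius_mean < 4:
                raise ValueError("radius_mean must be >= 4 px for cell phenotypes")
            if self.peak_phase_mean <= 0.8:
                raise ValueError("peak_phase_mean must exceed 0.8 rad")
        if min(self.radius_sd, self.peak_phase_sd, self.granularity_sd) < 0:
            raise ValueError("sd parameters must be non-negative")
        if not 0 <= self.eccentricity_mean < 1:
            raise ValueError("eccentricity_mean must lie in [0, 1)")
        if self.lobe_count < 0:
            raise ValueError("lobe_count must be non-negative")


def blood_phenotypes() -> list[ClassPhenotype]:
    """Default blood classes: granulocyte / lymphocyte / monocyte.

    Values are stand-ins chosen to mimic the qualitative ordering seen in
    phase images of leukocytes — lymphocytes small, round and optically tall;
    granulocytes mid-sized with lobed texture; monocytes large, flatter and
    more eccentric — while keeping the classes overlapping enough that
    classifier comparisons stay non-trivial.
    """
    return [
        ClassPhenotype("granulocyte", radius_mean=9.5, radius_sd=0.6,
                       peak_phase_mean=1.7, peak_phase_sd=0.12,
                       lobe_count=3, granularity_sd=0.12, eccentricity_mean=0.15),
        ClassPhenotype("lymphocyte", radius_mean=7.0, radius_sd=0.4,
                       peak_phase_mean=2.4, peak_phase_sd=0.15,
                       lobe_count=0, granularity_sd=0.05, eccentricity_mean=0.05),
        ClassPhenotype("monocyte", radius_mean=12.0, radius_sd=0.8,
                       peak_phase_mean=1.4, peak_phase_sd=0.10,
                       lobe_count=1, granularity_sd=0.08, eccentricity_mean=0.30),
    ]


def milk_phenotypes(include_debris: bool = False) -> list[ClassPhenotype]:
    """Default milk classes: granulocyte / lymphocyte / macrophage.

    Macrophages replace monocytes and are modelled larger, flatter and more
    variable. ``include_debris`` adds a sub-resolution junk class emulating
    isolation-process remnants; debris phantoms segment above the phase
    threshold but fall below the 30-px area filter.
    """
    classes = [
        ClassPhenotype("granulocyte", radius_mean=9.5, radius_sd=0.7,
                       peak_phase_mean=1.6, peak_phase_sd=0.13,
                       lobe_count=3, granularity_sd=0.15, eccentricity_mean=0.15),
        ClassPhenotype("lymphocyte", radius_mean=7.0, radius_sd=0.45,
                       peak_phase_mean=2.3, peak_phase_sd=0.16,
                       lobe_count=0, granularity_sd=0.08, eccentricity_mean=0.05),
        ClassPhenotype("macrophage", radius_mean=13.0, radius_sd=1.0,
                       peak_phase_mean=1.45, peak_phase_sd=0.10,
                       lobe_count=0, granularity_sd=0.15, eccentricity_mean=0.35),
    ]
    if include_debris:
        classes.append(ClassPhenotype("debris", radius_mean=2.2, radius_sd=0.3,
                                      peak_phase_mean=1.5, peak_phase_sd=0.2,
                                      granularity_sd=0.2, debris=True))
    return classes


def phenotypes_for(matrix: str, include_debris: bool = False) -> list[ClassPhenotype]:
    if matrix == "blood":
        return blood_phenotypes()
    if matrix == "milk":
        return milk_phenotypes(include_debris=include_debris)
    raise ValueError(f"unknown matrix {matrix!r} (expected 'blood' or 'milk')")


@dataclass(frozen=True)
class SceneConfig:
    """Frame-level generation parameters.

    ``frame_shape`` is (rows, cols); the native sensor format is 384 x 512.
    ``cells_per_frame_mean`` is the Poisson mean of cells per frame (default
    5, the nominal load of the flow cell).  ``noise_sd`` is the SD of i.i.d.
    Gaussian background phase noise in radians; ``artifact_amplitude`` scales
    the static channel pattern shared by every frame of a recording.
    """

    frame_shape: tuple[int, int] = (384, 512)
    cells_per_frame_mean: float = 5.0
    noise_sd: float = 0.05
    artifact_amplitude: float = 0.3
    forbid_overlap: bool = True
    placement_margin: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("frame_shape must be positive")
        if self.cells_per_frame_mean < 0:
            raise ValueError("cells_per_frame_mean must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.placement_margin < 0:
            raise ValueError("placement_margin must be >= 0")


def artifact_pattern(scene: SceneConfig) -> np.ndarray:
    """Static channel-artifact background (identical for every frame).

    A smooth superposition of low-frequency waves standing in for microfluidic
    channel walls and illumination non-uniformity.  Closed-form, hence exactly
    reproducible and independent of the per-frame RNG stream.
    """
    rows, cols = scene.frame_shape
    r = np.arange(rows, dtype=np.float64)[:, None]
    c = np.arange(cols, dtype=np.float64)[None, :]
    amp = scene.artifact_amplitude
    return amp * (0.6 * np.sin(2 * np.pi * c / 160.0)
                  + 0.4 * np.cos(2 * np.pi * r / 120.0)
                  + 0.2 * np.sin(2 * np.pi * (r + c) / 310.0))


@dataclass
class CellTruth:
    """Ground-truth record for one rendered phantom."""

    class_name: str
    frame_index: int = -1
    centroid_row: float = 0.0
    centroid_col: float = 0.0
    area_px: int = 0
    radius: float = 0.0
    peak_phase: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_cell(phenotype: ClassPhenotype, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, CellTruth]:
    """Render one cell phantom on a tight square grid.

    Returns ``(patch, mask, truth)`` where ``patch`` is the phase image in
    radians (zero outside ``mask``), ``mask`` is the boolean elliptical
    footprint, and ``truth`` records the sampled morphology.  The maximum of
    ``patch`` over the mask equals the sampled peak phase exactly (the
    composite profile is renormalised after texturing).
    """
    radius = peak = -1.0
    for _ in range(_MAX_SAMPLE_RETRIES):
        radius = phenotype.radius_mean + phenotype.radius_sd * truncated_normal(rng)
        peak = phenotype.peak_phase_mean + phenotype.peak_phase_sd * truncated_normal(rng)
        if radius >= 1.0 and peak > 0:
            break
    else:
        raise RuntimeError(
            f"could not sample a positive radius/peak for {phenotype.class_name}")

    ecc = phenotype.eccentricity_mean
    q = (1.0 - ecc**2) ** 0.25
    a, b = radius / q, radius * q          # semi-axes, equal area to a disc
    theta = rng.uniform(0.0, 2.0 * np.pi)  # footprint orientation

    half = int(np.ceil(a)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ct, st = np.cos(theta), np.sin(theta)
    xr = xx * ct + yy * st
    yr = -xx * st + yy * ct
    rho2 = (xr / a) ** 2 + (yr / b) ** 2
    mask = rho2 <= 1.0
    rho = np.sqrt(np.minimum(rho2, 1.0))

    profile = 0.5 * (1.0 + np.cos(np.pi * rho))
    profile[~mask] = 0.0

    if phenotype.lobe_count > 0:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        sigma = 0.30 * radius
        for j in range(phenotype.lobe_count):
            phi = phi0 + 2.0 * np.pi * j / phenotype.lobe_count
            cx, cy = 0.45 * a * np.cos(phi), 0.45 * b * np.sin(phi)
            d2 = (xr - cx) ** 2 + (yr - cy) ** 2
            profile += 0.30 * np.exp(-d2 / (2.0 * sigma**2)) * mask

    if phenotype.granularity_sd > 0:
        fld = gaussian_filter(rng.standard_normal(profile.shape), sigma=1.5)
        sd = fld.std()
        if sd > 0:
            fld /= sd
        # taper the speckle toward the rim so the thresholded footprint stays
        # simply connected (no satellite blobs pinching off at the contour)
        w = profile / profile.max() if profile.max() > 0 else profile
        profile *= np.clip(1.0 + phenotype.granularity_sd * fld * w, 0.0, None)
        profile[~mask] = 0.0

    peak_now = profile.max()
    if peak_now > 0:
        profile *= peak / peak_now

    truth = CellTruth(class_name=phenotype.class_name, area_px=int(mask.sum()),
                      centroid_row=float(half), centroid_col=float(half),
                      radius=float(radius), peak_phase=float(peak))
    return profile, mask, truth


_DILATE_8 = np.ones((3, 3), dtype=bool)


def synthesize_frame(phenotypes: Sequence[ClassPhenotype],
                     mixture: Sequence[float],
                     scene: SceneConfig,
                     rng: np.random.Generator,
                     frame_index: int = 0,
                     ) -> tuple[np.ndarray, list[CellTruth]]:
    """Synthesize one phase frame: artifact + noise + placed phantoms.

    The cell count is Poisson(``cells_per_frame_mean``); classes are drawn
    from ``mixture``.  With overlap forbidden (default), placed masks are kept
    at least two pixels apart so segmentation cannot merge neighbours; running
    out of room raises after bounded retries.
    """
    mixture = np.asarray(mixture, dtype=float)
    if len(phenotypes) == 0:
        raise ValueError("phenotypes must be non-empty")
    if mixture.shape != (len(phenotypes),) or abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError("mixture must align with phenotypes and sum to 1")

    frame = artifact_pattern(scene).copy()
    n_cells = int(rng.poisson(scene.cells_per_frame_mean))
    classes = rng.choice(len(phenotypes), size=n_cells, p=mixture)
    if scene.noise_sd > 0:
        frame += rng.normal(0.0, scene.noise_sd, size=frame.shape)

    rows, cols = scene.frame_shape
    m = scene.placement_margin
    occupancy = np.zeros(scene.frame_shape, dtype=bool)
    truths: list[CellTruth] = []
    for ci in classes:
        patch, mask, truth = render_cell(phenotypes[ci], rng)
        h, w = mask.shape
        # keep the phantom centre at least placement_margin from the border
        # (margin = patch_size/2 guarantees downstream windows stay in-frame)
        half = h // 2
        r_lo, r_hi = max(m - half, 0), min(rows - h, rows - m - half - 1)
        c_lo, c_hi = max(m - half, 0), min(cols - w, cols - m - half - 1)
        if r_hi < r_lo or c_hi < c_lo:
            raise RuntimeError("frame too small for phantom footprint and margin")
        for _ in range(_MAX_PLACE_RETRIES):
            r0 = int(rng.integers(r_lo, r_hi + 1))
            c0 = int(rng.integers(c_lo, c_hi + 1))
            win = (slice(r0, r0 + h), slice(c0, c0 + w))
            if scene.forbid_overlap and (occupancy[win] & mask).any():
                continue
            frame[win][mask] += patch[mask]
            if scene.forbid_overlap:
                # 2-px dilation keeps placed masks >2 px apart (Chebyshev), so
                # thresholded blobs can never merge under 8-connectivity
                occupancy[win] |= binary_dilation(mask, _DILATE_8, iterations=2)
            truth.frame_index = frame_index
            truth.centroid_row += r0
            truth.centroid_col += c0
            truths.append(truth)
            break
        else:
            raise RuntimeError(
                "could not place phantom without overlap after bounded retries")
    return frame, truths


# --------------------------------------------------------------------------
# dataset-level generators
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """A stack of frames plus per-phantom ground truth."""

    sample_id: str
    subject_id: str
    matrix: str
    frames: np.ndarray            # (n_frames, rows, cols) float32
    truths: list[CellTruth]
    day: int | None = None


def jitter_phenotypes(phenotypes: Sequence[ClassPhenotype],
                      rng: np.random.Generator,
                      scale: float = 0.04) -> list[ClassPhenotype]:
    """Systematic per-subject morphology shifts (multiplicative, clipped).

    Emulates inter-animal variation: each subject's cells are consistently a
    few percent larger/taller than the population phenotype, which is what
    makes leave-one-subject-out validation strictly harder than a same-subject
    hold-out.
    """
    out = []
    for ph in phenotypes:
        f_r = 1.0 + scale * truncated_normal(rng)
        f_p = 1.0 + scale * truncated_normal(rng)
        out.append(dataclasses.replace(
            ph,
            radius_mean=max(ph.radius_mean * f_r, 4.0 if not ph.debris else 1.0),
            peak_phase_mean=max(ph.peak_phase_mean * f_p,
                                0.801 if not ph.debris else 0.1),
        ))
    return out


def synthesize_recording(phenotypes: Sequence[ClassPhenotype],
                         mixture: Sequence[float],
                         scene: SceneConfig,
                         n_frames: int,
                         rng: np.random.Generator,
                         sample_id: str = "",
                         subject_id: str = "",
                         matrix: str = "blood",
                         day: int | None = None) -> Recording:
    frames = np.empty((n_frames, *scene.frame_shape), dtype=np.float32)
    truths: list[CellTruth] = []
    for i in range(n_frames):
        fr, tr = synthesize_frame(phenotypes, mixture, scene, rng, frame_index=i)
        frames[i] = fr
        truths.extend(tr)
    return Recording(sample_id=sample_id, subject_id=subject_id, matrix=matrix,
                     frames=frames, truths=truths, day=day)


def synthesize_isolation_dataset(phenotypes: Sequence[ClassPhenotype],
                                 subjects: Sequence[str],
                                 frames_per_class: int,
                                 scene: SceneConfig,
                                 rng: np.random.Generator,
                                 imbalance: Sequence[float] | None = None,
                                 subject_jitter: float = 0.04,
                                 matrix: str = "blood",
                                 ) -> list[Recording]:
    """Sorted-cell training recordings: one single-class stack per (subject, class).

    Mirrors a cell-sorting experiment in which each leukocyte class of each
    animal is measured in isolation, so truth labels are exact.  ``imbalance``
    weights the expected cell yield per class (default 5:3:1 for three
    classes, emulating biologically uneven counts); class shares converge to
    ``w_c / sum(w)``.  Per-subject phenotype jitter makes animals differ
    systematically.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject")
    if frames_per_class < 1:
        raise ValueError("frames_per_class must be >= 1")
    cell_classes = [ph for ph in phenotypes if not ph.debris]
    n_cls = len(cell_classes)
    if imbalance is None:
        imbalance = [5.0, 3.0, 1.0][:n_cls] if n_cls <= 3 else [1.0] * n_cls
    w = np.asarray(imbalance, dtype=float)
    if w.shape != (n_cls,) or (w <= 0).any():
        raise ValueError("imbalance must give one positive weight per cell class")
    load = w * n_cls / w.sum()   # per-class cells/frame multiplier, mean 1

    recordings: list[Recording] = []
    for subject in subjects:
        subj_rng = np.random.default_rng(derive_seed(int(rng.integers(2**31)),
                                                     f"subject:{subject}"))
        subj_phenos = jitter_phenotypes(phenotypes, subj_rng, subject_jitter)
        subj_cells = [ph for ph in subj_phenos if not ph.debris]
        for k, ph in enumerate(subj_cells):
            sub_scene = dataclasses.replace(
                scene, cells_per_frame_mean=scene.cells_per_frame_mean * load[k])
            rec = synthesize_recording(
                [ph], [1.0], sub_scene, frames_per_class, rng,
                sample_id=f"iso-{subject}-{ph.class_name}",
                subject_id=subject, matrix=matrix)
            recordings.append(rec)
    return recordings


@dataclass
class StudyDesign:
    """Longitudinal sampling design: subjects x ordered days, one matrix.

    ``compositions`` holds the designed (true) class-proportion vector per
    subject and day, shape (n_subjects, n_days, n_classes); each vector must
    be non-negative and sum to 1.  ``reference_noise_sd`` is the SD of the
    truncated additive noise used to derive the reference-method series
    (a flow-cytometry analogue) from realized truth.
    """

    subjects: list[str]
    time_points: list[int]
    class_names: list[str]
    compositions: np.ndarray
    matrix: str = "blood"
    reference_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        self.compositions = np.asarray(self.compositions, dtype=float)
        S, T, C = len(self.subjects), len(self.time_points), len(self.class_names)
        if self.compositions.shape != (S, T, C):
            raise ValueError("compositions must have shape (subjects, days, classes)")
        if (self.compositions < 0).any():
            raise ValueError("compositions must be non-negative")
        if np.abs(self.compositions.sum(axis=2) - 1.0).max() > 1e-9:
            raise ValueError("composition vectors must sum to 1")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time_points must be strictly increasing")
        if self.reference_noise_sd < 0:
            raise ValueError("reference_noise_sd must be >= 0")

    @classmethod
    def random(cls, rng: np.random.Generator,
               subjects: Sequence[str] | None = None,
               time_points: Sequence[int] | None = None,
               matrix: str = "blood",
               reference_noise_sd: float = 0.02,
               walk_sd: float = 0.15) -> "StudyDesign":
        """Smooth per-subject composition trajectories.

        Defaults follow the study layout: 5 subjects sampled on 14 days over
        26 days (4 pre-vaccination, 10 post).  Each subject starts at a
        Dirichlet draw around matrix-typical leukocyte shares and evolves by
        a multiplicative log-normal random walk, renormalised daily.
        """
        if subjects is None:
            subjects = [f"cow{i + 1}" for i in range(5)]
        if time_points is None:
            time_points = [1, 3, 5, 8, 9, 10, 11, 12, 15, 17, 19, 22, 24, 26]
        class_names = [ph.class_name for ph in phenotypes_for(matrix)]
        base = {"blood": np.array([0.55, 0.35, 0.10]),
                "milk": np.array([0.60, 0.25, 0.15])}[matrix]
        S, T, C = len(subjects), len(time_points), len(class_names)
        comps = np.empty((S, T, C))
        for s in range(S):
            p = rng.dirichlet(base * 40.0)
            for t in range(T):
                comps[s, t] = p
                p = p * np.exp(walk_sd * rng.standard_normal(C))
                p = np.clip(p, 1e-4, None)
                p /= p.sum()
        return cls(subjects=list(subjects), time_points=list(time_points),
                   class_names=class_names, compositions=comps, matrix=matrix,
                   reference_noise_sd=reference_noise_sd)


@dataclass
class SampleRecording:
    """One longitudinal sample: frames, truth, and both composition views."""

    subject_id: str
    day: int
    matrix: str
    frames: np.ndarray
    truths: list[CellTruth]
    true_composition: np.ndarray       # designed mixture
    realized_composition: np.ndarray   # truth-label shares actually rendered
    reference_composition: np.ndarray  # realized + truncated noise, renormalised
    class_names: list[str] = field(default_factory=list)

    @property
    def sample_id(self) -> str:
        return f"{self.matrix}-{self.subject_id}-d{self.day:02d}"


def iter_longitudinal_samples(design: StudyDesign,
                              phenotypes: Sequence[ClassPhenotype],
                              scene: SceneConfig,
                              frames_per_sample: int,
                              rng: np.random.Generator,
                              subject_jitter: float = 0.0,
                              ) -> Iterator[SampleRecording]:
    """Lazily generate one recording per (subject, day).

    A generator rather than a list because a full-scale study (70 samples of
    hundreds of frames) does not fit in memory at once; consume and discard.
    """
    cell_classes = [ph for ph in phenotypes if not ph.debris]
    names = [ph.class_name for ph in cell_classes]
    if names != list(design.class_names):
        raise ValueError("phenotype classes do not match the study design")
    for s, subject in enumerate(design.subjects):
        subj_rng = np.random.default_rng(derive_seed(int(rng.integers(2**31)),
                                                     f"subject:{subject}"))
        subj_phenos = (jitter_phenotypes(phenotypes, subj_rng, subject_jitter)
                       if subject_jitter > 0 else list(phenotypes))
        subj_cells = [ph for ph in subj_phenos if not ph.debris]
        for t, day in enumerate(design.time_points):
            mix = design.compositions[s, t]
            # debris phantoms (if present) ride along at fixed 10% of load
            phenos, full_mix = subj_cells, mix
            debris = [ph for ph in subj_phenos if ph.debris]
            if debris:
                phenos = subj_cells + debris
                full_mix = np.concatenate([mix * 0.9,
                                           [0.1 / len(debris)] * len(debris)])
            rec = synthesize_recording(
                phenos, full_mix, scene, frames_per_sample, rng,
                sample_id=f"{design.matrix}-{subject}-d{day:02d}",
                subject_id=subject, matrix=design.matrix, day=day)
            counts = np.array([sum(tr.class_name == n for tr in rec.truths)
                               for n in names], dtype=float)
            realized = counts / counts.sum() if counts.sum() else mix.copy()
            if design.reference_noise_sd > 0:
                ref = realized + rng.normal(0.0, design.reference_noise_sd,
                                            size=len(names))
                ref = np.clip(ref, 0.0, None)
                ref = ref / ref.sum() if ref.sum() > 0 else realized.copy()
            else:
                ref = realized.copy()
            yield SampleRecording(subject_id=subject, day=day,
                                  matrix=design.matrix, frames=rec.frames,
                                  truths=rec.truths, true_composition=mix.copy(),
                                  realized_composition=realized,
                                  reference_composition=ref, class_names=names)


def synthesize_longitudinal_study(design: StudyDesign,
                                  phenotypes: Sequence[ClassPhenotype],
                                  scene: SceneConfig,
                                  frames_per_sample: int,
                                  rng: np.random.Generator,
                                  subject_jitter: float = 0.0,
                                  ) -> tuple[list[SampleRecording], list]:
    """Eager variant of :func:`iter_longitudinal_samples`.

    Returns the recordings plus the reference-method series (one
    ``CompositionSeries`` per subject).  Only suitable for reduced scales that
    fit in memory.
    """
    samples = list(iter_longitudinal_samples(
        design, phenotypes, scene, frames_per_sample, rng,
        subject_jitter=subject_jitter))
    return samples, reference_series(design, samples)


def reference_series(design: StudyDesign,
                     samples: Iterable[SampleRecording]) -> list:
    """Collect per-subject reference-method composition series."""
    from .evaluate import CompositionSeries

    by_subject: dict[str, list[SampleRecording]] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)
    out = []
    for subject in design.subjects:
        recs = sorted(by_subject.get(subject, []), key=lambda r: r.day)
        if not recs:
            continue
        out.append(CompositionSeries(
            subject_id=subject, matrix=design.matrix,
            days=[r.day for r in recs], classes=list(design.class_names),
            proportions=np.vstack([r.reference_composition for r in recs]),
            source="reference"))
    return out
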