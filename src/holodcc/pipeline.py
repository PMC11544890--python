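"""End-to-end orchestration: simulate -> preprocess/features -> train -> evaluate.

One ``RunConfig`` drives a full reproducible run.  A single global seed fans
out to per-stage seeds (stable hash of the stage name), so each stage is
individually reproducible; every output file lands in the run directory and
is content-hashed into ``run_manifest.json``.  Stages are skipped on re-runs
when their configuration hash and output hashes are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from ._util import derive_seed, sha256_file, stable_json
from .evaluate import (CompositionSeries, classification_metrics,
                       compare_series, confusion_matrix,
                       leave_one_subject_out, sample_composition)
from .features import build_feature_table
from .preprocess import SegmentationParams, preprocess_recording
from .simulate import (SceneConfig, StudyDesign, iter_longitudinal_samples,
                       phenotypes_for, reference_series,
                       synthesize_isolation_dataset)
from .train import (SmoteParams, SplitSpec, fit_classifier, grid_search_cv,
                    predict, smote_balance, stratified_split)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    The defaults describe a reduced-scale study that keeps the full run
    desk-sized: 3 isolation subjects, a 5-subject x 14-day longitudinal
    design, small frames.  The native-scale recording (384 x 512 frames,
    ~10,000 frames per measurement) is reached by overriding ``frame_shape``,
    ``frames_per_class`` and ``frames_per_sample``.
    """

    seed: int = 0
    matrix: str = "blood"
    families: tuple[str, ...] = ("rf",)
    grids: dict = field(default_factory=lambda: {"rf": {"n_estimators": [100]}})

    frame_shape: tuple[int, int] = (256, 320)
    cells_per_frame_mean: float = 6.0
    noise_sd: float = 0.05
    artifact_amplitude: float = 0.3

    isolation_subjects: tuple[str, ...] = ("cow1", "cow2", "cow3")
    frames_per_class: int = 30
    imbalance: tuple[float, ...] | None = None
    subject_jitter: float = 0.04

    study_subjects: tuple[str, ...] = ("cow1", "cow2", "cow3", "cow4", "cow5")
    time_points: tuple[int, ...] = (1, 3, 5, 8, 9, 10, 11, 12, 15, 17, 19, 22, 24, 26)
    frames_per_sample: int = 25
    reference_noise_sd: float = 0.02
    include_debris: bool = False

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    smote: SmoteParams = field(default_factory=SmoteParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    paper_protocol: bool = False   # balance before splitting (leaky, faithful)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("segmentation", SegmentationParams),
                         ("smote", SmoteParams), ("split", SplitSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        for key in ("families", "isolation_subjects", "study_subjects",
                    "time_points", "imbalance"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _scene(config: RunConfig, stage: str) -> SceneConfig:
    return SceneConfig(frame_shape=config.frame_shape,
                       cells_per_frame_mean=config.cells_per_frame_mean,
                       noise_sd=config.noise_sd,
                       artifact_amplitude=config.artifact_amplitude,
                       placement_margin=config.segmentation.patch_size // 2 + 2,
                       seed=derive_seed(config.seed, stage))


class _Stages:
    """Tiny content-addressed stage cache inside the run directory."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.config_json = stable_json(config.to_dict())
        self.path = outdir / ".stage_hashes.json"
        self.state = (json.loads(self.path.read_text())
                      if self.path.exists() else {})

    def key(self, stage: str) -> str:
        return hashlib.sha256((stage + self.config_json).encode()).hexdigest()

    def fresh(self, stage: str) -> bool:
        entry = self.state.get(stage)
        if not entry or entry.get("key") != self.key(stage):
            return False
        for rel, digest in entry.get("outputs", {}).items():
            p = self.outdir / rel
            if not p.exists() or sha256_file(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.state[stage] = {
            "key": self.key(stage),
            "outputs": {str(p.relative_to(self.outdir)): sha256_file(p)
                        for p in outputs}}
        self.path.write_text(stable_json(self.state))


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full stage graph into ``outdir``; returns the directory."""
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    (outdir / "reports").mkdir(exist_ok=True)
    stages = _Stages(outdir, config)
    phenos = phenotypes_for(config.matrix, include_debris=config.include_debris)

    # ---- stage: simulate + features (streamed together to bound memory) ----
    iso_csv = outdir / "isolation_features.csv"
    vacc_csv = outdir / "vacc_features.csv"
    ref_csv = outdir / "reference_series.csv"
    truth_csv = outdir / "true_compositions.csv"
    if not stages.fresh("features"):
        rng = np.random.default_rng(derive_seed(config.seed, "simulate-iso"))
        recs = synthesize_isolation_dataset(
            phenos, list(config.isolation_subjects), config.frames_per_class,
            _scene(config, "iso"), rng,
            imbalance=list(config.imbalance) if config.imbalance else None,
            subject_jitter=config.subject_jitter, matrix=config.matrix)
        tables = []
        for rec in recs:
            hio.write_recording(outdir / "recordings" / f"{rec.sample_id}.tiff",
                                rec, seed=config.seed)
            patches, _ = preprocess_recording(rec.frames, config.segmentation,
                                              sample_id=rec.sample_id)
            cls = rec.sample_id.rsplit("-", 1)[-1]
            tables.append(build_feature_table(
                patches, config.segmentation, labels=[cls] * len(patches),
                subject_id=rec.subject_id, matrix=rec.matrix))
        iso = (pd.concat(tables, ignore_index=True) if tables
               else build_feature_table([], config.segmentation, labels=[]))
        hio.write_table_csv(iso_csv, iso)

        design = StudyDesign.random(
            np.random.default_rng(derive_seed(config.seed, "design")),
            subjects=list(config.study_subjects),
            time_points=list(config.time_points), matrix=config.matrix,
            reference_noise_sd=config.reference_noise_sd)
        vrng = np.random.default_rng(derive_seed(config.seed, "simulate-vacc"))
        vtables, samples_meta = [], []
        for sample in iter_longitudinal_samples(
                design, phenos, _scene(config, "vacc"),
                config.frames_per_sample, vrng,
                subject_jitter=config.subject_jitter):
            patches, _ = preprocess_recording(sample.frames, config.segmentation,
                                              sample_id=sample.sample_id)
            vtables.append(build_feature_table(
                patches, config.segmentation, subject_id=sample.subject_id,
                matrix=sample.matrix, day=sample.day))
            samples_meta.append(sample)
            sample.frames = np.empty(0)   # free the stack eagerly
        vacc = (pd.concat(vtables, ignore_index=True) if vtables
                else build_feature_table([], config.segmentation))
        hio.write_table_csv(vacc_csv, vacc)
        hio.write_series_csv(ref_csv, reference_series(design, samples_meta))
        truth = [CompositionSeries(
            subject_id=s, matrix=config.matrix, days=list(design.time_points),
            classes=list(design.class_names),
            proportions=design.compositions[i], source="truth")
            for i, s in enumerate(design.subjects)]
        hio.write_series_csv(truth_csv, truth)
        stages.record("features", [iso_csv, vacc_csv, ref_csv, truth_csv])
    iso = hio.read_table_csv(iso_csv)
    vacc = hio.read_table_csv(vacc_csv)

    # ---- stage: train + evaluate ----
    metrics_json = outdir / "reports" / "metrics.json"
    loso_json = outdir / "reports" / "loso.json"
    if len(iso) == 0 or "label" not in iso.columns or iso["label"].nunique() < 2:
        log.warning("no labeled cells extracted; skipping model training")
        metrics_json.write_text(stable_json({"warning": "no labeled cells"}))
        manifest = _write_manifest(outdir, config)
        return outdir
    if not stages.fresh("train"):
        report: dict = {}
        models = {}
        classes = sorted(iso["label"].unique())
        for family in config.families:
            fseed = derive_seed(config.seed, f"train-{family}")
            if config.paper_protocol:
                balanced = smote_balance(iso, SmoteParams(
                    k_neighbors=config.smote.k_neighbors,
                    seed=derive_seed(config.seed, "smote-all")))
                train_t, test_t = stratified_split(balanced, config.split)
            else:
                train_t, test_t = stratified_split(iso, config.split)
            grid = config.grids.get(family)
            best, cv = grid_search_cv(train_t, family, grid, config.split,
                                      smote=config.smote,
                                      balance=not config.paper_protocol,
                                      seed=fseed)
            cv.to_csv(outdir / "reports" / f"cv_{family}.csv", index=False)
            fit_t = (train_t if config.paper_protocol
                     else smote_balance(train_t, SmoteParams(
                         k_neighbors=config.smote.k_neighbors,
                         seed=derive_seed(config.seed, f"smote-{family}"))))
            model = fit_classifier(fit_t, family, best, seed=fseed, cv_summary=cv)
            models[family] = model
            pred = predict(model, test_t)
            cm = confusion_matrix(test_t["label"].to_numpy(), pred, classes)
            pd.DataFrame(cm.counts, index=classes, columns=classes).to_csv(
                outdir / "reports" / f"confusion_{family}.csv")
            report[family] = {"best_hyperparameters": best,
                              **classification_metrics(cm).to_dict()}
        metrics_json.write_text(stable_json(report))

        loso_report = {}
        for family in config.families:
            loso_report[family] = leave_one_subject_out(
                iso, family, models[family].hyperparameters,
                smote=config.smote,
                seed=derive_seed(config.seed, f"loso-{family}")).to_dict()
        loso_json.write_text(stable_json(loso_report))
        import joblib

        for family, model in models.items():
            joblib.dump(model, outdir / f"model_{family}.joblib")
        stages.record("train", [metrics_json, loso_json] +
                      [outdir / "reports" / f"cv_{f}.csv" for f in config.families] +
                      [outdir / "reports" / f"confusion_{f}.csv" for f in config.families] +
                      [outdir / f"model_{f}.joblib" for f in config.families])

    # ---- stage: differential counts + method comparison ----
    dcc_csv = outdir / "dcc.csv"
    compare_json = outdir / "reports" / "comparison.json"
    if not stages.fresh("dcc") and len(vacc) > 0:
        import joblib

        refs = hio.read_series_csv(ref_csv)
        comparison: dict = {}
        dcc_frames = []
        for family in config.families:
            model = joblib.load(outdir / f"model_{family}.joblib")
            series = []
            for subject, grp in vacc.groupby("subject_id", sort=True):
                days = sorted(grp["day"].unique())
                props = []
                for day in days:
                    sub = grp[grp["day"] == day]
                    labels = predict(model, sub)
                    _, p = sample_composition(labels, classes=model.classes)
                    props.append(p)
                series.append(CompositionSeries(
                    subject_id=str(subject), matrix=config.matrix,
                    days=[int(d) for d in days], classes=model.classes,
                    proportions=np.vstack(props), source=f"dhm-{family}"))
            dcc_frames.extend(s.to_frame() for s in series)
            comparison[family] = compare_series(series, refs).to_dict()
        pd.concat(dcc_frames, ignore_index=True).to_csv(dcc_csv, index=False)
        compare_json.write_text(stable_json(comparison))
        stages.record("dcc", [dcc_csv, compare_json])

    _write_manifest(outdir, config)
    return outdir


def _write_manifest(outdir: Path, config: RunConfig) -> Path:
    """Manifest: config snapshot, seed, and a content hash per output file."""
    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name not in ("run_manifest.json", ".stage_hashes.json"):
            files[str(p.relative_to(outdir))] = sha256_file(p)
    manifest = {"config": config.to_dict(), "seed": config.seed, "files": files}
    path = outdir / "run_manifest.json"
    path.write_text(stable_json(manifest))
    return path
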