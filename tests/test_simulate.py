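"""Generator contracts: phantom geometry, frame composition, study designs."""

import numpy as np
import pytest

from holodcc.simulate import (ClassPhenotype, SceneConfig, StudyDesign,
                              artifact_pattern, blood_phenotypes,
                              milk_phenotypes, render_cell, synthesize_frame,
                              synthesize_isolation_dataset,
                              synthesize_longitudinal_study)


def _plain(radius=5.0, radius_sd=0.0):
    return ClassPhenotype("lymphocyte", radius_mean=radius, radius_sd=radius_sd,
                          peak_phase_mean=2.0, peak_phase_sd=0.0)


class TestRenderCell:
    def test_degenerate_texture_is_a_symmetric_disc(self):
        patch, mask, truth = render_cell(_plain(), np.random.default_rng(0))
        # digital disc x^2+y^2 <= 25 has 81 lattice points
        assert mask.sum() == 81
        assert truth.area_px == 81
        assert np.allclose(patch, np.rot90(patch))   # radial symmetry
        assert patch[~mask].max() == 0.0
        assert patch.max() == pytest.approx(2.0)

    def test_seeded_reproducibility_is_bit_exact(self):
        p1, m1, _ = render_cell(blood_phenotypes()[0], np.random.default_rng(42))
        p2, m2, _ = render_cell(blood_phenotypes()[0], np.random.default_rng(42))
        assert np.array_equal(p1, p2) and np.array_equal(m1, m2)

    def test_peak_phase_is_hit_exactly_with_texture(self):
        ph = blood_phenotypes()[0]  # lobed + speckled granulocyte
        patch, mask, truth = render_cell(ph, np.random.default_rng(3))
        assert patch.max() == pytest.approx(truth.peak_phase)

    def test_phenotype_invariants_rejected(self):
        with pytest.raises(ValueError):
            ClassPhenotype("x", radius_mean=3, radius_sd=0,
                           peak_phase_mean=2.0, peak_phase_sd=0)
        with pytest.raises(ValueError):
            ClassPhenotype("x", radius_mean=5, radius_sd=0,
                           peak_phase_mean=0.5, peak_phase_sd=0)
        with pytest.raises(ValueError):
            ClassPhenotype("x", radius_mean=5, radius_sd=-1,
                           peak_phase_mean=2.0, peak_phase_sd=0)


class TestSynthesizeFrame:
    def test_empty_scene_equals_static_artifact(self):
        scene = SceneConfig(frame_shape=(64, 96), cells_per_frame_mean=0,
                            noise_sd=0.0)
        frame, truths = synthesize_frame([_plain()], [1.0], scene,
                                         np.random.default_rng(0))
        assert truths == []
        assert np.array_equal(frame, artifact_pattern(scene))

    def test_degenerate_mixture_yields_one_class(self):
        scene = SceneConfig(frame_shape=(128, 128), cells_per_frame_mean=4)
        phenos = blood_phenotypes()
        _, truths = synthesize_frame(phenos, [0.0, 1.0, 0.0], scene,
                                     np.random.default_rng(1))
        assert truths and all(t.class_name == "lymphocyte" for t in truths)

    def test_total_count_follows_poisson_moments(self, phenotypes):
        # 2000 frames at mean 5 -> 10000 expected cells, SD = 100
        scene = SceneConfig(frame_shape=(96, 128), cells_per_frame_mean=5,
                            noise_sd=0.0, forbid_overlap=False)
        rng = np.random.default_rng(11)
        total = sum(len(synthesize_frame(phenotypes, [0.5, 0.3, 0.2], scene,
                                         rng)[1]) for _ in range(2000))
        assert abs(total - 10000) < 3 * np.sqrt(10000)

    def test_forbidden_overlap_keeps_masks_disjoint(self, phenotypes):
        scene = SceneConfig(frame_shape=(192, 192), cells_per_frame_mean=12)
        rng = np.random.default_rng(5)
        frame, truths = synthesize_frame(phenotypes, [1 / 3] * 3, scene, rng)
        # rendered masks never touch: each phantom's peak must survive in the
        # frame, i.e. local neighbourhoods around distinct centroids differ
        centers = {(round(t.centroid_row), round(t.centroid_col)) for t in truths}
        assert len(centers) == len(truths)

    def test_overfull_frame_raises(self):
        scene = SceneConfig(frame_shape=(40, 40), cells_per_frame_mean=30)
        with pytest.raises(RuntimeError):
            synthesize_frame([_plain(radius=10)], [1.0], scene,
                             np.random.default_rng(2))


class TestIsolationDataset:
    def test_single_class_recordings_per_subject(self, phenotypes):
        scene = SceneConfig(frame_shape=(128, 160), cells_per_frame_mean=4)
        recs = synthesize_isolation_dataset(
            phenotypes, ["a", "b", "c"], 2, scene, np.random.default_rng(0))
        assert len(recs) == 9
        for rec in recs:
            names = {t.class_name for t in rec.truths}
            assert len(names) <= 1

    def test_imbalance_weights_control_class_shares(self, phenotypes):
        scene = SceneConfig(frame_shape=(192, 256), cells_per_frame_mean=6)
        recs = synthesize_isolation_dataset(
            phenotypes, ["a", "b", "c"], 12, scene, np.random.default_rng(1),
            imbalance=[5, 3, 1], subject_jitter=0.0)
        counts = {}
        for rec in recs:
            for t in rec.truths:
                counts[t.class_name] = counts.get(t.class_name, 0) + 1
        total = sum(counts.values())
        minority = counts["monocyte"]
        # expected share 1/9; allow 4 sigma of Poisson error
        expect = total / 9
        assert abs(minority - expect) < 4 * np.sqrt(expect)


class TestLongitudinalStudy:
    def test_five_subjects_fourteen_days_gives_70_recordings(self):
        rng = np.random.default_rng(0)
        design = StudyDesign.random(rng, reference_noise_sd=0.0)
        assert len(design.subjects) == 5 and len(design.time_points) == 14
        scene = SceneConfig(frame_shape=(128, 160), cells_per_frame_mean=3)
        samples, refs = synthesize_longitudinal_study(
            design, blood_phenotypes(), scene, 2, np.random.default_rng(1))
        assert len(samples) == 70
        assert len(refs) == 5

    def test_zero_reference_noise_reproduces_realized_truth(self):
        rng = np.random.default_rng(3)
        design = StudyDesign.random(rng, subjects=["a"], time_points=[1, 2],
                                    reference_noise_sd=0.0)
        scene = SceneConfig(frame_shape=(160, 160), cells_per_frame_mean=6)
        samples, _ = synthesize_longitudinal_study(
            design, blood_phenotypes(), scene, 4, np.random.default_rng(4))
        for s in samples:
            assert np.array_equal(s.reference_composition,
                                  s.realized_composition)

    def test_seeded_compositions_are_reproducible(self):
        mk = lambda: synthesize_longitudinal_study(
            StudyDesign.random(np.random.default_rng(9), subjects=["a"],
                               time_points=[1, 2]),
            blood_phenotypes(),
            SceneConfig(frame_shape=(128, 128), cells_per_frame_mean=4),
            3, np.random.default_rng(10))[0]
        s1, s2 = mk(), mk()
        for a, b in zip(s1, s2):
            assert np.array_equal(a.frames, b.frames)
            assert np.array_equal(a.reference_composition,
                                  b.reference_composition)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(subjects=["a"], time_points=[2, 1],
                        class_names=["x", "y"],
                        compositions=np.full((1, 2, 2), 0.5))
        with pytest.raises(ValueError):
            StudyDesign(subjects=["a"], time_points=[1],
                        class_names=["x", "y"],
                        compositions=np.array([[[0.7, 0.2]]]))
        with pytest.raises(ValueError):
            StudyDesign(subjects=["a"], time_points=[1],
                        class_names=["x", "y"],
                        compositions=np.array([[[0.5, 0.5]]]),
                        reference_noise_sd=-0.1)


class TestStatisticalStructure:
    def test_realized_composition_converges_to_mixture(self, phenotypes):
        # multinomial law: at ~5000 cells the realized shares sit within 0.02
        scene = SceneConfig(frame_shape=(96, 128), cells_per_frame_mean=10,
                            noise_sd=0.0, forbid_overlap=False)
        rng = np.random.default_rng(21)
        mixture = np.array([0.5, 0.3, 0.2])
        counts = np.zeros(3)
        names = [p.class_name for p in phenotypes]
        for _ in range(500):
            _, truths = synthesize_frame(phenotypes, mixture, scene, rng)
            for t in truths:
                counts[names.index(t.class_name)] += 1
        realized = counts / counts.sum()
        assert np.abs(realized - mixture).max() < 0.02

    def test_phantoms_are_detectable_above_threshold(self):
        # every default phantom must expose >= 30 px above 0.8 rad so that the
        # downstream segmentation contract is exercisable
        rng = np.random.default_rng(17)
        for ph in blood_phenotypes() + milk_phenotypes():
            for _ in range(200):
                patch, mask, _ = render_cell(ph, rng)
                assert (patch > 0.8).sum() >= 30, ph.class_name

    def test_debris_phantoms_fall_below_area_filter(self):
        rng = np.random.default_rng(19)
        debris = milk_phenotypes(include_debris=True)[-1]
        for _ in range(100):
            patch, mask, _ = render_cell(debris, rng)
            assert (patch > 0.8).sum() < 30
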