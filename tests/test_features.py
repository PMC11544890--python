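"""Feature catalog: oracle equivalence, invariances, class separability.

The ten constructed patches use only exact binary-fraction phase values so
that histogram bin edges agree bit-for-bit between implementation and
oracle.
"""

import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import disc_mask, make_patch
from holodcc.features import (FEATURE_NAMES, build_feature_table,
                              compute_features, schema_fingerprint,
                              table_fingerprint)
from holodcc.preprocess import CellPatch, SegmentationParams

PA = 11.9

# features exactly determined by integer pixel counts
_EXACT = {"area_um2", "extent", "local_maxima_count", "max_phase", "min_phase",
          "phase_range"}


def _bar(h, w, size, values=None):
    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = (size - h) // 2, (size - w) // 2
    mask[r0:r0 + h, c0:c0 + w] = True
    v = np.zeros((size, size))
    v[mask] = 1.5 if values is None else values
    return v, mask


def _ten_patches():
    """(name, values, mask) constructions on 9x9 / 11x11 grids."""
    out = []
    # 1: uniform disc r=3 at 2.0
    m = disc_mask(3, 9)
    v = np.where(m, 2.0, 0.0)
    out.append(("disc3_uniform", v, m))
    # 2: uniform disc r=4 at 1.0
    m = disc_mask(4, 11)
    out.append(("disc4_uniform", np.where(m, 1.0, 0.0), m))
    # 3: two-level disc: 1.0 with r=2 core at 2.0
    m = disc_mask(4, 11)
    core = disc_mask(2, 11)
    v = np.where(m, 1.0, 0.0) + np.where(core, 1.0, 0.0)
    out.append(("disc4_twolevel", v, m))
    # 4: horizontal bar 3x7 uniform
    v, m = _bar(3, 7, 9)
    out.append(("hbar_uniform", v, m))
    # 5: vertical bar 7x3 with a ramp along its length (multiples of 1/8)
    m = np.zeros((9, 9), dtype=bool)
    m[1:8, 3:6] = True
    v = np.zeros((9, 9))
    for i, r in enumerate(range(1, 8)):
        v[r, 3:6] = 0.5 + i * 0.125
    out.append(("vbar_ramp", v, m))
    # 6: 5x5 square uniform 1.0
    v, m = _bar(5, 5, 9, values=1.0)
    out.append(("square_uniform", v, m))
    # 7: 5x5 square with a diagonal ramp
    m = np.zeros((9, 9), dtype=bool)
    m[2:7, 2:7] = True
    v = np.zeros((9, 9))
    for r in range(2, 7):
        for c in range(2, 7):
            v[r, c] = 1.0 + 0.25 * (r - 2) + 0.125 * (c - 2)
    out.append(("square_ramp", v, m))
    # 8: disc r=3 with an off-centre raised quadrant
    m = disc_mask(3, 9)
    v = np.where(m, 1.0, 0.0)
    v[2:4, 2:4] += 0.5 * m[2:4, 2:4]
    out.append(("disc3_bump", v, m))
    # 9: L-shaped (non-convex) uniform mask
    m = np.zeros((9, 9), dtype=bool)
    m[2:8, 2:4] = True
    m[6:8, 2:8] = True
    out.append(("L_uniform", np.where(m, 1.25, 0.0), m))
    # 10: diamond |x|+|y| <= 3 with deterministic binary-fraction texture
    yy, xx = np.mgrid[:9, :9]
    m = np.abs(yy - 4) + np.abs(xx - 4) <= 3
    rng = np.random.default_rng(99)
    v = np.where(m, 1.0 + np.round(rng.random((9, 9)) * 16) / 32.0, 0.0)
    out.append(("diamond_textured", v, m))
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("name,values,mask",
                             _ten_patches(),
                             ids=[p[0] for p in _ten_patches()])
    def test_all_24_features_match_brute_force(self, name, values, mask):
        params = SegmentationParams()
        got = compute_features(make_patch(values, mask), params)
        want = _oracles.oracle_features(values, mask, PA)
        assert set(got) == set(FEATURE_NAMES) == set(want)
        for feat in FEATURE_NAMES:
            if feat in _EXACT:
                assert got[feat] == want[feat], feat
            else:
                assert got[feat] == pytest.approx(want[feat], rel=1e-9,
                                                  abs=1e-9), feat

    def test_uniform_disc_closed_form_values(self):
        # disc r=5 at phase 2.0: 81 px, optical volume 81*2*11.9 = 1927.8
        m = disc_mask(5, 13)
        v = np.where(m, 2.0, 0.0)
        f = compute_features(make_patch(v, m), SegmentationParams())
        assert m.sum() == 81
        assert f["area_um2"] == pytest.approx(81 * PA)
        assert f["optical_volume"] == pytest.approx(1927.8)
        assert f["mean_phase"] == 2.0
        assert f["std_phase"] == 0.0
        assert f["phase_range"] == 0.0
        assert f["phase_entropy"] == 0.0
        assert f["eccentricity"] == pytest.approx(0.0, abs=1e-12)
        # flat top: the smoothed interior is an exact plateau, which by the
        # strict-maximum convention contains no local maximum
        assert f["local_maxima_count"] == 0.0

    def test_raised_cosine_bump_has_one_maximum(self):
        yy, xx = np.mgrid[:13, :13]
        r = np.sqrt((yy - 6.0) ** 2 + (xx - 6.0) ** 2)
        m = r <= 5.0
        v = np.where(m, 0.5 * (1 + np.cos(np.pi * np.minimum(r / 5.0, 1.0))) * 2.0, 0.0)
        f = compute_features(make_patch(v, m), SegmentationParams())
        assert f["local_maxima_count"] == 1.0


class TestInvariances:
    def _base(self):
        m = disc_mask(3, 9)
        v = np.where(m, 1.0, 0.0)
        v[3:5, 3:5] += 0.5 * m[3:5, 3:5]
        return v, m

    def test_translation_invariance_is_exact(self):
        v, m = self._base()
        params = SegmentationParams()
        a = compute_features(make_patch(v, m, size=96), params)
        big_v = np.zeros((96, 96)); big_m = np.zeros((96, 96), dtype=bool)
        big_v[30:39, 51:60] = v; big_m[30:39, 51:60] = m
        b = compute_features(CellPatch(values=big_v, mask=big_m), params)
        for feat in FEATURE_NAMES:
            assert a[feat] == b[feat], feat

    def test_rotation_by_90_degrees(self):
        v, m = self._base()
        params = SegmentationParams()
        a = compute_features(make_patch(v, m, size=32), params)
        b = compute_features(make_patch(np.rot90(v).copy(),
                                        np.rot90(m).copy(), size=32), params)
        for feat in FEATURE_NAMES:
            assert a[feat] == pytest.approx(b[feat], rel=1e-9, abs=1e-9), feat

    def test_phase_scaling_homogeneity(self):
        v, m = self._base()
        params = SegmentationParams()
        a = compute_features(make_patch(v, m, size=32), params)
        b = compute_features(make_patch(2 * v, m, size=32), params)
        doubled = {"mean_phase", "median_phase", "max_phase", "min_phase",
                   "phase_range", "std_phase", "optical_volume",
                   "mean_gradient_magnitude", "radial_contrast"}
        unchanged = {"area_um2", "equivalent_diameter_um", "perimeter_um",
                     "circularity", "eccentricity", "major_axis_um",
                     "minor_axis_um", "aspect_ratio", "solidity", "extent",
                     "phase_skewness", "phase_kurtosis", "phase_entropy",
                     "mass_displacement_um", "local_maxima_count"}
        for feat in doubled:
            assert b[feat] == pytest.approx(2 * a[feat], rel=1e-12), feat
        for feat in unchanged:
            assert b[feat] == pytest.approx(a[feat], rel=1e-9, abs=1e-12), feat

    def test_cross_check_moments_against_skimage(self):
        # independent route: regionprops on random blobs
        from skimage.measure import regionprops

        rng = np.random.default_rng(5)
        params = SegmentationParams(pixel_area_um2=1.0)
        for _ in range(20):
            m = np.zeros((24, 24), dtype=bool)
            r, c = rng.integers(6, 14, 2)
            h, w = rng.integers(4, 9, 2)
            m[r:r + h, c:c + w] = True
            m &= rng.random((24, 24)) < 0.9
            if m.sum() < 8:
                continue
            f = compute_features(make_patch(np.where(m, 1.0, 0.0), m, size=32),
                                 params)
            # regionprops needs the same single connected region; skip others
            props = regionprops(m.astype(np.uint8))
            if len(props) != 1:
                continue
            assert f["eccentricity"] == pytest.approx(props[0].eccentricity,
                                                      abs=1e-9)
            assert f["major_axis_um"] == pytest.approx(
                props[0].axis_major_length, abs=1e-9)
            assert f["extent"] == pytest.approx(props[0].extent, abs=1e-12)


class TestErrors:
    def test_empty_and_tiny_masks_raise(self, params):
        with pytest.raises(ValueError):
            compute_features(make_patch(np.zeros((9, 9)),
                                        np.zeros((9, 9), dtype=bool)), params)
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = m[4, 5] = True
        with pytest.raises(ValueError):
            compute_features(make_patch(np.ones((9, 9)), m), params)


class TestFeatureTable:
    def test_empty_table_keeps_full_schema(self, params):
        t = build_feature_table([], params, labels=[])
        assert list(t.columns[:24]) == FEATURE_NAMES
        assert "label" in t.columns and len(t) == 0

    def test_label_alignment_enforced(self, params):
        m = disc_mask(3, 9)
        p = make_patch(np.where(m, 1.0, 0.0), m)
        with pytest.raises(ValueError):
            build_feature_table([p, p], params, labels=["a"])

    def test_no_labels_no_label_column(self, params):
        m = disc_mask(3, 9)
        p = make_patch(np.where(m, 1.0, 0.0), m)
        t = build_feature_table([p, p], params)
        assert "label" not in t.columns and len(t) == 2

    def test_csv_export_is_byte_identical(self, tmp_path, params,
                                          small_patches):
        patches, _ = small_patches
        t1 = build_feature_table(patches[:40], params,
                                 labels=["x"] * 40)
        t2 = build_feature_table(patches[:40], params,
                                 labels=["x"] * 40)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t1.to_csv(f1, index=False)
        t2.to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_fingerprint_detects_schema_drift(self):
        assert schema_fingerprint() == schema_fingerprint(FEATURE_NAMES)
        assert schema_fingerprint(FEATURE_NAMES[:-1]) != schema_fingerprint()
        df = pd.DataFrame(columns=FEATURE_NAMES)
        assert table_fingerprint(df) == schema_fingerprint()


class TestClassSeparability:
    def test_default_phenotypes_separate_in_key_features(self, params,
                                                         phenotypes):
        # qualitative analogue of per-feature density plots: every class pair
        # is >= 1 pooled SD apart in at least one of area / optical volume /
        # phase contrast
        from holodcc.features import build_feature_table
        from holodcc.simulate import SceneConfig, synthesize_recording

        scene = SceneConfig(frame_shape=(256, 320), cells_per_frame_mean=6,
                            placement_margin=50, seed=1)
        rng = np.random.default_rng(31)
        tables = []
        for ph in phenotypes:
            rec = synthesize_recording([ph], [1.0], scene, 25, rng)
            patches, _ = __import__("holodcc").preprocess_recording(
                rec.frames, params)
            tables.append(build_feature_table(
                patches, params, labels=[ph.class_name] * len(patches)))
        tab = pd.concat(tables, ignore_index=True)
        feats = ["area_um2", "optical_volume", "std_phase"]
        classes = [ph.class_name for ph in phenotypes]
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                a = tab[tab["label"] == classes[i]]
                b = tab[tab["label"] == classes[j]]
                seps = []
                for f in feats:
                    pooled = np.sqrt((a[f].var() + b[f].var()) / 2)
                    seps.append(abs(a[f].mean() - b[f].mean()) / pooled)
                assert max(seps) >= 1.0, (classes[i], classes[j], seps)
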