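"""Feature formulas against hand-derived values and literal transcriptions."""

import dataclasses
import math

import numpy as np
import pytest

import radrank as rr
from oracles import (
    literal_first_order,
    literal_glcm_features,
    literal_ngtdm_features,
    literal_size_features,
    random_label_volume,
)


class TestRegistry:
    def test_partition_and_names(self):
        assert len(rr.FEATURE_REGISTRY) == 43
        from radrank.features import registry_class_counts

        assert registry_class_counts() == {
            "first-order": 3,
            "GLCM": 9,
            "GLRLM": 13,
            "GLSZM": 13,
            "NGTDM": 5,
        }
        assert len(set(rr.FEATURE_NAMES)) == 43
        assert "GLSZM SZE" in rr.FEATURE_NAMES
        assert "NGTDM Coarseness" in rr.FEATURE_NAMES


class TestFirstOrder:
    def test_textbook_population_variance(self):
        out = rr.first_order([2, 4, 4, 4, 5, 5, 7, 9])
        assert out["Variance"] == pytest.approx(4.0)

    def test_symmetric_input_zero_skewness(self):
        assert rr.first_order([1, 2, 3])["Skewness"] == pytest.approx(0.0)

    def test_constant_input_convention(self):
        assert rr.first_order([5, 5, 5]) == {
            "Variance": 0.0,
            "Skewness": 0.0,
            "Kurtosis": 0.0,
        }

    def test_matches_literal_moments(self, rng):
        x = rng.normal(10, 5, 200)
        got = rr.first_order(x)
        expect = literal_first_order(x)
        for k in got:
            assert got[k] == pytest.approx(expect[k], abs=1e-10)


class TestGLCMFeatures:
    def test_hand_example(self):
        p = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        out = rr.glcm_features(p)
        assert out["GLCM Contrast"] == pytest.approx(1 / 3)
        assert out["GLCM Dissimilarity"] == pytest.approx(1 / 3)
        assert out["GLCM Energy"] == pytest.approx(5 / 18)

    def test_single_entry_matrix(self):
        p = np.zeros((3, 3))
        p[0, 0] = 1.0
        out = rr.glcm_features(p)
        assert out["GLCM Energy"] == 1.0
        assert out["GLCM Contrast"] == 0.0
        assert out["GLCM Entropy"] == 0.0
        assert math.isnan(out["GLCM Correlation"])  # constant marginal

    def test_uniform_matrix_zero_correlation(self):
        p = np.full((2, 2), 0.25)
        assert rr.glcm_features(p)["GLCM Correlation"] == pytest.approx(0.0)

    def test_all_zero_matrix_gives_nan(self):
        out = rr.glcm_features(np.zeros((4, 4)))
        assert all(math.isnan(v) for v in out.values())


class TestRunZoneFeatures:
    def test_glrlm_hand_example(self):
        counts = np.zeros((2, 3), dtype=int)
        counts[0, 1] = 1  # level 1, length 2
        counts[1, 2] = 1  # level 2, length 3
        out = rr.glrlm_features(counts, n_voxels=5)
        assert out["GLRLM RP"] == pytest.approx(0.4)
        assert out["GLRLM SRE"] == pytest.approx(13 / 72)

    def test_all_unit_runs_limit(self):
        counts = np.array([[3], [2]])
        out = rr.glrlm_features(counts, n_voxels=5)
        assert out["GLRLM SRE"] == 1.0
        assert out["GLRLM LRE"] == 1.0
        assert out["GLRLM RP"] == 1.0

    def test_single_run_zero_variances(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[1, 3] = 1
        out = rr.glrlm_features(counts, n_voxels=4)
        assert out["GLRLM GLV"] == 0.0
        assert out["GLRLM RLV"] == 0.0

    def test_glszm_hand_example(self):
        counts = np.zeros((3, 2), dtype=int)
        counts[0, 1] = 1  # level 1 zone of size 2
        counts[1, 0] = 1
        counts[2, 0] = 1
        out = rr.glszm_features(counts, n_voxels=4)
        assert out["GLSZM ZP"] == pytest.approx(0.75)
        assert out["GLSZM SZE"] == pytest.approx(0.75)

    def test_single_zone_covering_roi(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 7] = 1
        out = rr.glszm_features(counts, n_voxels=8)
        assert out["GLSZM ZP"] == pytest.approx(1 / 8)
        assert out["GLSZM ZSV"] == 0.0

    def test_empty_matrix_gives_nan(self):
        out = rr.glrlm_features(np.zeros((2, 2), dtype=int), n_voxels=4)
        assert all(math.isnan(v) for v in out.values())


class TestNGTDMFeatures:
    def test_constant_roi_coarseness_capped(self):
        out = rr.ngtdm_features([10], [1.0], [0.0])
        assert out["NGTDM Coarseness"] == 1.0e6
        assert math.isnan(out["NGTDM Contrast"])  # single occupied level
        assert math.isnan(out["NGTDM Busyness"])

    def test_two_level_hand_example(self):
        out = rr.ngtdm_features([5, 5], [0.5, 0.5], [2.0, 1.0])
        assert out["NGTDM Coarseness"] == pytest.approx(2 / 3)

    def test_coarseness_scales_inversely_with_s(self):
        a = rr.ngtdm_features([5, 5], [0.5, 0.5], [2.0, 1.0])
        b = rr.ngtdm_features([5, 5], [0.5, 0.5], [6.0, 3.0])
        assert b["NGTDM Coarseness"] == pytest.approx(a["NGTDM Coarseness"] / 3)


class TestLiteralTranscriptionOracle:
    """Every feature must match its literal defining formula on random ROIs."""

    def test_all_43_match_on_random_rois(self, rng):
        for _ in range(25):
            vol = random_label_volume(rng, ng=4)
            n_vox = int((vol > 0).sum())
            intensities = rng.normal(50, 40, n_vox)

            got = {}
            got.update(rr.first_order(intensities))
            got.update(rr.glcm_features(rr.build_glcm(vol, 4, "merged")))
            got.update(
                rr.glrlm_features(rr.build_glrlm(vol, 4, "merged"), n_vox,
                                  n_directions=13)
            )
            got.update(rr.glszm_features(rr.build_glszm(vol, 4), n_vox))
            got.update(rr.ngtdm_features(*rr.build_ngtdm(vol, 4)))

            expect = {}
            expect.update(literal_first_order(intensities))
            expect.update(literal_glcm_features(rr.build_glcm(vol, 4, "merged")))
            expect.update(
                literal_size_features(
                    rr.build_glrlm(vol, 4, "merged"), 13 * n_vox,
                    [f"GLRLM {s}" for s in
                     ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                      "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")]
                )
            )
            expect.update(
                literal_size_features(
                    rr.build_glszm(vol, 4), n_vox,
                    [f"GLSZM {s}" for s in
                     ("SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
                      "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV")]
                )
            )
            expect.update(literal_ngtdm_features(*rr.build_ngtdm(vol, 4)))

            assert set(got) == set(rr.FEATURE_NAMES)
            for name in rr.FEATURE_NAMES:
                g, e = got[name], expect[name]
                if math.isnan(e):
                    assert math.isnan(g), name
                else:
                    assert g == pytest.approx(e, abs=1e-10, rel=1e-10), name


class TestEndToEndExtraction:
    def test_output_has_exactly_43_keys(self, demo_scan):
        vol, mask = demo_scan
        fv = rr.extract_feature_vector(vol, mask, rr.QuantizationSpec())
        assert tuple(fv.values.keys()) == rr.FEATURE_NAMES

    def test_deterministic(self, demo_scan):
        vol, mask = demo_scan
        spec = rr.QuantizationSpec(method=rr.IUQ)
        a = rr.extract_feature_vector(vol, mask, spec)
        b = rr.extract_feature_vector(vol, mask, spec)
        assert a.values == b.values

    def test_dialects_agree_on_constant_roi(self):
        vol = rr.ImageVolume(data=np.full((6, 6, 6), 50.0))
        mask = rr.ROIMask(data=np.ones((6, 6, 6)))
        spec = rr.QuantizationSpec(method=rr.IUQ, levels=8)
        merged = rr.extract_feature_vector(vol, mask, spec, dialect="merged")
        averaged = rr.extract_feature_vector(vol, mask, spec, dialect="averaged")
        from radrank.features import GLCM_NAMES

        for name in GLCM_NAMES:
            a, b = merged.values[name], averaged.values[name]
            assert (math.isnan(a) and math.isnan(b)) or a == b

    def test_dialects_differ_on_textured_roi(self, demo_scan):
        vol, mask = demo_scan
        spec = rr.QuantizationSpec(levels=32)
        merged = rr.extract_feature_vector(vol, mask, spec, dialect="merged")
        averaged = rr.extract_feature_vector(vol, mask, spec, dialect="averaged")
        diffs = [
            name
            for name in rr.FEATURE_NAMES
            if not np.isclose(merged.values[name], averaged.values[name],
                              equal_nan=True)
        ]
        assert diffs  # the aggregation dialect is a real degree of freedom

    def test_iuq_affine_invariance_end_to_end(self, demo_scan):
        vol, mask = demo_scan
        spec = rr.QuantizationSpec(
            method=rr.IUQ, levels=64, threshold=rr.ThresholdWindow(enabled=False)
        )
        base = rr.extract_feature_vector(vol, mask, spec)
        transformed = rr.ImageVolume(
            data=2.0 * vol.data + 100.0, spacing=vol.spacing
        )
        other = rr.extract_feature_vector(transformed, mask, spec)
        for name in rr.FEATURE_NAMES[3:]:  # the 40 matrix-based features
            assert base.values[name] == other.values[name], name
        assert other.values["Variance"] == pytest.approx(4 * base.values["Variance"])
        assert other.values["Skewness"] == pytest.approx(base.values["Skewness"])
        assert other.values["Kurtosis"] == pytest.approx(base.values["Kurtosis"])
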