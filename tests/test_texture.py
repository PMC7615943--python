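"""Texture matrix builders against hand examples and brute-force enumeration."""

import numpy as np
import pytest

import radrank as rr
from oracles import (
    naive_glcm_counts,
    naive_glrlm_counts,
    naive_glszm_counts,
    naive_ngtdm,
    random_label_volume,
)
from radrank.texture import glcm_direction_counts, glrlm_direction_counts


def _line_volume(labels):
    """A 1D ROI laid out along x."""
    arr = np.zeros((len(labels), 1, 1), dtype=np.int64)
    arr[:, 0, 0] = labels
    return arr


class TestDirections:
    def test_thirteen_unique_offsets_no_negations(self):
        offs = rr.direction_offsets()
        assert offs.shape == (13, 3)
        as_set = {tuple(o) for o in offs}
        assert len(as_set) == 13
        assert not any(tuple(-o) in as_set for o in offs)
        assert all(set(o) <= {-1, 0, 1} for o in offs)


class TestGLCM:
    def test_hand_example_1d(self):
        vol = _line_volume([1, 1, 2, 2])
        counts = glcm_direction_counts(vol, ng=2)
        merged = counts.sum(axis=0)
        np.testing.assert_array_equal(merged, [[2, 1], [1, 2]])
        glcm = rr.build_glcm(vol, ng=2, dialect="merged")
        np.testing.assert_allclose(
            glcm, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]], atol=1e-15
        )

    def test_constant_roi_single_entry(self):
        vol = np.ones((3, 3, 3), dtype=np.int64)
        glcm = rr.build_glcm(vol, ng=2, dialect="merged")
        assert glcm[0, 0] == pytest.approx(1.0)
        assert glcm.sum() == pytest.approx(1.0)

    def test_single_voxel_roi_flagged_zero(self):
        vol = np.zeros((3, 3, 3), dtype=np.int64)
        vol[1, 1, 1] = 1
        assert rr.build_glcm(vol, ng=2, dialect="merged").sum() == 0.0
        assert len(rr.build_glcm(vol, ng=2, dialect="averaged")) == 0

    def test_matches_bruteforce_per_direction(self, rng):
        for _ in range(10):
            vol = random_label_volume(rng)
            np.testing.assert_array_equal(
                glcm_direction_counts(vol, ng=4), naive_glcm_counts(vol, ng=4)
            )

    def test_merged_equals_normalized_sum_of_directions(self, rng):
        vol = random_label_volume(rng)
        per_dir = naive_glcm_counts(vol, ng=4)
        total = per_dir.sum(axis=0)
        np.testing.assert_allclose(
            rr.build_glcm(vol, ng=4, dialect="merged"),
            total / total.sum(),
            atol=1e-15,
        )

    def test_label_reversal_symmetry(self, rng):
        ng = 4
        vol = random_label_volume(rng, ng=ng)
        rev = np.where(vol > 0, ng + 1 - vol, 0)
        a = rr.build_glcm(vol, ng=ng, dialect="merged")
        b = rr.build_glcm(rev, ng=ng, dialect="merged")
        np.testing.assert_allclose(b, a[::-1, ::-1], atol=1e-15)

    def test_mask_shrinkage_never_adds_pairs(self, rng):
        vol = random_label_volume(rng)
        shrunk = vol.copy()
        occupied = np.argwhere(shrunk > 0)
        shrunk[tuple(occupied[0])] = 0
        n_full = naive_glcm_counts(vol, ng=4).sum()
        n_less = naive_glcm_counts(shrunk, ng=4).sum()
        assert n_less <= n_full


class TestGLRLM:
    def test_hand_example_runs(self):
        vol = _line_volume([1, 1, 2, 2, 2])
        mats = glrlm_direction_counts(vol, ng=2)
        x_dir = [tuple(d) for d in rr.direction_offsets()].index((1, 0, 0))
        mat = mats[x_dir]
        assert mat[0, 1] == 1  # level 1, length 2
        assert mat[1, 2] == 1  # level 2, length 3
        assert mat.sum() == 2

    def test_constant_line_single_run(self):
        vol = _line_volume([1] * 6)
        x_dir = [tuple(d) for d in rr.direction_offsets()].index((1, 0, 0))
        mat = glrlm_direction_counts(vol, ng=1)[x_dir]
        assert mat[0, 5] == 1 and mat.sum() == 1

    def test_out_of_mask_breaks_runs(self):
        vol = _line_volume([1, 1, 0, 1, 1])
        x_dir = [tuple(d) for d in rr.direction_offsets()].index((1, 0, 0))
        mat = glrlm_direction_counts(vol, ng=1)[x_dir]
        assert mat[0, 1] == 2  # two separate runs of length 2

    def test_run_lengths_partition_voxels_each_direction(self, rng):
        vol = random_label_volume(rng)
        n_vox = int((vol > 0).sum())
        for mat in glrlm_direction_counts(vol, ng=4):
            lengths = np.arange(1, mat.shape[1] + 1)
            assert (mat * lengths).sum() == n_vox

    def test_matches_bruteforce_per_direction(self, rng):
        for _ in range(10):
            vol = random_label_volume(rng)
            got = glrlm_direction_counts(vol, ng=4)
            expect = naive_glrlm_counts(vol, ng=4)
            for g, e in zip(got, expect):
                r = max(g.shape[1], e.shape[1])
                gp = np.zeros((4, r), dtype=np.int64)
                ep = np.zeros((4, r), dtype=np.int64)
                gp[:, : g.shape[1]] = g
                ep[:, : e.shape[1]] = e
                np.testing.assert_array_equal(gp, ep)


class TestGLSZM:
    def test_hand_example_zones(self):
        vol = np.zeros((2, 2, 1), dtype=np.int64)
        vol[:, :, 0] = [[1, 1], [2, 3]]
        mat = rr.build_glszm(vol, ng=3)
        assert mat[0, 1] == 1  # one zone of level 1, size 2
        assert mat[1, 0] == 1 and mat[2, 0] == 1

    def test_constant_roi_single_zone(self):
        vol = np.ones((3, 3, 3), dtype=np.int64)
        mat = rr.build_glszm(vol, ng=1)
        assert mat[0, 26] == 1 and mat.sum() == 1

    def test_zone_sizes_partition_voxels(self, rng):
        vol = random_label_volume(rng)
        mat = rr.build_glszm(vol, ng=4)
        sizes = np.arange(1, mat.shape[1] + 1)
        assert (mat * sizes).sum() == (vol > 0).sum()

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            vol = random_label_volume(rng)
            got = rr.build_glszm(vol, ng=4)
            expect = naive_glszm_counts(vol, ng=4)
            z = max(got.shape[1], expect.shape[1])
            gp = np.zeros((4, z), dtype=np.int64)
            ep = np.zeros((4, z), dtype=np.int64)
            gp[:, : got.shape[1]] = got
            ep[:, : expect.shape[1]] = expect
            np.testing.assert_array_equal(gp, ep)


class TestNGTDM:
    def test_hand_example(self):
        vol = _line_volume([1, 2, 1])
        n, p, s = rr.build_ngtdm(vol, ng=2)
        np.testing.assert_array_equal(n, [2, 1])
        assert s[1] == pytest.approx(1.0)  # center: |2 - mean(1,1)|
        assert s[0] == pytest.approx(2.0)  # ends: |1 - 2| each

    def test_isolated_voxel_contributes_nothing(self):
        # a lone in-mask voxel has no in-mask neighbor: all components stay zero
        vol = np.zeros((3, 3, 3), dtype=np.int64)
        vol[1, 1, 1] = 1
        n, p, s = rr.build_ngtdm(vol, ng=1)
        assert n.sum() == 0 and p.sum() == 0 and s.sum() == 0

    def test_constant_roi_zero_deviation(self):
        vol = np.ones((3, 3, 3), dtype=np.int64)
        n, p, s = rr.build_ngtdm(vol, ng=2)
        assert n[0] == 27 and p[0] == 1.0
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            vol = random_label_volume(rng)
            n, p, s = rr.build_ngtdm(vol, ng=4)
            en, ep, es = naive_ngtdm(vol, ng=4)
            np.testing.assert_array_equal(n, en)
            np.testing.assert_allclose(p, ep, atol=1e-12)
            np.testing.assert_allclose(s, es, atol=1e-10)
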