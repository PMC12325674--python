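"""Metric oracles: Dice, surface extraction, HD95, aggregation, NoC/PoF."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from clickseg.evaluation import (
    MetricRecord,
    aggregate,
    dsc,
    extract_surface,
    hd95,
    noc,
    noc_mean,
    pof,
    NoCResult,
)
from clickseg.volumes import BinaryMask

from conftest import random_mask


def brute_force_surface(mask: BinaryMask) -> np.ndarray:
    """Oracle: neighbor check over all voxels, outside counts as background."""
    m = mask.data.astype(bool)
    out = []
    for v in np.argwhere(m):
        i, j, k = v
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1] and 0 <= nk < m.shape[2]):
                out.append(v)
                break
            if not m[ni, nj, nk]:
                out.append(v)
                break
    return np.array(out, dtype=np.int64).reshape(-1, 3)


def brute_force_hd95(G: BinaryMask, S: BinaryMask) -> float:
    """Oracle: all-pairs distances between the two surfaces."""
    sg = brute_force_surface(G).astype(float)
    ss = brute_force_surface(S).astype(float)
    d = cdist(sg, ss)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def _cube(lo, size, shape=(16, 16, 16)):
    m = np.zeros(shape, dtype=np.uint8)
    m[lo[0] : lo[0] + size, lo[1] : lo[1] + size, lo[2] : lo[2] + size] = 1
    return BinaryMask(m)


class TestDice:
    def test_identical_masks_score_one(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        assert dsc(_cube((0, 0, 0), 3), _cube((8, 8, 8), 3)) == 0.0

    def test_partial_overlap_hand_value(self):
        G = BinaryMask(np.pad(np.ones((1, 1, 4), np.uint8), ((0, 15), (0, 15), (0, 12))))
        S = BinaryMask(np.pad(np.ones((1, 1, 2), np.uint8), ((0, 15), (0, 15), (0, 14))))
        # |G|=4, |S|=2, |overlap|=2 -> 2*2/(4+2)
        assert dsc(G, S) == pytest.approx(2.0 / 3.0)

    def test_both_empty_is_perfect_agreement(self):
        e = BinaryMask(np.zeros((8, 8, 8), np.uint8))
        assert dsc(e, e) == 1.0

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dsc(a, b) == dsc(b, a)


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        s = extract_surface(_cube((5, 5, 5), 1))
        np.testing.assert_array_equal(s, [[5, 5, 5]])

    def test_cube_surface_is_all_but_center(self):
        s = extract_surface(_cube((6, 6, 6), 3))
        assert len(s) == 26
        assert [7, 7, 7] not in s.tolist()

    def test_empty_mask_has_empty_surface(self):
        assert len(extract_surface(BinaryMask(np.zeros((8, 8, 8), np.uint8)))) == 0

    def test_volume_edge_voxels_count_as_surface(self):
        m = np.ones((8, 8, 8), dtype=np.uint8)
        s = extract_surface(BinaryMask(m))
        oracle = brute_force_surface(BinaryMask(m))
        assert {tuple(v) for v in s} == {tuple(v) for v in oracle}

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            m = random_mask(rng)
            got = {tuple(v) for v in extract_surface(m)}
            want = {tuple(v) for v in brute_force_surface(m)}
            assert got == want


class TestHD95:
    def test_identical_masks_have_zero_distance(self, rng):
        m = random_mask(rng)
        assert hd95(m, m) == 0.0

    def test_two_voxels_five_apart(self):
        assert hd95(_cube((2, 8, 8), 1), _cube((7, 8, 8), 1)) == pytest.approx(5.0)

    def test_shifted_cube_matches_brute_force(self):
        G = _cube((5, 5, 5), 3)
        S = _cube((6, 5, 5), 3)
        assert hd95(G, S) == pytest.approx(brute_force_hd95(G, S), abs=1e-12)

    def test_random_pairs_match_brute_force(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert hd95(a, b) == hd95(b, a)

    def test_empty_cases(self):
        e = BinaryMask(np.zeros((8, 8, 8), np.uint8))
        m = _cube((2, 2, 2), 2, (8, 8, 8))
        assert hd95(e, e) == 0.0
        assert math.isinf(hd95(m, e))
        assert math.isinf(hd95(e, m))


class TestAggregate:
    def test_hd95_median_iqr_hand_values(self):
        recs = [MetricRecord(0.9, v) for v in (1.0, 2.0, 3.0, 4.0)]
        agg = aggregate(recs)
        assert agg["hd95_median"] == pytest.approx(2.5)
        assert agg["hd95_iqr"] == pytest.approx(1.5)

    def test_single_record(self):
        agg = aggregate([MetricRecord(0.8, 3.0)])
        assert agg["hd95_median"] == 3.0 and agg["hd95_iqr"] == 0.0

    def test_dsc_mean(self):
        agg = aggregate([MetricRecord(0.5, 1.0), MetricRecord(0.7, 1.0)])
        assert agg["dsc_mean"] == pytest.approx(0.6)

    def test_infinite_hd95_excluded_and_counted(self):
        agg = aggregate([MetricRecord(0.5, 1.0), MetricRecord(0.0, math.inf)])
        assert agg["hd95_median"] == 1.0 and agg["hd95_n_inf"] == 1

    def test_permutation_invariance(self, rng):
        recs = [MetricRecord(rng.random(), rng.random() * 10) for _ in range(9)]
        perm = [recs[i] for i in rng.permutation(9)]
        a, b = aggregate(recs), aggregate(perm)
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12), k


class TestNoCPoF:
    def test_threshold_already_met_at_zero_clicks(self):
        assert noc([0.8, 0.9], 0.75, "ge").clicks == 0

    def test_first_crossing(self):
        seq = [0.5, 0.6, 0.7, 0.76, 0.8] + [0.8] * 16
        assert noc(seq, 0.75, "ge").clicks == 3

    def test_hd95_direction_is_strictly_below(self):
        seq = [6.0, 5.0, 4.9] + [4.9] * 18
        assert noc(seq, 5.0, "lt").clicks == 2  # 5.0 itself does not count

    def test_never_crossing_is_a_failure(self):
        res = noc([0.5] * 21, 0.75, "ge")
        assert res.failed and res.clicks is None

    def test_short_converged_sequence_carries_forward(self):
        assert noc([0.5, 0.9], 0.85, "ge").clicks == 1
        assert noc([0.5], 0.85, "ge").failed

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            noc([0.5], 0.75, "up")

    def test_noc_non_increasing_under_pointwise_improvement(self, rng):
        seq = np.sort(rng.random(21)).tolist()
        better = [min(1.0, v + 0.05) for v in seq]
        a, b = noc(seq, 0.75, "ge"), noc(better, 0.75, "ge")
        if not a.failed:
            assert not b.failed and b.clicks <= a.clicks

    @pytest.mark.parametrize(
        "failures,total,expected",
        [(0, 10, 0.0), (1, 4, 25.0), (7, 67, 100.0 * 7 / 67)],
    )
    def test_pof_formula(self, failures, total, expected):
        results = [NoCResult(None, True)] * failures + [
            NoCResult(2, False)
        ] * (total - failures)
        assert pof(results) == pytest.approx(expected)

    def test_noc_mean_excludes_failures_by_default(self):
        res = [NoCResult(2, False), NoCResult(4, False), NoCResult(None, True)]
        assert noc_mean(res) == 3.0
        assert noc_mean(res, include_failed=True) == pytest.approx((2 + 4 + 20) / 3)
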