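import math

import numpy as np
import pytest

from vigan.metrics import (
    confusion_counts,
    evaluate_pair,
    overlap_metrics,
    psnr,
    quantile_threshold,
    ssim_volume,
    threshold_sweep,
    uqi,
    vsi,
)
from vigan.volume_io import Volume


def vol(values, shape=(2, 2, 1)):
    return Volume(np.asarray(values, dtype=float).reshape(shape))


V4 = vol([0.8, 0.2, 0.6, 0.1])
VHAT4 = vol([0.7, 0.1, 0.2, 0.9])


class TestConfusion:
    def test_hand_enumeration(self):
        c = confusion_counts(V4, VHAT4, 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (0.25, 0.25, 0.25, 0.25)

    def test_identity_no_errors(self, random_volume):
        c = confusion_counts(random_volume, random_volume, 0.5)
        assert c.fp == 0.0 and c.fn == 0.0

    def test_partition_to_one(self, rng):
        for _ in range(100):
            a = Volume(rng.random((4, 4, 4)))
            b = Volume(rng.random((4, 4, 4)))
            c = confusion_counts(a, b, float(rng.random()))
            assert c.tp + c.fp + c.fn + c.tn == pytest.approx(1.0, abs=1e-12)

    def test_oracle_double_loop(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(1, 5, size=3))
            a, b = Volume(rng.random(shape)), Volume(rng.random(shape))
            t = float(rng.random())
            tp = fp = fn = tn = 0
            for x in range(shape[0]):
                for y in range(shape[1]):
                    for z in range(shape[2]):
                        pa = a.data[x, y, z] > t
                        pb = b.data[x, y, z] > t
                        tp += pa and pb
                        fp += (not pa) and pb
                        fn += pa and (not pb)
                        tn += (not pa) and (not pb)
            n = a.n_voxels
            c = confusion_counts(a, b, t)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp / n, fp / n, fn / n, tn / n)

    def test_as_printed_fn_duplicates_tn(self):
        c = confusion_counts(V4, VHAT4, 0.5, convention="as_printed")
        assert c.fn == c.tn

    def test_strict_inequality_at_threshold(self):
        v = vol([0.5, 0.5, 0.5, 0.5])
        c = confusion_counts(v, v, 0.5)
        assert c.tp == 0.0 and c.tn == 1.0


class TestOverlapMetrics:
    def test_formula_evaluation(self):
        c = confusion_counts(V4, VHAT4, 0.5)  # tp=fp=fn=0.25
        iou, dice, f1, precision, recall = overlap_metrics(c)
        assert iou == pytest.approx(1 / 3)
        assert dice == pytest.approx(0.5)
        assert f1 == pytest.approx(0.5)
        assert precision == pytest.approx(0.5)
        assert recall == pytest.approx(0.5)

    def test_perfect_prediction(self, random_volume):
        vals = overlap_metrics(confusion_counts(random_volume, random_volume, 0.5))
        assert vals == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_dice_iou_identity_and_f1(self, rng):
        for _ in range(100):
            a, b = Volume(rng.random((4, 4, 4))), Volume(rng.random((4, 4, 4)))
            iou, dice, f1, _, _ = overlap_metrics(
                confusion_counts(a, b, float(rng.random()))
            )
            assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-9)
            assert f1 == pytest.approx(dice, abs=1e-9)

    def test_rejects_as_printed(self):
        c = confusion_counts(V4, VHAT4, 0.5, convention="as_printed")
        with pytest.raises(ValueError, match="standard convention"):
            overlap_metrics(c)


class TestQuantileThreshold:
    def test_uniform_spacing(self):
        v = Volume(np.linspace(0, 1, 64).reshape(4, 4, 4))
        assert quantile_threshold(v, 0.75) == pytest.approx(0.75, abs=0.02)

    def test_constant_volume(self):
        v = Volume(np.full((4, 4, 4), 0.3))
        for q in (0.1, 0.5, 0.9):
            assert quantile_threshold(v, q) == 0.3

    def test_monotone_in_q(self, random_volume):
        qs = np.linspace(0.05, 0.95, 10)
        ts = [quantile_threshold(random_volume, q) for q in qs]
        assert all(t2 >= t1 for t1, t2 in zip(ts, ts[1:]))

    def test_domain_errors(self, random_volume):
        for q in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError, match="quantile"):
                quantile_threshold(random_volume, q)


class TestPSNR:
    def test_closed_forms(self):
        a = Volume(np.zeros((10, 10, 1)))
        b = Volume(np.full((10, 10, 1), 0.1))  # MSE 0.01
        assert psnr(a, b) == pytest.approx(20.0)
        c = Volume(np.ones((10, 10, 1)))  # MSE 1.0
        assert psnr(a, c) == pytest.approx(0.0)

    def test_identity_infinity(self, random_volume):
        assert math.isinf(psnr(random_volume, random_volume))


class TestSliceSimilarity:
    def test_self_similarity_ones(self, vertebra16):
        t = vertebra16.truth
        assert uqi(t, t) == pytest.approx(1.0, abs=1e-9)
        assert vsi(t, t) == pytest.approx(1.0, abs=1e-9)
        assert ssim_volume(t, t) == pytest.approx(1.0, abs=1e-7)

    def test_identical_constants(self):
        c = Volume(np.full((16, 16, 2), 0.4))
        assert uqi(c, c) == 1.0
        assert vsi(c, c) == pytest.approx(1.0)

    def test_uqi_degrades_with_noise(self, rng, vertebra16):
        t = vertebra16.truth
        tiny = Volume(np.clip(t.data + rng.normal(0, 0.005, t.shape), 0, 1))
        heavy = Volume(rng.random(t.shape))
        assert uqi(t, heavy) < uqi(t, tiny)

    def test_vsi_penalizes_distortion(self, rng, vertebra16):
        t = vertebra16.truth
        noisy = Volume(np.clip(t.data + rng.normal(0, 0.2, t.shape), 0, 1))
        assert vsi(t, noisy) < 1.0


class TestEvaluatePair:
    def test_identity_report(self, vertebra16):
        r = evaluate_pair(vertebra16.truth, vertebra16.truth)
        assert r.iou == r.dice == r.f1 == 1.0
        assert r.l1 == 0.0
        assert math.isinf(r.psnr)
        assert r.ssim == pytest.approx(1.0, abs=1e-7)
        assert r.uqi == pytest.approx(1.0, abs=1e-9)

    def test_dice_iou_consistency(self, rng):
        a = Volume(rng.random((12, 12, 12)))
        b = Volume(rng.random((12, 12, 12)))
        r = evaluate_pair(a, b, compute_vsi=False)
        assert r.dice == pytest.approx(2 * r.iou / (1 + r.iou), abs=1e-9)

    def test_thresholds_from_ground_truth_only(self, rng, vertebra16):
        other = Volume(rng.random(vertebra16.truth.shape))
        r = evaluate_pair(vertebra16.truth, other, compute_vsi=False)
        assert r.thresholds["Q1"] == quantile_threshold(vertebra16.truth, 0.25)
        assert r.thresholds["Q3"] == quantile_threshold(vertebra16.truth, 0.75)

    def test_complement_at_median_empty_intersection(self):
        # symmetric values, no voxel exactly at the median
        v = Volume(np.linspace(0, 1, 64).reshape(4, 4, 4))
        comp = Volume(1.0 - v.data)
        r = evaluate_pair(v, comp, metric_threshold_q=0.5, compute_vsi=False)
        assert r.iou == 0.0


class TestThresholdSweep:
    def test_default_quantile_grid(self, vertebra16):
        rows = threshold_sweep(vertebra16.truth, vertebra16.truth)
        assert [r["quantile"] for r in rows] == [0.25, 0.375, 0.5, 0.625, 0.75]
        assert all(r["iou"] == 1.0 for r in rows)

    def test_thresholds_monotone(self, vertebra16, rng):
        other = Volume(rng.random(vertebra16.truth.shape))
        rows = threshold_sweep(vertebra16.truth, other)
        ts = [r["threshold"] for r in rows]
        assert ts == sorted(ts)

    def test_too_few_points(self, vertebra16):
        with pytest.raises(ValueError, match="n >= 2"):
            threshold_sweep(vertebra16.truth, vertebra16.truth, n=1)
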