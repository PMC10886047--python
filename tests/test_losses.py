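import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from vigan.losses import (
    LossConfig,
    discriminator_loss,
    distance_loss,
    feature_loss,
    gaussian_window,
    generator_adversarial_loss,
    reconstruction_loss,
    similarity_loss,
    soft_feature_loss,
    ssim_2d,
)
from vigan.volume_io import Volume

C1 = 0.01**2


def vol(values, shape=(2, 2, 1)):
    return Volume(np.asarray(values, dtype=float).reshape(shape))


V4 = vol([0.8, 0.2, 0.6, 0.1])
VHAT4 = vol([0.7, 0.1, 0.2, 0.9])


class TestDistance:
    def test_identity(self, random_volume):
        assert distance_loss(random_volume, random_volume) == 0.0

    def test_maximal(self):
        ones = Volume(np.ones((3, 3, 3)))
        zeros = Volume(np.zeros((3, 3, 3)))
        assert distance_loss(ones, zeros) == 1.0

    def test_hand_enumeration(self):
        # (0.1 + 0.1 + 0.4 + 0.8) / 4
        assert distance_loss(V4, VHAT4) == pytest.approx(0.35)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = Volume(rng.random((4, 4, 4)))
            b = Volume(rng.random((4, 4, 4)))
            d = distance_loss(a, b)
            assert d == distance_loss(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch(self, random_volume):
        with pytest.raises(ValueError, match="shapes differ"):
            distance_loss(random_volume, Volume(np.zeros((4, 4, 4))))


class TestFeature:
    def test_self_overlap_zero(self, random_volume):
        cfg = LossConfig(thresholds=(0.2, 0.5))
        assert random_volume.data.max() >= 0.5
        assert feature_loss(random_volume, random_volume, cfg) == 0.0

    def test_disjoint_full_union(self):
        ones = Volume(np.ones((3, 3, 3)))
        zeros = Volume(np.zeros((3, 3, 3)))
        assert feature_loss(ones, zeros, LossConfig(thresholds=(0.5,))) == 1.0

    def test_hand_enumeration(self):
        # t=0.5: intersection {m0}, union {m0, m2, m3} -> 1 - 1/3
        got = feature_loss(V4, VHAT4, LossConfig(thresholds=(0.5,)))
        assert got == pytest.approx(1 - 1 / 3)

    def test_empty_union_counts_as_agreement(self):
        low = Volume(np.full((3, 3, 3), 0.1))
        assert feature_loss(low, low, LossConfig(thresholds=(0.9,))) == 0.0

    def test_oracle_double_loop(self, rng):
        """Exact agreement with per-voxel enumeration on tiny volumes."""
        cfg = LossConfig(thresholds=(0.25, 0.5, 0.75))
        for _ in range(50):
            shape = tuple(rng.integers(1, 5, size=3))
            a = Volume(rng.random(shape))
            b = Volume(rng.random(shape))
            total = 0.0
            for t in cfg.thresholds:
                inter = union = 0
                for x in range(shape[0]):
                    for y in range(shape[1]):
                        for z in range(shape[2]):
                            pa = a.data[x, y, z] >= t
                            pb = b.data[x, y, z] >= t
                            inter += pa and pb
                            union += pa or pb
                total += 1.0 if union == 0 else inter / union
            expected = 1.0 - total / len(cfg.thresholds)
            assert feature_loss(a, b, cfg) == expected

    def test_symmetry_and_range(self, rng):
        cfg = LossConfig()
        for _ in range(20):
            a = Volume(rng.random((4, 4, 4)))
            b = Volume(rng.random((4, 4, 4)))
            f = feature_loss(a, b, cfg)
            assert f == feature_loss(b, a, cfg)
            assert 0.0 <= f <= 1.0

    def test_unnormalized_formulation(self):
        cfg = LossConfig(thresholds=(0.25, 0.5), normalize_feature_by_nr=False)
        v = Volume(np.full((2, 2, 2), 0.6))
        # both thresholds give overlap 1 -> 1 - 2 = -1 (can leave [0, 1])
        assert feature_loss(v, v, cfg) == -1.0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError, match="increasing"):
            LossConfig(thresholds=(0.5, 0.5)).validate()
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            LossConfig(thresholds=(-0.1,)).validate()


class TestSoftFeature:
    def test_converges_to_hard_loss(self, rng):
        cfg_base = LossConfig()
        gaps = {}
        pairs = [
            (Volume(rng.random((4, 4, 4))), Volume(rng.random((4, 4, 4))))
            for _ in range(20)
        ]
        for tau in (10.0, 50.0, 250.0):
            cfg = LossConfig(tau=tau)
            gaps[tau] = max(
                abs(soft_feature_loss(a, b, cfg) - feature_loss(a, b, cfg_base))
                for a, b in pairs
            )
        assert gaps[250.0] < gaps[50.0] < gaps[10.0]


class TestSSIM:
    def test_self_identity(self, rng):
        img = rng.random((16, 16))
        assert ssim_2d(img, img) == pytest.approx(1.0, abs=1e-7)

    def test_identical_constants(self):
        c = np.full((16, 16), 0.5)
        assert ssim_2d(c, c) == pytest.approx(1.0, abs=1e-7)

    def test_distinct_constants_closed_form(self):
        # zero variance/covariance: SSIM = (2*0*1 + C1)/(0+1+C1) = C1/(1+C1)
        got = ssim_2d(np.zeros((16, 16)), np.ones((16, 16)))
        assert got == pytest.approx(C1 / (1 + C1), rel=1e-12)

    def test_matches_direct_formula(self, rng):
        """Independent dense-loop implementation of windowed SSIM."""
        cfg = LossConfig()
        win = gaussian_window(cfg.ssim_window, cfg.ssim_sigma)
        r = cfg.ssim_window // 2
        for _ in range(20):
            a = rng.random((14, 15))
            b = np.clip(a + rng.normal(0, 0.2, a.shape), 0, 1)
            vals = []
            for i in range(r, a.shape[0] - r):
                for j in range(r, a.shape[1] - r):
                    wa = a[i - r : i + r + 1, j - r : j + r + 1]
                    wb = b[i - r : i + r + 1, j - r : j + r + 1]
                    mu_a = (win * wa).sum()
                    mu_b = (win * wb).sum()
                    va = (win * wa * wa).sum() - mu_a**2
                    vb = (win * wb * wb).sum() - mu_b**2
                    cov = (win * wa * wb).sum() - mu_a * mu_b
                    vals.append(
                        (2 * mu_a * mu_b + C1)
                        * (2 * cov + 0.03**2)
                        / ((mu_a**2 + mu_b**2 + C1) * (va + vb + 0.03**2))
                    )
            assert ssim_2d(a, b, cfg) == pytest.approx(np.mean(vals), abs=1e-6)

    def test_matches_skimage(self, rng):
        for _ in range(5):
            a = rng.random((20, 20))
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
            ref = sk_ssim(
                a, b, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=1.0,
            )
            assert ssim_2d(a, b) == pytest.approx(ref, abs=1e-9)


class TestSimilarity:
    def test_identity(self, vertebra16):
        assert similarity_loss(vertebra16.truth, vertebra16.truth) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_constant_volumes_closed_form(self):
        v0 = Volume(np.zeros((16, 16, 4)))
        v1 = Volume(np.ones((16, 16, 4)))
        assert similarity_loss(v0, v1) == pytest.approx(1 - C1 / (1 + C1), rel=1e-9)

    def test_range(self, rng):
        for _ in range(5):
            a = Volume(rng.random((12, 12, 4)))
            b = Volume(rng.random((12, 12, 4)))
            assert 0.0 <= similarity_loss(a, b) <= 2.0


class TestReconstruction:
    def test_identity_vanishes(self, vertebra16):
        bd = reconstruction_loss(vertebra16.truth, vertebra16.truth)
        assert bd.l_recon == pytest.approx(0.0, abs=1e-6)

    def test_sum_of_components(self, volume_pair):
        v, vhat = volume_pair
        bd = reconstruction_loss(v, vhat)
        assert bd.l_recon == pytest.approx(bd.l_dist + bd.l_feat + bd.l_sim)
        assert bd.l_recon >= max(bd.l_dist, bd.l_feat, bd.l_sim)


class TestAdversarial:
    @pytest.mark.parametrize(
        "d_fake,expected", [(0.5, 0.0), (0.0, 0.25), (1.0, 0.25)]
    )
    def test_generator_targets_half(self, d_fake, expected):
        assert generator_adversarial_loss(d_fake) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "d_real,d_fake,expected", [(0.5, 0.0, 0.0), (1.0, 1.0, 1.25), (0.0, 0.5, 0.5)]
    )
    def test_discriminator_optimum(self, d_real, d_fake, expected):
        assert discriminator_loss(d_real, d_fake) == pytest.approx(expected)

    def test_standard_targets_option(self):
        cfg = LossConfig(lsgan_targets="standard")
        assert generator_adversarial_loss(1.0, cfg) == 0.0
        assert discriminator_loss(1.0, 0.0, cfg) == 0.0
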