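"""Adversarial and composite reconstruction losses.

The generator is trained with a least-squares adversarial term plus a
weighted reconstruction term

    L_G = (D(x, v̂) − 1/2)² + α · L_recon,      L_recon = L_dist + L_f + L_sim

where

* ``L_dist`` is the mean absolute voxel difference (L1),
* ``L_f`` ("feature loss") is one minus the threshold-averaged Jaccard
  overlap of high-value voxel sets — per threshold t, the fraction
  |{v≥t} ∩ {v̂≥t}| / |{v≥t} ∪ {v̂≥t}|, averaged over the threshold list,
* ``L_sim`` ("similarity loss") is one minus the mean slice-wise SSIM along
  the z-axis.

The discriminator minimizes (D(x, v) − 1/2)² + D(x, v̂)²: real volumes are
driven to score 1/2 and generated ones to 0 (the generator in turn pushes
its fakes toward 1/2).  The conventional least-squares targets 1/0/1 are
available via ``LossConfig.lsgan_targets = "standard"``.

All functions here return hard (exact-indicator) values on plain numpy
volumes.  The threshold indicators of ``L_f`` have zero gradient almost
everywhere, so training uses :func:`soft_feature_loss` — a sigmoid surrogate
sharpened by ``tau`` that converges to the hard value as ``tau → ∞`` — and
differentiable counterparts of the other terms (see :mod:`vigan.training`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volume_io import Volume, _ensure_same_shape, extract_slice

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "distance_loss",
    "feature_loss",
    "soft_feature_loss",
    "ssim_2d",
    "similarity_loss",
    "reconstruction_loss",
    "generator_adversarial_loss",
    "discriminator_loss",
    "gaussian_window",
]


@dataclass
class LossConfig:
    """Weights and constants of the composite objective.

    ``alpha`` scales the reconstruction term inside the generator loss
    (default 33.0).  ``thresholds`` are the N_r feature-loss cut points t_s
    in [0, 1], strictly increasing.  SSIM uses an 11×11 Gaussian window
    (sd 1.5) with the canonical stability constants k1=0.01, k2=0.03 on a
    dynamic range of 1.0.
    """

    alpha: float = 33.0
    thresholds: Sequence[float] = field(default_factory=lambda: (0.2, 0.4, 0.6, 0.8))
    ssim_window: int = 11
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_sigma: float = 1.5
    normalize_feature_by_nr: bool = True
    tau: float = 50.0  # sharpness of the soft indicator used during training
    lsgan_targets: str = "as_printed"  # or "standard" (1/0/1)

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        t = np.asarray(self.thresholds, dtype=float)
        if t.size < 1:
            raise ValueError("at least one threshold required")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.lsgan_targets not in ("as_printed", "standard"):
            raise ValueError("lsgan_targets must be 'as_printed' or 'standard'")


@dataclass
class LossBreakdown:
    """All scalar loss components of one generator/discriminator update."""

    l_dist: float = np.nan
    l_feat: float = np.nan
    l_sim: float = np.nan
    l_recon: float = np.nan
    l_adv_g: float = np.nan
    l_g_total: float = np.nan
    l_d: float = np.nan

    COLUMNS = ("l_dist", "l_feat", "l_sim", "l_recon", "l_adv_g", "l_g_total", "l_d")


# ----------------------------------------------------------- reconstruction

def distance_loss(v: Volume, vhat: Volume) -> float:
    """Mean absolute voxel difference (L1)."""
    _ensure_same_shape(v, vhat)
    return float(np.abs(v.data - vhat.data).mean())


def feature_loss(v: Volume, vhat: Volume, cfg: LossConfig | None = None) -> float:
    """One minus the threshold-averaged high-value voxel overlap.

    Per threshold t the overlap is the Jaccard index of the voxel sets
    {v ≥ t} and {v̂ ≥ t}; a threshold at which both sets are empty counts as
    overlap 1 (the volumes agree that nothing exceeds t).  With
    ``normalize_feature_by_nr=False`` the per-threshold terms are summed
    instead of averaged, matching a formulation that can exceed 1.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    _ensure_same_shape(v, vhat)
    total = 0.0
    for t in cfg.thresholds:
        a = v.data >= t
        b = vhat.data >= t
        union = np.logical_or(a, b).sum()
        inter = np.logical_and(a, b).sum()
        total += 1.0 if union == 0 else inter / union
    n_r = len(list(cfg.thresholds))
    if cfg.normalize_feature_by_nr:
        return float(1.0 - total / n_r)
    return float(1.0 - total)


def soft_feature_loss(v: Volume, vhat: Volume, cfg: LossConfig | None = None) -> float:
    """Differentiable surrogate of :func:`feature_loss` (numpy value).

    Indicators I(x ≥ t) are replaced by sigmoid((x − t)·tau); the value
    converges to the hard loss as tau → ∞.  The autodiff twin used in
    training lives in :mod:`vigan.training`; this function provides the
    matching scalar for convergence checks.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    _ensure_same_shape(v, vhat)
    total = 0.0
    for t in cfg.thresholds:
        a = _sigmoid((v.data - t) * cfg.tau)
        b = _sigmoid((vhat.data - t) * cfg.tau)
        inter = (a * b).sum()
        union = (a + b - a * b).sum()
        total += inter / (union + 1e-12)
    n_r = len(list(cfg.thresholds))
    if cfg.normalize_feature_by_nr:
        return float(1.0 - total / n_r)
    return float(1.0 - total)


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2D Gaussian kernel used as the SSIM local window."""
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_2d(a: np.ndarray, b: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Mean local structural similarity of two [0, 1] grayscale images.

    Gaussian-weighted local statistics (window ``ssim_window``, sd
    ``ssim_sigma``), dynamic range 1.0, C1 = k1², C2 = k2².  Local maps are
    computed only over fully contained ("valid") windows, i.e. edge pixels
    whose window would leave the image are excluded from the mean — the same
    convention as cropping the filter radius off a padded SSIM map.  If the
    image is smaller than the configured window, the largest odd window that
    fits is used.  Returns a value in [−1, 1]; 1 iff the images are
    identical (to numerical tolerance).
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    size = min(cfg.ssim_window, min(a.shape))
    if size % 2 == 0:
        size -= 1
    win = gaussian_window(size, cfg.ssim_sigma)
    c1 = cfg.ssim_k1**2
    c2 = cfg.ssim_k2**2
    mu_a = _filter_valid(a, win)
    mu_b = _filter_valid(b, win)
    s_aa = _filter_valid(a * a, win) - mu_a**2
    s_bb = _filter_valid(b * b, win) - mu_b**2
    s_ab = _filter_valid(a * b, win) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * s_ab + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (s_aa + s_bb + c2)
    return float((num / den).mean())


def _filter_valid(img: np.ndarray, win: np.ndarray) -> np.ndarray:
    """Valid-mode correlation of a 2D image with a window kernel."""
    w = sliding_window_view(img, win.shape)
    return np.tensordot(w, win, axes=([2, 3], [0, 1]))


def similarity_loss(v: Volume, vhat: Volume, cfg: LossConfig | None = None) -> float:
    """One minus the mean slice-wise SSIM over all h axial slices."""
    _ensure_same_shape(v, vhat)
    h = v.shape[2]
    s = sum(ssim_2d(extract_slice(v, k), extract_slice(vhat, k), cfg) for k in range(h))
    return float(1.0 - s / h)


def reconstruction_loss(
    v: Volume, vhat: Volume, cfg: LossConfig | None = None
) -> LossBreakdown:
    """Distance + feature + similarity terms of one volume pair."""
    cfg = cfg or LossConfig()
    out = LossBreakdown(
        l_dist=distance_loss(v, vhat),
        l_feat=feature_loss(v, vhat, cfg),
        l_sim=similarity_loss(v, vhat, cfg),
    )
    out.l_recon = out.l_dist + out.l_feat + out.l_sim
    return out


# ------------------------------------------------------------- adversarial

def generator_adversarial_loss(d_fake: float, cfg: LossConfig | None = None) -> float:
    """Least-squares generator term: fakes are pushed toward the real target.

    As-printed targets: (D(x, v̂) − 1/2)², zero at D = 1/2.  With
    ``lsgan_targets="standard"`` the target is 1.
    """
    cfg = cfg or LossConfig()
    target = 0.5 if cfg.lsgan_targets == "as_printed" else 1.0
    return float((d_fake - target) ** 2)


def discriminator_loss(d_real: float, d_fake: float, cfg: LossConfig | None = None) -> float:
    """Least-squares discriminator term: (D_real − target)² + D_fake².

    As-printed targets: real → 1/2, fake → 0; zero at (1/2, 0).  With
    ``lsgan_targets="standard"`` the real target is 1.
    """
    cfg = cfg or LossConfig()
    target = 0.5 if cfg.lsgan_targets == "as_printed" else 1.0
    return float((d_real - target) ** 2 + d_fake**2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
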