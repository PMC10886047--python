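"""Volumetric evaluation protocol.

Generated volumes are compared with their ground truth through

* a voxel confusion matrix at an intensity threshold t (strict ``>`` on both
  volumes), expressed as fractions of the total voxel count;
* overlap scores derived from it — IoU (Jaccard), Dice, F1, precision,
  recall.  Thresholds are taken from the *ground-truth* volume's intensity
  quantiles: Q3 emphasises rigid (bone-like) structure, Q1 soft tissue;
* voxelwise L1 and PSNR (dynamic range 1.0);
* slice-averaged image-quality indices: SSIM, UQI (the Wang–Bovik universal
  quality index, SSIM with C1 = C2 = 0 over a sliding uniform window) and
  VSI (visual saliency-induced index; saliency here is a simplified SDSP —
  log-Gabor frequency prior × Gaussian location prior, no color prior since
  slices are grayscale);
* a threshold sweep over n evenly spaced quantiles from Q1 to Q3
  (0.25, 0.375, 0.5, 0.625, 0.75 by default).

Note: the confusion matrix is also available in an ``as_printed`` convention
whose "FN" cell counts voxels below threshold in *both* volumes (i.e. the
standard TN); it is kept for transparency and rejected by the metric
formulas, which require the standard convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .losses import LossConfig, ssim_2d
from .volume_io import Volume, _ensure_same_shape, extract_slice

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "overlap_metrics",
    "quantile_threshold",
    "l1_error",
    "psnr",
    "uqi",
    "vsi",
    "ssim_volume",
    "evaluate_pair",
    "threshold_sweep",
]


@dataclass
class ConfusionCounts:
    """Voxel confusion fractions at one threshold.

    Standard convention: tp = v>t ∧ v̂>t, fp = v≤t ∧ v̂>t, fn = v>t ∧ v̂≤t,
    tn = v≤t ∧ v̂≤t; the four fractions partition to 1.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    threshold: float
    convention: str = "standard"


@dataclass
class MetricReport:
    """All evaluation factors for one (ground truth, generated) pair."""

    iou: float
    dice: float
    f1: float
    precision: float
    recall: float
    l1: float
    psnr: float
    uqi: float
    vsi: Optional[float]
    ssim: float
    thresholds: dict = field(default_factory=dict)  # label -> threshold value

    def to_dict(self) -> dict:
        return {
            "iou": self.iou,
            "dice": self.dice,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "l1": self.l1,
            "psnr": self.psnr,
            "uqi": self.uqi,
            "vsi": self.vsi,
            "ssim": self.ssim,
            "thresholds": self.thresholds,
        }


# --------------------------------------------------------------- confusion

def confusion_counts(
    v: Volume, vhat: Volume, t: float, convention: str = "standard"
) -> ConfusionCounts:
    """Voxel confusion fractions at threshold t (strict > on both volumes)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    if convention not in ("standard", "as_printed"):
        raise ValueError(f"unknown convention {convention!r}")
    _ensure_same_shape(v, vhat)
    n = v.n_voxels
    pos_t = v.data > t
    pos_p = vhat.data > t
    tp = float(np.logical_and(pos_t, pos_p).sum()) / n
    fp = float(np.logical_and(~pos_t, pos_p).sum()) / n
    tn = float(np.logical_and(~pos_t, ~pos_p).sum()) / n
    if convention == "as_printed":
        # the literal printed FN formula counts v<=t AND vhat<=t (the TN cell)
        return ConfusionCounts(tp=tp, fp=fp, fn=tn, tn=tn, threshold=t, convention=convention)
    fn = float(np.logical_and(pos_t, ~pos_p).sum()) / n
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, threshold=t, convention=convention)


def overlap_metrics(c: ConfusionCounts):
    """(iou, dice, f1, precision, recall) from standard-convention counts.

    A 0/0 ratio is 1 when fp = fn = 0 (a perfect empty prediction) and 0
    otherwise.
    """
    if c.convention != "standard":
        raise ValueError(
            "overlap metrics require the standard convention; the as_printed "
            "FN cell duplicates TN and leaves recall/F1/Dice undefined"
        )

    def ratio(num, den):
        if den == 0:
            return 1.0 if (c.fp == 0 and c.fn == 0) else 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2 * precision * recall, precision + recall)
    dice = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    iou = ratio(c.tp, c.tp + c.fp + c.fn)
    return iou, dice, f1, precision, recall


def quantile_threshold(v: Volume, q: float) -> float:
    """The q-quantile of all voxel values (linear interpolation between order
    statistics); Q1 = 0.25, Q3 = 0.75."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    return float(np.quantile(v.ravel(), q))


# ------------------------------------------------------------ fidelity

def l1_error(v: Volume, vhat: Volume) -> float:
    _ensure_same_shape(v, vhat)
    return float(np.abs(v.data - vhat.data).mean())


def psnr(v: Volume, vhat: Volume) -> float:
    """10·log10(1 / MSE) dB with MAX = 1.0; +inf for identical volumes."""
    _ensure_same_shape(v, vhat)
    mse = float(((v.data - vhat.data) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


# ---------------------------------------------------- slice-wise similarity

def _uqi_2d(a: np.ndarray, b: np.ndarray, window: int = 8) -> float:
    """Wang–Bovik universal quality index over sliding windows.

    Q = 4·σ_ab·μ_a·μ_b / ((σ_a²+σ_b²)(μ_a²+μ_b²)) per window, averaged.
    Degenerate windows (zero denominator) score 1 when the window contents
    are identical, else 0.
    """
    size = min(window, min(a.shape))
    wa = sliding_window_view(a, (size, size)).reshape(-1, size * size)
    wb = sliding_window_view(b, (size, size)).reshape(-1, size * size)
    mu_a, mu_b = wa.mean(axis=1), wb.mean(axis=1)
    va = wa.var(axis=1)
    vb = wb.var(axis=1)
    cov = (wa * wb).mean(axis=1) - mu_a * mu_b
    num = 4.0 * cov * mu_a * mu_b
    den = (va + vb) * (mu_a**2 + mu_b**2)
    eps = 1e-12  # rounding floor: variances of constant windows are ~1e-17, not 0
    q = np.where(den > eps, num / np.maximum(den, eps), 0.0)
    degenerate = den <= eps
    if degenerate.any():
        same = np.all(wa[degenerate] == wb[degenerate], axis=1)
        q[degenerate] = np.where(same, 1.0, 0.0)
    return float(q.mean())


def _sdsp_saliency(img: np.ndarray) -> np.ndarray:
    """Simplified SDSP saliency of a grayscale [0, 1] image.

    Frequency prior: band-pass (log-Gabor) filtered luminance magnitude;
    location prior: Gaussian centered on the image; color prior omitted
    (grayscale input).  Output is min-max scaled to [0, 1].
    """
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.sqrt(fy**2 + fx**2)
    omega0, sigma_f = 0.06, 0.55  # canonical SDSP band-pass parameters
    with np.errstate(divide="ignore"):
        lg = np.exp(-((np.log(np.maximum(r, 1e-12) / omega0)) ** 2) / (2 * sigma_f**2))
    lg[r == 0] = 0.0
    sf = np.abs(np.fft.ifft2(np.fft.fft2(img) * lg))
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma_d = 0.5 * math.hypot(h, w)
    sd = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / sigma_d**2))
    s = sf * sd
    rng = s.max() - s.min()
    if rng == 0:
        return np.zeros_like(s)
    return (s - s.min()) / rng


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.correlate(img, _SCHARR, mode="nearest")
    gy = ndimage.correlate(img, _SCHARR.T, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


_SCHARR = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


def _vsi_2d(a: np.ndarray, b: np.ndarray) -> float:
    """Visual saliency-induced index of two grayscale [0, 1] slices.

    S(x) = S_VS(x) · S_G(x)^alpha weighted by max(VS1, VS2); constants from
    the published formulation on a 0–255 dynamic range.
    """
    c1, c2 = 1.27, 386.0  # VS and gradient stability constants (0-255 range)
    alpha = 0.40
    a255, b255 = a * 255.0, b * 255.0
    vs1, vs2 = _sdsp_saliency(a), _sdsp_saliency(b)
    g1, g2 = _gradient_magnitude(a255), _gradient_magnitude(b255)
    s_vs = (2 * vs1 * vs2 + c1) / (vs1**2 + vs2**2 + c1)
    s_g = (2 * g1 * g2 + c2) / (g1**2 + g2**2 + c2)
    s = s_vs * s_g**alpha
    vsm = np.maximum(vs1, vs2)
    wsum = vsm.sum()
    if wsum == 0:
        return float(s.mean())
    return float((s * vsm).sum() / wsum)


def _slice_average(v: Volume, vhat: Volume, fn) -> float:
    h = v.shape[2]
    return float(np.mean([fn(extract_slice(v, k), extract_slice(vhat, k)) for k in range(h)]))


def uqi(v: Volume, vhat: Volume, window: int = 8) -> float:
    """Mean universal quality index over all axial slices."""
    _ensure_same_shape(v, vhat)
    return _slice_average(v, vhat, lambda a, b: _uqi_2d(a, b, window))


def vsi(v: Volume, vhat: Volume) -> float:
    """Mean visual saliency-induced index over all axial slices."""
    _ensure_same_shape(v, vhat)
    return _slice_average(v, vhat, _vsi_2d)


def ssim_volume(v: Volume, vhat: Volume, cfg: Optional[LossConfig] = None) -> float:
    """Mean slice-wise SSIM (shares the Gaussian-window ssim_2d)."""
    _ensure_same_shape(v, vhat)
    return _slice_average(v, vhat, lambda a, b: ssim_2d(a, b, cfg))


# ------------------------------------------------------------- reporting

def evaluate_pair(
    v: Volume,
    vhat: Volume,
    quantiles: Sequence[float] = (0.25, 0.75),
    metric_threshold_q: float = 0.25,
    compute_vsi: bool = True,
) -> MetricReport:
    """Full metric report for one pair; thresholds from the ground truth only.

    ``metric_threshold_q`` selects the quantile used for the overlap metrics
    (Q1 by default); every quantile in ``quantiles`` is resolved against the
    ground-truth distribution and recorded in the report.
    """
    _ensure_same_shape(v, vhat)
    thresholds = {_q_label(q): quantile_threshold(v, q) for q in quantiles}
    t = quantile_threshold(v, metric_threshold_q)
    thresholds[_q_label(metric_threshold_q)] = t
    c = confusion_counts(v, vhat, t)
    iou_, dice, f1, prec, rec = overlap_metrics(c)
    return MetricReport(
        iou=iou_,
        dice=dice,
        f1=f1,
        precision=prec,
        recall=rec,
        l1=l1_error(v, vhat),
        psnr=psnr(v, vhat),
        uqi=uqi(v, vhat),
        vsi=vsi(v, vhat) if compute_vsi else None,
        ssim=ssim_volume(v, vhat),
        thresholds=thresholds,
    )


def threshold_sweep(
    v: Volume, vhat: Volume, q_lo: float = 0.25, q_hi: float = 0.75, n: int = 5
) -> List[dict]:
    """Overlap metrics at n evenly spaced ground-truth quantiles in [q_lo, q_hi].

    Defaults reproduce the 5-point Q1→Q3 protocol: quantiles 0.25, 0.375,
    0.5, 0.625, 0.75.
    """
    if n < 2:
        raise ValueError("sweep needs n >= 2 points")
    _ensure_same_shape(v, vhat)
    rows = []
    for q in np.linspace(q_lo, q_hi, n):
        t = quantile_threshold(v, float(q))
        iou_, dice, f1, _, _ = overlap_metrics(confusion_counts(v, vhat, t))
        rows.append(
            {"quantile": float(q), "threshold": t, "iou": iou_, "f1": f1, "dice": dice}
        )
    return rows


def _q_label(q: float) -> str:
    named = {0.25: "Q1", 0.5: "Q2", 0.75: "Q3"}
    return named.get(round(q, 4), f"q{q:g}")
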