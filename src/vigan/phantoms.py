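"""Synthetic anatomical phantoms.

The reconstruction method assumes CT-like volumes: a low-value background
majority ("undefined" space around the anatomy), a mid-value soft interior,
and — for skeletal structures — a thin high-value cortical shell whose
voxels dominate the upper quartile of the intensity distribution.  The
generators here produce that structure deterministically from a seed, so the
whole training/evaluation pipeline can be exercised without clinical data.

Three phantom families:

* ``vertebra`` — ellipsoidal body with a ~2-voxel cortical shell plus a
  posterior rectangular process (rigid structure; Q3 thresholding regime).
* ``liver``    — smoothed union of two overlapping ellipsoids at interior
  intensity, no shell (soft tissue; Q1 thresholding regime).
* ``sphere``   — a plain ball; the analytically simplest fixture.

Conditioning image sets are degraded views of the ground truth: the full
axial stack, every n-th slice, or a noise-corrupted stack.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .volume_io import ImageSet, Volume

__all__ = ["PhantomSpec", "PhantomPair", "make_phantom", "degrade_to_condition", "make_dataset"]

_KINDS = ("vertebra", "liver", "sphere")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Intensities are unitless voxel values in [0, 1]; for bone-like kinds the
    ordering background < interior < shell must hold.  ``noise_sd`` is the
    standard deviation of additive Gaussian noise applied before clipping;
    ``deform`` scales a small random affine warp (0 disables it).
    """

    kind: str = "vertebra"
    resolution: tuple = (32, 32, 32)
    shell_intensity: float = 0.85
    interior_intensity: float = 0.45
    background_intensity: float = 0.05
    noise_sd: float = 0.02
    deform: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if len(self.resolution) != 3 or any(int(r) < 8 for r in self.resolution):
            raise ValueError(f"resolution components must be >= 8, got {self.resolution}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("shell_intensity", "interior_intensity", "background_intensity"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.kind != "liver" and not (
            self.background_intensity < self.interior_intensity < self.shell_intensity
        ):
            raise ValueError("bone-like kinds need background < interior < shell intensity")


@dataclass
class PhantomPair:
    """A ground-truth volume and its conditioning image set."""

    truth: Volume
    condition: ImageSet
    spec: PhantomSpec


# ----------------------------------------------------------------- shapes

def _ellipsoid_mask(res, center, semi):
    grids = np.meshgrid(*[np.arange(r, dtype=np.float64) for r in res], indexing="ij")
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d2 <= 1.0


def _vertebra_masks(res, rng, deform):
    l, w, h = res
    jitter = lambda s: 1.0 + deform * (rng.random() - 0.5)  # noqa: E731
    # sized so the solid fills ~35% of the grid: background stays the majority
    # while the upper quartile of the histogram lands inside the anatomy
    body_semi = (0.47 * l * jitter(0), 0.44 * w * jitter(1), 0.47 * h * jitter(2))
    center = (0.45 * l, 0.5 * w, 0.5 * h)
    body = _ellipsoid_mask(res, center, body_semi)
    # posterior process: rectangular block behind the body along x
    x0 = int(round(center[0] + body_semi[0] * 0.8))
    x1 = min(l, x0 + max(2, l // 5))
    y0, y1 = int(0.40 * w), int(np.ceil(0.60 * w))
    z0, z1 = int(0.35 * h), int(np.ceil(0.65 * h))
    process = np.zeros(res, dtype=bool)
    process[x0:x1, y0:y1, z0:z1] = True
    solid = body | process
    interior = ndimage.binary_erosion(solid, iterations=2)
    shell = solid & ~interior
    return solid, interior, shell


def _liver_masks(res, rng, deform):
    l, w, h = res
    jitter = lambda s: 1.0 + deform * (rng.random() - 0.5)  # noqa: E731
    m1 = _ellipsoid_mask(
        res, (0.42 * l, 0.45 * w, 0.5 * h), (0.30 * l * jitter(0), 0.32 * w, 0.30 * h)
    )
    m2 = _ellipsoid_mask(
        res, (0.58 * l, 0.58 * w, 0.48 * h), (0.24 * l, 0.25 * w * jitter(1), 0.26 * h)
    )
    solid = m1 | m2
    return solid, solid, np.zeros(res, dtype=bool)


def _sphere_masks(res, rng, deform):
    semi = tuple(0.35 * r for r in res)
    center = tuple(0.5 * (r - 1) for r in res)
    solid = _ellipsoid_mask(res, center, semi)
    return solid, solid, np.zeros(res, dtype=bool)


_BUILDERS = {"vertebra": _vertebra_masks, "liver": _liver_masks, "sphere": _sphere_masks}


# ------------------------------------------------------------- operations

def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Build one deterministic phantom pair from a spec.

    Identical spec (including seed) yields bit-identical output.  The
    conditioning image set defaults to the full axial stack of the truth.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    res = tuple(int(r) for r in spec.resolution)
    solid, interior, shell = _BUILDERS[spec.kind](res, rng, spec.deform)

    vol = np.full(res, spec.background_intensity, dtype=np.float64)
    vol[interior] = spec.interior_intensity
    if shell.any():
        vol[shell] = spec.shell_intensity
    if spec.kind == "liver":
        # soft-tissue phantom: smooth the boundary so no rigid shell exists
        vol = ndimage.gaussian_filter(vol, sigma=1.0)
    if spec.deform > 0:
        shift = spec.deform * 2.0 * (rng.random(3) - 0.5)
        vol = ndimage.shift(vol, shift, order=1, mode="nearest")
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=res)
    truth = Volume(np.clip(vol, 0.0, 1.0))
    condition = degrade_to_condition(truth, mode="full_stack")
    return PhantomPair(truth=truth, condition=condition, spec=spec)


def degrade_to_condition(
    truth: Volume,
    mode: str = "full_stack",
    step: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ImageSet:
    """Derive the generator's conditioning image set from a ground-truth volume.

    Modes: ``full_stack`` (every axial slice unchanged), ``sparse_slices``
    (every ``step``-th slice, z positions recorded), ``noisy_stack`` (clipped
    additive Gaussian noise per slice).
    """
    h = truth.shape[2]
    stack = np.moveaxis(truth.data, -1, 0)  # (h, l, w)
    if mode == "full_stack":
        return ImageSet(stack.copy(), z_positions=np.arange(h))
    if mode == "sparse_slices":
        if step > h:
            raise ValueError(f"sparse step {step} exceeds slice count {h}")
        idx = np.arange(0, h, step)
        return ImageSet(stack[idx].copy(), z_positions=idx)
    if mode == "noisy_stack":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        noisy = stack + (rng.normal(0.0, noise_sd, size=stack.shape) if noise_sd > 0 else 0.0)
        return ImageSet(np.clip(noisy, 0.0, 1.0), z_positions=np.arange(h))
    raise ValueError(f"unknown degradation mode {mode!r}")


def make_dataset(
    n: int,
    spec_template: Optional[PhantomSpec] = None,
    seed: int = 0,
    condition_mode: str = "full_stack",
    condition_params: Optional[dict] = None,
) -> List[PhantomPair]:
    """Generate ``n`` phantom pairs with per-item seeds split from ``seed``.

    Item seeds come from ``np.random.SeedSequence(seed).spawn``, so the
    dataset is reproducible and independent of generation order.
    """
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    template = spec_template if spec_template is not None else PhantomSpec()
    template.validate()
    children = np.random.SeedSequence(seed).spawn(n)
    pairs = []
    params = dict(condition_params or {})
    for i, child in enumerate(children):
        item_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = replace(template, seed=item_seed)
        pair = make_phantom(spec)
        if condition_mode != "full_stack" or params:
            pair.condition = degrade_to_condition(
                pair.truth, mode=condition_mode, seed=item_seed, **params
            )
        pairs.append(pair)
    return pairs
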