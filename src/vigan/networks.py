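"""Conditional volume generator and volumetric discriminator.

Generator: the conditioning image set is rasterized into a one-channel 3D
tensor on the output grid (missing z positions zero-filled), passed through
a 3D local-feature-fusion block (LFFB: parallel 3D convolutions at several
kernel sizes, concatenation, 1×1×1 fusion, local residual), then through a
U-Net: ``depth_down`` stride-2 4³ encoder convolutions, ``depth_mid``
stride-1 residual refinement blocks with dropout, ``depth_up`` stride-2 4³
transposed convolutions with skip concatenation, and a stride-1 output
convolution squashed by a sigmoid so every voxel lies in [0, 1].

Discriminator: the condition tensor is concatenated channel-wise with the
candidate volume and reduced by a stack of stride-2 4³ convolutions; a final
fully connected layer with sigmoid yields the authenticity score p ∈ (0, 1).

All parameters live in ordered name → Tensor dictionaries and are
initialized N(0, 0.02) deterministically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from ._autodiff import Tensor
from .volume_io import ImageSet, Volume

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "generator_forward",
    "discriminator_forward",
    "condition_to_tensor",
]


@dataclass
class GeneratorConfig:
    depth_down: int = 3
    depth_mid: int = 3
    depth_up: int = 3
    base_channels: int = 16
    channel_growth: float = 2.0
    channel_cap: int = 256
    dropout: float = 0.2
    lffb_branches: Sequence[int] = field(default_factory=lambda: (1, 3, 5))
    input_slices: Optional[int] = None
    out_resolution: tuple = (32, 32, 32)

    def validate(self) -> None:
        if self.depth_down != self.depth_up:
            raise ValueError("U-Net symmetry requires depth_down == depth_up")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        div = 2**self.depth_down
        if any(int(r) % div for r in self.out_resolution):
            raise ValueError(
                f"out_resolution {self.out_resolution} must be divisible by 2^depth_down={div}"
            )
        if any(k % 2 == 0 for k in self.lffb_branches):
            raise ValueError("lffb branch kernels must be odd (shape-preserving)")

    def channels(self, level: int) -> int:
        return min(int(round(self.base_channels * self.channel_growth**level)), self.channel_cap)


@dataclass
class DiscriminatorConfig:
    depth: int = 3
    base_channels: int = 16
    channel_growth: float = 2.0
    channel_cap: int = 256
    in_resolution: tuple = (32, 32, 32)

    def validate(self) -> None:
        div = 2**self.depth
        if any(int(r) % div for r in self.in_resolution):
            raise ValueError(
                f"in_resolution {self.in_resolution} must be divisible by 2^depth={div}"
            )
        if any(int(r) // div < 1 for r in self.in_resolution):
            raise ValueError("final spatial extent must be >= 1")

    def channels(self, level: int) -> int:
        return min(int(round(self.base_channels * self.channel_growth**level)), self.channel_cap)


# ----------------------------------------------------------- param helpers

def _conv_w(rng, oc, ic, k) -> Tensor:
    return Tensor(rng.normal(0.0, 0.02, size=(oc, ic, k, k, k)), requires_grad=True)


def _bias(oc) -> Tensor:
    return Tensor(np.zeros(oc), requires_grad=True)


def _norm_params(c):
    return (
        Tensor(np.ones(c), requires_grad=True),
        Tensor(np.zeros(c), requires_grad=True),
    )


class _Module:
    """Shared parameter-dictionary plumbing."""

    def __init__(self):
        self.params: Dict[str, Tensor] = {}

    def _add(self, name: str, t: Tensor) -> Tensor:
        self.params[name] = t
        return t

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in arrays:
                raise KeyError(f"checkpoint missing parameter {k}")
            if arrays[k].shape != p.data.shape:
                raise ValueError(f"parameter {k} shape mismatch")
            p.data = np.array(arrays[k], dtype=p.data.dtype)


class Generator(_Module):
    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        bc = cfg.base_channels
        # LFFB: parallel odd-kernel branches + input projection + 1x1x1 fusion
        for i, k in enumerate(cfg.lffb_branches):
            self._add(f"lffb.branch{i}.w", Tensor(rng.normal(0, 0.02, (bc, 1, k, k, k)), True))
            self._add(f"lffb.branch{i}.b", _bias(bc))
        self._add("lffb.proj.w", Tensor(rng.normal(0, 0.02, (bc, 1, 1, 1, 1)), True))
        self._add("lffb.proj.b", _bias(bc))
        nb = len(cfg.lffb_branches)
        self._add("lffb.fuse.w", Tensor(rng.normal(0, 0.02, (bc, nb * bc, 1, 1, 1)), True))
        self._add("lffb.fuse.b", _bias(bc))
        # encoder
        ic = bc
        self.down_channels = [bc]
        for d in range(cfg.depth_down):
            oc = cfg.channels(d + 1)
            self._add(f"down{d}.w", _conv_w(rng, oc, ic, 4))
            self._add(f"down{d}.b", _bias(oc))
            g, b = _norm_params(oc)
            self._add(f"down{d}.g", g)
            self._add(f"down{d}.beta", b)
            self.down_channels.append(oc)
            ic = oc
        # refiner (ResNet blocks, stride 1)
        for r in range(cfg.depth_mid):
            for j in (0, 1):
                self._add(f"mid{r}.conv{j}.w", _conv_w(rng, ic, ic, 4))
                self._add(f"mid{r}.conv{j}.b", _bias(ic))
                g, b = _norm_params(ic)
                self._add(f"mid{r}.conv{j}.g", g)
                self._add(f"mid{r}.conv{j}.beta", b)
        # decoder (transposed convs + skip concat)
        for u in range(cfg.depth_up):
            oc = self.down_channels[cfg.depth_down - 1 - u]
            self._add(f"up{u}.w", Tensor(rng.normal(0, 0.02, (ic, oc, 4, 4, 4)), True))
            self._add(f"up{u}.b", _bias(oc))
            g, b = _norm_params(oc)
            self._add(f"up{u}.g", g)
            self._add(f"up{u}.beta", b)
            ic = oc + self.down_channels[cfg.depth_down - 1 - u]  # after skip concat
        # output layer: stride 1 (resolution-preserving), sigmoid squash.
        # Its input carries the last decoder feature, the LFFB feature and the
        # raw conditioning tensor (level-0 skip): a direct path for the
        # voxel-level detail the reconstruction losses demand.
        self._add("out.w", _conv_w(rng, 1, ic + 1, 4))
        self._add("out.b", _bias(1))

    # ------------------------------------------------------------ forward
    def forward(
        self,
        x: Tensor,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Map a (N, 1, l, w, h) condition tensor to a (N, 1, l, w, h) volume."""
        cfg = self.cfg
        p = self.params
        if x.shape[2:] != tuple(cfg.out_resolution):
            raise ValueError(f"condition grid {x.shape[2:]} != out_resolution {cfg.out_resolution}")
        branches = [
            x.conv3d(p[f"lffb.branch{i}.w"], p[f"lffb.branch{i}.b"], 1, k // 2)
            for i, k in enumerate(cfg.lffb_branches)
        ]
        fused = Tensor.concat(branches, axis=1).conv3d(p["lffb.fuse.w"], p["lffb.fuse.b"], 1, 0)
        feat = fused + x.conv3d(p["lffb.proj.w"], p["lffb.proj.b"], 1, 0)  # local residual
        skips = [feat]
        h = feat
        for d in range(cfg.depth_down):
            h = h.conv3d(p[f"down{d}.w"], p[f"down{d}.b"], 2, 1)
            h = h.instance_norm(p[f"down{d}.g"], p[f"down{d}.beta"])
            h = h.leaky_relu(0.2)
            skips.append(h)
        for r in range(cfg.depth_mid):
            res = h
            h = h.conv3d(p[f"mid{r}.conv0.w"], p[f"mid{r}.conv0.b"], 1, (1, 2))
            h = h.instance_norm(p[f"mid{r}.conv0.g"], p[f"mid{r}.conv0.beta"]).relu()
            if training and cfg.dropout > 0:
                h = h.dropout(cfg.dropout, rng or np.random.default_rng())
            h = h.conv3d(p[f"mid{r}.conv1.w"], p[f"mid{r}.conv1.b"], 1, (1, 2))
            h = h.instance_norm(p[f"mid{r}.conv1.g"], p[f"mid{r}.conv1.beta"])
            h = (h + res).relu()
        for u in range(cfg.depth_up):
            h = h.conv_transpose3d(p[f"up{u}.w"], p[f"up{u}.b"], 2, 1)
            h = h.instance_norm(p[f"up{u}.g"], p[f"up{u}.beta"]).relu()
            h = Tensor.concat([h, skips[cfg.depth_down - 1 - u]], axis=1)
        h = Tensor.concat([h, x], axis=1)
        return h.conv3d(p["out.w"], p["out.b"], 1, (1, 2)).sigmoid()

    def generate(self, condition: ImageSet) -> Volume:
        """Evaluation-mode forward from an image set to a Volume."""
        x = condition_to_tensor(condition, self.cfg.out_resolution)
        out = self.forward(Tensor(x), training=False)
        return Volume(np.clip(out.data[0, 0], 0.0, 1.0))


class Discriminator(_Module):
    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        ic = 2  # condition + candidate, channel-wise
        for d in range(cfg.depth):
            oc = cfg.channels(d)
            self._add(f"conv{d}.w", _conv_w(rng, oc, ic, 4))
            self._add(f"conv{d}.b", _bias(oc))
            if d > 0:  # no normalization on the first layer
                g, b = _norm_params(oc)
                self._add(f"conv{d}.g", g)
                self._add(f"conv{d}.beta", b)
            ic = oc
        sp = tuple(int(r) // 2**cfg.depth for r in cfg.in_resolution)
        n_feat = ic * int(np.prod(sp))
        self._add("fc.w", Tensor(rng.normal(0, 0.02, (n_feat, 1)), True))
        self._add("fc.b", Tensor(np.zeros(1), True))
        self._flat = n_feat

    def forward(self, condition: Tensor, volume: Tensor) -> Tensor:
        """Score (N,) authenticity probabilities for condition/candidate pairs."""
        if condition.shape[2:] != volume.shape[2:]:
            raise ValueError(
                f"condition grid {condition.shape[2:]} != volume grid {volume.shape[2:]}"
            )
        p = self.params
        h = Tensor.concat([condition, volume], axis=1)
        for d in range(self.cfg.depth):
            h = h.conv3d(p[f"conv{d}.w"], p[f"conv{d}.b"], 2, 1)
            if d > 0:
                h = h.instance_norm(p[f"conv{d}.g"], p[f"conv{d}.beta"])
            h = h.leaky_relu(0.2)
        n = h.shape[0]
        flat = h.reshape(n, self._flat)
        return (flat.matmul(p["fc.w"]) + p["fc.b"]).sigmoid().reshape(n)


# ------------------------------------------------------------- operations

def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(cfg, seed)


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, seed)


def generator_forward(gen: Generator, image_set: ImageSet) -> Volume:
    return gen.generate(image_set)


def discriminator_forward(disc: Discriminator, image_set: ImageSet, volume: Volume) -> float:
    cond = Tensor(condition_to_tensor(image_set, volume.shape))
    vol = Tensor(volume.data[None, None])
    return float(disc.forward(cond, vol).data[0])


def condition_to_tensor(image_set: ImageSet, out_resolution) -> np.ndarray:
    """Rasterize an image set onto the (1, 1, l, w, h) output grid.

    Slices land at their recorded z positions (zero-filling the gaps of a
    sparse set); a set without positions must have exactly h slices, mapped
    in order.
    """
    l, w, h = (int(r) for r in out_resolution)
    if image_set.resolution != (l, w):
        raise ValueError(
            f"slice resolution {image_set.resolution} != output in-plane grid {(l, w)}"
        )
    grid = np.zeros((1, 1, l, w, h), dtype=np.float64)
    if image_set.z_positions is not None:
        zs = image_set.z_positions
        if np.any(zs < 0) or np.any(zs >= h):
            raise ValueError("z_positions outside output grid")
    else:
        if image_set.count != h:
            raise ValueError(f"{image_set.count} slices cannot fill h={h} without z_positions")
        zs = np.arange(h)
    for sl, z in zip(image_set.slices, zs):
        grid[0, 0, :, :, int(z)] = sl
    return grid
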