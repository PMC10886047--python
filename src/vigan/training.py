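"""Alternating adversarial training with Adam.

Each iteration performs one discriminator update followed by one generator
update:

1. D step — minimize ``(D(x, v) − 1/2)² + D(x, v̂)²`` with the generated
   volume detached;
2. G step — minimize ``(D(x, v̂) − 1/2)² + α · (L_dist + L_f^soft + L_sim)``.

Defaults follow the reference configuration: Adam with learning rate 2e-4
(β₁ = 0.5, β₂ = 0.999), dropout 0.2 in the refiner blocks, α = 33.0, batch
size 1.  The feature loss trains through a sigmoid surrogate of its
threshold indicators (sharpness ``LossConfig.tau``); logged values report
the same soft scalar the optimizer sees, alongside the full breakdown.

Runs are deterministic given the seed (on one device/BLAS build): parameter
init, dropout and batch order all derive from ``TrainConfig.seed``.
Checkpoints are ``.npz`` archives of named parameter/moment arrays with a
JSON sidecar recording configs, seed and step; save → load → generate is
bit-exact.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from ._autodiff import Tensor
from .losses import LossBreakdown, LossConfig, gaussian_window
from .networks import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    condition_to_tensor,
)
from .phantoms import PhantomPair
from .volume_io import ImageSet, Volume

__all__ = ["TrainConfig", "TrainState", "train", "generate", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    batch_size: int = 1
    steps: int = 500
    alpha: float = 33.0
    dropout: float = 0.2
    seed: int = 0
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    device: str = "cpu"
    log_path: Optional[str] = None
    adversarial: bool = True  # False: generator-only reconstruction training

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported in this build")


class _Adam:
    """Adam over a named parameter dict."""

    def __init__(self, params, lr: float, betas):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.eps = 1e-8

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)

    def state_arrays(self, prefix):
        out = {f"{prefix}.t": np.array([self.t])}
        for k in self.m:
            out[f"{prefix}.m.{k}"] = self.m[k]
            out[f"{prefix}.v.{k}"] = self.v[k]
        return out

    def load_state_arrays(self, arrays, prefix):
        self.t = int(arrays[f"{prefix}.t"][0])
        for k in self.m:
            self.m[k] = arrays[f"{prefix}.m.{k}"].copy()
            self.v[k] = arrays[f"{prefix}.v.{k}"].copy()


@dataclass
class TrainState:
    """Everything needed to continue or deploy a run."""

    gen: Generator
    disc: Optional[Discriminator]
    gen_cfg: GeneratorConfig
    disc_cfg: Optional[DiscriminatorConfig]
    loss_cfg: LossConfig
    train_cfg: TrainConfig
    step: int = 0
    opt_g: Optional[_Adam] = None
    opt_d: Optional[_Adam] = None
    history: List[LossBreakdown] = field(default_factory=list)


# ----------------------------------------------------- differentiable terms

def _distance_t(truth: Tensor, fake: Tensor) -> Tensor:
    return (truth - fake).abs().mean()


def _soft_feature_t(truth: Tensor, fake: Tensor, cfg: LossConfig) -> Tensor:
    total = None
    for t in cfg.thresholds:
        a = ((truth - t) * cfg.tau).sigmoid()
        b = ((fake - t) * cfg.tau).sigmoid()
        inter = (a * b).sum()
        union = (a + b - a * b).sum() + 1e-12
        term = inter / union
        total = term if total is None else total + term
    n_r = len(list(cfg.thresholds))
    if cfg.normalize_feature_by_nr:
        return 1.0 - total * (1.0 / n_r)
    return 1.0 - total


def _similarity_t(truth: Tensor, fake: Tensor, cfg: LossConfig) -> Tensor:
    """1 − mean slice-wise SSIM, differentiable; matches losses.ssim_2d."""
    n, _, l, w, h = truth.shape
    size = min(cfg.ssim_window, l, w)
    if size % 2 == 0:
        size -= 1
    win = gaussian_window(size, cfg.ssim_sigma)
    c1, c2 = cfg.ssim_k1**2, cfg.ssim_k2**2

    def slices(t: Tensor) -> Tensor:
        return t.reshape(n, l, w, h).transpose(0, 3, 1, 2).reshape(n * h, l, w)

    a, b = slices(truth), slices(fake)
    mu_a, mu_b = a.filter2d(win), b.filter2d(win)
    s_aa = (a * a).filter2d(win) - mu_a * mu_a
    s_bb = (b * b).filter2d(win) - mu_b * mu_b
    s_ab = (a * b).filter2d(win) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * s_ab + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (s_aa + s_bb + c2)
    return 1.0 - (num / den).mean()


def _mean_sq(x: Tensor, target: float) -> Tensor:
    d = x - target
    return (d * d).mean()


# --------------------------------------------------------------- training

def train(
    dataset: Sequence[PhantomPair],
    gen_cfg: Optional[GeneratorConfig] = None,
    disc_cfg: Optional[DiscriminatorConfig] = None,
    loss_cfg: Optional[LossConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    checkpoint_dir: Optional[str] = None,
) -> TrainState:
    """Run the alternating optimization over a dataset of (truth, condition) pairs."""
    if len(dataset) < 1:
        raise ValueError("dataset must contain at least one pair")
    res = dataset[0].truth.shape
    if any(p.truth.shape != res for p in dataset):
        raise ValueError("all volumes must share one resolution")
    gen_cfg = gen_cfg or GeneratorConfig(out_resolution=res)
    if tuple(gen_cfg.out_resolution) != tuple(res):
        raise ValueError(f"gen_cfg.out_resolution {gen_cfg.out_resolution} != data {res}")
    train_cfg = train_cfg or TrainConfig()
    train_cfg.validate()
    loss_cfg = loss_cfg or LossConfig(alpha=train_cfg.alpha)
    loss_cfg.alpha = train_cfg.alpha
    loss_cfg.validate()
    gen_cfg.dropout = train_cfg.dropout

    ss = np.random.SeedSequence(train_cfg.seed)
    s_init_g, s_init_d, s_run = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
    gen = Generator(gen_cfg, seed=s_init_g)
    disc = None
    if train_cfg.adversarial:
        disc_cfg = disc_cfg or DiscriminatorConfig(in_resolution=res)
        disc_cfg.validate()
        disc = Discriminator(disc_cfg, seed=s_init_d)
    rng = np.random.default_rng(np.random.SeedSequence(s_run))

    state = TrainState(
        gen=gen,
        disc=disc,
        gen_cfg=gen_cfg,
        disc_cfg=disc_cfg,
        loss_cfg=loss_cfg,
        train_cfg=train_cfg,
        opt_g=_Adam(gen.params, train_cfg.learning_rate, train_cfg.adam_betas),
        opt_d=_Adam(disc.params, train_cfg.learning_rate, train_cfg.adam_betas)
        if disc is not None
        else None,
    )

    conds = [condition_to_tensor(p.condition, res) for p in dataset]
    truths = [p.truth.data[None, None] for p in dataset]
    n_items = len(dataset)

    log_file = None
    writer = None
    if train_cfg.log_path:
        log_file = open(train_cfg.log_path, "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(("step",) + LossBreakdown.COLUMNS)

    try:
        for step in range(1, train_cfg.steps + 1):
            idx = [(step - 1) * train_cfg.batch_size + j for j in range(train_cfg.batch_size)]
            idx = [i % n_items for i in idx]
            cond = Tensor(np.concatenate([conds[i] for i in idx], axis=0))
            truth = Tensor(np.concatenate([truths[i] for i in idx], axis=0))

            fake = gen.forward(cond, training=True, rng=rng)

            bd = LossBreakdown()
            if disc is not None:
                real_target = 0.5 if loss_cfg.lsgan_targets == "as_printed" else 1.0
                disc.zero_grad()
                d_real = disc.forward(cond, truth)
                d_fake = disc.forward(cond, fake.detach())
                l_d = _mean_sq(d_real, real_target) + (d_fake * d_fake).mean()
                l_d.backward()
                state.opt_d.step()
                bd.l_d = l_d.item()

            gen.zero_grad()
            l_dist = _distance_t(truth, fake)
            l_feat = _soft_feature_t(truth, fake, loss_cfg)
            l_sim = _similarity_t(truth, fake, loss_cfg)
            l_recon = l_dist + l_feat + l_sim
            if disc is not None:
                real_target = 0.5 if loss_cfg.lsgan_targets == "as_printed" else 1.0
                d_fake2 = disc.forward(cond, fake)
                l_adv = _mean_sq(d_fake2, real_target)
                bd.l_adv_g = l_adv.item()
                l_total = l_adv + loss_cfg.alpha * l_recon
            else:
                bd.l_adv_g = 0.0
                l_total = loss_cfg.alpha * l_recon
            l_total.backward()
            state.opt_g.step()

            bd.l_dist = l_dist.item()
            bd.l_feat = l_feat.item()
            bd.l_sim = l_sim.item()
            bd.l_recon = l_recon.item()
            bd.l_g_total = bd.l_adv_g + loss_cfg.alpha * bd.l_recon
            if disc is None:
                bd.l_d = 0.0
            if not np.isfinite(bd.l_g_total) or not np.isfinite(bd.l_d):
                raise FloatingPointError(f"non-finite loss at step {step}: {bd}")
            state.history.append(bd)
            state.step = step
            if writer is not None:
                writer.writerow(
                    (step,) + tuple(getattr(bd, c) for c in LossBreakdown.COLUMNS)
                )
            if (
                checkpoint_dir
                and train_cfg.checkpoint_every
                and step % train_cfg.checkpoint_every == 0
            ):
                save_checkpoint(state, Path(checkpoint_dir) / f"step{step:06d}")
    finally:
        if log_file is not None:
            log_file.close()
    return state


def generate(state_or_path: Union[TrainState, str, Path], condition: ImageSet) -> Volume:
    """Evaluation-mode generation (dropout off) from a state or checkpoint path."""
    state = (
        state_or_path
        if isinstance(state_or_path, TrainState)
        else load_checkpoint(state_or_path)
    )
    return state.gen.generate(condition)


# ------------------------------------------------------------ checkpointing

def save_checkpoint(state: TrainState, path: Union[str, Path]) -> Path:
    """Write <path>.npz (parameters + Adam moments) and <path>.json (configs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"gen.{k}": v for k, v in state.gen.state_arrays().items()}
    if state.disc is not None:
        arrays.update({f"disc.{k}": v for k, v in state.disc.state_arrays().items()})
    if state.opt_g is not None:
        arrays.update(state.opt_g.state_arrays("opt_g"))
    if state.opt_d is not None:
        arrays.update(state.opt_d.state_arrays("opt_d"))
    np.savez(str(path) + ".npz", **arrays)
    meta = {
        "step": state.step,
        "gen_cfg": dataclasses.asdict(state.gen_cfg),
        "disc_cfg": dataclasses.asdict(state.disc_cfg) if state.disc_cfg else None,
        "loss_cfg": dataclasses.asdict(state.loss_cfg),
        "train_cfg": dataclasses.asdict(state.train_cfg),
    }
    with open(str(path) + ".json", "w") as f:
        json.dump(meta, f, indent=2, default=list)
    return path


def load_checkpoint(path: Union[str, Path]) -> TrainState:
    path = str(path)
    if path.endswith(".npz") or path.endswith(".json"):
        path = path[:-4] if path.endswith(".npz") else path[:-5]
    try:
        with open(path + ".json") as f:
            meta = json.load(f)
        arrays = dict(np.load(path + ".npz"))
    except FileNotFoundError as e:
        raise FileNotFoundError(f"checkpoint not found at {path}(.npz/.json)") from e
    gen_cfg = GeneratorConfig(**_tupled(meta["gen_cfg"]))
    gen = Generator(gen_cfg, seed=0)
    gen.load_state_arrays(
        {k[len("gen.") :]: v for k, v in arrays.items() if k.startswith("gen.")}
    )
    disc = None
    disc_cfg = None
    if meta.get("disc_cfg"):
        disc_cfg = DiscriminatorConfig(**_tupled(meta["disc_cfg"]))
        disc = Discriminator(disc_cfg, seed=0)
        disc.load_state_arrays(
            {k[len("disc.") :]: v for k, v in arrays.items() if k.startswith("disc.")}
        )
    loss_cfg = LossConfig(**_tupled(meta["loss_cfg"]))
    train_cfg = TrainConfig(**_tupled(meta["train_cfg"]))
    state = TrainState(
        gen=gen,
        disc=disc,
        gen_cfg=gen_cfg,
        disc_cfg=disc_cfg,
        loss_cfg=loss_cfg,
        train_cfg=train_cfg,
        step=int(meta["step"]),
        opt_g=_Adam(gen.params, train_cfg.learning_rate, train_cfg.adam_betas),
        opt_d=_Adam(disc.params, train_cfg.learning_rate, train_cfg.adam_betas)
        if disc is not None
        else None,
    )
    if any(k.startswith("opt_g.") for k in arrays):
        state.opt_g.load_state_arrays(arrays, "opt_g")
    if state.opt_d is not None and any(k.startswith("opt_d.") for k in arrays):
        state.opt_d.load_state_arrays(arrays, "opt_d")
    return state


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
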