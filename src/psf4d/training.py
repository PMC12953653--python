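"""Training loop, metrics harness and checkpointing for the restoration model.

Synthetic (phase-1 style) training only: paired samples come from the
package's own degradation pipeline.  Optimization is Adam with cosine
annealing warm restarts (moments (0.9, 0.999), initial learning rate 2e-5,
restarts every 20 epochs, batch size 8 — the training recipe of the imaging
system this package models; epoch count is configurable and defaults to a
desk-scale 5).  All randomness flows from the config's master seed, and
checkpoints carry both model and optimizer state so a resumed run reproduces
an uninterrupted one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .autograd import Tensor
from .degrade import DegradedSample, augment, degrade, psf_set_for, _dihedral
from .dgnet import DegradationGuidedRestorer, NetworkConfig
from .dictionary import PSFDictionary
from .forward_ops import chw_to_hwc, hwc_to_chw
from .losses import total_loss
from .metrics import psnr, ssim
from .specimens import STYLES, generate_specimen

__all__ = [
    "LossWeights", "TrainConfig", "Adam", "cosine_restart_lr",
    "make_dataset", "samples_from_manifest", "train", "TrainResult",
    "evaluate", "bicubic_upsample", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class LossWeights:
    """Composite-loss weights (all >= 0, at least one positive).

    Defaults put the four terms at comparable magnitudes on synthetic
    fixtures: GT fidelity 1, physics 0.5, (1 - MS-SSIM) 0.15, TV 1e-4.
    """

    w_fid: float = 1.0
    w_phys: float = 0.5
    w_ssim: float = 0.15
    w_tv: float = 1e-4

    def __post_init__(self):
        vals = (self.w_fid, self.w_phys, self.w_ssim, self.w_tv)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    beta1: float = 0.9
    beta2: float = 0.999
    lr: float = 2e-5
    restart_period: int = None  # epochs per cosine-annealing restart
    epochs: int = 5
    seed: int = 0
    ssim_levels: int = 4

    def __post_init__(self):
        if self.restart_period is None:
            # reference recipe restarts every 20 epochs; clamp for short runs
            object.__setattr__(self, "restart_period",
                               min(20, max(1, self.epochs)))
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if min(self.batch_size, self.restart_period) < 1:
            raise ValueError("batch_size and restart_period must be >= 1")
        if self.epochs >= 1 and self.restart_period > self.epochs:
            raise ValueError("restart_period must not exceed epochs")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1 and self.lr > 0):
            raise ValueError("invalid optimizer hyperparameters")


def cosine_restart_lr(lr0: float, epoch: int, restart_period: int) -> float:
    """Cosine-annealed learning rate, restarting every ``restart_period`` epochs."""
    t = epoch % restart_period
    return 0.5 * lr0 * (1.0 + math.cos(math.pi * t / restart_period))


class Adam:
    """Adam on a list of named parameters, with serializable state."""

    def __init__(self, named_params, lr: float = 2e-5,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.named_params = list(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.named_params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.named_params}

    def step(self, lr: float = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for name, p in self.named_params:
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {n: v.copy() for n, v in self.m.items()},
                "v": {n: v.copy() for n, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {n: np.asarray(v, dtype=float).copy()
                  for n, v in state["m"].items()}
        self.v = {n: np.asarray(v, dtype=float).copy()
                  for n, v in state["v"].items()}


def make_dataset(dictionary: PSFDictionary, n: int, gt_size: int = 128,
                 seed: int = 0, zoom_levels=None, styles=STYLES,
                 margin: int = 16, with_augment: bool = False) -> list:
    """Generate ``n`` paired samples in memory, round-robin over zoom levels.

    Noise std is drawn uniformly from [2, 10] per sample; deterministic from
    the master seed.
    """
    if zoom_levels is None:
        zoom_levels = dictionary.zoom_levels
    master = np.random.default_rng(seed)
    out = []
    i = 0
    while len(out) < n:
        style = styles[i % len(styles)]
        gt_seed = int(master.integers(0, 2**31 - 1))
        gt = generate_specimen(gt_seed, size=gt_size, style=style)
        beta = zoom_levels[i % len(zoom_levels)]
        sigma = float(master.uniform(2.0, 10.0))
        noise_seed = int(master.integers(0, 2**31 - 1))
        sample = degrade(gt, dictionary, beta=beta, sigma=sigma,
                         seed=noise_seed, margin=margin)
        if with_augment:
            out.extend(augment(sample))
        else:
            out.append(sample)
        i += 1
    return out[:n]


def samples_from_manifest(manifest_csv, dictionary: PSFDictionary) -> list:
    """Reload DegradedSamples from a dataset directory written by build_dataset."""
    from PIL import Image

    path = Path(manifest_csv)
    root = path.parent
    table = pd.read_csv(path)
    out = []
    for row in table.itertuples():
        inp = np.asarray(Image.open(root / f"{row.path}_input.png"),
                         dtype=float) / 255.0
        gt = np.asarray(Image.open(root / f"{row.path}_gt.png"),
                        dtype=float) / 255.0
        psf = psf_set_for(dictionary, row.beta)
        psf = _dihedral(psf, row.transform, axes=(0, 1))
        psf = _dihedral(psf, row.transform, axes=(3, 4))
        out.append(DegradedSample(
            input_y=inp, gt_x=gt, psf_set=np.ascontiguousarray(psf),
            sigma=float(row.sigma), beta=float(row.beta), seed=int(row.seed),
            tile=int(row.tile), margin=int(row.margin), style=row.style))
    return out


@dataclass
class TrainResult:
    model: DegradationGuidedRestorer
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    optimizer_state: dict = None


def _sample_loss(model, sample: DegradedSample, weights: LossWeights,
                 ssim_levels: int):
    y = Tensor(hwc_to_chw(sample.input_y))
    gt = Tensor(hwc_to_chw(sample.gt_x))
    corrected = model.calw.corrected_psf_set(sample.psf_set)
    out, _ = model(y, sample.psf_set, training=True)
    return total_loss(out, gt, y, corrected, weights,
                      tile=sample.tile, margin=sample.margin,
                      ssim_levels=ssim_levels)


def train(model: DegradationGuidedRestorer, samples: list,
          config: TrainConfig = TrainConfig(),
          weights: LossWeights = LossWeights(),
          val_samples: list = None, optimizer: Adam = None,
          start_epoch: int = 0, end_epoch: int = None, log=None) -> TrainResult:
    """Optimize the CALW + DGT parameters end to end on paired samples.

    Per epoch, samples are shuffled (seeded), grouped into batches whose
    gradients are averaged, and one Adam step is taken per batch with the
    cosine-restart learning rate.  A non-finite loss aborts, keeping the last
    finite parameter state.  Returns the per-epoch loss breakdown (and
    validation PSNR/SSIM when ``val_samples`` is given).
    """
    if optimizer is None:
        optimizer = Adam(model.named_parameters(), lr=config.lr,
                         betas=(config.beta1, config.beta2))
    rows = []
    if end_epoch is None:
        end_epoch = config.epochs
    for epoch in range(start_epoch, end_epoch):
        rng = np.random.default_rng(config.seed + 1000 + epoch)
        order = rng.permutation(len(samples))
        lr = cosine_restart_lr(config.lr, epoch, config.restart_period)
        epoch_terms: dict = {}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            model.zero_grad()
            batch_terms: dict = {}
            acc = None
            for idx in batch:
                loss, terms = _sample_loss(model, samples[idx], weights,
                                           config.ssim_levels)
                acc = loss if acc is None else acc + loss
                for k, v in terms.items():
                    batch_terms[k] = batch_terms.get(k, 0.0) + v / len(batch)
            mean_loss = acc * (1.0 / len(batch))
            if not math.isfinite(mean_loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting with the "
                    "last finite parameters")
            mean_loss.backward()
            optimizer.step(lr=lr)
            n_batches += 1
            for k, v in batch_terms.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
        row = {"epoch": epoch, "lr": lr}
        row.update({k: v / n_batches for k, v in epoch_terms.items()})
        if val_samples:
            val = evaluate_samples(model, val_samples)
            row["val_psnr"] = val["psnr_full"]
            row["val_ssim"] = val["ssim_full"]
        rows.append(row)
        if log is not None:
            log(" ".join(f"{k}={v:.6g}" for k, v in row.items()))
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       optimizer_state=optimizer.state_dict())


def bicubic_upsample(img_hwc: np.ndarray, factor: int = 2) -> np.ndarray:
    """Bicubic 2x upsampling baseline (order-3 spline, clipped to [0, 1])."""
    h, w = img_hwc.shape[:2]
    out = _sk_resize(img_hwc, (factor * h, factor * w), order=3,
                     mode="reflect", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def evaluate_samples(model, samples: list) -> dict:
    """Mean PSNR/SSIM of full model, Wiener-only and bicubic baselines."""
    acc = {k: 0.0 for k in ("psnr_full", "ssim_full", "psnr_wiener",
                            "ssim_wiener", "psnr_bicubic", "ssim_bicubic")}
    for s in samples:
        gt = s.gt_x
        full = model.restore(s.input_y, s.psf_set)
        wiener = model.wiener_only(s.input_y, s.psf_set)
        cubic = bicubic_upsample(s.input_y)
        acc["psnr_full"] += psnr(full, gt)
        acc["ssim_full"] += ssim(full, gt)
        acc["psnr_wiener"] += psnr(wiener, gt)
        acc["ssim_wiener"] += ssim(wiener, gt)
        acc["psnr_bicubic"] += psnr(cubic, gt)
        acc["ssim_bicubic"] += ssim(cubic, gt)
    return {k: v / len(samples) for k, v in acc.items()}


def evaluate(model, samples: list, out_csv=None) -> pd.DataFrame:
    """Per-magnification PSNR/SSIM table over an evaluation set.

    Rows: one per magnification level present in ``samples`` with columns for
    the full model, the Wiener-only path and the bicubic-upsampled-input
    baseline, plus the sample count n.
    """
    table = []
    betas = sorted({s.beta for s in samples})
    for beta in betas:
        group = [s for s in samples if s.beta == beta]
        row = {"beta": beta, "n": len(group)}
        row.update(evaluate_samples(model, group))
        table.append(row)
    df = pd.DataFrame(table)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def save_checkpoint(path, model: DegradationGuidedRestorer,
                    optimizer: Adam = None, extra: dict = None) -> None:
    """Single-container checkpoint: named parameter groups + config echo."""
    payload = {f"param/{n}": v for n, v in model.state_dict().items()}
    meta = {"profile": model.config.profile,
            "extra": extra or {}}
    if optimizer is not None:
        state = optimizer.state_dict()
        payload.update({f"adam_m/{n}": v for n, v in state["m"].items()})
        payload.update({f"adam_v/{n}": v for n, v in state["v"].items()})
        meta["adam_t"] = state["t"]
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path, seed: int = 0):
    """Rebuild (model, optimizer_state_or_None, meta) from a checkpoint file."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        params = {k[len("param/"):]: z[k] for k in z.files
                  if k.startswith("param/")}
        adam_m = {k[len("adam_m/"):]: z[k] for k in z.files
                  if k.startswith("adam_m/")}
        adam_v = {k[len("adam_v/"):]: z[k] for k in z.files
                  if k.startswith("adam_v/")}
    model = DegradationGuidedRestorer(NetworkConfig(profile=meta["profile"]),
                                      seed=seed)
    model.load_state_dict(params)
    opt_state = None
    if adam_m:
        opt_state = {"t": meta["adam_t"], "m": adam_m, "v": adam_v}
    return model, opt_state, meta
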