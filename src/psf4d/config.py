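"""YAML configuration loading for the simulator, dataset and training runs."""

from __future__ import annotations

from pathlib import Path

import yaml

from .dgnet import NetworkConfig
from .optics import DEFAULT_POWER_BOUNDS, LiquidLensParams
from .pupil import PupilModel
from .training import LossWeights, TrainConfig

__all__ = ["load_config", "pupil_from_config", "lens_from_config",
           "train_config_from_config", "loss_weights_from_config",
           "network_config_from_config"]


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg)}")
    return cfg


def pupil_from_config(cfg: dict) -> PupilModel:
    sec = cfg.get("pupil", {})
    kwargs = {k: sec[k] for k in
              ("defocus_w", "astig_w", "coma_w", "spherical_w",
               "severity_floor") if k in sec}
    if "chromatic_defocus" in sec:
        kwargs["chromatic_defocus"] = {
            float(k): float(v) for k, v in sec["chromatic_defocus"].items()}
    if "wavelengths" in sec:
        kwargs["wavelengths"] = tuple(float(w) for w in sec["wavelengths"])
    if "beta_range" in sec:
        kwargs["beta_range"] = tuple(float(b) for b in sec["beta_range"])
    return PupilModel(**kwargs)


def lens_from_config(cfg: dict) -> LiquidLensParams:
    sec = cfg["lens"]
    return LiquidLensParams(
        aperture_D=float(sec["aperture_D"]),
        n_conductive=float(sec["n_conductive"]),
        n_nonconductive=float(sec["n_nonconductive"]),
        theta0=float(sec["theta0"]),
        eps_rel=float(sec["eps_rel"]),
        thickness_H=float(sec["thickness_H"]),
        tension_gamma=float(sec["tension_gamma"]),
    )


def power_bounds_from_config(cfg: dict) -> tuple:
    b = cfg.get("power_bounds", DEFAULT_POWER_BOUNDS)
    return (float(b[0]), float(b[1]))


def train_config_from_config(cfg: dict) -> TrainConfig:
    sec = cfg.get("train", {})
    fields = ("batch_size", "beta1", "beta2", "lr", "restart_period",
              "epochs", "seed", "ssim_levels")
    return TrainConfig(**{k: sec[k] for k in fields if k in sec})


def loss_weights_from_config(cfg: dict) -> LossWeights:
    sec = cfg.get("loss", {})
    fields = ("w_fid", "w_phys", "w_ssim", "w_tv")
    return LossWeights(**{k: float(sec[k]) for k in fields if k in sec})


def network_config_from_config(cfg: dict) -> NetworkConfig:
    sec = cfg.get("network", {})
    return NetworkConfig(profile=sec.get("profile", "tiny"))
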