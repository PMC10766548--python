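"""YAML run-configuration loading and object builders for the CLI."""

from __future__ import annotations

from pathlib import Path

import yaml

from .active_learning import ALConfig, Scenario
from .dynamics import ThermostatParams
from .ensemble import TrainingConfig
from .toy_oracles import DoubleWellBond, MuellerBrown, OraclePotential
from .uncertainty_bias import BiasParams

__all__ = [
    "load_config",
    "build_oracle",
    "build_training_config",
    "build_bias_params",
    "build_thermostat",
    "build_al_config",
    "build_scenarios",
]

_ORACLES = {"muller_brown": MuellerBrown, "double_well_bond": DoubleWellBond}


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def build_oracle(cfg: dict) -> OraclePotential:
    block = dict(cfg.get("oracle", {}))
    name = block.pop("name", "muller_brown")
    if name not in _ORACLES:
        raise ValueError(f"unknown oracle {name!r}; choose from {sorted(_ORACLES)}")
    return _ORACLES[name](**block)


def build_training_config(cfg: dict, seed: int = 0) -> TrainingConfig:
    block = dict(cfg.get("training", {}))
    block.setdefault("seed", seed)
    return TrainingConfig(**block)


def build_bias_params(cfg: dict) -> tuple[BiasParams, int]:
    """Returns (BiasParams, active_from_iteration)."""
    block = dict(cfg.get("bias", {}))
    active_from = int(block.pop("active_from_iteration", 15))
    block.pop("target_r", None)  # used by the calibration helper, not BiasParams
    block.setdefault("A", 15.4)
    block.setdefault("B", 0.12)
    return BiasParams(**block), active_from


def build_thermostat(cfg: dict, seed: int = 0) -> ThermostatParams:
    md = cfg.get("md", {})
    return ThermostatParams(
        temperature=float(md.get("temperature", 350.0)),
        friction=float(md.get("friction", 0.01)),
        dt=float(md.get("dt", 1.0)),
        seed=seed,
    )


def build_al_config(cfg: dict, seed: int = 0) -> ALConfig:
    md = cfg.get("md", {})
    al = cfg.get("al", {})
    bias, active_from = build_bias_params(cfg)
    return ALConfig(
        n_sims_per_iteration=int(al.get("n_sims_per_iteration", 16)),
        threshold=float(md.get("threshold", 0.35)),
        max_steps=int(md.get("max_steps", 5_000)),
        dt=float(md.get("dt", 1.0)),
        temperature=float(md.get("temperature", 350.0)),
        friction=float(md.get("friction", 0.01)),
        bias=bias,
        active_from_iteration=active_from,
        n_iterations=int(al.get("n_iterations", 20)),
        seed_pool_size=int(al.get("seed_pool_size", 25)),
        seed=seed,
        store_stride=int(md.get("store_stride", 10)),
    )


def build_scenarios(cfg: dict) -> list[Scenario]:
    out = []
    for block in cfg.get("compare", {}).get("scenarios", []):
        out.append(
            Scenario(
                name=block["name"],
                temperature=float(block["temperature"]),
                bias_active=bool(block.get("bias", False)),
                active_from_iteration=block.get("active_from_iteration"),
            )
        )
    if not out:
        raise ValueError("config has no compare.scenarios block")
    return out
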