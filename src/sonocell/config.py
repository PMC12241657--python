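"""Configuration: packaged defaults, YAML experiment configs, validation."""

from __future__ import annotations

import copy
import importlib.resources
from functools import lru_cache
from pathlib import Path

import yaml

from .acoustics import AcousticContext
from .bubble_dynamics import BubbleParams

__all__ = [
    "load_defaults",
    "load_config",
    "default_free_bubble",
    "default_phagocytosed_bubble",
    "imaging_context",
    "pcd_context",
]


@lru_cache(maxsize=1)
def _defaults() -> dict:
    text = importlib.resources.files("sonocell").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_defaults() -> dict:
    """Deep copy of the packaged default parameter tree."""
    return copy.deepcopy(_defaults())


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults merged with an optional user YAML file."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, user)
    return cfg


def default_free_bubble(cfg: dict | None = None) -> BubbleParams:
    """Free microbubble with the configured shell constants."""
    b = (cfg or _defaults())["bubble"]
    return BubbleParams(
        rest_radius=b["rest_radius_um"] * 1e-6,
        shell_elasticity=b["shell_elasticity"],
        shell_viscosity=b["shell_viscosity"],
        buckling_radius_ratio=b["buckling_radius_ratio"],
        rupture_tension=b["rupture_tension"],
        gas_polytropic_exponent=b["gas_polytropic_exponent"],
        liquid_viscosity=b["liquid_viscosity"],
        compartment="free",
    )


def default_phagocytosed_bubble(cfg: dict | None = None) -> BubbleParams:
    """Phagocytosed microbubble with the calibrated damping multiplier."""
    b = (cfg or _defaults())["bubble"]
    from dataclasses import replace

    return replace(
        default_free_bubble(cfg),
        compartment="phagocytosed",
        intracellular_viscosity_multiplier=b["intracellular_viscosity_multiplier"],
    )


def imaging_context(cfg: dict | None = None) -> AcousticContext:
    a = (cfg or _defaults())["acoustics"]
    return AcousticContext(
        center_frequency=a["imaging"]["center_frequency_mhz"] * 1e6,
        sampling_rate=a["imaging"]["sampling_rate_mhz"] * 1e6,
        sound_speed=a["sound_speed"],
    )


def pcd_context(cfg: dict | None = None) -> AcousticContext:
    a = (cfg or _defaults())["acoustics"]
    return AcousticContext(
        center_frequency=a["pcd"]["center_frequency_mhz"] * 1e6,
        sampling_rate=a["pcd"]["sampling_rate_mhz"] * 1e6,
        sound_speed=a["sound_speed"],
    )
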