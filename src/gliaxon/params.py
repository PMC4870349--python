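"""Physical parameterization of the scar/axon guidance model.

The model is specified in the literature-standard ratio form: one absolute
diffusion coefficient (the attractant's), one characteristic diffusion
distance, and dimensionless ratios for everything else.  This module resolves
that form into absolute constants in a single internal unit system:

* lengths in μm, time in s, concentrations in μM.

Factor indices follow the biology: factor 1 is the attractant (neurotrophic
factors such as NGF released by target cells), factor 2 the inhibitor (CSPGs
carried on the scar surface), factor 3 the promoter (Schwann-cell derived
adhesion/growth molecules).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "BaseConfig",
    "ResolvedParams",
    "resolve_parameters",
    "load_base_config",
    "dump_base_config",
]


class ConfigError(ValueError):
    """Raised when a configuration field is missing, unknown, or out of range."""


@dataclass(frozen=True)
class BaseConfig:
    """Ratio-style model parameters with the baseline defaults.

    Attributes
    ----------
    D1 : attractant diffusion coefficient (μm² s⁻¹).
    lambda_diff : characteristic diffusion distance sqrt(D1/k-1) of the
        attractant (μm); sets the attenuation coefficient k-1.
    Kd : receptor-ligand dissociation constant (nM).
    sigma1 : attractant release rate per target-cell source node (μM s⁻¹).
    eta2, eta3 : basic release-rate ratios σ20/σ1 and σ30/σ1 (dimensionless).
    ratio_D : D1/D2 = D1/D3.
    ratio_k : k-1/k-2 = k-1/k-3.
    lambda1_over_mu : growth-cone mobility λ1/μ (μm s⁻¹ per unit of the
        dimensionless gradient signal p).
    ratio_lambda2 : λ1/(−λ2); the inhibitor coefficient λ2 is negative
        (repulsive), the config takes the conventional positive ratio.
    ratio_lambda3 : λ1/λ3.
    delta_r : growth-cone sampling distance |Δr| (μm), the sensing diameter.
    L : side of the cubic simulation domain (μm).
    """

    D1: float = 100.0
    lambda_diff: float = 1000.0
    Kd: float = 1.0
    sigma1: float = 6.0e-3
    eta2: float = 0.03
    eta3: float = 0.03
    ratio_D: float = 10.0 / 3.0
    ratio_k: float = 3.0e-3
    lambda1_over_mu: float = 1.0
    ratio_lambda2: float = 1.0
    ratio_lambda3: float = 1.0
    delta_r: float = 20.0
    L: float = 6720.0

    def validate(self) -> None:
        for name in (
            "D1",
            "lambda_diff",
            "Kd",
            "sigma1",
            "ratio_D",
            "ratio_k",
            "lambda1_over_mu",
            "ratio_lambda2",
            "ratio_lambda3",
            "delta_r",
            "L",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ConfigError(f"field {name!r} must be a finite number, got {value!r}")
            if value <= 0:
                raise ConfigError(f"field {name!r} must be strictly positive, got {value!r}")
        for name in ("eta2", "eta3"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ConfigError(f"field {name!r} must be a finite number, got {value!r}")
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"field {name!r} must lie in [0, 1], got {value!r}")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ResolvedParams:
    """Absolute physical constants (μm / s / μM internal units).

    ``mob1..mob3`` are the mobilities λi/μ (μm s⁻¹ per unit p); ``mob2`` is
    negative because factor 2 is repulsive.
    """

    D1: float
    D2: float
    D3: float
    k1: float
    k2: float
    k3: float
    sigma1: float
    sigma20: float
    sigma30: float
    Kd: float  # μM
    mob1: float
    mob2: float
    mob3: float
    delta_r: float
    L: float

    @property
    def D(self) -> tuple[float, float, float]:
        return (self.D1, self.D2, self.D3)

    @property
    def k(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)

    @property
    def mob(self) -> tuple[float, float, float]:
        return (self.mob1, self.mob2, self.mob3)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: float) -> "ResolvedParams":
        return dataclasses.replace(self, **kwargs)


def resolve_parameters(cfg: BaseConfig) -> ResolvedParams:
    """Resolve ratio-style parameters into absolute constants.

    The attenuation coefficient of the attractant follows from the
    characteristic diffusion distance, k-1 = D1/λ²; the remaining factors'
    coefficients follow from the configured ratios.  λ2 is stored negative.
    """
    cfg.validate()
    k1 = cfg.D1 / cfg.lambda_diff**2
    D2 = cfg.D1 / cfg.ratio_D
    k2 = k1 / cfg.ratio_k
    mob1 = cfg.lambda1_over_mu
    return ResolvedParams(
        D1=cfg.D1,
        D2=D2,
        D3=D2,
        k1=k1,
        k2=k2,
        k3=k2,
        sigma1=cfg.sigma1,
        sigma20=cfg.eta2 * cfg.sigma1,
        sigma30=cfg.eta3 * cfg.sigma1,
        Kd=cfg.Kd * 1.0e-3,  # nM -> μM
        mob1=mob1,
        mob2=-mob1 / cfg.ratio_lambda2,
        mob3=mob1 / cfg.ratio_lambda3,
        delta_r=cfg.delta_r,
        L=cfg.L,
    )


_FIELDS = {f.name for f in dataclasses.fields(BaseConfig)}


def base_config_from_mapping(mapping: Mapping[str, Any]) -> BaseConfig:
    """Build a :class:`BaseConfig` from a key/value mapping.

    Every field is optional (defaults are the baseline values); unknown keys
    are rejected so that typos do not silently fall back to defaults.
    """
    unknown = sorted(set(mapping) - _FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    cfg = BaseConfig(**{k: float(v) for k, v in mapping.items()})
    cfg.validate()
    return cfg


def load_base_config(path: str) -> BaseConfig:
    """Load a YAML configuration file of :class:`BaseConfig` fields."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return base_config_from_mapping(data)


def dump_base_config(cfg: BaseConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
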