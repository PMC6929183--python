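"""Run configuration: YAML schema, validation and defaults for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

from .synthetic import ToySystemSpec


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


@dataclass(frozen=True)
class BatchConfig:
    k_light_per_s: float = 2.0e-5
    times_h: Tuple[float, ...] = (0.0, 2, 4, 8, 12, 18, 24, 32, 40, 48)
    c0: float = 1.0
    conc_noise_rel: float = 0.0
    delta_noise_permil: float = 0.5
    fit_through_origin: bool = False


@dataclass(frozen=True)
class UmbrellaConfig:
    n_windows: int = 14
    z_min: float = -0.65
    z_max: float = 0.65
    bias_k: float = 150.0
    n_per_window: int = 2000
    profile_form: str = "double-well"
    profile_params: dict = field(
        default_factory=lambda: {"barrier": 6.0, "half_separation": 0.5}
    )
    reactant_range: Tuple[float, float] = (-0.7, -0.3)


@dataclass(frozen=True)
class PIConfig:
    beads: int = 64
    n_classical: int = 2000
    pi_steps_per_config: int = 10

    def __post_init__(self) -> None:
        p = self.beads
        if p < 2 or (p & (p - 1)) != 0:
            raise ConfigError(
                f"bead count must be a power of two (bisection sampling), got {p}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the end-to-end demo pipeline.

    The per-element position bookkeeping (``positions``) carries the number
    of same-element positions in the compound (6 each for C, Cl, H in γ-HCH)
    and the assumed secondary KIE entering the hybrid bulk assembly; the
    primary KIEs are computed, not configured.
    """

    temperature: float = 298.15
    seed: int = 20191126
    output_dir: str = "demo_out"
    toy: ToySystemSpec = field(default_factory=lambda: _default_toy())
    positions: Dict[str, dict] = field(
        default_factory=lambda: {
            "C": {"n": 6, "secondary_kie": 1.0029},
            "Cl": {"n": 6, "secondary_kie": 1.0008},
            "H": {"n": 6, "secondary_kie": 1.0156},
        }
    )
    batch: BatchConfig = field(default_factory=BatchConfig)
    umbrella: UmbrellaConfig = field(default_factory=UmbrellaConfig)
    pi: PIConfig = field(default_factory=PIConfig)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ConfigError(f"temperature must be > 0 K, got {self.temperature}")
        if not isinstance(self.seed, int):
            raise ConfigError("an explicit integer seed is required")
        for el, spec in self.positions.items():
            if spec.get("n", 0) < 1:
                raise ConfigError(f"positions[{el}].n must be >= 1")
            if not spec.get("secondary_kie", 1.0) > 0:
                raise ConfigError(f"positions[{el}].secondary_kie must be > 0")


def _default_toy() -> ToySystemSpec:
    from .synthetic import default_transfer_spec

    return default_transfer_spec(with_chlorine=True)


_TOY_KEYS = {"labels", "masses", "distances", "bond_k", "coupling", "bend_k"}


def _build(section: dict, cls, name: str):
    allowed = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    kwargs = dict(section)
    for key, val in kwargs.items():
        if isinstance(val, list):
            kwargs[key] = tuple(val)
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def validate_config(path) -> RunConfig:
    """Parse, default and schema-check a YAML run configuration.

    Unknown keys are rejected outright — silent typos in a reproducibility
    config are worse than a hard failure.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    kwargs = {}
    for key in ("temperature", "seed", "output_dir", "positions"):
        if key in raw:
            kwargs[key] = raw[key]
    if "toy" in raw:
        toy = dict(raw["toy"])
        unknown = set(toy) - _TOY_KEYS
        if unknown:
            raise ConfigError(f"unknown keys in 'toy': {sorted(unknown)}")
        toy.setdefault("kind", None)
        toy.pop("kind")
        try:
            kwargs["toy"] = ToySystemSpec(
                kind="collinear-transfer",
                labels=tuple(toy["labels"]),
                masses=tuple(toy["masses"]),
                distances=tuple(toy["distances"]),
                bond_k=tuple(toy["bond_k"]),
                coupling=float(toy.get("coupling", 0.0)),
                bend_k=tuple(toy.get("bend_k", ())),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"invalid 'toy' section: {exc}") from exc
    if "batch" in raw:
        kwargs["batch"] = _build(raw["batch"], BatchConfig, "batch")
    if "umbrella" in raw:
        kwargs["umbrella"] = _build(raw["umbrella"], UmbrellaConfig, "umbrella")
    if "pi" in raw:
        kwargs["pi"] = _build(raw["pi"], PIConfig, "pi")
    return _build_run(kwargs)


def _build_run(kwargs: dict) -> RunConfig:
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
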