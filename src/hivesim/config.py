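"""Configuration parsing, replicate seeding, and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .scheme import SchemeConfig

__all__ = ["TraitParams", "parse_config", "seed_replicates", "RunManifest"]

#: parameter bounds of the simulated design space
_BOUNDS = {
    "sister_group_size": (1, 10, "sister group size k_d is simulated for 1..10"),
    "sire_rate_percent": (1, 10, "sire selection rate k_s is simulated for 1..10 percent"),
}


@dataclass(frozen=True)
class TraitParams:
    """Genetic parameters of one selection trait.

    Defaults are the standard honeybee setting: unit maternal variance, direct
    variance 2, moderately negative maternal-direct covariance -0.75
    (correlation -0.53) and unit residual variance.
    """

    n_loci: int = 200
    sigma_am2: float = 1.0
    sigma_ad2: float = 2.0
    sigma_amd: float = -0.75
    sigma_e2: float = 1.0

    def sigma_a(self) -> np.ndarray:
        return np.array(
            [[self.sigma_am2, self.sigma_amd], [self.sigma_amd, self.sigma_ad2]]
        )

    @property
    def r_md(self) -> float:
        return self.sigma_amd / float(np.sqrt(self.sigma_am2 * self.sigma_ad2))

    @property
    def name(self) -> str:
        return f"T{self.n_loci}{self.r_md:+.2f}".replace("+", "")


_TRAIT_KEYS = {f.name for f in dataclasses.fields(TraitParams)}
_SCHEME_KEYS = {f.name for f in dataclasses.fields(SchemeConfig)}


def parse_config(
    source: str | Path | dict | None = None,
    strict: bool = True,
    **overrides,
) -> tuple[SchemeConfig, TraitParams]:
    """Build (SchemeConfig, TraitParams) from a YAML file, dict and overrides.

    All keys are optional and default to the standard setting; unknown keys
    are rejected.  With ``strict=True`` parameters outside the simulated
    design bounds (k_d, k_s in 1..10) raise a descriptive error.
    """
    data: dict = {}
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        data = dict(source)
    data.update(overrides)

    unknown = set(data) - _TRAIT_KEYS - _SCHEME_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    if strict:
        for key, (lo, hi, msg) in _BOUNDS.items():
            if key in data and not lo <= data[key] <= hi:
                raise ValueError(f"{key}={data[key]} out of range: {msg}")

    scheme = SchemeConfig(**{k: v for k, v in data.items() if k in _SCHEME_KEYS})
    trait = TraitParams(**{k: v for k, v in data.items() if k in _TRAIT_KEYS})
    return scheme, trait


def seed_replicates(master_seed: int, n_replicates: int) -> list[np.random.SeedSequence]:
    """Independent, reproducible child streams for replicate runs."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    return np.random.SeedSequence(master_seed).spawn(n_replicates)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    scheme: dict
    trait: dict
    master_seed: int
    n_replicates: int
    version: str = "0.1.0"
    timestamp: str = ""
    r_md: float = 0.0

    @classmethod
    def create(
        cls,
        scheme: SchemeConfig,
        trait: TraitParams,
        master_seed: int,
        n_replicates: int,
    ) -> "RunManifest":
        return cls(
            scheme=dataclasses.asdict(scheme),
            trait=dataclasses.asdict(trait),
            master_seed=int(master_seed),
            n_replicates=int(n_replicates),
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            r_md=trait.r_md,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def reconstruct(self) -> tuple[SchemeConfig, TraitParams, int, int]:
        return (
            SchemeConfig(**self.scheme),
            TraitParams(**self.trait),
            self.master_seed,
            self.n_replicates,
        )
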