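"""Run configuration: stage parameters, seeds, output paths.

One global ``rng_seed`` lives in the config; each stochastic stage derives
its own child seed by hashing ``(rng_seed, stage_name)`` so stages are
reproducible independently of execution order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError

#: Defaults for every stage. Geometry is realistic confocal scale:
#: 0.2 µm pixels, 60 µm ooplasm radius (porcine oocyte ~120 µm across),
#: granule spot sigma 0.25 µm (granules are 0.2-0.6 µm in diameter).
DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "image_size": 680,
        "pixel_size": 0.2,
        "oocyte_radius": 60.0,
        "n_granules": 2000,
        "peripheral_bias": 0.5,
        "granule_sigma": 0.25,
        "granule_amplitude": 60.0,
        "background": 5.0,
        "noise_model": "gaussian",
        "noise_sd": 2.0,
    },
    "segment": {"smoothing_sigma": 4.0, "min_area": 500.0},
    "partition": {"central_fraction": 0.8, "tolerance": 0.02},
    "spots": {"scales": [0.2, 0.25, 0.3], "response_threshold": 10.0},
    "density": {"window_um": 20.0, "n_windows": 3},
    "stats": {"alpha": 0.05, "variant": "pooled"},
    "de": {"fold_threshold": 2.0, "p_threshold": 0.05},
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed for a stage, independent of other stages."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Stage parameters keyed by stage name, plus the global seed and paths."""

    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    rng_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        merged = {k: dict(v) for k, v in DEFAULTS.items()}
        for stage, params in self.stages.items():
            merged.setdefault(stage, {}).update(params)
        self.stages = merged
        cf = self.stages["partition"]["central_fraction"]
        if not 0.0 < cf < 1.0:
            raise ValidationError(f"central_fraction must be in (0,1), got {cf}")
        alpha = self.stages["stats"]["alpha"]
        if not 0.0 < alpha < 1.0:
            raise ValidationError(f"alpha must be in (0,1), got {alpha}")

    def __getitem__(self, stage: str) -> dict[str, Any]:
        return self.stages[stage]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.rng_seed, stage)

    def to_dict(self) -> dict[str, Any]:
        return {"stages": self.stages, "rng_seed": self.rng_seed, "out_dir": self.out_dir}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            stages=raw.get("stages", {}),
            rng_seed=int(raw.get("rng_seed", 0)),
            out_dir=raw.get("out_dir", "results"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
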