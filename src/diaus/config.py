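"""Run configuration: YAML-backed parameter blocks with validation.

A :class:`RunConfig` collects every tunable of the pipeline stages plus the
seed and output directory.  Outputs embed the configuration hash and seed so
any result file can be traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from diaus.attenuation import AttenuationConfig
from diaus.mmode import (
    DEFAULT_MIN_PROMINENCE_MM,
    DEFAULT_MIN_SEPARATION_S,
    DEFAULT_SMOOTH_WINDOW_S,
)


@dataclass(frozen=True)
class MModeConfig:
    min_prominence_mm: float = DEFAULT_MIN_PROMINENCE_MM
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S
    baseline: str = "per_breath"  # or global_median

    def __post_init__(self) -> None:
        if self.min_prominence_mm <= 0 or self.min_separation_s <= 0:
            raise ValueError("detection parameters must be positive")
        if self.baseline not in ("per_breath", "global_median"):
            raise ValueError(f"unknown baseline mode {self.baseline!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, resolvable from a YAML file."""

    out_dir: Path = Path("diaus_out")
    seed: int = 0
    alpha: float = 0.05
    delta_mode: str = "means"  # or per_animal
    attenuation: AttenuationConfig = field(default_factory=AttenuationConfig)
    mmode: MModeConfig = field(default_factory=MModeConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta_mode not in ("means", "per_animal"):
            raise ValueError(f"unknown delta mode {self.delta_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        att = AttenuationConfig(**raw.pop("attenuation", {}))
        mm = MModeConfig(**raw.pop("mmode", {}))
        return cls(attenuation=att, mmode=mm, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d

    def config_hash(self) -> str:
        """Short stable hash of the analysis parameters.

        Paths are excluded: two runs with identical parameters and seed are
        the same analysis wherever their outputs land.
        """
        params = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance_header(self) -> str:
        """Comment line embedded at the top of every output CSV."""
        return f"# diaus config_hash={self.config_hash()} seed={self.seed}\n"


def write_csv_with_provenance(df, path: Path, config: RunConfig) -> None:
    """Write a DataFrame CSV prefixed with the provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(config.provenance_header())
        df.to_csv(fh, index=False)
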