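"""Pipeline configuration, serializable losslessly to YAML or JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Knobs for the portrayal pipeline.

    grid_rows/grid_cols : SOM grid size (paper-scale landscapes use 50x50).
    epochs              : batch-SOM training epochs.
    final_radius        : Gaussian neighborhood radius at the last epoch.
    spot_quantile       : summary-map quantile above which pixels are spot
                          candidates. 0.98 suits a 50x50 landscape of real
                          data where over-expression spots cover a small map
                          fraction; planted synthetic cohorts use a quantile
                          matched to the planted module share (see
                          ``pipeline.synthetic_spot_quantile``).
    min_spot_size       : smallest retained spot, in pixels.
    pat_quantile        : per-sample portrait quantile a spot must exceed to
                          count as activated in the PAT label.
    total_samples       : cohort size for the synthetic generator.
    """

    grid_rows: int = 50
    grid_cols: int = 50
    epochs: int = 20
    final_radius: float = 1.0
    spot_quantile: float = 0.98
    min_spot_size: int = 3
    pat_quantile: float = 0.90
    quantile_normalize: bool = False
    impute_missing: bool = False
    total_samples: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid must have at least 4 pixels")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.final_radius <= 0:
            raise ValueError("final_radius must be positive")
        for name in ("spot_quantile", "pat_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
        if self.min_spot_size < 1:
            raise ValueError("min_spot_size must be >= 1")
        if self.total_samples < 1:
            raise ValueError("total_samples must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)
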