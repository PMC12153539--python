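"""Flat run configuration with YAML round-trip and override merging.

Every random operation in a run traces back to the single ``seed`` field
(stage seeds are derived from it by fixed offsets), and the effective
configuration is serialised verbatim into every output directory so a run
can be reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # run
    seed: int = 0
    out_dir: str = "runs/demo"
    # synthetic cohort (demo / synth subcommand)
    cohort: str = "omentum"
    n_benign_train: int = 14
    n_malignant_train: int = 14
    n_benign_holdout: int = 6
    n_malignant_holdout: int = 6
    canvas_px: int = 768
    mpp: float = 1.0
    n_tissue_blobs: int = 3
    focus_diameter_min_um: float = 120.0
    focus_diameter_max_um: float = 350.0
    # segmentation
    sat_threshold: float = 8.0 / 255.0
    min_region_area_px: int = 16
    closing_radius_px: int = 2
    mask_downsample: int = 16
    # patching
    patch_size_level0: int = 256
    out_size: int = 64
    min_tissue_frac: float = 0.5
    # features
    extractor_id: str = "toy-v1"
    # model / training
    learning_rate: float = 2e-4
    weight_decay: float = 1e-5
    dropout: float = 0.25
    max_epochs: int = 150
    patience: int = 20
    min_epochs: int = 40
    # evaluation
    k_folds: int = 5
    n_bootstrap: int = 2000
    # heatmap
    heatmap_alpha: float = 0.4
    heatmap_cmap: str = "coolwarm"
    n_heatmaps: int = 2

    def __post_init__(self) -> None:
        if self.patch_size_level0 % self.out_size != 0:
            raise ValueError("patch_size_level0 must be a multiple of out_size")
        if self.seed < 0 or self.seed >= 2**31 - 10_000:
            raise ValueError("seed must be a small non-negative integer")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.merged(data, overrides)

    @classmethod
    def merged(cls, *mappings) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        merged: dict = {}
        for m in mappings:
            for key, value in (m or {}).items():
                if value is None:
                    continue
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                merged[key] = value
        return cls(**merged)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
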