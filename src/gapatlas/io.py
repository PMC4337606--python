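"""File formats and run provenance.

Tidy TSV is the interchange format for all tables. Every file written by
the pipeline starts with a provenance header (package version, config
hash, seed) in ``#``-prefixed comment lines, so a result can always be
traced to the configuration that produced it. Images are TIFF or PNG with
the mask as a companion image (same stem, ``_mask`` suffix).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__version__ = "0.1.0"

__all__ = [
    "PipelineConfig",
    "write_tsv",
    "read_tsv",
    "write_image",
    "read_image",
    "mask_path_for",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the pipeline, with their defaults.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    strip_fraction: float = 0.10
    n_bins: int = 100
    background_pct: float = 5.0
    scale_pct: float = 95.0
    min_amplitude: float = 0.2
    min_width: float = 3.0
    mad_multiplier: float = 1.5
    envelope_k: float = 2.0
    strong_severity: float = 5.0
    weak_severity: float = 2.0
    min_penetrance: float = 25.0
    strong_penetrance: float = 50.0
    absent_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.strip_fraction <= 0.5):
            raise ValueError("strip_fraction must lie in (0, 0.5]")
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if not (0 <= self.background_pct < self.scale_pct <= 100):
            raise ValueError("need 0 <= background_pct < scale_pct <= 100")
        for name in ("min_amplitude", "min_width", "mad_multiplier",
                     "envelope_k", "strong_severity", "weak_severity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.min_penetrance <= self.strong_penetrance <= 100):
            raise ValueError(
                "need 0 <= min_penetrance <= strong_penetrance <= 100")
        if not (0.0 <= self.absent_threshold <= 1.0):
            raise ValueError("absent_threshold must lie in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(config: PipelineConfig | None, seed: int | None) -> list[str]:
    lines = [f"# gapatlas {__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config.hash}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig | None = None,
              seed: int | None = None, float_format: str = "%.4f") -> Path:
    """Write a table as TSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  lineterminator="\n")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def mask_path_for(image_path) -> Path:
    p = Path(image_path)
    return p.with_name(p.stem + "_mask" + p.suffix)


def write_image(image: np.ndarray, path) -> Path:
    """Write a 2-D array as TIFF (float32) or PNG (8-bit, [0, 1.2] scaled)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    elif path.suffix.lower() == ".png":
        from PIL import Image
        scaled = np.clip(np.asarray(image, float) / 1.2, 0, 1) * 255
        Image.fromarray(scaled.astype(np.uint8)).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix.lower() == ".png":
        from PIL import Image
        return np.asarray(Image.open(path), dtype=float) / 255.0 * 1.2
    raise ValueError(f"unsupported image format {path.suffix!r}")
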