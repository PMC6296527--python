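"""File formats: grayscale images, outline annotations, score tables, config.

Conventions (stated in every annotation file): pixel coordinates are 0-based
with origin at the top-left, ``x`` = column, ``y`` = row.  CSV artifacts are
comma-separated UTF-8 with ``.`` decimal and empty fields for missing values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import HemicryptOutline

__all__ = [
    "PipelineConfig",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "write_segment_scores",
    "read_segment_scores",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline-wide settings, loadable from a YAML file."""

    n_segments: int = 50
    upper_zone_fraction: float = 0.4
    ci_level: float = 0.95
    confounder_threshold: float = 0.10
    background_mode: str = "annotation_region"  # or "explicit_value"
    background_intensity: float | None = None
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.upper_zone_fraction < 1:
            raise ValueError("upper_zone_fraction must be in (0, 1)")
        if self.n_segments < 1:
            raise ValueError("n_segments must be positive")
        split = self.n_segments * self.upper_zone_fraction
        if abs(split - round(split)) > 1e-9:
            raise ValueError(
                "n_segments * upper_zone_fraction must be an integer "
                f"(got {split})"
            )
        if self.background_mode not in ("annotation_region", "explicit_value"):
            raise ValueError("background_mode must be annotation_region or explicit_value")
        if self.background_mode == "explicit_value" and (
            self.background_intensity is None or self.background_intensity <= 0
        ):
            raise ValueError("explicit_value background mode needs a positive background_intensity")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8/16-bit TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel image, got shape {arr.shape}")
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray, dtype: str = "uint16") -> None:
    """Write a float image as 8- or 16-bit grayscale (values clipped)."""
    path = Path(path)
    info = np.iinfo(dtype)
    arr = np.clip(np.round(image), info.min, info.max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


_COORD_NOTE = "0-based pixel coordinates, origin top-left, x=column, y=row"


def write_annotations(
    path: str | Path,
    outlines: list[HemicryptOutline],
    background_region: list[tuple[int, int]] | None = None,
) -> None:
    """Write hemicrypt outlines (and optional background pixels) as JSON."""
    payload = {
        "coordinate_convention": _COORD_NOTE,
        "hemicrypts": [
            {
                "hemicrypt_id": o.hemicrypt_id,
                "image_id": o.image_id,
                "marker_id": o.marker_id,
                "vertices": [[x, y] for x, y in o.vertices],
                "base_range": list(o.base_range),
                "apex_range": list(o.apex_range),
            }
            for o in outlines
        ],
    }
    if background_region is not None:
        payload["background_region"] = [[int(r), int(c)] for r, c in background_region]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations(path: str | Path) -> tuple[list[HemicryptOutline], list[tuple[int, int]] | None]:
    """Read an annotation JSON; returns (outlines, background_region or None)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    outlines = []
    for i, rec in enumerate(payload.get("hemicrypts", [])):
        try:
            outlines.append(
                HemicryptOutline(
                    vertices=tuple((float(x), float(y)) for x, y in rec["vertices"]),
                    base_range=tuple(rec["base_range"]),
                    apex_range=tuple(rec["apex_range"]),
                    hemicrypt_id=str(rec.get("hemicrypt_id", f"h{i}")),
                    image_id=str(rec.get("image_id", "")),
                    marker_id=str(rec.get("marker_id", "other")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad hemicrypt record #{i}: {exc}") from exc
    bg = payload.get("background_region")
    if bg is not None:
        bg = [(int(r), int(c)) for r, c in bg]
    return outlines, bg


def write_segment_scores(path: str | Path, profiles) -> None:
    """Segment-score CSV: hemicrypt_id, marker_id, segment_index (1..n then
    'whole'), od."""
    rows = []
    for p in profiles:
        for k, od in enumerate(p.od_segments, start=1):
            rows.append((p.hemicrypt_id, p.marker_id, str(k), od))
        rows.append((p.hemicrypt_id, p.marker_id, "whole", p.od_whole))
    df = pd.DataFrame(rows, columns=["hemicrypt_id", "marker_id", "segment_index", "od"])
    df.to_csv(path, index=False)


def read_segment_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"segment_index": str})
    needed = {"hemicrypt_id", "marker_id", "segment_index", "od"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: segment score CSV missing columns {sorted(missing)}")
    return df
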