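"""Slide container and manifest I/O.

A slide here is a single-level 8-bit RGB raster with a physical pixel size
(microns per pixel, mpp) and an optional slide-level label.  Real
whole-slide images are stored as multi-resolution pyramids; this package
works from the base level and derives coarser views on the fly by block
averaging, which is sufficient for the synthetic study and keeps the
container trivially portable (plain PNG/TIFF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._utils import block_mean, to_uint8

#: the two slide-level classes, in canonical order
LABELS = ("benign", "metastatic")

#: required manifest columns, in file order
MANIFEST_COLUMNS = ("slide_id", "case_id", "cohort", "label", "mpp", "path")


@dataclass
class SlideImage:
    """An RGB slide raster plus resolution metadata and optional label.

    Attributes
    ----------
    slide_id : str
        Unique identifier of the slide.
    image : np.ndarray
        ``(H, W, 3)`` uint8 RGB raster at level 0.
    mpp : float
        Microns per pixel at level 0.
    label : str or None
        Slide-level class, one of :data:`LABELS`, if known.
    """

    slide_id: str
    image: np.ndarray
    mpp: float
    label: str | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(
                f"slide {self.slide_id!r}: expected (H, W, 3) RGB raster, "
                f"got shape {img.shape}"
            )
        if img.dtype != np.uint8:
            raise ValueError(f"slide {self.slide_id!r}: raster must be uint8")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in level-0 pixels."""
        return self.image.shape[:2]

    def thumbnail(self, downsample: int) -> np.ndarray:
        """Block-averaged uint8 RGB view at the given integer downsample."""
        return to_uint8(block_mean(self.image, downsample))

    def save(self, path: str | Path) -> Path:
        """Write the raster as 8-bit RGB (format chosen from the suffix)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(self.image).save(path)
        return path

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        mpp: float,
        slide_id: str | None = None,
        label: str | None = None,
    ) -> "SlideImage":
        """Load a slide raster from a PNG/TIFF file."""
        path = Path(path)
        img = np.asarray(Image.open(path).convert("RGB"))
        return cls(slide_id or path.stem, img, mpp, label)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a slide manifest CSV.

    The manifest is the tabular entry point of the pipeline: one row per
    slide with columns ``slide_id,case_id,cohort,label,mpp,path``.
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "case_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest {path} contains unknown labels: {sorted(bad)}")
    if df["slide_id"].duplicated().any():
        raise ValueError(f"manifest {path} contains duplicate slide ids")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)
    return path
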