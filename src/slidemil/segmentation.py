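"""Tissue segmentation and non-overlapping patch extraction.

Tissue is separated from the near-white slide background by thresholding
HSV saturation on a block-averaged view of the slide (background glass is
essentially unsaturated; stained tissue is not), followed by light
morphological cleanup.  Patches are then enumerated on a fixed grid of
non-overlapping ``patch_size_level0``-pixel boxes anchored at the origin,
keeping only boxes with enough tissue, and each retained box is read back
at a 4x linear downsample (1024 px at full resolution -> 256 px working
patches, i.e. 40x optical -> 10x apparent magnification for a real scan).

Defaults the underlying literature leaves unstated are declared here:
saturation threshold 8/255 (the CLAM-lineage convention), median blur of
radius 2 at mask resolution before thresholding, minimum patch tissue
fraction 0.5, mask computed at a 16x downsample, and partial edge boxes
discarded rather than padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk, remove_small_objects

from ._utils import block_mean, to_uint8
from .slide import SlideImage

DEFAULT_SAT_THRESHOLD = 8.0 / 255.0
DEFAULT_MASK_DOWNSAMPLE = 16


@dataclass
class TissueMask:
    """Binary tissue mask at an integer downsample from level 0."""

    mask: np.ndarray
    downsample: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    @property
    def tissue_fraction(self) -> float:
        """Fraction of mask pixels classified as tissue."""
        return float(self.mask.mean())

    def save(self, path: str | Path) -> Path:
        from PIL import Image

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.where(self.mask, 255, 0).astype(np.uint8)).save(path)
        return path

    @classmethod
    def from_file(cls, path: str | Path, downsample: int) -> "TissueMask":
        from PIL import Image

        return cls(np.asarray(Image.open(path).convert("L")) > 127, downsample)


@dataclass
class PatchSet:
    """Grid-aligned non-overlapping patch coordinates for one slide.

    ``coords`` holds 0-based level-0 top-left corners of half-open boxes
    ``[x, x+patch_size) x [y, y+patch_size)``; every retained box lies
    fully inside the slide and met the tissue-fraction rule at build time.
    """

    slide_id: str
    patch_size_level0: int = 1024
    out_size: int = 256
    coords: list[tuple[int, int]] = field(default_factory=list)
    min_tissue_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.patch_size_level0 < 1 or self.out_size < 1:
            raise ValueError("patch sizes must be positive")
        if self.patch_size_level0 % self.out_size != 0:
            raise ValueError(
                f"patch_size_level0 ({self.patch_size_level0}) must be a "
                f"positive multiple of out_size ({self.out_size})"
            )
        self.coords = [(int(x), int(y)) for x, y in self.coords]
        if len(set(self.coords)) != len(self.coords):
            raise ValueError("duplicate patch coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def downsample(self) -> int:
        """Linear downsample applied when reading a patch (level0 -> out)."""
        return self.patch_size_level0 // self.out_size

    def save(self, path: str | Path) -> Path:
        """Persist coordinates as CSV plus a JSON parameter sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "x": [c[0] for c in self.coords],
                "y": [c[1] for c in self.coords],
                "patch_size_level0": self.patch_size_level0,
                "out_size": self.out_size,
            }
        ).to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "slide_id": self.slide_id,
                    "patch_size_level0": self.patch_size_level0,
                    "out_size": self.out_size,
                    "min_tissue_frac": self.min_tissue_frac,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PatchSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        coords = list(zip(df["x"].astype(int), df["y"].astype(int)))
        return cls(
            slide_id=meta["slide_id"],
            patch_size_level0=int(meta["patch_size_level0"]),
            out_size=int(meta["out_size"]),
            coords=coords,
            min_tissue_frac=float(meta["min_tissue_frac"]),
        )


def segment_tissue(
    slide: SlideImage,
    sat_threshold: float = DEFAULT_SAT_THRESHOLD,
    min_region_area_px: int = 16,
    closing_radius_px: int = 2,
    downsample: int = DEFAULT_MASK_DOWNSAMPLE,
) -> TissueMask:
    """Segment tissue from background by saturation thresholding.

    The slide is block-averaged by ``downsample``, converted to HSV, and a
    pixel is called tissue iff its saturation exceeds ``sat_threshold``
    (after a radius-2 median blur).  Morphological closing with a disk of
    ``closing_radius_px`` bridges small gaps, and connected components
    smaller than ``min_region_area_px`` (at mask resolution) are dropped.
    """
    if not 0.0 <= sat_threshold <= 1.0:
        raise ValueError("sat_threshold must lie in [0, 1]")
    small = block_mean(slide.image, downsample) / 255.0
    sat = rgb2hsv(small)[..., 1]
    sat = ndimage.median_filter(sat, footprint=disk(2))
    mask = sat > sat_threshold
    if closing_radius_px > 0:
        mask = closing(mask, disk(closing_radius_px))
    if min_region_area_px > 1:
        # drop connected components with area < min_region_area_px
        mask = remove_small_objects(mask, max_size=min_region_area_px - 1)
    return TissueMask(mask, downsample)


def _box_tissue_fraction(mask: TissueMask, x: int, y: int, size: int) -> float:
    ds = mask.downsample
    x0, x1 = x // ds, max(x // ds + 1, (x + size) // ds)
    y0, y1 = y // ds, max(y // ds + 1, (y + size) // ds)
    sub = mask.mask[y0:y1, x0:x1]
    if sub.size == 0:
        return 0.0
    return float(sub.mean())


def extract_patch_grid(
    slide: SlideImage,
    mask: TissueMask,
    patch_size_level0: int = 1024,
    out_size: int = 256,
    min_tissue_frac: float = 0.5,
) -> PatchSet:
    """Enumerate the non-overlapping tissue patch grid of a slide.

    The grid is anchored at (0, 0) with stride ``patch_size_level0``;
    boxes extending past the slide bounds are discarded, and a box is
    retained iff its tissue fraction on *mask* is at least
    ``min_tissue_frac``.
    """
    h, w = slide.shape
    coords = [
        (x, y)
        for y in range(0, h - patch_size_level0 + 1, patch_size_level0)
        for x in range(0, w - patch_size_level0 + 1, patch_size_level0)
        if _box_tissue_fraction(mask, x, y, patch_size_level0) >= min_tissue_frac
    ]
    return PatchSet(
        slide_id=slide.slide_id,
        patch_size_level0=patch_size_level0,
        out_size=out_size,
        coords=coords,
        min_tissue_frac=min_tissue_frac,
    )


def read_patch(
    slide: SlideImage,
    coord: tuple[int, int],
    patch_size_level0: int = 1024,
    out_size: int = 256,
) -> np.ndarray:
    """Read one patch at level 0 and area-average it down to ``out_size``.

    Returns an ``(out_size, out_size, 3)`` uint8 raster.  Deterministic:
    the downsample is a plain block mean, rounded once at the end.
    """
    if patch_size_level0 % out_size != 0:
        raise ValueError("patch_size_level0 must be a multiple of out_size")
    x, y = int(coord[0]), int(coord[1])
    h, w = slide.shape
    if x < 0 or y < 0 or x + patch_size_level0 > w or y + patch_size_level0 > h:
        raise ValueError(
            f"patch at ({x}, {y}) size {patch_size_level0} out of bounds "
            f"for slide of shape {(h, w)}"
        )
    region = slide.image[y : y + patch_size_level0, x : x + patch_size_level0]
    factor = patch_size_level0 // out_size
    return to_uint8(block_mean(region, factor))
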