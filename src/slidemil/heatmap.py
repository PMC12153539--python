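"""Attention heatmaps: overlapping-patch scoring, blending and overlay.

For visualisation the slide is re-tiled with 50% overlap (stride = half
the level-0 patch size) so attention varies smoothly, every tissue patch
is scored by the model's attention head computed over the full overlapping
patch set, and scores are converted to within-slide percentile ranks —
raw softmax attention scales as 1/N and is incomparable across slides.
Each thumbnail pixel then receives the mean rank of all patches covering
it, and the raster is colour-mapped red (high attention) to blue (low)
and alpha-composited over the slide thumbnail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image
from scipy.stats import rankdata

from ._utils import to_uint8
from .features import Extractor, FeatureBag, TOY_EXTRACTOR, extract_features
from .model import AbmilParams, attention_weights
from .segmentation import PatchSet, TissueMask, _box_tissue_fraction
from .slide import SlideImage

DEFAULT_ALPHA = 0.4
DEFAULT_CMAP = "coolwarm"  # low -> blue, high -> red
DEFAULT_THUMB_DOWNSAMPLE = 16


@dataclass
class HeatmapOverlay:
    """A blended attention raster and its rendered overlay.

    ``raster`` holds per-pixel mean attention percentile ranks in [0, 1]
    (NaN where no patch covers the pixel); ``overlay`` is the composited
    uint8 RGB image, same shape as the thumbnail.
    """

    raster: np.ndarray
    overlay: np.ndarray
    downsample: int
    alpha: float
    norm_bounds: tuple[float, float]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(self.overlay).save(path)
        return path


def overlapping_patch_grid(
    slide: SlideImage,
    mask: TissueMask,
    patch_size_level0: int = 1024,
    out_size: int = 256,
    min_tissue_frac: float = 0.5,
) -> PatchSet:
    """Enumerate the 50%-overlap grid (stride = patch_size_level0 // 2)."""
    stride = patch_size_level0 // 2
    h, w = slide.shape
    coords = [
        (x, y)
        for y in range(0, h - patch_size_level0 + 1, stride)
        for x in range(0, w - patch_size_level0 + 1, stride)
        if _box_tissue_fraction(mask, x, y, patch_size_level0) >= min_tissue_frac
    ]
    return PatchSet(
        slide_id=slide.slide_id,
        patch_size_level0=patch_size_level0,
        out_size=out_size,
        coords=coords,
        min_tissue_frac=min_tissue_frac,
    )


def score_overlapping_patches(
    model: AbmilParams | list[AbmilParams],
    slide: SlideImage,
    mask: TissueMask,
    patch_size_level0: int = 1024,
    out_size: int = 256,
    min_tissue_frac: float = 0.5,
    extractor: Extractor = TOY_EXTRACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention scores on the 50%-overlap tissue patch grid.

    Returns ``(coords, scores)`` where scores is the attention weight
    vector over the overlapping patch set (non-negative, sums to 1).  For
    an ensemble the member attention vectors are averaged and renormalised.
    """
    patches = overlapping_patch_grid(
        slide, mask, patch_size_level0, out_size, min_tissue_frac
    )
    if len(patches) == 0:
        raise ValueError(f"slide {slide.slide_id!r}: no tissue patches to score")
    bag = extract_features(slide, patches, extractor)
    members = model if isinstance(model, list) else [model]
    att = np.mean([attention_weights(m, bag) for m in members], axis=0)
    att = att / att.sum()
    return np.asarray(patches.coords, dtype=np.int64), att


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Within-slide percentile rank of each score, in (0, 1); ties share
    their average rank."""
    scores = np.asarray(scores, dtype=np.float64)
    return (rankdata(scores, method="average") - 0.5) / len(scores)


def blend_scores(
    coords: np.ndarray,
    scores: np.ndarray,
    downsample: int,
    slide_shape: tuple[int, int],
    patch_size_level0: int,
) -> np.ndarray:
    """Per-pixel average of all covering patches' scores, at ``downsample``.

    Pixels covered by no patch are NaN (rendered transparent downstream).
    """
    coords = np.asarray(coords)
    scores = np.asarray(scores, dtype=np.float64)
    if len(coords) == 0:
        raise ValueError("need at least one scored patch")
    if len(coords) != len(scores):
        raise ValueError("coords and scores must align")
    h, w = slide_shape
    hd, wd = h // downsample, w // downsample
    total = np.zeros((hd, wd))
    cover = np.zeros((hd, wd))
    for (x, y), s in zip(coords, scores):
        x0, y0 = int(x) // downsample, int(y) // downsample
        x1 = min(wd, (int(x) + patch_size_level0) // downsample)
        y1 = min(hd, (int(y) + patch_size_level0) // downsample)
        total[y0:y1, x0:x1] += s
        cover[y0:y1, x0:x1] += 1.0
    with np.errstate(invalid="ignore"):
        raster = np.where(cover > 0, total / np.maximum(cover, 1.0), np.nan)
    return raster


def render_overlay(
    raster: np.ndarray,
    thumbnail: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    cmap: str = DEFAULT_CMAP,
    downsample: int = DEFAULT_THUMB_DOWNSAMPLE,
) -> HeatmapOverlay:
    """Colour-map the attention raster and composite it on the thumbnail.

    Finite raster values are min-max normalised (the bounds are recorded
    on the overlay), mapped through a blue-to-red colormap and blended
    with weight ``alpha``; uncovered (NaN) pixels keep the thumbnail.
    """
    raster = np.asarray(raster, dtype=np.float64)
    thumbnail = np.asarray(thumbnail)
    if raster.shape != thumbnail.shape[:2]:
        raise ValueError(
            f"raster shape {raster.shape} does not match thumbnail "
            f"{thumbnail.shape[:2]}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    finite = np.isfinite(raster)
    if finite.any():
        vmin = float(np.nanmin(raster))
        vmax = float(np.nanmax(raster))
    else:
        vmin = vmax = 0.0
    span = vmax - vmin
    norm = np.where(finite, (raster - vmin) / span if span > 0 else 0.5, 0.0)
    colour = matplotlib.colormaps[cmap](np.clip(norm, 0.0, 1.0))[..., :3] * 255.0
    out = thumbnail.astype(np.float64).copy()
    out[finite] = (1.0 - alpha) * out[finite] + alpha * colour[finite]
    return HeatmapOverlay(
        raster=np.where(finite, norm, np.nan),
        overlay=to_uint8(out),
        downsample=downsample,
        alpha=alpha,
        norm_bounds=(vmin, vmax),
    )


def heatmap_for_slide(
    model: AbmilParams | list[AbmilParams],
    slide: SlideImage,
    mask: TissueMask,
    patch_size_level0: int = 1024,
    out_size: int = 256,
    min_tissue_frac: float = 0.5,
    extractor: Extractor = TOY_EXTRACTOR,
    downsample: int = DEFAULT_THUMB_DOWNSAMPLE,
    alpha: float = DEFAULT_ALPHA,
    cmap: str = DEFAULT_CMAP,
) -> HeatmapOverlay:
    """End-to-end heatmap: overlapping scoring -> percentile ranks ->
    blending -> overlay on the slide thumbnail."""
    coords, scores = score_overlapping_patches(
        model, slide, mask, patch_size_level0, out_size, min_tissue_frac, extractor
    )
    raster = blend_scores(
        coords, percentile_ranks(scores), downsample, slide.shape, patch_size_level0
    )
    return render_overlay(raster, slide.thumbnail(downsample), alpha, cmap, downsample)
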