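"""Patch feature extraction behind a pluggable extractor contract.

The slide classifier never sees pixels — only a bag of fixed-length patch
feature vectors.  In production pipelines those vectors come from a
pretrained histopathology encoder (e.g. a self-supervised foundation
model); such encoders are deliberately kept behind the :class:`Extractor`
interface so they can be plugged in without touching the rest of the
pipeline.  The package ships one concrete extractor, a deterministic
hand-crafted colour/texture descriptor (:func:`toy_descriptor`, 62
dimensions), which is sufficient to separate the synthetic generator's
tumour texture from plain tissue and lets every downstream stage be tested
end to end with no pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import sobel

from ._utils import block_mean
from .segmentation import PatchSet, read_patch
from .slide import SlideImage

#: grey level below which a pixel counts towards the dark-nucleus fraction
DARK_GREY_THRESHOLD = 0.35

TOY_EXTRACTOR_ID = "toy-v1"
TOY_FEATURE_DIM = 62


@dataclass
class FeatureBag:
    """The MIL bag: per-patch feature vectors with aligned coordinates.

    ``features`` is ``(N, D)``; row *i* describes the patch whose level-0
    top-left corner is ``coords[i]``.  ``witness_idx`` is an optional
    ground-truth annotation used only by the synthetic bag generator.
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    extractor_id: str
    witness_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(
                f"bag {self.slide_id!r}: features must be a non-empty (N, D) "
                f"matrix, got shape {self.features.shape}"
            )
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError(
                f"bag {self.slide_id!r}: coords must be (N, 2) aligned with "
                f"features"
            )
        if not np.isfinite(self.features).all():
            raise ValueError(f"bag {self.slide_id!r}: non-finite feature values")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class Extractor:
    """A patch-feature extractor: identifier, output dimension and the
    patch -> vector map.  The contract: same raster in, same vector out,
    and the dimension never varies for a given ``extractor_id``."""

    extractor_id: str
    feature_dim: int
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        v = np.asarray(self.fn(patch), dtype=np.float64).ravel()
        if v.shape != (self.feature_dim,):
            raise ValueError(
                f"extractor {self.extractor_id!r} produced {v.shape[0]} "
                f"components, expected {self.feature_dim}"
            )
        return v


def toy_descriptor(patch: np.ndarray) -> np.ndarray:
    """Deterministic 62-component colour/texture descriptor of a patch.

    Components, in order:

    ==========  =============================================================
    0–5         per-channel mean and standard deviation in RGB (scaled 0–1)
    6–11        per-channel mean and standard deviation in HSV
    12–27       16-bin grey-level histogram (fractions, sum to 1)
    28          mean Sobel gradient magnitude of the grey image
    29          dark-pixel fraction (grey < 0.35; nucleus surrogate)
    30–45       4x4 grid of grey block means (row-major)
    46–61       4x4 grid of saturation block means (row-major)
    ==========  =============================================================

    The patch must be square RGB with a side divisible by 4.
    """
    patch = np.asarray(patch)
    if (
        patch.ndim != 3
        or patch.shape[2] != 3
        or patch.shape[0] != patch.shape[1]
        or patch.shape[0] % 4 != 0
    ):
        raise ValueError(
            f"expected a square RGB patch with side divisible by 4, got "
            f"shape {patch.shape}"
        )
    rgb = patch.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb)
    grey = rgb2gray(rgb)
    block = patch.shape[0] // 4

    hist, _ = np.histogram(grey, bins=16, range=(0.0, 1.0))
    hist = hist / grey.size

    parts = [
        rgb.mean(axis=(0, 1)),
        rgb.std(axis=(0, 1)),
        hsv.mean(axis=(0, 1)),
        hsv.std(axis=(0, 1)),
        hist,
        [float(sobel(grey).mean())],
        [float((grey < DARK_GREY_THRESHOLD).mean())],
        block_mean(grey, block).ravel(),
        block_mean(hsv[..., 1], block).ravel(),
    ]
    return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts])


TOY_EXTRACTOR = Extractor(TOY_EXTRACTOR_ID, TOY_FEATURE_DIM, toy_descriptor)

_REGISTRY = {TOY_EXTRACTOR_ID: TOY_EXTRACTOR}


def get_extractor(extractor_id: str) -> Extractor:
    """Look up a registered extractor by id."""
    try:
        return _REGISTRY[extractor_id]
    except KeyError:
        raise KeyError(
            f"unknown extractor {extractor_id!r}; registered: "
            f"{sorted(_REGISTRY)}"
        ) from None


def register_extractor(extractor: Extractor) -> None:
    """Register a user-supplied extractor (e.g. a pretrained encoder)."""
    _REGISTRY[extractor.extractor_id] = extractor


def extract_features(
    slide: SlideImage, patches: PatchSet, extractor: Extractor = TOY_EXTRACTOR
) -> FeatureBag:
    """Apply an extractor to every patch of a slide, in coordinate order."""
    if len(patches) == 0:
        raise ValueError(f"slide {slide.slide_id!r}: empty patch set")
    feats = np.stack(
        [
            extractor(
                read_patch(slide, c, patches.patch_size_level0, patches.out_size)
            )
            for c in patches.coords
        ]
    )
    return FeatureBag(
        slide_id=slide.slide_id,
        features=feats,
        coords=np.asarray(patches.coords, dtype=np.int64),
        extractor_id=extractor.extractor_id,
    )


def save_bag(bag: FeatureBag, path: str | Path) -> Path:
    """Write a bag to an HDF5 file (datasets ``features``/``coords``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features)
        f.create_dataset("coords", data=bag.coords)
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["extractor_id"] = bag.extractor_id
    return path


def load_bag(
    path: str | Path,
    expected_dim: int | None = None,
    expected_extractor: str | None = None,
) -> FeatureBag:
    """Read a bag back; optionally enforce the consumer's expectations.

    Raises ``ValueError`` if the stored feature dimension or extractor id
    disagrees with what the caller's model was built for.
    """
    with h5py.File(path, "r") as f:
        bag = FeatureBag(
            slide_id=str(f.attrs["slide_id"]),
            features=f["features"][()],
            coords=f["coords"][()],
            extractor_id=str(f.attrs["extractor_id"]),
        )
    if expected_dim is not None and bag.feature_dim != expected_dim:
        raise ValueError(
            f"bag {bag.slide_id!r} has feature dim {bag.feature_dim}, "
            f"expected {expected_dim}"
        )
    if expected_extractor is not None and bag.extractor_id != expected_extractor:
        raise ValueError(
            f"bag {bag.slide_id!r} extracted with {bag.extractor_id!r}, "
            f"expected {expected_extractor!r}"
        )
    return bag
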