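"""Synthetic slides and synthetic MIL feature bags with known ground truth.

Real metastasis-detection cohorts pair gigapixel H&E slides with weak
slide-level labels: a "metastatic" slide contains at least one tumour
deposit — sometimes large, sometimes a focus only ~100 µm across — embedded
in benign tissue, on a near-white low-saturation background.  This module
emulates exactly the statistical structure the downstream analysis relies
on, at desk scale, with ground-truth masks so that segmentation, attention
and heatmaps can be scored against a known truth:

* :func:`generate_slide` draws eosin-pink elliptical tissue blobs on a
  near-white background and, for positive slides, renders tumour foci as
  hue-shifted stroma scattered with dark nuclei-like dots.  The saturation
  gap between background (< ~0.02) and tissue (> ~0.45) is enforced by
  construction so saturation thresholding is testable against the returned
  masks.
* :func:`generate_cohort` writes a cohort of such slides with a manifest,
  grouping slides into multi-slide synthetic cases so that case-level
  splitting is exercised.
* :func:`generate_feature_bags` skips the imaging stage entirely and draws
  feature-space MIL bags: background instances from a standard normal,
  witness instances mean-shifted by a chosen effect size, with the standard
  MIL assumption (positive bag ⇔ at least one witness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import draw
from skimage.color import hsv2rgb

from ._utils import to_uint8
from .slide import LABELS, MANIFEST_COLUMNS, SlideImage, write_manifest


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Full description of one synthetic slide; rendering is a pure
    function of this spec (including the seed).

    ``tumour_focus_diameters_um`` lists the diameters (µm) of the deposits
    to place in tissue; it must be non-empty iff ``tumour_present``.
    """

    canvas_size_px: tuple[int, int] = (1024, 1024)
    mpp: float = 1.0
    n_tissue_blobs: int = 3
    tumour_present: bool = False
    tumour_focus_diameters_um: tuple[float, ...] = ()
    tissue_hue_range: tuple[float, float] = (0.90, 0.97)
    tumour_hue_range: tuple[float, float] = (0.75, 0.82)
    background_saturation_max: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas_size_px
        if h < 16 or w < 16:
            raise ValueError(f"canvas {self.canvas_size_px} too small")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.n_tissue_blobs < 1:
            raise ValueError("need at least one tissue blob")
        if self.tumour_present != bool(self.tumour_focus_diameters_um):
            raise ValueError(
                "tumour_present must match presence of tumour_focus_diameters_um"
            )
        if not 0.0 <= self.background_saturation_max < 0.3:
            raise ValueError("background_saturation_max out of range")


@dataclass(frozen=True)
class BagSimSpec:
    """Feature-space MIL bag simulation.

    Background instances are i.i.d. standard multivariate normal; witness
    instances shift every coordinate's mean by ``effect_size`` (in units of
    the per-dimension standard deviation).  Exactly one of ``witness_rate``
    and ``witness_count`` selects how many witnesses a positive bag gets;
    either way a positive bag has at least one and a negative bag has none.
    """

    n_bags_per_class: int = 50
    bag_size_range: tuple[int, int] = (20, 50)
    feature_dim: int = 32
    effect_size: float = 2.0
    witness_rate: float | None = None
    witness_count: int | None = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bag_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid bag_size_range {self.bag_size_range}")
        if self.n_bags_per_class < 1:
            raise ValueError("need at least one bag per class")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if (self.witness_rate is None) == (self.witness_count is None):
            raise ValueError("set exactly one of witness_rate / witness_count")
        if self.witness_rate is not None and not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must lie in (0, 1]")
        if self.witness_count is not None:
            if self.witness_count < 1:
                raise ValueError("witness_count must be >= 1")
            if self.witness_count > lo:
                raise ValueError(
                    f"witness_count {self.witness_count} exceeds minimum bag "
                    f"size {lo}"
                )


def generate_slide(
    spec: SyntheticSlideSpec, slide_id: str | None = None
) -> tuple[SlideImage, np.ndarray, np.ndarray]:
    """Render one synthetic slide.

    Returns ``(slide, tumour_mask, tissue_mask)`` where the masks are
    boolean rasters aligned with the level-0 image.  The tumour mask is
    empty iff ``spec.tumour_present`` is false, and tumour pixels are a
    subset of tissue pixels.

    Raises
    ------
    ValueError
        If a requested focus diameter does not fit inside any tissue blob.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size_px

    # near-white background: tiny saturation, high value
    hue = rng.uniform(0.0, 1.0, (h, w))
    sat = rng.uniform(0.0, spec.background_saturation_max, (h, w))
    val = rng.uniform(0.94, 0.98, (h, w))

    # overlapping elliptical tissue blobs, eosin-like pink
    tissue = np.zeros((h, w), dtype=bool)
    short = min(h, w)
    for blob in range(spec.n_tissue_blobs):
        cy = rng.uniform(0.28 * h, 0.72 * h)
        cx = rng.uniform(0.28 * w, 0.72 * w)
        # the first blob is an anchor with a guaranteed minimum size so
        # that foci up to ~half the short canvas dimension always fit
        lo_frac = 0.25 if blob == 0 else 0.16
        ry = rng.uniform(lo_frac, 0.30) * short
        rx = rng.uniform(lo_frac, 0.30) * short
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        tissue[rr, cc] = True
    hue[tissue] = rng.uniform(*spec.tissue_hue_range, size=int(tissue.sum()))
    sat[tissue] = rng.uniform(0.45, 0.70, size=int(tissue.sum()))
    val[tissue] = rng.uniform(0.72, 0.88, size=int(tissue.sum()))

    tumour = np.zeros((h, w), dtype=bool)
    if spec.tumour_present:
        # distance to background limits where a disc-shaped focus can sit
        dist = ndimage.distance_transform_edt(tissue)
        for d_um in spec.tumour_focus_diameters_um:
            r_px = max(1, int(round(d_um / spec.mpp / 2.0)))
            candidates = np.argwhere(dist >= r_px + 1)
            if len(candidates) == 0:
                raise ValueError(
                    f"tumour focus of {d_um} µm (radius {r_px} px at "
                    f"{spec.mpp} µm/px) does not fit inside any tissue blob"
                )
            cy, cx = candidates[rng.integers(len(candidates))]
            rr, cc = draw.disk((cy, cx), r_px, shape=(h, w))
            tumour[rr, cc] = True
        n_t = int(tumour.sum())
        # hue-shifted stroma within the focus
        hue[tumour] = rng.uniform(*spec.tumour_hue_range, size=n_t)
        sat[tumour] = rng.uniform(0.50, 0.75, size=n_t)
        val[tumour] = rng.uniform(0.62, 0.80, size=n_t)
        # Poisson-scattered dark nuclei surrogates inside the foci
        ys, xs = np.nonzero(tumour)
        n_dots = rng.poisson(0.02 * n_t)
        if n_dots > 0:
            pick = rng.integers(0, len(ys), size=n_dots)
            radii = rng.integers(1, 3, size=n_dots)
            for (dy, dx, dr) in zip(ys[pick], xs[pick], radii):
                rr, cc = draw.disk((dy, dx), int(dr), shape=(h, w))
                keep = tumour[rr, cc]
                rr, cc = rr[keep], cc[keep]
                val[rr, cc] = rng.uniform(0.18, 0.30)
                sat[rr, cc] = rng.uniform(0.55, 0.80)

    rgb = to_uint8(hsv2rgb(np.stack([hue, sat, val], axis=-1)) * 255.0)
    label = LABELS[1] if spec.tumour_present else LABELS[0]
    slide = SlideImage(slide_id or f"synthetic-{spec.seed}", rgb, spec.mpp, label)
    return slide, tumour, tissue


def _save_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG mask back to boolean."""
    return np.asarray(Image.open(path).convert("L")) > 127


def mask_paths(manifest_row: pd.Series) -> tuple[Path, Path]:
    """Paths of the ground-truth (tissue, tumour) masks for a cohort slide."""
    img = Path(manifest_row["path"])
    stem = img.stem
    return (
        img.parent / f"{stem}_tissue_mask.png",
        img.parent / f"{stem}_tumour_mask.png",
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    cohort: str,
    seed: int,
    out_dir: str | Path,
    *,
    slides_per_case: tuple[int, int] = (1, 3),
    slide_spec: SyntheticSlideSpec | None = None,
    foci_per_slide: tuple[int, int] = (1, 2),
    focus_diameter_range_um: tuple[float, float] = (100.0, 350.0),
) -> pd.DataFrame:
    """Write a synthetic cohort to disk and return its manifest.

    Slides are grouped into synthetic cases, each holding a number of
    slides drawn uniformly from ``slides_per_case`` (the last case of each
    class is truncated to hit the requested slide count exactly).  Every
    slide of a malignant case carries at least one tumour focus with a
    diameter drawn log-uniformly from ``focus_diameter_range_um``.

    Ground-truth tissue and tumour masks are written next to each slide
    image as 0/255 PNGs; the manifest CSV (``manifest.csv`` in *out_dir*)
    has the columns ``slide_id,case_id,cohort,label,mpp,path``.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one slide of each class")
    lo, hi = slides_per_case
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid slides_per_case {slides_per_case}")
    base = slide_spec or SyntheticSlideSpec()
    # the anchor blob guarantees room for foci up to half its radius;
    # reject focus ranges that could not be placed on this canvas
    short = min(base.canvas_size_px)
    max_safe_um = 2.0 * (0.25 * short - 2.0) * base.mpp
    if focus_diameter_range_um[1] > max_safe_um:
        raise ValueError(
            f"largest focus diameter {focus_diameter_range_um[1]} µm cannot "
            f"be guaranteed to fit a {base.canvas_size_px} px canvas at "
            f"{base.mpp} µm/px (max ~{max_safe_um:.0f} µm); enlarge the "
            f"canvas or shrink the foci"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    rows = []
    case_no = 0
    for label, n_slides in ((LABELS[0], n_benign), (LABELS[1], n_malignant)):
        done = 0
        while done < n_slides:
            case_no += 1
            case_id = f"{cohort}-case-{case_no:04d}"
            in_case = min(int(rng.integers(lo, hi + 1)), n_slides - done)
            for _ in range(in_case):
                done += 1
                slide_id = f"{cohort}-{label[:3]}-{done:04d}"
                if label == LABELS[1]:
                    n_foci = int(rng.integers(foci_per_slide[0], foci_per_slide[1] + 1))
                    d_lo, d_hi = focus_diameter_range_um
                    diams = tuple(
                        float(np.exp(rng.uniform(np.log(d_lo), np.log(d_hi))))
                        for _ in range(n_foci)
                    )
                else:
                    diams = ()
                spec = replace(
                    base,
                    tumour_present=label == LABELS[1],
                    tumour_focus_diameters_um=diams,
                    seed=int(rng.integers(2**31)),
                )
                slide, tumour, tissue = generate_slide(spec, slide_id=slide_id)
                img_path = out_dir / f"{slide_id}.png"
                slide.save(img_path)
                _save_mask(tissue, out_dir / f"{slide_id}_tissue_mask.png")
                _save_mask(tumour, out_dir / f"{slide_id}_tumour_mask.png")
                rows.append(
                    {
                        "slide_id": slide_id,
                        "case_id": case_id,
                        "cohort": cohort,
                        "label": label,
                        "mpp": spec.mpp,
                        "path": str(img_path),
                    }
                )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def generate_feature_bags(spec: BagSimSpec):
    """Draw synthetic MIL feature bags.

    Returns ``(bags, labels)``: a list of :class:`~slidemil.features.FeatureBag`
    and an aligned list of slide-level labels (``benign``/``metastatic``).
    Each positive bag records its ground-truth witness indices on
    ``bag.witness_idx``; negative bags record an empty index array.
    """
    from .features import FeatureBag  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    bags: list[FeatureBag] = []
    labels: list[str] = []
    lo, hi = spec.bag_size_range
    for positive in (False, True):
        for b in range(spec.n_bags_per_class):
            n = int(rng.integers(lo, hi + 1))
            x = rng.standard_normal((n, spec.feature_dim))
            if positive:
                if spec.witness_count is not None:
                    k = spec.witness_count
                else:
                    k = max(1, int(rng.binomial(n, spec.witness_rate)))
                if k > n:
                    raise ValueError(f"witness count {k} exceeds bag size {n}")
                witness = rng.choice(n, size=k, replace=False)
                x[witness] += spec.effect_size
            else:
                witness = np.empty(0, dtype=np.int64)
            label = LABELS[1] if positive else LABELS[0]
            coords = np.stack(
                [np.arange(n) * 256, np.zeros(n, dtype=np.int64)], axis=1
            )
            bag = FeatureBag(
                slide_id=f"simbag-{label[:3]}-{b:04d}",
                features=x,
                coords=coords,
                extractor_id="synthetic-gaussian",
                witness_idx=np.sort(np.asarray(witness, dtype=np.int64)),
            )
            bags.append(bag)
            labels.append(label)
    return bags, labels


def bag_manifest(bags, labels, cohort: str = "simbags", bags_per_case: int = 2) -> pd.DataFrame:
    """Build a slide manifest for feature-space bags (no images on disk).

    Consecutive same-label bags are grouped ``bags_per_case`` to a synthetic
    case so the case-level splitters can operate on pure bag cohorts.
    """
    rows = []
    counters: dict[str, int] = {}
    for bag, label in zip(bags, labels):
        idx = counters.get(label, 0)
        counters[label] = idx + 1
        rows.append(
            {
                "slide_id": bag.slide_id,
                "case_id": f"{cohort}-{label[:3]}-case-{idx // bags_per_case:04d}",
                "cohort": cohort,
                "label": label,
                "mpp": float("nan"),
                "path": "",
            }
        )
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
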