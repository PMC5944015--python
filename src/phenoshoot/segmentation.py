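"""Plant/background segmentation for fixed-background side-view frames.

The pipeline mirrors how greenhouse imaging chambers are processed in
practice: (optional) feature-based registration of the frame onto the
plant-free background, frame differencing, superimposition of the green
pixels of the original image onto the rough foreground, HSV-band
binarization, and a morphological clean-up that keeps a single connected
component.

Default HSV plant band: hue 0.051-0.503, saturation 0.102-0.804,
value 0.000-0.786 (all channels scaled to [0, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import ORB, match_descriptors
from skimage.measure import label, ransac
from skimage.morphology import (
    dilation,
    disk,
    erosion,
    remove_small_holes,
    remove_small_objects,
)
from skimage.util import img_as_float

from .errors import EmptyInputError, InvalidArgumentError, RegistrationError


@dataclass(frozen=True)
class HsvRanges:
    """Per-channel inclusive [lo, hi] bands in [0, 1]."""

    hue: tuple[float, float] = (0.051, 0.503)
    saturation: tuple[float, float] = (0.102, 0.804)
    value: tuple[float, float] = (0.000, 0.786)

    def __post_init__(self):
        for name in ("hue", "saturation", "value"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidArgumentError(f"{name} range has lo > hi")


DEFAULT_HSV = HsvRanges()

#: Hue sub-band treated as "green" during green-pixel superimposition.
DEFAULT_GREEN_HUE: tuple[float, float] = (0.17, 0.45)


@dataclass(frozen=True)
class SegmentationConfig:
    hsv: HsvRanges = DEFAULT_HSV
    green_hue: tuple[float, float] = DEFAULT_GREEN_HUE
    register: bool = False
    difference_threshold: float = 15.0 / 255.0
    erosion_radius: int = 1
    dilation_radius: int = 2
    min_component_area: int = 50

    def __post_init__(self):
        if self.difference_threshold < 0:
            raise InvalidArgumentError("difference_threshold must be >= 0")
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise InvalidArgumentError("morphology radii must be >= 0")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidArgumentError("expected an RGB raster (H, W, 3)")
    return img_as_float(image)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def estimate_registration(
    image: np.ndarray,
    background: np.ndarray,
    n_keypoints: int = 500,
    residual_threshold: float = 2.0,
) -> sktransform.SimilarityTransform:
    """Similarity transform mapping ``image`` coordinates onto ``background``.

    Local features (ORB corners/blobs: pot corners, cabinet frame edges in
    real chambers) are matched and a scale+rotation+translation model is
    estimated robustly with RANSAC.
    """
    img_g = rgb2gray(_as_float_rgb(image))
    bg_g = rgb2gray(_as_float_rgb(background))
    matches = None
    try:
        orb_a = ORB(n_keypoints=n_keypoints)
        orb_a.detect_and_extract(img_g)
        orb_b = ORB(n_keypoints=n_keypoints)
        orb_b.detect_and_extract(bg_g)
        matches = match_descriptors(orb_a.descriptors, orb_b.descriptors,
                                    cross_check=True)
    except (RuntimeError, ValueError) as exc:
        raise RegistrationError(f"feature detection failed: {exc}") from exc
    if matches is None or len(matches) < 3:
        raise RegistrationError(
            f"only {0 if matches is None else len(matches)} feature matches; "
            "need at least 3"
        )
    src = orb_a.keypoints[matches[:, 0]][:, ::-1]  # (row,col) -> (x,y)
    dst = orb_b.keypoints[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst),
        sktransform.SimilarityTransform,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=500,
        rng=0,
    )
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationError("RANSAC found fewer than 3 reliable matches")
    return model


def register_to_background(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Warp ``image`` onto the background frame's geometry."""
    image_f = _as_float_rgb(image)
    background_f = _as_float_rgb(background)
    model = estimate_registration(image_f, background_f)
    warped = sktransform.warp(
        image_f, model.inverse, output_shape=background_f.shape[:2],
        preserve_range=True,
    )
    return warped


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def frame_difference(
    aligned: np.ndarray, background: np.ndarray, threshold: float
) -> np.ndarray:
    """Foreground where the max-channel absolute difference exceeds threshold."""
    a = _as_float_rgb(aligned)
    b = _as_float_rgb(background)
    if a.shape != b.shape:
        raise InvalidArgumentError(
            f"dimension mismatch: {a.shape} vs {b.shape}"
        )
    return np.abs(a - b).max(axis=2) > threshold


def green_superimpose(
    image: np.ndarray,
    rough_mask: np.ndarray,
    green_hue: tuple[float, float] = DEFAULT_GREEN_HUE,
) -> np.ndarray:
    """Keep original green pixels inside the rough mask; zero everything else.

    Removes residual background/soil pixels that survive frame differencing
    under lighting variation: only pixels whose hue falls in the green band
    and that lie inside the rough foreground retain their original values.
    """
    img = _as_float_rgb(image)
    rough_mask = np.asarray(rough_mask, dtype=bool)
    if rough_mask.shape != img.shape[:2]:
        raise InvalidArgumentError("mask / image dimension mismatch")
    hue = rgb2hsv(img)[:, :, 0]
    keep = rough_mask & (hue >= green_hue[0]) & (hue <= green_hue[1])
    out = np.zeros_like(img)
    out[keep] = img[keep]
    return out


def hsv_binarize(image: np.ndarray, hsv: HsvRanges = DEFAULT_HSV) -> np.ndarray:
    """Pixels whose H, S and V all fall inside the band; black pixels never set."""
    img = _as_float_rgb(image)
    h, s, v = np.moveaxis(rgb2hsv(img), 2, 0)
    mask = (
        (h >= hsv.hue[0]) & (h <= hsv.hue[1])
        & (s >= hsv.saturation[0]) & (s <= hsv.saturation[1])
        & (v >= hsv.value[0]) & (v <= hsv.value[1])
    )
    mask &= img.max(axis=2) > 0  # zero-valued pixels are background
    return mask


def morphological_clean(
    mask: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> np.ndarray:
    """Speck removal, hole filling and single-component selection.

    Erosion removes isolated noise, dilation regrows the surviving shape,
    and the result is constrained back to the input mask so true boundaries
    are not displaced (reconstruction-style opening). Interior holes no
    larger than the dilation disk are then filled, small components dropped,
    and the largest 8-connected component returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    work = mask
    if config.erosion_radius > 0:
        work = erosion(work, disk(config.erosion_radius))
    if config.dilation_radius > 0:
        work = dilation(work, disk(config.dilation_radius))
    work &= mask
    hole_area = int(disk(max(config.dilation_radius, 1)).sum())
    work = remove_small_holes(work, max_size=hole_area)
    if config.min_component_area > 1:
        work = remove_small_objects(work, max_size=config.min_component_area - 1)
    if not work.any():
        return np.zeros_like(mask)
    labels = label(work, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment(
    image: np.ndarray,
    background: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Full segmentation pipeline; returns the clean binary plant mask."""
    aligned = np.asarray(image)
    if config.register:
        try:
            aligned = register_to_background(image, background)
        except RegistrationError as exc:
            warnings.warn(
                f"registration failed ({exc}); proceeding unregistered",
                stacklevel=2,
            )
            aligned = image
    rough = frame_difference(aligned, background, config.difference_threshold)
    sup = green_superimpose(aligned, rough, config.green_hue)
    binary = hsv_binarize(sup, config.hsv)
    clean = morphological_clean(binary, config)
    # the final mask never contains pixels the HSV band rejected; pixels a
    # hole fill added between near-touching strokes are dropped again here
    return clean & binary


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise EmptyInputError("both masks are empty")
    return float(np.logical_and(a, b).sum() / union)
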