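"""Sclera and iris localization with validity checks.

The segmenter interface is pluggable: anything callable as
``segmenter(image) -> EyeSegmentation`` may be registered and substituted
for the classical baseline (e.g. a learned model, or ground-truth masks in
tests).  Downstream scoring depends on the segmentation only through the
``EyeSegmentation`` contract.

The classical baseline locates the iris as the largest dark, roughly
circular blob, then grows the sclera as the surrounding bright,
low-saturation region touching the iris; skin is excluded by its higher
color saturation.  Saturation here is (max - min) / max of the RGB triple,
which is invariant to global exposure.  Validity checks mirror the clinical
requirements: the iris must be coupled to (bordered by) sclera over a
minimum fraction of its perimeter, the sclera must not be degenerately
small, and an image with no iris candidate is flagged as having no eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "FLAG_EYE_MISSING",
    "FLAG_UNCOUPLED",
    "FLAG_TOO_SMALL",
    "EyeSegmentation",
    "ValidationResult",
    "segment_eye",
    "validate_segmentation",
    "GroundTruthSegmenter",
    "register_segmenter",
    "get_segmenter",
]

def _disk(radius: int) -> "np.ndarray":
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


_DISK2 = _disk(2)
_DISK3 = _disk(3)

FLAG_EYE_MISSING = "eye_missing"
FLAG_UNCOUPLED = "iris_sclera_uncoupled"
FLAG_TOO_SMALL = "mask_too_small"

# Defaults for the validity checks: the coupling fraction tolerates partial
# eyelid occlusion; the sclera-area floor rejects blink frames but not side
# gazes, where a smaller sclera portion is exposed.
DEFAULT_COUPLING_FRACTION = 0.3
DEFAULT_MIN_SCLERA_FRACTION = 0.02


@dataclass
class EyeSegmentation:
    """Masks and validity flags for one eye image.

    Masks always match the source image shape and never overlap.  If
    ``quality_flags`` is nonempty the segmentation must not be used for
    redness scoring.
    """

    sclera_mask: np.ndarray
    iris_mask: np.ndarray
    eye_open: bool
    quality_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sclera_mask.shape != self.iris_mask.shape:
            raise ValueError("mask shapes differ")
        if bool(np.any(self.sclera_mask & self.iris_mask)):
            raise ValueError("sclera and iris masks overlap")

    @property
    def usable(self) -> bool:
        return not self.quality_flags


@dataclass
class ValidationResult:
    passed: bool
    flags: frozenset


def _saturation(f: np.ndarray) -> np.ndarray:
    mx = f.max(axis=-1)
    mn = f.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return sat


def _coupling_fraction(iris: np.ndarray, sclera: np.ndarray) -> float:
    """Fraction of the iris perimeter adjacent (within 2 px) to sclera."""
    if not iris.any():
        return 0.0
    perimeter = iris & ~ndi.binary_erosion(iris)
    if not perimeter.any():
        return 0.0
    near_sclera = ndi.binary_dilation(sclera, structure=_DISK2)
    return float((perimeter & near_sclera).sum() / perimeter.sum())


def _find_iris(
    value: np.ndarray, dark_threshold: float, min_area: int, max_area_fraction: float
) -> np.ndarray | None:
    dark = value < dark_threshold
    labels = measure.label(dark)
    if labels.max() == 0:
        return None
    best = None
    best_area = 0
    max_area = max_area_fraction * value.size
    for region in measure.regionprops(labels):
        if region.area < min_area or region.area > max_area:
            continue
        # roughly circular: filled area close to the area of the fitted disk
        r_equiv = np.sqrt(region.area / np.pi)
        extent_ok = region.area_filled <= np.pi * (1.6 * r_equiv) ** 2
        if extent_ok and region.area > best_area:
            best = region
            best_area = region.area
    if best is None:
        return None
    iris = labels == best.label
    return ndi.binary_fill_holes(iris)


def segment_eye(
    image: np.ndarray,
    *,
    dark_threshold: float = 0.35,
    brightness_threshold: float = 0.45,
    saturation_threshold: float = 0.32,
    min_iris_area: int = 64,
    max_iris_area_fraction: float = 0.3,
    coupling_fraction: float = DEFAULT_COUPLING_FRACTION,
    min_sclera_fraction: float = DEFAULT_MIN_SCLERA_FRACTION,
) -> EyeSegmentation:
    """Classical baseline segmenter for a single pre-cropped eye image.

    Returns an :class:`EyeSegmentation`; if no iris candidate is found the
    result carries the ``eye_missing`` flag and empty masks.
    """
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    f = image.astype(np.float64) / 255.0
    value = f.mean(axis=-1)
    sat = _saturation(f)

    iris = _find_iris(value, dark_threshold, min_iris_area, max_iris_area_fraction)
    empty = np.zeros(value.shape, dtype=bool)
    if iris is None:
        return EyeSegmentation(
            sclera_mask=empty,
            iris_mask=empty.copy(),
            eye_open=False,
            quality_flags=frozenset({FLAG_EYE_MISSING}),
        )

    candidate = (~iris) & (value > brightness_threshold) & (sat < saturation_threshold)
    near_iris = ndi.binary_dilation(iris, structure=_DISK3)
    labels = measure.label(candidate)
    keep = np.unique(labels[near_iris & (labels > 0)])
    sclera = np.isin(labels, keep) if keep.size else empty.copy()
    if sclera.any():
        sclera = ndi.binary_closing(sclera, structure=_DISK2)
        sclera = ndi.binary_fill_holes(sclera)
        sclera &= ~iris

    flags = set()
    if sclera.sum() < min_sclera_fraction * value.size:
        flags.add(FLAG_TOO_SMALL)
    if _coupling_fraction(iris, sclera) < coupling_fraction:
        flags.add(FLAG_UNCOUPLED)
    return EyeSegmentation(
        sclera_mask=sclera,
        iris_mask=iris,
        eye_open=True,
        quality_flags=frozenset(flags),
    )


def validate_segmentation(
    seg: EyeSegmentation,
    min_sclera_fraction: float = DEFAULT_MIN_SCLERA_FRACTION,
    coupling_fraction: float = DEFAULT_COUPLING_FRACTION,
) -> ValidationResult:
    """Re-derive the validity verdict from the masks.

    Fails iff the eye is missing, the sclera area is below
    ``min_sclera_fraction`` of the image, or the iris shares a border with
    the sclera over less than ``coupling_fraction`` of its perimeter.
    Always returns a verdict.
    """
    flags = set(seg.quality_flags & {FLAG_EYE_MISSING})
    if not seg.iris_mask.any() or not seg.eye_open:
        flags.add(FLAG_EYE_MISSING)
    if seg.sclera_mask.sum() < min_sclera_fraction * seg.sclera_mask.size:
        flags.add(FLAG_TOO_SMALL)
    if _coupling_fraction(seg.iris_mask, seg.sclera_mask) < coupling_fraction:
        flags.add(FLAG_UNCOUPLED)
    return ValidationResult(passed=not flags, flags=frozenset(flags))


class GroundTruthSegmenter:
    """Segmenter that replays known ground-truth masks.

    Useful for isolating downstream scoring from segmentation error: masks
    are looked up by image content hash, so the segmenter honors the same
    ``segmenter(image) -> EyeSegmentation`` contract as the baseline.
    """

    def __init__(self) -> None:
        self._masks: Dict[bytes, tuple] = {}

    def register(self, image: np.ndarray, sclera_mask: np.ndarray, iris_mask: np.ndarray) -> None:
        self._masks[image.tobytes()] = (sclera_mask.copy(), iris_mask.copy())

    def __call__(self, image: np.ndarray) -> EyeSegmentation:
        key = image.tobytes()
        if key not in self._masks:
            raise KeyError("no ground-truth masks registered for this image")
        sclera, iris = self._masks[key]
        return EyeSegmentation(
            sclera_mask=sclera.copy(),
            iris_mask=iris.copy(),
            eye_open=True,
            quality_flags=frozenset(),
        )


_REGISTRY: Dict[str, Callable] = {"baseline": segment_eye}


def register_segmenter(name: str, segmenter: Callable) -> None:
    _REGISTRY[name] = segmenter


def get_segmenter(name: str = "baseline") -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown segmenter {name!r}; registered: {sorted(_REGISTRY)}")
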