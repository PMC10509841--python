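"""Per-pixel scleral redness index, redness distributions and gradient features.

The core quantity is a colorimetric redness index computed per pixel from
8-bit RGB intensities normalized to [0, 1] (value / 255):

    R = (27/4) * (r - sqrt((g^2 + b^2)/2)) / s * (1 - s)^2,   s = sqrt(r^2+g^2+b^2)

The numerator ``r - sqrt((g^2+b^2)/2)`` is a red-chromaticity term (red in
excess of the quadratic mean of green and blue), normalized by the Euclidean
color magnitude ``s`` so the ratio depends on chromaticity rather than
brightness, and weighted by ``(1 - s)^2`` which vanishes for pixels at unit
color magnitude (e.g. a fully saturated pure channel).  Achromatic pixels
(r = g = b) score exactly 0; black pixels (s = 0) are assigned 0 by the
limit convention.

Redness over a sclera mask is summarized as a 256-bin histogram over the
index's attainable range together with the exact (unbinned) mean; texture
of the redness field is summarized as histograms of squared redness
differences at axial spatial lags 1-4 ("squared gradient" distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PREFACTOR",
    "REDNESS_MIN",
    "REDNESS_MAX",
    "N_BINS",
    "BIN_EDGES",
    "BIN_WIDTH",
    "PURE_RED_GRID_MAX",
    "GRADIENT_STEPS",
    "pixel_redness",
    "RednessMap",
    "redness_map",
    "RednessDistribution",
    "redness_distribution",
    "distribution_from_values",
    "GradientDistribution",
    "gradient_distribution",
]

PREFACTOR = 27.0 / 4.0

# Attainable range of the index over the full 8-bit RGB cube, found once by
# exhaustive evaluation of all 256^3 quantized colors.  The maximum sits at
# the dimmest pure-red pixel (r = 1/255), the minimum at the dimmest pure
# cyan-ish pixels (r = 0), both pushed toward the s -> 0 limit where the
# (1 - s)^2 weight is largest.
REDNESS_MIN = -4.735609110210861
REDNESS_MAX = 6.697162629757786

# Supremum of the index over pure-red pixels (g = b = 0) on a uniform grid of
# 10^4 points in the open interval (0, 1); frozen as the normalization
# reference of this factor arrangement.  Note that 27/4 does not normalize
# this arrangement's maximum to 1: for pure red the index reduces to
# (27/4)(1-r)^2, which approaches 27/4 as r -> 0.
PURE_RED_GRID_MAX = 6.748650202473003

N_BINS = 256
BIN_EDGES = np.linspace(REDNESS_MIN, REDNESS_MAX, N_BINS + 1)
BIN_WIDTH = (REDNESS_MAX - REDNESS_MIN) / N_BINS

GRADIENT_STEPS = (1, 2, 3, 4)


def pixel_redness(r, g, b):
    """Redness index of one pixel or an array of pixels.

    Parameters are the normalized channel intensities in [0, 1] (scalar or
    broadcastable arrays).  Returns the index with the same broadcast shape;
    black pixels (r = g = b = 0) map to 0.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for name, c in (("r", r), ("g", g), ("b", b)):
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError(f"channel {name} outside [0, 1]")
    s = np.sqrt(r * r + g * g + b * b)
    chroma = r - np.sqrt((g * g + b * b) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = PREFACTOR * chroma / s * (1.0 - s) ** 2
    out = np.where(s > 0, out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def image_redness(image: np.ndarray) -> np.ndarray:
    """Redness index raster of an 8-bit RGB image (H x W x 3 uint8)."""
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    f = image.astype(np.float64) / 255.0
    return pixel_redness(f[..., 0], f[..., 1], f[..., 2])


@dataclass
class RednessMap:
    """Per-pixel redness over a valid (sclera) mask.

    ``values`` is a full-frame float raster; it is only meaningful where
    ``mask`` is True.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("empty redness mask")

    @property
    def mask_values(self) -> np.ndarray:
        """1-D array of the redness values of the masked pixels."""
        return self.values[self.mask]

    @property
    def mean(self) -> float:
        return float(self.mask_values.mean())


def redness_map(image: np.ndarray, seg) -> RednessMap:
    """Apply the redness index to every sclera pixel of a segmented image.

    ``seg`` is an ``EyeSegmentation``; a segmentation carrying quality flags
    must not be scored and is refused.
    """
    if seg.quality_flags:
        raise ValueError(
            f"segmentation failed validation (flags: {sorted(seg.quality_flags)}); "
            "refusing to compute redness"
        )
    values = image_redness(image)
    return RednessMap(values=values, mask=seg.sclera_mask.copy())


@dataclass
class RednessDistribution:
    """Histogram of per-pixel redness over one or more sclera masks.

    The histogram uses the fixed 256-bin grid over the index's attainable
    range; ``mean_redness`` is the exact pooled pixel mean (not the binned
    mean), and stays exact under shifting.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    mean_redness: float
    n_pixels: int
    applied_shift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")
        if int(self.counts.sum()) != self.n_pixels:
            raise ValueError("histogram counts do not sum to the pixel count")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_occupied_bins(self) -> int:
        return int((self.counts > 0).sum())

    def normalized(self) -> np.ndarray:
        return self.counts / max(self.n_pixels, 1)

    def shifted(self, delta: float) -> "RednessDistribution":
        """Distribution translated by ``delta`` redness units.

        The exact mean moves by exactly ``delta``; histogram counts move by
        the nearest whole number of bins, with mass running off the grid
        accumulated in the edge bins.
        """
        k = int(round(delta / self.bin_width))
        counts = np.zeros_like(self.counts)
        n = len(self.counts)
        if k == 0:
            counts[:] = self.counts
        elif k > 0:
            if k < n:
                counts[k:] = self.counts[: n - k]
            counts[-1] += self.counts[max(n - k, 0):].sum()
        else:
            m = -k
            if m < n:
                counts[: n - m] = self.counts[m:]
            counts[0] += self.counts[: min(m, n)].sum()
        return RednessDistribution(
            counts=counts,
            bin_edges=self.bin_edges,
            mean_redness=self.mean_redness + delta,
            n_pixels=self.n_pixels,
            applied_shift=self.applied_shift + delta,
        )


def distribution_from_values(values: np.ndarray) -> RednessDistribution:
    """Build a :class:`RednessDistribution` from raw per-pixel redness values."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot build a redness distribution from zero pixels")
    clipped = np.clip(values, REDNESS_MIN, REDNESS_MAX)
    counts, _ = np.histogram(clipped, bins=BIN_EDGES)
    return RednessDistribution(
        counts=counts,
        bin_edges=BIN_EDGES.copy(),
        mean_redness=float(values.mean()),
        n_pixels=int(values.size),
    )


def redness_distribution(maps: Iterable[RednessMap] | RednessMap) -> RednessDistribution:
    """Pool one or more redness maps (e.g. the 3 gaze positions) into one
    distribution.  The pooled mean equals the pixel-count-weighted mean of
    the per-map means."""
    if isinstance(maps, RednessMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one redness map")
    values = np.concatenate([m.mask_values for m in maps])
    return distribution_from_values(values)


@dataclass
class GradientDistribution:
    """Histograms of squared redness differences at axial spatial lags.

    For each step k the squared differences (R[y, x+k] - R[y, x])^2 and
    (R[y+k, x] - R[y, x])^2 are collected over all pixel pairs whose both
    endpoints lie in the mask.  Masks too thin for a step yield an empty
    histogram for that step, recorded in ``empty_steps``.
    """

    steps: tuple
    bin_edges: np.ndarray
    counts: dict = field(default_factory=dict)
    n_pairs: dict = field(default_factory=dict)
    empty_steps: tuple = ()

    def total(self, step: int) -> int:
        return int(self.counts[step].sum())


# Squared differences between neighboring sclera pixels are small (the
# index varies by ~0.1 across a vessel edge); binning over the theoretical
# span^2 would collapse all structure into the first bin.  The histogram
# covers [0, 1] in squared-redness units; rarer larger values are clipped
# into the top bin so pair counts are conserved.
GRADIENT_RANGE = 1.0
GRADIENT_BIN_EDGES = np.linspace(0.0, GRADIENT_RANGE, N_BINS + 1)


def _lag_squared_diffs(values: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    horiz = mask[:, k:] & mask[:, :-k]
    vert = mask[k:, :] & mask[:-k, :]
    dh = (values[:, k:] - values[:, :-k])[horiz]
    dv = (values[k:, :] - values[:-k, :])[vert]
    d = np.concatenate([dh, dv])
    return d * d


def gradient_distribution(
    rmap: RednessMap, steps: Sequence[int] = GRADIENT_STEPS
) -> GradientDistribution:
    """Squared-gradient histograms of a redness map at the given lags."""
    counts: dict = {}
    n_pairs: dict = {}
    empty = []
    for k in steps:
        if k < 1:
            raise ValueError("spatial steps must be >= 1")
        if k >= min(rmap.values.shape):
            sq = np.empty(0)
        else:
            sq = _lag_squared_diffs(rmap.values, rmap.mask, k)
        c, _ = np.histogram(np.clip(sq, 0.0, GRADIENT_RANGE), bins=GRADIENT_BIN_EDGES)
        counts[k] = c
        n_pairs[k] = int(sq.size)
        if sq.size == 0:
            empty.append(k)
    return GradientDistribution(
        steps=tuple(steps),
        bin_edges=GRADIENT_BIN_EDGES.copy(),
        counts=counts,
        n_pairs=n_pairs,
        empty_steps=tuple(empty),
    )
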