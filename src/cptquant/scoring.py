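"""White-balance normalization against the untreated eye and the per-step
instrument score.

The untreated (right) eye never receives allergen, so any change of its
scleral redness distribution between the baseline and a provocation
timepoint is attributed to illumination / white-balance drift.  The
timepoint's distributions (both eyes) are rigidly shifted by the amount
that maximizes the histogram-intersection overlap of the control eye's
timepoint distribution with its baseline distribution; the instrument
score is then the increase of the treated eye's mean redness over its
baseline, clipped at zero:

    delta* = argmax_d overlap(control_baseline, shift(control_timepoint, d))
    raw    = mean(shift(treated_timepoint, delta*)) - mean(treated_baseline)
    score  = max(raw, 0)

The shift is searched on a grid of one-bin granularity spanning the full
redness range, ties broken toward the smallest |shift|.  A measurement is
classified positive iff its score is strictly above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .redness import RednessDistribution, redness_distribution, redness_map
from .segmentation import get_segmenter, validate_segmentation
from .session import CONTROL_EYE, GAZES, TREATED_EYE, MeasurementSession

__all__ = [
    "AlignmentResult",
    "align_distributions",
    "InstrumentScore",
    "ScoringError",
    "score_from_distributions",
    "score_timepoint",
    "score_session",
    "classify_score",
]


class ScoringError(RuntimeError):
    """A score could not be computed (failed segmentation, missing data)."""


@dataclass
class AlignmentResult:
    """Optimal rigid shift of a moving distribution onto a reference."""

    shift: float  # redness units (a whole number of bins unless degenerate)
    shift_bins: int
    overlap: float  # histogram intersection at the optimum, in [0, 1]
    low_confidence: bool = False


def _histogram_intersection(p: np.ndarray, q: np.ndarray, k: int) -> float:
    """Overlap of q shifted by k bins against p."""
    n = len(p)
    if k >= n or k <= -n:
        return 0.0
    if k >= 0:
        return float(np.minimum(p[k:], q[: n - k]).sum())
    return float(np.minimum(p[: n + k], q[-k:]).sum())


def align_distributions(
    reference: RednessDistribution, moving: RednessDistribution
) -> AlignmentResult:
    """Shift maximizing the histogram-intersection overlap of ``moving``
    against ``reference``.

    Both distributions must share the same binning.  Degenerate
    (single-occupied-bin) histograms carry no shape information; for those
    the difference of means is returned, flagged low-confidence.
    """
    if not np.allclose(reference.bin_edges, moving.bin_edges):
        raise ValueError("distributions must share the same binning")
    if reference.n_pixels == 0 or moving.n_pixels == 0:
        raise ValueError("cannot align empty distributions")

    if reference.n_occupied_bins == 1 or moving.n_occupied_bins == 1:
        delta = reference.mean_redness - moving.mean_redness
        return AlignmentResult(
            shift=float(delta),
            shift_bins=int(round(delta / reference.bin_width)),
            overlap=_histogram_intersection(
                reference.normalized(),
                moving.normalized(),
                int(round(delta / reference.bin_width)),
            ),
            low_confidence=True,
        )

    p = reference.normalized()
    q = moving.normalized()
    n = len(p)
    shifts = np.arange(-n, n + 1)
    overlaps = np.array([_histogram_intersection(p, q, int(k)) for k in shifts])
    best = overlaps.max()
    candidates = shifts[overlaps >= best - 1e-12]
    # ties toward the smallest |shift|, then the smaller signed shift
    k_star = int(sorted(candidates, key=lambda k: (abs(k), k))[0])
    return AlignmentResult(
        shift=float(k_star * reference.bin_width),
        shift_bins=k_star,
        overlap=float(best),
        low_confidence=False,
    )


@dataclass
class InstrumentScore:
    """Instrument redness score of one provocation step.

    ``raw_difference`` is preserved for audit; the reported score is
    clipped at zero (published score axes span 0-3.7).  ``applied_shift``
    is the white-balance correction, in redness units, that was applied to
    the timepoint distributions.
    """

    timepoint: str
    raw_difference: float
    score: float
    applied_shift: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if abs(self.score - max(self.raw_difference, 0.0)) > 1e-12:
            raise ValueError("score must equal max(raw_difference, 0)")


def score_from_distributions(
    treated_reference: RednessDistribution,
    treated_timepoint: RednessDistribution,
    control_reference: RednessDistribution,
    control_timepoint: RednessDistribution,
    *,
    timepoint: str = "?",
    normalize: bool = True,
) -> InstrumentScore:
    """Score one provocation step from the four pooled redness
    distributions.  ``normalize=False`` skips the internal-control shift
    (exposed for auditing how large the white-balance confounder is)."""
    if normalize:
        alignment = align_distributions(control_reference, control_timepoint)
        shift = alignment.shift
        low_confidence = alignment.low_confidence
    else:
        shift, low_confidence = 0.0, False
    shifted_treated = treated_timepoint.shifted(shift)
    raw = shifted_treated.mean_redness - treated_reference.mean_redness
    return InstrumentScore(
        timepoint=timepoint,
        raw_difference=float(raw),
        score=float(max(raw, 0.0)),
        applied_shift=float(shift),
        low_confidence=low_confidence,
    )


def _pooled_distribution(
    session: MeasurementSession,
    timepoint: str,
    eye: str,
    segmenter: Callable,
    cache: Optional[Dict[Tuple[str, str], RednessDistribution]] = None,
) -> RednessDistribution:
    key = (timepoint, eye)
    if cache is not None and key in cache:
        return cache[key]
    maps = []
    for gaze in GAZES:
        image = session.images[timepoint][eye][gaze]
        seg = segmenter(image)
        verdict = validate_segmentation(seg)
        if not verdict.passed:
            raise ScoringError(
                f"segmentation failed for {eye} eye, gaze {gaze!r} at {timepoint!r}: "
                f"{sorted(verdict.flags)}"
            )
        maps.append(redness_map(image, seg))
    dist = redness_distribution(maps)
    if cache is not None:
        cache[key] = dist
    return dist


def score_timepoint(
    session: MeasurementSession,
    timepoint: str,
    *,
    segmenter: Optional[Callable] = None,
    reference_timepoint: str = "baseline",
    normalize: bool = True,
    _cache: Optional[Dict] = None,
) -> InstrumentScore:
    """Instrument score of one provocation timepoint of a session.

    Builds the four pooled (3-gaze) redness distributions — control eye at
    the reference and the timepoint, treated eye at the reference and the
    timepoint — then applies the internal-control normalization and takes
    the treated-eye mean difference.  The reference defaults to the
    pre-test baseline; pass ``reference_timepoint="control"`` to reference
    the post-control-solution image instead.
    """
    if reference_timepoint not in session.timepoints:
        raise ScoringError(f"session has no {reference_timepoint!r} reference timepoint")
    if timepoint not in session.timepoints:
        raise ScoringError(f"session has no timepoint {timepoint!r}")
    segmenter = segmenter or get_segmenter("baseline")
    cache = _cache if _cache is not None else {}
    treated_ref = _pooled_distribution(session, reference_timepoint, TREATED_EYE, segmenter, cache)
    treated_tp = _pooled_distribution(session, timepoint, TREATED_EYE, segmenter, cache)
    control_ref = _pooled_distribution(session, reference_timepoint, CONTROL_EYE, segmenter, cache)
    control_tp = _pooled_distribution(session, timepoint, CONTROL_EYE, segmenter, cache)
    return score_from_distributions(
        treated_ref,
        treated_tp,
        control_ref,
        control_tp,
        timepoint=timepoint,
        normalize=normalize,
    )


def score_session(
    session: MeasurementSession,
    *,
    segmenter: Optional[Callable] = None,
    reference_timepoint: str = "baseline",
    normalize: bool = True,
) -> list:
    """Score every provocation timepoint of a session (segmenting each
    image once)."""
    cache: Dict = {}
    return [
        score_timepoint(
            session,
            tp,
            segmenter=segmenter,
            reference_timepoint=reference_timepoint,
            normalize=normalize,
            _cache=cache,
        )
        for tp in session.provocation_timepoints
        if tp != reference_timepoint
    ]


def classify_score(score: InstrumentScore | float, threshold: float) -> bool:
    """Positive iff the score is strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    value = score.score if isinstance(score, InstrumentScore) else float(score)
    return value > threshold
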