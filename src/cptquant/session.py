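"""Measurement-session container for one patient's titrated CPT.

A session holds, per timepoint (pre-test baseline, control solution, then
allergen dilutions 1:1000, 1:100, 1:10 and stock at 30 HEP/mL), RGB images
of both eyes in the 3 gaze positions, plus the per-timepoint symptom
grades.  The protocol treats the left eye; the right eye stays untreated
and serves as the internal control for white-balance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = [
    "TIMEPOINTS",
    "DILUTIONS",
    "GAZES",
    "TREATED_EYE",
    "CONTROL_EYE",
    "EYES",
    "STOCK_HEP_PER_ML",
    "MeasurementSession",
]

TIMEPOINTS = ("baseline", "control", "1:1000", "1:100", "1:10", "stock")
DILUTIONS = ("1:1000", "1:100", "1:10", "stock")
GAZES = ("straight", "left", "right")
TREATED_EYE = "left"
CONTROL_EYE = "right"
EYES = (TREATED_EYE, CONTROL_EYE)
STOCK_HEP_PER_ML = 30.0


@dataclass
class MeasurementSession:
    """One patient's CPT image series.

    ``images[timepoint][eye][gaze]`` is an 8-bit RGB array.  Timepoints must
    form a prefix of the protocol order (early stop after the first reactive
    dilution is allowed) and the baseline must be present.
    """

    patient_id: str
    timepoints: tuple
    images: Dict[str, Dict[str, Dict[str, np.ndarray]]]
    symptoms: Dict[str, object] = field(default_factory=dict)
    stock_concentration_hep_per_ml: float = STOCK_HEP_PER_ML

    def __post_init__(self) -> None:
        self.timepoints = tuple(self.timepoints)
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("duplicate timepoints in session")
        if self.timepoints != TIMEPOINTS[: len(self.timepoints)]:
            raise ValueError(
                f"timepoints {self.timepoints} are not an ordered prefix of {TIMEPOINTS}"
            )
        if "baseline" not in self.timepoints:
            raise ValueError("session is missing the baseline timepoint")
        for tp in self.timepoints:
            if tp not in self.images:
                raise ValueError(f"missing images for timepoint {tp!r}")
            for eye in EYES:
                if eye not in self.images[tp]:
                    raise ValueError(f"missing {eye} eye images at timepoint {tp!r}")
                for gaze in GAZES:
                    if gaze not in self.images[tp][eye]:
                        raise ValueError(
                            f"missing {gaze!r} gaze image for {eye} eye at {tp!r}"
                        )

    @property
    def provocation_timepoints(self) -> tuple:
        """All timepoints after the baseline (control solution + dilutions)."""
        return tuple(tp for tp in self.timepoints if tp != "baseline")

    @property
    def dilution_timepoints(self) -> tuple:
        return tuple(tp for tp in self.timepoints if tp in DILUTIONS)

    def eye_images(self, timepoint: str, eye: str) -> Dict[str, np.ndarray]:
        return self.images[timepoint][eye]
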