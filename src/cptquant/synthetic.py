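"""Synthetic eye phantoms, CPT sessions and patient cohorts.

Every downstream module is testable without any external data: the phantom
renderer produces eye images with exact ground-truth masks and a known
injected redness signal, the session renderer emulates the titration
protocol (both eyes, 3 gaze positions, per-timepoint illumination cast),
and the cohort simulator produces patient tables with known latent
allergen sensitivity.

What the phantom emulates: an elliptical sclera on a skin background, a
dark iris disk whose position follows gaze, conjunctival vessels drawn as
random-walk polylines with a Gaussian cross-section, diffuse redness as a
uniform red-channel increment over the sclera, a per-channel multiplicative
illumination cast (the white-balance confounder), global exposure, and
per-channel Gaussian sensor noise before 8-bit quantization
(round-half-up, so renders are bit-reproducible).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import redness as _redness
from .session import CONTROL_EYE, DILUTIONS, GAZES, TIMEPOINTS, TREATED_EYE, MeasurementSession

__all__ = [
    "EyePhantomSpec",
    "GroundTruth",
    "GeometryError",
    "render_eye_image",
    "render_session",
    "sample_cast_drift",
    "CohortSpec",
    "simulate_cohort",
    "phantom_grid",
    "SENSITIVITY_LEVEL",
]

#: numeric sensitivity level: higher = reacts at a weaker dilution
SENSITIVITY_LEVEL = {"none": 0, "stock": 1, "1:10": 2, "1:100": 3, "1:1000": 4}

_GAZE_INDEX = {g: i for i, g in enumerate(GAZES)}
#: lateral iris displacement per gaze, as a fraction of the iris radius
_GAZE_SHIFT = {"straight": 0.0, "left": -0.45, "right": 0.45}


class GeometryError(ValueError):
    """Phantom geometry is invalid (iris not strictly inside the sclera)."""


@dataclass(frozen=True)
class EyePhantomSpec:
    """Parameters of one synthetic eye.

    Colors are RGB triples in [0, 1]; the illumination cast is a
    per-channel multiplicative gain applied (with exposure) after the scene
    colors are composed, emulating a white-balance shift of the capture.
    """

    image_width: int = 192
    image_height: int = 144
    iris_center: Tuple[float, float] = (96.0, 72.0)
    iris_radius: float = 26.0
    sclera_ellipse: Tuple[Tuple[float, float], Tuple[float, float]] = ((96.0, 72.0), (74.0, 40.0))
    base_sclera_color: Tuple[float, float, float] = (0.82, 0.80, 0.78)
    vessel_count: int = 6
    vessel_intensity: float = 0.12
    diffuse_redness: float = 0.0
    illumination_cast: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    exposure: float = 1.0
    noise_sd: float = 0.008
    seed: int = 0
    skin_color: Tuple[float, float, float] = (0.80, 0.62, 0.52)
    iris_color: Tuple[float, float, float] = (0.30, 0.24, 0.18)

    def __post_init__(self) -> None:
        if self.image_width < 16 or self.image_height < 16:
            raise ValueError("image too small")
        if self.iris_radius <= 0:
            raise ValueError("iris radius must be positive")
        if self.vessel_count < 0:
            raise ValueError("vessel count must be >= 0")
        for name in ("vessel_intensity", "diffuse_redness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(c <= 0 for c in self.illumination_cast):
            raise ValueError("illumination cast gains must be > 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for name in ("base_sclera_color", "skin_color", "iris_color"):
            if any(not 0.0 <= c <= 1.0 for c in getattr(self, name)):
                raise ValueError(f"{name} components must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact masks and injected-redness signal of a rendered phantom.

    ``mean_injected_redness`` is the mean, over the sclera mask, of the
    redness-index increase caused by the vessel and diffuse redness
    sources, measured on the ideal (cast-, noise- and quantization-free)
    scene against the same scene without redness sources.
    """

    sclera_mask: np.ndarray
    iris_mask: np.ndarray
    mean_injected_redness: float

    def __post_init__(self) -> None:
        if bool(np.any(self.sclera_mask & self.iris_mask)):
            raise ValueError("ground-truth masks overlap")
        if not self.sclera_mask.any():
            raise ValueError("ground-truth sclera mask is empty")


def _gaze_iris_center(spec: EyePhantomSpec, gaze: str) -> Tuple[float, float]:
    cx, cy = spec.iris_center
    return (cx + _GAZE_SHIFT[gaze] * spec.iris_radius, cy)


def _check_geometry(spec: EyePhantomSpec, gaze: str) -> None:
    (ecx, ecy), (ea, eb) = spec.sclera_ellipse
    icx, icy = _gaze_iris_center(spec, gaze)
    theta = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
    px = icx + spec.iris_radius * np.cos(theta)
    py = icy + spec.iris_radius * np.sin(theta)
    inside = ((px - ecx) / ea) ** 2 + ((py - ecy) / eb) ** 2 < 1.0
    if not inside.all():
        raise GeometryError(
            f"iris (center {icx:.1f},{icy:.1f}, radius {spec.iris_radius}) is not "
            f"strictly inside the sclera ellipse for gaze {gaze!r}"
        )


def _vessel_field(spec: EyePhantomSpec, sclera: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vessel intensity raster in [0, 1]: random-walk polylines stamped with
    a Gaussian cross-section, restricted to the sclera."""
    h, w = sclera.shape
    f = np.zeros((h, w))
    if spec.vessel_count == 0 or not sclera.any():
        return f
    ys, xs = np.nonzero(sclera)
    sigma = 1.1
    win = 3
    offs = np.arange(-win, win + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    for _ in range(spec.vessel_count):
        i = rng.integers(len(xs))
        x, y = float(xs[i]), float(ys[i])
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(25, 45))
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.35)
            x += 1.6 * np.cos(ang)
            y += 1.6 * np.sin(ang)
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h) or not sclera[yi, xi]:
                break
            yy = np.clip(yi + oy, 0, h - 1)
            xx = np.clip(xi + ox, 0, w - 1)
            d2 = (yi + oy - y) ** 2 + (xi + ox - x) ** 2
            np.maximum.at(f, (yy, xx), np.exp(-d2 / (2 * sigma**2)))
    f *= sclera
    return np.clip(f, 0.0, 1.0)


def _quantize(img: np.ndarray) -> np.ndarray:
    """8-bit quantization with round-half-up (fixed for bit-exact renders)."""
    return np.floor(np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def _compose_scene(
    spec: EyePhantomSpec, gaze: str, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ideal (pre-cast, pre-noise) scene; returns (scene, base_scene,
    sclera_mask, iris_mask).  ``base_scene`` is the same scene with the
    redness sources removed, used for the injected-redness ground truth."""
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w]
    (ecx, ecy), (ea, eb) = spec.sclera_ellipse
    ellipse = ((xx - ecx) / ea) ** 2 + ((yy - ecy) / eb) ** 2 <= 1.0
    icx, icy = _gaze_iris_center(spec, gaze)
    iris = (xx - icx) ** 2 + (yy - icy) ** 2 <= spec.iris_radius**2
    sclera = ellipse & ~iris

    base = np.empty((h, w, 3))
    base[:] = spec.skin_color
    base[ellipse] = spec.base_sclera_color
    base[iris] = spec.iris_color

    vessels = _vessel_field(spec, sclera, rng)
    injected = (spec.diffuse_redness * sclera + spec.vessel_intensity * vessels) * sclera

    scene = base.copy()
    scene[..., 0] = np.clip(scene[..., 0] + injected, 0.0, 1.0)
    return scene, base, sclera, iris


def render_eye_image(
    spec: EyePhantomSpec,
    gaze: str = "straight",
    *,
    noise_salt: int = 0,
    validate_geometry: bool = True,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render one 8-bit RGB eye image plus its ground truth.

    The gaze position shifts the iris laterally, exposing a different
    portion of the sclera.  Vessel layout is a pure function of
    ``spec.seed`` and the gaze, so the same eye keeps its vessels across
    timepoints; ``noise_salt`` decorrelates only the sensor noise between
    repeated captures.  Identical spec, gaze and salt give a bit-identical
    image.
    """
    if gaze not in GAZES:
        raise ValueError(f"unknown gaze {gaze!r}; expected one of {GAZES}")
    if validate_geometry:
        _check_geometry(spec, gaze)

    vessel_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _GAZE_INDEX[gaze]]))
    scene, base, sclera, iris = _compose_scene(spec, gaze, vessel_rng)

    def _index_mean(img: np.ndarray) -> float:
        vals = _redness.pixel_redness(img[..., 0], img[..., 1], img[..., 2])
        return float(vals[sclera].mean())

    mean_injected = max(0.0, _index_mean(scene) - _index_mean(base))

    cast = np.asarray(spec.illumination_cast) * spec.exposure
    out = scene * cast
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, _GAZE_INDEX[gaze], 1 + noise_salt])
        )
        out = out + noise_rng.normal(0.0, spec.noise_sd, out.shape)
    image = _quantize(out)
    gt = GroundTruth(
        sclera_mask=sclera, iris_mask=iris, mean_injected_redness=mean_injected
    )
    return image, gt


def _mix_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def sample_cast_drift(
    timepoints: Sequence[str], seed: int
) -> Dict[str, Tuple[float, float, float]]:
    """Draw a per-timepoint illumination cast emulating warm room-light
    drift during the titration.

    The LED face mask stabilizes most of the illumination, so the modeled
    residual drift is a red-channel gain of +8-14% with ~1% jitter on
    green/blue, applied identically to both eyes.  The baseline timepoint
    keeps the neutral cast.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    drift: Dict[str, Tuple[float, float, float]] = {}
    for tp in timepoints:
        if tp == "baseline":
            drift[tp] = (1.0, 1.0, 1.0)
        else:
            drift[tp] = (
                float(rng.uniform(1.08, 1.14)),
                float(rng.uniform(0.99, 1.01)),
                float(rng.uniform(0.99, 1.01)),
            )
    return drift


def render_session(
    phantom: EyePhantomSpec,
    reaction_profile: Mapping[str, float],
    cast_drift: Optional[Mapping[str, Tuple[float, float, float]]] = None,
    *,
    patient_id: str = "synthetic",
    symptoms: Optional[Mapping[str, object]] = None,
    return_ground_truth: bool = False,
):
    """Render a full CPT session for one synthetic patient.

    ``reaction_profile`` maps each timepoint of an ordered protocol prefix
    to the diffuse-redness increment of the treated (left) eye at that
    timepoint; entries may also be ``{"left": x}`` mappings.  Any redness
    assigned to the untreated (right) eye is rejected — by protocol the
    right eye is the internal control and never receives allergen.  The
    illumination cast of a timepoint applies to both eyes equally.

    With ``return_ground_truth=True`` also returns
    ``{timepoint: {eye: {gaze: GroundTruth}}}``.
    """
    increments: Dict[str, float] = {}
    for tp, entry in reaction_profile.items():
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
        if isinstance(entry, Mapping):
            bad = {e: v for e, v in entry.items() if e != TREATED_EYE and v}
            if bad:
                raise ValueError(
                    f"reaction profile assigns redness to the untreated eye at {tp!r}: {bad}"
                )
            increments[tp] = float(entry.get(TREATED_EYE, 0.0))
        else:
            increments[tp] = float(entry)
        if increments[tp] < 0:
            raise ValueError("redness increments must be >= 0")

    timepoints = TIMEPOINTS[: len(increments)]
    if set(increments) != set(timepoints):
        raise ValueError(
            f"reaction profile must cover an ordered prefix of {TIMEPOINTS}, got {sorted(increments)}"
        )
    cast_drift = dict(cast_drift or {})

    eye_seeds = {
        TREATED_EYE: _mix_seed(phantom.seed, 0),
        CONTROL_EYE: _mix_seed(phantom.seed, 1),
    }
    images: Dict[str, Dict[str, Dict[str, np.ndarray]]] = {}
    truths: Dict[str, Dict[str, Dict[str, GroundTruth]]] = {}
    for t_idx, tp in enumerate(timepoints):
        tp_cast = np.asarray(cast_drift.get(tp, (1.0, 1.0, 1.0)))
        cast = tuple(float(c) for c in np.asarray(phantom.illumination_cast) * tp_cast)
        images[tp] = {}
        truths[tp] = {}
        for eye in (TREATED_EYE, CONTROL_EYE):
            extra = increments[tp] if eye == TREATED_EYE else 0.0
            spec = dataclasses.replace(
                phantom,
                seed=eye_seeds[eye],
                diffuse_redness=min(1.0, phantom.diffuse_redness + extra),
                illumination_cast=cast,
            )
            images[tp][eye] = {}
            truths[tp][eye] = {}
            for gaze in GAZES:
                img, gt = render_eye_image(spec, gaze, noise_salt=t_idx)
                images[tp][eye][gaze] = img
                truths[tp][eye][gaze] = gt

    session = MeasurementSession(
        patient_id=patient_id,
        timepoints=timepoints,
        images=images,
        symptoms=dict(symptoms or {}),
    )
    if return_ground_truth:
        return session, truths
    return session


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Latent structure of a synthetic CPT cohort.

    ``latent_sensitivity_distribution`` gives the probabilities of the five
    sensitivity categories (weakest reactive dilution, or "none").
    ``cap_class_model`` maps each category to the median sIgE in kU/L and
    the log-normal spread of its distribution.  Instrument scores at the
    reactive timepoint rise with latent sensitivity above the noise floor;
    symptom grades carry a weak reactive signal on top of dominant
    observer/subject noise.
    """

    n_patients: int = 41
    latent_sensitivity_distribution: Mapping[str, float] = field(
        default_factory=lambda: {
            "1:1000": 4 / 41,
            "1:100": 11 / 41,
            "1:10": 16 / 41,
            "stock": 7 / 41,
            "none": 3 / 41,
        }
    )
    cap_class_model: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "1:1000": (40.0, 0.6),
            "1:100": (15.0, 0.6),
            "1:10": (6.0, 0.6),
            "stock": (2.0, 0.6),
            "none": (0.5, 0.6),
        }
    )
    symptom_noise_sd: float = 0.8
    instrument_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        probs = dict(self.latent_sensitivity_distribution)
        if set(probs) != set(SENSITIVITY_LEVEL):
            raise ValueError(f"distribution must cover categories {sorted(SENSITIVITY_LEVEL)}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("category probabilities must be >= 0 and sum to 1")
        if self.symptom_noise_sd < 0 or self.instrument_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


def _quota_counts(probs: Mapping[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of n patients to categories, so a
    probability vector that is an exact multiple of 1/n reproduces its
    counts exactly."""
    cats = list(probs)
    raw = np.array([probs[c] * n for c in cats])
    counts = np.floor(raw + 1e-9).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        for i in order[:short]:
            counts[i] += 1
    return dict(zip(cats, counts.tolist()))


#: instrument-score model at the reactive timepoint: noise floor offset plus
#: a slope in the latent sensitivity level (range stays within the 0-3.7
#: score axis)
_SCORE_BASE = 0.65
_SCORE_SLOPE = 0.25
#: symptom-grade model: weak mean shift at the reactive timepoint on top of
#: a constant propensity, before dominant Gaussian observer noise
_SYMPTOM_BASE = 0.3
_SYMPTOM_REACTIVE_SHIFT = 0.7


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a CPT cohort; one row per patient-dilution measurement.

    Measurements follow the clinical stop rule keyed to the *latent*
    sensitivity (the operator stops at the first reactive dilution), so the
    ground truth stays exact: a patient's rows cover the dilutions up to
    and including their first reactive one, or all four if non-reactive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    counts = _quota_counts(dict(spec.latent_sensitivity_distribution), spec.n_patients)
    categories = [c for c, k in counts.items() for _ in range(k)]
    categories = [categories[i] for i in rng.permutation(len(categories))]

    rows = []
    for p_idx, category in enumerate(categories):
        median, sigma = spec.cap_class_model[category]
        sige = float(median * np.exp(rng.normal(0.0, sigma)))
        level = SENSITIVITY_LEVEL[category]
        if category == "none":
            measured = list(DILUTIONS)
        else:
            measured = list(DILUTIONS[: DILUTIONS.index(category) + 1])
        for dilution in measured:
            reactive = dilution == category
            if reactive:
                score = _SCORE_BASE + _SCORE_SLOPE * level + rng.normal(
                    0.0, spec.instrument_noise_sd
                )
                score = max(score, 0.0)
            else:
                score = abs(rng.normal(0.0, spec.instrument_noise_sd))
            grade_mean = _SYMPTOM_BASE + (_SYMPTOM_REACTIVE_SHIFT if reactive else 0.0)
            grades = np.clip(
                np.round(grade_mean + rng.normal(0.0, spec.symptom_noise_sd, 4)), 0, 3
            ).astype(int)
            rows.append(
                {
                    "patient_id": f"P{p_idx:03d}",
                    "latent_sensitivity": category,
                    "sige_ku_per_l": sige,
                    "dilution": dilution,
                    "tearing": grades[0],
                    "itching": grades[1],
                    "irritation": grades[2],
                    "redness_grade": grades[3],
                    "sss": int(grades.sum()),
                    "instrument_score": float(score),
                    "reactive": reactive,
                }
            )
    return pd.DataFrame(rows)


def phantom_grid(n: int = 20, *, seed: int = 202) -> list:
    """Fixed grid of phantom specs used as the validation fixture set.

    Sweeps diffuse redness, vessel density, illumination cast and exposure
    over realistic CPT ranges; the layout seed is part of each spec so the
    grid is fully deterministic.
    """
    diffuse = (0.0, 0.05, 0.10, 0.15)
    vessels = (4, 6, 8)
    casts = ((1.0, 1.0, 1.0), (1.08, 1.0, 0.99), (1.12, 1.0, 1.0))
    exposures = (0.9, 1.0, 1.1)
    specs = []
    for i in range(n):
        specs.append(
            EyePhantomSpec(
                diffuse_redness=diffuse[i % len(diffuse)],
                vessel_count=vessels[i % len(vessels)],
                illumination_cast=casts[i % len(casts)],
                exposure=exposures[i % len(exposures)],
                seed=seed + i,
            )
        )
    return specs
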