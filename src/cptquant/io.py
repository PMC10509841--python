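"""File formats: session manifests, images/masks, cohort tables, config.

Sessions round-trip through a JSON manifest that names every image by
timepoint, eye and gaze (explicit labels prevent silent left/right swaps,
which would invert the internal-control logic) plus 8-bit PNG images.
Masks round-trip as single-channel 0/255 PNG, redness maps as 32-bit float
TIFF, distributions and cohorts as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .clinical import CAP_BOUNDARIES, SYMPTOMS, SymptomRecord
from .redness import N_BINS, RednessDistribution, RednessMap
from .session import EYES, GAZES, TIMEPOINTS, MeasurementSession

__all__ = [
    "SessionLoadError",
    "write_session",
    "read_session",
    "write_mask",
    "read_mask",
    "write_redness_map",
    "write_distribution_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "RunConfig",
    "load_config",
]


class SessionLoadError(ValueError):
    """A session manifest or its referenced images failed to load."""


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def read_image(path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim != 3 or img.shape[-1] < 3:
        raise SessionLoadError(f"{path}: not an RGB image")
    return np.ascontiguousarray(img[..., :3])


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_redness_map(path, rmap: RednessMap) -> None:
    """Redness map as 32-bit float TIFF; off-mask pixels are NaN."""
    out = np.where(rmap.mask, rmap.values, np.nan).astype(np.float32)
    tifffile.imwrite(Path(path), out)


def write_distribution_csv(path, dist: RednessDistribution) -> None:
    pd.DataFrame({"bin_edge": dist.bin_edges[:-1], "count": dist.counts}).to_csv(
        Path(path), index=False
    )


def write_session(session: MeasurementSession, outdir) -> Path:
    """Write a session as PNG images plus a JSON manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tp in session.timepoints:
        record = {"timepoint": tp, "images": {}}
        for eye in EYES:
            record["images"][eye] = {}
            for gaze in GAZES:
                name = f"{tp.replace(':', '_')}__{eye}__{gaze}.png"
                write_image(outdir / name, session.images[tp][eye][gaze])
                record["images"][eye][gaze] = name
        if tp in session.symptoms:
            rec = session.symptoms[tp]
            record["symptoms"] = {s: getattr(rec, s) for s in SYMPTOMS}
        entries.append(record)
    manifest = {
        "patient_id": session.patient_id,
        "stock_concentration_hep_per_ml": session.stock_concentration_hep_per_ml,
        "timepoints": entries,
    }
    path = outdir / "session.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_session(manifest_path) -> MeasurementSession:
    """Load a session manifest, enforcing schema, eye labels, timepoint
    ordering and image existence."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionLoadError(f"cannot read manifest {manifest_path}: {exc}") from exc
    for key in ("patient_id", "timepoints"):
        if key not in manifest:
            raise SessionLoadError(f"manifest missing required key {key!r}")

    seen = set()
    images: Dict[str, Dict[str, Dict[str, np.ndarray]]] = {}
    symptoms: Dict[str, SymptomRecord] = {}
    order = []
    for record in manifest["timepoints"]:
        tp = record.get("timepoint")
        if tp not in TIMEPOINTS:
            raise SessionLoadError(f"unknown timepoint {tp!r}")
        if tp in seen:
            raise SessionLoadError(f"duplicate timepoint {tp!r} in manifest")
        seen.add(tp)
        order.append(tp)
        images[tp] = {}
        for eye in EYES:
            if eye not in record.get("images", {}):
                raise SessionLoadError(f"timepoint {tp!r} missing {eye!r} eye images")
            images[tp][eye] = {}
            for gaze in GAZES:
                if gaze not in record["images"][eye]:
                    raise SessionLoadError(
                        f"timepoint {tp!r}, eye {eye!r} missing gaze {gaze!r}"
                    )
                path = manifest_path.parent / record["images"][eye][gaze]
                if not path.exists():
                    raise SessionLoadError(f"referenced image does not exist: {path}")
                images[tp][eye][gaze] = read_image(path)
        if "symptoms" in record:
            symptoms[tp] = SymptomRecord(**record["symptoms"])
    if "baseline" not in seen:
        raise SessionLoadError("manifest is missing the 'baseline' timepoint")
    try:
        return MeasurementSession(
            patient_id=manifest["patient_id"],
            timepoints=tuple(order),
            images=images,
            symptoms=symptoms,
            stock_concentration_hep_per_ml=manifest.get(
                "stock_concentration_hep_per_ml", 30.0
            ),
        )
    except ValueError as exc:
        raise SessionLoadError(str(exc)) from exc


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(Path(path), index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"patient_id", "sige_ku_per_l", "dilution", "sss", "instrument_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """Run-level configuration; unknown keys in a config file are rejected."""

    histogram_bins: int = N_BINS
    shift_search_span_bins: int = N_BINS
    clip_scores: bool = True
    classification_threshold: float = 0.3
    stringent_threshold: float = 0.5
    cap_boundaries: Tuple[float, ...] = CAP_BOUNDARIES
    specificity_floor: float = 0.97
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.histogram_bins < 2 or self.shift_search_span_bins < 1:
            raise ValueError("histogram/shift-span sizes must be positive")
        for name in ("classification_threshold", "stringent_threshold", "specificity_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.cap_boundaries = tuple(float(b) for b in self.cap_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(self.cap_boundaries, self.cap_boundaries[1:])):
            raise ValueError("cap_boundaries must be strictly increasing")


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
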