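# cptquant

Instrument-grade quantification of eye redness in the **conjunctival
provocation test (CPT)**, for allergologists and researchers who need an
objective, reproducible alternative to subjective symptom grading.

In a titrated CPT, allergen is applied to the left eye in increasing
concentrations (1:1000, 1:100, 1:10, stock at 30 HEP/mL) and the reaction
is read from conjunctival redness.  `cptquant` turns per-session eye
photographs (both eyes × 3 gaze positions × timepoints) into a scalar
redness score per provocation step:

1. **Segmentation** — sclera and iris masks with validity checks
   (pluggable; a classical baseline is included).
2. **Per-pixel redness** over the sclera, for normalized channels
   `r, g, b` and `s = √(r²+g²+b²)`:

   `R = (27/4) · (r − √((g²+b²)/2)) / s · (1 − s)²`

   Achromatic pixels score 0; saturated pixels (`s = 1`) are suppressed.
3. **Internal-control white-balance normalization** — the untreated right
   eye never receives allergen, so its redness distribution is aligned
   between timepoints (maximum histogram-intersection overlap) and the
   resulting shift removes illumination drift from both eyes.
4. **Score** — the increase of the treated eye's mean redness over its
   baseline after normalization, clipped at 0 (score axis 0–3.7).
5. **Clinical evaluation** — summation symptom score (SSS, 0–12), the
   titration stop rule, sIgE CAP classes (0–6), sensitivity categories
   under human/instrument rules, ROC threshold calibration (optimal by
   Youden's J, stringent by a specificity floor) and CAP-vs-sensitivity
   t-test tables.

A synthetic module renders eye phantoms with exact ground-truth masks and
injected-redness signal, full sessions with illumination cast drift, and
cohorts with known latent sensitivity, so the entire pipeline is testable
without any clinical data.

## Worked example

Render a synthetic session with illumination drift and a reaction starting
at dilution 1:100, then score it:

```python
from cptquant import EyePhantomSpec, render_session, score_session
from cptquant.synthetic import sample_cast_drift

phantom = EyePhantomSpec(seed=7)
profile = {"baseline": 0.0, "control": 0.0, "1:1000": 0.0,
           "1:100": 0.06, "1:10": 0.12}          # diffuse redness increments
drift = sample_cast_drift(list(profile), seed=7)  # warm white-balance drift
session = render_session(phantom, profile, drift, patient_id="demo")

for r in score_session(session):
    print(f"{r.timepoint:>7s}  score={r.score:.3f}  "
          f"raw={r.raw_difference:+.3f}  shift={r.applied_shift:+.3f}")
```

```
control  score=0.000  raw=-0.015  shift=-0.089
 1:1000  score=0.006  raw=+0.006  shift=-0.089
  1:100  score=0.074  raw=+0.074  shift=-0.089
   1:10  score=0.116  raw=+0.116  shift=-0.089
```

The control-solution and 1:1000 steps score ≈ 0 — the applied shift of
−0.089 redness units has absorbed the simulated white-balance drift — and
the score then rises with the injected redness (ground truth ≈ 0.05 and
0.12 at the last two steps).  At the usual classification threshold of
0.3 this synthetic patient would be graded non-reactive; phantom scores
are small because the injected diffuse increments are kept below channel
clipping (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
cptquant simulate --patients 41 --seed 1 --out cohort.csv
cptquant classify cohort.csv --rule instrument --threshold 0.5
cptquant report cohort.csv
```

## Layout

| module | contents |
| --- | --- |
| `cptquant.redness` | per-pixel index, distributions, gradient features |
| `cptquant.segmentation` | baseline segmenter, validity checks, registry |
| `cptquant.scoring` | distribution alignment, instrument score, classification |
| `cptquant.clinical` | SSS, titration stop rule, CAP classes, category rules |
| `cptquant.evaluation` | ROC sweep, threshold selection, CAP comparisons |
| `cptquant.synthetic` | phantoms, sessions, cohorts with ground truth |
| `cptquant.io` / `cptquant.cli` | manifests, masks, CSV/TIFF/config, CLI |
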