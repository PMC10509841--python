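"""Generator contracts: determinism, geometry, ground truth, cohorts."""

import numpy as np
import pandas as pd
import pytest

from cptquant import redness as rd
from cptquant.session import DILUTIONS, GAZES, TIMEPOINTS
from cptquant.synthetic import (
    CohortSpec,
    EyePhantomSpec,
    GeometryError,
    render_eye_image,
    render_session,
    simulate_cohort,
)


def sclera_mean_redness(image, gt):
    f = image.astype(float) / 255.0
    vals = rd.pixel_redness(f[..., 0], f[..., 1], f[..., 2])
    return vals[gt.sclera_mask].mean()


class TestRenderEyeImage:
    def test_same_seed_and_spec_bit_identical(self, default_spec):
        a, _ = render_eye_image(default_spec, "straight")
        b, _ = render_eye_image(default_spec, "straight")
        assert np.array_equal(a, b)

    def test_no_redness_sources_uniform_sclera(self, flat_spec):
        spec = flat_spec
        img, gt = render_eye_image(spec)
        sclera_px = img[gt.sclera_mask]
        assert (sclera_px == sclera_px[0]).all()
        expected = np.floor(
            np.clip(np.array(spec.base_sclera_color) * np.array(spec.illumination_cast)
                    * spec.exposure, 0, 1) * 255 + 0.5
        ).astype(np.uint8)
        assert np.array_equal(sclera_px[0], expected)

    def test_gain_and_exposure_applied_multiplicatively(self):
        spec = EyePhantomSpec(vessel_count=0, noise_sd=0.0,
                              illumination_cast=(1.1, 0.95, 1.0), exposure=0.9)
        img, gt = render_eye_image(spec)
        expected = np.floor(
            np.clip(np.array(spec.base_sclera_color) * np.array([1.1, 0.95, 1.0]) * 0.9, 0, 1)
            * 255 + 0.5
        )
        assert np.array_equal(img[gt.sclera_mask][0], expected.astype(np.uint8))

    def test_gaze_shifts_iris(self, default_spec):
        centers = {}
        for gaze in GAZES:
            _, gt = render_eye_image(default_spec, gaze)
            ys, xs = np.nonzero(gt.iris_mask)
            centers[gaze] = xs.mean()
        assert centers["left"] < centers["straight"] < centers["right"]

    def test_invalid_geometry_rejected(self):
        spec = EyePhantomSpec(iris_radius=50.0)  # larger than the ellipse minor axis
        with pytest.raises(GeometryError):
            render_eye_image(spec)

    def test_masks_disjoint_and_sclera_nonempty(self, clean_render):
        _, gt = clean_render
        assert not (gt.sclera_mask & gt.iris_mask).any()
        assert gt.sclera_mask.any()

    def test_diffuse_redness_raises_measured_mean(self):
        lo = EyePhantomSpec(diffuse_redness=0.0, noise_sd=0.0, seed=7)
        hi = EyePhantomSpec(diffuse_redness=0.2, noise_sd=0.0, seed=7)
        img_lo, gt_lo = render_eye_image(lo)
        img_hi, gt_hi = render_eye_image(hi)
        assert sclera_mean_redness(img_hi, gt_hi) > sclera_mean_redness(img_lo, gt_lo)
        assert gt_hi.mean_injected_redness > gt_lo.mean_injected_redness

    def test_measured_mean_monotone_in_diffuse_redness(self):
        amplitudes = [0.0, 0.04, 0.08, 0.12, 0.16, 0.20]
        means = []
        for a in amplitudes:
            img, gt = render_eye_image(EyePhantomSpec(diffuse_redness=a, noise_sd=0.0, seed=9))
            means.append(sclera_mean_redness(img, gt))
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_injected_redness_confined_to_sclera(self):
        # against the same spec without redness sources, only sclera pixels change
        with_red = EyePhantomSpec(diffuse_redness=0.15, vessel_count=8, noise_sd=0.0, seed=3)
        without = EyePhantomSpec(diffuse_redness=0.0, vessel_count=0, noise_sd=0.0, seed=3)
        img_a, gt = render_eye_image(with_red)
        img_b, _ = render_eye_image(without)
        changed = (img_a != img_b).any(axis=-1)
        assert changed.any()
        assert not (changed & ~gt.sclera_mask).any()


class TestRenderSession:
    def test_control_eye_never_receives_redness(self, default_spec):
        profile = {"baseline": 0.0, "control": {"left": 0.0, "right": 0.1}}
        with pytest.raises(ValueError, match="untreated eye"):
            render_session(default_spec, profile)

    def test_zero_increments_images_identical_up_to_noise(self):
        spec = EyePhantomSpec(noise_sd=0.0, seed=11)
        sess = render_session(spec, {"baseline": 0.0, "control": 0.0, "1:1000": 0.0})
        base = sess.images["baseline"]["left"]["straight"]
        for tp in ("control", "1:1000"):
            assert np.array_equal(sess.images[tp]["left"]["straight"], base)

    def test_first_redness_change_at_specified_timepoint(self):
        spec = EyePhantomSpec(noise_sd=0.0, seed=12)
        profile = {tp: 0.0 for tp in TIMEPOINTS[:5]}
        profile["1:10"] = 0.1
        sess, gts = render_session(spec, profile, return_ground_truth=True)
        base = gts["baseline"]["left"]["straight"].mean_injected_redness
        for tp in TIMEPOINTS[:5]:
            injected = gts[tp]["left"]["straight"].mean_injected_redness
            if tp == "1:10":
                assert injected > base + 0.01
            else:
                assert injected == pytest.approx(base, abs=1e-9)

    def test_session_structure(self, default_spec):
        sess = render_session(default_spec, {"baseline": 0.0, "control": 0.0})
        assert sess.timepoints == ("baseline", "control")
        for tp in sess.timepoints:
            for eye in ("left", "right"):
                assert set(sess.images[tp][eye]) == set(GAZES)

    def test_cast_applies_to_both_eyes_equally(self):
        spec = EyePhantomSpec(vessel_count=0, noise_sd=0.0, seed=13)
        cast = {"baseline": (1.0, 1.0, 1.0), "control": (1.1, 1.0, 0.95)}
        sess, gts = render_session(
            spec, {"baseline": 0.0, "control": 0.0}, cast, return_ground_truth=True
        )
        for eye in ("left", "right"):
            gt = gts["control"][eye]["straight"]
            px = sess.images["control"][eye]["straight"][gt.sclera_mask]
            expected = np.floor(
                np.clip(np.array(spec.base_sclera_color) * np.array([1.1, 1.0, 0.95]), 0, 1)
                * 255 + 0.5
            )
            assert np.array_equal(px[0], expected.astype(np.uint8))


class TestSimulateCohort:
    def test_deterministic_given_seed(self):
        a = simulate_cohort(CohortSpec(seed=5))
        b = simulate_cohort(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_point_mass_on_strongest_sensitivity_one_measurement_each(self):
        dist = {"1:1000": 1.0, "1:100": 0.0, "1:10": 0.0, "stock": 0.0, "none": 0.0}
        c = simulate_cohort(CohortSpec(n_patients=10, latent_sensitivity_distribution=dist))
        assert (c.groupby("patient_id").size() == 1).all()

    def test_point_mass_on_none_four_measurements_each(self):
        dist = {"1:1000": 0.0, "1:100": 0.0, "1:10": 0.0, "stock": 0.0, "none": 1.0}
        c = simulate_cohort(CohortSpec(n_patients=10, latent_sensitivity_distribution=dist))
        assert (c.groupby("patient_id").size() == 4).all()

    def test_study_cohort_structure_gives_114_measurements(self):
        c = simulate_cohort(CohortSpec(seed=1))
        assert c.patient_id.nunique() == 41
        assert len(c) == 114

    def test_stop_rule_no_measurement_past_first_reactive(self):
        c = simulate_cohort(CohortSpec(seed=2))
        for _, grp in c.groupby("patient_id"):
            cat = grp.latent_sensitivity.iloc[0]
            measured = set(grp.dilution)
            if cat == "none":
                assert measured == set(DILUTIONS)
            else:
                expected = set(DILUTIONS[: DILUTIONS.index(cat) + 1])
                assert measured == expected
                reactive_rows = grp[grp.reactive]
                assert list(reactive_rows.dilution) == [cat]

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(latent_sensitivity_distribution={"1:1000": 1.0})
        with pytest.raises(ValueError):
            CohortSpec(
                latent_sensitivity_distribution={
                    "1:1000": 0.5, "1:100": 0.5, "1:10": 0.5, "stock": -0.25, "none": -0.25
                }
            )
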