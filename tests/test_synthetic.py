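"""Synthetic renderers and cohort generators: determinism and round trips."""

import numpy as np
import pytest

from lbikit import (
    CameraModel,
    CohortSpec,
    EffectModel,
    OpticalProperties,
    extract_lbi_parameters,
    farrell_reflectance,
    generate_fruit_cohort,
    generate_phantom_images,
    generate_phantom_profiles,
    locate_incident_point,
    radial_attenuation_profile,
    render_backscatter_image,
    render_profile,
)
from lbikit.errors import InvalidInputError
from lbikit.phantoms import design_phantom_grid, mu_s_from_intralipid
from lbikit.synthetic import default_amplitude


class TestRenderImage:
    def test_noise_free_rendering_is_deterministic(self, small_camera):
        props = OpticalProperties(0.2, 4.0)
        a = render_backscatter_image(props, small_camera, seed=1)
        b = render_backscatter_image(props, small_camera, seed=99)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_same_seed_same_noisy_image(self):
        cam = CameraModel(width=128, height=128, noise_sigma=0.1, n_frames=1)
        props = OpticalProperties(0.2, 4.0)
        a = render_backscatter_image(props, cam, seed=7)
        b = render_backscatter_image(props, cam, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = render_backscatter_image(props, cam, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_center_saturates_with_default_amplitude(self, small_camera):
        img = render_backscatter_image(OpticalProperties(0.2, 4.0), small_camera)
        _, dip = locate_incident_point(img)
        assert dip > 0

    def test_extracted_profile_matches_generating_curve(self, small_camera):
        props = OpticalProperties(0.19, 3.10)
        amp = default_amplitude(props, small_camera)
        img = render_backscatter_image(props, small_camera, amplitude=amp)
        center, _ = locate_incident_point(img)
        prof = radial_attenuation_profile(img, center)
        model = amp * farrell_reflectance(prof.radii, props)
        unsat = (model < 0.9 * small_camera.saturation) & (model > 10)
        np.testing.assert_allclose(
            prof.intensities[unsat], model[unsat], rtol=0.02, atol=0.6
        )

    def test_blank_image_warns(self, small_camera):
        with pytest.warns(UserWarning, match="blank"):
            render_backscatter_image(OpticalProperties(0.5, 4.0), small_camera,
                                     amplitude=1e-9)


class TestRenderProfile:
    def test_round_trip_recovers_lbi_parameters(self):
        # descriptors from the rendered (quantized, clipped) profile agree
        # with those of the analytically clipped continuous curve within 2%
        cam = CameraModel(noise_sigma=0.0, n_frames=1)
        props = OpticalProperties(0.25, 3.5)
        amp = default_amplitude(props, cam)
        rendered = extract_lbi_parameters(render_profile(props, cam, amplitude=amp))
        radii = cam.profile_radii()
        from lbikit import AttenuationProfile

        clipped = np.minimum(amp * farrell_reflectance(radii, props), cam.saturation)
        analytic = extract_lbi_parameters(
            AttenuationProfile(radii=radii, intensities=clipped)
        )
        for name in ("Q1R", "FWHM", "Q3R", "SLP"):
            assert getattr(rendered, name) == pytest.approx(
                getattr(analytic, name), rel=0.02
            )
        assert rendered.DIP == pytest.approx(analytic.DIP, abs=cam.pixel_size)

    def test_frame_averaging_reduces_noise(self):
        props = OpticalProperties(0.2, 4.0)
        one = CameraModel(noise_sigma=0.1, n_frames=1)
        ten = CameraModel(noise_sigma=0.1, n_frames=10)
        amp = default_amplitude(props, one)
        ref = np.minimum(np.rint(amp * farrell_reflectance(one.profile_radii(), props)),
                         one.saturation)
        res_one, res_ten = [], []
        for seed in range(8):
            p1 = render_profile(props, one, amplitude=amp, seed=seed)
            p10 = render_profile(props, ten, amplitude=amp, seed=seed)
            sel = (ref > 10) & (ref < 0.9 * one.saturation)
            res_one.append(np.var((p1.intensities - ref)[sel]))
            res_ten.append(np.var((p10.intensities - ref)[sel]))
        assert np.mean(res_ten) < np.mean(res_one) / 4


class TestPhantomGenerators:
    def test_full_design_counts_and_truth(self, small_camera):
        profs, truth = generate_phantom_profiles(design_phantom_grid(), small_camera,
                                                 seed=0)
        assert len(profs) == 56 and len(truth) == 56
        expected = [mu_s_from_intralipid(c) for c in truth["intralipid_pct"]]
        np.testing.assert_allclose(truth["mu_s_star"], expected)

    def test_empty_design_rejected(self, small_camera):
        with pytest.raises(InvalidInputError):
            generate_phantom_profiles([], small_camera)

    def test_image_generator_stacks(self):
        cam = CameraModel(width=96, height=96, noise_sigma=0.05, n_frames=3)
        design = design_phantom_grid([5.2], [0.0, 0.3])
        stacks, truth = generate_phantom_images(design, cam, seed=4)
        assert len(stacks) == 2 and all(len(s) == 3 for s in stacks)
        again, _ = generate_phantom_images(design, cam, seed=4)
        np.testing.assert_array_equal(stacks[0][0].pixels, again[0][0].pixels)

    def test_profiles_deterministic_in_seed(self, noisy_small_camera):
        design = design_phantom_grid([3.12, 9.36], [0.0])
        a, _ = generate_phantom_profiles(design, noisy_small_camera, seed=21)
        b, _ = generate_phantom_profiles(design, noisy_small_camera, seed=21)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.intensities, pb.intensities)


class TestFruitCohort:
    small = dict(n_sound=6, n_moderate=4, n_severe=3)

    def test_same_seed_same_cohort(self, noisy_small_camera):
        a = generate_fruit_cohort(CohortSpec(**self.small, seed=5), noisy_small_camera)
        b = generate_fruit_cohort(CohortSpec(**self.small, seed=5), noisy_small_camera)
        for ra, rb in zip(a, b):
            assert ra.severity == rb.severity
            for pos in (1, 2, 3, 4):
                np.testing.assert_allclose(ra.lbi[pos].as_array(),
                                           rb.lbi[pos].as_array())

    def test_cohort_sizes_and_positions(self, noisy_small_camera):
        recs = generate_fruit_cohort(CohortSpec(**self.small, seed=2),
                                     noisy_small_camera)
        assert len(recs) == 13
        assert all(set(r.lbi) == {1, 2, 3, 4} for r in recs)
        assert sum(r.severity == "severe" for r in recs) == 3

    def test_null_effect_model_gives_chance_classification(self, noisy_small_camera):
        from lbikit.fda import fit_fda
        from lbikit.severity import cohort_features, per_class_tp_rate

        null = EffectModel(
            mu_a_multipliers={"sound": 1.0, "moderate": 1.0, "severe": 1.0},
            mu_s_multipliers={"sound": 1.0, "moderate": 1.0, "severe": 1.0},
        )
        spec = CohortSpec(n_sound=20, n_moderate=20, n_severe=20, effect=null, seed=9)
        recs = generate_fruit_cohort(spec, noisy_small_camera)
        feats, labels = cohort_features(recs, "wf")
        model = fit_fda(feats, labels)
        rates = per_class_tp_rate(labels, model.predict(feats))
        # no class should be recovered far above the 33% chance level
        assert np.mean(list(rates.values())) < 60.0

    def test_severe_effect_shifts_stylar_end_more_than_equator(self,
                                                               noisy_small_camera):
        recs = generate_fruit_cohort(CohortSpec(n_sound=10, n_moderate=2, n_severe=10,
                                                seed=3), noisy_small_camera)
        from lbikit.severity import cohort_features

        se, labels = cohort_features(recs, "se")
        eq, _ = cohort_features(recs, "eq")
        sev = np.array(labels) == "severe"
        snd = np.array(labels) == "sound"
        # SLP rises with absorption: the stylar end shows the larger shift
        d_se = se[sev, 4].mean() - se[snd, 4].mean()
        d_eq = eq[sev, 4].mean() - eq[snd, 4].mean()
        assert d_se > d_eq > 0
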