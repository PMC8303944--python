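"""Forward diffusion-reflectance model and inverse fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbikit import (
    DiffusionProfile,
    OpticalProperties,
    derive_farrell_params,
    farrell_reflectance,
    fit_optical_properties,
    simulate_profile,
)
from lbikit.errors import (
    FitUnderdeterminedError,
    InvalidInputError,
    InvalidParameterError,
)


def reflectance_oracle(r, mu_a, mu_s, n_rel):
    """Independent scalar evaluation of the closed-form reflectance.

    Written with the math module and explicit intermediate steps, no shared
    code with the implementation.
    """
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    z0 = 1.0 / mu_t
    mu_eff = math.sqrt(3.0 * mu_a * mu_t)
    r_d = -1.440 / (n_rel * n_rel) + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    big_a = (1.0 + r_d) / (1.0 - r_d)
    zb = 2.0 * big_a / (3.0 * mu_t)
    r1 = math.hypot(z0, r)
    r2 = math.hypot(z0 + 2.0 * zb, r)
    t1 = z0 * (mu_eff + 1.0 / r1) * math.exp(-mu_eff * r1) / (r1 * r1)
    t2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * math.exp(-mu_eff * r2) / (r2 * r2)
    return albedo / (4.0 * math.pi) * (t1 + t2)


class TestFarrellParams:
    def test_zero_absorption_limit(self):
        p = derive_farrell_params(OpticalProperties(1e-10, 5.0), n_rel=1.35)
        assert p.mu_eff == pytest.approx(0.0, abs=1e-4)
        assert p.albedo == pytest.approx(1.0, abs=1e-9)

    def test_analytic_values(self):
        p = derive_farrell_params(OpticalProperties(0.1, 5.0), n_rel=1.4)
        assert p.mu_t_prime == pytest.approx(5.1)
        assert p.z0 == pytest.approx(1 / 5.1)
        assert p.mu_eff == pytest.approx(math.sqrt(3 * 0.1 * 5.1), rel=1e-12)
        assert p.mu_eff == pytest.approx(1.2369, abs=1e-4)

    def test_boundary_offset_hand_evaluated(self):
        # r_d(1.33) = -1.440/1.7689 + 0.710/1.33 + 0.668 + 0.0636*1.33
        #           = 0.4723577...; A = 1.4723577/0.5276423 = 2.790448...
        # zb = 2 * A * 1/(3*3.3) = 0.5637268...
        p = derive_farrell_params(OpticalProperties(0.3, 3.0), n_rel=1.33)
        assert p.zb == pytest.approx(0.5637268, abs=1e-6)

    @pytest.mark.parametrize("mu_a,mu_s,n_rel", [
        (-0.1, 5.0, 1.35), (0.1, 0.0, 1.35), (0.1, -3.0, 1.35),
    ])
    def test_invalid_coefficients_rejected(self, mu_a, mu_s, n_rel):
        with pytest.raises(InvalidParameterError):
            derive_farrell_params(OpticalProperties(mu_a, mu_s), n_rel)

    @pytest.mark.parametrize("n_rel", [0.9, 1.7])
    def test_refractive_index_out_of_range(self, n_rel):
        with pytest.raises(InvalidParameterError):
            derive_farrell_params(OpticalProperties(0.1, 5.0), n_rel)


class TestReflectance:
    def test_monotone_decay_example(self):
        props = OpticalProperties(0.2, 4.0)
        assert farrell_reflectance(2.0, props, 1.35) < farrell_reflectance(0.2, props, 1.35)

    def test_strong_attenuation_ratio(self):
        props = OpticalProperties(0.5, 5.0)
        ratio = farrell_reflectance(5.0, props, 1.35) / farrell_reflectance(0.5, props, 1.35)
        expected = reflectance_oracle(5.0, 0.5, 5.0, 1.35) / reflectance_oracle(0.5, 0.5, 5.0, 1.35)
        assert ratio == pytest.approx(expected, rel=1e-10)
        assert ratio < 1e-2

    def test_scaling_relation_against_oracle(self):
        # doubling both coefficients and halving r rescales the geometry;
        # the oracle provides the exact factor
        r, mu_a, mu_s = 0.8, 0.2, 4.0
        val = farrell_reflectance(r / 2, OpticalProperties(2 * mu_a, 2 * mu_s), 1.35)
        assert val == pytest.approx(reflectance_oracle(r / 2, 2 * mu_a, 2 * mu_s, 1.35),
                                    rel=1e-10)

    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(100):
            mu_a = rng.uniform(1e-4, 1.0)
            mu_s = rng.uniform(1.0, 10.0)
            n_rel = rng.uniform(1.0, 1.6)
            r = rng.uniform(0.01, 5.0)
            ours = farrell_reflectance(r, OpticalProperties(mu_a, mu_s), n_rel)
            ref = reflectance_oracle(r, mu_a, mu_s, n_rel)
            assert ours == pytest.approx(ref, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mu_a=st.floats(1e-6, 1.0), mu_s=st.floats(0.5, 12.0),
        n_rel=st.floats(1.0, 1.6),
    )
    def test_strictly_decreasing_property(self, mu_a, mu_s, n_rel):
        r = np.linspace(0.01, 4.0, 300)
        vals = farrell_reflectance(r, OpticalProperties(mu_a, mu_s), n_rel)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 0) and np.all(np.isfinite(vals))

    def test_zero_absorption_decays_slower_than_finite(self):
        r = np.array([1.0, 2.0, 3.0])
        slow = farrell_reflectance(r, OpticalProperties(1e-10, 4.0), 1.35)
        fast = farrell_reflectance(r, OpticalProperties(0.3, 4.0), 1.35)
        # beyond 1 cm the finite-absorption profile dies off faster
        assert np.all(slow[1:] / slow[0] > fast[1:] / fast[0])


class TestSimulateProfile:
    def test_zero_amplitude(self):
        prof = simulate_profile(OpticalProperties(0.1, 4.0), [0.1, 0.2, 0.5], amplitude=0.0)
        assert np.all(prof.intensities == 0)

    def test_single_radius_identity(self):
        prof = simulate_profile(OpticalProperties(0.1, 4.0), [0.3], amplitude=1.0)
        assert prof.intensities[0] == pytest.approx(
            farrell_reflectance(0.3, OpticalProperties(0.1, 4.0))
        )

    def test_pointwise_against_oracle(self):
        radii = np.linspace(0.05, 3.0, 120)
        prof = simulate_profile(OpticalProperties(0.19, 3.10), radii, amplitude=2.5,
                                n_rel=1.33)
        expected = [2.5 * reflectance_oracle(r, 0.19, 3.10, 1.33) for r in radii]
        np.testing.assert_allclose(prof.intensities, expected, rtol=1e-10)

    def test_empty_radii_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_profile(OpticalProperties(0.1, 4.0), [])


class TestFit:
    def make_profile(self, mu_a, mu_s, amplitude=1e5):
        radii = np.linspace(0.12, 2.5, 80)
        return simulate_profile(OpticalProperties(mu_a, mu_s), radii, amplitude=amplitude)

    def test_noise_free_round_trip(self):
        fit = fit_optical_properties(self.make_profile(0.29, 4.34))
        assert fit.properties.mu_a == pytest.approx(0.29, rel=0.05)
        assert fit.properties.mu_s_prime == pytest.approx(4.34, rel=0.05)
        assert fit.amplitude == pytest.approx(1e5, rel=0.05)
        assert not fit.at_bound["mu_s_prime"]

    def test_bounded_optimum_lands_on_boundary(self):
        fit = fit_optical_properties(
            self.make_profile(0.29, 4.34), bounds={"mu_s_prime": (4.9, 6.5)}
        )
        assert fit.properties.mu_s_prime == pytest.approx(4.9, abs=1e-6)
        assert fit.at_bound["mu_s_prime"]

    def test_fixed_absorption_mode(self):
        fit = fit_optical_properties(self.make_profile(0.29, 4.34), fixed_mu_a=0.29)
        assert fit.properties.mu_a == 0.29
        assert fit.properties.mu_s_prime == pytest.approx(4.34, rel=0.01)

    def test_fixed_mu_a_conflicts_with_mu_a_bounds(self):
        with pytest.raises(InvalidParameterError):
            fit_optical_properties(
                self.make_profile(0.2, 4.0),
                bounds={"mu_a": (0.1, 0.3)}, fixed_mu_a=0.2,
            )

    def test_underdetermined_profile_rejected(self):
        prof = DiffusionProfile(radii=np.linspace(0.1, 0.5, 5),
                                intensities=np.ones(5))
        with pytest.raises(FitUnderdeterminedError):
            fit_optical_properties(prof)

    def test_result_always_inside_box(self, rng):
        for _ in range(5):
            mu_a, mu_s = rng.uniform(0.05, 0.5), rng.uniform(2, 6)
            box = {"mu_a": (0.1, 0.4), "mu_s_prime": (3.0, 5.0)}
            fit = fit_optical_properties(self.make_profile(mu_a, mu_s), bounds=box)
            assert box["mu_a"][0] <= fit.properties.mu_a <= box["mu_a"][1]
            assert box["mu_s_prime"][0] <= fit.properties.mu_s_prime <= box["mu_s_prime"][1]

    def test_shrinking_box_around_truth_keeps_exact_recovery(self):
        prof = self.make_profile(0.25, 4.0)
        wide = fit_optical_properties(prof, bounds={"mu_a": (0.01, 1.0),
                                                    "mu_s_prime": (1.0, 8.0)})
        tight = fit_optical_properties(prof, bounds={"mu_a": (0.2, 0.3),
                                                     "mu_s_prime": (3.5, 4.5)})
        assert tight.residual <= wide.residual + 1e-8

    def test_serialization_round_trip(self, tmp_path):
        fit = fit_optical_properties(self.make_profile(0.29, 4.34))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["mu_a"] == pytest.approx(fit.properties.mu_a)
        assert "at_bound" in data

    def test_profile_csv_round_trip(self, tmp_path):
        prof = self.make_profile(0.2, 4.0)
        prof.to_csv(tmp_path / "p.csv")
        back = DiffusionProfile.from_csv(tmp_path / "p.csv")
        np.testing.assert_allclose(back.radii, prof.radii)
        np.testing.assert_allclose(back.intensities, prof.intensities)
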