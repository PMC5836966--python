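import numpy as np
import pytest

from ivimdti import (
    Config1Spec,
    SpatialPhantomSpec,
    add_rician_noise,
    extravascular_signal,
    make_scheme,
    osm_fit,
    plugflow_dstar,
    spatial_phantom,
    synthesize_voxel,
    vascular_signal_plugflow,
)
from ivimdti import initialize_params, mean_diffusivity, principal_direction, angle_error
from ivimdti.phantom import noise_free_signal, sample_watson, gmrf_field


class TestScheme:
    def test_printed_protocol_has_612_measurements(self, scheme):
        assert len(scheme) == 12 + 10 * 60
        assert scheme.n_b0 == 12

    def test_direction_count_formula(self):
        sch = make_scheme(b_values=(0, 100, 200), n_b0=3, n_directions=12, seed=2)
        assert len(sch) == 3 + 2 * 12

    def test_directions_non_colinear(self, scheme):
        dirs = scheme.bvecs[scheme.bvals == 1150.0]
        dots = np.abs(dirs @ dirs.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 1.0 - 1e-6

    def test_deterministic_under_seed(self):
        a = make_scheme(seed=7)
        b = make_scheme(seed=7)
        c = make_scheme(seed=8)
        assert np.array_equal(a.bvecs, b.bvecs)
        assert not np.array_equal(a.bvecs, c.bvecs)

    def test_directions_well_spread(self, scheme):
        # electrostatic repulsion should leave no near-duplicate axes
        dirs = scheme.bvecs[scheme.bvals == 1150.0]
        dots = np.abs(dirs @ dirs.T)
        np.fill_diagonal(dots, 0.0)
        min_angle = np.degrees(np.arccos(dots.max()))
        assert min_angle > 10.0


class TestPlugFlow:
    def test_unity_at_b0(self, scheme):
        y = vascular_signal_plugflow(scheme)
        assert np.allclose(y[scheme.b0_mask], 1.0)

    def test_perpendicular_gradient_sees_only_blood_diffusion(self):
        from conftest import make_single_direction_scheme

        sch = make_single_direction_scheme([0.0, 1.0, 0.0], [0, 300, 900])
        y = vascular_signal_plugflow(sch, flow_dir=(1.0, 0.0, 0.0), d_blood=3e-3)
        assert np.allclose(y, np.exp(-sch.bvals * 3e-3), rtol=1e-12)

    def test_closed_form_matches_quadrature(self, scheme):
        """Direct numerical integration of the phase-dispersion integral.

        The oracle integrates exp(-i γ m·v) over the Gaussian velocity
        ensemble on a dense grid and takes the magnitude, independently of
        the closed-form attenuation code path.
        """
        gamma = 2.675e8
        mu_v, sigma_v = 0.86, 0.34
        flow = np.array([1.0, 0.0, 0.0])
        d_blood = 3e-3
        closed = vascular_signal_plugflow(scheme, mu_v, sigma_v, flow, d_blood)
        v = np.linspace(mu_v - 8 * sigma_v, mu_v + 8 * sigma_v, 4001)
        pdf = np.exp(-0.5 * ((v - mu_v) / sigma_v) ** 2)
        pdf /= np.trapezoid(pdf, v)
        delta, Delta = scheme.delta, scheme.Delta
        for i in range(len(scheme)):
            b, g = scheme.bvals[i], scheme.bvecs[i]
            if b == 0:
                expected = 1.0
            else:
                # m = G δ Δ ĝ with G from b = γ² G² δ² (Δ − δ/3)
                G = np.sqrt(b / (gamma**2 * delta**2 * (Delta - delta / 3.0)))
                a = gamma * G * delta * Delta * float(g @ flow)
                integ = np.trapezoid(np.exp(-1j * a * v) * pdf, v)
                expected = abs(integ) * np.exp(-b * d_blood)
            assert closed[i] == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_effective_tensor_reproduces_signal_exactly(self, scheme):
        dstar = plugflow_dstar(scheme.delta, scheme.Delta, 0.34, (1, 0, 0), 3e-3)
        q = np.einsum("ij,jk,ik->i", scheme.bvecs, dstar, scheme.bvecs)
        assert np.allclose(
            vascular_signal_plugflow(scheme), np.exp(-scheme.bvals * q), rtol=1e-14
        )

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            plugflow_dstar(2e-3, 1e-3, 0.34, (1, 0, 0), 3e-3)


class TestExtravascular:
    def test_unity_at_b0_and_known_quadratic_forms(self, scheme, config1):
        d = config1.diffusion_tensor
        y = extravascular_signal(scheme, d)
        assert np.allclose(y[scheme.b0_mask], 1.0)
        from conftest import make_single_direction_scheme

        n = np.asarray(config1.axon_dir)
        perp = np.array([-n[1], n[0], 0.0])
        for g, dval in (
            (perp, 0.8 * config1.d_iso),
            (n, 0.2 * config1.d_par + 0.8 * config1.d_iso),
        ):
            sch = make_single_direction_scheme(g, [700.0])
            assert extravascular_signal(sch, d)[0] == pytest.approx(
                np.exp(-700.0 * dval), rel=1e-12
            )


class TestRicianNoise:
    def test_infinite_snr_is_identity(self):
        rng = np.random.default_rng(0)
        s = np.linspace(0, 1, 11)
        assert np.array_equal(add_rician_noise(s, np.inf, rng), s)

    def test_zero_signal_rayleigh_mean(self):
        rng = np.random.default_rng(1)
        draws = add_rician_noise(np.zeros(20000), 10.0, rng)
        sigma = 0.1
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se

    def test_second_moment_is_exact_rician(self):
        # E[M^2] = S^2 + 2 sigma^2 holds exactly for the Rician distribution
        rng = np.random.default_rng(2)
        s, snr = 0.7, 5.0
        sigma = 1.0 / snr
        draws = add_rician_noise(np.full(40000, s), snr, rng)
        expected = s**2 + 2 * sigma**2
        assert np.mean(draws**2) == pytest.approx(expected, rel=0.02)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), 0.0, np.random.default_rng(0))


class TestConfig1Voxel:
    def test_deterministic_given_seed(self, scheme):
        spec = Config1Spec(n_realizations=4, seed=5)
        a, _ = synthesize_voxel(spec, scheme)
        b, _ = synthesize_voxel(spec, scheme)
        assert np.array_equal(a, b)

    def test_infinite_snr_returns_clean_mixture(self, scheme):
        spec = Config1Spec(snr=np.inf, n_realizations=2, seed=3)
        reals, truth = synthesize_voxel(spec, scheme)
        clean = noise_free_signal(spec, scheme)
        assert np.allclose(reals, clean[None, :])
        assert np.allclose(clean[scheme.b0_mask], spec.s0)

    def test_ground_truth_tensors(self, scheme):
        spec = Config1Spec()
        truth = spec.ground_truth(scheme)
        assert truth.f == 0.12 and truth.s0 == 1.0
        assert np.allclose(truth.d, spec.diffusion_tensor, atol=1e-15)
        assert np.allclose(truth.d_star, spec.pseudo_diffusion_tensor(scheme), atol=1e-15)
        # effective D* = D_blood I + [σ²Δ²/(2(Δ-δ/3))] x̂x̂ᵀ
        w = 0.34**2 * scheme.Delta**2 / (2 * (scheme.Delta - scheme.delta / 3))
        assert truth.d_star[0, 0] == pytest.approx(3e-3 + w, rel=1e-12)
        assert truth.d_star[1, 1] == pytest.approx(3e-3, rel=1e-12)

    def test_b0_mean_shows_rician_bias(self, scheme):
        spec = Config1Spec(snr=3.0, n_realizations=2000, seed=9)
        reals, _ = synthesize_voxel(spec, scheme)
        b0_draws = reals[:, scheme.b0_mask].ravel()
        sigma = spec.s0 / spec.snr
        # exact Rician second moment; mean must exceed the clean S0
        assert np.mean(b0_draws**2) == pytest.approx(
            spec.s0**2 + 2 * sigma**2, rel=0.02
        )
        assert b0_draws.mean() > spec.s0


class TestSpatialPhantom:
    def test_watson_concentration_limit(self):
        rng = np.random.default_rng(0)
        mu = np.array([0.0, 1.0, 0.0])
        axes = sample_watson(mu, 1e5, 200, rng)
        assert np.all(np.abs(axes @ mu) > 0.99)

    def test_watson_dispersion_increases_with_small_kappa(self):
        rng = np.random.default_rng(1)
        mu = np.array([1.0, 0.0, 0.0])
        tight = np.mean(np.abs(sample_watson(mu, 64.0, 500, rng) @ mu))
        loose = np.mean(np.abs(sample_watson(mu, 2.0, 500, rng) @ mu))
        assert tight > loose

    def test_gmrf_unit_variance_and_determinism(self):
        f1 = gmrf_field((4, 1, 6), 4.0, np.random.default_rng(3))
        f2 = gmrf_field((4, 1, 6), 4.0, np.random.default_rng(3))
        assert np.array_equal(f1, f2)
        assert f1.shape == (4, 1, 6)

    def test_zero_vascular_fraction_gives_pure_dti_volume(self, scheme):
        spec = SpatialPhantomSpec(shape=(2, 1, 2), f=0.0, snr=np.inf, seed=4)
        vol, truth = spatial_phantom(spec, scheme)
        assert vol.shape == (2, 1, 2, len(scheme))
        assert np.allclose(vol[..., scheme.b0_mask], truth["s0"][..., None])

    def test_mean_orientation_recovered_from_fit(self, scheme):
        spec = SpatialPhantomSpec(
            shape=(1, 1, 1), kappa_range=(64.0, 64.0), snr=50.0, seed=6, f=0.02
        )
        vol, truth = spatial_phantom(spec, scheme)
        y = vol[0, 0, 0]
        x0 = initialize_params(float(y[scheme.b0_mask].mean()), 0.05, 5e-3, 7e-4)
        fit = osm_fit(y, scheme, x0)
        ang = angle_error(principal_direction(fit.params.d), truth["mean_dir"][0, 0, 0])
        assert ang < 5.0

    def test_truth_maps_shapes(self, scheme):
        spec = SpatialPhantomSpec(shape=(3, 1, 2), seed=11)
        vol, truth = spatial_phantom(spec, scheme)
        assert truth["s0"].shape == (3, 1, 2)
        assert truth["d"].shape == (3, 1, 2, 6)
        assert truth["d_star"].shape == (3, 1, 2, 6)
        assert np.all(truth["f"] == spec.f)
        # MD of the vascular tensor matches the requested field value
        from ivimdti import cholesky_to_tensor

        md = mean_diffusivity(cholesky_to_tensor(truth["d_star"][0, 0, 0]))
        assert md == pytest.approx(spec.md_star, rel=1e-10)
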