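import numpy as np
import pytest

from ivimdti import (
    GaussianPrior,
    ParamVector,
    SolverOptions,
    build_prior,
    dgn_fit,
    initialize_params,
    lm_fit,
    osm_fit,
    predict_signal,
    regularization_weight,
    tensor_to_cholesky,
    tsm_fit,
)
from ivimdti import add_rician_noise
from ivimdti.estimators import f_init_from_ratio
from ivimdti.params import N_PARAMS


def _recovery_error(fit, truth):
    """Largest parameter error scaled per block (S0 | f | U | V)."""
    est = fit.params.canonical().to_array()
    tr = truth.canonical().to_array()
    scale = np.array(
        [max(abs(tr[0]), 1e-12), max(abs(tr[1]), 1e-12)]
        + [max(np.abs(tr[2:8]).max(), 1e-12)] * 6
        + [max(np.abs(tr[8:14]).max(), 1e-12)] * 6
    )
    return np.max(np.abs(est - tr) / scale)


class TestLM:
    def test_converges_immediately_at_truth(self, scheme, config1_truth):
        y = predict_signal(config1_truth, scheme)
        fit = lm_fit(y, scheme, config1_truth)
        assert fit.converged
        assert fit.residual == pytest.approx(0.0, abs=1e-16)

    def test_lambda_schedule_divide_multiply_by_ten(self, scheme, config1_truth):
        rng = np.random.default_rng(5)
        y = add_rician_noise(predict_signal(config1_truth, scheme), 15.0, rng)
        x0 = initialize_params(1.0, 0.3, 7e-3, 1.5e-3)
        fit = lm_fit(y, scheme, x0)
        trace = fit.lambda_trace
        assert len(trace) >= 2
        assert any(acc for _, acc in trace) and fit.n_iterations >= 1
        for (lam_prev, accepted), (lam_next, _) in zip(trace, trace[1:]):
            if accepted:
                assert lam_next == pytest.approx(lam_prev / 10.0, rel=1e-12)
            else:
                assert lam_next == pytest.approx(lam_prev * 10.0, rel=1e-12)

    def test_noise_free_recovery_from_offset_init(self, scheme, config1, config1_truth):
        y = predict_signal(config1_truth, scheme)
        from ivimdti import mean_diffusivity

        mds = mean_diffusivity(config1_truth.d_star)
        md = mean_diffusivity(config1_truth.d)
        x0 = initialize_params(1.0, 1.2 * config1.f, 1.2 * mds, 1.2 * md)
        fit = lm_fit(y, scheme, x0)
        assert _recovery_error(fit, config1_truth) < 0.01

    def test_residual_trace_nonincreasing(self, scheme, config1_truth):
        rng = np.random.default_rng(9)
        y = add_rician_noise(predict_signal(config1_truth, scheme), 10.0, rng)
        fit = lm_fit(y, scheme, initialize_params(1.0, 0.2, 5e-3, 1e-3))
        assert np.all(np.diff(fit.residual_trace) <= 1e-12)

    def test_fixed_mask_freezes_parameters(self, scheme, config1_truth):
        rng = np.random.default_rng(11)
        y = add_rician_noise(predict_signal(config1_truth, scheme), 20.0, rng)
        x0 = initialize_params(1.0, 0.15, 4e-3, 8e-4)
        fixed = np.zeros(N_PARAMS, dtype=bool)
        fixed[1] = True  # freeze f
        fit = lm_fit(y, scheme, x0, fixed_mask=fixed)
        assert fit.params.f == pytest.approx(0.15)


class TestDGN:
    def test_fixed_point_at_truth(self, scheme, config1_truth):
        y = predict_signal(config1_truth, scheme)
        fit = dgn_fit(y, scheme, config1_truth)
        assert fit.converged
        assert fit.residual == pytest.approx(0.0, abs=1e-16)

    def test_prior_mean_is_fixed_point(self, scheme):
        prior = build_prior([1.0])
        x_star = ParamVector.from_array(prior.mean)
        y = predict_signal(x_star, scheme)
        fit = dgn_fit(y, scheme, x_star, prior=prior)
        assert np.allclose(fit.params.to_array(), prior.mean, atol=1e-8)

    def test_objective_nonincreasing_on_noisy_voxel(self, scheme, config1_truth):
        rng = np.random.default_rng(13)
        y = add_rician_noise(predict_signal(config1_truth, scheme), 10.0, rng)
        fit = dgn_fit(y, scheme, initialize_params(1.0, 0.3, 7.6e-3, 1.9e-3))
        for pre, post in fit.objective_steps:
            assert post <= pre + 1e-12
        assert np.all(np.diff(fit.residual_trace) <= 1e-12)  # no-prior objective = R

    def test_method_tags(self, scheme, config1_truth):
        y = predict_signal(config1_truth, scheme)
        assert dgn_fit(y, scheme, config1_truth).method == "osm-dgn1"
        assert (
            dgn_fit(y, scheme, config1_truth, prior=build_prior([1.0])).method
            == "osm-dgn2"
        )


class TestOSM:
    def test_is_lm_on_all_parameters(self, scheme, config1_truth):
        rng = np.random.default_rng(17)
        y = add_rician_noise(predict_signal(config1_truth, scheme), 20.0, rng)
        x0 = initialize_params(1.0, 0.15, 4e-3, 8e-4)
        a = osm_fit(y, scheme, x0)
        b = lm_fit(y, scheme, x0, fixed_mask=None)
        assert np.allclose(a.params.to_array(), b.params.to_array())
        assert a.method == "osm"


class TestTSM:
    def test_pure_diffusion_data_recovers_d_exactly(self, scheme):
        d = np.diag([1.5e-3, 0.8e-3, 0.6e-3])
        x = ParamVector(s0=1.0, f=0.0, u=np.full(6, 0.05), v=tensor_to_cholesky(d))
        y = predict_signal(x, scheme)
        fit = tsm_fit(y, scheme, s0_measured=1.0, b_cutoff=500.0)
        assert fit.params.f == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.params.d, d, rtol=1e-4, atol=1e-9)

    def test_high_b_subset_size_with_printed_scheme(self, scheme):
        assert np.count_nonzero(scheme.bvals >= 500.0) == 5 * 60

    def test_noisy_amplitude_above_s0_clips_f_to_zero(self, scheme):
        d = np.diag([1.0e-3, 1.0e-3, 1.0e-3])
        x = ParamVector(s0=1.0, f=0.0, u=np.full(6, 0.05), v=tensor_to_cholesky(d))
        y = predict_signal(x, scheme)
        # measured S0 below the fitted amplitude forces a negative raw f
        fit = tsm_fit(y, scheme, s0_measured=0.9, b_cutoff=500.0)
        assert fit.params.f == 0.0

    def test_too_few_high_b_measurements_rejected(self, small_scheme):
        y = np.ones(len(small_scheme))
        with pytest.raises(ValueError):
            tsm_fit(y, small_scheme, s0_measured=1.0, b_cutoff=1200.0)

    def test_nonpositive_s0_rejected(self, scheme):
        with pytest.raises(ValueError):
            tsm_fit(np.ones(len(scheme)), scheme, s0_measured=0.0)


class TestPrior:
    def test_tabulated_rows(self):
        prior = build_prior([1.0, 1.0, 1.0])
        assert prior.mean[1] == 0.1 and np.sqrt(prior.variances[1]) == 0.1
        # diffusivity-scale rows propagated to component scale
        assert prior.mean[2] == pytest.approx(np.sqrt(0.007))
        assert np.sqrt(prior.variances[2]) == pytest.approx(0.005 / (2 * np.sqrt(0.007)))
        assert prior.mean[8] == pytest.approx(np.sqrt(0.0007))
        assert np.sqrt(prior.variances[8]) == pytest.approx(
            0.000025 / (2 * np.sqrt(0.0007))
        )
        assert np.allclose(prior.mean[5:8], 0.0) and np.allclose(prior.mean[11:14], 0.0)

    def test_s0_row_from_replicates(self):
        reps = [0.9, 1.0, 1.1, 1.0, 1.0, 1.0, 0.5, 1.5, 1.0, 1.0, 1.0, 1.0]
        prior = build_prior(reps)
        assert prior.mean[0] == pytest.approx(np.mean(reps))
        assert np.sqrt(prior.variances[0]) == pytest.approx(np.std(reps, ddof=1))

    def test_single_replicate_std_fallback(self):
        prior = build_prior([1.0])
        assert prior.mean[0] == 1.0
        assert np.sqrt(prior.variances[0]) == pytest.approx(0.1)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            build_prior([])

    def test_regularization_weight_identity(self):
        prior = GaussianPrior(np.zeros(14), np.ones(14), scale=1e-2)
        lam = regularization_weight(np.eye(14), prior)
        assert lam == pytest.approx(1e-2)

    def test_regularization_weight_quadratic_in_j(self):
        rng = np.random.default_rng(2)
        j = rng.normal(size=(40, 14))
        prior = build_prior([1.0])
        assert regularization_weight(2 * j, prior) == pytest.approx(
            4 * regularization_weight(j, prior)
        )

    def test_regularization_weight_matches_explicit_traces(self):
        rng = np.random.default_rng(4)
        j = rng.normal(size=(25, 14))
        prior = build_prior([1.0])
        expected = 1e-2 * np.trace(j.T @ j) / np.sum(1.0 / prior.variances)
        assert regularization_weight(j, prior) == pytest.approx(expected)


class TestInitialization:
    def test_isotropic_factors(self):
        x = initialize_params(1.0, 0.1, 3e-3, 5e-4)
        assert np.allclose(x.v[:3], np.sqrt(5e-4))
        assert x.v[0] == pytest.approx(0.02236, abs=1e-5)
        assert np.allclose(x.u[3:], 0.0) and np.allclose(x.v[3:], 0.0)

    def test_initial_md_exact(self):
        from ivimdti import mean_diffusivity

        x = initialize_params(2.0, 0.2, 4.2e-3, 6.6e-4)
        assert mean_diffusivity(x.d_star) == pytest.approx(4.2e-3, rel=1e-12)
        assert mean_diffusivity(x.d) == pytest.approx(6.6e-4, rel=1e-12)

    def test_ratio_helper(self):
        assert f_init_from_ratio(0.12, 2.5) == pytest.approx(0.30)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            initialize_params(1.0, 0.1, -1e-3, 5e-4)
        with pytest.raises(ValueError):
            initialize_params(1.0, 1.5, 3e-3, 5e-4)


def test_all_methods_return_psd_tensors(small_scheme):
    rng = np.random.default_rng(21)
    for _ in range(50):
        truth = initialize_params(
            1.0, rng.uniform(0.05, 0.5), rng.uniform(1e-3, 8e-3), rng.uniform(2e-4, 2e-3)
        )
        y = add_rician_noise(
            predict_signal(truth, small_scheme), rng.uniform(3, 30), rng
        )
        x0 = initialize_params(1.0, 0.2, 3e-3, 6e-4)
        for fit in (
            osm_fit(y, small_scheme, x0),
            dgn_fit(y, small_scheme, x0),
            dgn_fit(y, small_scheme, x0, prior=build_prior(y[small_scheme.b0_mask])),
        ):
            assert np.linalg.eigvalsh(fit.params.d_star).min() >= -1e-12
            assert np.linalg.eigvalsh(fit.params.d).min() >= -1e-12
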