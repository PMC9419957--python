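"""Variational Laplace: conjugate exactness, self-inversion, subject fits."""

import math

import numpy as np
import pytest

from chronodcm import forward as fw
from chronodcm import inversion as inv
from chronodcm import synthetic as syn


def conjugate_setup(rng, d=5, pi=4.0):
    m0 = rng.normal(0, 1, d)
    S0 = np.diag(rng.uniform(0.5, 2.0, d))
    y = rng.normal(0, 1, d)
    prior = inv.GaussianDensity([f"p{i}" for i in range(d)], m0, S0)
    P0 = np.linalg.inv(S0)
    Pp = P0 + pi * np.eye(d)
    mp = np.linalg.solve(Pp, P0 @ m0 + pi * y)
    C = S0 + np.eye(d) / pi
    logZ = -0.5 * (y - m0) @ np.linalg.solve(C, y - m0) - 0.5 * np.linalg.slogdet(
        2 * np.pi * C
    )[1]
    return prior, y, mp, np.linalg.inv(Pp), logZ


class TestDefaultPriors:
    def test_connectivity_block_dimension_for_eight_rois(self):
        prior = inv.default_priors(8)
        a_names = [n for n in prior.names if n.startswith("a_")]
        assert len(a_names) == 64

    def test_prior_mean_is_admissible_and_stable(self):
        prior = inv.default_priors(4)
        p = fw.DCMParams.from_vector(prior.mean, 4)
        assert p.is_stable()

    def test_prior_mean_implies_half_hertz_self_inhibition(self):
        prior = inv.default_priors(3)
        p = fw.DCMParams.from_vector(prior.mean, 3)
        np.testing.assert_allclose(np.diag(p.effective_a()), -0.5)

    def test_documented_variances(self):
        prior = inv.default_priors(2)
        var = dict(zip(prior.names, np.diag(prior.cov)))
        assert var["a_1_2"] == var["a_self_1"] == 1 / 64
        assert var["transit_1"] == var["decay"] == var["epsilon"] == 1 / 256
        assert var["alpha_v"] == var["beta_e"] == 1 / 64


class TestConjugateExactness:
    def test_free_energy_equals_log_evidence(self, rng):
        prior, y, mp, Sp, logZ = conjugate_setup(rng)
        F = inv.free_energy(
            mp, y, prior, math.log(4.0),
            forward=lambda th: th, jacobian=lambda th: (th, np.eye(5)),
        )
        assert abs(F - logZ) < 1e-6

    def test_vl_recovers_conjugate_posterior(self, rng):
        prior, y, mp, Sp, _ = conjugate_setup(rng)
        cfg = inv.InversionConfig(hyper_mean=math.log(4.0), hyper_var=1e-8)
        res = inv.variational_laplace(
            y, prior, cfg, forward=lambda th: th,
            jacobian=lambda th: (th, np.eye(5)),
        )
        assert np.abs(res.posterior.mean - mp).max() < 1e-6
        assert np.abs(res.posterior.cov - Sp).max() < 1e-6

    def test_noisier_features_lower_free_energy(self, rng):
        prior, y, mp, _, _ = conjugate_setup(rng)
        f_clean = inv.free_energy(
            mp, y, prior, math.log(4.0),
            forward=lambda th: th, jacobian=lambda th: (th, np.eye(5)),
        )
        y_noisy = y + rng.normal(0, 2.0, y.size)
        f_noisy = inv.free_energy(
            mp, y_noisy, prior, math.log(4.0),
            forward=lambda th: th, jacobian=lambda th: (th, np.eye(5)),
        )
        assert f_noisy < f_clean


class TestVariationalLaplace:
    def test_accepted_trace_is_nondecreasing(self, random_params):
        p = random_params(3)
        grid = fw.default_grid(256, 0.72, 16)
        model = inv.CsdForwardModel(3, grid)
        feats = model.features(p.to_vector())
        res = inv.variational_laplace(
            feats, inv.default_priors(3), forward=model.features,
            jacobian=model.features_and_jac, block_index=model.block_index,
        )
        assert np.all(np.diff(res.diagnostics["trace"]) >= 0)

    def test_noise_free_self_inversion_recovers_connectivity(self, random_params):
        p = random_params(3, seed=7)
        grid = fw.default_grid(400, 0.72, 32)
        model = inv.CsdForwardModel(3, grid)
        feats = model.features(p.to_vector())
        res = inv.variational_laplace(
            feats, inv.default_priors(3), forward=model.features,
            jacobian=model.features_and_jac, block_index=model.block_index,
        )
        est = fw.DCMParams.from_vector(res.posterior.mean, 3)
        mask = ~np.eye(3, dtype=bool)
        rel = np.linalg.norm(est.a_offdiag[mask] - p.a_offdiag[mask]) / np.linalg.norm(
            p.a_offdiag[mask]
        )
        assert rel <= 0.05

    def test_local_optimality_at_noise_free_optimum(self, random_params, rng):
        p = random_params(3, seed=3)
        grid = fw.default_grid(256, 0.72, 16)
        model = inv.CsdForwardModel(3, grid)
        feats = model.features(p.to_vector())
        prior = inv.default_priors(3)
        res = inv.variational_laplace(
            feats, prior, forward=model.features,
            jacobian=model.features_and_jac, block_index=model.block_index,
        )
        prior_sd = np.sqrt(np.diag(prior.cov))
        assert np.all(np.abs(res.posterior.mean - p.to_vector()) < 2 * prior_sd)
        lam = np.array(res.diagnostics["lambda"])
        for _ in range(5):
            jitter = res.posterior.mean + 0.05 * prior_sd * rng.standard_normal(
                prior.dim
            )
            f_j = inv.free_energy(
                jitter, feats, prior, lam,
                forward=model.features, jacobian=model.features_and_jac,
                block_index=model.block_index,
            )
            f_opt = inv.free_energy(
                res.posterior.mean, feats, prior, lam,
                forward=model.features, jacobian=model.features_and_jac,
                block_index=model.block_index,
            )
            assert f_opt >= f_j

    def test_fd_jacobian_path_agrees_with_analytic(self, random_params):
        p = random_params(3, seed=1)
        grid = fw.default_grid(200, 0.72, 8)
        model = inv.CsdForwardModel(3, grid)
        feats = model.features(p.to_vector()) * 1.01
        cfg_an = inv.InversionConfig(max_iter=8)
        cfg_fd = inv.InversionConfig(max_iter=8, jacobian="fd")
        res_an = inv.variational_laplace(
            feats, inv.default_priors(3), cfg_an, forward=model.features,
            jacobian=model.features_and_jac, block_index=model.block_index,
        )
        res_fd = inv.variational_laplace(
            feats, inv.default_priors(3), cfg_fd, forward=model.features,
            block_index=model.block_index,
        )
        assert np.abs(res_an.posterior.mean - res_fd.posterior.mean).max() < 1e-4


@pytest.fixture(scope="module")
def cohort():
    cfg = syn.CohortConfig(
        n_rois=4, n_subjects_per_timespan=1, n_volumes=400, tr=0.72,
        effect_model_id=18, effect_targets=(), between_subject_sd=0.0, seed=11,
    )
    truth = syn.make_ground_truth(cfg)
    return cfg, truth


class TestInvertSubject:
    def test_two_sessions_give_two_independent_results(self, cohort):
        _, truth = cohort
        lr = inv.invert_subject(syn.simulate_subject(truth, 1, "LR", 0))
        rl = inv.invert_subject(syn.simulate_subject(truth, 1, "RL", 0))
        assert not np.allclose(lr.posterior.mean, rl.posterior.mean)

    def test_deterministic_across_repeated_runs(self, cohort):
        _, truth = cohort
        rec = syn.simulate_subject(truth, 2, "LR", 1)
        a = inv.invert_subject(rec)
        b = inv.invert_subject(rec)
        np.testing.assert_array_equal(a.posterior.mean, b.posterior.mean)
        assert a.free_energy == b.free_energy

    def test_connectivity_recovery_across_eight_subjects(self, cohort):
        """At 4 ROIs / 400 volumes with no between-subject variability, the
        posterior connectivity should correlate >= 0.7 with the truth on
        average over eight seeded subjects."""
        _, truth = cohort
        mask = ~np.eye(4, dtype=bool)
        cors = []
        for s in range(8):
            rec = syn.simulate_subject(truth, 1, "LR", s)
            res = inv.invert_subject(rec)
            est = fw.DCMParams.from_vector(res.posterior.mean, 4)
            cors.append(
                np.corrcoef(est.a_offdiag[mask], truth.base_params.a_offdiag[mask])[0, 1]
            )
        assert np.mean(cors) >= 0.7


class TestEstimatorChoice:
    def test_welch_estimator_also_recovers_structure(self, cohort):
        _, truth = cohort
        rec = syn.simulate_subject(truth, 1, "LR", 0)
        res = inv.invert_subject(rec, inv.InversionConfig(estimator="welch"))
        assert res.posterior.mean.size == fw.DCMParams.n_params(4)
        with pytest.raises(ValueError):
            inv.invert_subject(rec, inv.InversionConfig(estimator="multitaper"))

    def test_result_serializes_to_json(self, cohort):
        import json

        _, truth = cohort
        rec = syn.simulate_subject(truth, 1, "LR", 2)
        res = inv.invert_subject(rec)
        d = json.loads(res.to_json())
        assert d["converged"] in (True, False)
        assert len(d["mean"]) == fw.DCMParams.n_params(4)
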