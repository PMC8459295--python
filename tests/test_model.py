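"""Design matrix, horseshoe log density, Gibbs sampler, and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crnpipe.config import MCMCSettings
from crnpipe.model import (
    HorseshoeSpec,
    PosteriorFit,
    build_design_matrix,
    compute_tau0,
    diagnose_and_summarize,
    fit_mcmc,
    log_joint_density,
    _slice_batch,
    _slice_scalar,
)
from crnpipe.synthetic import GroundTruth, simulate_trial_amplitudes


def brute_force_log_joint(params, design, spec, y, extended=False):
    """Independent scalar-loop implementation built from scipy distributions."""
    B, I, lam = params["B"], params["I"], params["lam"]
    sg, sI, nu = params["sigma_g"], params["sigma_I"], params["nu"]
    tau, c2, I0 = params["tau"], params["c2"], params["I0"]
    total = 0.0
    for k in range(design.n_trials):
        mu = float(B[design.condition_index[k]] @ design.X[k]) + I[design.subject_index[k]]
        if extended:
            mu += params["b"][design.subject_index[k]] * design.X[k, design.rt_column]
        total += sps.t.logpdf(y[k], nu, loc=mu, scale=sg)
    tau0 = spec.p0 / (design.n_predictors * design.n_conditions - spec.p0) * sg / math.sqrt(design.n_trials)
    for i in range(design.n_conditions):
        for p in range(design.n_predictors):
            lt2 = c2 * lam[i, p] ** 2 / (c2 + tau**2 * lam[i, p] ** 2)
            total += sps.norm.logpdf(B[i, p], 0.0, math.sqrt(tau**2 * lt2))
            total += sps.halfcauchy.logpdf(lam[i, p], scale=1.0)
    total += sps.halfcauchy.logpdf(tau, scale=tau0)
    total += sps.invgamma.logpdf(c2, spec.nu0 / 2.0, scale=spec.nu0 * spec.s**2 / 2.0)
    for j in range(design.n_subjects):
        total += sps.norm.logpdf(I[j], I0, sI)
    total += sps.norm.logpdf(I0, 0.0, 1.0)
    total += sps.halfnorm.logpdf(sI) + sps.halfnorm.logpdf(sg)
    total += sps.gamma.logpdf(nu, spec.nu_prior_shape, scale=1.0 / spec.nu_prior_rate)
    if extended:
        lb = params["lam_b"]
        ltb2 = c2 * lb**2 / (c2 + tau**2 * lb**2)
        for j in range(design.n_subjects):
            total += sps.norm.logpdf(params["b"][j], 0.0, math.sqrt(tau**2 * ltb2))
        total += sps.halfcauchy.logpdf(lb, scale=1.0)
    return float(total)


def random_params(rng, C=3, P=11, S=3):
    return dict(
        B=0.3 * rng.standard_normal((C, P)),
        I=0.5 * rng.standard_normal(S),
        I0=0.3 * rng.standard_normal(),
        lam=np.abs(rng.standard_normal((C, P))) + 0.1,
        sigma_g=abs(rng.standard_normal()) + 0.5,
        sigma_I=abs(rng.standard_normal()) + 0.3,
        nu=rng.uniform(2, 40),
        tau=abs(rng.standard_normal()) * 0.1 + 0.01,
        c2=rng.uniform(0.5, 3),
        b=0.1 * rng.standard_normal(S),
        lam_b=abs(rng.standard_normal()) + 0.1,
    )


class TestDesignMatrix:
    def test_exactly_the_eleven_columns(self, tiny_design):
        design, _, _ = tiny_design
        assert design.column_names == (
            "rt",
            "prom",
            "prev",
            "errn",
            "rt_prom",
            "rt_prev",
            "rt_errn",
            "prom_errn",
            "prev_errn",
            "rt_prom_errn",
            "rt_prev_errn",
        )
        assert design.X.shape[1] == 11
        # no column mixes promotion and prevention strength
        assert not any("prom" in c and "prev" in c for c in design.column_names)

    def test_base_columns_standardized(self, tiny_design):
        design, _, _ = tiny_design
        for name in ("rt", "prom", "prev", "errn"):
            col = design.X[:, design.column_names.index(name)]
            assert abs(col.mean()) < 1e-8
            assert abs(col.std() - 1.0) < 1e-8

    def test_interactions_are_products_of_z_scores(self, tiny_design):
        design, _, _ = tiny_design
        cols = {n: design.X[:, i] for i, n in enumerate(design.column_names)}
        assert np.allclose(cols["rt_prom"], cols["rt"] * cols["prom"])
        assert np.allclose(cols["rt_prom_errn"], cols["rt"] * cols["prom"] * cols["errn"])

    def test_z_scoring_is_idempotent(self, tiny_design):
        design, amps, traits = tiny_design
        again = build_design_matrix(amps, traits, conditions=design.conditions)
        assert np.array_equal(design.X, again.X)

    def test_equal_rts_get_equal_entries(self, tiny_design):
        _, amps, traits = tiny_design
        amps2 = amps.copy()
        amps2.loc[amps2.index[:2], "rt_s"] = 0.42
        d = build_design_matrix(amps2, traits)
        assert d.X[0, d.rt_column] == d.X[1, d.rt_column]

    def test_zero_variance_predictor_is_error(self, tiny_design):
        _, amps, traits = tiny_design
        traits0 = traits.copy()
        traits0["n_miss"] = 0
        with pytest.raises(ValueError, match="errn"):
            build_design_matrix(amps, traits0)

    def test_outcome_z_scored(self, tiny_design):
        design, _, _ = tiny_design
        assert abs(design.y.mean()) < 1e-8
        assert abs(design.y.std() - 1.0) < 1e-8


class TestTau0:
    def test_printed_formula_value(self):
        assert compute_tau0(HorseshoeSpec(), sigma_g=1.0, N=1) == pytest.approx(9 / 24)

    def test_sqrt_n_scaling(self):
        spec = HorseshoeSpec()
        assert compute_tau0(spec, 1.0, 400) == pytest.approx(compute_tau0(spec, 1.0, 100) / 2)

    def test_linear_in_sigma(self):
        spec = HorseshoeSpec()
        assert compute_tau0(spec, 2.0, 50) == pytest.approx(2 * compute_tau0(spec, 1.0, 50))

    def test_p0_bound(self):
        with pytest.raises(ValueError):
            compute_tau0(HorseshoeSpec(p0=40), 1.0, 100)


class TestLogJoint:
    def test_matches_brute_force_oracle(self, tiny_design):
        design, _, _ = tiny_design
        spec = HorseshoeSpec()
        rng = np.random.default_rng(0)
        for _ in range(5):
            params = random_params(rng)
            for extended in (False, True):
                mine = log_joint_density(params, design, spec, design.y, extended=extended)
                ref = brute_force_log_joint(params, design, spec, design.y, extended=extended)
                assert mine == pytest.approx(ref, abs=1e-8)

    def test_out_of_support_returns_minus_inf(self, tiny_design):
        design, _, _ = tiny_design
        params = random_params(np.random.default_rng(1))
        params["sigma_g"] = -0.5
        assert log_joint_density(params, design, HorseshoeSpec(), design.y) == -np.inf

    def test_slab_limit_of_lambda_tilde(self):
        """lambda -> inf with finite c: the prior SD of B approaches c*... the
        regularized-horseshoe slab."""
        from crnpipe.model import _lambda_tilde_sq

        c2, tau2 = 4.0, 0.25
        assert _lambda_tilde_sq(1e12, tau2, c2) == pytest.approx(c2 / tau2, rel=1e-6)

    def test_likelihood_term_is_student_t(self, tiny_design):
        """With B=0, I=0 the data-dependent part of the joint equals the sum of
        standard-t log densities (the prior cancels between two outcomes)."""
        design, _, _ = tiny_design
        spec = HorseshoeSpec()
        params = random_params(np.random.default_rng(2))
        params.update(B=np.zeros((3, 11)), I=np.zeros(3), I0=0.0, nu=1000.0, sigma_g=1.0)
        y0 = np.zeros(design.n_trials)
        y1 = np.linspace(-2, 2, design.n_trials)
        diff = log_joint_density(params, design, spec, y1) - log_joint_density(params, design, spec, y0)
        expected = sps.t.logpdf(y1, 1000.0).sum() - design.n_trials * sps.t.logpdf(0.0, 1000.0)
        assert diff == pytest.approx(expected, abs=1e-9)


class TestSliceSamplers:
    def test_scalar_slice_targets_standard_normal(self):
        rng = np.random.default_rng(3)
        logf = lambda x: -0.5 * x**2
        x, out = 0.0, []
        for _ in range(4000):
            x = _slice_scalar(logf, x, rng)
            out.append(x)
        assert sps.kstest(np.array(out[500:]), "norm").pvalue > 0.01

    def test_batch_slice_targets_independent_normals(self):
        rng = np.random.default_rng(4)
        mus = np.array([-2.0, 0.0, 3.0])
        logf = lambda x: -0.5 * (x - mus) ** 2
        x = np.zeros(3)
        draws = []
        for _ in range(3000):
            x = _slice_batch(logf, x, rng)
            draws.append(x.copy())
        draws = np.array(draws[500:])
        assert np.allclose(draws.mean(axis=0), mus, atol=0.15)
        assert np.allclose(draws.std(axis=0), 1.0, atol=0.15)


class TestFitMCMC:
    def test_seeded_determinism(self, tiny_design):
        design, _, _ = tiny_design
        settings = MCMCSettings(chains=2, warmup=50, samples=30, seed=9)
        f1 = fit_mcmc(design, settings=settings)
        f2 = fit_mcmc(design, settings=settings)
        for name in f1.draws:
            assert np.array_equal(f1.draws[name], f2.draws[name])

    def test_recovers_strong_coefficient_sign_and_size(self, small_cohort):
        trials, traits, _ = small_cohort
        n = trials.subject.nunique()
        rng = np.random.default_rng(5)
        B = np.zeros((3, 11))
        B[:, 0] = -0.4
        truth = GroundTruth(B=B, I0=0.0, I=0.2 * rng.standard_normal(n), b=np.zeros(n), sigma_g=0.8, nu=10.0, sigma_I=0.2, slope_sd=0.0)
        amps = simulate_trial_amplitudes(trials, traits, truth, seed=6)
        design = build_design_matrix(amps, traits, conditions=("gain", "loss", "control"))
        fit = fit_mcmc(design, settings=MCMCSettings(chains=2, warmup=300, samples=200, seed=7))
        med = np.median(fit.stacked("B"), axis=0)
        scaled = -0.4 / design.y_sd
        # ~1100 trials per condition: posterior SD is about 0.025
        assert np.all(np.abs(med[:, 0] - scaled) < 0.1)
        assert np.abs(med[:, 1:]).max() < 0.05

    def test_nonconformable_outcome_rejected(self, tiny_design):
        design, _, _ = tiny_design
        with pytest.raises(ValueError, match="conformable"):
            fit_mcmc(design, y=np.zeros(3))

    def test_extended_variant_draws_slopes(self, tiny_design):
        design, _, _ = tiny_design
        fit = fit_mcmc(design, settings=MCMCSettings(chains=1, warmup=30, samples=20, seed=1), extended=True)
        assert fit.draws["b"].shape == (1, 20, design.n_subjects)
        assert np.all(fit.draws["lam_b"] > 0)

    def test_positive_scales_in_every_draw(self, tiny_design):
        design, _, _ = tiny_design
        fit = fit_mcmc(design, settings=MCMCSettings(chains=1, warmup=50, samples=40, seed=2))
        for name in ("tau", "lam", "sigma_g", "sigma_I", "c2", "nu"):
            assert np.all(fit.draws[name] > 0)
            assert np.all(np.isfinite(fit.draws[name]))


def _fake_fit(draws_B, extra=None):
    C, P = draws_B.shape[2], draws_B.shape[3]
    draws = {"B": draws_B}
    if extra:
        draws.update(extra)
    return PosteriorFit(
        draws=draws,
        column_names=tuple(f"p{i}" for i in range(P)),
        conditions=tuple(f"c{i}" for i in range(C)),
        subjects=np.arange(2),
        extended=False,
        settings=MCMCSettings(chains=draws_B.shape[0], warmup=0, samples=draws_B.shape[1]),
        spec=HorseshoeSpec(),
    )


class TestDiagnostics:
    def test_iid_chains_have_rhat_near_one(self, rng):
        fit = _fake_fit(rng.standard_normal((4, 1000, 1, 2)))
        out = diagnose_and_summarize(fit)
        assert (out.rhat < 1.01).all()
        assert out.attrs["all_rhat_ok"]

    def test_offset_chain_fails_rhat(self, rng):
        draws = rng.standard_normal((4, 500, 1, 1))
        draws[0] += 10.0
        out = diagnose_and_summarize(_fake_fit(draws))
        assert (out.rhat > 1.05).any()
        assert not out.attrs["all_rhat_ok"]

    def test_symmetric_draws_summary(self, rng):
        x = rng.standard_normal((2, 2000, 1, 1))
        out = diagnose_and_summarize(_fake_fit(x))
        row = out.iloc[0]
        assert abs(row["median"]) < 0.05
        assert row["q2.5"] == pytest.approx(-row["q97.5"], abs=0.15)

    def test_single_chain_flagged(self, rng):
        out = diagnose_and_summarize(_fake_fit(rng.standard_normal((1, 500, 1, 1))))
        assert not out.attrs["all_rhat_ok"]
        assert np.isnan(out.rhat).all()
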