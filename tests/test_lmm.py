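import dataclasses
import shutil
import subprocess

import numpy as np
import pytest

from slopesim import (
    DesignCondition,
    FitResult,
    NotConvergedError,
    DEFAULT_BASE_PARAMS,
    fit_lmm,
    is_singular,
    resolve_params,
    simulate_dataset,
    write_dataset,
)
from slopesim.design import wave_times
from slopesim.lmm import EstimationError, fit_arrays, reml_criterion_at

from oracle_reml import dense_deviance, dense_optimum


def _simulate(cond, seed, params=None):
    params = params or resolve_params(cond, DEFAULT_BASE_PARAMS)
    return simulate_dataset(cond, params, np.random.default_rng(seed))


def _fit_fast(cond, seed, params=None):
    ds = _simulate(cond, seed, params)
    T, m, J = cond.n_waves, cond.class_size, cond.n_classrooms
    return fit_arrays(
        ds.y, wave_times(T), ds.treatment[::T].astype(float), ds.aptitude[::T], T, m, J
    )


class TestDevianceAgainstDenseOracle:
    def test_criterion_matches_dense_evaluation_pointwise(self, small_dataset):
        """The structured deviance equals a dense-matrix evaluation."""
        df = small_dataset.to_frame()
        for theta in [(1.0, 0.0, 1.0, 1.0), (0.4, 0.1, 0.3, 0.5),
                      (0.0, 0.0, 0.0, 0.0), (0.2, -0.5, 0.0, 1.3)]:
            assert reml_criterion_at(small_dataset, theta) == pytest.approx(
                dense_deviance(df, theta), abs=1e-7
            )

    def test_fit_attains_dense_oracle_optimum(self, small_dataset):
        """No generic-optimizer probe of the dense REML surface beats the fit."""
        fit = fit_lmm(small_dataset)
        df = small_dataset.to_frame()
        assert dense_deviance(df, fit.diagnostics["theta"]) == pytest.approx(
            fit.reml_criterion, abs=1e-6
        )
        _, f_oracle = dense_optimum(df)
        assert fit.reml_criterion <= f_oracle + 1e-4


class TestRecovery:
    def test_noise_free_data_recovers_gammas_exactly(self):
        cond = DesignCondition(3, 5, 8, 0.5, 0.2, "large", 1)
        p = resolve_params(cond)
        p = dataclasses.replace(
            p, sigma2_e=1e-300, tau_pi00=0.0, tau_pi01=0.0, tau_pi11=0.0,
            tau_beta00=0.0,
        )
        ds = _simulate(cond, 4, p)
        fit = fit_lmm(ds)
        assert np.allclose(fit.beta_hat, p.fixed_effects, atol=1e-6)
        for v in (fit.sigma2_hat, fit.tau_pi00_hat, fit.tau_pi11_hat,
                  fit.tau_beta00_hat):
            assert v <= 1e-8

    def test_parameter_recovery_large_dataset(self):
        cond = DesignCondition(5, 30, 50, 0.5, 0.2, "large", 1)
        p = resolve_params(cond)
        fit = _fit_fast(cond, 777)
        assert fit.converged
        est = dict(
            sigma2_e=fit.sigma2_hat, tau_pi00=fit.tau_pi00_hat,
            tau_pi01=fit.tau_pi01_hat, tau_pi11=fit.tau_pi11_hat,
            tau_beta00=fit.tau_beta00_hat,
        )
        for name, value in est.items():
            truth = getattr(p, name)
            assert value == pytest.approx(truth, rel=0.25), name
        se = fit.beta_se
        for i, (b, truth) in enumerate(zip(fit.beta_hat, p.fixed_effects)):
            assert abs(b - truth) <= 3 * se[i], fit.beta_names[i]

    def test_vcov_shrinks_with_more_classrooms(self):
        small = DesignCondition(3, 5, 10, 0.5, 0.113, "medium", 1)
        large = DesignCondition(3, 5, 20, 0.5, 0.113, "medium", 1)
        diag_small = np.zeros(8)
        diag_large = np.zeros(8)
        n = 50
        for i in range(n):
            diag_small += np.diag(_fit_fast(small, 3_000 + i).vcov_beta)
            diag_large += np.diag(_fit_fast(large, 3_000 + i).vcov_beta)
        assert np.all(diag_large < diag_small)


class TestDiagnostics:
    def test_singular_flag_rules(self):
        base = dict(
            beta_hat=np.zeros(8), vcov_beta=np.eye(8), sigma2_hat=1.0,
            reml_criterion=0.0, converged=True, singular=False,
        )
        fit = FitResult(tau_pi00_hat=0.2, tau_pi01_hat=0.05, tau_pi11_hat=0.0,
                        tau_beta00_hat=0.1, **base)
        assert is_singular(fit)  # zero slope variance: boundary
        fit = FitResult(tau_pi00_hat=0.2, tau_pi01_hat=0.05 * np.sqrt(2) / 2,
                        tau_pi11_hat=0.1, tau_beta00_hat=0.1, **base)
        assert not is_singular(fit)  # interior, |corr| = 0.25
        rho = 0.99999
        fit = FitResult(tau_pi00_hat=0.2, tau_pi01_hat=rho * np.sqrt(0.02),
                        tau_pi11_hat=0.1, tau_beta00_hat=0.1, **base)
        assert is_singular(fit, tol=1e-4)  # |corr| >= 1 - tol

    def test_boundary_generation_yields_singular_majority(self):
        # no classroom variance generated: tau_beta00_hat sits at the boundary
        cond = DesignCondition(3, 5, 10, 0.5, 0.2, "medium", 1)
        p = dataclasses.replace(resolve_params(cond), tau_beta00=0.0)
        n_singular = 0
        n = 100
        for i in range(n):
            fit = _fit_fast(cond, 9_000 + i, p)
            n_singular += fit.singular
        assert n_singular > n / 2

    def test_single_arm_data_rejected(self, small_dataset):
        df = small_dataset.to_frame()
        df["treatment"] = 0
        with pytest.raises(EstimationError):
            fit_lmm(df)

    def test_probe_refuses_non_converged(self, small_dataset):
        from slopesim.probe import slopes_difference_test

        fit = fit_lmm(small_dataset)
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(NotConvergedError):
            slopes_difference_test(bad)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestLme4CrossCheck:
    def test_agrees_with_lme4(self, tmp_path, small_dataset):
        """Same model in lme4: criterion, estimates and SEs agree."""
        path = tmp_path / "ds.csv"
        write_dataset(small_dataset, path)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{path}")\n'
            'm <- lmer(y ~ treatment*aptitude*time + (1 + time | student)'
            ' + (1 | classroom), data=d, REML=TRUE)\n'
            'cat(REMLcrit(m), fixef(m), sqrt(diag(as.matrix(vcov(m)))),'
            ' sigma(m)^2, "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=300, check=True,
        )
        vals = np.array([float(x) for x in out.stdout.split()])
        crit, beta_r, se_r, s2_r = vals[0], vals[1:9], vals[9:17], vals[17]
        fit = fit_lmm(small_dataset)
        assert fit.reml_criterion == pytest.approx(crit, abs=1e-2)
        assert np.allclose(fit.beta_hat, beta_r, rtol=1e-3, atol=1e-5)
        assert np.allclose(fit.beta_se, se_r, rtol=1e-2)
        assert fit.sigma2_hat == pytest.approx(s2_r, rel=1e-2)
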