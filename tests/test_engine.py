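import numpy as np
import pytest

from rdrbc import (
    GibbsConfig,
    RDRBCImputer,
    build_design,
    build_priors,
    conditional_impute,
    conditional_normal,
    gibbs_fit_impute,
    mmrm_reference_fit,
)
from rdrbc.simulate import SyntheticConfig, generate_trial
from rdrbc.trial_data import PatientRecord, TrialData

from conftest import simple_two_visit_trial, small_config


class TestConditionalNormal:
    def test_two_visit_worked_case(self):
        """Sigma = [[1, .5], [.5, 1]], means (0, 0), observed Y1 = 2 gives
        conditional mean 1.0 and variance 0.75 (textbook formula)."""
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        cm, cc = conditional_normal(
            np.zeros(2), sigma, np.array([2.0, np.nan]), np.array([True, False])
        )
        assert cm[0] == pytest.approx(1.0)
        assert cc[0, 0] == pytest.approx(0.75)

    def test_empty_conditioning_set_is_unconditional(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        mean = np.array([5.0, -1.0])
        cm, cc = conditional_normal(
            mean, sigma, np.array([np.nan, np.nan]), np.array([False, False])
        )
        np.testing.assert_allclose(cm, mean)
        np.testing.assert_allclose(cc, sigma)

    def test_diagonal_sigma_ignores_observed_values(self):
        sigma = np.diag([1.0, 2.0])
        cm, _ = conditional_normal(
            np.array([3.0, 4.0]), sigma, np.array([-50.0, np.nan]),
            np.array([True, False]),
        )
        assert cm[0] == pytest.approx(4.0)

    def test_singular_observed_block_raises(self):
        sigma = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            conditional_normal(
                np.zeros(2), sigma, np.array([1.0, np.nan]),
                np.array([True, False]),
            )

    def test_conditional_impute_requires_missing_cells(self):
        p = PatientRecord("x", 0, 0.0, np.array([1.0, 2.0]), 2, 2)
        with pytest.raises(ValueError, match="missing"):
            conditional_impute(np.zeros(2), np.eye(2), p, np.eye(2))


class TestMMRM:
    def test_parameter_recovery_at_large_n(self, mmrm_big):
        data, truth, fit = mmrm_big
        cfg = truth.config
        assert fit.converged
        np.testing.assert_allclose(fit.sigma, cfg.sigma, rtol=0.2, atol=1.5)
        # fitted means at the average baseline reproduce the marginal profile
        mu_at_mean_baseline = fit.mu + cfg.baseline_mean * fit.beta[
            2 * data.n_visits : 4 * data.n_visits
        ].reshape(2, data.n_visits)
        np.testing.assert_allclose(mu_at_mean_baseline, cfg.mu, atol=0.6)

    def test_balanced_complete_data_reduces_to_cell_means(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(40, 3)) + np.array([1.0, 2.0, 3.0])
        data = TrialData(
            ids=np.arange(40), arm=np.repeat([0, 1], 20),
            baseline=np.zeros(40) + 1.0, y=y,
            dev_visit=np.full(40, 3), last_visit=np.full(40, 3),
        )
        fit = mmrm_reference_fit(data, baseline="none")
        for t in (0, 1):
            np.testing.assert_allclose(
                fit.mu[t], y[data.arm == t].mean(axis=0), atol=1e-6
            )

    def test_one_patient_arm_rejected(self):
        y = np.ones((3, 2))
        data = TrialData(
            ids=list("abc"), arm=[0, 0, 1], baseline=np.zeros(3), y=y,
            dev_visit=[2] * 3, last_visit=[2] * 3,
        )
        with pytest.raises(ValueError, match="degenerate arm"):
            mmrm_reference_fit(data)

    def test_all_missing_visit_column_rejected(self):
        y = np.ones((4, 2))
        y[:2, 1] = np.nan
        data = TrialData(
            ids=list("abcd"), arm=[0, 0, 1, 1], baseline=np.zeros(4), y=y,
            dev_visit=[1, 1, 2, 2], last_visit=[1, 1, 2, 2],
        )
        with pytest.raises(ValueError, match="no on-treatment observations"):
            mmrm_reference_fit(data)


class TestGibbs:
    def test_chains_reproduce_bit_for_bit(self, covered_small):
        data, _ = covered_small
        kw = dict(core="J2R", compliance="historic", prior_variance=4.0,
                  n_imputations=10, n_burn=20, seed=42)
        a = RDRBCImputer(**kw).fit(data).draws_
        b = RDRBCImputer(**kw).fit(data).draws_
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(a.missing_y, b.missing_y)
        c = RDRBCImputer(**{**kw, "seed": 43}).fit(data).draws_
        assert not np.array_equal(a.beta, c.beta)

    def test_no_missing_data_matches_gls_posterior(self):
        """With Sigma fixed and complete data, beta draws are exact draws
        from the closed-form Gaussian posterior: the sample mean and
        covariance must match the GLS oracle within MC tolerance."""
        cfg = small_config(stop_prob=(0.0, 0.0), dev_hazard=np.zeros((2, 2)))
        data, _ = generate_trial(cfg, seed=7)
        sigma = cfg.sigma
        design = build_design(data, "J2R", "historic")
        prior = build_priors(
            design, v=2.0, diffuse_variance=1e8,
            iw_scale=np.eye(3),
        )
        draws = gibbs_fit_impute(
            data, design, prior,
            GibbsConfig(n_burn=50, n_draws=4000, seed=1, fixed_sigma=sigma),
        )
        assert draws.missing_y.shape[1] == 0

        # independent GLS oracle
        X, P0 = design.X, prior.precision
        Sinv = np.linalg.inv(sigma)
        A = P0 + np.einsum("njp,jk,nkq->pq", X, Sinv, X)
        b = np.einsum("njp,jk,nk->p", X, Sinv, data.y - design.offset)
        m = np.linalg.solve(A, b)
        cov = np.linalg.inv(A)

        active = ~np.array(
            [lab in design.never_observed for lab in design.labels]
        )
        sd = np.sqrt(np.diag(cov))
        err = (draws.beta.mean(axis=0) - m) / sd
        assert np.abs(err[active]).max() < 5.0 / np.sqrt(4000)
        emp = np.cov(draws.beta[:, active].T)
        ratio = np.diag(emp) / np.diag(cov)[active]
        assert np.all(np.abs(ratio - 1) < 0.15)

    def test_pinned_j2r_imputation_matches_conditional_mean_oracle(self):
        """With deviation coefficients pinned and Sigma fixed, the mean
        imputed value for a patient missing all off-treatment visits equals
        the J2R conditional mean E[Y_J | pre-deviation Y, E(beta), Sigma]."""
        cfg = small_config(stop_prob=(1.0, 1.0))
        data, _ = generate_trial(cfg, seed=9)
        sigma = cfg.sigma
        imp = RDRBCImputer(
            core="J2R", pin_deviation=True, use_off_treatment=False,
            n_imputations=4000, n_burn=100, seed=3, fixed_sigma=sigma,
        ).fit(data)
        draws = imp.draws_
        # pick an active patient with D=1 (missing visits 2, 3)
        i = int(np.flatnonzero((data.arm == 1) & (data.dev_visit == 1))[0])
        sel = (draws.missing_index[:, 0] == i) & (draws.missing_index[:, 1] == 2)
        imputed = draws.missing_y[:, np.flatnonzero(sel)[0]]

        beta_bar = draws.beta.mean(axis=0)
        mean_i = imp.design_.X[i] @ beta_bar + imp.design_.offset[i]
        cm, cc = conditional_normal(
            mean_i, sigma, data.y[i], ~np.isnan(data.y[i])
        )
        mc_se = np.sqrt(cc[-1, -1] / draws.n_draws)
        assert imputed.mean() == pytest.approx(cm[-1], abs=4 * mc_se + 1e-3)

    def test_posterior_gamma_matches_conjugate_closed_form(self):
        """Two-visit trial emulating the one-visit setting: the posterior
        mean of the deviation coefficients must match the closed-form joint
        normal-normal solution within MC error."""
        rho = 2.0
        counts = dict(n_on0=50, n_off0=15, n_miss0=15,
                      n_on1=40, n_off1=20, n_miss1=20)
        data = simple_two_visit_trial(mu2=(0.0, 1.0), gamma=(0.3, 0.8), **counts)
        imp = RDRBCImputer(
            core="J2R", compliance="historic", prior_variance=1.0 / rho,
            baseline="none", n_imputations=6000, n_burn=200, seed=2,
            fixed_sigma=np.eye(2), diffuse_scale=1e8,
        ).fit(data)
        draws = imp.draws_

        # closed-form joint posterior of (mu_02, gamma*_012, gamma*_112)
        obs = data.observed_mask()
        on2 = obs[:, 1] & (data.dev_visit == 2)
        off2 = obs[:, 1] & (data.dev_visit == 1)
        a = int((on2 & (data.arm == 0)).sum())
        b = int((off2 & (data.arm == 0)).sum())
        c = int((off2 & (data.arm == 1)).sum())
        ybar_a = data.y[on2 & (data.arm == 0), 1].mean()
        ybar_b = data.y[off2 & (data.arm == 0), 1].mean()
        ybar_c = data.y[off2 & (data.arm == 1), 1].mean()
        Lam = np.array(
            [[a + b + c, b, c], [b, b + rho, 0.0], [c, 0.0, c + rho]]
        )
        h = np.array(
            [a * ybar_a + b * ybar_b + c * ybar_c, b * ybar_b, c * ybar_c]
        )
        theta = np.linalg.solve(Lam, h)
        post_sd = np.sqrt(np.diag(np.linalg.inv(Lam)))

        idx = {lab: i for i, lab in enumerate(draws.labels)}
        K = draws.n_draws
        for col, target, sd in [
            (("mu", 0, 2), theta[0], post_sd[0]),
            (("gamma*", 0, 1, 2), theta[1], post_sd[1]),
            (("gamma*", 1, 1, 2), theta[2], post_sd[2]),
        ]:
            est = draws.beta[:, idx[col]].mean()
            # direct sampling: draws are nearly independent
            assert est == pytest.approx(target, abs=5 * sd / np.sqrt(K) + 2e-3)

    def test_observed_cells_preserved_in_completed_datasets(self, covered_small):
        data, _ = covered_small
        imp = RDRBCImputer(
            core="J2R", prior_variance=4.0, n_imputations=5, n_burn=20, seed=0
        ).fit(data)
        obs = data.observed_mask()
        for y in imp.impute():
            assert not np.isnan(y).any()
            np.testing.assert_array_equal(y[obs], data.y[obs])

    def test_draws_export_round_trip(self, covered_small, tmp_path):
        import pandas as pd

        data, _ = covered_small
        draws = RDRBCImputer(
            core="J2R", prior_variance=4.0, n_imputations=6, n_burn=10, seed=1
        ).fit(data).draws_
        draws.to_csv(str(tmp_path / "chain"))
        beta = pd.read_csv(tmp_path / "chain_beta.csv")
        assert beta.shape == draws.beta.shape
        np.testing.assert_allclose(beta.to_numpy(), draws.beta)

    def test_posterior_predictive_coverage_matched_model(self):
        """Under a matched generating model, nominal 90% posterior-predictive
        intervals for held-out off-treatment cells cover about 90%."""
        cfg = small_config(
            n_ref=120, n_act=120, dev_hazard=np.full((2, 2), 0.2),
            stop_prob=(0.0, 0.0), truth="j2r",
        )
        data, _ = generate_trial(cfg, seed=21)
        off_obs = data.off_treatment_mask() & data.observed_mask()
        cells = np.argwhere(off_obs)
        truth_vals = data.y[off_obs]
        held = data.copy()
        held.y[off_obs] = np.nan

        imp = RDRBCImputer(
            core="J2R", compliance="historic", prior_variance=1.0,
            n_imputations=400, n_burn=200, seed=5,
        ).fit(held)
        draws = imp.draws_
        pos = {tuple(ij): k for k, ij in enumerate(map(tuple, draws.missing_index))}
        covered = 0
        for (i, j), val in zip(map(tuple, cells), truth_vals):
            col = draws.missing_y[:, pos[(i, j)]]
            lo, hi = np.quantile(col, [0.05, 0.95])
            covered += lo <= val <= hi
        frac = covered / len(cells)
        se = np.sqrt(0.9 * 0.1 / len(cells))
        assert abs(frac - 0.90) < 4 * se + 0.02
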