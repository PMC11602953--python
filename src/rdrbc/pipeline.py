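"""Multiple-imputation pipeline: impute, analyse, pool.

Orchestrates the generic algorithm: build the extended design and priors,
run the conjugate Gibbs sampler, form K completed datasets, analyse each by
ANCOVA at the final visit (outcome on randomised treatment + baseline), and
combine with Rubin's rules using the Barnard–Rubin small-sample degrees of
freedom.

The central object is :class:`RDRBCImputer`, a scikit-learn-style estimator
(``fit`` / ``impute`` / ``transform``, ``get_params``/``set_params``,
fitted attributes with trailing underscores).  :class:`ClassicRBIImputer`
is the classic reference-based comparator: deviation coefficients
structurally pinned at zero and (optionally) off-treatment observations
excluded from the likelihood, with observed values merged back after
imputation if requested.  ``run_rdrbc_mi`` / ``run_classic_rbi`` /
``run_compliance_mi`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .design import (
    ComplianceSpec,
    CoreModelSpec,
    build_design,
    build_priors,
    check_nesting,
    default_prior_variance,
)
from .engine import GibbsConfig, PosteriorDraws, gibbs_fit_impute
from .trial_data import TrialData, merge_observed_off_treatment

__all__ = [
    "MIResult",
    "RDRBCImputer",
    "ClassicRBIImputer",
    "run_rdrbc_mi",
    "run_classic_rbi",
    "run_compliance_mi",
    "ancova_final_visit",
    "pool_rubin",
    "compare_methods",
]


# ---------------------------------------------------------------------------
# Analysis model and pooling
# ---------------------------------------------------------------------------

def ancova_final_visit(
    y, arm: np.ndarray, baseline: np.ndarray
) -> tuple[float, float]:
    """ANCOVA of the final-visit outcome on treatment and baseline.

    ``y`` may be a completed (N, J) matrix (final column is analysed) or an
    (N,) vector.  Returns the treatment-difference estimate and its
    sampling variance.
    """
    y = np.asarray(y, float)
    if y.ndim == 2:
        y = y[:, -1]
    if np.isnan(y).any():
        raise ValueError("final-visit outcomes contain missing values")
    baseline = np.asarray(baseline, float)
    if np.ptp(baseline) == 0:
        raise ValueError("baseline is constant (collinear with the intercept)")
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([np.asarray(arm, float), baseline]))
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1] ** 2)


@dataclass
class PooledResult:
    estimate: float
    se: float
    df: float
    ci: tuple
    p_value: float
    W: float
    B: float
    K: int


def pool_rubin(
    estimates, variances, complete_data_df: float, alpha: float = 0.05
) -> PooledResult:
    """Rubin's rules with the Barnard–Rubin small-sample degrees of freedom.

    Pooled variance T = W + (1 + 1/K) B with W the mean within-imputation
    variance and B the between-imputation variance; the df are
    1 / (1/nu_m + 1/nu_obs) referenced against the complete-data df.
    """
    q = np.asarray(estimates, float)
    w = np.asarray(variances, float)
    K = len(q)
    if K < 2:
        raise ValueError("Rubin's rules require at least 2 imputations")
    if (w <= 0).any():
        raise ValueError("non-positive within-imputation variance")
    qbar = float(q.mean())
    wbar = float(w.mean())
    B = float(q.var(ddof=1))
    T = wbar + (1.0 + 1.0 / K) * B
    lam = (1.0 + 1.0 / K) * B / T
    nu_com = float(complete_data_df)
    if lam <= 0:
        df = nu_com
    else:
        nu_m = (K - 1) / max(lam**2, 1e-300)  # guard underflow for tiny B
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        df = 1.0 / (1.0 / nu_m + 1.0 / nu_obs)
    se = float(np.sqrt(T))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else 0.0
    return PooledResult(
        estimate=qbar,
        se=se,
        df=float(df),
        ci=(qbar - tcrit * se, qbar + tcrit * se),
        p_value=float(p),
        W=wbar,
        B=B,
        K=K,
    )


@dataclass
class MIResult:
    """Pooled treatment-policy inference plus per-imputation bookkeeping.

    ``mc_se`` = sqrt(B / K) is the Monte Carlo SE of the pooled estimate
    from using finitely many imputations.
    """

    estimate: float
    se: float
    df: float
    ci: tuple
    p_value: float
    K: int
    estimates: np.ndarray
    variances: np.ndarray
    W: float
    B: float
    mc_se: float
    v: float | None
    never_observed: list
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"treatment difference {self.estimate:.3f} (SE {self.se:.3f}, "
            f"95% CI {lo:.3f} to {hi:.3f}, df {self.df:.1f}, K={self.K}, "
            f"MC SE {self.mc_se:.4f})"
        )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class RDRBCImputer(BaseEstimator):
    """Retrieved-dropout reference-base centred multiple imputer.

    Fits the Bayesian repeated-measures MVN model whose mean is a
    reference-based core (``core``) plus zero-centred compliance-deviation
    parameters (``compliance``) with prior variance ``prior_variance``, and
    draws ``n_imputations`` completed datasets from the chain.

    Parameters mirror the analysis choices: ``prior_variance`` may be a
    number (outcome units squared) or ``"mmrm_residual"`` / ``"range"`` for
    the data-driven defaults; ``pin_deviation=True`` structurally fixes the
    deviation coefficients at zero (the classic reference-based limit);
    ``use_off_treatment=False`` removes observed off-treatment values from
    the likelihood (they are then re-imputed); ``raw_compliance=True``
    drops the centring and fits the plain compliance model with diffuse
    priors (the unpenalised comparator).

    Fitted attributes: ``design_``, ``prior_``, ``draws_``, ``v_``,
    ``never_observed_``, ``nesting_``, ``fit_data_`` (the data as seen by
    the likelihood) and ``data_`` (the original input).
    """

    def __init__(
        self,
        core="J2R",
        compliance="historic",
        prior_variance="mmrm_residual",
        adjacent_corr: float = 0.0,
        diffuse_scale: float = 1e6,
        baseline: str = "visit_trt",
        grouped_covariance: bool = False,
        pin_deviation: bool = False,
        use_off_treatment: bool = True,
        raw_compliance: bool = False,
        n_imputations: int = 200,
        n_burn: int = 1000,
        thin: int = 1,
        seed: int | None = None,
        iw_df: float | None = None,
        iw_scale=None,
        fixed_sigma=None,
    ):
        self.core = core
        self.compliance = compliance
        self.prior_variance = prior_variance
        self.adjacent_corr = adjacent_corr
        self.diffuse_scale = diffuse_scale
        self.baseline = baseline
        self.grouped_covariance = grouped_covariance
        self.pin_deviation = pin_deviation
        self.use_off_treatment = use_off_treatment
        self.raw_compliance = raw_compliance
        self.n_imputations = n_imputations
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.fixed_sigma = fixed_sigma

    # -- sklearn-style API --------------------------------------------------
    def fit(self, X: TrialData, y=None) -> "RDRBCImputer":
        if not isinstance(X, TrialData):
            raise TypeError("X must be a TrialData instance")
        data = X
        fit_data = data
        if not self.use_off_treatment:
            fit_data = data.copy()
            drop = data.off_treatment_mask() & data.observed_mask()
            fit_data.y[drop] = np.nan

        core = (
            self.core
            if isinstance(self.core, CoreModelSpec)
            else CoreModelSpec(kind=self.core)
        )
        if isinstance(self.prior_variance, str):
            v = default_prior_variance(fit_data, method=self.prior_variance)
        elif self.prior_variance is None:
            v = None
        else:
            v = float(self.prior_variance)

        design = build_design(
            fit_data,
            core,
            compliance=self.compliance,
            baseline=self.baseline,
            include_deviation=not self.pin_deviation,
            raw_compliance=self.raw_compliance,
        )
        obs_y = fit_data.y[fit_data.observed_mask()]
        sample_var = float(np.var(obs_y)) if obs_y.size > 1 else 1.0
        diffuse = self.diffuse_scale * max(sample_var, 1e-12)
        if v is None:  # raw compliance model: deviations get diffuse priors
            v = diffuse
        iw_scale = (
            np.eye(fit_data.n_visits) * sample_var
            if self.iw_scale is None
            else np.asarray(self.iw_scale, float)
        )
        prior = build_priors(
            design,
            v=v,
            diffuse_variance=diffuse,
            adjacent_corr=self.adjacent_corr,
            iw_df=self.iw_df,
            iw_scale=iw_scale,
        )
        cfg = GibbsConfig(
            n_burn=self.n_burn,
            n_draws=self.n_imputations,
            thin=self.thin,
            seed=self.seed,
            grouped_covariance=self.grouped_covariance,
            fixed_sigma=self.fixed_sigma,
        )
        self.data_ = data
        self.fit_data_ = fit_data
        self.design_ = design
        self.prior_ = prior
        self.v_ = float(v)
        self.never_observed_ = design.never_observed
        self.nesting_ = (
            check_nesting(core, self.compliance, fit_data.n_visits)
            if not (self.pin_deviation or self.raw_compliance)
            else None
        )
        self.draws_ = gibbs_fit_impute(fit_data, design, prior, cfg)
        return self

    def impute(self):
        """Yield K completed (N, J) outcome matrices (observed cells of the
        likelihood data preserved exactly)."""
        return self.draws_.completed_datasets(self.fit_data_)

    def transform(self, X=None) -> np.ndarray:
        """Stacked completed datasets, shape (K, N, J)."""
        return np.stack(list(self.impute()))

    def fit_transform(self, X: TrialData, y=None) -> np.ndarray:
        return self.fit(X).transform()


class ClassicRBIImputer(RDRBCImputer):
    """Classic reference-based multiple imputation (J2R / CIR / CR).

    Imputes all post-deviation cells from the core model fitted to
    on-treatment data only (the deviation block is structurally absent and,
    unless ``use_off_treatment_data``, observed off-treatment values are
    excluded from the likelihood).  With ``merge_back`` the observed
    off-treatment values overwrite their imputations before analysis.
    """

    def __init__(
        self,
        core="J2R",
        use_off_treatment_data: bool = False,
        merge_back: bool = False,
        baseline: str = "visit_trt",
        grouped_covariance: bool = False,
        n_imputations: int = 200,
        n_burn: int = 1000,
        thin: int = 1,
        seed: int | None = None,
        iw_df: float | None = None,
        iw_scale=None,
        fixed_sigma=None,
    ):
        super().__init__(
            core=core,
            compliance="historic",
            prior_variance=1.0,  # irrelevant: deviation block is pinned
            baseline=baseline,
            grouped_covariance=grouped_covariance,
            pin_deviation=True,
            use_off_treatment=use_off_treatment_data,
            n_imputations=n_imputations,
            n_burn=n_burn,
            thin=thin,
            seed=seed,
            iw_df=iw_df,
            iw_scale=iw_scale,
            fixed_sigma=fixed_sigma,
        )
        self.use_off_treatment_data = use_off_treatment_data
        self.merge_back = merge_back

    def fit(self, X: TrialData, y=None) -> "ClassicRBIImputer":
        self.use_off_treatment = self.use_off_treatment_data
        super().fit(X)
        return self

    def impute(self):
        for y in super().impute():
            yield (
                merge_observed_off_treatment(y, self.data_)
                if self.merge_back
                else y
            )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def _analyse(imputer: RDRBCImputer, data: TrialData) -> MIResult:
    ests, varis = [], []
    for y in imputer.impute():
        e, w = ancova_final_visit(y, data.arm, data.baseline)
        ests.append(e)
        varis.append(w)
    pooled = pool_rubin(ests, varis, complete_data_df=data.n_patients - 3)
    return MIResult(
        estimate=pooled.estimate,
        se=pooled.se,
        df=pooled.df,
        ci=pooled.ci,
        p_value=pooled.p_value,
        K=pooled.K,
        estimates=np.asarray(ests),
        variances=np.asarray(varis),
        W=pooled.W,
        B=pooled.B,
        mc_se=float(np.sqrt(pooled.B / pooled.K)),
        v=getattr(imputer, "v_", None),
        never_observed=list(getattr(imputer, "never_observed_", [])),
        config=imputer.get_params(deep=False),
    )


def run_rdrbc_mi(data: TrialData, **params) -> MIResult:
    """Run the full retrieved-dropout reference-base centred MI analysis.

    Keyword arguments are :class:`RDRBCImputer` parameters.  Returns pooled
    ANCOVA inference for the final-visit treatment difference.
    """
    imp = RDRBCImputer(**params).fit(data)
    return _analyse(imp, data)


def run_classic_rbi(
    data: TrialData,
    core="J2R",
    use_off_treatment_data: bool = False,
    merge_back: bool = False,
    **params,
) -> MIResult:
    """Classic reference-based MI comparator (see :class:`ClassicRBIImputer`)."""
    imp = ClassicRBIImputer(
        core=core,
        use_off_treatment_data=use_off_treatment_data,
        merge_back=merge_back,
        **params,
    ).fit(data)
    return _analyse(imp, data)


def run_compliance_mi(data: TrialData, compliance="historic", **params) -> MIResult:
    """Unpenalised retrieved-dropout compliance MI (diffuse priors on the
    off-treatment stratum means) — the v -> infinity comparator."""
    imp = RDRBCImputer(
        core="MAR",
        compliance=compliance,
        prior_variance=None,
        raw_compliance=True,
        **params,
    ).fit(data)
    return _analyse(imp, data)


def compare_methods(
    data: TrialData,
    v_grid=(1.0, 10.0, 40.0, 160.0, 1000.0),
    cores=("J2R",),
    compliances=("historic", "current"),
    include_classic: bool = True,
    **params,
):
    """Run a grid of methods and prior variances; returns a tidy DataFrame
    (method, core, compliance, v, estimate, SE) shaped like a results table."""
    import pandas as pd

    rows = []
    if include_classic:
        for merge in (False, True):
            res = run_classic_rbi(data, core="J2R", merge_back=merge, **params)
            rows.append(
                {
                    "method": "classic_rbi" + ("_merge_back" if merge else ""),
                    "core": "J2R",
                    "compliance": "",
                    "v": np.nan,
                    "estimate": res.estimate,
                    "se": res.se,
                }
            )
    for core in cores:
        for comp in compliances:
            if not check_nesting(core, comp, data.n_visits):
                continue
            for v in v_grid:
                res = run_rdrbc_mi(
                    data, core=core, compliance=comp, prior_variance=v, **params
                )
                rows.append(
                    {
                        "method": "rdrbc",
                        "core": core if isinstance(core, str) else core.kind,
                        "compliance": comp,
                        "v": v,
                        "estimate": res.estimate,
                        "se": res.se,
                    }
                )
    return pd.DataFrame(rows)
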