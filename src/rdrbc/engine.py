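"""Conjugate Gibbs sampler for the Bayesian repeated-measures MVN model.

The model for patient i is ``Y_i ~ MVN(X_i beta + offset_i, Sigma)`` with a
Gaussian prior on ``beta`` (diffuse for core coefficients, mildly
informative zero-centred for the deviation coefficients) and an
inverse-Wishart prior on the unstructured ``Sigma`` (optionally one per
arm).  All full conditionals are available in closed form, so the sampler
is pure direct sampling with very little serial correlation:

1. draw each patient's missing outcome cells from their conditional MVN
   given the observed cells and the current (beta, Sigma);
2. draw beta from its conjugate multivariate-normal full conditional given
   the completed data;
3. draw Sigma from its inverse-Wishart full conditional.

Imputations fall out of the chain: every stored sweep's missing-cell draws
form one completed dataset.  Missing cells contribute no information about
beta once integrated out, so coefficients with no observed data behind them
(perforated strata) retain exactly their prior — by design.

``mmrm_reference_fit`` provides the maximum-likelihood repeated-measures
fit to on-treatment data (an EM algorithm over the unstructured covariance)
used for sampler initialisation and the default deviation-prior variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.stats import invwishart

from .design import DesignMatrices, PriorSpec, build_design
from .trial_data import PatientRecord, TrialData

__all__ = [
    "GibbsConfig",
    "PosteriorDraws",
    "MMRMFit",
    "gibbs_fit_impute",
    "conditional_normal",
    "conditional_impute",
    "mmrm_reference_fit",
]


@dataclass
class GibbsConfig:
    """Sampler settings; ``n_draws`` is the number K of stored sweeps
    (= imputed datasets), taken every ``thin`` sweeps after ``n_burn``."""

    n_burn: int = 1000
    n_draws: int = 200
    thin: int = 1
    seed: int | None = None
    grouped_covariance: bool = False
    fixed_sigma: np.ndarray | None = None


@dataclass
class PosteriorDraws:
    """Stored posterior sample: beta (K, P), sigma (K, J, J) or
    (K, 2, J, J) when grouped by arm, and the missing-cell draws
    (K, M) matching ``missing_index`` (row i, visit j pairs, 0-based)."""

    beta: np.ndarray
    sigma: np.ndarray
    missing_y: np.ndarray
    missing_index: np.ndarray
    labels: list
    n_burn: int
    thin: int
    seed: int | None
    grouped: bool

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def completed_datasets(self, data: TrialData):
        """Yield (N, J) completed outcome matrices, one per stored draw.

        Observed cells are carried over bit-identically from ``data``.
        """
        for k in range(self.n_draws):
            y = data.y.copy()
            if self.missing_index.size:
                y[self.missing_index[:, 0], self.missing_index[:, 1]] = (
                    self.missing_y[k]
                )
            yield y

    def to_csv(self, prefix: str) -> None:
        """Export beta and vectorised sigma draws for external diagnostics."""
        import pandas as pd

        pd.DataFrame(
            self.beta, columns=[str(l) for l in self.labels]
        ).to_csv(f"{prefix}_beta.csv", index=False)
        K = self.sigma.shape[0]
        pd.DataFrame(self.sigma.reshape(K, -1)).to_csv(
            f"{prefix}_sigma.csv", index=False
        )


# ---------------------------------------------------------------------------
# Conditional-normal helpers
# ---------------------------------------------------------------------------

def conditional_normal(
    mean: np.ndarray, sigma: np.ndarray, y: np.ndarray, obs_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moments of the missing sub-vector given the observed one.

    Returns the conditional mean and covariance of ``y[~obs_mask]`` given
    ``y[obs_mask]`` under ``y ~ MVN(mean, sigma)``.  With an empty
    conditioning set this is the unconditional distribution.
    """
    mean = np.asarray(mean, float)
    obs_mask = np.asarray(obs_mask, bool)
    mis = ~obs_mask
    if not obs_mask.any():
        return mean[mis], sigma[np.ix_(mis, mis)]
    Soo = sigma[np.ix_(obs_mask, obs_mask)]
    Smo = sigma[np.ix_(mis, obs_mask)]
    try:
        cf = sla.cho_factor(Soo)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular observed-block covariance"
        ) from exc
    B = sla.cho_solve(cf, Smo.T).T
    cond_mean = mean[mis] + B @ (y[obs_mask] - mean[obs_mask])
    cond_cov = sigma[np.ix_(mis, mis)] - B @ Smo.T
    return cond_mean, cond_cov


def conditional_impute(
    beta: np.ndarray,
    sigma: np.ndarray,
    patient: PatientRecord,
    design_rows: np.ndarray,
    offset_rows: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one patient's missing visits from their conditional MVN.

    The mean vector is ``design_rows @ beta (+ offset)``; the draw is from
    the distribution of the missing sub-vector conditional on the observed
    one, and is deterministic given the random state.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(patient.outcomes, float)
    mis = np.isnan(y)
    if not mis.any():
        raise ValueError("patient has no missing cells to impute")
    mean = design_rows @ beta
    if offset_rows is not None:
        mean = mean + offset_rows
    cm, cc = conditional_normal(mean, sigma, y, ~mis)
    L = np.linalg.cholesky(cc + 1e-12 * np.eye(cc.shape[0]))
    return cm + L @ rng.standard_normal(mis.sum())


# ---------------------------------------------------------------------------
# MMRM (EM) reference fit
# ---------------------------------------------------------------------------

@dataclass
class MMRMFit:
    beta: np.ndarray
    mu: np.ndarray  # (2, J) arm-by-visit on-treatment means
    sigma: np.ndarray  # (J, J) unstructured residual covariance
    labels: list
    converged: bool
    n_iter: int


def mmrm_reference_fit(
    data: TrialData,
    baseline: str = "visit_trt",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MMRMFit:
    """Repeated-measures ML fit (arm-by-visit means + baseline terms,
    unstructured covariance) to on-treatment data only.

    Off-treatment and missing cells are excluded from the likelihood; the
    unstructured Sigma is estimated by EM over the incomplete on-treatment
    vectors.  Used for sampler initialisation and the default
    deviation-prior variance.
    """
    N, J = data.y.shape
    for t in (0, 1):
        if (data.arm == t).sum() < 2:
            raise ValueError("degenerate arm with fewer than 2 patients")
    use = data.observed_mask() & ~data.off_treatment_mask()
    for t in (0, 1):
        per_visit = use[data.arm == t].sum(axis=0)
        if (per_visit == 0).any():
            raise ValueError(
                f"arm {t}: no on-treatment observations at visit(s) "
                f"{list(np.flatnonzero(per_visit == 0) + 1)}"
            )

    design = build_design(
        data, core="MAR", include_deviation=False, baseline=baseline, check=False
    )
    X = design.X  # (N, J, P)
    P = X.shape[2]
    y = data.y

    # initial beta by per-cell least squares on used cells, Sigma diagonal
    rows = X[use]
    beta = np.linalg.lstsq(rows, y[use], rcond=None)[0]
    resid0 = y[use] - rows @ beta
    sigma = np.eye(J) * max(float(np.var(resid0)), 1e-8)

    patterns: dict[tuple, np.ndarray] = {}
    for i in range(N):
        patterns.setdefault(tuple(use[i]), []).append(i)
    patterns = {k: np.array(v) for k, v in patterns.items()}

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = np.zeros((P, P))
        b = np.zeros(P)
        yhat = np.where(use, y, 0.0)
        cond_cov_sum = np.zeros((J, J))
        sinv_cache = {}
        # E-step: conditional means of unused cells, expected Gram
        for pat, idx in patterns.items():
            obs = np.array(pat)
            mis = ~obs
            mean = np.einsum("njp,p->nj", X[idx], beta)
            if mis.any():
                if obs.any():
                    Soo = sigma[np.ix_(obs, obs)]
                    Smo = sigma[np.ix_(mis, obs)]
                    B = np.linalg.solve(Soo, Smo.T).T
                    cm = mean[:, mis] + (y[idx][:, obs] - mean[:, obs]) @ B.T
                    cc = sigma[np.ix_(mis, mis)] - B @ Smo.T
                else:
                    cm = mean[:, mis]
                    cc = sigma
                yhat[np.ix_(idx, np.flatnonzero(mis))] = cm
                full_cc = np.zeros((J, J))
                full_cc[np.ix_(mis, mis)] = cc
                cond_cov_sum += len(idx) * full_cc
        # M-step for beta: GLS with current Sigma on completed data
        Sinv = np.linalg.inv(sigma)
        G = np.einsum("njp,nkq->jkpq", X, X)
        A = np.einsum("jk,jkpq->pq", Sinv, G)
        b = np.einsum("njp,nj->p", X, yhat @ Sinv.T)
        beta_new = np.linalg.solve(A, b)
        resid = yhat - np.einsum("njp,p->nj", X, beta_new)
        sigma_new = (resid.T @ resid + cond_cov_sum) / N
        delta = max(
            np.max(np.abs(beta_new - beta)), np.max(np.abs(sigma_new - sigma))
        )
        beta, sigma = beta_new, sigma_new
        if delta < tol:
            converged = True
            break

    mu = beta[: 2 * J].reshape(2, J)
    return MMRMFit(
        beta=beta,
        mu=mu,
        sigma=sigma,
        labels=design.labels,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _draw_sigma(rng, df, scale, max_retry: int = 5) -> np.ndarray:
    jitter = 0.0
    for attempt in range(max_retry):
        try:
            S = scale + jitter * np.eye(scale.shape[0])
            return invwishart.rvs(df=df, scale=S, random_state=rng)
        except np.linalg.LinAlgError:
            jitter = max(jitter, 1e-10 * np.trace(scale)) * 10
    raise np.linalg.LinAlgError(
        "inverse-Wishart draw failed repeatedly (non-PD scale)"
    )


def gibbs_fit_impute(
    data: TrialData,
    design: DesignMatrices,
    priors: PriorSpec,
    cfg: GibbsConfig,
) -> PosteriorDraws:
    """Run the conjugate Gibbs sampler and collect imputation draws.

    Reproducible bit-for-bit given identical seed, data and configuration.
    """
    N, J = data.y.shape
    X = design.X
    P = X.shape[2]
    if X.shape[:2] != (N, J):
        raise ValueError("design rows do not align with patient-visits")
    offset = design.offset
    rng = np.random.default_rng(cfg.seed)

    miss = np.isnan(data.y)
    miss_idx = np.argwhere(miss)
    M = len(miss_idx)

    grouped = bool(cfg.grouped_covariance)
    group_of = data.arm if grouped else np.zeros(N, dtype=int)
    n_groups = 2 if grouped else 1

    P0 = priors.precision
    P0m0 = P0 @ priors.mean

    # fixed per-group Gram tensors G[g][j, k, p, q] = sum_i X[i,j,p] X[i,k,q]
    grams = []
    group_idx = []
    for g in range(n_groups):
        idx = np.flatnonzero(group_of == g)
        if idx.size == 0:
            raise ValueError("empty arm in grouped-covariance fit")
        group_idx.append(idx)
        grams.append(np.einsum("njp,nkq->jkpq", X[idx], X[idx]))

    # patient groups by (sigma group, missingness pattern), fixed order
    pat_groups: dict[tuple, list] = {}
    for i in range(N):
        pat_groups.setdefault((group_of[i], tuple(miss[i])), []).append(i)
    pat_keys = sorted(pat_groups)
    pat_groups = {k: np.array(pat_groups[k]) for k in pat_keys}

    # ---- initialisation ---------------------------------------------------
    baseline_mode = {0: "none", J: "visit", 2 * J: "visit_trt"}[
        sum(1 for l in design.labels if l[0] == "baseline")
    ]
    beta = np.zeros(P)
    if cfg.fixed_sigma is not None:
        sigmas = np.repeat(
            np.asarray(cfg.fixed_sigma, float)[None], n_groups, axis=0
        )
    else:
        sigmas = np.repeat(priors.iw_scale[None], n_groups, axis=0)
    try:
        init = mmrm_reference_fit(data, baseline=baseline_mode)
        n_init = len(init.beta)
        beta[:n_init] = init.beta  # mu + baseline blocks; deviations stay 0
        if cfg.fixed_sigma is None:
            sigmas = np.repeat(init.sigma[None], n_groups, axis=0)
    except Exception as exc:  # noqa: BLE001 - fall back to prior-based init
        warnings.warn(f"MMRM initialisation failed ({exc}); using prior init")

    y = data.y.copy()
    # start missing cells at their conditional means
    for (g, pat), idx in pat_groups.items():
        mrow = np.array(pat)
        if not mrow.any():
            continue
        mean = np.einsum("njp,p->nj", X[idx], beta) + offset[idx]
        for i, row in zip(idx, mean):
            cm, _ = conditional_normal(row, sigmas[g], data.y[i], ~mrow)
            y[i, mrow] = cm

    K = cfg.n_draws
    beta_out = np.empty((K, P))
    sig_out = np.empty((K, n_groups, J, J))
    miss_out = np.empty((K, M))

    n_sweeps = cfg.n_burn + K * cfg.thin
    stored = 0
    for sweep in range(n_sweeps):
        # 1. impute missing cells given (beta, Sigma)
        for (g, pat), idx in pat_groups.items():
            mrow = np.array(pat)
            if not mrow.any():
                continue
            sig = sigmas[g]
            obs = ~mrow
            mean = np.einsum("njp,p->nj", X[idx], beta) + offset[idx]
            if obs.any():
                Soo = sig[np.ix_(obs, obs)]
                Smo = sig[np.ix_(mrow, obs)]
                try:
                    cf = sla.cho_factor(Soo)
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        "singular observed-block covariance"
                    ) from exc
                B = sla.cho_solve(cf, Smo.T).T
                cm = mean[:, mrow] + (y[idx][:, obs] - mean[:, obs]) @ B.T
                cc = sig[np.ix_(mrow, mrow)] - B @ Smo.T
            else:
                cm = mean[:, mrow]
                cc = sig
            L = np.linalg.cholesky(cc + 1e-12 * np.eye(cc.shape[0]))
            z = rng.standard_normal((len(idx), int(mrow.sum())))
            y[np.ix_(idx, np.flatnonzero(mrow))] = cm + z @ L.T

        # 2. draw beta from its conjugate full conditional
        A = P0.copy()
        b = P0m0.copy()
        for g in range(n_groups):
            Sinv = np.linalg.inv(sigmas[g])
            A += np.einsum("jk,jkpq->pq", Sinv, grams[g])
            idx = group_idx[g]
            R = y[idx] - offset[idx]
            b += np.einsum("njp,nj->p", X[idx], R @ Sinv.T)
        L = np.linalg.cholesky(A)
        m = sla.cho_solve((L, True), b)
        beta = m + sla.solve_triangular(
            L.T, rng.standard_normal(P), lower=False
        )

        # 3. draw Sigma from its inverse-Wishart full conditional
        if cfg.fixed_sigma is None:
            fitted = np.einsum("njp,p->nj", X, beta) + offset
            resid = y - fitted
            for g in range(n_groups):
                idx = group_idx[g]
                S = priors.iw_scale + resid[idx].T @ resid[idx]
                sigmas[g] = _draw_sigma(rng, priors.iw_df + len(idx), S)

        s = sweep - cfg.n_burn
        if s >= 0 and (s + 1) % cfg.thin == 0:
            beta_out[stored] = beta
            sig_out[stored] = sigmas
            miss_out[stored] = y[miss] if M else np.empty(0)
            stored += 1

    sigma_final = sig_out if grouped else sig_out[:, 0]
    return PosteriorDraws(
        beta=beta_out,
        sigma=sigma_final,
        missing_y=miss_out,
        missing_index=miss_idx,
        labels=design.labels,
        n_burn=cfg.n_burn,
        thin=cfg.thin,
        seed=cfg.seed,
        grouped=grouped,
    )
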