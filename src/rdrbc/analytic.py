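"""Exact bias and RMSE of the centred estimator in the one-visit setting.

A two-arm trial with a single Gaussian outcome (variance sigma^2, known),
no baseline covariate, and in each arm t a proportion p_t who withdraw from
treatment before the outcome, of whom a proportion q_t are unobserved.
Patients therefore fall into on-treatment observed, off-treatment observed,
and off-treatment missing groups with means mu_on_t, mu_off_t and
mu_miss_t = mu_off_t (missingness at random given deviation status).

The centred imputation model writes the off-treatment means as departures
from the reference on-treatment mean,

    mu_miss_t = mu_off_t = mu_on_0 + gamma_t,   gamma_t ~ N(0, sigma^2 / rho),

with flat priors on the on-treatment means; ``rho`` is the prior precision
relative to the residual precision (the effective number of extra data
points backing the core model).  With gamma pinned at zero this is
jump-to-reference; with rho -> 0 it is the MAR compliance model.

At an infinite number of imputations the MI point estimate of each arm mean
replaces the missing group by the posterior mean of mu_miss_t, making the
treatment estimate a linear function of the observed group means.  Its
first two moments are therefore available in closed form conditional on the
deviation/missingness counts, and the marginal bias and RMSE follow by
summing over the binomial distribution of those counts
(n_dev_t ~ Bin(n, p_t), n_miss_t | n_dev_t ~ Bin(n_dev_t, q_t),
independently per arm).  ``mc_oracle`` provides a brute-force simulation
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "SimpleScenario",
    "PatternCounts",
    "te_real",
    "conditional_moments",
    "bias_rmse",
    "mc_oracle",
]


@dataclass(frozen=True)
class SimpleScenario:
    """One-visit two-arm configuration for the analytic calculator.

    gamma_t = mu_off_t - mu_on_0 by construction (the generating model sets
    mu_miss_t = mu_off_t); sigma2 is treated as known.
    """

    n_per_arm: int = 100
    p0: float = 0.4
    p1: float = 0.4
    q0: float = 0.5
    q1: float = 0.5
    mu_on_0: float = 1.0
    mu_off_0: float = 1.0
    mu_on_1: float = 1.0
    mu_off_1: float = 1.0
    sigma2: float = 1.0
    rho: float = 1.0

    def __post_init__(self):
        for name in ("p0", "p1", "q0", "q1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @property
    def gamma0(self) -> float:
        return self.mu_off_0 - self.mu_on_0

    @property
    def gamma1(self) -> float:
        return self.mu_off_1 - self.mu_on_0

    def with_rho(self, rho: float) -> "SimpleScenario":
        return replace(self, rho=rho)


@dataclass(frozen=True)
class PatternCounts:
    """Realised per-arm pattern: on-treatment, observed off-treatment and
    missing counts (they sum to the arm size)."""

    n_on: int
    n_off: int
    n_miss: int

    @property
    def n(self) -> int:
        return self.n_on + self.n_off + self.n_miss


def te_real(s: SimpleScenario) -> float:
    """Population treatment-policy contrast
    [(1-p1) mu_on_1 + p1 mu_off_1] - [(1-p0) mu_on_0 + p0 mu_off_0]."""
    a1 = (1 - s.p1) * s.mu_on_1 + s.p1 * s.mu_off_1
    a0 = (1 - s.p0) * s.mu_on_0 + s.p0 * s.mu_off_0
    return a1 - a0


# ---------------------------------------------------------------------------
# Posterior-mean weights given counts
# ---------------------------------------------------------------------------
# Parameters (mu_on_0, gamma0, gamma1) have joint Gaussian posterior with
# precision (in units of 1/sigma^2)
#     [[a+b+c, b, c], [b, b+rho, 0], [c, 0, c+rho]]
# where a = n_on_0, b = n_off_0, c = n_off_1, and natural parameter
#     h = [a ybar_on0 + b ybar_off0 + c ybar_off1, b ybar_off0, c ybar_off1].
# The imputation targets are mu_on_0 + gamma_t.  ``_impute_weights`` returns,
# for each arm, the weights of (ybar_on0, ybar_off0, ybar_off1) in that
# posterior mean.  All arrays broadcast over a leading batch axis.

def _impute_weights(a, b, c, rho, posterior="joint"):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    shape = np.broadcast_shapes(a.shape, b.shape, c.shape)
    a, b, c = (np.broadcast_to(x, shape) for x in (a, b, c))

    if posterior == "plugin":
        # mu_on_0 estimated by ybar_on0 alone; gamma_t shrunk around it
        w0 = np.zeros(shape + (3,))
        w1 = np.zeros(shape + (3,))
        s0 = np.divide(b, b + rho, out=np.zeros(shape), where=(b + rho) > 0)
        s1 = np.divide(c, c + rho, out=np.zeros(shape), where=(c + rho) > 0)
        w0[..., 0] = 1.0 - s0
        w0[..., 1] = s0
        w1[..., 0] = 1.0 - s1
        w1[..., 2] = s1
        return w0, w1
    if posterior != "joint":
        raise ValueError(f"unknown posterior {posterior!r}")

    Lam = np.zeros(shape + (3, 3))
    Lam[..., 0, 0] = a + b + c
    Lam[..., 0, 1] = Lam[..., 1, 0] = b
    Lam[..., 0, 2] = Lam[..., 2, 0] = c
    Lam[..., 1, 1] = b + rho
    Lam[..., 2, 2] = c + rho
    M = np.zeros(shape + (3, 3))  # columns: ybar_on0, ybar_off0, ybar_off1
    M[..., 0, 0] = a
    M[..., 0, 1] = b
    M[..., 0, 2] = c
    M[..., 1, 1] = b
    M[..., 2, 2] = c

    det = np.linalg.det(Lam)
    ok = det > 1e-9
    safe = np.where(ok[..., None, None], Lam, np.eye(3))
    W = np.linalg.solve(safe, M)  # rows of W: weights of theta components
    W = np.where(ok[..., None, None], W, 0.0)  # degenerate: fall back to 0
    w0 = W[..., 0, :] + W[..., 1, :]  # mu_on_0 + gamma_0
    w1 = W[..., 0, :] + W[..., 2, :]  # mu_on_0 + gamma_1
    return w0, w1


def _moments_given_counts(a, b, m0, non1, c, m1, s: SimpleScenario, posterior,
                          weights=None):
    """Conditional bias (vs the conditional-on-counts truth) and conditional
    MSE (vs TE_Real), vectorised over a batch axis.  ``weights`` may carry
    precomputed imputation weights (they depend on (a, b, c) only)."""
    n = float(s.n_per_arm)
    if weights is None:
        w0, w1 = _impute_weights(a, b, c, s.rho, posterior=posterior)
    else:
        w0, w1 = weights
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    m0 = np.asarray(m0, float)
    non1 = np.asarray(non1, float)
    m1 = np.asarray(m1, float)

    # weights of (ybar_on0, ybar_off0, ybar_on1, ybar_off1) in the estimate
    W = np.zeros(np.broadcast_shapes(a.shape, m1.shape) + (4,))
    W[..., 2] = non1 / n
    W[..., 3] = c / n
    W[..., [0, 1, 3]] += (m1[..., None] * w1 - m0[..., None] * w0) / n
    W[..., 0] -= a / n
    W[..., 1] -= b / n

    mu = np.array([s.mu_on_0, s.mu_off_0, s.mu_on_1, s.mu_off_1])
    est_mean = W @ mu
    counts = np.stack(np.broadcast_arrays(a, b, non1, c), axis=-1)
    var_terms = np.divide(
        W**2 * s.sigma2, counts, out=np.zeros_like(W), where=counts > 0
    )
    est_var = var_terms.sum(axis=-1)

    cond_truth = (
        non1 * s.mu_on_1
        + (c + m1) * s.mu_off_1
        - a * s.mu_on_0
        - (b + m0) * s.mu_off_0
    ) / n
    te = te_real(s)
    cond_bias = est_mean - cond_truth
    cond_mse = (est_mean - te) ** 2 + est_var
    return cond_bias, cond_mse


def conditional_moments(
    counts0: PatternCounts,
    counts1: PatternCounts,
    s: SimpleScenario,
    posterior: str = "joint",
) -> tuple[float, float]:
    """Exact moments of the infinite-imputation estimate given the counts.

    Returns ``(conditional bias, conditional MSE)``.  The bias is taken
    against the conditional-on-counts treatment-policy mean (so that its
    pmf-weighted sum over count patterns is exactly the marginal bias
    against TE_Real, and it is identically zero when no imputation occurs);
    the MSE is against TE_Real so that its pmf-weighted sum is the marginal
    squared error.  With ``n_off = 0`` in an arm the posterior for that
    arm's gamma is its prior (mean zero).
    """
    for cts in (counts0, counts1):
        if cts.n != s.n_per_arm:
            raise ValueError("counts do not sum to n_per_arm")
    bias, mse = _moments_given_counts(
        np.array(counts0.n_on),
        np.array(counts0.n_off),
        np.array(counts0.n_miss),
        np.array(counts1.n_on),
        np.array(counts1.n_off),
        np.array(counts1.n_miss),
        s,
        posterior,
    )
    return float(bias), float(mse)


def _arm_patterns(n: int, p: float, q: float, tail: float):
    """Support of (n_dev, n_miss) with joint pmf, truncated to patterns whose
    pmf exceeds ``tail`` (the discarded mass is far below any tolerance)."""
    ndev = np.arange(n + 1)
    pdev = stats.binom.pmf(ndev, n, p)
    rows = []
    for d in ndev[pdev > tail * 1e-3]:
        m = np.arange(d + 1)
        pm = stats.binom.pmf(m, d, q) * pdev[d]
        keep = pm > tail
        for mm, w in zip(m[keep], pm[keep]):
            rows.append((int(d), int(mm), float(w)))
    dev = np.array([r[0] for r in rows])
    mis = np.array([r[1] for r in rows])
    w = np.array([r[2] for r in rows])
    return dev, mis, w


def bias_rmse(
    s: SimpleScenario, posterior: str = "joint", tail: float = 1e-14
) -> tuple[float, float]:
    """Marginal bias and RMSE of the estimator against TE_Real.

    Sums the conditional moments over the joint binomial pmf of the
    deviation/missingness counts in the two arms (support truncated at
    negligible pmf; the retained mass exceeds 1 - 1e-10).
    """
    n = s.n_per_arm
    d0, m0, w0 = _arm_patterns(n, s.p0, s.q0, tail)
    d1, m1, w1 = _arm_patterns(n, s.p1, s.q1, tail)

    bias_acc = 0.0
    mse_acc = 0.0
    wtot = 0.0
    # the posterior weights depend on arm 1 only through its off-observed
    # count c = d1 - m1: compute them on the deduplicated (a, b, c) grid
    c_all = d1 - m1
    c_uniq, c_inv = np.unique(c_all, return_inverse=True)
    # batch over arm-0 patterns; broadcast arm-1 patterns inside
    chunk = max(1, int(2e6 // max(len(d1), 1)))
    for start in range(0, len(d0), chunk):
        sl = slice(start, start + chunk)
        a = (n - d0[sl])[:, None]
        b = (d0[sl] - m0[sl])[:, None]
        mm0 = m0[sl][:, None]
        non1 = (n - d1)[None, :]
        c = c_all[None, :]
        mm1 = m1[None, :]
        wu0, wu1 = _impute_weights(a, b, c_uniq[None, :], s.rho, posterior)
        weights = (wu0[:, c_inv, :], wu1[:, c_inv, :])
        cb, cm = _moments_given_counts(
            a, b, mm0, non1, c, mm1, s, posterior, weights=weights
        )
        wgt = w0[sl][:, None] * w1[None, :]
        bias_acc += float((wgt * cb).sum())
        mse_acc += float((wgt * cm).sum())
        wtot += float(wgt.sum())
    # renormalise for the (negligible) truncated tail
    return bias_acc / wtot, float(np.sqrt(mse_acc / wtot))


class OracleResult(NamedTuple):
    bias: float
    rmse: float
    mc_se: float


def mc_oracle(
    s: SimpleScenario,
    reps: int = 100_000,
    seed: int | None = None,
    posterior: str = "joint",
    force_positive_counts: bool = False,
) -> OracleResult:
    """Brute-force simulation of repeated trials.

    Draws the deviation/missingness counts and the observed group means,
    applies the same shrinkage estimator, and averages; ``mc_se`` is the
    Monte Carlo standard error of the bias estimate.  With
    ``force_positive_counts`` degenerate zero-count patterns are redrawn
    (used for boundary checks at rho = 0).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = s.n_per_arm
    te = te_real(s)

    errs = np.empty(reps)
    done = 0
    chunk = 200_000
    while done < reps:
        r = min(chunk, reps - done)
        d0 = rng.binomial(n, s.p0, size=r)
        m0 = rng.binomial(d0, s.q0)
        d1 = rng.binomial(n, s.p1, size=r)
        m1 = rng.binomial(d1, s.q1)
        if force_positive_counts:
            for _ in range(100):
                bad = (d0 - m0 == 0) | (d1 - m1 == 0) | (n - d0 == 0)
                if not bad.any():
                    break
                nb = int(bad.sum())
                d0[bad] = rng.binomial(n, s.p0, size=nb)
                m0[bad] = rng.binomial(d0[bad], s.q0)
                d1[bad] = rng.binomial(n, s.p1, size=nb)
                m1[bad] = rng.binomial(d1[bad], s.q1)
        a = n - d0
        b = d0 - m0
        non1 = n - d1
        c = d1 - m1

        sd = np.sqrt(s.sigma2)

        def gmean(mu, cnt):
            out = np.full(r, mu, float)
            pos = cnt > 0
            out[pos] += rng.standard_normal(int(pos.sum())) * sd / np.sqrt(cnt[pos])
            # cells with zero count never enter the estimate (weight zero)
            return out

        y_on0 = gmean(s.mu_on_0, a)
        y_off0 = gmean(s.mu_off_0, b)
        y_on1 = gmean(s.mu_on_1, non1)
        y_off1 = gmean(s.mu_off_1, c)

        w0, w1 = _impute_weights(a, b, c, s.rho, posterior=posterior)
        ybar3 = np.stack([y_on0, y_off0, y_off1], axis=-1)
        imp0 = (w0 * ybar3).sum(axis=-1)
        imp1 = (w1 * ybar3).sum(axis=-1)
        arm1 = (non1 * y_on1 + c * y_off1 + m1 * imp1) / n
        arm0 = (a * y_on0 + b * y_off0 + m0 * imp0) / n
        errs[done : done + r] = arm1 - arm0 - te
        done += r

    bias = float(errs.mean())
    rmse = float(np.sqrt((errs**2).mean()))
    mc_se = float(errs.std(ddof=1) / np.sqrt(reps))
    return OracleResult(bias=bias, rmse=rmse, mc_se=mc_se)
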