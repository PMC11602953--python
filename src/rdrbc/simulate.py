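"""Synthetic trial generator with covered and perforated layouts.

Generates two-arm longitudinal Gaussian trials with the structure the
imputation method assumes: multivariate-normal outcome trajectories around
arm-by-visit means with an unstructured covariance, a baseline covariate
entering every visit, a discrete per-visit treatment-withdrawal hazard, and
an all-or-nothing follow-up rule — each deviator either stops observation
immediately (probability q per arm) or is observed off treatment to the end
of the study.  Off-treatment means follow a configurable truth rule
(jump-to-reference, copy-increments-in-reference, MAR, or a custom gamma
table of departures from the reference profile).

Deviation is outcome-independent by default (deviation completely at
random, which the analytic calculator assumes); a DNAR coefficient makes
the hazard depend on the current latent outcome for stress tests.  A
perforation spec empties chosen (arm, deviation-visit) strata of observed
off-treatment data, reproducing the "hole" that makes unpenalised
compliance models non-estimable.

The generating parameters, including the exact treatment-policy effect,
are returned alongside the data so tests never re-derive them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .analytic import SimpleScenario
from .trial_data import TrialData

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_trial",
    "make_perforated",
    "scenario_preset",
    "example_layout_trial",
    "EXAMPLE_LAYOUTS",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "no_effect_dcar",
    "no_effect_dnar",
    "j2r",
    "effect_dcar",
    "example_trial",
)


@dataclass
class SyntheticConfig:
    """Generating model for a two-arm longitudinal trial.

    ``mu`` is the (2, J) on-treatment mean matrix (reference row first);
    ``dev_hazard`` the (2, J-1) probability of deviating at visit k (i.e.
    last on-treatment visit k) given still on treatment; ``stop_prob`` the
    per-arm probability that a deviator stops observation immediately.
    ``baseline_effect`` multiplies the centred baseline at every visit, so
    ``mu`` stays the marginal mean profile.  ``truth`` selects the
    off-treatment mean rule; ``gamma_table`` (2, J-1, J) holds custom
    departures from the reference profile indexed by (arm, deviation visit,
    visit).  ``perforate`` lists (arm, deviation visit) strata forced to
    have no observed off-treatment data.
    """

    n_ref: int = 88
    n_act: int = 84
    n_visits: int = 4
    mu: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-1.0, -2.0, -3.0, -4.0], [-2.0, -4.0, -6.0, -8.0]]
        )
    )
    sigma: np.ndarray = field(
        default_factory=lambda: (
            np.sqrt(np.array([16.0, 25.0, 32.0, 40.0]))[:, None]
            * (0.6 ** np.abs(np.subtract.outer(np.arange(4), np.arange(4))))
            * np.sqrt(np.array([16.0, 25.0, 32.0, 40.0]))[None, :]
        )
    )
    baseline_mean: float = 18.0
    baseline_sd: float = 5.0
    baseline_effect: float = -0.2
    dev_hazard: np.ndarray = field(
        default_factory=lambda: np.array(
            [[7 / 88, 5 / 81, 11 / 76], [6 / 84, 5 / 78, 9 / 73]]
        )
    )
    stop_prob: tuple = (0.5, 0.5)
    truth: str = "j2r"
    gamma_table: np.ndarray | None = None
    dnar_coef: float = 0.0
    partial_followup: bool = False
    perforate: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        self.dev_hazard = np.atleast_2d(np.asarray(self.dev_hazard, float))
        J = self.n_visits
        if self.mu.shape != (2, J):
            raise ValueError(f"mu must have shape (2, {J})")
        if self.sigma.shape != (J, J):
            raise ValueError(f"sigma must have shape ({J}, {J})")
        np.linalg.cholesky(self.sigma)  # PD check
        if self.dev_hazard.shape != (2, J - 1):
            raise ValueError(f"dev_hazard must have shape (2, {J - 1})")
        if ((self.dev_hazard < 0) | (self.dev_hazard > 1)).any():
            raise ValueError("hazards must lie in [0, 1]")
        if self.truth not in ("j2r", "cir", "mar", "custom"):
            raise ValueError(f"unknown truth rule {self.truth!r}")
        if self.truth == "custom":
            self.gamma_table = np.asarray(self.gamma_table, float)
            if self.gamma_table.shape != (2, J - 1, J):
                raise ValueError(f"gamma_table must have shape (2, {J-1}, {J})")
        for t, k in self.perforate:
            if t not in (0, 1) or not (1 <= k <= J - 1):
                raise ValueError(f"perforation stratum ({t}, {k}) out of range")


@dataclass
class TruthRecord:
    """Generating parameters and bookkeeping written next to the data."""

    true_effect: float
    dev_probs: np.ndarray  # (2, J) P(D = k), k = 1..J (k = J: completer)
    mean_final: tuple
    config: SyntheticConfig
    stratum_counts: dict = field(default_factory=dict)  # (t, D, stop?) -> n


def _off_mean(cfg: SyntheticConfig, t: int, k: int, j: int) -> float:
    """Marginal off-treatment mean for arm t, deviation visit k, visit j > k."""
    mu = cfg.mu
    if cfg.truth == "j2r":
        return float(mu[0, j - 1])
    if cfg.truth == "cir":
        return float(mu[0, j - 1] + mu[t, k - 1] - mu[0, k - 1])
    if cfg.truth == "mar":
        return float(mu[t, j - 1])
    return float(mu[0, j - 1] + cfg.gamma_table[t, k - 1, j - 1])


def _dev_probs(cfg: SyntheticConfig) -> np.ndarray:
    """P(D = k) per arm under the (outcome-independent) hazard process."""
    J = cfg.n_visits
    out = np.zeros((2, J))
    for t in (0, 1):
        surv = 1.0
        for k in range(1, J):
            h = cfg.dev_hazard[t, k - 1]
            out[t, k - 1] = surv * h
            surv *= 1.0 - h
        out[t, J - 1] = surv
    return out


def true_effect(cfg: SyntheticConfig) -> tuple[float, tuple]:
    """Exact treatment-policy contrast at the final visit implied by the
    generating model (valid for the outcome-independent deviation process)."""
    J = cfg.n_visits
    probs = _dev_probs(cfg)
    means = []
    for t in (0, 1):
        m = probs[t, J - 1] * cfg.mu[t, J - 1]
        for k in range(1, J):
            m += probs[t, k - 1] * _off_mean(cfg, t, k, J)
        means.append(float(m))
    return means[1] - means[0], tuple(means)


def generate_trial(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[TrialData, TruthRecord]:
    """Draw one synthetic trial; returns the data and its truth record.

    Residual trajectories are MVN(0, sigma); deviation visits come from the
    per-visit hazard (independent of future residuals; with ``dnar_coef``
    the hazard shifts with the current standardised residual); follow-up is
    all-or-nothing per patient unless ``partial_followup``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    J = cfg.n_visits
    n = cfg.n_ref + cfg.n_act
    arm = np.repeat([0, 1], [cfg.n_ref, cfg.n_act])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    eps = rng.multivariate_normal(np.zeros(J), cfg.sigma, size=n, method="cholesky")
    sd = np.sqrt(np.diag(cfg.sigma))

    dev = np.full(n, J, dtype=int)
    at_risk = np.ones(n, dtype=bool)
    for k in range(1, J):
        h = cfg.dev_hazard[arm, k - 1]
        if cfg.dnar_coef != 0.0:
            with np.errstate(divide="ignore"):
                h = expit(logit(np.clip(h, 1e-12, 1 - 1e-12))
                          + cfg.dnar_coef * eps[:, k - 1] / sd[k - 1])
        hit = at_risk & (rng.random(n) < h)
        dev[hit] = k
        at_risk &= ~hit

    mean = np.empty((n, J))
    for i in range(n):
        t, k = int(arm[i]), int(dev[i])
        for j in range(1, J + 1):
            mean[i, j - 1] = (
                cfg.mu[t, j - 1] if j <= k else _off_mean(cfg, t, k, j)
            )
    y = mean + cfg.baseline_effect * (baseline - cfg.baseline_mean)[:, None] + eps

    last = np.full(n, J, dtype=int)
    deviator = dev < J
    if cfg.partial_followup:
        u = rng.random(n)
        stop = deviator & (u < np.asarray(cfg.stop_prob)[arm])
        span = J - dev
        extra = rng.integers(0, span + 1)  # S uniform on {D, ..., J}
        last = np.where(stop, dev, np.where(deviator, dev + extra, J))
    else:
        stop = deviator & (rng.random(n) < np.asarray(cfg.stop_prob)[arm])
        last[stop] = dev[stop]

    for t, k in cfg.perforate:
        sel = (arm == t) & (dev == k)
        if not sel.any():
            raise ValueError(
                f"infeasible perforation: stratum (arm={t}, D={k}) is empty"
            )
        last[sel] = k

    visits = np.arange(1, J + 1)
    y = np.where(visits[None, :] > last[:, None], np.nan, y)

    data = TrialData(
        ids=np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object),
        arm=arm,
        baseline=baseline,
        y=y,
        dev_visit=dev,
        last_visit=last,
        arm_labels=("reference", "active"),
    )
    te, mean_final = true_effect(cfg)
    tally = {}
    for t in (0, 1):
        tally[(t, J, "continue")] = int(((arm == t) & (dev == J)).sum())
        for k in range(1, J):
            for stopped in (True, False):
                sel = (arm == t) & (dev == k) & ((last == dev) == stopped)
                tally[(t, k, "stop" if stopped else "continue")] = int(sel.sum())
    truth = TruthRecord(
        true_effect=te,
        dev_probs=_dev_probs(cfg),
        mean_final=mean_final,
        config=cfg,
        stratum_counts=tally,
    )
    return data, truth


def make_perforated(data: TrialData, strata) -> TrialData:
    """Delete the off-treatment observations of the listed
    (arm, deviation-visit) strata by setting S = D there (idempotent)."""
    out = data.copy()
    J = data.n_visits
    visits = np.arange(1, J + 1)
    for t, k in strata:
        sel = (out.arm == t) & (out.dev_visit == k)
        out.last_visit[sel] = k
        out.y[np.ix_(sel, np.arange(J))] = np.where(
            visits[None, :] > k, np.nan, out.y[sel]
        )
    out.validate()
    return out


# Published pattern frequencies of the antidepressant example datasets:
# per arm, a list of (deviation visit, n stopping immediately, n continuing
# observed off treatment) plus the on-treatment completer count.
EXAMPLE_LAYOUTS = {
    "covered": {
        "reference": ([(1, 4, 3), (2, 1, 4), (3, 6, 5)], 65),
        "active": ([(1, 2, 4), (2, 4, 1), (3, 4, 5)], 64),
    },
    "perforated": {
        "reference": ([(1, 2, 5), (2, 1, 4), (3, 8, 3)], 65),
        "active": ([(1, 6, 0), (2, 1, 4), (3, 3, 6)], 64),
    },
}


def example_layout_trial(
    kind: str = "covered", seed: int = 0, cfg: SyntheticConfig | None = None
) -> TrialData:
    """Synthetic trial with *exactly* the published deviation/missingness
    pattern frequencies of the covered or perforated example layout
    (J = 4 visits, 88 reference / 84 active patients).

    The (arm, deviation visit, stop/continue) stratum counts are fixed;
    outcome and baseline values are drawn from the ``example_trial``
    generating model.  This is a synthetic stand-in for the published
    example datasets — only the pattern bookkeeping is reproduced, not the
    outcome values.
    """
    if kind not in EXAMPLE_LAYOUTS:
        raise ValueError(f"unknown layout {kind!r}")
    if cfg is None:
        cfg = SyntheticConfig()
    rng = np.random.default_rng(seed)
    J = cfg.n_visits
    ids, arm, dev, last = [], [], [], []
    for t, label in ((0, "reference"), (1, "active")):
        strata, completers = EXAMPLE_LAYOUTS[kind][label]
        for k, n_stop, n_cont in strata:
            for _ in range(n_stop):
                arm.append(t), dev.append(k), last.append(k)
            for _ in range(n_cont):
                arm.append(t), dev.append(k), last.append(J)
        for _ in range(completers):
            arm.append(t), dev.append(J), last.append(J)
    n = len(arm)
    arm = np.array(arm)
    dev = np.array(dev)
    last = np.array(last)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    eps = rng.multivariate_normal(np.zeros(J), cfg.sigma, size=n, method="cholesky")
    mean = np.empty((n, J))
    for i in range(n):
        t, k = int(arm[i]), int(dev[i])
        for j in range(1, J + 1):
            mean[i, j - 1] = cfg.mu[t, j - 1] if j <= k else _off_mean(cfg, t, k, j)
    y = mean + cfg.baseline_effect * (baseline - cfg.baseline_mean)[:, None] + eps
    visits = np.arange(1, J + 1)
    y = np.where(visits[None, :] > last[:, None], np.nan, y)
    return TrialData(
        ids=np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object),
        arm=arm,
        baseline=baseline,
        y=y,
        dev_visit=dev,
        last_visit=last,
        arm_labels=("reference", "active"),
    )


def scenario_preset(name: str, **overrides):
    """Named study conditions.

    The four one-visit scenarios return a :class:`SimpleScenario` with
    n = 100 per arm, 40% deviation and 50% missingness given deviation and
    the four means (mu_off_0, mu_on_0, mu_off_1, mu_on_1):

    * ``no_effect_dcar`` — (1, 1, 1, 1), gamma = (0, 0)
    * ``no_effect_dnar`` — (1, 2, 1, 2), gamma = (-1, -1)
    * ``j2r``            — (1, 1, 1, 2), gamma = (0, 0)
    * ``effect_dcar``    — (1, 1, 2, 2), gamma = (0, 1)

    (gamma_t = mu_off_t - mu_on_0 throughout.)  ``example_trial`` returns a
    longitudinal :class:`SyntheticConfig` with J = 4 visits, arms of 88/84
    and deviation hazards calibrated to a covered layout.
    """
    if name == "example_trial":
        return SyntheticConfig(**overrides)
    means = {
        "no_effect_dcar": (1.0, 1.0, 1.0, 1.0),
        "no_effect_dnar": (1.0, 2.0, 1.0, 2.0),
        "j2r": (1.0, 1.0, 1.0, 2.0),
        "effect_dcar": (1.0, 1.0, 2.0, 2.0),
    }
    if name not in means:
        raise ValueError(f"unknown preset {name!r} (choose from {PRESET_NAMES})")
    mu_off_0, mu_on_0, mu_off_1, mu_on_1 = means[name]
    kw = dict(
        n_per_arm=100,
        p0=0.4,
        p1=0.4,
        q0=0.5,
        q1=0.5,
        mu_on_0=mu_on_0,
        mu_off_0=mu_off_0,
        mu_on_1=mu_on_1,
        mu_off_1=mu_off_1,
        sigma2=1.0,
    )
    kw.update(overrides)
    return SimpleScenario(**kw)
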