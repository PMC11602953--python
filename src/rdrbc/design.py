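"""Mean-model design construction for reference-base centred imputation.

The imputation model for a patient-visit cell has three blocks:

* a *core* block expressing the cell's reference-based mean (J2R, CIR,
  LMCF, RTB, MAR or MAR+delta) as a linear functional of the on-treatment
  mean parameters ``mu[t, j]`` plus a fixed offset,
* a *deviation* block of compliance-model parameters (``alpha*[t, j]`` for
  the current model, ``gamma*[t, k, j]`` for the historic model) measuring
  how far the off-treatment means depart from the core, and
* a baseline-covariate block (baseline crossed with visit, optionally also
  with treatment).

With every deviation coefficient at zero the model collapses to classic
reference-based imputation; with a diffuse prior on them it recovers the
unpenalised retrieved-dropout compliance model.  The core must be *nested*
in the compliance model (its implied off-treatment mean constant within
each compliance stratum), which :func:`check_nesting` verifies numerically.

Deviation cells that never occur in the observed data are deliberately
retained: their posterior equals their prior, which is exactly what makes
perforated datasets tractable.  They are listed in the design report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trial_data import TrialData, derive_patterns

__all__ = [
    "CORE_KINDS",
    "COMPLIANCE_KINDS",
    "CoreModelSpec",
    "ComplianceSpec",
    "DesignMatrices",
    "PriorSpec",
    "NestingError",
    "NestingReport",
    "core_offset_means",
    "core_cell_functional",
    "build_design",
    "check_nesting",
    "default_prior_variance",
    "build_priors",
]

CORE_KINDS = ("MAR", "J2R", "CIR", "CR", "LMCF", "RTB", "MAR_DELTA")
COMPLIANCE_KINDS = ("current", "historic", "full_pattern")


class NestingError(ValueError):
    """Core model not nested within the requested compliance model."""


@dataclass
class CoreModelSpec:
    """Reference-based core mean model.

    ``delta`` (MAR_DELTA only) maps arm code -> offsets indexed by visits
    since deviation, in outcome units; shorter vectors are extended with
    their last element.  ``rtb_pooled`` selects the pooled-arms baseline
    mean for the RTB core (per-arm otherwise).  CR (copy reference) is
    applied to off-treatment cells only, where it coincides with J2R.
    """

    kind: str = "J2R"
    delta: dict | None = None
    rtb_pooled: bool = True
    reference_arm: object | None = None  # informational; code 0 is reference

    def __post_init__(self) -> None:
        self.kind = str(self.kind).upper()
        if self.kind not in CORE_KINDS:
            raise ValueError(f"unknown core kind {self.kind!r}")
        if self.kind == "MAR_DELTA":
            if self.delta is None:
                self.delta = {0: (0.0,), 1: (0.0,)}
            self.delta = {int(t): tuple(map(float, v)) for t, v in self.delta.items()}
        elif self.delta is not None:
            raise ValueError("delta is only meaningful for the MAR_DELTA core")

    def delta_for(self, t: int, gap: int) -> float:
        """Offset for arm ``t`` at ``gap`` = j - k visits after deviation."""
        vec = self.delta.get(int(t), (0.0,))
        return vec[min(gap - 1, len(vec) - 1)]

    @property
    def history_dependent(self) -> bool:
        """Whether the implied off-treatment mean depends on the deviation visit."""
        if self.kind in ("CIR", "LMCF"):
            return True
        if self.kind == "MAR_DELTA":
            return any(len(set(v)) > 1 for v in self.delta.values())
        return False


@dataclass
class ComplianceSpec:
    """Retrieved-dropout compliance model: which strata get free off-means."""

    kind: str = "historic"

    def __post_init__(self) -> None:
        self.kind = str(self.kind).lower()
        if self.kind not in COMPLIANCE_KINDS:
            raise ValueError(f"unknown compliance kind {self.kind!r}")


def _as_core(core) -> CoreModelSpec:
    return core if isinstance(core, CoreModelSpec) else CoreModelSpec(kind=core)


def _as_compliance(compliance) -> ComplianceSpec:
    return (
        compliance
        if isinstance(compliance, ComplianceSpec)
        else ComplianceSpec(kind=compliance)
    )


# ---------------------------------------------------------------------------
# Core mean functionals
# ---------------------------------------------------------------------------

def _rtb_consts(core: CoreModelSpec, data: TrialData | None) -> tuple[float, float]:
    # Placeholder values are used for structural checks without data; they
    # are distinct per arm so a per-arm RTB is not mistaken for pooled.
    if data is None:
        return (1.234375, 1.234375) if core.rtb_pooled else (1.234375, 2.234375)
    if core.rtb_pooled:
        m = float(np.mean(data.baseline))
        return (m, m)
    return (
        float(np.mean(data.baseline[data.arm == 0])),
        float(np.mean(data.baseline[data.arm == 1])),
    )


def core_cell_functional(
    core, t: int, k: int, j: int, J: int, data: TrialData | None = None
) -> tuple[np.ndarray, float]:
    """Express the core-implied mean of cell (t, D=k, visit j) as
    ``w @ mu_flat + const`` with ``mu_flat = [mu[0,1..J], mu[1,1..J]]``.
    """
    core = _as_core(core)
    w = np.zeros(2 * J)

    def e(tt: int, jj: int) -> None:
        w[tt * J + (jj - 1)] += 1.0

    if j <= k:  # on treatment: the mu[t, j] structure for every core
        e(t, j)
        return w, 0.0

    kind = core.kind
    if kind in ("J2R", "CR"):
        e(0, j)
        return w, 0.0
    if kind == "CIR":
        e(0, j)
        e(t, k)
        w[0 * J + (k - 1)] -= 1.0
        return w, 0.0
    if kind == "LMCF":
        e(t, k)
        return w, 0.0
    if kind == "MAR":
        e(t, j)
        return w, 0.0
    if kind == "MAR_DELTA":
        e(t, j)
        return w, core.delta_for(t, j - k)
    if kind == "RTB":
        consts = _rtb_consts(core, data)
        return w, consts[t]
    raise ValueError(f"unknown core kind {kind!r}")  # pragma: no cover


def core_offset_means(
    core,
    mu: np.ndarray,
    t: int,
    k: int,
    j: int,
    baseline_mean: float | Sequence[float] | None = None,
) -> float:
    """Core-implied off-treatment mean of cell (t, D=k, visit j), j > k.

    ``mu`` is the (2, J) on-treatment mean array.  Written directly from the
    defining formulas (J2R -> mu[0,j]; CIR -> mu[0,j] + mu[t,k] - mu[0,k];
    LMCF -> mu[t,k]; RTB -> baseline mean; MAR -> mu[t,j]; MAR+delta ->
    mu[t,j] + delta_t(j-k)) so it can cross-check the design-row encoding.
    """
    core = _as_core(core)
    mu = np.asarray(mu, dtype=float)
    if j <= k:
        raise ValueError(f"off-treatment cell requires j > k (got j={j}, k={k})")
    kind = core.kind
    if kind in ("J2R", "CR"):
        return float(mu[0, j - 1])
    if kind == "CIR":
        return float(mu[0, j - 1] + mu[t, k - 1] - mu[0, k - 1])
    if kind == "LMCF":
        return float(mu[t, k - 1])
    if kind == "MAR":
        return float(mu[t, j - 1])
    if kind == "MAR_DELTA":
        return float(mu[t, j - 1] + core.delta_for(t, j - k))
    if kind == "RTB":
        if baseline_mean is None:
            raise ValueError("RTB core requires a baseline mean")
        bm = np.atleast_1d(np.asarray(baseline_mean, dtype=float))
        return float(bm[0] if bm.size == 1 else bm[t])
    raise ValueError(f"unknown core kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Nesting
# ---------------------------------------------------------------------------

@dataclass
class NestingReport:
    ok: bool
    offending: list
    max_residual: float
    core: str
    compliance: str

    def __bool__(self) -> bool:
        return self.ok


def check_nesting(core, compliance, J: int, rtol: float = 1e-8) -> NestingReport:
    """Verify the core model is nested within the compliance model.

    For every off-treatment cell (t, k, j > k) the core-implied mean is a
    linear functional of (mu, constants).  Nesting holds iff that functional
    is constant across the cells sharing one compliance stratum (so a single
    free compliance parameter can absorb it).  The historic and full-pattern
    models give each (t, k, j) cell its own stratum, hence nest any core;
    the current model pools over k within (t, j), rejecting history-
    dependent cores such as CIR, LMCF or MAR+delta with a non-constant delta.
    """
    core = _as_core(core)
    compliance = _as_compliance(compliance)
    groups: dict[tuple, list] = {}
    for t in (0, 1):
        for k in range(1, J):
            for j in range(k + 1, J + 1):
                w, c = core_cell_functional(core, t, k, j, J, data=None)
                f = np.concatenate([w, [c]])
                key = (t, j) if compliance.kind == "current" else (t, k, j)
                groups.setdefault(key, []).append(((t, k, j), f))

    offending = []
    max_resid = 0.0
    for key, cells in groups.items():
        F = np.stack([f for _, f in cells])
        centre = F.mean(axis=0)
        resid = np.abs(F - centre).max(axis=1)
        scale = 1.0 + np.abs(centre).max()
        max_resid = max(max_resid, float(resid.max() / scale))
        for (cell, _), r in zip(cells, resid):
            if r / scale > rtol:
                offending.append(cell)
    return NestingReport(
        ok=not offending,
        offending=sorted(offending),
        max_residual=max_resid,
        core=core.kind,
        compliance=compliance.kind,
    )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Stacked per patient-visit design.

    ``X`` has shape (N, J, P) and ``offset`` (N, J); the fitted mean of cell
    (i, j) is ``X[i, j] @ beta + offset[i, j]``.  ``labels`` names every
    column; ``is_deviation`` flags the compliance-deviation block.
    ``deviation_groups`` maps each deviation column to its prior-correlation
    group (same (t, k) for historic, same t for current) and its visit, so
    adjacent-visit prior correlation can be applied.  ``never_observed``
    lists deviation columns with no observed outcome behind them (their
    posterior will equal their prior).
    """

    X: np.ndarray
    offset: np.ndarray
    labels: list
    is_deviation: np.ndarray
    deviation_groups: list
    never_observed: list
    rank_report: dict
    core: CoreModelSpec
    compliance: ComplianceSpec | None
    n_visits: int

    @property
    def n_params(self) -> int:
        return self.X.shape[2]

    def mu_index(self, t: int, j: int) -> int:
        return t * self.n_visits + (j - 1)


def build_design(
    data: TrialData,
    core,
    compliance="historic",
    baseline: str = "visit_trt",
    include_deviation: bool = True,
    check: bool = True,
    raw_compliance: bool = False,
) -> DesignMatrices:
    """Assemble the extended-model design (core + deviation + baseline).

    ``include_deviation=False`` structurally pins the deviation coefficients
    at zero (the classic reference-based limit).  ``raw_compliance=True``
    builds the *uncentred* compliance model instead: off-treatment cells get
    zero core weight and the deviation columns carry the full off-treatment
    means (used by the pure-compliance comparator with diffuse priors).

    Rank deficiency of the observed-data design is reported, not fatal —
    never-occurring deviation cells are kept on purpose.
    """
    core = _as_core(core)
    compliance = _as_compliance(compliance) if include_deviation else None
    N, J = data.y.shape
    if check and compliance is not None and not raw_compliance:
        rep = check_nesting(core, compliance, J)
        if not rep:
            raise NestingError(
                f"core {core.kind} is not nested in the {compliance.kind} "
                f"compliance model (offending cells: {rep.offending[:6]}...)"
            )

    pats = derive_patterns(data, core)
    blocks = [pats.mu_weights]
    offset = pats.offset.copy()
    labels: list = [("mu", t, j) for t in (0, 1) for j in range(1, J + 1)]

    if raw_compliance:
        # uncentred compliance model: off-treatment cells carry no core mean
        off = data.off_treatment_mask()
        blocks[0] = np.where(off[:, :, None], 0.0, pats.mu_weights)
        offset = np.where(off, 0.0, offset)

    if baseline not in ("visit_trt", "visit", "none"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if baseline == "visit_trt":
        B = np.zeros((N, J, 2 * J))
        for i in range(N):
            t = int(data.arm[i])
            for j in range(J):
                B[i, j, t * J + j] = data.baseline[i]
        blocks.append(B)
        labels += [("baseline", t, j) for t in (0, 1) for j in range(1, J + 1)]
    elif baseline == "visit":
        B = np.zeros((N, J, J))
        for i in range(N):
            for j in range(J):
                B[i, j, j] = data.baseline[i]
        blocks.append(B)
        labels += [("baseline", None, j) for j in range(1, J + 1)]

    dev_meta: list = []
    dev_groups: list = []
    if compliance is not None:
        if compliance.kind == "current":
            dev_meta = [("alpha*", t, None, j) for t in (0, 1) for j in range(2, J + 1)]
            dev_groups = [((t,), j) for t in (0, 1) for j in range(2, J + 1)]
        elif compliance.kind == "historic":
            dev_meta = [
                ("gamma*", t, k, j)
                for t in (0, 1)
                for k in range(1, J)
                for j in range(k + 1, J + 1)
            ]
            dev_groups = [((t, k), j) for _, t, k, j in dev_meta]
        else:  # full_pattern: subject-level pattern crossed with every visit
            dev_meta = [
                ("gamma*", t, k, j)
                for t in (0, 1)
                for k in range(1, J)
                for j in range(1, J + 1)
            ]
            dev_groups = [((t, k), j) for _, t, k, j in dev_meta]

        D = np.zeros((N, J, len(dev_meta)))
        off_t = pats.off_t
        for c, (_, t, k, j) in enumerate(dev_meta):
            sel = data.arm == t
            if compliance.kind == "current":
                D[sel, j - 1, c] = off_t[sel, j - 1]
            elif compliance.kind == "historic":
                sel = sel & (data.dev_visit == k)
                D[sel, j - 1, c] = off_t[sel, j - 1]
            else:  # full_pattern applies at all visits of the (t, k) deviators
                sel = sel & (data.dev_visit == k)
                D[sel, j - 1, c] = 1.0
        blocks.append(D)
        labels += dev_meta

    X = np.concatenate(blocks, axis=2)
    P = X.shape[2]
    is_dev = np.zeros(P, dtype=bool)
    if dev_meta:
        is_dev[P - len(dev_meta):] = True

    obs = data.observed_mask()
    Xobs = X[obs]  # (n_obs_cells, P)
    active = (Xobs != 0).any(axis=0)
    never_observed = [labels[c] for c in np.flatnonzero(~active & is_dev)]
    rank = int(np.linalg.matrix_rank(Xobs)) if Xobs.size else 0
    rank_report = {
        "n_params": P,
        "rank_observed": rank,
        "deficient": rank < P,
        "inactive_columns": [labels[c] for c in np.flatnonzero(~active)],
    }

    return DesignMatrices(
        X=X,
        offset=offset,
        labels=labels,
        is_deviation=is_dev,
        deviation_groups=dev_groups,
        never_observed=never_observed,
        rank_report=rank_report,
        core=core,
        compliance=compliance,
        n_visits=J,
    )


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Gaussian prior over the mean-model coefficients plus the
    inverse-Wishart prior for the residual covariance.

    Deviation coefficients get the mildly informative zero-centred variance
    ``v`` (with optional correlation between visit-adjacent deviations in
    the same (t, k) group); core coefficients get ``diffuse_variance`` —
    effectively flat yet proper, keeping the sampler conjugate.
    """

    mean: np.ndarray
    cov: np.ndarray
    is_deviation: np.ndarray
    v: float
    diffuse_variance: float
    adjacent_corr: float
    iw_df: float
    iw_scale: np.ndarray

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)


def default_prior_variance(data: TrialData, method: str = "mmrm_residual") -> float:
    """Default deviation-prior variance v from the on-treatment data.

    ``mmrm_residual`` (default): the (J, J) diagonal element of the
    unstructured residual covariance from a repeated-measures fit to
    on-treatment data only — one extra patient-visit worth of likelihood.
    ``range``: the square of one sixth of the observed final-visit range.
    """
    J = data.n_visits
    on_final = (data.dev_visit == J) & ~np.isnan(data.y[:, J - 1])
    vals = data.y[on_final, J - 1]
    if vals.size < 2:
        raise ValueError("fewer than 2 on-treatment final-visit observations")
    if method == "range":
        rng = float(vals.max() - vals.min())
        if rng == 0.0:
            warnings.warn(
                "degenerate input: constant final-visit outcome gives a zero "
                "range-based prior variance",
                RuntimeWarning,
            )
        return (rng / 6.0) ** 2
    if method == "mmrm_residual":
        from .engine import mmrm_reference_fit  # local import avoids a cycle

        fit = mmrm_reference_fit(data)
        return float(fit.sigma[J - 1, J - 1])
    raise ValueError(f"unknown method {method!r}")


def build_priors(
    design: DesignMatrices,
    v: float,
    diffuse_variance: float,
    adjacent_corr: float = 0.0,
    iw_df: float | None = None,
    iw_scale: np.ndarray | None = None,
) -> PriorSpec:
    """Assemble the coefficient prior: diffuse core, informative deviations.

    The deviation block is block-diagonal across (t, k) groups; within a
    group the prior has variance ``v`` on the diagonal and
    ``adjacent_corr * v`` between visit-adjacent deviation coefficients.
    """
    if v <= 0:
        raise ValueError("prior variance v must be positive")
    if not (0.0 <= adjacent_corr < 1.0):
        raise ValueError("adjacent_corr must lie in [0, 1)")
    P = design.n_params
    J = design.n_visits
    cov = np.zeros((P, P))
    core_idx = np.flatnonzero(~design.is_deviation)
    cov[core_idx, core_idx] = diffuse_variance
    dev_idx = np.flatnonzero(design.is_deviation)
    cov[dev_idx, dev_idx] = v
    if adjacent_corr > 0 and dev_idx.size:
        groups = design.deviation_groups
        for a in range(len(dev_idx)):
            for b in range(a + 1, len(dev_idx)):
                ga, ja = groups[a]
                gb, jb = groups[b]
                if ga == gb and abs(ja - jb) == 1:
                    cov[dev_idx[a], dev_idx[b]] = adjacent_corr * v
                    cov[dev_idx[b], dev_idx[a]] = adjacent_corr * v
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("prior covariance is not positive definite") from exc

    if iw_df is None:
        iw_df = J + 2  # weakest proper conjugate choice
    if iw_scale is None:
        iw_scale = np.eye(J)
    iw_scale = np.asarray(iw_scale, dtype=float)
    return PriorSpec(
        mean=np.zeros(P),
        cov=cov,
        is_deviation=design.is_deviation.copy(),
        v=float(v),
        diffuse_variance=float(diffuse_variance),
        adjacent_corr=float(adjacent_corr),
        iw_df=float(iw_df),
        iw_scale=iw_scale,
    )
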