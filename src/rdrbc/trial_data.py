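"""Longitudinal trial data with treatment-deviation bookkeeping.

The data model follows the standard treatment-policy setting: ``N`` patients
observed at ``J`` post-baseline visits (1-based), randomised to a reference
arm (coded 0) or an active arm (coded 1).  Each patient carries

* a baseline covariate (same scale as the outcome, e.g. baseline HAMD17),
* an outcome vector ``Y[1..J]`` (NaN = missing),
* a deviation visit ``D`` — the last visit on randomised treatment
  (``D = J`` for on-treatment completers), and
* a last study visit ``S`` — the last visit with any observation
  (``S = J`` for study completers).

Patients halt treatment when leaving the study, so ``S >= D``.  Outcomes at
visits ``D < j <= S`` are the *retrieved dropout* (off-treatment) values;
outcomes after ``S`` are missing.  Intermediate missing values at visits
``j <= S`` are permitted and are treated as MAR by the imputation engine.
Missingness after ``S`` must be monotone by construction.

Baseline is visit 0 and is stored as a covariate, never as an outcome row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "TrialData",
    "PatternVariables",
    "PatternSummary",
    "TrialDataError",
    "load_trial_csv",
    "write_trial_csv",
    "derive_patterns",
    "pattern_summary",
    "merge_observed_off_treatment",
]

DEFAULT_SCHEMA: Mapping[str, str] = {
    "subject": "subject",
    "arm": "arm",
    "visit": "visit",
    "outcome": "outcome",
    "baseline": "baseline",
    "off_treatment": "off_treatment",  # optional per-visit 0/1 flag
    "deviation_visit": "deviation_visit",  # optional per-subject D
    "last_study_visit": "last_study_visit",  # optional per-subject S
}


class TrialDataError(ValueError):
    """Raised on structurally invalid trial data."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's longitudinal record.

    ``outcomes`` has length ``J`` with NaN marking missing values;
    ``deviation_visit`` (D) and ``last_study_visit`` (S) satisfy S >= D.
    """

    subject_id: object
    arm: int
    baseline: float
    outcomes: np.ndarray
    deviation_visit: int
    last_study_visit: int

    @property
    def n_visits(self) -> int:
        return len(self.outcomes)


@dataclass
class TrialData:
    """Array-backed container for a two-arm longitudinal trial.

    Attributes
    ----------
    ids : (N,) array of subject identifiers
    arm : (N,) int array, 0 = reference, 1 = active
    baseline : (N,) float array
    y : (N, J) float array, NaN = missing
    dev_visit : (N,) int array of D values in 1..J
    last_visit : (N,) int array of S values in 1..J
    arm_labels : (reference label, active label)
    """

    ids: np.ndarray
    arm: np.ndarray
    baseline: np.ndarray
    y: np.ndarray
    dev_visit: np.ndarray
    last_visit: np.ndarray
    arm_labels: tuple = ("reference", "active")

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.arm = np.asarray(self.arm, dtype=int)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.dev_visit = np.asarray(self.dev_visit, dtype=int)
        self.last_visit = np.asarray(self.last_visit, dtype=int)
        self.arm_labels = tuple(self.arm_labels)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    def __len__(self) -> int:
        return self.n_patients

    @property
    def patients(self) -> Iterator[PatientRecord]:
        for i in range(self.n_patients):
            yield PatientRecord(
                subject_id=self.ids[i],
                arm=int(self.arm[i]),
                baseline=float(self.baseline[i]),
                outcomes=self.y[i].copy(),
                deviation_visit=int(self.dev_visit[i]),
                last_study_visit=int(self.last_visit[i]),
            )

    def copy(self) -> "TrialData":
        return TrialData(
            ids=self.ids.copy(),
            arm=self.arm.copy(),
            baseline=self.baseline.copy(),
            y=self.y.copy(),
            dev_visit=self.dev_visit.copy(),
            last_visit=self.last_visit.copy(),
            arm_labels=self.arm_labels,
        )

    def validate(self) -> None:
        n, J = self.y.shape
        if J < 2:
            raise TrialDataError(f"need at least 2 visits, got J={J}")
        for name in ("ids", "arm", "baseline", "dev_visit", "last_visit"):
            if len(getattr(self, name)) != n:
                raise TrialDataError(f"length mismatch in '{name}'")
        if not np.isin(self.arm, [0, 1]).all():
            raise TrialDataError("arm codes must be 0 (reference) or 1 (active)")
        if not ((self.arm == 0).any() and (self.arm == 1).any()):
            raise TrialDataError("both arms must be present")
        if ((self.dev_visit < 1) | (self.dev_visit > J)).any():
            raise TrialDataError("deviation visit outside 1..J")
        if ((self.last_visit < 1) | (self.last_visit > J)).any():
            raise TrialDataError("last study visit outside 1..J")
        bad = self.last_visit < self.dev_visit
        if bad.any():
            raise TrialDataError(
                f"S < D for subjects {list(self.ids[bad])}: patients halt "
                "treatment when leaving the study"
            )
        if np.isnan(self.baseline).any():
            raise TrialDataError("missing baseline values are not supported")
        # outcomes strictly after S must be missing (monotone after S)
        visits = np.arange(1, J + 1)
        after_s = visits[None, :] > self.last_visit[:, None]
        if (~np.isnan(self.y) & after_s).any():
            raise TrialDataError("observed outcome after last study visit S")

    # -- masks -------------------------------------------------------------
    def observed_mask(self) -> np.ndarray:
        """(N, J) boolean, True where the outcome was observed."""
        return ~np.isnan(self.y)

    def off_treatment_mask(self) -> np.ndarray:
        """(N, J) boolean, True at visits strictly after D."""
        visits = np.arange(1, self.n_visits + 1)
        return visits[None, :] > self.dev_visit[:, None]


@dataclass
class PatternVariables:
    """Per patient-visit covariates derived from (T, D, J) and a core model.

    ``off_t``        (N, J) 0/1 — on/off treatment indicator (1 iff j > D).
    ``pattern``      (N, J) int — current visit while on treatment, frozen at
                     D afterwards (non-decreasing, constant after deviation).
    ``j2r_factor``   (N, J) int arm level — as-randomised while on treatment,
                     the reference level (0) while off.
    ``mu_weights``   (N, J, 2J) — weights over the on-treatment mean
                     parameters mu[t, j] expressing each cell's core-implied
                     mean as a linear functional of mu (columns ordered
                     t-major: mu[0,1..J], mu[1,1..J]).  This generalises the
                     quantitative treatment-by-visit covariates needed for
                     history-dependent cores such as CIR or LMCF.
    ``offset``       (N, J) — fixed additive part of the core mean (nonzero
                     only for RTB and MAR+delta cores).
    """

    off_t: np.ndarray
    pattern: np.ndarray
    j2r_factor: np.ndarray
    mu_weights: np.ndarray | None = None
    offset: np.ndarray | None = None


@dataclass
class PatternSummary:
    """Stratum bookkeeping in the shape of the usual deviation-pattern tables.

    ``visit_status`` — per (arm, visit): counts of patients on treatment,
    observed off treatment, and missing off treatment; the three add up to
    the arm size at every visit.

    ``strata`` — one row per (arm, deviation visit, stop/continue) stratum
    with its patient count and the per-visit means of *observed* outcomes
    (NaN where a stratum has no observed value at a visit — empty, not zero).
    """

    visit_status: pd.DataFrame
    strata: pd.DataFrame
    n_per_arm: dict


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def load_trial_csv(
    path,
    schema: Mapping[str, str] | None = None,
    reference_arm: object | None = None,
    n_visits: int | None = None,
    outcome_is_change: bool = True,
) -> TrialData:
    """Read long-format trial data (one row per subject-visit).

    The CSV must contain subject, arm, visit, outcome (empty string =
    missing) and baseline columns; per-visit on/off flags and/or explicit
    per-subject D and S columns are optional.  D defaults to the last visit
    with off-flag 0 (or J when no flag column is present), S to the last
    visit with a non-missing outcome; explicit values win and are
    cross-checked against the observed pattern.

    With ``outcome_is_change=False`` the outcome column holds raw scores
    and the change from baseline is computed on load.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, dtype={sch["subject"]: str})
    data = trial_data_from_long(
        df, schema=sch, reference_arm=reference_arm, n_visits=n_visits
    )
    if not outcome_is_change:
        data.y = data.y - data.baseline[:, None]
    return data


def trial_data_from_long(
    df: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    reference_arm: object | None = None,
    n_visits: int | None = None,
) -> TrialData:
    """Build :class:`TrialData` from a long-format DataFrame (see loader)."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    for key in ("subject", "arm", "visit", "outcome", "baseline"):
        if sch[key] not in df.columns:
            raise TrialDataError(f"required column '{sch[key]}' not found")

    visits = df[sch["visit"]].astype(int)
    J = int(n_visits if n_visits is not None else visits.max())
    if ((visits < 1) | (visits > J)).any():
        raise TrialDataError(f"visit outside 1..{J}")
    if df.duplicated([sch["subject"], sch["visit"]]).any():
        raise TrialDataError("duplicate (subject, visit) rows")

    arm_values = pd.unique(df[sch["arm"]])
    if len(arm_values) != 2:
        raise TrialDataError(
            f"expected exactly 2 arm labels, found {list(arm_values)}"
        )
    if reference_arm is None:
        reference_arm = sorted(arm_values, key=str)[0]
    if reference_arm not in set(arm_values):
        raise TrialDataError(f"unknown arm label {reference_arm!r}")
    active_arm = next(a for a in arm_values if a != reference_arm)

    has_flag = sch["off_treatment"] in df.columns
    has_dev = sch["deviation_visit"] in df.columns
    has_last = sch["last_study_visit"] in df.columns

    ids, arm, base, dev, last = [], [], [], [], []
    y = []
    for sid, g in df.groupby(sch["subject"], sort=False):
        g = g.sort_values(sch["visit"])
        v = g[sch["visit"]].astype(int).to_numpy()
        row = np.full(J, np.nan)
        row[v - 1] = pd.to_numeric(g[sch["outcome"]], errors="coerce")
        a = g[sch["arm"]].iloc[0]
        if g[sch["arm"]].nunique() != 1:
            raise TrialDataError(f"subject {sid!r} appears in both arms")

        obs = np.flatnonzero(~np.isnan(row)) + 1
        s_derived = int(obs.max()) if obs.size else J

        if has_flag:
            flags = np.zeros(J)
            fv = pd.to_numeric(g[sch["off_treatment"]], errors="coerce").to_numpy()
            flags[v - 1] = np.where(np.isnan(fv), 0, fv)
            off_idx = np.flatnonzero(flags > 0) + 1
            if off_idx.size:
                d_derived = int(off_idx.min()) - 1
                if d_derived < 1:
                    raise TrialDataError(
                        f"subject {sid!r} flagged off-treatment at visit 1"
                    )
                if (flags[d_derived:] == 0)[: max(0, s_derived - d_derived)].any():
                    raise TrialDataError(
                        f"subject {sid!r}: off-treatment flag is not monotone"
                    )
            else:
                d_derived = J
        else:
            d_derived = J  # no flag information: on-treatment throughout

        d_final = d_derived
        if has_dev:
            d_explicit = int(g[sch["deviation_visit"]].iloc[0])
            if has_flag and d_explicit != d_derived:
                raise TrialDataError(
                    f"subject {sid!r}: explicit D={d_explicit} contradicts "
                    f"off-treatment flags (D={d_derived})"
                )
            d_final = d_explicit
        s_final = s_derived
        if has_last:
            s_explicit = int(g[sch["last_study_visit"]].iloc[0])
            if obs.size and s_explicit < obs.max():
                raise TrialDataError(
                    f"subject {sid!r}: outcome observed after explicit "
                    f"S={s_explicit}"
                )
            s_final = s_explicit

        ids.append(sid)
        arm.append(0 if a == reference_arm else 1)
        base.append(float(g[sch["baseline"]].iloc[0]))
        dev.append(d_final)
        last.append(s_final)
        y.append(row)

    return TrialData(
        ids=np.array(ids, dtype=object),
        arm=np.array(arm),
        baseline=np.array(base),
        y=np.array(y),
        dev_visit=np.array(dev),
        last_visit=np.array(last),
        arm_labels=(reference_arm, active_arm),
    )


def write_trial_csv(data: TrialData, path, schema: Mapping[str, str] | None = None) -> None:
    """Write long-format CSV in the reader's dialect (empty cell = missing)."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = to_long(data, schema=sch)
    df.to_csv(path, index=False)


def to_long(data: TrialData, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    off = data.off_treatment_mask().astype(int)
    rows = {
        sch["subject"]: np.repeat(data.ids, data.n_visits),
        sch["arm"]: np.repeat(
            np.asarray(data.arm_labels, dtype=object)[data.arm], data.n_visits
        ),
        sch["baseline"]: np.repeat(data.baseline, data.n_visits),
        sch["visit"]: np.tile(np.arange(1, data.n_visits + 1), data.n_patients),
        sch["outcome"]: data.y.ravel(),
        sch["off_treatment"]: off.ravel(),
        sch["deviation_visit"]: np.repeat(data.dev_visit, data.n_visits),
        sch["last_study_visit"]: np.repeat(data.last_visit, data.n_visits),
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pattern covariates and summaries
# ---------------------------------------------------------------------------

def derive_patterns(data: TrialData, core=None) -> PatternVariables:
    """Derive the per patient-visit covariates used by the mean models.

    ``off_t``, ``pattern`` and ``j2r_factor`` depend only on (T, D, J).
    When a core-model specification is supplied the core-implied mean of
    every cell is additionally expressed as weights over the on-treatment
    mean parameters mu[t, j] plus a fixed offset (the generalised
    treatment-by-visit covariates required by history-dependent cores).
    """
    N, J = data.y.shape
    visits = np.arange(1, J + 1)
    off_t = (visits[None, :] > data.dev_visit[:, None]).astype(int)
    pattern = np.minimum(visits[None, :], data.dev_visit[:, None])
    j2r_factor = np.where(off_t == 1, 0, data.arm[:, None])

    mu_weights = offset = None
    if core is not None:
        from .design import core_cell_functional  # local import avoids a cycle

        mu_weights = np.zeros((N, J, 2 * J))
        offset = np.zeros((N, J))
        for i in range(N):
            t, k = int(data.arm[i]), int(data.dev_visit[i])
            for j in range(1, J + 1):
                w, c = core_cell_functional(core, t, k, j, J, data=data)
                mu_weights[i, j - 1] = w
                offset[i, j - 1] = c
    return PatternVariables(
        off_t=off_t,
        pattern=pattern,
        j2r_factor=j2r_factor,
        mu_weights=mu_weights,
        offset=offset,
    )


def pattern_summary(data: TrialData) -> PatternSummary:
    """Tally strata and means the way deviation-pattern tables are laid out."""
    N, J = data.y.shape
    visits = np.arange(1, J + 1)
    obs = data.observed_mask()
    on = visits[None, :] <= data.dev_visit[:, None]
    off_obs = ~on & obs
    off_miss = ~on & ~obs

    ref_label, act_label = data.arm_labels
    labels = {0: ref_label, 1: act_label}
    status_rows = []
    n_per_arm = {}
    for t in (0, 1):
        sel = data.arm == t
        n_per_arm[labels[t]] = int(sel.sum())
        for j in range(J):
            status_rows.append(
                {
                    "arm": labels[t],
                    "visit": j + 1,
                    "on": int(on[sel, j].sum()),
                    "off_obs": int(off_obs[sel, j].sum()),
                    "off_miss": int(off_miss[sel, j].sum()),
                }
            )
    visit_status = pd.DataFrame(status_rows)

    strata_rows = []
    followup = np.where(data.last_visit == data.n_visits, "continue", "stop")
    # completers (D == J) always fall in the 'continue' column
    for t in (0, 1):
        for k in range(1, J + 1):
            for fu in ("stop", "continue"):
                sel = (data.arm == t) & (data.dev_visit == k) & (followup == fu)
                if k == J and fu == "stop":
                    continue  # completers cannot stop before the end
                count = int(sel.sum())
                row = {
                    "arm": labels[t],
                    "deviation_visit": k,
                    "followup": fu,
                    "count": count,
                }
                for j in range(J):
                    vals = data.y[sel, j]
                    vals = vals[~np.isnan(vals)]
                    row[f"mean_visit_{j + 1}"] = (
                        float(vals.mean()) if vals.size else np.nan
                    )
                strata_rows.append(row)
    strata = pd.DataFrame(strata_rows)
    return PatternSummary(visit_status=visit_status, strata=strata, n_per_arm=n_per_arm)


def merge_observed_off_treatment(imputed: np.ndarray, original: TrialData) -> np.ndarray:
    """Overwrite imputed cells with the originally observed values.

    ``imputed`` is a completed (N, J) outcome matrix; every cell observed in
    ``original`` carries its observed value in the result, so only
    originally-missing cells retain imputed values.
    """
    imputed = np.asarray(imputed, dtype=float)
    if imputed.shape != original.y.shape:
        raise TrialDataError(
            f"shape mismatch: imputed {imputed.shape} vs original {original.y.shape}"
        )
    if np.isnan(imputed).any():
        raise TrialDataError("imputed dataset still contains missing values")
    out = imputed.copy()
    obs = original.observed_mask()
    out[obs] = original.y[obs]
    return out
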