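"""Desk-scale observational cohort study emulator.

Implements the comparative-cohort design used to test whether a pediatric
beta-2 adrenergic (ADRB2) agonist exposure changes the rate of inpatient
visits associated with an adult schizophrenia diagnosis: cohort construction
from EHR-like event tables, outcome extraction with a diagnosis-lag rule,
a propensity model, stabilized inverse-probability weights, greedy caliper
matching, covariate balance diagnostics, and a from-scratch weighted Cox
proportional-hazards fitter (Breslow ties, Newton-Raphson, robust sandwich
variance under weighting).

All dates are fractional ages in years; calendar time is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import ConvergenceError, StudyInfeasibleError, ValidationError

DAYS_PER_YEAR = 365.25


@dataclass
class PatientTable:
    """EHR-like event tables keyed by ``person_id`` (ages in years).

    persons:   person_id, obs_start_age, obs_end_age
    exposures: person_id, concept_id, age
    diagnoses: person_id, concept_id, age
    visits:    person_id, visit_type ("inpatient"/"outpatient"), age
    covariates: person_id plus one column per covariate
    """

    persons: pd.DataFrame
    exposures: pd.DataFrame
    diagnoses: pd.DataFrame
    visits: pd.DataFrame
    covariates: pd.DataFrame

    _TABLES = ("persons", "exposures", "diagnoses", "visits", "covariates")

    def write_dir(self, directory) -> None:
        """Write the five tables as <name>.tsv under ``directory``."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def read_dir(cls, directory) -> "PatientTable":
        """Read the five <name>.tsv tables written by :meth:`write_dir`."""
        from pathlib import Path

        directory = Path(directory)
        return cls(
            **{
                name: pd.read_csv(
                    directory / f"{name}.tsv", sep="\t", dtype={"person_id": str}
                )
                for name in cls._TABLES
            }
        )


@dataclass
class CohortAssignment:
    """Target/comparator membership and per-patient index age."""

    arm: pd.Series          # person_id -> "target" | "comparator" | "excluded"
    index_age: pd.Series    # person_id -> index age (included patients only)

    @property
    def n_target(self) -> int:
        return int((self.arm == "target").sum())

    @property
    def n_comparator(self) -> int:
        return int((self.arm == "comparator").sum())


@dataclass(frozen=True)
class HazardEstimate:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    n_target: int
    n_comparator: int
    n_events: int
    method: str
    beta: tuple = ()
    n_iter: int = 0


@dataclass
class PropensityResult:
    scores: pd.Series
    coefficients: pd.Series
    auc: float


def read_concept_list(path) -> frozenset:
    """One-concept-id-per-line text file to a concept set."""
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def build_cohorts(
    patients: PatientTable,
    exposure_concepts,
    disease_concepts,
    exposure_age_range: tuple = (6.0, 18.0),
    diagnosis_age_min: float = 18.0,
) -> CohortAssignment:
    """Assign each patient to target / comparator / excluded.

    Target: >= 1 exposure-concept record at an age in the closed interval
    ``exposure_age_range`` AND >= 1 disease-concept diagnosis at age strictly
    above ``diagnosis_age_min``.  Comparator: the adult diagnosis and NO
    pediatric exposure.  Everyone else is excluded.  The index age is the
    first qualifying adult diagnosis.
    """
    exposure_concepts, disease_concepts = set(exposure_concepts), set(disease_concepts)
    if not exposure_concepts or not disease_concepts:
        raise ValidationError("exposure and disease concept sets must be nonempty")
    lo, hi = exposure_age_range

    exp = patients.exposures
    ped = exp[
        exp["concept_id"].isin(exposure_concepts)
        & (exp["age"] >= lo)
        & (exp["age"] <= hi)
    ]
    exposed_ids = set(ped["person_id"])

    dx = patients.diagnoses
    adult = dx[dx["concept_id"].isin(disease_concepts) & (dx["age"] > diagnosis_age_min)]
    index = adult.groupby("person_id")["age"].min()

    arm = {}
    for pid in patients.persons["person_id"]:
        if pid not in index.index:
            arm[pid] = "excluded"
        elif pid in exposed_ids:
            arm[pid] = "target"
        else:
            arm[pid] = "comparator"
    arm = pd.Series(arm, name="arm")
    n_t, n_c = int((arm == "target").sum()), int((arm == "comparator").sum())
    if n_t == 0 or n_c == 0:
        raise StudyInfeasibleError(
            f"empty arm after cohort construction (target={n_t}, comparator={n_c})"
        )
    included = arm[arm != "excluded"].index
    return CohortAssignment(arm=arm, index_age=index.loc[included].rename("index_age"))


def extract_outcomes(
    patients: PatientTable,
    assignment: CohortAssignment,
    disease_concepts,
    lag_days: float = 3.0,
) -> pd.DataFrame:
    """Reduce event tables to survival rows (time, event, exposure, covariates).

    The outcome is the first inpatient visit after index with a disease
    diagnosis dated within [visit age, visit age + lag_days] (diagnoses are
    often logged a few days after the visit for billing).  Patients without a
    qualifying visit are censored at the end of their observation window.
    Rows with non-positive time-at-risk are dropped; the count of dropped
    rows is in ``.attrs["n_dropped_nonpositive_time"]``.
    """
    disease_concepts = set(disease_concepts)
    lag = lag_days / DAYS_PER_YEAR
    included = assignment.arm[assignment.arm != "excluded"].index

    dx = patients.diagnoses[patients.diagnoses["concept_id"].isin(disease_concepts)]
    dx_by_person = {pid: grp["age"].to_numpy() for pid, grp in dx.groupby("person_id")}
    inpat = patients.visits[patients.visits["visit_type"] == "inpatient"]
    visits_by_person = {
        pid: np.sort(grp["age"].to_numpy()) for pid, grp in inpat.groupby("person_id")
    }
    obs_end = patients.persons.set_index("person_id")["obs_end_age"]
    covs = patients.covariates.set_index("person_id")

    rows, dropped = [], 0
    for pid in included:
        idx = float(assignment.index_age.loc[pid])
        ages_dx = dx_by_person.get(pid, np.empty(0))
        event_age = np.inf
        for v in visits_by_person.get(pid, ()):  # sorted ascending
            if v <= idx:
                continue
            near = ages_dx[(ages_dx >= v) & (ages_dx <= v + lag)]
            if near.size:
                event_age = v
                break
        if np.isfinite(event_age):
            time, event = event_age - idx, True
        else:
            time, event = float(obs_end.loc[pid]) - idx, False
        if time <= 0:
            dropped += 1
            continue
        rows.append(
            {
                "person_id": pid,
                "time": time,
                "event": event,
                "exposure": int(assignment.arm.loc[pid] == "target"),
                "weight": 1.0,
                **covs.loc[pid].to_dict(),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped_nonpositive_time"] = dropped
    return out


def covariate_columns(rows: pd.DataFrame) -> list:
    """Covariate column names of a survival-row table."""
    reserved = {"person_id", "time", "event", "exposure", "weight"}
    return [c for c in rows.columns if c not in reserved]


def fit_propensity(rows: pd.DataFrame, C: float = 1.0) -> PropensityResult:
    """Regularized logistic regression of exposure on the covariates.

    Scores are clipped away from {0, 1}; the AUC is the Mann-Whitney rank
    statistic of score against exposure.
    """
    cols = covariate_columns(rows)
    if not cols:
        raise ValidationError("no covariate columns found")
    y = rows["exposure"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValidationError("exposure is constant; propensity model unidentifiable")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValidationError("need >= 2 patients in each exposure arm")
    x = rows[cols].to_numpy(dtype=float)
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    model.fit(x, y)
    scores = np.clip(model.predict_proba(x)[:, 1], 1e-6, 1.0 - 1e-6)
    return PropensityResult(
        scores=pd.Series(scores, index=rows.index, name="propensity"),
        coefficients=pd.Series(model.coef_.ravel(), index=cols),
        auc=float(roc_auc_score(y, scores)),
    )


def ipw_weights(
    scores, exposure, scheme: str = "ate", truncate_percentile: float = 99.0
) -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights.

    ATE (default): exposed get P(exposed)/score, unexposed
    (1-P(exposed))/(1-score).  ATT: exposed get 1, unexposed
    score(1-P)/((1-score)P) — kept for the alternative estimand.  Weights are
    truncated at the given upper percentile to bound the influence of extreme
    scores.
    """
    s = np.asarray(scores, dtype=float)
    z = np.asarray(exposure, dtype=int)
    if np.any((s <= 0) | (s >= 1)):
        raise ValidationError("propensity scores must lie strictly inside (0, 1)")
    prev = z.mean()
    if scheme == "ate":
        w = np.where(z == 1, prev / s, (1.0 - prev) / (1.0 - s))
    elif scheme == "att":
        w = np.where(z == 1, 1.0, s / (1.0 - s) * (1.0 - prev) / prev)
    else:
        raise ValidationError(f"unknown weighting scheme: {scheme!r}")
    if truncate_percentile is not None:
        w = np.minimum(w, np.percentile(w, truncate_percentile))
    return w


@dataclass
class MatchResult:
    """Variable-ratio matched sample.

    ``indices`` are positional row indices of the matched sample (targets and
    their comparators); ``weights`` align with ``indices`` and carry the
    standard match weights — 1 for targets, 1/ratio for each comparator of a
    matched set — so that the weighted comparator covariate distribution
    mirrors the matched-target distribution.
    """

    indices: np.ndarray
    weights: np.ndarray
    n_unmatched_targets: int
    ratios: dict = field(default_factory=dict)  # target index -> n comparators


def match_cohorts(
    scores,
    exposure,
    caliper_sd: float = 0.2,
    max_ratio: int = 20,
) -> MatchResult:
    """Greedy variable-ratio nearest-neighbor matching on the logit score.

    Caliper = ``caliper_sd`` x SD of all logit scores; matching is without
    replacement, up to ``max_ratio`` comparators per target.  Comparators are
    allocated in round-robin rounds (every target receives its nearest free
    comparator within the caliper before any target receives a second one),
    with targets processed in descending score order within each round, so
    scarce high-score comparators are not exhausted by a few targets.
    Targets with no comparator in the caliper are dropped and counted.
    """
    s = np.asarray(scores, dtype=float)
    z = np.asarray(exposure, dtype=int)
    lg = logit(np.clip(s, 1e-12, 1 - 1e-12))
    caliper = caliper_sd * float(np.std(lg))
    t_idx = np.flatnonzero(z == 1)
    c_idx = np.flatnonzero(z == 0)
    if t_idx.size == 0 or c_idx.size == 0:
        raise StudyInfeasibleError("both arms must be nonempty for matching")

    order = t_idx[np.argsort(-s[t_idx], kind="stable")]
    comp_sorted = c_idx[np.argsort(lg[c_idx], kind="stable")]
    comp_lg = lg[comp_sorted]
    used = np.zeros(comp_sorted.size, dtype=bool)

    taken: dict = {t: [] for t in order}
    active = list(order)
    for _ in range(max_ratio):
        still_active = []
        for t in active:
            j = _nearest_free(comp_lg, used, lg[t])
            if j is None or abs(comp_lg[j] - lg[t]) > caliper:
                continue
            used[j] = True
            taken[t].append(comp_sorted[j])
            still_active.append(t)
        if not still_active:
            break
        active = still_active

    indices, weights, ratios = [], [], {}
    n_unmatched = 0
    for t in order:
        if not taken[t]:
            n_unmatched += 1
            continue
        k = len(taken[t])
        ratios[int(t)] = k
        indices.append(t)
        weights.append(1.0)
        indices.extend(taken[t])
        weights.extend([1.0 / k] * k)
    if not indices:
        raise StudyInfeasibleError("no target could be matched within the caliper")
    ordering = np.argsort(indices, kind="stable")
    return MatchResult(
        indices=np.asarray(indices)[ordering],
        weights=np.asarray(weights)[ordering],
        n_unmatched_targets=n_unmatched,
        ratios=ratios,
    )


def _nearest_free(sorted_vals: np.ndarray, used: np.ndarray, x: float):
    """Index (into sorted_vals) of the nearest unused value, else None."""
    n = sorted_vals.size
    j = int(np.searchsorted(sorted_vals, x))
    left, right = j - 1, j
    while left >= 0 and used[left]:
        left -= 1
    while right < n and used[right]:
        right += 1
    if left < 0 and right >= n:
        return None
    if left < 0:
        return right
    if right >= n:
        return left
    return left if abs(sorted_vals[left] - x) <= abs(sorted_vals[right] - x) else right


# ---------------------------------------------------------------------------
# Cox proportional hazards: weighted partial likelihood, Breslow ties
# ---------------------------------------------------------------------------


def _cox_sums(times, events, x, w, beta):
    """Log-likelihood, gradient and information of the weighted Breslow
    partial likelihood, plus per-event-time quantities for residuals.

    Risk sets are formed by descending-time cumulative sums; tied times share
    one risk set (Breslow).
    """
    eta = x @ beta
    r = w * np.exp(eta)
    rx = r[:, None] * x
    rxx = np.einsum("i,ij,ik->ijk", r, x, x)

    # descending time order; cumsum gives risk-set sums at each position
    desc = np.argsort(-times, kind="stable")
    s0_d = np.cumsum(r[desc])
    s1_d = np.cumsum(rx[desc], axis=0)
    s2_d = np.cumsum(rxx[desc], axis=0)
    t_desc = times[desc]

    ev_times = np.unique(times[events])          # ascending
    # position of the last index in desc with time >= each event time
    pos = t_desc.size - 1 - np.searchsorted(t_desc[::-1], ev_times, side="left")
    s0 = s0_d[pos]
    s1 = s1_d[pos]
    s2 = s2_d[pos]

    # weighted event count and covariate sum at each event time
    et_index = np.searchsorted(ev_times, times)
    d_k = np.zeros(ev_times.size)
    dx_k = np.zeros((ev_times.size, x.shape[1]))
    np.add.at(d_k, et_index[events], w[events])
    np.add.at(dx_k, et_index[events], (w[:, None] * x)[events])
    deta_k = np.zeros(ev_times.size)
    np.add.at(deta_k, et_index[events], (w * eta)[events])

    loglik = float(np.sum(deta_k - d_k * np.log(s0)))
    xbar = s1 / s0[:, None]
    grad = (dx_k - d_k[:, None] * xbar).sum(axis=0)
    info = np.einsum(
        "k,kij->ij", d_k, s2 / s0[:, None, None]
    ) - np.einsum("k,ki,kj->ij", d_k, xbar, xbar)
    return loglik, grad, info, ev_times, s0, xbar, d_k


def cox_partial_loglik(times, events, x, w, beta) -> float:
    """Weighted Breslow partial log-likelihood at ``beta`` (oracle-friendly)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.atleast_2d(np.asarray(x, float).T).T
    w = np.ones(times.size) if w is None else np.asarray(w, float)
    beta = np.atleast_1d(np.asarray(beta, float))
    return _cox_sums(times, events, x, w, beta)[0]


def _score_residuals(times, events, x, w, beta, ev_times, s0, xbar, d_k):
    """Per-subject score residuals for the sandwich variance."""
    eta = x @ beta
    dlam = d_k / s0
    cum_dlam = np.concatenate([[0.0], np.cumsum(dlam)])
    cum_xbar_dlam = np.vstack(
        [np.zeros((1, x.shape[1])), np.cumsum(xbar * dlam[:, None], axis=0)]
    )
    k_i = np.searchsorted(ev_times, times, side="right")
    own = np.zeros_like(x)
    ev_pos = np.searchsorted(ev_times, times[events])
    own[events] = x[events] - xbar[ev_pos]
    u = own - np.exp(eta)[:, None] * (
        x * cum_dlam[k_i][:, None] - cum_xbar_dlam[k_i]
    )
    return u


def fit_cox(
    rows: pd.DataFrame,
    covariates: list | None = None,
    weights=None,
    method: str = "unadjusted",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HazardEstimate:
    """Weighted Cox regression of the outcome on exposure.

    Maximizes the Breslow partial likelihood by Newton-Raphson until the
    gradient norm drops below ``tol``.  The exposure coefficient comes first;
    extra covariates may be adjusted for via ``covariates``.  The confidence
    interval uses a robust (sandwich) variance whenever any weight differs
    from 1, and the model-based inverse information otherwise.
    """
    times = rows["time"].to_numpy(dtype=float)
    events = rows["event"].to_numpy(dtype=bool)
    z = rows["exposure"].to_numpy(dtype=float)
    if weights is None:
        w = rows["weight"].to_numpy(dtype=float) if "weight" in rows else np.ones(len(rows))
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    if np.any(times <= 0):
        raise ValidationError("times must be positive")
    n_ev_t = int(events[z == 1].sum())
    n_ev_c = int(events[z == 0].sum())
    if n_ev_t == 0 or n_ev_c == 0:
        raise StudyInfeasibleError(
            "monotone likelihood: an arm has no events; the hazard-ratio "
            f"estimate is infinite (events: target={n_ev_t}, comparator={n_ev_c})"
        )

    cols = [z]
    for c in covariates or []:
        cols.append(rows[c].to_numpy(dtype=float))
    x = np.column_stack(cols)

    beta = np.zeros(x.shape[1])
    trace = []
    for it in range(1, max_iter + 1):
        loglik, grad, info, ev_times, s0, xbar, d_k = _cox_sums(
            times, events, x, w, beta
        )
        trace.append((it, loglik, float(np.linalg.norm(grad))))
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(info, grad)
        # halve overshooting steps; keeps Newton stable far from the optimum
        while np.max(np.abs(step)) > 5.0:
            step = step / 2.0
        beta = beta + step
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations",
            trace=trace,
        )

    robust = not np.allclose(w, 1.0)
    if robust:
        u = _score_residuals(times, events, x, w, beta, ev_times, s0, xbar, d_k)
        uw = u * w[:, None]
        ainv = np.linalg.inv(info)
        cov = ainv @ (uw.T @ uw) @ ainv
    else:
        cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[0, 0]))
    zcrit = float(norm.ppf(0.975))
    b0 = float(beta[0])
    return HazardEstimate(
        hr=float(np.exp(b0)),
        ci_low=float(np.exp(b0 - zcrit * se)),
        ci_high=float(np.exp(b0 + zcrit * se)),
        log_hr_se=se,
        n_target=int((z == 1).sum()),
        n_comparator=int((z == 0).sum()),
        n_events=int(events.sum()),
        method=method,
        beta=tuple(float(b) for b in beta),
        n_iter=it,
    )


def covariate_balance(
    rows: pd.DataFrame, weights=None, covariates: list | None = None
) -> pd.DataFrame:
    """Standardized mean differences before and after adjustment.

    SMD = (mean_T - mean_C) / pooled SD, where the pooled SD is the
    unweighted root-mean of the two arm variances; the "after" column uses
    the supplied weights for the means and variances.  Constant covariates
    report SMD 0.
    """
    cols = covariates or covariate_columns(rows)
    if not cols:
        raise ValidationError("no covariates for balance table")
    z = rows["exposure"].to_numpy(dtype=int)
    w = np.ones(len(rows)) if weights is None else np.asarray(weights, dtype=float)

    def _smd(v, wt):
        out = []
        for arm in (1, 0):
            m = z == arm
            ww = wt[m]
            mu = np.average(v[m], weights=ww)
            var = np.average((v[m] - mu) ** 2, weights=ww)
            out.append((mu, var))
        (mu_t, var_t), (mu_c, var_c) = out
        pooled = np.sqrt((var_t + var_c) / 2.0)
        return 0.0 if pooled == 0 else (mu_t - mu_c) / pooled

    recs = []
    for c in cols:
        v = rows[c].to_numpy(dtype=float)
        recs.append(
            {
                "covariate": c,
                "smd_before": float(_smd(v, np.ones(len(rows)))),
                "smd_after": float(_smd(v, w)),
            }
        )
    return pd.DataFrame(recs)


def study_report(
    rows: pd.DataFrame,
    design: str = "both",
    caliper_sd: float = 0.2,
    max_ratio: int = 20,
) -> dict:
    """Run the full desk-scale study on survival rows and report estimates.

    Fits the propensity model, then the requested designs: "ipw" (stabilized
    ATE weights, robust-variance Cox), "matched" (greedy caliper matching,
    unweighted Cox on the matched subset) or "both".  The crude (unadjusted)
    estimate and the balance table are always included — the machine analogue
    of a published hazard-ratio table plus attrition counts.
    """
    if design not in ("ipw", "matched", "both"):
        raise ValidationError(f"unknown design: {design!r}")
    prop = fit_propensity(rows)
    crude = fit_cox(rows, method="crude")
    report = {
        "propensity_auc": prop.auc,
        "crude": _estimate_dict(crude),
        "estimates": {},
        "balance": {},
        "attrition": {
            "n_rows": int(len(rows)),
            "n_target": int(rows["exposure"].sum()),
            "n_comparator": int((1 - rows["exposure"]).sum()),
        },
    }
    if design in ("ipw", "both"):
        w = ipw_weights(prop.scores.to_numpy(), rows["exposure"].to_numpy())
        est = fit_cox(rows, weights=w, method="IPW")
        report["estimates"]["IPW"] = _estimate_dict(est)
        report["balance"]["IPW"] = covariate_balance(rows, w).to_dict("records")
    if design in ("matched", "both"):
        match = match_cohorts(
            prop.scores.to_numpy(), rows["exposure"].to_numpy(),
            caliper_sd=caliper_sd, max_ratio=max_ratio,
        )
        sub = rows.iloc[match.indices]
        est = fit_cox(sub, weights=match.weights, method="matched")
        report["estimates"]["matched"] = _estimate_dict(est)
        report["balance"]["matched"] = covariate_balance(
            sub, match.weights
        ).to_dict("records")
        report["attrition"]["n_unmatched_targets"] = int(match.n_unmatched_targets)
        report["attrition"]["n_matched_rows"] = int(len(sub))
    return report


def _estimate_dict(est: HazardEstimate) -> dict:
    return {
        "hr": est.hr,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_target": est.n_target,
        "n_comparator": est.n_comparator,
        "n_events": est.n_events,
        "method": est.method,
    }
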