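"""Follow-up construction, PRS quantile groups, and Cox proportional-hazards
association models.

Mirrors the prospective-cohort analysis: follow-up runs from recruitment to
the first of site-specific cancer, death, or the administrative date, capped
at 20 years; subjects are ranked into PRS quintiles with the middle quintile
as reference; hazard ratios come from Cox models on time since recruitment
with Efron tie handling, adjusted for age at recruitment (and, for the
per-SD model, the full lifestyle covariate set); trend uses a two-sided Wald
test on the ordinal group code and the proportional-hazards assumption is
checked with the Grambsch-Therneau score test on scaled Schoenfeld
residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "FollowUp",
    "QuantileAssignment",
    "CoxFit",
    "HRTable",
    "compute_followup",
    "assign_quantile_groups",
    "fit_cox",
    "trend_test",
    "ph_check",
    "hr_table",
    "per_sd_model",
]

log = logging.getLogger(__name__)

#: default covariate schema of the fully adjusted per-SD model
ADJUSTMENT_COVARIATES = (
    "age_at_recruitment", "dialect", "education", "bmi", "smoking",
    "alcohol", "moderate_pa", "vigorous_pa", "family_history",
)


@dataclass
class FollowUp:
    time: np.ndarray  # years since recruitment, capped
    event: np.ndarray  # 1 = site-specific cancer before cap, else 0


@dataclass
class QuantileAssignment:
    group: np.ndarray  # 1..K
    n_groups: int
    reference_group: int


@dataclass
class CoxFit:
    coef: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_events: int
    diverged: bool = False
    model: object = field(default=None, repr=False)  # fitted lifelines object

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.diag(self.cov.values))
        return pd.DataFrame({
            "hr": np.exp(self.coef.values),
            "ci_low": np.exp(self.coef.values - zq * se),
            "ci_high": np.exp(self.coef.values + zq * se),
            "p": 2 * stats.norm.sf(np.abs(self.coef.values / se)),
        }, index=self.coef.index)


@dataclass
class HRTable:
    groups: pd.DataFrame  # one row per group: n, n_cases, hr, ci_low, ci_high
    reference_group: int
    p_trend: float
    ph_test_p: float
    per_sd: pd.DataFrame | None = None  # per-SD model hazard-ratio rows


def compute_followup(
    cohort: pd.DataFrame, cap_years: float = 20.0
) -> FollowUp:
    """Follow-up time and event indicator for the cancer endpoint.

    Death and the administrative end are censorings; anything after the
    cap (including cancers) is censored at the cap.
    """
    time = cohort["time"].to_numpy(dtype=float)
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    capped = np.minimum(time, cap_years)
    event = ((cohort["event"].to_numpy() == "cancer") & (time <= cap_years)).astype(int)
    return FollowUp(time=capped, event=event)


def assign_quantile_groups(z: np.ndarray, K: int = 5) -> QuantileAssignment:
    """Rank subjects into K near-equal groups (quintiles by default).

    Boundary ties are resolved by stable rank order so group sizes differ
    by at most one; the middle group — (K+1)//2, i.e. the 40-60% band for
    K=5 — is the reference, representing average population risk.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < K:
        raise ValueError(f"need at least K={K} samples")
    if np.unique(z).size < K:
        raise ValueError(f"fewer than K={K} distinct score values")
    order = np.argsort(z, kind="stable")
    group = np.empty(n, dtype=int)
    # split positions into K contiguous blocks of near-equal size
    edges = np.linspace(0, n, K + 1).round().astype(int)
    for k in range(K):
        group[order[edges[k]:edges[k + 1]]] = k + 1
    boundary_vals = z[order][edges[1:-1] - 1]
    if np.any(boundary_vals == z[order][np.minimum(edges[1:-1], n - 1)]):
        log.info("ties cross a quantile cut-point; stable order used")
    return QuantileAssignment(group=group, n_groups=K, reference_group=(K + 1) // 2)


def _check_covariates(covariates: pd.DataFrame) -> None:
    for c in covariates.columns:
        if covariates[c].nunique(dropna=False) <= 1:
            raise ValueError(f"constant covariate {c!r}: model not identifiable")


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
) -> CoxFit:
    """Maximum partial likelihood Cox fit (Efron ties), Wald covariance.

    A monotone-likelihood (divergent) fit is returned with its capped
    estimate and flagged rather than raised.
    """
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events; cannot fit a Cox model")
    _check_covariates(covariates)
    df = covariates.copy().reset_index(drop=True)
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = event
    cph = CoxPHFitter()
    diverged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        cph.fit(df, duration_col="_time", event_col="_event")
        diverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if diverged:
        log.warning("possible monotone likelihood: estimates may be capped")
    return CoxFit(
        coef=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        loglik=float(cph.log_likelihood_),
        n_events=int(event.sum()),
        diverged=diverged,
        model=cph,
    )


def trend_test(
    groups: np.ndarray,
    followup: FollowUp,
    age: np.ndarray,
) -> float:
    """Two-sided Wald p for an ordinal (1..K) group score, age-adjusted."""
    groups = np.asarray(groups, dtype=float)
    populated = np.unique(groups[followup.event == 1])
    if populated.size < 2:
        raise ValueError("trend test needs events in at least 2 groups")
    fit = fit_cox(
        followup.time, followup.event,
        pd.DataFrame({"group_ordinal": groups, "age": np.asarray(age, float)}),
    )
    se = np.sqrt(fit.cov.loc["group_ordinal", "group_ordinal"])
    zstat = fit.coef["group_ordinal"] / se
    return float(2 * stats.norm.sf(abs(zstat)))


def ph_check(
    fit: CoxFit,
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    time_transform: str = "identity",
) -> pd.Series:
    """Proportional-hazards score test on scaled Schoenfeld residuals,
    against a transform of time (identity by default). Returns the
    per-covariate p-values."""
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events; proportional-hazards test undefined")
    if fit.model is None:
        raise ValueError("CoxFit carries no fitted model object")
    df = covariates.copy().reset_index(drop=True)
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = event
    res = proportional_hazard_test(fit.model, df, time_transform=time_transform)
    p = res.summary["p"]
    p.index = res.summary.index.get_level_values(0)
    return p


def hr_table(
    z: np.ndarray,
    followup: FollowUp,
    age: np.ndarray,
    K: int = 5,
) -> HRTable:
    """Hazard ratios by PRS quantile group, middle group as referent.

    Cox model with K-1 group indicators plus age at recruitment; per-group
    HR with 95% CI and case counts, the ordinal trend p, and the PH score
    test p for the group indicators (minimum across indicators).
    A group with zero events yields a divergence-flagged fit, not an error.
    """
    qa = assign_quantile_groups(z, K)
    age = np.asarray(age, dtype=float)
    ref = qa.reference_group
    design = pd.DataFrame({"age": age})
    labels = []
    for k in range(1, K + 1):
        if k == ref:
            continue
        col = f"Q{k}"
        design[col] = (qa.group == k).astype(float)
        labels.append(col)
    fit = fit_cox(followup.time, followup.event, design)

    zq = stats.norm.ppf(0.975)
    rows = []
    for k in range(1, K + 1):
        n_k = int(np.sum(qa.group == k))
        cases_k = int(np.sum((qa.group == k) & (followup.event == 1)))
        if k == ref:
            rows.append({"group": k, "n": n_k, "n_cases": cases_k,
                         "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                         "diverged": False})
        else:
            b = fit.coef[f"Q{k}"]
            se = np.sqrt(fit.cov.loc[f"Q{k}", f"Q{k}"])
            with np.errstate(over="ignore"):  # divergent groups: inf CI is meaningful
                rows.append({
                    "group": k, "n": n_k, "n_cases": cases_k,
                    "hr": float(np.exp(b)),
                    "ci_low": float(np.exp(b - zq * se)),
                    "ci_high": float(np.exp(b + zq * se)),
                    "diverged": bool(fit.diverged and cases_k == 0),
                })
    p_trend = trend_test(qa.group, followup, age)
    ph_p = ph_check(fit, followup.time, followup.event, design)
    ph_group_p = float(ph_p[labels].min())
    return HRTable(
        groups=pd.DataFrame(rows),
        reference_group=ref,
        p_trend=p_trend,
        ph_test_p=ph_group_p,
    )


def _encode_covariates(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Dummy-code categorical covariates (first level as reference),
    pass numeric ones through."""
    parts = []
    for c in columns:
        col = cohort[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(col.astype("category"), prefix=c,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1).reset_index(drop=True)


def per_sd_model(
    z: np.ndarray,
    followup: FollowUp,
    cohort: pd.DataFrame,
    covariates=ADJUSTMENT_COVARIATES,
) -> CoxFit:
    """Fully adjusted per-SD Cox model: hazard ratio per SD increase in the
    standardized PRS, adjusted for age and the lifestyle covariate schema
    (those columns present in the cohort table)."""
    present = [c for c in covariates if c in cohort.columns]
    design = _encode_covariates(cohort, present)
    design.insert(0, "prs_per_sd", np.asarray(z, dtype=float))
    return fit_cox(followup.time, followup.event, design)
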