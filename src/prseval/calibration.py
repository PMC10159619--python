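"""Calibration of predicted 5-year absolute risks within PRS deciles.

Expected (mean model-predicted 5-year risk) and observed (proportion with
the cancer within 5 years) are compared per PRS decile; overall calibration
is summarized by the ordinary-least-squares slope of the 10 observed-on-
expected points — slope above 1 means the model underestimates absolute
risk, below 1 that it overestimates — and by a Hosmer-Lemeshow chi-square
statistic. Subjects who die cancer-free within the window stay in the
denominator, consistent with a competing-risk predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import FollowUp

__all__ = [
    "CalibrationReport",
    "decile_expected_observed",
    "calibration_slope",
    "hosmer_lemeshow",
    "calibrate",
]

log = logging.getLogger(__name__)


@dataclass
class CalibrationReport:
    table: pd.DataFrame  # per decile: n, expected, observed, observed_count
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    hl_stat: float
    hl_df: int
    hl_p: float

    def to_dict(self) -> dict:
        return {
            "deciles": self.table.to_dict(orient="records"),
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "hl_stat": self.hl_stat,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
        }


def decile_expected_observed(
    z: np.ndarray,
    followup: FollowUp,
    predicted_risk: np.ndarray,
    horizon: float = 5.0,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Per-PRS-decile sample size, mean predicted risk, and observed
    5-year event proportion (deaths stay in the denominator)."""
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} subjects")
    predicted_risk = np.asarray(predicted_risk, dtype=float)
    observed_event = (followup.event == 1) & (followup.time < horizon)

    order = np.argsort(z, kind="stable")
    edges = np.linspace(0, n, n_groups + 1).round().astype(int)
    rows = []
    for d in range(n_groups):
        idx = order[edges[d]:edges[d + 1]]
        count = int(observed_event[idx].sum())
        rows.append({
            "decile": d + 1,
            "n": idx.size,
            "expected": float(predicted_risk[idx].mean()),
            "observed": count / idx.size,
            "observed_count": count,
        })
    return pd.DataFrame(rows)


def calibration_slope(
    expected: np.ndarray, observed: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """OLS of observed on expected: (slope, intercept, slope 95% CI)."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all expected values equal; slope undefined")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    res = stats.linregress(x, y)
    tq = stats.t.ppf(1 - alpha / 2, df=x.size - 2)
    ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    return float(res.slope), float(res.intercept), (float(ci[0]), float(ci[1]))


def hosmer_lemeshow(
    n: np.ndarray,
    expected: np.ndarray,
    observed_counts: np.ndarray,
    df: int | None = None,
    n_fitted_params: int = 0,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over risk groups.

    ``expected`` are mean predicted risks per group; the statistic is
    sum_d (O_d - E_d)^2 / (E_d (1 - E_d/n_d)) with E_d = n_d * expected_d.
    Groups with zero expected events are skipped with a warning and the
    degrees of freedom reduced. For risks from an external model nothing
    is estimated on the data at hand, so the default df is the number of
    usable groups; set ``n_fitted_params=2`` for the classical in-sample
    g-2 convention, or pass ``df`` outright.
    """
    n = np.asarray(n, dtype=float)
    expected = np.asarray(expected, dtype=float)
    obs = np.asarray(observed_counts, dtype=float)
    e_counts = n * expected
    usable = e_counts > 0
    n_skipped = int(np.sum(~usable))
    if n_skipped:
        log.warning(
            "%d group(s) with zero expected events skipped; df reduced", n_skipped
        )
    n_usable = int(usable.sum())
    if n_usable < 3:
        raise ValueError("fewer than 3 usable groups")
    e = e_counts[usable]
    o = obs[usable]
    nn = n[usable]
    stat = float(np.sum((o - e) ** 2 / (e * (1.0 - e / nn))))
    if df is None:
        df = n_usable - n_fitted_params
    p = float(stats.chi2.sf(stat, df))
    return stat, int(df), p


def calibrate(
    z: np.ndarray,
    followup: FollowUp,
    predicted_risk: np.ndarray,
    horizon: float = 5.0,
    n_groups: int = 10,
    hl_fitted_params: int = 0,
) -> CalibrationReport:
    """Full decile calibration: table, slope with CI, and HL test."""
    table = decile_expected_observed(
        z, followup, predicted_risk, horizon=horizon, n_groups=n_groups
    )
    slope, intercept, ci = calibration_slope(
        table["expected"].to_numpy(), table["observed"].to_numpy()
    )
    hl_stat, hl_df, hl_p = hosmer_lemeshow(
        table["n"].to_numpy(),
        table["expected"].to_numpy(),
        table["observed_count"].to_numpy(),
        n_fitted_params=hl_fitted_params,
    )
    return CalibrationReport(
        table=table, slope=slope, slope_ci=ci, intercept=intercept,
        hl_stat=hl_stat, hl_df=hl_df, hl_p=hl_p,
    )
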