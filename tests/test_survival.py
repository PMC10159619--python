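"""Follow-up, quantile groups, and Cox proportional-hazards models."""

import math

import numpy as np
import pandas as pd
import pytest

from prseval.simulate import SimConfig, simulate_cohort
from prseval.survival import (
    assign_quantile_groups,
    compute_followup,
    fit_cox,
    hr_table,
    per_sd_model,
    ph_check,
    trend_test,
)


def efron_log_partial_likelihood(beta, time, event, x):
    """Independent single-covariate Efron partial log-likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    eta = beta * x
    exps = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        sum_dead = exps[dead].sum()
        sum_risk = exps[at_risk].sum()
        ll += eta[dead].sum()
        for ell in range(d):
            ll -= math.log(sum_risk - (ell / d) * sum_dead)
    return ll


def grid_maximize(time, event, x, lo=-5.0, hi=5.0):
    grid = np.arange(lo, hi, 1e-3)
    vals = [efron_log_partial_likelihood(b, time, event, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-5)
    vals = [efron_log_partial_likelihood(b, time, event, x) for b in fine]
    return fine[int(np.argmax(vals))]


# small fixture suite of <=6-subject datasets, with and without ties
TINY_DATASETS = [
    ([1.0, 2.0, 3.0], [1, 1, 0], [0.5, -0.5, 1.0]),
    ([2.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], [1.0, 0.0, -1.0, 0.5]),
    ([1.0, 1.0, 1.0, 2.0, 3.0], [1, 1, 0, 1, 1], [0.2, -0.1, 0.4, 0.0, -0.3]),
    ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 0, 1, 0, 1, 1],
     [0.3, 0.1, -0.2, 0.7, 0.0, -0.5]),
]


class TestFollowup:
    def cohort(self, time, event):
        return pd.DataFrame({"time": time, "event": event})

    def test_event_before_cap(self):
        fu = compute_followup(self.cohort([8.0], ["cancer"]))
        assert fu.time[0] == 8.0 and fu.event[0] == 1

    def test_death_after_cap_censored_at_cap(self):
        fu = compute_followup(self.cohort([22.0], ["death"]))
        assert fu.time[0] == 20.0 and fu.event[0] == 0

    def test_cancer_after_cap_censored(self):
        fu = compute_followup(self.cohort([21.5], ["cancer"]))
        assert fu.time[0] == 20.0 and fu.event[0] == 0

    def test_administrative_censoring_passthrough(self):
        fu = compute_followup(self.cohort([17.3], ["censored"]))
        assert fu.time[0] == 17.3 and fu.event[0] == 0

    def test_negative_time_error(self):
        with pytest.raises(ValueError):
            compute_followup(self.cohort([-1.0], ["cancer"]))


class TestQuantileGroups:
    def test_even_split(self):
        qa = assign_quantile_groups(np.arange(1.0, 11.0), K=5)
        sizes = np.bincount(qa.group)[1:]
        assert sizes.tolist() == [2, 2, 2, 2, 2]
        assert qa.reference_group == 3
        assert qa.group[np.argsort(np.arange(1.0, 11.0))][0] == 1

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            assign_quantile_groups(np.ones(20), K=5)

    def test_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in (21_694, 103, 57):
            qa = assign_quantile_groups(rng.normal(size=n), K=5)
            sizes = np.bincount(qa.group)[1:]
            assert sizes.max() - sizes.min() <= 1
            assert sizes.sum() == n

    def test_ties_keep_sizes_balanced(self):
        z = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 4)  # ties at every cut
        qa = assign_quantile_groups(z, K=5)
        sizes = np.bincount(qa.group)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_even_k_reference(self):
        qa = assign_quantile_groups(np.arange(8.0), K=4)
        assert qa.reference_group == 2

    def test_ordered_by_score(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100)
        qa = assign_quantile_groups(z, K=5)
        means = [z[qa.group == k].mean() for k in range(1, 6)]
        assert np.all(np.diff(means) > 0)


class TestFitCox:
    def test_constant_covariate_error(self):
        with pytest.raises(ValueError, match="constant covariate"):
            fit_cox(np.array([1.0, 2, 3]), np.array([1, 1, 0]),
                    pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_no_events_error(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox(np.array([1.0, 2.0]), np.array([0, 0]),
                    pd.DataFrame({"x": [0.0, 1.0]}))

    @pytest.mark.parametrize("time,event,x", TINY_DATASETS)
    def test_matches_grid_search_oracle(self, time, event, x):
        fit = fit_cox(np.array(time), np.array(event), pd.DataFrame({"x": x}))
        oracle = grid_maximize(time, event, x)
        assert abs(fit.coef["x"] - oracle) < 1e-3

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(2)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(0.3 * x1)))
        fit = fit_cox(np.minimum(t, 10), (t <= 10).astype(int),
                      pd.DataFrame({"x1": x1, "x2": x2}))
        cov = fit.cov.values
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfectly separating covariate -> divergent coefficient
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fit_cox(time, event, pd.DataFrame({"x": x}))
        assert fit.diverged
        assert np.isfinite(fit.coef["x"])


class TestTrendAndPH:
    def _sim(self, beta, n, seed):
        cfg = SimConfig(n_samples=n, per_sd_log_hr=beta, seed=seed)
        rng = cfg.rng()
        z = rng.standard_normal(n)
        coh = simulate_cohort(cfg, z, rng=rng)
        fu = compute_followup(coh)
        return z, coh, fu

    def test_trend_significant_under_effect(self):
        z, coh, fu = self._sim(math.log(1.5), 20_000, 21)
        qa = assign_quantile_groups(z, K=5)
        p = trend_test(qa.group, fu, coh["age_at_recruitment"].to_numpy())
        assert p < 1e-4

    def test_trend_single_group_error(self):
        fu = compute_followup(pd.DataFrame({
            "time": [1.0, 2.0, 3.0], "event": ["cancer", "cancer", "censored"],
        }))
        with pytest.raises(ValueError):
            trend_test(np.array([1, 1, 1]), fu, np.array([50.0, 55.0, 60.0]))

    def test_ph_check_returns_p_per_covariate(self):
        z, coh, fu = self._sim(math.log(1.5), 5000, 22)
        fit = fit_cox(fu.time, fu.event, pd.DataFrame({
            "z": z, "age": coh["age_at_recruitment"].to_numpy()}))
        p = ph_check(fit, fu.time, fu.event, pd.DataFrame({
            "z": z, "age": coh["age_at_recruitment"].to_numpy()}))
        assert set(p.index) == {"z", "age"}
        assert ((p > 0) & (p <= 1)).all()

    def test_ph_check_no_events_error(self):
        z, coh, fu = self._sim(0.0, 200, 23)
        fit = fit_cox(fu.time, fu.event, pd.DataFrame({"z": z}))
        with pytest.raises(ValueError):
            ph_check(fit, fu.time, np.zeros_like(fu.event),
                     pd.DataFrame({"z": z}))

    def test_ph_power_against_decaying_effect(self):
        # effect that halves after year 5 violates proportional hazards
        rng = np.random.default_rng(24)
        n = 20_000
        z = rng.standard_normal(n)
        beta0 = math.log(3.0)
        h1 = 0.02 * np.exp(beta0 * z)
        t1 = rng.exponential(1 / h1)
        t2 = 5 + rng.exponential(1 / (0.02 * np.exp(0.0 * z)))
        t = np.where(t1 < 5, t1, t2)
        time = np.minimum(t, 20.0)
        event = (t <= 20.0).astype(int)
        fit = fit_cox(time, event, pd.DataFrame({"z": z}))
        p = ph_check(fit, time, event, pd.DataFrame({"z": z}))
        assert p["z"] < 0.05


class TestHRTable:
    def test_reference_group_unit_hazard(self):
        cfg = SimConfig(n_samples=4000, seed=31)
        rng = cfg.rng()
        z = rng.standard_normal(cfg.n_samples)
        coh = simulate_cohort(cfg, z, rng=rng)
        fu = compute_followup(coh)
        tab = hr_table(z, fu, coh["age_at_recruitment"].to_numpy(), K=5)
        ref = tab.groups[tab.groups["group"] == tab.reference_group]
        assert ref["hr"].iloc[0] == 1.0
        assert np.isnan(ref["ci_low"].iloc[0])

    def test_case_counts_partition_events(self):
        cfg = SimConfig(n_samples=4000, seed=32)
        rng = cfg.rng()
        z = rng.standard_normal(cfg.n_samples)
        coh = simulate_cohort(cfg, z, rng=rng)
        fu = compute_followup(coh)
        tab = hr_table(z, fu, coh["age_at_recruitment"].to_numpy(), K=5)
        assert tab.groups["n_cases"].sum() == fu.event.sum()
        assert tab.groups["n"].sum() == cfg.n_samples

    def test_top_vs_middle_quintile_matches_truncated_normal_oracle(self):
        # E[Z|Q5] - E[Z|Q3] = 1.40 for standard normal quintiles, so the
        # Q5-vs-Q3 log HR should be near beta * 1.40
        beta = math.log(1.5)
        cfg = SimConfig(n_samples=20_000, per_sd_log_hr=beta, seed=33)
        rng = cfg.rng()
        z = rng.standard_normal(cfg.n_samples)
        coh = simulate_cohort(cfg, z, rng=rng)
        fu = compute_followup(coh)
        tab = hr_table(z, fu, coh["age_at_recruitment"].to_numpy(), K=5)
        q5 = tab.groups.loc[tab.groups["group"] == 5, "hr"].iloc[0]
        assert abs(math.log(q5) - beta * 1.3998) < 0.25

    def test_per_sd_model_affine_invariant(self):
        from prseval.scoring import standardize

        cfg = SimConfig(n_samples=3000, seed=34)
        rng = cfg.rng()
        raw = rng.normal(5.0, 2.0, cfg.n_samples)
        z = standardize(raw)
        coh = simulate_cohort(cfg, z, rng=rng)
        fu = compute_followup(coh)
        f1 = per_sd_model(z, fu, coh)
        f2 = per_sd_model(standardize(10.0 * raw - 3.0), fu, coh)
        assert f1.coef["prs_per_sd"] == pytest.approx(
            f2.coef["prs_per_sd"], abs=1e-10
        )
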