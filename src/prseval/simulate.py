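"""Synthetic prospective cohort generator.

Emulates the statistical structure a PRS evaluation assumes: hard-call
genotypes in Hardy-Weinberg proportions, published-style scoring files,
recruitment ages matching a middle-aged Asian cohort (median 54, IQR
roughly 49-61, range 45-74), incident cancer under a proportional-hazards
effect of the standardized PRS, competing death from all causes, and
administrative censoring at 20 years. The matching population "registry"
rate table carries the analytic marginal incidence
``baseline(a) * E[exp(beta Z)] = baseline(a) * exp(beta^2 / 2)``.

Survival times are drawn with piecewise-constant hazards on 1-year steps
since recruitment, the same discretization the absolute-risk solver uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .rates import RateTable
from .scoring import GenotypeMatrix, ScoreFile, ScoreVariant

__all__ = [
    "SimConfig",
    "default_incidence",
    "default_mortality",
    "draw_recruit_ages",
    "hwe_exact_p",
    "simulate_genotypes",
    "simulate_scorefile",
    "simulate_cohort",
    "make_rate_table",
    "write_cohort_csv",
    "read_cohort_csv",
]


def default_incidence(age):
    """Site-specific cancer incidence per person-year, rising with age
    (about 2 per 1,000 py at age 60, registry order of magnitude)."""
    return 2e-3 * (np.asarray(age, dtype=float) / 60.0) ** 4


def default_mortality(age):
    """All-cause mortality per person-year, Gompertz in age."""
    return 6e-5 * np.exp(0.085 * np.asarray(age, dtype=float))


@dataclass
class SimConfig:
    n_samples: int = 20_000
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.01, 0.5)
    weight_sd: float = 0.05
    per_sd_log_hr: float = math.log(1.5)
    baseline_hazard: Callable = default_incidence
    mortality_hazard: Callable = default_mortality
    recruit_age_median: float = 54.0
    recruit_age_sigma: float = 1.0
    recruit_age_range: tuple[float, float] = (45.0, 74.0)
    admin_censor_years: float = 20.0
    sex_ratio: float = 0.5  # fraction female
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_recruit_ages(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Recruitment ages: min_age + lognormal, truncated to the cohort's
    eligibility window by rejection. The lognormal location is solved so
    the *truncated* median equals the configured target; a pragmatic fit
    to the reported median/IQR, not a reconstruction."""
    from scipy import optimize, stats

    lo, hi = cfg.recruit_age_range
    sigma = cfg.recruit_age_sigma

    def truncated_median(mu: float) -> float:
        p_keep = stats.norm.cdf((math.log(hi - lo) - mu) / sigma)
        return lo + math.exp(mu + sigma * stats.norm.ppf(0.5 * p_keep))

    mu = optimize.brentq(
        lambda m: truncated_median(m) - cfg.recruit_age_median, 0.1, 4.0
    )
    ages = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = lo + rng.lognormal(mu, cfg.recruit_age_sigma, todo.size)
        ok = draw <= hi
        ages[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return ages


# ---------------------------------------------------------------------------
# genotypes


def hwe_exact_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of heterozygote-count
    probabilities no larger than the observed one, conditional on allele
    counts)."""
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return 1.0
    n_b = n_het + 2 * n_hom_b
    n_minor = min(n_b, 2 * n - n_b)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * math.log(2)
        - gammaln(hets + 1) - gammaln(hom_minor + 1) - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = min(n_het, n_minor)  # het count bounded by minor-allele count
    p_obs = p[hets == obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Hard-call genotypes under Hardy-Weinberg proportions.

    Per-variant allele frequencies are uniform on ``maf_range``; dosages
    count the ``allele_b`` allele. Metadata carry the empirical MAF, an
    INFO of 1 (directly observed genotypes), the exact-test HWE p, and a
    call rate of 1 (no missingness injected by default).
    """
    rng = cfg.rng() if rng is None else rng
    n, k = cfg.n_samples, cfg.n_variants
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    dosage = rng.binomial(2, p[None, :], size=(n, k)).astype(float)

    bases = np.array(list("ACGT"))
    # non-palindromic allele pairs only, so harmonization keeps them all
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    pick = rng.integers(0, len(pairs), size=k)
    allele_a = np.array([pairs[i][0] for i in pick])
    allele_b = np.array([pairs[i][1] for i in pick])

    meta_rows = []
    for j in range(k):
        counts = np.bincount(dosage[:, j].astype(int), minlength=3)
        eaf = dosage[:, j].mean() / 2.0
        meta_rows.append({
            "maf": min(eaf, 1 - eaf),
            "info": 1.0,
            "hwe_p": hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])),
            "call_rate": 1.0,
            "n_alleles": 2,
        })
    variants = pd.DataFrame({
        "chrom": np.repeat("1", k),
        "pos": np.arange(1, k + 1) * 1000,
        "allele_a": allele_a,
        "allele_b": allele_b,
    })
    return GenotypeMatrix(
        sample_ids=[f"S{i:06d}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        variant_meta=pd.DataFrame(meta_rows),
    )


def simulate_scorefile(
    g: GenotypeMatrix,
    rng: np.random.Generator,
    pgs_id: str = "PGS900001",
    weight_sd: float = 0.05,
    subset: float = 1.0,
    shuffle_orientation: bool = True,
) -> ScoreFile:
    """A published-style score over (a subset of) the panel's variants.

    Weights are N(0, weight_sd) log odds ratios. With
    ``shuffle_orientation`` each variant is randomly written in direct,
    swapped, or strand-complement orientation relative to the panel, which
    exercises harmonization without changing the score it defines.
    """
    k = g.n_variants
    take = np.sort(rng.choice(k, size=max(1, int(round(subset * k))), replace=False))
    variants = []
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for j in take:
        row = g.variants.iloc[j]
        a, b = str(row["allele_a"]), str(row["allele_b"])
        w = float(rng.normal(0.0, weight_sd))
        eff, oth = b, a  # effect allele = counted allele
        mode = rng.integers(0, 4) if shuffle_orientation else 0
        if mode in (1, 3):  # swap effect/other, negate weight
            eff, oth, w = oth, eff, -w
        if mode in (2, 3):  # write on the opposite strand
            eff, oth = comp[eff], comp[oth]
        variants.append(ScoreVariant(
            variant_id=f"rs{int(row['pos'])}",
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=eff,
            other_allele=oth,
            weight=w,
        ))
    return ScoreFile(
        pgs_id=pgs_id, trait_label="synthetic trait",
        weight_type="log_odds", variants=variants,
    )


def write_scorefile(score: ScoreFile, path) -> None:
    """Write in the tab-separated, '#'-metadata dialect the parser reads."""
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={score.pgs_id}\n")
        fh.write(f"#trait_reported={score.trait_label}\n")
        fh.write("#weight_type=log(OR)\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for v in score.variants:
            fh.write(
                f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.effect_allele}\t"
                f"{v.other_allele or ''}\t{v.weight!r}\n"
            )


# ---------------------------------------------------------------------------
# cohort outcomes


_COVARIATE_SCHEMA = {
    # category frequencies chosen to resemble a middle-aged Singapore cohort
    "dialect": (["hokkien", "cantonese"], [0.49, 0.51]),
    "education": (["none", "primary", "secondary_plus"], [0.21, 0.45, 0.34]),
    "smoking": (["never", "ex", "current"], [0.72, 0.11, 0.17]),
    "alcohol": (["never", "weekly", "daily"], [0.88, 0.09, 0.03]),
    "moderate_pa": (["none", "1-3h", "3h_plus"], [0.76, 0.15, 0.09]),
    "vigorous_pa": (["no", "yes"], [0.85, 0.15]),
    "family_history": (["no", "yes"], [0.84, 0.16]),
}


def simulate_cohort(
    cfg: SimConfig,
    prs_standardized: np.ndarray,
    rng: np.random.Generator | None = None,
    sex: str = "female",
    sample_ids: list[str] | None = None,
    ages: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw follow-up outcomes for one sex stratum.

    Cancer hazard is ``baseline(a) * exp(beta * z)`` and death hazard
    ``mortality(a)`` at attained age ``a``, piecewise-constant on 1-year
    steps since recruitment; the observed record is the first of cancer,
    death, or administrative censoring. Lifestyle covariates are drawn
    independent of outcome by default, so adjusted and unadjusted models
    agree in expectation.
    """
    rng = cfg.rng() if rng is None else rng
    z = np.asarray(prs_standardized, dtype=float)
    n = z.size
    age0 = draw_recruit_ages(cfg, rng, n) if ages is None else np.asarray(ages, float)
    beta = cfg.per_sd_log_hr

    T = cfg.admin_censor_years
    time = np.full(n, float(T))
    event = np.full(n, "censored", dtype=object)
    alive = np.ones(n, dtype=bool)
    step = 0
    while step < T:
        step_len = min(1.0, T - step)
        a = age0 + step
        hc = np.asarray(cfg.baseline_hazard(a), dtype=float) * np.exp(beta * z)
        hd = np.asarray(cfg.mortality_hazard(a), dtype=float)
        h = hc + hd
        u = rng.random(n)
        v = rng.random(n)
        with np.errstate(divide="ignore"):
            te = np.where(h > 0, -np.log(u) / np.maximum(h, 1e-300), np.inf)
        hit = alive & (te < step_len)
        is_cancer = v < np.where(h > 0, hc / np.maximum(h, 1e-300), 0.0)
        time[hit] = step + te[hit]
        event[hit] = np.where(is_cancer[hit], "cancer", "death")
        alive &= ~hit
        step += 1

    cov = {
        name: rng.choice(levels, size=n, p=probs)
        for name, (levels, probs) in _COVARIATE_SCHEMA.items()
    }
    bmi = rng.normal(23.0, 3.0, size=n)
    return pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None
        else [f"S{i:06d}" for i in range(n)],
        "sex": sex,
        "age_at_recruitment": age0,
        "time": time,
        "event": event,
        "bmi": bmi,
        **cov,
    })


def make_rate_table(
    cfg: SimConfig, bands: list[tuple[float, float]] | None = None
) -> RateTable:
    """The "population registry" implied by the generator.

    Marginal incidence in each band is the per-year baseline times
    ``E[exp(beta Z)] = exp(beta^2 / 2)`` for standard-normal Z, averaged
    over the band's integer ages; mortality is the configured hazard
    likewise averaged. Default bands: 1-year steps from 30 to the oldest
    attainable age.
    """
    if bands is None:
        top = int(math.ceil(cfg.recruit_age_range[1] + cfg.admin_censor_years)) + 1
        bands = [(float(a), float(a + 1)) for a in range(30, top)]
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    if np.any(lows[1:] != highs[:-1]):
        raise ValueError("bands must be contiguous and non-overlapping")
    frailty = math.exp(cfg.per_sd_log_hr ** 2 / 2.0)
    inc, mort = [], []
    for lo, hi in bands:
        years = np.arange(lo, hi)
        inc.append(float(np.mean(cfg.baseline_hazard(years))) * frailty)
        mort.append(float(np.mean(cfg.mortality_hazard(years))))
    return RateTable(age_low=lows, age_high=highs, incidence=inc, mortality=mort)


# ---------------------------------------------------------------------------
# cohort IO


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "sex", "age_at_recruitment", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ValueError("negative follow-up time in cohort table")
    bad = set(df["event"].unique()) - {"cancer", "death", "censored"}
    if bad:
        raise ValueError(f"unknown event states {sorted(bad)}")
    return df
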