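"""End-to-end orchestration of a PRS evaluation.

One config drives, per stratum (cancer site x sex): scoring of every
scorefile against the QC-filtered panel, distribution and discrimination
summaries, selection of the best score by AUC, quintile and per-SD Cox
hazard-ratio tables, band-level 5-year absolute risks under competing
mortality, and decile calibration. Any stage failure marks the stratum
failed and the remaining strata continue. All randomness flows from the
config seed; outputs are plain JSON/CSV and bit-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import absrisk, calibration, discrimination, simulate, survival
from .rates import RateTable, read_rate_csv
from .scoring import (
    GenotypeMatrix,
    QCThresholds,
    compute_prs,
    harmonize,
    parse_scorefile,
    qc_filter_variants,
    read_dosage_tsv,
    read_vcf,
    standardize,
    write_dosage_tsv,
)

__all__ = ["PipelineConfig", "StratumSpec", "run_pipeline", "simulate_demo"]

log = logging.getLogger(__name__)


@dataclass
class StratumSpec:
    name: str
    sex: str
    rates: str  # path to the stratum's rate-table CSV


@dataclass
class PipelineConfig:
    scorefiles: list[str]
    genotypes: str
    cohort: str
    strata: list[StratumSpec]
    genotypes_meta: str | None = None  # sidecar for TSV dosage matrices
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_quantiles: int = 5
    band_width_pct: float = 5.0
    horizon_years: float = 5.0
    cap_years: float = 20.0
    seed: int = 0
    output_dir: str = "prseval_out"
    figures: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years > self.cap_years:
            raise ValueError("horizon must not exceed the follow-up cap")

    def validate_paths(self, base: Path | None = None) -> None:
        base = base or Path(".")
        paths = list(self.scorefiles) + [self.genotypes, self.cohort]
        paths += [s.rates for s in self.strata]
        if self.genotypes_meta:
            paths.append(self.genotypes_meta)
        missing = [p for p in paths if not (base / p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        base = path.parent
        raw["scorefiles"] = [str(base / p) for p in raw["scorefiles"]]
        raw["genotypes"] = str(base / raw["genotypes"])
        raw["cohort"] = str(base / raw["cohort"])
        if raw.get("genotypes_meta"):
            raw["genotypes_meta"] = str(base / raw["genotypes_meta"])
        raw["strata"] = [
            StratumSpec(name=s["name"], sex=s["sex"], rates=str(base / s["rates"]))
            for s in raw["strata"]
        ]
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        cfg = cls(**raw)
        cfg.validate_paths()
        return cfg


def _read_genotypes(config: PipelineConfig) -> GenotypeMatrix:
    p = str(config.genotypes)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    if config.genotypes_meta is None:
        raise ValueError("TSV dosage matrix requires a genotypes_meta sidecar")
    return read_dosage_tsv(p, config.genotypes_meta)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _evaluate_stratum(
    config: PipelineConfig,
    stratum: StratumSpec,
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    outdir: Path,
) -> dict:
    sub = cohort[cohort["sex"] == stratum.sex].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum.name}: no samples of sex {stratum.sex}")
    row_of = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    idx = [row_of[s] for s in sub["sample_id"]]
    g_strat = genotypes.take_samples(idx)

    fu = survival.compute_followup(sub, cap_years=config.cap_years)
    age = sub["age_at_recruitment"].to_numpy(dtype=float)

    per_score = {}
    disc_results = []
    z_by_id = {}
    for sf_path in config.scorefiles:
        score = parse_scorefile(sf_path)
        mapping, harm = harmonize(score, g_strat)
        prs = compute_prs(score, g_strat, mapping)
        z = standardize(prs.raw)
        z_by_id[score.pgs_id] = z

        dist = discrimination.compare_distributions(
            z[fu.event == 1], z[fu.event == 0]
        )
        disc = discrimination.auc_mw(
            z, fu.event, pgs_id=score.pgs_id, age=age
        )
        disc.missing_fraction = harm.missing_fraction
        disc.auc_cd_5y = discrimination.auc_cd(
            fu.time, fu.event, z, horizon=config.horizon_years
        )
        disc_results.append(disc)
        per_score[score.pgs_id] = {
            "harmonization": harm.to_dict(),
            "distribution": dataclasses.asdict(dist),
            "discrimination": dataclasses.asdict(disc),
        }

    best = discrimination.select_best_prs(disc_results)
    z = z_by_id[best]

    hr = survival.hr_table(z, fu, age, K=config.n_quantiles)
    adj = survival.per_sd_model(z, fu, sub)
    age_adj = survival.fit_cox(
        fu.time, fu.event,
        pd.DataFrame({"prs_per_sd": z, "age": age}),
    )
    beta_hat = float(age_adj.coef["prs_per_sd"])

    rates = read_rate_csv(stratum.rates)
    groups = absrisk.make_risk_groups(beta_hat, config.band_width_pct)
    baseline = absrisk.solve_baseline_hazard(rates, groups)
    curve = absrisk.five_year_absolute_risk(baseline, rates, groups)
    resid = absrisk.marginal_check(baseline, rates, groups)

    predicted = absrisk.predicted_risk_per_subject(curve, groups, z, age)
    calib = calibration.calibrate(
        z, fu, predicted, horizon=config.horizon_years
    )

    hr.groups.to_csv(outdir / f"{stratum.name}_hr_table.csv", index=False)
    curve.to_frame(groups).to_csv(
        outdir / f"{stratum.name}_absolute_risk.csv", index=False
    )
    calib.table.to_csv(outdir / f"{stratum.name}_calibration.csv", index=False)
    if config.figures:
        _figures(stratum.name, curve, groups, calib, outdir)

    zq = 1.959963984540054
    per_sd_se = float(np.sqrt(adj.cov.loc["prs_per_sd", "prs_per_sd"]))
    return {
        "sex": stratum.sex,
        "n_samples": int(len(sub)),
        "n_events": int(fu.event.sum()),
        "scores": per_score,
        "best_prs": best,
        "hazard_ratios": {
            "groups": hr.groups.to_dict(orient="records"),
            "reference_group": hr.reference_group,
            "p_trend": hr.p_trend,
            "ph_test_p": hr.ph_test_p,
            "per_sd_age_adjusted_hr": float(np.exp(beta_hat)),
            "per_sd_fully_adjusted_hr": float(np.exp(adj.coef["prs_per_sd"])),
            "per_sd_fully_adjusted_ci": [
                float(np.exp(adj.coef["prs_per_sd"] - zq * per_sd_se)),
                float(np.exp(adj.coef["prs_per_sd"] + zq * per_sd_se)),
            ],
        },
        "absolute_risk": {
            "per_sd_log_hr_used": beta_hat,
            "solver_iterations": baseline.n_iter,
            "constraint_residual": baseline.residual,
            "marginal_check_residual": resid,
        },
        "calibration": calib.to_dict(),
    }


def _figures(name, curve, groups, calib, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in range(groups.n_groups):
        ax.plot(curve.ages, 100 * curve.ar5[:, g], lw=0.8)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("5-year absolute risk (%)")
    ax.set_title(f"{name}: absolute risk by PRS band")
    fig.savefig(outdir / f"{name}_absolute_risk.svg", metadata={"Date": None})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(calib.table["expected"], calib.table["observed"])
    lim = max(calib.table["expected"].max(), calib.table["observed"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.plot([0, lim], [calib.intercept, calib.intercept + calib.slope * lim])
    ax.set_xlabel("Expected 5-year risk")
    ax.set_ylabel("Observed proportion")
    ax.set_title(f"{name}: calibration (slope {calib.slope:.2f})")
    fig.savefig(outdir / f"{name}_calibration.svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stratum; return (and write) the report."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genotypes = _read_genotypes(config)
    genotypes, qc_log = qc_filter_variants(genotypes, config.qc)
    cohort = simulate.read_cohort_csv(config.cohort)

    report: dict = {
        "seed": config.seed,
        "n_variants_after_qc": genotypes.n_variants,
        "n_variants_excluded_qc": int(len(qc_log)),
        "strata": {},
    }
    for stratum in config.strata:
        try:
            report["strata"][stratum.name] = _evaluate_stratum(
                config, stratum, genotypes, cohort, outdir
            )
        except Exception as exc:  # stratum isolation: continue with the rest
            log.exception("stratum %s failed", stratum.name)
            report["strata"][stratum.name] = {
                "skipped": True, "reason": f"{type(exc).__name__}: {exc}",
            }

    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    tmp = outdir / "report.json.tmp"
    tmp.write_text(payload + "\n")
    tmp.replace(outdir / "report.json")
    return report


def simulate_demo(
    cfg: simulate.SimConfig,
    outdir,
    n_scorefiles: int = 2,
) -> PipelineConfig:
    """Write a complete runnable synthetic input set.

    Genotypes (TSV + metadata sidecar), published-style scorefiles (the
    first is the causal score; the others are noise scores over random
    variant subsets), a two-sex cohort with outcomes driven by the causal
    score, per-stratum rate tables, and a pipeline config (JSON with
    relative paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()

    g = simulate.simulate_genotypes(cfg, rng)
    scores = []
    for i in range(n_scorefiles):
        s = simulate.simulate_scorefile(
            g, rng, pgs_id=f"PGS90{i:04d}",
            weight_sd=cfg.weight_sd, subset=1.0 if i == 0 else 0.5,
        )
        simulate.write_scorefile(s, outdir / f"scorefile_{i + 1}.txt")
        scores.append(s)

    # outcomes driven by the first (causal) score, standardized within sex
    mapping, _ = harmonize(scores[0], g)
    raw = compute_prs(scores[0], g, mapping).raw
    n = cfg.n_samples
    is_female = rng.random(n) < cfg.sex_ratio
    cohorts = []
    for sex, mask in (("female", is_female), ("male", ~is_female)):
        z = standardize(raw[mask])
        ids = [g.sample_ids[i] for i in np.flatnonzero(mask)]
        cohorts.append(simulate.simulate_cohort(
            cfg, z, rng=rng, sex=sex, sample_ids=ids,
        ))
    cohort = pd.concat(cohorts, ignore_index=True)
    simulate.write_cohort_csv(cohort, outdir / "cohort.csv")

    rates = simulate.make_rate_table(cfg)
    strata = []
    for sex in ("female", "male"):
        rates.to_csv(outdir / f"rates_{sex}.csv")
        strata.append({"name": f"site_{sex}", "sex": sex,
                       "rates": f"rates_{sex}.csv"})

    write_dosage_tsv(g, outdir / "genotypes.tsv", outdir / "genotypes_meta.tsv")
    config_raw = {
        "scorefiles": [f"scorefile_{i + 1}.txt" for i in range(n_scorefiles)],
        "genotypes": "genotypes.tsv",
        "genotypes_meta": "genotypes_meta.tsv",
        "cohort": "cohort.csv",
        "strata": strata,
        "seed": cfg.seed,
        "output_dir": str(outdir / "results"),
    }
    (outdir / "config.json").write_text(
        json.dumps(config_raw, indent=2, sort_keys=True) + "\n"
    )
    return PipelineConfig.from_json(outdir / "config.json")
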