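"""The whole evaluation in one call.

Writes a complete synthetic input set (genotypes, two scorefiles, cohort,
rate tables, config), runs every stage per sex stratum, and prints the
headline numbers. Equivalent shell usage:

    prseval simulate --out demo --n 5000 --seed 1
    prseval evaluate --config demo/config.json
"""

import tempfile

from prseval.pipeline import run_pipeline, simulate_demo
from prseval.simulate import SimConfig

with tempfile.TemporaryDirectory() as tmp:
    config = simulate_demo(SimConfig(n_samples=5000, n_variants=60, seed=1), tmp)
    report = run_pipeline(config)

for name, stratum in report["strata"].items():
    best = stratum["best_prs"]
    disc = stratum["scores"][best]["discrimination"]
    hr = stratum["hazard_ratios"]
    cal = stratum["calibration"]
    print(f"{name}: n={stratum['n_samples']}, events={stratum['n_events']}")
    print(f"  best PRS {best}: AUC {disc['auc']:.3f} "
          f"({disc['ci_low']:.3f}-{disc['ci_high']:.3f}), "
          f"5y time-dependent AUC {disc['auc_cd_5y']:.3f}")
    print(f"  per-SD HR {hr['per_sd_fully_adjusted_hr']:.2f}, "
          f"top-vs-middle quintile HR "
          f"{[g for g in hr['groups'] if g['group'] == 5][0]['hr']:.2f}, "
          f"trend p {hr['p_trend']:.1e}")
    print(f"  calibration slope {cal['slope']:.2f}, HL p {cal['hl_p']:.3f}")
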