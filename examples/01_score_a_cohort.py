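"""Score a cohort against a published-style weight file.

Builds a small synthetic genotype panel, writes a PGS-Catalog-style
scoring file with shuffled allele orientations, then parses, harmonizes,
applies variant QC, and computes raw + standardized scores.
"""

import tempfile
from pathlib import Path

from prseval.scoring import (
    compute_prs, harmonize, parse_scorefile, qc_filter_variants, standardize,
)
from prseval.simulate import SimConfig, simulate_genotypes, simulate_scorefile, write_scorefile

cfg = SimConfig(n_samples=1000, n_variants=50, seed=11)
rng = cfg.rng()
genotypes = simulate_genotypes(cfg, rng)
score = simulate_scorefile(genotypes, rng, pgs_id="PGS900011")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "score.txt"
    write_scorefile(score, path)
    score = parse_scorefile(path)  # round-trip through the file format

genotypes, qc_log = qc_filter_variants(genotypes)
print(f"panel: {genotypes.n_samples} samples x {genotypes.n_variants} variants "
      f"after QC ({len(qc_log)} excluded)")

mapping, report = harmonize(score, genotypes)
print("harmonization:", report.to_dict())
# direct / swapped / complement counts show how allele labels were
# reconciled; 'missing' variants are absent from the panel entirely.

prs = compute_prs(score, genotypes, mapping)
z = standardize(prs.raw)
print(f"raw PRS: mean {prs.raw.mean():+.4f}, SD {prs.raw.std(ddof=1):.4f}")
print(f"standardized: mean {z.mean():+.1e}, SD {z.std(ddof=1):.3f} "
      "(z-scale, one unit = one cohort SD of genetic risk)")
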