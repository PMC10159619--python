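import numpy as np
import pandas as pd
import pytest

from prseval.scoring import GenotypeMatrix


def make_genotypes(
    dosage,
    alleles=None,
    maf=None,
    info=None,
    hwe_p=None,
    call_rate=None,
    n_alleles=None,
    chrom="1",
    pos=None,
):
    """Small genotype matrix with sensible metadata defaults."""
    dosage = np.asarray(dosage, dtype=float)
    n, k = dosage.shape
    if alleles is None:
        alleles = [("A", "G")] * k
    if pos is None:
        pos = [1000 * (j + 1) for j in range(k)]
    with np.errstate(invalid="ignore"):
        eaf = np.nanmean(dosage, axis=0) / 2.0
    meta = pd.DataFrame({
        "maf": maf if maf is not None else np.minimum(eaf, 1 - eaf),
        "info": info if info is not None else np.ones(k),
        "hwe_p": hwe_p if hwe_p is not None else np.ones(k),
        "call_rate": call_rate if call_rate is not None
        else np.mean(~np.isnan(dosage), axis=0),
        "n_alleles": n_alleles if n_alleles is not None else np.full(k, 2),
    })
    variants = pd.DataFrame({
        "chrom": [chrom] * k,
        "pos": pos,
        "allele_a": [a for a, _ in alleles],
        "allele_b": [b for _, b in alleles],
    })
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        variant_meta=meta,
    )


@pytest.fixture
def genotypes_factory():
    return make_genotypes


def write_scorefile_text(path, rows, weight_col="effect_weight", meta=None):
    """Write a minimal PGS-Catalog-style scoring file.

    rows: list of (rsid, chrom, pos, effect, other, weight).
    """
    lines = []
    for k, v in (meta or {}).items():
        lines.append(f"#{k}={v}")
    lines.append(
        "\t".join(["rsID", "chr_name", "chr_position",
                   "effect_allele", "other_allele", weight_col])
    )
    for r in rows:
        lines.append("\t".join(str(x) if x is not None else "" for x in r))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def scorefile_writer():
    return write_scorefile_text
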