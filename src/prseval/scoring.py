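"""Polygenic score files, genotype dosages, harmonization, and scoring.

A polygenic risk score (PRS) is the weighted sum of effect-allele dosages

    PRS_i = sum_k beta_k * x_ik,    x_ik in [0, 2],

with weights ``beta_k`` taken as log odds ratios from a published scoring
file. This module parses PGS-Catalog-style scoring files, holds cohort
dosages with per-variant QC metadata, reconciles allele labels between the
two (direct / swapped / strand-complement / palindromic), applies variant
QC, and computes raw and standardized scores.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreVariant",
    "ScoreFile",
    "GenotypeMatrix",
    "HarmonizationReport",
    "VariantMapping",
    "PRSVector",
    "QCThresholds",
    "ScoreFileError",
    "AmbiguousVariantError",
    "parse_scorefile",
    "qc_filter_variants",
    "harmonize",
    "compute_prs",
    "standardize",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: weight types accepted after validation (odds ratios are log-transformed
#: at parse time so downstream math is uniformly on the log-odds scale).
_ACCEPTED_WEIGHT_TYPES = {"log_odds", "odds_ratio"}

#: weight types explicitly excluded from analysis.
_EXCLUDED_WEIGHT_TYPES = (
    "odds ratio over expected risk",
    "inverse-variance",
    "inverse variance",
    "unweighted",
)


class ScoreFileError(ValueError):
    """Raised for malformed or excluded scoring files."""


class AmbiguousVariantError(ValueError):
    """Raised when several cohort variants at one position match a score variant."""


@dataclass(frozen=True)
class ScoreVariant:
    """One row of a scoring file: a variant and its log-odds weight."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str | None
    weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ScoreFileError(f"non-finite weight for {self.variant_id}")
        if self.other_allele is not None and self.effect_allele == self.other_allele:
            raise ScoreFileError(
                f"effect allele equals other allele for {self.variant_id}"
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, where strand is undecidable."""
        return (
            self.other_allele is not None
            and _COMPLEMENT.get(self.effect_allele) == self.other_allele
        )


@dataclass
class ScoreFile:
    pgs_id: str
    trait_label: str
    weight_type: str
    variants: list[ScoreVariant]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ScoreFileError(f"{self.pgs_id}: no variants")
        if self.weight_type not in _ACCEPTED_WEIGHT_TYPES:
            raise ScoreFileError(
                f"{self.pgs_id}: weight type {self.weight_type!r} is not usable "
                "(only odds ratios or log odds ratios are accepted)"
            )

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)


@dataclass
class QCThresholds:
    """Variant-level QC gates. Defaults: INFO >= 0.8, MAF >= 1%, HWE p >= 1e-6,
    call rate >= 95%, biallelic only."""

    min_info: float = 0.8
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_call_rate: float = 0.95
    biallelic_only: bool = True


_META_COLUMNS = ("maf", "info", "hwe_p", "call_rate", "n_alleles")


@dataclass
class GenotypeMatrix:
    """Sample x variant dosages of the counted allele (``allele_b``).

    ``dosage`` is float with NaN marking missing calls; every non-missing
    entry lies in [0, 2]. ``variants`` has columns chrom, pos, allele_a,
    allele_b (and optionally id); ``variant_meta`` has columns
    maf, info, hwe_p, call_rate, n_alleles aligned to ``variants``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")
        missing_meta = [c for c in _META_COLUMNS if c not in self.variant_meta.columns]
        if missing_meta:
            raise ValueError(f"variant_meta missing columns {missing_meta}")
        if len(self.variant_meta) != len(self.variants):
            raise ValueError("variant_meta not aligned to variants")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
            variant_meta=self.variant_meta.copy(),
        )


@dataclass
class HarmonizationReport:
    """Accounting of how a score's variant list mapped onto the cohort panel.

    The five counts partition ``n_score_variants``.
    """

    n_score_variants: int
    n_matched_direct: int = 0
    n_matched_swapped: int = 0
    n_matched_complement: int = 0
    n_palindromic_dropped: int = 0
    n_missing: int = 0

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_score_variants

    def validate(self) -> None:
        total = (
            self.n_matched_direct
            + self.n_matched_swapped
            + self.n_matched_complement
            + self.n_palindromic_dropped
            + self.n_missing
        )
        if total != self.n_score_variants:
            raise AssertionError(
                f"harmonization counts {total} do not partition "
                f"{self.n_score_variants} score variants"
            )

    def to_dict(self) -> dict:
        return {
            "n_score_variants": self.n_score_variants,
            "n_matched_direct": self.n_matched_direct,
            "n_matched_swapped": self.n_matched_swapped,
            "n_matched_complement": self.n_matched_complement,
            "n_palindromic_dropped": self.n_palindromic_dropped,
            "n_missing": self.n_missing,
            "missing_fraction": self.missing_fraction,
        }


@dataclass(frozen=True)
class VariantMapping:
    """Resolved link: score variant -> matrix column, with orientation.

    ``flip`` is True for the swapped orientations, where the counted allele
    is the score's *other* allele and the effect-allele dosage is ``2 - x``.
    """

    score_index: int
    column: int
    orientation: str  # direct | swapped | complement | complement_swapped

    @property
    def flip(self) -> bool:
        return self.orientation in ("swapped", "complement_swapped")


@dataclass
class PRSVector:
    pgs_id: str
    raw: np.ndarray
    standardized: np.ndarray | None = None
    n_imputed: np.ndarray | None = None


# ---------------------------------------------------------------------------
# scoring-file parsing


def _normalize_weight_type(raw: str) -> str:
    s = raw.strip().lower()
    for excluded in _EXCLUDED_WEIGHT_TYPES:
        if excluded in s:
            raise ScoreFileError(f"excluded weight type: {raw!r}")
    if "log" in s or "beta" in s:
        return "log_odds"
    if s in ("or", "odds ratio", "odds_ratio", "odds ratios") or "odds ratio" in s:
        return "odds_ratio"
    if s in ("nr", "", "other"):
        return "other"
    return "other"


def parse_scorefile(path) -> ScoreFile:
    """Parse a PGS-Catalog-style scoring file.

    Format: '#'-prefixed ``key=value`` metadata lines, then a tab-separated
    table. The effect-allele column and a weight column are mandatory.
    Odds-ratio weights (a column named ``OR`` or a declared odds-ratio
    weight type) are converted to natural-log scale. Scores weighted by
    excluded schemes (odds ratio over expected risk, inverse-variance,
    unweighted) are rejected.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = re.match(r"#\s*([^=]+?)\s*=\s*(.*?)\s*$", line)
            if m:
                meta[m.group(1).lower()] = m.group(2)
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", dtype=str)
    table.columns = [c.strip() for c in table.columns]

    cols = {c.lower(): c for c in table.columns}
    ea_col = cols.get("effect_allele")
    if ea_col is None:
        raise ScoreFileError("missing required column 'effect_allele'")
    oa_col = cols.get("other_allele") or cols.get("reference_allele")

    declared = meta.get("weight_type", "")
    weight_col = cols.get("effect_weight")
    if weight_col is not None:
        weight_type = _normalize_weight_type(declared) if declared else "log_odds"
    elif "or" in cols:
        weight_col = cols["or"]
        weight_type = "odds_ratio"
        if declared:  # still honour an excluded declaration
            _normalize_weight_type(declared)
    else:
        raise ScoreFileError("missing required column 'effect_weight' (or 'OR')")
    if weight_type == "other":
        raise ScoreFileError(
            f"weight type {declared!r} is not usable; only odds ratios or "
            "log odds ratios are accepted"
        )

    id_col = cols.get("rsid") or cols.get("variant_id") or cols.get("id")
    chrom_col = cols.get("chr_name") or cols.get("chrom") or cols.get("chromosome")
    pos_col = cols.get("chr_position") or cols.get("pos") or cols.get("position")

    variants: list[ScoreVariant] = []
    seen: set[tuple] = set()
    n_dup = 0
    for i, row in table.iterrows():
        w = float(row[weight_col])
        if weight_type == "odds_ratio":
            if w <= 0:
                raise ScoreFileError(f"row {i}: odds-ratio weight {w} must be > 0")
            w = math.log(w)
        chrom = str(row[chrom_col]).strip() if chrom_col else ""
        pos = int(row[pos_col]) if pos_col and pd.notna(row[pos_col]) else 0
        ea = str(row[ea_col]).strip().upper()
        oa = str(row[oa_col]).strip().upper() if oa_col and pd.notna(row[oa_col]) else None
        vid = (
            str(row[id_col]).strip()
            if id_col and pd.notna(row[id_col])
            else f"{chrom}:{pos}"
        )
        key = (chrom, pos, frozenset((ea, oa or "")))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        variants.append(
            ScoreVariant(
                variant_id=vid, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, weight=w,
            )
        )
    if n_dup:
        log.warning("%s: dropped %d duplicate variant rows", path, n_dup)

    return ScoreFile(
        pgs_id=meta.get("pgs_id", str(path)),
        trait_label=meta.get("trait_reported", meta.get("trait_mapped", "")),
        weight_type="log_odds" if weight_type == "log_odds" else "odds_ratio",
        variants=variants,
    )


# ---------------------------------------------------------------------------
# variant QC


def qc_filter_variants(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing the QC gates; return (filtered matrix, log).

    The log has one row per *excluded* variant with its reason(s).
    An empty result is permitted (with a warning), not an error.
    """
    thr = thresholds or QCThresholds()
    meta = g.variant_meta
    reasons: list[tuple[int, str]] = []
    keep = np.ones(g.n_variants, dtype=bool)

    checks = [
        (meta["info"].to_numpy() < thr.min_info, f"INFO < {thr.min_info}"),
        (meta["maf"].to_numpy() < thr.min_maf, f"MAF < {thr.min_maf}"),
        (meta["hwe_p"].to_numpy() < thr.min_hwe_p, f"HWE p < {thr.min_hwe_p}"),
        (meta["call_rate"].to_numpy() < thr.min_call_rate,
         f"call rate < {thr.min_call_rate}"),
    ]
    if thr.biallelic_only:
        checks.append((meta["n_alleles"].to_numpy() != 2, "not biallelic"))
    for mask, why in checks:
        keep &= ~mask
        for j in np.flatnonzero(mask):
            reasons.append((j, why))

    qc_log = (
        pd.DataFrame(reasons, columns=["variant_index", "reason"])
        .groupby("variant_index")["reason"]
        .apply("; ".join)
        .reset_index()
    )
    if not keep.any():
        warnings.warn("all variants excluded by QC", stacklevel=2)
    return g.take_variants(np.flatnonzero(keep)), qc_log


# ---------------------------------------------------------------------------
# harmonization


def _orient(eff: str, oth: str | None, a: str, b: str) -> str | None:
    """Orientation of a score variant (eff/oth) against cohort alleles (a, b)
    where b is the counted allele. None if irreconcilable."""
    if eff == b and (oth is None or oth == a):
        return "direct"
    if eff == a and (oth is None or oth == b):
        return "swapped"
    if oth is None:
        return None
    ce = _COMPLEMENT.get(eff)
    co = _COMPLEMENT.get(oth)
    if ce is None or co is None:
        return None
    if ce == b and co == a:
        return "complement"
    if ce == a and co == b:
        return "complement_swapped"
    return None


def harmonize(
    score: ScoreFile,
    g: GenotypeMatrix,
    *,
    palindromic_policy: str = "drop",
    match_by: str = "position",
) -> tuple[list[VariantMapping], HarmonizationReport]:
    """Map score variants onto matrix columns, resolving allele orientation.

    Matching is by (chrom, pos) by default (``match_by='id'`` uses variant
    ids instead). Palindromic (A/T, C/G) score variants are dropped under
    the default policy because their strand cannot be verified;
    ``palindromic_policy='keep'`` matches them as if strand were certain.
    Swapped orientations mark the dosage transform x -> 2 - x.
    """
    if palindromic_policy not in ("drop", "keep"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    index: dict = {}
    if match_by == "position":
        for j, row in enumerate(g.variants.itertuples(index=False)):
            index.setdefault((str(row.chrom), int(row.pos)), []).append(j)
    elif match_by == "id":
        if "id" not in g.variants.columns:
            raise ValueError("genotype variants carry no 'id' column")
        for j, vid in enumerate(g.variants["id"]):
            index.setdefault(str(vid), []).append(j)
    else:
        raise ValueError(f"unknown match_by {match_by!r}")

    report = HarmonizationReport(n_score_variants=len(score.variants))
    mapping: list[VariantMapping] = []
    for i, sv in enumerate(score.variants):
        if palindromic_policy == "drop" and sv.is_palindromic:
            report.n_palindromic_dropped += 1
            continue
        key = (sv.chrom, sv.pos) if match_by == "position" else sv.variant_id
        candidates = []
        for j in index.get(key, []):
            row = g.variants.iloc[j]
            orient = _orient(
                sv.effect_allele, sv.other_allele,
                str(row["allele_a"]).upper(), str(row["allele_b"]).upper(),
            )
            if orient is not None:
                candidates.append((j, orient))
        if len(candidates) > 1:
            raise AmbiguousVariantError(
                f"{sv.variant_id}: {len(candidates)} cohort variants match "
                f"at {key}: columns {[c[0] for c in candidates]}"
            )
        if not candidates:
            report.n_missing += 1
            continue
        j, orient = candidates[0]
        mapping.append(VariantMapping(score_index=i, column=j, orientation=orient))
        if orient == "direct":
            report.n_matched_direct += 1
        elif orient == "swapped":
            report.n_matched_swapped += 1
        else:
            report.n_matched_complement += 1
    report.validate()
    return mapping, report


# ---------------------------------------------------------------------------
# scoring


def compute_prs(
    score: ScoreFile,
    g: GenotypeMatrix,
    mapping: Sequence[VariantMapping],
    missing_policy: str = "impute_mean",
) -> PRSVector:
    """Raw PRS per sample: sum of beta_k times effect-allele dosage.

    Missing dosages are imputed at twice the sample effect-allele frequency
    (``impute_mean``, the allelic-scoring default) or set to zero
    (``zero``). The per-sample count of imputed entries is recorded.
    """
    if missing_policy not in ("impute_mean", "zero"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if len(mapping) == 0:
        raise ValueError(f"{score.pgs_id}: zero matched variants; cannot score")

    n = g.n_samples
    raw = np.zeros(n)
    n_imputed = np.zeros(n, dtype=int)
    for m in mapping:
        x = g.dosage[:, m.column]
        d = 2.0 - x if m.flip else x
        miss = np.isnan(d)
        if miss.any():
            if miss.all():
                fill = 0.0
            elif missing_policy == "impute_mean":
                fill = float(np.nanmean(d))  # = 2 x effect-allele frequency
            else:
                fill = 0.0
            d = np.where(miss, fill, d)
            n_imputed += miss
        raw += score.variants[m.score_index].weight * d
    return PRSVector(pgs_id=score.pgs_id, raw=raw, n_imputed=n_imputed)


def standardize(
    raw: np.ndarray, stratum: np.ndarray | None = None
) -> np.ndarray:
    """Z-scale a raw score: subtract the mean and divide by the SD.

    Mean and SD (ddof=1) are computed over ``stratum`` (boolean mask or
    index array; default all samples) and applied to every sample, so that
    scores standardized within e.g. the sex-specific analysis set remain
    comparable across the whole cohort.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if stratum is None else raw[stratum]
    if ref.size < 2:
        raise ValueError("standardization stratum needs at least 2 samples")
    mu = ref.mean()
    sd = ref.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate score: zero standard deviation")
    return (raw - mu) / sd


# ---------------------------------------------------------------------------
# genotype IO (TSV with metadata sidecar; VCF via cyvcf2)


def write_dosage_tsv(g: GenotypeMatrix, path, meta_path) -> None:
    """Write dosages as variants x samples TSV plus a variant-metadata sidecar."""
    header = ["chrom", "pos", "allele_a", "allele_b"] + list(g.sample_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for j in range(g.n_variants):
            row = g.variants.iloc[j]
            vals = [
                str(row["chrom"]), str(int(row["pos"])),
                str(row["allele_a"]), str(row["allele_b"]),
            ]
            col = g.dosage[:, j]
            vals += ["." if np.isnan(x) else repr(float(x)) for x in col]
            fh.write("\t".join(vals) + "\n")
    meta = g.variant_meta.copy()
    meta.insert(0, "pos", g.variants["pos"].values)
    meta.insert(0, "chrom", g.variants["chrom"].values)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(path, meta_path) -> GenotypeMatrix:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = list(tab.columns[4:])
    variants = tab[["chrom", "pos", "allele_a", "allele_b"]].copy()
    dos = tab[sample_ids].apply(pd.to_numeric, errors="coerce").to_numpy().T
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    meta = meta[list(_META_COLUMNS)]
    return GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, dosage=dos, variant_meta=meta
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal sites+DS VCF. REF = allele_a, ALT = allele_b (counted),
    so the DS field is the dosage of the ALT/counted allele. QC metadata go
    into INFO (MAF/INFO/HWE_P/CR)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        for key, desc in [
            ("MAF", "Minor allele frequency"), ("INFO_SCORE", "Imputation INFO"),
            ("HWE_P", "HWE exact p"), ("CR", "Call rate"),
        ]:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids) + "\n"
        )
        for j in range(g.n_variants):
            row = g.variants.iloc[j]
            meta = g.variant_meta.iloc[j]
            info = (
                f"MAF={meta['maf']:.6g};INFO_SCORE={meta['info']:.6g};"
                f"HWE_P={meta['hwe_p']:.6g};CR={meta['call_rate']:.6g}"
            )
            ds = ["." if np.isnan(x) else f"{x:g}" for x in g.dosage[:, j]]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['allele_a']}\t"
                f"{row['allele_b']}\t.\tPASS\t{info}\tDS\t" + "\t".join(ds) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read genotype dosages from a VCF. Uses the DS FORMAT field when
    present, else falls back to the GT allele count. Multi-allelic sites are
    kept (flagged by n_alleles) so that QC can exclude them."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, poss, ref, alt, cols, metas = [], [], [], [], [], []
    for rec in vcf:
        n_alleles = 1 + len(rec.ALT)
        alt0 = rec.ALT[0] if rec.ALT else "."
        try:
            ds = np.array(rec.format("DS"), dtype=float).reshape(-1)
        except Exception:
            ds = None
        if ds is None:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            ds = np.nansum(np.where(np.isnan(gt), np.nan, (gt > 0)), axis=1)
            ds[np.isnan(gt).all(axis=1)] = np.nan
        ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        call_rate = float(np.mean(~np.isnan(ds)))
        eaf = float(np.nanmean(ds) / 2.0) if call_rate > 0 else np.nan
        maf = min(eaf, 1 - eaf) if np.isfinite(eaf) else np.nan
        info = rec.INFO
        metas.append({
            "maf": float(info.get("MAF", maf if np.isfinite(maf) else 0.0)),
            "info": float(info.get("INFO_SCORE", info.get("INFO", 1.0) or 1.0)),
            "hwe_p": float(info.get("HWE_P", 1.0)),
            "call_rate": float(info.get("CR", call_rate)),
            "n_alleles": n_alleles,
        })
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ref.append(rec.REF)
        alt.append(alt0)
        cols.append(ds)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "allele_a": ref, "allele_b": alt}
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=np.column_stack(cols) if cols else np.empty((len(sample_ids), 0)),
        variant_meta=pd.DataFrame(metas),
    )
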