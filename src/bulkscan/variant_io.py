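"""VCF input and filtering to effective, parent-polymorphic SNPs.

Reading goes through cyvcf2.  Only biallelic SNPs are kept; multi-allelic
and indel records are skipped with counters.  The SNP-index downstream is
always the frequency of the *tolerant-parent* (HHZ) allele, so orientation
is taken from parent A's homozygous genotype at each site, never from
REF/ALT status.

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
convert to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "SampleMap",
    "FilterConfig",
    "VcfFormatError",
    "read_vcf",
    "variant_table",
    "filter_effective",
    "orient_hhz",
]

log = logging.getLogger(__name__)

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


class VcfFormatError(ValueError):
    """Malformed or unusable VCF input."""


@dataclass(frozen=True)
class SampleMap:
    """Names of the four VCF sample columns."""

    parent_a: str = "HHZ"  # tolerant parent; defines the counted allele
    parent_b: str = "9311"
    tolerant: str = "T_pool"
    sensitive: str = "S_pool"

    def indices(self, samples: list[str]) -> dict[str, int]:
        idx = {}
        for role in ("parent_a", "parent_b", "tolerant", "sensitive"):
            name = getattr(self, role)
            if name not in samples:
                raise VcfFormatError(
                    f"sample {name!r} ({role}) not in VCF samples {samples}"
                )
            idx[role] = samples.index(name)
        return idx


@dataclass
class FilterConfig:
    """Depth/genotype criteria defining an 'effective' SNP.

    The source pipeline's exact high-quality/effective cutoffs are vendor
    defaults that were never published, so these are explicit and logged.
    ``max_pool_depth`` of None means 3x the observed mean pool depth.
    """

    min_pool_depth: int = 8
    max_pool_depth: int | None = None
    min_parent_depth: int = 6
    require_parent_homozygous_opposite: bool = True

    def __post_init__(self) -> None:
        if self.min_pool_depth <= 0:
            raise ValueError("min_pool_depth must be positive")
        if self.max_pool_depth is not None and self.max_pool_depth < self.min_pool_depth:
            raise ValueError("max_pool_depth must be >= min_pool_depth")


@dataclass
class VariantRecord:
    """One biallelic SNP with parent genotypes and raw per-sample depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt_a: int  # 0 hom-ref, 1 het, 2 hom-alt, -1 missing
    gt_b: int
    dp_a: int
    dp_b: int
    t_ref: int
    t_alt: int
    s_ref: int
    s_alt: int


_GT_CODE = {_HOM_REF: 0, _HET: 1, _HOM_ALT: 2, _UNKNOWN: -1}


def read_vcf(path: str | Path, sample_map: SampleMap | None = None):
    """Yield VariantRecord for each biallelic SNP, plus a final skip report.

    This is a generator of ``VariantRecord``; attach ``.skip_report`` needs a
    materialised pass, so use :func:`variant_table` for the DataFrame + report
    pair.  Records must arrive sorted by position within each chromosome; a
    position decrease raises :class:`VcfFormatError` advising a sort.
    """
    sample_map = sample_map or SampleMap()
    vcf = VCF(str(path), gts012=True)
    idx = sample_map.indices(vcf.samples)
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        pos = v.POS
        if last.get(v.CHROM, 0) > pos:
            raise VcfFormatError(
                f"VCF not sorted at {v.CHROM}:{pos}; sort it (e.g. bcftools sort)"
            )
        last[v.CHROM] = pos
        ad = v.format("AD")
        if ad is None:
            raise VcfFormatError(f"record {v.CHROM}:{pos} lacks the AD FORMAT field")
        ad = np.where(ad < 0, 0, ad)
        gts = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        code = lambda g: -1 if g == 3 else int(g)
        ia, ib = idx["parent_a"], idx["parent_b"]
        it, is_ = idx["tolerant"], idx["sensitive"]
        yield VariantRecord(
            chrom=v.CHROM,
            pos=pos,
            ref=v.REF,
            alt=v.ALT[0],
            gt_a=code(gts[ia]),
            gt_b=code(gts[ib]),
            dp_a=int(ad[ia].sum()),
            dp_b=int(ad[ib].sum()),
            t_ref=int(ad[it, 0]),
            t_alt=int(ad[it, 1]),
            s_ref=int(ad[is_, 0]),
            s_alt=int(ad[is_, 1]),
        )


def variant_table(
    path: str | Path, sample_map: SampleMap | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Materialise :func:`read_vcf` as a DataFrame plus a skip report.

    The report counts records not yielded: multi-allelic / non-SNP.
    """
    sample_map = sample_map or SampleMap()
    vcf = VCF(str(path), gts012=True)
    sample_map.indices(vcf.samples)  # validate early
    n_total = 0
    for _ in vcf:
        n_total += 1
    records = list(read_vcf(path, sample_map))
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "gt_a", "gt_b",
                "dp_a", "dp_b", "t_ref", "t_alt", "s_ref", "s_alt",
            ]
        )
    report = {"input": n_total, "kept": len(df), "skipped_non_biallelic_snp": n_total - len(df)}
    return df, report


def filter_effective(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep sites usable for the SNP-index scan; report removals per rule.

    Rules (first failing rule attributed, so counts + kept == input):
    parents genotyped, parents opposite homozygotes, parent depth, pool depth
    window.  Idempotent by construction.
    """
    cfg = cfg or FilterConfig()
    df = records
    n = len(df)
    if n == 0:
        log.warning("filter_effective received an empty table")
        return df.copy(), {"input": 0, "kept": 0}

    t_depth = df["t_ref"] + df["t_alt"]
    s_depth = df["s_ref"] + df["s_alt"]
    max_depth = cfg.max_pool_depth
    if max_depth is None:
        max_depth = int(np.ceil(3.0 * float((t_depth.mean() + s_depth.mean()) / 2)))

    parent_missing = (df["gt_a"] == -1) | (df["gt_b"] == -1)
    parent_het = ~parent_missing & ((df["gt_a"] == 1) | (df["gt_b"] == 1))
    considered = ~parent_missing & ~parent_het
    not_opposite = considered & (df["gt_a"] == df["gt_b"])
    if not cfg.require_parent_homozygous_opposite:
        parent_het[:] = False
        not_opposite[:] = False
        considered = ~parent_missing
    parent_low = (
        considered
        & ~not_opposite
        & ((df["dp_a"] < cfg.min_parent_depth) | (df["dp_b"] < cfg.min_parent_depth))
    )
    so_far = parent_missing | parent_het | not_opposite | parent_low
    pool_low = ~so_far & ((t_depth < cfg.min_pool_depth) | (s_depth < cfg.min_pool_depth))
    so_far |= pool_low
    pool_high = ~so_far & ((t_depth > max_depth) | (s_depth > max_depth))
    keep = ~(so_far | pool_high)

    report = {
        "input": n,
        "parent_missing": int(parent_missing.sum()),
        "parent_het": int(parent_het.sum()),
        "parent_not_opposite": int(not_opposite.sum()),
        "parent_low_depth": int(parent_low.sum()),
        "pool_low_depth": int(pool_low.sum()),
        "pool_high_depth": int(pool_high.sum()),
        "kept": int(keep.sum()),
        "max_pool_depth_used": int(max_depth),
    }
    if report["kept"] == 0:
        log.warning("no sites passed filtering: %s", report)
    return df[keep].reset_index(drop=True), report


def orient_hhz(records: pd.DataFrame) -> pd.DataFrame:
    """Add HHZ-oriented pool counts: n_hhz_t/s and depth_t/s.

    Orientation comes from parent A's homozygous genotype (hom-ref: HHZ allele
    is REF).  Sites where parent A is not homozygous are dropped — they have
    no defined HHZ allele.
    """
    df = records[records["gt_a"].isin([0, 2])].reset_index(drop=True).copy()
    hhz_is_ref = df["gt_a"] == 0
    df["depth_t"] = df["t_ref"] + df["t_alt"]
    df["depth_s"] = df["s_ref"] + df["s_alt"]
    df["n_hhz_t"] = np.where(hhz_is_ref, df["t_ref"], df["t_alt"])
    df["n_hhz_s"] = np.where(hhz_is_ref, df["s_ref"], df["s_alt"])
    return df


def write_effective_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Export oriented effective sites as TSV."""
    cols = ["chrom", "pos", "n_hhz_t", "depth_t", "n_hhz_s", "depth_s"]
    df[cols].to_csv(path, sep="\t", index=False)
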