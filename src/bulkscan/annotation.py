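"""Gene models under candidate regions and per-gene variant counts.

GFF3 parsing goes through gffutils (in-memory database).  A gene belongs to
a region when its span overlaps it by at least 1 bp — genes straddling a
boundary are included, matching how mapped intervals are reported by
physical location rather than by CDS containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from urllib.parse import unquote

import gffutils
import numpy as np
import pandas as pd

__all__ = ["GeneModel", "genes_in_region", "variants_per_gene", "read_gene_models"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def _validate_gff_lines(gff_path: str | Path) -> None:
    # gffutils drops malformed lines silently; fail loudly with the line number
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 line {lineno} in {gff_path}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )


def read_gene_models(gff_path: str | Path, featuretype: str = "gene") -> list[GeneModel]:
    """All gene features from a GFF3 file, sorted by (chrom, start)."""
    _validate_gff_lines(gff_path)
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps line errors variously
        raise ValueError(f"failed to parse GFF3 {gff_path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type(featuretype):
        desc = feat.attributes.get("description", [""])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                description=unquote(desc),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def genes_in_region(
    gff_path: str | Path,
    chrom: str,
    start: int,
    end: int,
    exclude_descriptions: tuple[str, ...] = (),
) -> list[GeneModel]:
    """Genes overlapping [start, end] (1-based inclusive) by >= 1 bp.

    ``exclude_descriptions`` drops genes whose description contains any of
    the given substrings (e.g. 'retrotransposon protein'); exclusion happens
    after the interval intersection.
    """
    genes = read_gene_models(gff_path)
    if chrom not in {g.chrom for g in genes}:
        log.warning("chromosome %s absent from %s; empty gene list", chrom, gff_path)
        return []
    hits = [
        g
        for g in genes
        if g.chrom == chrom and g.start <= end and g.end >= start
    ]
    if exclude_descriptions:
        hits = [
            g
            for g in hits
            if not any(pat in g.description for pat in exclude_descriptions)
        ]
    return hits


def variants_per_gene(
    sites: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Count distinct variant positions overlapping each gene span.

    ``sites`` needs chrom and pos columns (1-based), sorted by position
    within chromosome.  Duplicate positions are counted once (and logged).
    The returned table carries one row per gene plus one ``intergenic`` row
    per chromosome, so totals are conserved against the region-wide count.
    A position inside two overlapping genes counts toward both genes but
    once toward the chromosome total.
    """
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = np.unique(sub["pos"].to_numpy())
        if len(pos) != len(sub):
            log.info(
                "%s: %d duplicate variant positions deduplicated",
                chrom,
                len(sub) - len(pos),
            )
        in_any = np.zeros(pos.size, dtype=bool)
        for g in genes:
            if g.chrom != chrom:
                continue
            lo, hi = np.searchsorted(pos, [g.start, g.end + 1])
            in_any[lo:hi] = True
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": chrom,
                    "start": g.start,
                    "end": g.end,
                    "description": g.description,
                    "n_variants": int(hi - lo),
                }
            )
        rows.append(
            {
                "gene_id": "intergenic",
                "chrom": chrom,
                "start": np.nan,
                "end": np.nan,
                "description": "",
                "n_variants": int((~in_any).sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "description", "n_variants"],
    )
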