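"""Synthetic bulked-segregant datasets with known ground truth.

Emulates the statistical structure of an F2 / F2:3 QTL-seq experiment in
rice: a biparental cross between a tolerant parent (HHZ) and a sensitive
parent (9311), 365 F2 plants genotyped implicitly through pooled short-read
sequencing of the 50 phenotypically most extreme plants per tail, and a
spikelet-fertility phenotype scored as the mean of a small F3 family grown
from each F2 plant.

Meiosis uses a Poisson crossover process with the Haldane (no-interference)
map function; the physical-to-genetic scale defaults to 250 kb/cM, the
genome-wide average for rice.  Pooled reads are sampled per site as
``depth ~ Poisson(mean_depth)`` and
``reads_HHZ ~ Binomial(depth, f(1-eps) + (1-f)eps)`` where ``f`` is the true
HHZ-allele frequency among the pooled plants and ``eps`` a per-read miscall
probability.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` substreams, so a dataset is byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimConfig",
    "F2Genotype",
    "SimTruth",
    "SimulationError",
    "simulate_f2",
    "simulate_phenotypes",
    "simulate_pool_reads",
    "simulate_dataset",
    "simulate_ct_table",
    "write_vcf",
    "write_gff3",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


#: Approximate IRGSP chromosome lengths (bp) for Oryza sativa.
RICE_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 43_300_000,
    "chr2": 35_900_000,
    "chr3": 36_400_000,
    "chr4": 35_500_000,
    "chr5": 29_900_000,
    "chr6": 31_200_000,
    "chr7": 29_700_000,
    "chr8": 28_400_000,
    "chr9": 23_000_000,
    "chr10": 23_200_000,
    "chr11": 29_000_000,
    "chr12": 27_500_000,
}


@dataclass(frozen=True)
class SimConfig:
    """Study design and sampling parameters for one synthetic experiment.

    Defaults reproduce the design of the mapping study the package targets:
    365 F2 plants, bulks of 50, one major fertility QTL on chromosome 8 at
    4.0 Mb, pool depth ~57x, parent depth ~36x, and a residual SD tuned so
    the total phenotype SD is ~0.1847 on the proportion scale.
    """

    n_f2: int = 365
    bulk_size: int = 50
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(RICE_CHROM_LENGTHS)
    )
    snp_density: float = 20.0  # informative SNPs per Mb
    #: (chrom, pos bp, additive effect a, dominance effect d), fertility scale
    qtl: tuple[tuple[str, int, float, float], ...] = (
        ("chr8", 4_000_000, 0.18, 0.0),
    )
    baseline_mu: float = 0.50
    resid_sd: float = 0.131  # family-mean residual SD; see docs/methods.md
    f3_family_size: int = 12
    panicle_grains: int = 200
    fully_filled_fraction: float = 0.9  # of filled grains, rest partial
    mean_depth_pool: float = 57.0
    mean_depth_parent: float = 36.0
    seq_error: float = 0.001
    bp_per_cm: float = 250_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 <= 0:
            raise SimulationError("n_f2 must be positive")
        if not (0 < self.bulk_size <= self.n_f2 // 2):
            raise SimulationError("bulk_size must satisfy 0 < bulk_size <= n_f2/2")
        if not self.chrom_lengths:
            raise SimulationError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise SimulationError(f"chromosome {chrom} has non-positive length")
        if not (0.0 <= self.seq_error < 0.5):
            raise SimulationError("seq_error must lie in [0, 0.5)")
        if not self.bp_per_cm > 0:
            raise SimulationError("bp_per_cm must be positive")
        for chrom, pos, _a, _d in self.qtl:
            if chrom not in self.chrom_lengths:
                raise SimulationError(f"QTL chromosome {chrom!r} not in chrom_lengths")
            if not (1 <= pos <= self.chrom_lengths[chrom]):
                raise SimulationError(f"QTL position {pos} outside {chrom}")

    def rng(self, *stream: object) -> np.random.Generator:
        """Named deterministic substream of the root seed (process-independent)."""
        key = tuple(zlib.crc32(repr(s).encode()) for s in stream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key)
        )


@dataclass
class F2Genotype:
    """Dosage of the HHZ allele (0/1/2) at every marker for one plant."""

    plant_id: int
    dosage: np.ndarray  # int8, aligned to the marker table


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    qtl: list[tuple[str, int, float, float]]
    fertility: np.ndarray  # per-plant true fertility proportion
    tolerant_ids: list[int]
    sensitive_ids: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "qtl": [
                    {"chrom": c, "pos": int(p), "a": a, "d": d}
                    for c, p, a, d in self.qtl
                ],
                "fertility": [round(float(x), 6) for x in self.fertility],
                "tolerant_ids": [int(i) for i in self.tolerant_ids],
                "sensitive_ids": [int(i) for i in self.sensitive_ids],
            },
            indent=1,
        )


def marker_table(config: SimConfig) -> pd.DataFrame:
    """Marker positions per chromosome (QTL positions always included).

    Columns: chrom, pos, is_qtl.  Positions are unique and sorted within
    each chromosome; the count per chromosome is ``length * snp_density/Mb``.
    """
    rng = config.rng("markers")
    frames = []
    qtl_by_chrom: dict[str, set[int]] = {}
    for chrom, pos, _a, _d in config.qtl:
        qtl_by_chrom.setdefault(chrom, set()).add(pos)
    for chrom, length in config.chrom_lengths.items():
        n = int(round(length * config.snp_density / 1e6))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        qtl_pos = np.array(sorted(qtl_by_chrom.get(chrom, ())), dtype=np.int64)
        pos = np.unique(np.concatenate([pos, qtl_pos]))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "is_qtl": np.isin(pos, qtl_pos),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _gametes(
    positions: np.ndarray,
    length: int,
    n_gametes: int,
    morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample F1 gametes: haplotype (1=HHZ) at each position, (n_gametes, n_snps).

    Crossovers fall as a Poisson process along the chromosome (Haldane model,
    no interference); the starting parental phase of each gamete is fair.
    """
    n_snps = positions.size
    out = np.empty((n_gametes, n_snps), dtype=np.int8)
    n_co = rng.poisson(morgans, size=n_gametes)
    phase = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_co[g] == 0:
            out[g] = phase[g]
            continue
        breaks = np.sort(rng.uniform(0, length, size=n_co[g]))
        crossings = np.searchsorted(breaks, positions)
        out[g] = (phase[g] + crossings) % 2
    return out


def simulate_f2(
    config: SimConfig, markers: pd.DataFrame | None = None
) -> list[F2Genotype]:
    """Simulate F2 genotypes: each plant is the union of two independent gametes."""
    if markers is None:
        markers = marker_table(config)
    n = config.n_f2
    dosage = np.empty((n, len(markers)), dtype=np.int8)
    for chrom, sub in markers.groupby("chrom", sort=False):
        length = config.chrom_lengths[chrom]
        morgans = length / (config.bp_per_cm * 100.0)
        if not math.isfinite(morgans):
            raise SimulationError("bp_per_cm produced a non-finite map length")
        rng = config.rng("meiosis", chrom)
        gam = _gametes(sub["pos"].to_numpy(), length, 2 * n, morgans, rng)
        dosage[:, sub.index] = gam[:n] + gam[n:]
    return [F2Genotype(plant_id=i, dosage=dosage[i]) for i in range(n)]


def _qtl_effect(
    dosage_at_qtl: np.ndarray, a: float, d: float
) -> np.ndarray:
    """Genetic value of one locus: a*(dosage-1) + d*[dosage==1]."""
    return a * (dosage_at_qtl - 1.0) + d * (dosage_at_qtl == 1)


def simulate_phenotypes(
    genotypes: list[F2Genotype],
    config: SimConfig,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fertility proportions and grain counts per plant.

    The phenotype of plant *i* mimics F2:3 family-mean scoring: the genetic
    value is averaged over ``f3_family_size`` selfed progeny of the F2 plant
    (progeny dosage at a heterozygous locus segregates 1:2:1), a family-level
    residual ``Normal(0, resid_sd)`` is added to ``baseline_mu``, and the sum
    is clamped to [0, 1].  Grain counts are drawn per plant as
    ``filled ~ Binomial(panicle_grains, fertility)`` and split into fully and
    partially filled at ``fully_filled_fraction``.

    Returns a DataFrame: plant_id, fertility (proportion), N_FG, N_PG, N_EG.
    """
    if markers is None:
        markers = marker_table(config)
    rng = config.rng("phenotype")
    n = len(genotypes)
    m = config.f3_family_size
    genetic = np.zeros(n)
    for chrom, pos, a, d in config.qtl:
        idx = markers.index[(markers["chrom"] == chrom) & (markers["pos"] == pos)]
        (j,) = idx.to_numpy()
        dos = np.array([g.dosage[j] for g in genotypes], dtype=np.int64)
        if m <= 1:
            genetic += _qtl_effect(dos.astype(float), a, d)
        else:
            # selfed progeny of a het parent segregate 1:2:1; homozygotes breed true
            prog = np.where(
                (dos == 1)[:, None],
                rng.binomial(2, 0.5, size=(n, m)),
                dos[:, None],
            )
            genetic += _qtl_effect(prog.astype(float), a, d).mean(axis=1)
    resid = rng.normal(0.0, config.resid_sd, size=n) if config.resid_sd > 0 else 0.0
    fertility = np.clip(config.baseline_mu + genetic + resid, 0.0, 1.0)

    filled = rng.binomial(config.panicle_grains, fertility)
    n_fg = rng.binomial(filled, config.fully_filled_fraction)
    n_pg = filled - n_fg
    n_eg = config.panicle_grains - filled
    return pd.DataFrame(
        {
            "plant_id": [g.plant_id for g in genotypes],
            "fertility": fertility,
            "N_FG": n_fg,
            "N_PG": n_pg,
            "N_EG": n_eg,
        }
    )


def simulate_pool_reads(
    genotypes: list[F2Genotype],
    bulk_members: dict[str, list[int]],
    config: SimConfig,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pooled and parental read counts at every marker.

    ``bulk_members`` maps pool name ('T', 'S') to lists of plant ids.  The
    true pool HHZ frequency at a site is the mean dosage over members / 2;
    read support adds the symmetric miscall ``f(1-eps) + (1-f)eps``.

    Returns the site table with, per pool P in {t, s}: ``P_hhz`` (reads
    supporting the HHZ allele) and ``P_depth``; and parental depths/support;
    plus the REF/ALT encoding used when the table is written to VCF
    (``hhz_is_ref``, ``ref``, ``alt``).
    """
    if markers is None:
        markers = marker_table(config)
    for name, members in bulk_members.items():
        if len(members) == 0:
            raise SimulationError(f"bulk {name!r} is empty")
    by_id = {g.plant_id: g for g in genotypes}
    missing = {
        m for members in bulk_members.values() for m in members if m not in by_id
    }
    if missing:
        raise SimulationError(f"bulk members not among plants: {sorted(missing)[:5]}")

    eps = config.seq_error
    rng = config.rng("reads")
    n_sites = len(markers)
    out = markers.copy()

    # REF/ALT orientation is random so downstream code must orient by parent
    hhz_is_ref = rng.integers(0, 2, size=n_sites).astype(bool)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    out["hhz_is_ref"] = hhz_is_ref
    out["ref"] = bases[ref_idx]
    out["alt"] = bases[alt_idx]

    for name, members in bulk_members.items():
        dos = np.stack([by_id[m].dosage for m in members]).astype(np.int64)
        f = dos.sum(axis=0) / (2.0 * len(members))
        depth = rng.poisson(config.mean_depth_pool, size=n_sites)
        p = f * (1 - eps) + (1 - f) * eps
        hhz = rng.binomial(depth, p)
        key = name.lower()
        out[f"{key}_depth"] = depth
        out[f"{key}_hhz"] = hhz

    # parents: fixed opposite homozygotes (HHZ carries the HHZ allele)
    for key, p_hhz in (("pa", 1.0 - eps), ("pb", eps)):
        depth = rng.poisson(config.mean_depth_parent, size=n_sites)
        out[f"{key}_depth"] = depth
        out[f"{key}_hhz"] = rng.binomial(depth, p_hhz)
    return out


def write_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    config: SimConfig,
    sample_names: tuple[str, str, str, str] = ("HHZ", "9311", "T_pool", "S_pool"),
) -> None:
    """Write the simulated site table as an uncompressed VCF v4.2 with AD/DP."""
    header = pysam.VariantHeader()
    for chrom, length in config.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in sample_names:
        header.add_sample(s)
    name_a, name_b, name_t, name_s = sample_names
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sites.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=row.pos - 1,
                stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            # HHZ-supporting reads go to REF or ALT depending on orientation
            def _ad(hhz: int, depth: int) -> tuple[int, int]:
                other = depth - hhz
                return (hhz, other) if row.hhz_is_ref else (other, hhz)

            gt_a = (0, 0) if row.hhz_is_ref else (1, 1)
            gt_b = (1, 1) if row.hhz_is_ref else (0, 0)
            rec.samples[name_a]["GT"] = gt_a
            rec.samples[name_b]["GT"] = gt_b
            rec.samples[name_t]["GT"] = (None, None)
            rec.samples[name_s]["GT"] = (None, None)
            for name, hhz, depth in (
                (name_a, row.pa_hhz, row.pa_depth),
                (name_b, row.pb_hhz, row.pb_depth),
                (name_t, row.t_hhz, row.t_depth),
                (name_s, row.s_hhz, row.s_depth),
            ):
                rec.samples[name]["AD"] = _ad(int(hhz), int(depth))
                rec.samples[name]["DP"] = int(depth)
            vcf.write(rec)


def write_gff3(
    config: SimConfig,
    path: str | Path,
    gene_spacing: int = 15_000,
    gene_length: int = 3_000,
) -> pd.DataFrame:
    """Write synthetic, non-overlapping gene models covering the genome.

    Gene density (one gene per ``gene_spacing`` bp) approximates the rice
    annotation, where a ~1 Mb region holds ~65 genes.  Returns the gene table.
    """
    rng = config.rng("genes")
    descriptions = [
        "expressed protein",
        "hypothetical protein",
        "transporter domain containing protein, expressed",
        "AP2 domain containing protein, expressed",
        "transcription factor, putative, expressed",
        "receptor kinase precursor, putative, expressed",
        "retrotransposon protein",
    ]
    rows = []
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
            k = 0
            for start0 in range(1, length - gene_length, gene_spacing):
                k += 1
                jitter = int(rng.integers(0, gene_spacing - gene_length))
                start = start0 + jitter
                end = start + gene_length - 1
                gene_id = f"SimGene_{chrom}_{k:05d}"
                strand = "+" if rng.integers(0, 2) else "-"
                desc = descriptions[int(rng.integers(0, len(descriptions)))]
                fh.write(
                    f"{chrom}\tbulkscan_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gene_id};description={desc.replace(' ', '%20')}\n"
                )
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "description": desc,
                    }
                )
    return pd.DataFrame(rows)


def simulate_ct_table(
    seed: int = 0,
    genes: tuple[str, ...] = ("SimGene_chr8_00261", "SimGene_chr8_00278"),
    induced_fold: float = 4.0,
    timepoints: int = 6,
    replicates: int = 3,
    ref_gene: str = "UBQ",
    tech_sd: float = 0.12,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for two genotypes under heat stress.

    Target genes are induced ``induced_fold``-fold in the tolerant genotype
    (HHZ) relative to the sensitive one (9311) at every timepoint; the
    reference gene is flat.  Ct noise is normal with SD ``tech_sd`` cycles.
    Columns: sample, gene, timepoint, replicate, ct.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
    rows = []
    for tp in range(1, timepoints + 1):
        for sample in ("HHZ", "9311"):
            for gene in genes + (ref_gene,):
                if gene == ref_gene:
                    base = 20.0
                else:
                    base = 26.0
                    if sample == "HHZ":
                        base -= math.log2(induced_fold)
                for rep in range(1, replicates + 1):
                    ct = base + rng.normal(0.0, tech_sd)
                    rows.append(
                        {
                            "sample": sample,
                            "gene": gene,
                            "timepoint": f"T{tp}",
                            "replicate": rep,
                            "ct": round(float(ct), 3),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every artifact to ``out_dir``.

    Writes: markers VCF (``variants.vcf``), phenotype TSV (``phenotypes.tsv``),
    bulk membership TSV (``bulks.tsv``), gene models (``genes.gff3``), truth
    JSON (``truth.json``) and a metadata JSON with the config snapshot.
    Returns the path map.
    """
    from . import phenotyping  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers = marker_table(config)
    genotypes = simulate_f2(config, markers)
    pheno = simulate_phenotypes(genotypes, config, markers)

    fert_pct = pheno.set_index("plant_id")["fertility"] * 100.0
    design = phenotyping.select_bulks(fert_pct, config.bulk_size)
    bulks = {"T": design.tolerant_ids, "S": design.sensitive_ids}
    sites = simulate_pool_reads(genotypes, bulks, config, markers)

    paths = {
        "vcf": out / "variants.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "bulks": out / "bulks.tsv",
        "gff3": out / "genes.gff3",
        "truth": out / "truth.json",
        "meta": out / "sim_meta.json",
    }
    write_vcf(sites, paths["vcf"], config)
    pheno_out = pheno.copy()
    pheno_out["fertility_percent"] = (pheno_out.pop("fertility") * 100.0).round(4)
    pheno_out.to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        {
            "plant_id": design.tolerant_ids + design.sensitive_ids,
            "bulk": ["T"] * len(design.tolerant_ids)
            + ["S"] * len(design.sensitive_ids),
        }
    ).to_csv(paths["bulks"], sep="\t", index=False)
    write_gff3(config, paths["gff3"])
    truth = SimTruth(
        qtl=list(config.qtl),
        fertility=pheno["fertility"].to_numpy(),
        tolerant_ids=design.tolerant_ids,
        sensitive_ids=design.sensitive_ids,
    )
    paths["truth"].write_text(truth.to_json())
    cfg = dataclasses.asdict(config)
    cfg["qtl"] = [list(q) for q in config.qtl]
    paths["meta"].write_text(json.dumps({"config": cfg}, indent=1))
    return paths
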