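"""End-to-end orchestration with a YAML config and a run manifest.

Stages run in dependency order: simulate -> phenotype -> scan -> regions ->
annotate (-> qpcr); any contiguous subset can be requested, provided the
config names the inputs each requested stage needs.  Every run writes a
JSON manifest recording the tool version, the config snapshot, SHA-256
checksums of the inputs, the root seed, per-stage runtimes and output
paths; deterministic stages reproduce byte-identical outputs when re-run
from the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, phenotyping, variant_io
from .annotation import genes_in_region, variants_per_gene
from .qpcr import compare_genotypes, fold_changes, read_ct_table
from .scan import ScanConfig, sliding_windows, snp_index_table
from .significance import (
    NullConfig,
    RegionCriteria,
    call_regions,
    regions_to_bed,
    regions_to_frame,
    threshold_for_windows,
)
from .simulate import SimConfig, simulate_dataset

__all__ = ["PipelineError", "RunManifest", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "phenotype", "scan", "regions", "annotate", "qpcr")


class PipelineError(RuntimeError):
    """Configuration or stage failure."""


@dataclass
class RunManifest:
    version: str
    config: dict
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_runtimes: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg.get("simulate", {}))
    if "qtl" in sim:
        sim["qtl"] = tuple(tuple(q) for q in sim["qtl"])
    if "seed" not in sim and "seed" in cfg:
        sim["seed"] = cfg["seed"]
    return SimConfig(**sim)


def run_pipeline(
    config_path: str | Path, out_dir: str | Path | None = None
) -> RunManifest:
    """Execute the stages listed in the config; write and return the manifest."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    stages = cfg.get("stages", list(STAGE_ORDER))
    bad = set(stages) - set(STAGE_ORDER)
    if bad:
        raise PipelineError(f"unknown stages: {sorted(bad)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    out = Path(out_dir or cfg.get("out_dir", "bulkscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(version=__version__, config=cfg, seed=seed)
    manifest_path = out / "manifest.json"

    # resolve the stage input chain before any work
    paths: dict[str, Path] = {}
    if "simulate" in stages:
        pass  # produces vcf/phenotypes/gff3 below
    else:
        if "scan" in stages:
            if "vcf" not in cfg:
                raise PipelineError("scan stage requires 'vcf' in config")
            paths["vcf"] = Path(cfg["vcf"])
        if "phenotype" in stages:
            if "phenotypes" not in cfg:
                raise PipelineError("phenotype stage requires 'phenotypes' in config")
            paths["phenotypes"] = Path(cfg["phenotypes"])
        if "annotate" in stages and "gff3" not in cfg:
            raise PipelineError("annotate stage requires 'gff3' in config")
    if "qpcr" in stages and "ct_table" not in cfg:
        raise PipelineError("qpcr stage requires 'ct_table' in config")

    windows = thresholds = regions = None
    try:
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "simulate":
                sim_cfg = _sim_config(cfg)
                sim_paths = simulate_dataset(sim_cfg, out / "sim")
                paths.update(sim_paths)
                for key in ("vcf", "phenotypes", "gff3"):
                    manifest.outputs[key] = str(sim_paths[key])
            elif stage == "phenotype":
                pheno = phenotyping.read_phenotypes(paths["phenotypes"])
                stats = phenotyping.summarize(
                    pheno["fertility_percent"] / 100.0, scale="proportion"
                )
                design = phenotyping.select_bulks(
                    pheno.set_index("plant_id")["fertility_percent"],
                    int(cfg.get("bulk_size", 50)),
                )
                (out / "phenotype_summary.json").write_text(
                    json.dumps(
                        {
                            "stats": dataclasses.asdict(stats),
                            "tolerant_range": design.tolerant_range,
                            "sensitive_range": design.sensitive_range,
                        },
                        indent=1,
                    )
                )
                manifest.outputs["phenotype_summary"] = str(out / "phenotype_summary.json")
            elif stage == "scan":
                sample_map = variant_io.SampleMap(**cfg.get("samples", {}))
                table, read_report = variant_io.variant_table(paths["vcf"], sample_map)
                fcfg = variant_io.FilterConfig(**cfg.get("filter", {}))
                kept, filter_report = variant_io.filter_effective(table, fcfg)
                oriented = variant_io.orient_hhz(kept)
                index_tbl = snp_index_table(oriented)
                scan_cfg = ScanConfig(**cfg.get("scan", {}))
                chrom_lengths = cfg.get("chrom_lengths")
                if chrom_lengths is None:
                    if "simulate" in stages:
                        chrom_lengths = _sim_config(cfg).chrom_lengths
                    else:
                        chrom_lengths = (
                            index_tbl.groupby("chrom", sort=False)["pos"].max().to_dict()
                        )
                windows = sliding_windows(index_tbl, scan_cfg, chrom_lengths)
                index_tbl.drop(columns=["is_qtl", "hhz_is_ref"], errors="ignore").to_csv(
                    out / "snp_index.tsv", sep="\t", index=False
                )
                windows.to_csv(out / "windows.tsv", sep="\t", index=False)
                (out / "filter_report.json").write_text(
                    json.dumps({"read": read_report, "filter": filter_report}, indent=1)
                )
                manifest.outputs["windows"] = str(out / "windows.tsv")
                manifest.outputs["snp_index"] = str(out / "snp_index.tsv")
                manifest.outputs["filter_report"] = str(out / "filter_report.json")
            elif stage == "regions":
                if windows is None:
                    raise PipelineError("regions stage requires the scan stage")
                null_cfg = NullConfig(
                    bulk_size=int(cfg.get("bulk_size", 50)),
                    seed=seed,
                    **cfg.get("null", {}),
                )
                thresholds = threshold_for_windows(windows, null_cfg)
                criteria = RegionCriteria(**cfg.get("regions", {}))
                regions = call_regions(
                    windows, thresholds, criteria, step=ScanConfig(**cfg.get("scan", {})).step
                )
                frame = regions_to_frame(regions)
                frame.to_csv(out / "regions.tsv", sep="\t", index=False)
                regions_to_bed(regions, out / "regions.bed")
                thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
                manifest.outputs["regions"] = str(out / "regions.tsv")
                manifest.outputs["regions_bed"] = str(out / "regions.bed")
                manifest.outputs["thresholds"] = str(out / "thresholds.tsv")
            elif stage == "annotate":
                if regions is None:
                    raise PipelineError("annotate stage requires the regions stage")
                gff = paths.get("gff3", Path(cfg.get("gff3", "")))
                gene_rows = []
                for r in regions:
                    genes = genes_in_region(gff, r.chrom, r.start, r.end)
                    gene_rows.append((r, genes))
                reports = []
                for r, genes in gene_rows:
                    reports.append(
                        pd.DataFrame(
                            {
                                "region": f"{r.chrom}:{r.start}-{r.end}",
                                "gene_id": [g.gene_id for g in genes],
                                "description": [g.description for g in genes],
                                "location": [f"{g.start}-{g.end}" for g in genes],
                            }
                        )
                    )
                genes_tsv = out / "region_genes.tsv"
                if reports:
                    pd.concat(reports, ignore_index=True).to_csv(
                        genes_tsv, sep="\t", index=False
                    )
                else:
                    genes_tsv.write_text("region\tgene_id\tdescription\tlocation\n")
                manifest.outputs["region_genes"] = str(genes_tsv)
            elif stage == "qpcr":
                ct = read_ct_table(cfg["ct_table"])
                q = cfg.get("qpcr", {})
                reference = q.get("reference_gene", "UBQ")
                calibrator = tuple(
                    q.get("calibrator")
                    or (q.get("sensitive_sample", "9311"), sorted(ct["timepoint"])[0])
                )
                folds = fold_changes(ct, reference, calibrator)
                comparisons = compare_genotypes(
                    folds,
                    q.get("tolerant_sample", "HHZ"),
                    q.get("sensitive_sample", "9311"),
                    welch=bool(q.get("welch", False)),
                )
                folds.drop(columns=["replicate_folds"]).to_csv(
                    out / "qpcr_folds.tsv", sep="\t", index=False
                )
                comparisons.to_csv(out / "qpcr_tests.tsv", sep="\t", index=False)
                manifest.outputs["qpcr_folds"] = str(out / "qpcr_folds.tsv")
                manifest.outputs["qpcr_tests"] = str(out / "qpcr_tests.tsv")
            manifest.stage_runtimes[stage] = round(time.perf_counter() - t0, 4)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(manifest_path)
        raise

    for key, p in paths.items():
        p = Path(p)
        if p.is_file():
            manifest.input_checksums[key] = _sha256(p)
    manifest.write(manifest_path)
    return manifest
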