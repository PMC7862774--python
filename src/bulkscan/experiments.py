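"""Seeded end-to-end calibration experiments on synthetic data.

Two standing experiments characterise the scan + threshold + region-calling
stack under known truth, both on a reduced genome (3 chromosomes x 10 Mb,
20 SNPs/Mb) with the full study design (365 F2 plants, bulks of 50, 57x
pools):

* recovery — one planted fertility QTL (additive effect 0.18 on the
  chromosome-8 analog at 4.0 Mb); did region calling find it, and where?
* null — no QTL; how often do windows exceed the 99.9% threshold, and are
  any regions called at all under the 0.7/0.3 pool-index criteria?

Problem sizes are chosen so a 20-seed batch of either experiment completes
in a few minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phenotyping
from .scan import ScanConfig, sliding_windows, snp_index_table
from .significance import (
    NullConfig,
    RegionCriteria,
    call_regions,
    threshold_for_windows,
)
from .simulate import SimConfig, marker_table, simulate_f2, simulate_phenotypes, simulate_pool_reads

__all__ = [
    "scaled_config",
    "run_scan_on_config",
    "recovery_experiment",
    "null_experiment",
    "RecoveryResult",
    "NullResult",
]

SCALED_CHROMS = {"chr2": 10_000_000, "chr8": 10_000_000, "chr11": 10_000_000}
TRUE_QTL = ("chr8", 4_000_000, 0.18, 0.0)


def scaled_config(seed: int, with_qtl: bool = True) -> SimConfig:
    """Reduced-genome study configuration used by the experiments."""
    return SimConfig(
        chrom_lengths=dict(SCALED_CHROMS),
        qtl=(TRUE_QTL,) if with_qtl else (),
        seed=seed,
    )


def run_scan_on_config(
    config: SimConfig,
    scan_cfg: ScanConfig | None = None,
    null_cfg: NullConfig | None = None,
    criteria: RegionCriteria | None = None,
):
    """Simulate -> bulk -> pool-read -> window scan -> thresholds -> regions.

    Works directly on the in-memory site table (no VCF round trip; that path
    is exercised by the pipeline and its tests).  Returns (windows,
    thresholds, regions).
    """
    scan_cfg = scan_cfg or ScanConfig()
    null_cfg = null_cfg or NullConfig(bulk_size=config.bulk_size, seed=config.seed)
    markers = marker_table(config)
    genotypes = simulate_f2(config, markers)
    pheno = simulate_phenotypes(genotypes, config, markers)
    fert = pheno.set_index("plant_id")["fertility"] * 100.0
    design = phenotyping.select_bulks(fert, config.bulk_size)
    sites = simulate_pool_reads(
        genotypes,
        {"T": design.tolerant_ids, "S": design.sensitive_ids},
        config,
        markers,
    )
    oriented = sites.rename(
        columns={"t_hhz": "n_hhz_t", "s_hhz": "n_hhz_s",
                 "t_depth": "depth_t", "s_depth": "depth_s"}
    )
    index_tbl = snp_index_table(oriented)
    windows = sliding_windows(index_tbl, scan_cfg, config.chrom_lengths)
    thresholds = threshold_for_windows(windows, null_cfg)
    regions = call_regions(windows, thresholds, criteria, step=scan_cfg.step)
    return windows, thresholds, regions


@dataclass
class RecoveryResult:
    n_seeds: int
    n_with_overlapping_region: int
    n_best_midpoint_within_window: int
    midpoint_errors_bp: list[float] = field(default_factory=list)
    peak_errors_bp: list[float] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        return self.n_with_overlapping_region / self.n_seeds


def recovery_experiment(
    n_seeds: int = 20, seed0: int = 1, window: int = 500_000
) -> RecoveryResult:
    """Planted-QTL recovery over seeded replicates.

    A replicate 'recovers' the QTL when at least one called region on the
    true chromosome overlaps the true position.  The best region is the one
    with the largest peak window Δ; its midpoint and peak-window position
    are compared with the truth.
    """
    chrom_q, pos_q, _a, _d = TRUE_QTL
    res = RecoveryResult(n_seeds=n_seeds, n_with_overlapping_region=0,
                         n_best_midpoint_within_window=0)
    for k in range(n_seeds):
        config = scaled_config(seed=seed0 + k, with_qtl=True)
        _w, _t, regions = run_scan_on_config(config)
        hits = [
            r for r in regions
            if r.chrom == chrom_q and r.start <= pos_q <= r.end
        ]
        if hits:
            res.n_with_overlapping_region += 1
        if regions:
            best = max(regions, key=lambda r: r.peak_delta)
            err_mid = abs(best.midpoint - pos_q) if best.chrom == chrom_q else np.inf
            err_peak = abs(best.peak_pos - pos_q) if best.chrom == chrom_q else np.inf
            res.midpoint_errors_bp.append(float(err_mid))
            res.peak_errors_bp.append(float(err_peak))
            if err_mid <= window:
                res.n_best_midpoint_within_window += 1
    return res


@dataclass
class NullResult:
    n_seeds: int
    exceedance_fractions: list[float]
    n_seeds_with_regions: int

    @property
    def mean_exceedance(self) -> float:
        return float(np.mean(self.exceedance_fractions))


def snp_index_bias_experiment(seed: int = 17, n_chroms: int = 520) -> tuple[float, float, int]:
    """Mean pooled SNP-index at unlinked null sites, with an honest SE.

    Uses many short chromosomes (100 kb, ~20 sites each) so blocks of sites
    are genuinely independent: within a chromosome the pooled genotype is
    almost fully linked, so the standard error is taken over per-chromosome
    means rather than per-site values.  The expectation is
    (1-2e)*0.5 + e = 0.5 at unlinked loci regardless of the error rate.

    Returns (mean_index, se, n_sites).
    """
    eps = 0.001
    cfg = SimConfig(
        n_f2=100,
        bulk_size=50,
        chrom_lengths={f"c{i}": 100_000 for i in range(n_chroms)},
        snp_density=200.0,
        qtl=(),
        seq_error=eps,
        seed=seed,
    )
    genotypes = simulate_f2(cfg)
    ids = [g.plant_id for g in genotypes]
    sites = simulate_pool_reads(genotypes, {"T": ids[:50], "S": ids[50:]}, cfg)
    index = sites["t_hhz"] / sites["t_depth"]
    block_means = index.groupby(sites["chrom"]).mean()
    se = float(block_means.std(ddof=1) / np.sqrt(len(block_means)))
    return float(index.mean()), se, int(len(index))


def null_experiment(n_seeds: int = 20, seed0: int = 1) -> NullResult:
    """No-QTL false-positive characterisation over seeded replicates.

    Reports, per seed, the fraction of threshold-bearing windows whose
    |mean Δ| exceeds their 99.9% threshold, and whether any region survives
    the full calling criteria.
    """
    fracs = []
    n_with_regions = 0
    for k in range(n_seeds):
        config = scaled_config(seed=seed0 + k, with_qtl=False)
        windows, thresholds, regions = run_scan_on_config(config)
        merged = windows.merge(
            thresholds[["chrom", "start", "thr_0.999"]], on=["chrom", "start"]
        )
        ok = np.isfinite(merged["thr_0.999"]) & ~merged["flagged"]
        exceed = ok & (merged["mean_delta"].abs() > merged["thr_0.999"])
        fracs.append(float(exceed.sum() / ok.sum()))
        if regions:
            n_with_regions += 1
    return NullResult(
        n_seeds=n_seeds,
        exceedance_fractions=fracs,
        n_seeds_with_regions=n_with_regions,
    )
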