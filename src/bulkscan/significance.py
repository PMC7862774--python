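"""Resampling null for Δ(SNP-index), confidence thresholds, region calls.

The null asks: with no QTL anywhere near a window, how large can the window
Δ(SNP-index) get purely from (a) drawing two bulks of ``bulk_size`` F2
plants and (b) sequencing each pool at finite depth?  Each replicate draws
one pair of bulk HHZ-allele frequencies at an unlinked locus —
``f = Binomial(2*bulk_size, 1/2) / (2*bulk_size)`` per pool, the exact F2
segregation null — and then samples reads binomially at the observed depths.

For window-level thresholds the bulk-frequency pair is drawn ONCE per
replicate and shared by all of the window's sites, while read noise is drawn
independently per site at the window's median pool depths.  SNPs within a
500 kb window ride on essentially the same chromosomes of the same 50+50
plants, so the genotype component of the window mean does not average out;
modelling the sites as independent (available via ``linkage="independent"``)
would shrink the null spread roughly ``sqrt(n_snps)``-fold and badly
understate the threshold.

Thresholds are upper quantiles of |Δ| at the configured confidence levels.
A window is significant when its mean Δ exceeds its 99.9% threshold and the
pool-index criteria hold (tolerant-pool index >= 0.7, sensitive <= 0.3, as
used to delimit the mapped region); runs of significant windows merge into
candidate regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NullConfig",
    "RegionCriteria",
    "CandidateRegion",
    "null_delta_distribution",
    "threshold_for_windows",
    "call_regions",
    "regions_to_bed",
    "regions_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullConfig:
    """Resampling-null settings (F2 population)."""

    bulk_size: int = 50
    n_reps: int = 1_000
    confidence: tuple[float, ...] = (0.95, 0.99, 0.999)
    seed: int = 0
    linkage: str = "complete"  # intra-window genotype linkage model

    def __post_init__(self) -> None:
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if self.linkage not in ("complete", "independent"):
            raise ValueError("linkage must be 'complete' or 'independent'")
        if max(self.confidence) >= 0.999 and self.n_reps < 10_000:
            warnings.warn(
                f"the {max(self.confidence):.1%} quantile from {self.n_reps} "
                "replicates is noisy; consider n_reps >= 10000 for production",
                stacklevel=2,
            )


def _rng_for(cfg: NullConfig, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=key)
    )


def null_delta_distribution(
    depth_t: int,
    depth_s: int,
    cfg: NullConfig,
    n_sites: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sampled |Δ(SNP-index)| under the no-QTL null; shape (n_reps,).

    With ``n_sites > 1`` each replicate is a window mean over that many
    sites sequenced at the given depths.  Replicates where any site has zero
    sampled... depths here are fixed (not Poisson), so every site has reads
    whenever depth >= 1.
    """
    if depth_t < 1 or depth_s < 1:
        raise ValueError("depths must be >= 1")
    if rng is None:
        rng = _rng_for(cfg, (int(depth_t), int(depth_s), int(n_sites)))
    n_alleles = 2 * cfg.bulk_size
    shape_f = (
        (cfg.n_reps, 1)
        if cfg.linkage == "complete"
        else (cfg.n_reps, n_sites)
    )
    f_t = rng.binomial(n_alleles, 0.5, size=shape_f) / n_alleles
    f_s = rng.binomial(n_alleles, 0.5, size=shape_f) / n_alleles
    idx_t = rng.binomial(depth_t, np.broadcast_to(f_t, (cfg.n_reps, n_sites))) / depth_t
    idx_s = rng.binomial(depth_s, np.broadcast_to(f_s, (cfg.n_reps, n_sites))) / depth_s
    return np.abs((idx_t - idx_s).mean(axis=1))


def _quantiles(samples: np.ndarray, levels: tuple[float, ...]) -> np.ndarray:
    # 'higher' keeps the threshold conservative at tail levels
    return np.quantile(samples, levels, method="higher")


def threshold_for_windows(
    windows: pd.DataFrame, cfg: NullConfig
) -> pd.DataFrame:
    """Per-window |Δ| thresholds at each confidence level.

    The null for a window is simulated at its median pool depths and averaged
    over its ``n_snps`` sites.  Windows flagged as under-populated get no
    threshold (NaN, inert for region calling).  Thresholds are cached by
    (median depth T, median depth S, n_snps) with a seed substream derived
    from the key, so identical windows get identical thresholds regardless
    of order.
    """
    levels = tuple(cfg.confidence)
    cache: dict[tuple[int, int, int], np.ndarray] = {}
    flagged = windows["flagged"].to_numpy()
    med_t = windows["median_depth_t"].to_numpy()
    med_s = windows["median_depth_s"].to_numpy()
    n_snps = windows["n_snps"].to_numpy()
    out = np.full((len(windows), len(levels)), np.nan)
    for i in range(len(windows)):
        if flagged[i] or not np.isfinite(med_t[i]) or not np.isfinite(med_s[i]):
            continue
        key = (int(round(med_t[i])), int(round(med_s[i])), int(n_snps[i]))
        if min(key[0], key[1]) < 1:
            continue
        if key not in cache:
            samples = null_delta_distribution(
                key[0], key[1], cfg, n_sites=key[2], rng=_rng_for(cfg, key)
            )
            cache[key] = _quantiles(samples, levels)
        out[i] = cache[key]
    result = windows[["chrom", "start", "end"]].copy()
    for j, level in enumerate(levels):
        result[_level_col(level)] = out[:, j]
    return result


def _level_col(level: float) -> str:
    return f"thr_{level:g}"


@dataclass(frozen=True)
class RegionCriteria:
    """Window-significance and merging rules for candidate regions."""

    confidence: float = 0.999
    min_index_t: float = 0.7
    max_index_s: float = 0.3
    apply_pool_criteria: bool = True
    gap_max: int | None = None  # default 2*step, resolved at call time


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    peak_delta: float
    peak_pos: int  # midpoint of the window with the largest mean delta
    mean_index_t: float
    mean_index_s: float
    n_windows: int

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def call_regions(
    windows: pd.DataFrame,
    thresholds: pd.DataFrame,
    criteria: RegionCriteria | None = None,
    step: int | None = None,
) -> list[CandidateRegion]:
    """Merge significant windows into candidate regions.

    A window is significant iff ``mean_delta > thr`` at the configured
    confidence and (optionally) ``mean_index_t >= 0.7`` and
    ``mean_index_s <= 0.3``.  Significant windows on the same chromosome
    merge while the gap between one window's end and the next window's start
    is at most ``gap_max`` (default twice the step inferred from window
    anchors).  The result is sorted by (chrom, start) and independent of
    input row order.
    """
    criteria = criteria or RegionCriteria()
    col = _level_col(criteria.confidence)
    if col not in thresholds.columns:
        raise ValueError(f"thresholds table lacks {col!r}")
    df = windows.merge(thresholds[["chrom", "start", col]], on=["chrom", "start"])
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    if step is None:
        starts = df["start"].drop_duplicates().sort_values().to_numpy()
        step = int(np.diff(starts).min()) if starts.size > 1 else 1
    gap_max = criteria.gap_max if criteria.gap_max is not None else 2 * step

    sig = (
        ~df["flagged"]
        & np.isfinite(df[col])
        & (df["mean_delta"] > df[col])
    )
    if criteria.apply_pool_criteria:
        sig &= (df["mean_index_t"] >= criteria.min_index_t) & (
            df["mean_index_s"] <= criteria.max_index_s
        )
    regions: list[CandidateRegion] = []
    for chrom, sub in df[sig].groupby("chrom", sort=False):
        block: list[pd.Series] = []
        prev_end = None
        for _, row in sub.iterrows():
            if prev_end is not None and row["start"] - prev_end > gap_max:
                regions.append(_close_block(chrom, block))
                block = []
            block.append(row)
            prev_end = max(prev_end or 0, int(row["end"]))
        if block:
            regions.append(_close_block(chrom, block))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _close_block(chrom: str, block: list[pd.Series]) -> CandidateRegion:
    b = pd.DataFrame(block)
    peak = b.loc[b["mean_delta"].idxmax()]
    return CandidateRegion(
        chrom=str(chrom),
        start=int(b["start"].min()),
        end=int(b["end"].max()),
        peak_delta=float(peak["mean_delta"]),
        peak_pos=int((peak["start"] + peak["end"]) // 2),
        mean_index_t=float(b["mean_index_t"].mean()),
        mean_index_s=float(b["mean_index_s"].mean()),
        n_windows=len(b),
    )


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "size_mb": r.size_mb,
            "peak_delta": r.peak_delta,
            "peak_pos": r.peak_pos,
            "mean_index_t": r.mean_index_t,
            "mean_index_s": r.mean_index_s,
            "n_windows": r.n_windows,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "size_mb", "peak_delta", "peak_pos",
            "mean_index_t", "mean_index_s", "n_windows",
        ],
    )


def regions_to_bed(regions: list[CandidateRegion], path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\n")
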