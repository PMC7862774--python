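"""Per-site SNP-index, Δ(SNP-index), and sliding-window means.

The SNP-index of a pool at a site is the fraction of that pool's reads
carrying the tolerant-parent (HHZ) allele; Δ(SNP-index) is the tolerant-pool
index minus the sensitive-pool index.  At loci unlinked to the trait an F2
bulk has expectation 0.5 (Δ = 0); at a fully tolerant-fixed locus the
tolerant pool approaches 1 and the sensitive pool 0.

Windows are anchored at bp 1, advance by ``step`` and span ``window`` bp
(default 500 kb / 5 kb); a SNP contributes to every window covering it; the
terminal windows are truncated at the chromosome end and kept with their
true span.  Window means are plain arithmetic means of the per-SNP values;
windows with fewer than ``min_snps`` SNPs are flagged and excluded from
region calling but retained in output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScanConfig", "snp_index", "delta_index", "snp_index_table", "sliding_windows"]


@dataclass(frozen=True)
class ScanConfig:
    window: int = 500_000
    step: int = 5_000
    min_snps: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


def snp_index(n_hhz: int, depth: int) -> float:
    """Exact ratio n_hhz/depth; NaN when the site has no reads."""
    if depth < 0 or n_hhz < 0 or n_hhz > depth:
        raise ValueError("require 0 <= n_hhz <= depth")
    if depth == 0:
        return float("nan")
    return n_hhz / depth


def delta_index(index_t: float, index_s: float) -> float:
    """Δ(SNP-index) = index_T - index_S, in [-1, 1]."""
    if not (0.0 <= index_t <= 1.0 and 0.0 <= index_s <= 1.0):
        raise ValueError("indices must lie in [0, 1]")
    return index_t - index_s


def snp_index_table(oriented: pd.DataFrame) -> pd.DataFrame:
    """Per-site index table from oriented pool counts.

    Input columns: chrom, pos, n_hhz_t, depth_t, n_hhz_s, depth_s.  Sites
    with zero depth in either pool are dropped (defensive; filtering should
    have removed them).  Output adds index_t, index_s, delta.
    """
    df = oriented[(oriented["depth_t"] > 0) & (oriented["depth_s"] > 0)].copy()
    df["index_t"] = df["n_hhz_t"] / df["depth_t"]
    df["index_s"] = df["n_hhz_s"] / df["depth_s"]
    df["delta"] = df["index_t"] - df["index_s"]
    return df.reset_index(drop=True)


def _window_starts(length: int, step: int) -> np.ndarray:
    """1-based window anchors: 1, 1+s, ... while start <= chromosome length."""
    n = (length - 1) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


def sliding_windows(
    sites: pd.DataFrame,
    cfg: ScanConfig,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Window means of index_t, index_s and delta for every chromosome.

    ``sites`` must be sorted by (chrom, pos) and contain only chromosomes
    present in ``chrom_lengths``.  Window sums are computed with prefix sums
    over the sorted site positions, O((n + windows) log n) per chromosome.

    Returns: chrom, start, end, n_snps, mean_index_t, mean_index_s,
    mean_delta, median_depth_t, median_depth_s, flagged.
    """
    unknown = set(sites["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"records on chromosomes without a length: {sorted(unknown)}")
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom} are not sorted by position")
        starts = _window_starts(length, cfg.step)
        ends = np.minimum(starts + cfg.window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n_snps = hi - lo

        def span_mean(values: np.ndarray) -> np.ndarray:
            csum = np.concatenate([[0.0], np.cumsum(values)])
            with np.errstate(invalid="ignore"):
                return np.where(n_snps > 0, (csum[hi] - csum[lo]) / n_snps, np.nan)

        med_t = np.full(len(starts), np.nan)
        med_s = np.full(len(starts), np.nan)
        if pos.size:
            depth_t = sub["depth_t"].to_numpy(dtype=float)
            depth_s = sub["depth_s"].to_numpy(dtype=float)
            occupied = np.flatnonzero(n_snps > 0)
            for w in occupied:
                med_t[w] = np.median(depth_t[lo[w] : hi[w]])
                med_s[w] = np.median(depth_s[lo[w] : hi[w]])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_snps": n_snps,
                    "mean_index_t": span_mean(sub["index_t"].to_numpy())
                    if pos.size
                    else np.nan,
                    "mean_index_s": span_mean(sub["index_s"].to_numpy())
                    if pos.size
                    else np.nan,
                    "mean_delta": span_mean(sub["delta"].to_numpy())
                    if pos.size
                    else np.nan,
                    "median_depth_t": med_t,
                    "median_depth_s": med_s,
                    "flagged": n_snps < cfg.min_snps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
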