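"""Spikelet-fertility phenotyping and extreme-bulk selection.

Spikelet fertility is the fraction of filled grains on the tagged panicles
after heat stress at anthesis:

    fertility (%) = (N_FG + N_PG) / (N_FG + N_PG + N_EG) * 100

where partially filled grains count as filled.  Bulks are the ``bulk_size``
plants from each phenotypic tail, selected by strict rank order with ties
broken by ascending plant id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrainCounts",
    "FertilityStats",
    "BulkDesign",
    "spikelet_fertility",
    "summarize",
    "cv_from_moments",
    "select_bulks",
    "read_phenotypes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrainCounts:
    plant_id: int
    n_fg: int  # fully filled
    n_pg: int  # partially filled
    n_eg: int  # empty

    def __post_init__(self) -> None:
        if min(self.n_fg, self.n_pg, self.n_eg) < 0:
            raise ValueError("grain counts must be non-negative")


@dataclass(frozen=True)
class FertilityStats:
    """Two-moment summary of fertility; ``scale`` flags percent vs proportion."""

    n: int
    mean: float
    sd: float
    cv_percent: float
    min: float
    max: float
    scale: str  # "percent" | "proportion"


@dataclass(frozen=True)
class BulkDesign:
    bulk_size: int
    tolerant_ids: list[int]
    sensitive_ids: list[int]
    tolerant_range: tuple[float, float]
    sensitive_range: tuple[float, float]


def spikelet_fertility(counts: GrainCounts) -> float:
    """Percent fertility; NaN (with a warning) if no grains were scored."""
    total = counts.n_fg + counts.n_pg + counts.n_eg
    if total == 0:
        log.warning("plant %s has no scored grains; fertility is missing",
                    counts.plant_id)
        return math.nan
    return 100.0 * (counts.n_fg + counts.n_pg) / total


def cv_from_moments(mean: float, sd: float) -> float:
    """Coefficient of variation (%) from a mean and SD on a common scale."""
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return 100.0 * sd / mean


def summarize(fertilities, scale: str = "proportion") -> FertilityStats:
    """Sample summary (n-1 SD) of non-missing fertility values."""
    x = np.asarray(pd.Series(fertilities).dropna(), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 non-missing fertility values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return FertilityStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv_percent=cv_from_moments(mean, sd) if mean > 0 else math.nan,
        min=float(x.min()),
        max=float(x.max()),
        scale=scale,
    )


def select_bulks(fertilities: pd.Series, bulk_size: int) -> BulkDesign:
    """Pick the lowest/highest ``bulk_size`` plants as sensitive/tolerant bulks.

    ``fertilities`` is indexed by plant id; missing values are dropped.
    Ties at either cutoff resolve by ascending plant id.
    """
    if bulk_size <= 0:
        raise ValueError("bulk_size must be positive")
    clean = fertilities.dropna()
    if len(clean) < 2 * bulk_size:
        raise ValueError(
            f"need at least {2 * bulk_size} scorable plants, have {len(clean)}"
        )
    order = clean.reset_index()
    order.columns = ["plant_id", "fertility"]
    order = order.sort_values(["fertility", "plant_id"], kind="mergesort")
    sensitive = order.head(bulk_size)
    tolerant = order.tail(bulk_size)
    return BulkDesign(
        bulk_size=bulk_size,
        tolerant_ids=tolerant["plant_id"].tolist(),
        sensitive_ids=sensitive["plant_id"].tolist(),
        tolerant_range=(
            float(tolerant["fertility"].min()),
            float(tolerant["fertility"].max()),
        ),
        sensitive_range=(
            float(sensitive["fertility"].min()),
            float(sensitive["fertility"].max()),
        ),
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (plant_id, N_FG, N_PG, N_EG, ...) and add fertility (%)."""
    df = pd.read_csv(path, sep="\t")
    required = {"plant_id", "N_FG", "N_PG", "N_EG"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df["fertility_percent"] = [
        spikelet_fertility(GrainCounts(r.plant_id, r.N_FG, r.N_PG, r.N_EG))
        for r in df.itertuples(index=False)
    ]
    return df
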