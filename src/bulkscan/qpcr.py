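"""Relative expression from qPCR threshold cycles (2^-ddCt) and genotype tests.

dCt = Ct(target) - Ct(reference gene) within a condition; ddCt subtracts the
calibrator condition's dCt; fold change is 2^-ddCt.  Technical replicates
are averaged on the dCt scale before ddCt (a per-replicate mode keeps them
separate for the genotype comparison).  Genotype contrasts use a two-sided
two-sample Student's t-test on replicate fold changes (equal variance by
default, Welch by flag), starred '*' below 0.05 and '**' below 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct",
    "fold_changes",
    "compare_genotypes",
    "stars",
    "read_ct_table",
]

REQUIRED_COLUMNS = ("sample", "gene", "timepoint", "replicate", "ct")


def ddct(
    target_ct: float,
    ref_ct: float,
    calibrator_target_ct: float,
    calibrator_ref_ct: float,
) -> float:
    """Fold change 2^-ddCt for one condition against a calibrator condition."""
    for v in (target_ct, ref_ct, calibrator_target_ct, calibrator_ref_ct):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    dct = target_ct - ref_ct
    dct_cal = calibrator_target_ct - calibrator_ref_ct
    return 2.0 ** -(dct - dct_cal)


def stars(p_value: float) -> str:
    if math.isnan(p_value):
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def fold_changes(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator: tuple[str, str],
    per_replicate: bool = True,
) -> pd.DataFrame:
    """2^-ddCt per (sample, gene, timepoint) relative to the calibrator.

    ``calibrator`` is the (sample, timepoint) pair whose mean dCt is the
    ddCt baseline for each gene.  With ``per_replicate`` (default) each
    replicate keeps its own dCt — replicate reference-gene Ct values are
    matched by replicate id — yielding per-replicate fold changes suitable
    for a t-test; otherwise replicates are averaged before ddCt.

    Returns: sample, gene, timepoint, fold_change (geometric-mean scale),
    sd_fold, n_replicates, plus per-replicate folds in ``replicate_folds``.
    """
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    ref = ct[ct["gene"] == reference_gene].set_index(
        ["sample", "timepoint", "replicate"]
    )["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    try:
        targets["ref_ct"] = [
            ref.loc[(r.sample, r.timepoint, r.replicate)]
            for r in targets.itertuples(index=False)
        ]
    except KeyError as exc:
        raise ValueError(f"missing reference-gene Ct for condition {exc}") from None
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    cal_sample, cal_timepoint = calibrator
    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        cal = sub[(sub["sample"] == cal_sample) & (sub["timepoint"] == cal_timepoint)]
        if cal.empty:
            raise ValueError(
                f"calibrator {calibrator!r} has no Ct for gene {gene!r}"
            )
        dct_cal = cal["dct"].mean()
        for (sample, timepoint), grp in sub.groupby(["sample", "timepoint"], sort=False):
            if per_replicate:
                folds = 2.0 ** -(grp["dct"] - dct_cal)
            else:
                folds = pd.Series([2.0 ** -(grp["dct"].mean() - dct_cal)])
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "timepoint": timepoint,
                    "fold_change": float(2.0 ** -(grp["dct"].mean() - dct_cal)),
                    "sd_fold": float(folds.std(ddof=1)) if len(folds) > 1 else math.nan,
                    "n_replicates": len(grp),
                    "replicate_folds": folds.tolist(),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenotypeComparison:
    gene: str
    timepoint: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    stars: str
    flagged: bool  # True when a side had < 2 replicates


def compare_genotypes(
    folds: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test of replicate fold changes, per (gene, timepoint)."""
    rows = []
    for (gene, timepoint), sub in folds.groupby(["gene", "timepoint"], sort=False):
        a_rows = sub[sub["sample"] == sample_a]
        b_rows = sub[sub["sample"] == sample_b]
        if a_rows.empty or b_rows.empty:
            continue
        a = np.concatenate([np.asarray(x) for x in a_rows["replicate_folds"]])
        b = np.concatenate([np.asarray(x) for x in b_rows["replicate_folds"]])
        if len(a) < 2 or len(b) < 2:
            rows.append(
                GenotypeComparison(
                    gene, timepoint, float(np.mean(a)), float(np.mean(b)),
                    math.nan, math.nan, "", True,
                )
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            GenotypeComparison(
                gene, timepoint, float(np.mean(a)), float(np.mean(b)),
                float(t), float(p), stars(float(p)), False,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
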