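"""Normalization, imputation, profile standardization and DEG filtering.

Metabolite intensities are scaled per compound by the median of its
detected values, so every feature's scaled median is 1.  Genes count as
expressed when FPKM reaches 1 in at least one sample (boundary inclusive);
differential expression requires |log2 ratio| >= 1 at BH-adjusted
p <= 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    fpkm_expressed_min: float = 1.0
    deg_abs_log2_min: float = 1.0
    deg_fdr_max: float = 0.001
    imputation: str = "min_observed"  # min_observed | half_min | none
    #: pseudo-count added to both group means before the log2 ratio
    pseudo_count: float = 0.01

    def __post_init__(self) -> None:
        if self.fpkm_expressed_min <= 0 or self.deg_abs_log2_min <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.deg_fdr_max < 1.0:
            raise ValueError("deg_fdr_max must be in (0, 1)")
        if self.imputation not in ("min_observed", "half_min", "none"):
            raise ValueError(f"unknown imputation {self.imputation!r}")


def median_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each feature's detected values by their median.

    Idempotent; raises for features with no detected values or a zero
    median (scaling those would divide by zero — impute or drop first).
    """
    values = matrix.values
    n_det = values.notna().sum(axis=1)
    empty = list(values.index[n_det == 0])
    if empty:
        raise ValueError(f"feature(s) with no detected values: {empty[:10]}")
    med = values.median(axis=1, skipna=True)
    zero = list(values.index[med == 0])
    if zero:
        raise ValueError(f"feature(s) with zero median: {zero[:10]}")
    scaled = values.div(med, axis=0)
    return FeatureMatrix(scaled, matrix.kind, matrix.samples)


def impute_missing(
    matrix: FeatureMatrix, params: PreprocessParams | None = None
) -> FeatureMatrix:
    """Replace non-detected entries by the per-feature minimum observed
    value (or half of it).  Features with no observed value at all are
    dropped with a warning, never silently kept."""
    params = params or PreprocessParams()
    if params.imputation == "none":
        raise ValueError("imputation is disabled (imputation='none')")
    values = matrix.values
    n_det = values.notna().sum(axis=1)
    dropped = list(values.index[n_det == 0])
    if dropped:
        logger.warning(
            "dropping %d feature(s) with no detected values: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
        values = values.drop(index=dropped)
    mins = values.min(axis=1, skipna=True)
    if params.imputation == "half_min":
        mins = mins / 2.0
    filled = values.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    return FeatureMatrix(filled, matrix.kind, matrix.samples)


def zscore_profiles(
    matrix: FeatureMatrix,
    by: Sequence[str] = ("tissue", "stage"),
    tissues: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature design-cell means, standardized to mean 0 / sd 1.

    Cells are defined by the ``by`` design factors (means over detected
    replicate values); the z-score uses the sample standard deviation
    (ddof=1).  Features with an empty cell or a zero-variance profile are
    excluded and returned separately.
    """
    if matrix.samples is None:
        raise ValueError("no sample metadata attached; run validate_design")
    meta = matrix.sample_table()
    if tissues is not None:
        keep = meta["tissue"].isin(list(tissues))
        meta = meta[keep]
    groups = meta.groupby(list(by), sort=True)["sample_id"].apply(list)
    cols = {}
    for key, ids in groups.items():
        name = (
            "_".join(str(k) for k in key)
            if isinstance(key, tuple)
            else str(key)
        )
        cols[name] = matrix.values[ids].mean(axis=1, skipna=True)
    profile = pd.DataFrame(cols)

    excluded: list[str] = []
    has_nan = profile.isna().any(axis=1)
    excluded.extend(profile.index[has_nan])
    profile = profile[~has_nan]
    sd = profile.std(axis=1, ddof=1)
    flat = sd == 0
    excluded.extend(profile.index[flat])
    profile = profile[~flat]
    sd = sd[~flat]
    if excluded:
        logger.warning(
            "%d feature(s) excluded from profiling (missing cell or "
            "zero variance)",
            len(excluded),
        )
    z = profile.sub(profile.mean(axis=1), axis=0).div(sd, axis=0)
    return z, excluded


def filter_expressed(
    matrix: FeatureMatrix, params: PreprocessParams | None = None
) -> FeatureMatrix:
    """Keep genes whose maximum FPKM reaches the expressed threshold."""
    params = params or PreprocessParams()
    if matrix.kind != "transcriptome":
        raise ValueError("filter_expressed applies to transcriptome matrices")
    if matrix.n_features == 0:
        return matrix
    keep = matrix.values.max(axis=1, skipna=True) >= params.fpkm_expressed_min
    kept = matrix.values[keep.fillna(False)]
    logger.info(
        "filter_expressed: kept %d / %d genes", kept.shape[0], matrix.n_features
    )
    return FeatureMatrix(kept, matrix.kind, matrix.samples)


def call_degs(
    matrix: FeatureMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Per-gene differential test between two sample groups.

    log2 ratio of group means (pseudo-count added to both means), Welch's
    t-test raw p, BH-adjusted p, and the DEG flag |log2| >= 1 and
    adjusted p <= 0.001.
    """
    from .effects import welch_t_arrays

    params = params or PreprocessParams()
    a_ids, b_ids = list(group_a), list(group_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("both groups need at least 2 replicates")
    A = matrix.values[a_ids].to_numpy(dtype=float)
    B = matrix.values[b_ids].to_numpy(dtype=float)
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)
    pc = params.pseudo_count
    log2_ratio = np.log2((mean_a + pc) / (mean_b + pc))
    _, _, p_raw = welch_t_arrays(A, B)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    is_deg = (np.abs(log2_ratio) >= params.deg_abs_log2_min) & (
        p_adj <= params.deg_fdr_max
    )
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "log2_ratio": log2_ratio,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_deg": is_deg,
        }
    )
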