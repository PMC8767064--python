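"""Position / compound / embryo effect decomposition.

The comparison system isolates the embryo's influence on endosperm
metabolism using the notched-belly (NB) mutant, whose notch blocks
transport between the two endosperm halves so the embryo's impact is
trapped in the bottom part (EnB):

* **position effect** — WT_EnB vs WT_EnU (the two halves of the wild-type
  endosperm differ only by position);
* **compound effect** — NB_EnB vs NB_EnU (position plus embryo);
* **embryo effect** — the ratio of ratios
  ``R = (NB_EnB / NB_EnU) / (WT_EnB / WT_EnU)``, which cancels whatever
  is common to the bottom half of both genotypes.

Position and compound calls use Duncan's multiple range test at alpha =
0.05 on the two cells being compared; the embryo-effect class is read
from R alone with inclusive thresholds (down <= 0.95, up >= 1.05).  A
Welch t-test of NB_EnB vs WT_EnB is reported alongside (BH-adjusted
within stage) as the significance overlay used when rendering per-feature
call tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import FeatureMatrix

logger = logging.getLogger(__name__)

UP, DOWN, NS, UNDEFINED = "up", "down", "ns", "undefined"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Marked-difference thresholds for the embryo-effect ratio."""

    tau_down: float = 0.95
    tau_up: float = 1.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_down < 1.0 < self.tau_up:
            raise ValueError("need 0 < tau_down < 1 < tau_up")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float


def welch_t_arrays(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t-test along rows of two replicate blocks.

    NaN entries count as missing.  Rows where both groups have zero
    variance get the limiting convention: p = 1 for equal means, p = 0
    (infinite statistic) otherwise.
    Returns (statistic, Satterthwaite df, two-sided p).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    if np.any(na < 2) or np.any(nb < 2):
        raise ValueError("Welch test needs >= 2 observations per group")
    ma = np.nanmean(A, axis=1)
    mb = np.nanmean(B, axis=1)
    va = np.nanvar(A, axis=1, ddof=1)
    vb = np.nanvar(B, axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    zero = se2 == 0
    if np.any(zero):
        logger.warning(
            "%d test(s) with zero variance in both groups", int(zero.sum())
        )
    equal = zero & (ma == mb)
    diff = zero & (ma != mb)
    t = np.where(equal, 0.0, t)
    t = np.where(diff, np.where(ma > mb, np.inf, -np.inf), t)
    df = np.where(zero, na + nb - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal, 1.0, np.where(diff, 0.0, p))
    return t, df, p


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch two-sample t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    t, df, p = welch_t_arrays(a[None, :], b[None, :])
    return TestResult(float(t[0]), float(df[0]), float(p[0]))


# Studentized-range quantiles are expensive; cache per (span, df, alpha).
_QCRIT_CACHE: dict[tuple[int, int, float], float] = {}


def _duncan_qcrit(span: int, df: int, alpha: float) -> float:
    """Critical studentized range at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(span - 1)."""
    key = (span, df, alpha)
    if key not in _QCRIT_CACHE:
        a_p = 1.0 - (1.0 - alpha) ** (span - 1)
        if span == 2:
            # q(2) = sqrt(2) * |t|, so invert through the t distribution
            q = math.sqrt(2.0) * stats.t.ppf(1.0 - a_p / 2.0, df)
        else:
            q = float(stats.studentized_range.ppf(1.0 - a_p, span, df))
        _QCRIT_CACHE[key] = q
    return _QCRIT_CACHE[key]


def _duncan_pair_p(q_obs: float, span: int, df: int) -> float:
    """Duncan-adjusted pair p: the protection level at which the observed
    range is exactly critical, inverted from
    alpha_p = 1 - (1 - alpha)^(span - 1)."""
    if math.isinf(q_obs):
        return 0.0
    if span == 2:
        p_span = 2.0 * stats.t.sf(q_obs / math.sqrt(2.0), df)
    else:
        p_span = float(stats.studentized_range.sf(q_obs, span, df))
    p_span = min(max(p_span, 0.0), 1.0)
    return 1.0 - (1.0 - p_span) ** (1.0 / (span - 1))


def duncan_mrt(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Duncan's multiple range test over k groups of replicate values.

    Ordered means are compared span-by-span against the critical range
    ``q*(p, df, alpha_p) * sqrt(MSE / n_h)`` (harmonic mean n for
    unbalanced groups); a pair inside a non-significant wider span is
    never declared significant (no-crossing rule).  With two groups the
    decision coincides with a pooled-variance t-test at ``alpha``.

    Returns one row per unordered pair: group indices, means, span size,
    Duncan-adjusted p and the significance flag.  With MSE = 0 any mean
    difference is significant (p -> 0) and equal means are not (p = 1).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} replicate(s); need >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    k = len(arrs)
    means = np.array([g.mean() for g in arrs])
    ns = np.array([g.size for g in arrs])
    df = int(np.sum(ns - 1))
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in arrs)
    mse = sse / df
    nh = k / float(np.sum(1.0 / ns))
    stderr = math.sqrt(mse / nh)

    # stable order: ties broken by group index
    order = sorted(range(k), key=lambda i: (means[i], i))
    om = means[order]

    sig: dict[tuple[int, int], bool] = {}

    def mark_ns(i: int, j: int) -> None:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                sig.setdefault((a, b), False)

    def test(i: int, j: int) -> None:
        if i >= j or (i, j) in sig:
            return
        span = j - i + 1
        rng_ = om[j] - om[i]
        if mse == 0.0:
            significant = rng_ > 0.0
        else:
            significant = rng_ > _duncan_qcrit(span, df, alpha) * stderr
        if not significant:
            mark_ns(i, j)
            return
        sig[(i, j)] = True
        test(i, j - 1)
        test(i + 1, j)

    test(0, k - 1)

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            span = b - a + 1
            rng_ = om[b] - om[a]
            if mse == 0.0:
                p = 1.0 if rng_ == 0.0 else 0.0
            else:
                p = _duncan_pair_p(rng_ / stderr if stderr else np.inf, span, df)
            gi, gj = order[a], order[b]
            lo, hi = min(gi, gj), max(gi, gj)
            rows.append(
                {
                    "group_i": lo,
                    "group_j": hi,
                    "mean_i": means[lo],
                    "mean_j": means[hi],
                    "span": span,
                    "p": p,
                    "significant": sig[(a, b)],
                }
            )
    out = pd.DataFrame(rows).sort_values(["group_i", "group_j"], kind="stable")
    return out.reset_index(drop=True)


def _cell_values(
    matrix: FeatureMatrix, feature: str, genotype: str, tissue: str, stage: int
) -> np.ndarray:
    cols = matrix.cell_columns(genotype, tissue, stage)
    vals = matrix.values.loc[feature, cols].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def _two_cell_call(
    matrix: FeatureMatrix,
    feature: str,
    genotype: str,
    stage: int,
    thresholds: ClassifierThresholds,
) -> dict:
    enu = _cell_values(matrix, feature, genotype, "EnU", stage)
    enb = _cell_values(matrix, feature, genotype, "EnB", stage)
    table = duncan_mrt([enu, enb], alpha=thresholds.alpha)
    row = table.iloc[0]
    if row["significant"]:
        direction = UP if enb.mean() > enu.mean() else DOWN
    else:
        direction = NS
    return {"direction": direction, "p": float(row["p"])}


def position_effect(
    matrix: FeatureMatrix,
    feature: str,
    stage: int,
    thresholds: ClassifierThresholds | None = None,
) -> dict:
    """Duncan call of WT_EnB vs WT_EnU for one feature at one stage."""
    return _two_cell_call(
        matrix, feature, "WT", stage, thresholds or ClassifierThresholds()
    )


def compound_effect(
    matrix: FeatureMatrix,
    feature: str,
    stage: int,
    thresholds: ClassifierThresholds | None = None,
) -> dict:
    """Duncan call of NB_EnB vs NB_EnU (embryo + position combined)."""
    return _two_cell_call(
        matrix, feature, "NB", stage, thresholds or ClassifierThresholds()
    )


def embryo_effect_ratio(
    matrix: FeatureMatrix,
    feature: str,
    stage: int,
    aggregator: str = "arithmetic",
) -> float:
    """The ratio of ratios R = (NB_EnB/NB_EnU) / (WT_EnB/WT_EnU).

    Cell values are aggregated over detected replicates by the arithmetic
    mean (geometric optional).  NaN when any cell is empty or has a
    non-positive aggregate.
    """
    cells = {}
    for g in ("WT", "NB"):
        for t in ("EnU", "EnB"):
            vals = _cell_values(matrix, feature, g, t, stage)
            if vals.size == 0:
                return float("nan")
            if aggregator == "arithmetic":
                m = float(vals.mean())
            elif aggregator == "geometric":
                if np.any(vals <= 0):
                    return float("nan")
                m = float(np.exp(np.log(vals).mean()))
            else:
                raise ValueError(f"unknown aggregator {aggregator!r}")
            if m <= 0:
                return float("nan")
            cells[(g, t)] = m
    return (cells[("NB", "EnB")] / cells[("NB", "EnU")]) / (
        cells[("WT", "EnB")] / cells[("WT", "EnU")]
    )


def classify_embryo_effect(
    R: float, thresholds: ClassifierThresholds | None = None
) -> str:
    """Three-way call from R with inclusive boundaries; NaN -> undefined."""
    thresholds = thresholds or ClassifierThresholds()
    if R is None or math.isnan(R):
        return UNDEFINED
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    if R <= thresholds.tau_down:
        return DOWN
    if R >= thresholds.tau_up:
        return UP
    return NS


def _pooled_t_arrays(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sample t (NaN-aware).

    This is exactly the Duncan two-group comparison: q(2) = sqrt(2)|t|
    and Duncan's protection level for a span of two is alpha itself.
    Returns (two-sided p, sign of mean difference B-vs-A as +1/0/-1).
    """
    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    ma = np.nanmean(A, axis=1)
    mb = np.nanmean(B, axis=1)
    va = np.nanvar(A, axis=1, ddof=1)
    vb = np.nanvar(B, axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero = sp2 == 0
    t = np.where(zero & (ma == mb), 0.0, t)
    t = np.where(zero & (ma != mb), np.where(mb > ma, np.inf, -np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, np.where(ma == mb, 1.0, 0.0), p)
    return p, np.sign(mb - ma)


def decompose_all(
    matrix: FeatureMatrix,
    thresholds: ClassifierThresholds | None = None,
    aggregator: str = "arithmetic",
) -> pd.DataFrame:
    """Full effect decomposition: one row per endosperm feature x stage.

    Expects a median-scaled matrix with sample records attached.  Features
    never detected in the endosperm (embryo-only) are excluded with a
    logged count.  Columns: feature_id, stage, position_dir, position_p,
    compound_dir, compound_p, R, embryo_class, welch_p (NB_EnB vs WT_EnB),
    welch_p_adj (BH within stage).
    """
    thresholds = thresholds or ClassifierThresholds()
    if matrix.samples is None:
        raise ValueError("no sample metadata attached; run validate_design")
    stages = sorted({r.stage for r in matrix.samples})
    endo_cols = [
        r.sample_id for r in matrix.samples if r.tissue in ("EnU", "EnB")
    ]
    in_endo = matrix.values[endo_cols].notna().any(axis=1)
    excluded = int((~in_endo).sum())
    if excluded:
        logger.info(
            "decompose_all: excluding %d feature(s) absent from endosperm",
            excluded,
        )
    features = list(matrix.values.index[in_endo])
    vals = matrix.values.loc[features]

    frames = []
    for stage in stages:
        cell = {
            (g, t): vals[matrix.cell_columns(g, t, stage)].to_numpy(dtype=float)
            for g in ("WT", "NB")
            for t in ("EnU", "EnB")
        }
        pos_p, pos_sign = _pooled_t_arrays(cell[("WT", "EnU")], cell[("WT", "EnB")])
        cmp_p, cmp_sign = _pooled_t_arrays(cell[("NB", "EnU")], cell[("NB", "EnB")])

        def agg(block: np.ndarray) -> np.ndarray:
            if aggregator == "arithmetic":
                return np.nanmean(block, axis=1)
            if aggregator == "geometric":
                with np.errstate(divide="ignore", invalid="ignore"):
                    return np.exp(np.nanmean(np.log(block), axis=1))
            raise ValueError(f"unknown aggregator {aggregator!r}")

        m = {k: agg(v) for k, v in cell.items()}
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (m[("NB", "EnB")] / m[("NB", "EnU")]) / (
                m[("WT", "EnB")] / m[("WT", "EnU")]
            )
        bad = np.zeros(len(features), dtype=bool)
        for v in m.values():
            bad |= ~np.isfinite(v) | (v <= 0)
        R = np.where(bad, np.nan, R)

        welch_t, _, welch_p = welch_t_arrays(
            cell[("NB", "EnB")], cell[("WT", "EnB")]
        )
        welch_adj = multipletests(welch_p, method="fdr_bh")[1]

        def calls(p: np.ndarray, sign: np.ndarray) -> list[str]:
            out = []
            for pi, si in zip(p, sign):
                if np.isnan(pi):
                    out.append(UNDEFINED)
                elif pi < thresholds.alpha and si != 0:
                    out.append(UP if si > 0 else DOWN)
                else:
                    out.append(NS)
            return out

        emb_class = [
            classify_embryo_effect(r, thresholds) if np.isfinite(r) else UNDEFINED
            for r in R
        ]
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": features,
                    "stage": stage,
                    "position_dir": calls(pos_p, pos_sign),
                    "position_p": pos_p,
                    "compound_dir": calls(cmp_p, cmp_sign),
                    "compound_p": cmp_p,
                    "R": R,
                    "embryo_class": emb_class,
                    "welch_p": welch_p,
                    "welch_p_adj": welch_adj,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["feature_id", "stage"], kind="stable")
    return out.reset_index(drop=True)
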