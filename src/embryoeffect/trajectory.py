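"""PCA of samples and the endosperm-part distance trajectory.

For each genotype the Euclidean distance between the EnU and EnB
replicate centroids in PC space is tracked across the three stages.  The
wild type's halves converge steadily (monotone decline), while in the
notched-belly mutant the embryo's pull makes the divergence largest at
10 DAF, smallest at 20 and partly recovered at 30 — the "V-type" pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FeatureMatrix, SampleRecord

logger = logging.getLogger(__name__)

V_TYPE = "v_type"
MONOTONE_DECLINE = "monotone_decline"
MONOTONE_INCREASE = "monotone_increase"
OTHER = "other"


@dataclass
class PcaResult:
    """Sample scores, loadings and per-component variance fractions."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_fraction: np.ndarray
    samples: list[SampleRecord] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    matrix: FeatureMatrix,
    n_components: int | None = None,
    log_transform: bool = True,
    autoscale: bool = True,
) -> PcaResult:
    """PCA of samples via SVD of the centered (autoscaled) data.

    Features are rows of ``matrix``; samples become the observations.
    Expects a complete matrix (impute first) — features with missing or,
    under the log transform, non-positive values are dropped with a
    warning, as are zero-variance features under autoscaling.  The sign
    of each component is fixed so its largest-magnitude loading is
    positive.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    feats = np.array(matrix.feature_ids)
    ok = ~np.any(np.isnan(X), axis=0)
    if log_transform:
        ok &= np.all(X > 0, axis=0) | ~ok
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.log(X)
    if not np.all(ok):
        logger.warning(
            "run_pca: dropping %d feature(s) with missing/non-positive values",
            int((~ok).sum()),
        )
        X, feats = X[:, ok], feats[ok]
    X = X - X.mean(axis=0)
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            logger.warning(
                "run_pca: dropping %d zero-variance feature(s)",
                int((~keep).sum()),
            )
            X, feats, sd = X[:, keep], feats[keep], sd[keep]
        X = X / sd
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    rank = min(n - 1, p)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        logger.warning(
            "requested %d components but rank is %d; truncating",
            n_components,
            rank,
        )
        n_components = rank
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(n_components):
        i = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, i] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    total_var = float((X**2).sum())
    evf = S**2 / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        loadings=pd.DataFrame(Vt.T, index=feats, columns=cols),
        explained_variance_fraction=evf,
        samples=matrix.samples,
    )


def part_distance(
    pca: PcaResult, genotype: str, stage: int, k: int = 3
) -> float:
    """Euclidean distance between the EnU and EnB replicate centroids of
    one genotype x stage, in the first ``k`` principal components."""
    if pca.samples is None:
        raise ValueError("PcaResult carries no sample metadata")
    k = min(k, pca.n_components)
    cents = {}
    for tissue in ("EnU", "EnB"):
        ids = [
            r.sample_id
            for r in pca.samples
            if r.cell == (genotype, tissue, stage)
        ]
        if not ids:
            raise ValueError(
                f"missing design cell ({genotype}, {tissue}, {stage})"
            )
        cents[tissue] = pca.scores.loc[ids].iloc[:, :k].mean(axis=0).to_numpy()
    return float(np.linalg.norm(cents["EnB"] - cents["EnU"]))


def classify_distance_pattern(d10: float, d20: float, d30: float) -> str:
    """Classify the three-stage distance trajectory.

    Strict inequalities; any tie falls through to ``other``.
    """
    for d in (d10, d20, d30):
        if d < 0:
            raise ValueError("distances must be non-negative")
    if d10 > d20 and d30 > d20:
        return V_TYPE
    if d10 > d20 > d30:
        return MONOTONE_DECLINE
    if d10 < d20 < d30:
        return MONOTONE_INCREASE
    return OTHER


def endosperm_trajectories(
    matrix: FeatureMatrix, k: int = 3, n_components: int | None = None
) -> tuple[pd.DataFrame, PcaResult]:
    """Per-genotype distance trajectory from a PCA of endosperm samples.

    ``matrix`` should be preprocessed (median-scaled, imputed); the log
    transform and autoscaling happen inside :func:`run_pca`.  Returns the
    trajectory table (genotype, d10, d20, d30, pattern) and the fitted
    PCA for score export.
    """
    if matrix.samples is None:
        raise ValueError("no sample metadata attached; run validate_design")
    endo_ids = [
        r.sample_id for r in matrix.samples if r.tissue in ("EnU", "EnB")
    ]
    sub = matrix.subset_samples(endo_ids)
    # drop features not detected across the endosperm
    detected = sub.values.notna().any(axis=1)
    sub = sub.subset_features(sub.values.index[detected])
    pca = run_pca(sub, n_components=n_components)
    stages = sorted({r.stage for r in sub.samples})
    rows = []
    for g in ("WT", "NB"):
        dists = {s: part_distance(pca, g, s, k=k) for s in stages}
        pattern = classify_distance_pattern(*(dists[s] for s in stages))
        row = {"genotype": g}
        row.update({f"d{s}": dists[s] for s in stages})
        row["pattern"] = pattern
        rows.append(row)
    return pd.DataFrame(rows), pca
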