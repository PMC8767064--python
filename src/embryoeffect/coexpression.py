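"""K-means coexpression modules and hypergeometric set enrichment.

Features are clustered on Z-scored design-cell profiles into modules
DP1..DPk ("dominant pattern"); modules concentrated at a single stage are
numbered first.  Pathway enrichment per module uses the upper-tail
hypergeometric test with the clustered feature set as the universe;
the significance flag follows raw p < alpha, with BH-adjusted p reported
alongside.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .types import PathwaySets

logger = logging.getLogger(__name__)

BROAD = "broad"


def _stage_means(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average profile columns that share a stage suffix.

    Column names are either plain stages ("10") or tissue_stage
    ("EnU_10"); the trailing integer is the stage.
    """
    stage_of = {}
    for col in profiles.columns:
        m = re.search(r"(\d+)$", str(col))
        if not m:
            raise ValueError(f"profile column {col!r} has no stage suffix")
        stage_of[col] = int(m.group(1))
    stages = sorted(set(stage_of.values()))
    out = {}
    for s in stages:
        cols = [c for c in profiles.columns if stage_of[c] == s]
        out[s] = profiles[cols].mean(axis=1)
    return pd.DataFrame(out)


def dominant_stage(
    member_profiles: pd.DataFrame, delta: float = 0.5
) -> int | str:
    """Stage with the highest mean Z across a module's members, if its
    margin over the runner-up exceeds ``delta`` Z units; else "broad"."""
    if member_profiles.empty:
        raise ValueError("module has no members")
    means = _stage_means(member_profiles).mean(axis=0).sort_values(
        ascending=False
    )
    if len(means) < 2 or means.iloc[0] - means.iloc[1] > delta:
        return int(means.index[0])
    return BROAD


def kmeans_modules(
    profiles: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
    metric: str = "euclidean",
    delta: float = 0.5,
) -> pd.DataFrame:
    """Cluster Z-scored profiles into modules DP1..DPk.

    Lloyd K-means with k-means++ seeding, best of ``n_init`` restarts.
    ``metric='correlation'`` re-standardizes rows first, making Euclidean
    distance monotone in (1 - Pearson r); on Z-scored profiles the two
    are already equivalent.  Clusters are relabeled by descending
    stage-specificity (margin of the top stage over the runner-up) then
    size, so the numbering is reproducible.

    Returns a DataFrame with feature_id, module and the module's
    dominant_stage label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {profiles.shape[0]}")
    X = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("profiles must be finite")
    if metric == "correlation":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance profile under correlation metric")
        X = (X - mu) / sd
    elif metric != "euclidean":
        raise ValueError(f"unknown metric {metric!r}")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    labels = km.labels_

    info = []
    for c in range(k):
        members = profiles.iloc[labels == c]
        means = _stage_means(members).mean(axis=0).sort_values(ascending=False)
        margin = (
            float(means.iloc[0] - means.iloc[1]) if len(means) > 1 else np.inf
        )
        dom = dominant_stage(members, delta=delta)
        info.append(
            {"cluster": c, "margin": margin, "size": int(members.shape[0]),
             "dominant": dom}
        )
    order = sorted(
        info, key=lambda d: (-d["margin"], -d["size"], d["cluster"])
    )
    name_of = {d["cluster"]: f"DP{i + 1}" for i, d in enumerate(order)}
    dom_of = {d["cluster"]: d["dominant"] for d in info}
    return pd.DataFrame(
        {
            "feature_id": profiles.index,
            "module": [name_of[c] for c in labels],
            "dominant_stage": [str(dom_of[c]) for c in labels],
        }
    )


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing ``n`` from a universe of ``N`` with
    ``K`` marked items."""
    if not (0 <= k <= min(n, K) <= N and n <= N):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_modules(
    assignments: pd.DataFrame,
    pathways: PathwaySets,
    universe: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each pathway in each module.

    The universe defaults to the clustered features; pathway members are
    intersected with it first and empty intersections are skipped.  The
    ``significant`` flag follows raw p < alpha; BH-adjusted p over all
    performed tests is reported alongside.
    """
    if universe is None:
        universe = list(assignments["feature_id"])
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    N = len(uni)
    module_members = {
        m: set(g["feature_id"]) & uni
        for m, g in assignments.groupby("module", sort=True)
    }
    rows = []
    for pw in pathways:
        members = set(pw.members) & uni
        K = len(members)
        if K == 0:
            logger.info(
                "pathway %s disjoint from universe; skipped", pw.pathway_id
            )
            continue
        for mod in sorted(module_members):
            mem = module_members[mod]
            n = len(mem)
            k = len(mem & members)
            rows.append(
                {
                    "module": mod,
                    "pathway_id": pw.pathway_id,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p_raw": hypergeometric_test(k, n, K, N),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_raw"] < alpha
    return out
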