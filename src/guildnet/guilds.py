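"""Guild-level statistics: contingency tests, PAM clustering, interactor contrasts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import silhouette_score


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    pearson_residuals: pd.DataFrame
    contribution_pct: pd.DataFrame


def chisq_independence(table: pd.DataFrame) -> ContingencyResult:
    """Chi-square test of independence with Pearson-residual contributions.

    No continuity correction (general r x c case).  Zero-margin rows/columns
    are dropped with a warning.  ``contribution_pct[i, j] = 100 r_ij^2 / chi2``
    sums to 100 whenever chi2 > 0; a table equal to its expectation reports
    chi2 = 0, p = 1 and all-zero contributions.
    """
    obs = pd.DataFrame(table).astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    zero_rows = obs.index[obs.sum(axis=1) == 0]
    zero_cols = obs.columns[obs.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(f"dropping {len(zero_rows)} zero row(s), {len(zero_cols)} zero col(s)")
        obs = obs.drop(index=zero_rows, columns=zero_cols)
    if obs.size == 0 or obs.to_numpy().sum() == 0:
        raise ValueError("empty contingency table")
    O = obs.to_numpy()
    row, col = O.sum(axis=1, keepdims=True), O.sum(axis=0, keepdims=True)
    E = row @ col / O.sum()
    resid = (O - E) / np.sqrt(E)
    chi2 = float((resid**2).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    contrib = 100 * resid**2 / chi2 if chi2 > 0 else np.zeros_like(resid)
    wrap = lambda a: pd.DataFrame(a, index=obs.index, columns=obs.columns)
    return ContingencyResult(obs, wrap(E), chi2, df, p, wrap(resid), wrap(contrib))


@dataclass
class ClusterResult:
    features: pd.DataFrame
    k: int
    medoids: list
    assignments: pd.Series
    silhouette: float
    objective: float


def _pam(dist: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """Classic PAM: greedy BUILD then full SWAP to a local optimum (deterministic)."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(cur - dist[:, c], 0).sum() if c not in medoids else -1.0
            for c in range(n)])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + medoids[mi + 1:] + [h])
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign, float(best)


def pam_cluster(features: pd.DataFrame, k_max: int = 10,
                metric: str = "euclidean") -> ClusterResult:
    """PAM k-medoids over k = 2..k_max; the k with the best average silhouette wins.

    ``features`` rows are genera (or any unit), columns explanatory-category
    proportions summing to ~1.  All-identical inputs degenerate to k = 2 with
    silhouette 0 and a warning.
    """
    X = features.to_numpy(dtype=float)
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("feature rows must sum to 1")
    n = len(features)
    if n < 3:
        raise ValueError("need at least 3 rows to cluster")
    if n < k_max + 1:
        warnings.warn(f"only {n} rows; shrinking k range to 2..{n - 1}")
        k_max = n - 1
    dist = squareform(pdist(X, metric=metric))
    if dist.max() == 0:
        warnings.warn("all points identical; degenerate clustering")
        meds, assign, obj = _pam(dist, 2)
        return ClusterResult(features, 2, [features.index[m] for m in meds],
                             pd.Series(assign, index=features.index), 0.0, obj)
    best = None
    for k in range(2, k_max + 1):
        meds, assign, obj = _pam(dist, k)
        if len(np.unique(assign)) < 2:
            continue
        sil = float(silhouette_score(dist, assign, metric="precomputed"))
        if best is None or sil > best[0]:
            best = (sil, k, meds, assign, obj)
    sil, k, meds, assign, obj = best
    return ClusterResult(features, k, [features.index[m] for m in meds],
                         pd.Series(assign, index=features.index, name="cluster"),
                         sil, obj)


def genus_cause_features(attributions: pd.DataFrame, taxonomy: pd.Series,
                         rank: int = 5) -> pd.DataFrame:
    """Per-genus proportions of its pairs explained by each cause category.

    ``taxonomy`` maps taxon id to a semicolon-separated lineage string; the
    genus is the field at ``rank`` (0-based, default 5 = rank 6).  Each pair
    contributes to both members' genera.
    """
    def genus(tid):
        parts = str(taxonomy.get(tid, "")).split(";")
        return parts[rank].strip() if len(parts) > rank and parts[rank].strip() else None

    counts: dict[str, dict[str, int]] = {}
    for _, row in attributions.iterrows():
        for tid in (row["taxon_a"], row["taxon_b"]):
            gname = genus(tid)
            if gname is None:
                continue
            counts.setdefault(gname, {})
            cause = row["final_cause"]
            counts[gname][cause] = counts[gname].get(cause, 0) + 1
    df = pd.DataFrame(counts).T.fillna(0.0).sort_index()
    if df.empty:
        return df
    return df.div(df.sum(axis=1), axis=0)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact for combined n <= 25 without ties,
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        warnings.warn("empty group in rank-sum test")
        return float("nan"), float("nan")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def interactor_contrast(network_nodes, annotations: pd.DataFrame) -> dict:
    """Occupancy/abundance contrast between interacting and non-interacting taxa.

    ``annotations`` indexes all filtered taxa with columns ``occupancy`` and
    ``mean_rel_abundance``; the interacting set is the network's node names.
    Returns group means and two-sided Wilcoxon rank-sum p-values.
    """
    names = set(network_nodes)
    inter = annotations.loc[annotations.index.isin(names)]
    non = annotations.loc[~annotations.index.isin(names)]
    out = {"n_interacting": len(inter), "n_noninteracting": len(non)}
    if len(inter) == 0 or len(non) == 0:
        warnings.warn("empty interacting or non-interacting group; contrast is NA")
    for col in ("occupancy", "mean_rel_abundance"):
        if len(inter) == 0 or len(non) == 0:
            out[col] = {"mean_interacting": float("nan"),
                        "mean_noninteracting": float("nan"), "p": float("nan")}
            continue
        _, p = rank_sum_test(inter[col], non[col])
        out[col] = {
            "mean_interacting": float(inter[col].mean()),
            "mean_noninteracting": float(non[col].mean()),
            "p": p,
        }
    return out


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration (oracle for small n)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    m = len(x)
    stats_all = [sum(c) for c in combinations(range(1, len(pooled) + 1), m)]
    mean = m * (len(pooled) + 1) / 2
    extreme = sum(1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats_all)
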