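"""Exact probabilistic pairwise co-occurrence classification.

Under the null that two species occupy sites independently, each with its
observed occupancy, the number of jointly occupied sites J follows the
hypergeometric distribution

    P(J = j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b)

on the support [max(0, n_a + n_b - N), min(n_a, n_b)].  A pair is aggregated
(co-occurring) when P(J >= j_obs) < alpha, segregated (co-excluding) when
P(J <= j_obs) < alpha, and random otherwise.  Both tails include the observed
point mass, so p_lt + p_gt >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

AGGREGATED = "aggregated"
SEGREGATED = "segregated"
RANDOM = "random"


@dataclass
class PairTest:
    taxon_a: str
    taxon_b: str
    N: int
    n_a: int
    n_b: int
    j_obs: int
    expected_j: float
    p_lt: float
    p_gt: float
    classification: str
    testable: bool = True


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def cooccurrence_distribution(N: int, n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the joint-presence count.

    Returns ``(support, pmf)``: the integer support and the probability of
    each joint count, computed in log space to avoid overflow at large N.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"occupancies must lie in [0, N]: N={N}, n_a={n_a}, n_b={n_b}")
    j_min = max(0, n_a + n_b - N)
    j_max = min(n_a, n_b)
    j = np.arange(j_min, j_max + 1)
    logp = _log_binom(n_a, j) + _log_binom(N - n_a, n_b - j) - _log_binom(N, n_b)
    p = np.exp(logp)
    p /= p.sum()  # renormalise away accumulated rounding at extreme N
    return j, p


def classify_pair(
    N: int, n_a: int, n_b: int, j_obs: int, alpha: float = 0.05,
    taxon_a: str = "A", taxon_b: str = "B",
) -> PairTest:
    """Classify one pair as aggregated, segregated or random at level ``alpha``."""
    support, pmf = cooccurrence_distribution(N, n_a, n_b)
    if j_obs < support[0] or j_obs > support[-1]:
        raise ValueError(
            f"j_obs={j_obs} outside support [{support[0]}, {support[-1]}]")
    idx = j_obs - support[0]
    p_lt = float(pmf[: idx + 1].sum())
    p_gt = float(pmf[idx:].sum())
    if p_gt < alpha and p_lt < alpha:
        raise RuntimeError("both tails below alpha; inconsistent for alpha <= 0.5")
    if p_gt < alpha:
        cls = AGGREGATED
    elif p_lt < alpha:
        cls = SEGREGATED
    else:
        cls = RANDOM
    return PairTest(taxon_a, taxon_b, N, n_a, n_b, j_obs,
                    expected_j=n_a * n_b / N, p_lt=min(p_lt, 1.0),
                    p_gt=min(p_gt, 1.0), classification=cls)


def test_all_pairs(occ, alpha: float = 0.05, min_expected: float = 1.0) -> pd.DataFrame:
    """Run the exact pair test on every unordered taxon pair.

    ``occ`` is an :class:`~guildnet.preprocess.OccurrenceMatrix` or a binary
    taxa x site DataFrame.  Pairs with expected joint count below
    ``min_expected`` are kept in the output but flagged untestable and
    classified random.  The result is symmetric in pair order.
    """
    presence = getattr(occ, "presence", occ)
    if presence.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    mat = (presence.to_numpy() > 0).astype(np.int32)
    taxa = list(presence.index)
    N = mat.shape[1]
    occup = mat.sum(axis=1)
    joint = mat @ mat.T  # joint-presence counts for all pairs at once

    cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for i, k in combinations(range(len(taxa)), 2):
        n_a, n_b = int(occup[i]), int(occup[k])
        key = (min(n_a, n_b), max(n_a, n_b))
        if key not in cache:
            support, pmf = cooccurrence_distribution(N, key[0], key[1])
            cache[key] = (support, np.cumsum(pmf))
        support, cdf = cache[key]
        j = int(joint[i, k])
        idx = j - int(support[0])
        p_lt = float(cdf[idx])
        p_gt = float(1.0 - (cdf[idx - 1] if idx > 0 else 0.0))
        expected = n_a * n_b / N
        testable = expected >= min_expected
        if not testable:
            cls = RANDOM
        elif p_gt < alpha:
            cls = AGGREGATED
        elif p_lt < alpha:
            cls = SEGREGATED
        else:
            cls = RANDOM
        rows.append((taxa[i], taxa[k], N, n_a, n_b, j, expected,
                     min(p_lt, 1.0), min(p_gt, 1.0), cls, testable))
    return pd.DataFrame(rows, columns=[
        "taxon_a", "taxon_b", "N", "n_a", "n_b", "j_obs", "expected_j",
        "p_lt", "p_gt", "classification", "testable",
    ])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def apply_pair_correction(pairs: pd.DataFrame, alpha: float,
                          method: str = "none") -> pd.DataFrame:
    """Optionally re-classify pairs after BH correction across all testable pairs."""
    if method == "none":
        return pairs
    if method != "bh":
        raise ValueError(f"unknown correction method {method!r}")
    out = pairs.copy()
    mask = out["testable"].to_numpy()
    for col in ("p_lt", "p_gt"):
        adj = out.loc[mask, col].to_numpy(copy=True)
        out.loc[mask, col + "_adj"] = benjamini_hochberg(adj)
    cls = np.where(out.loc[mask, "p_gt_adj"] < alpha, AGGREGATED,
                   np.where(out.loc[mask, "p_lt_adj"] < alpha, SEGREGATED, RANDOM))
    out.loc[mask, "classification"] = cls
    return out
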