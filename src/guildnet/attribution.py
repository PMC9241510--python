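"""Attribute non-random pairs to environment, dispersal, or potential interaction.

For a segregated pair the comparison groups are the allotypic sites (only A vs
only B); for an aggregated pair, sites with both species vs sites with neither.
Each environmental covariate is tested with a one-way ANOVA between the two
groups, and spatial segregation with a one-way MANOVA of the site coordinates
(Pillai's trace; with two groups this is Hotelling's T^2).  A pair with no
significant covariate and no spatial signal is a potential biotic interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import AGGREGATED, SEGREGATED, benjamini_hochberg
from .synthetic import ENV_VARS

CAUSE_ENV = "environment"
CAUSE_DISP = "dispersal"
CAUSE_ENV_DISP = "environment+dispersal"
CAUSE_INTERACTION = "interaction"
CAUSE_UNTESTABLE = "untestable"

#: both groups need >= _MIN_GROUP members for the 2-response MANOVA (and a
#: fortiori for the ANOVA); smaller groups make the pair untestable
_MIN_GROUP = 3


@dataclass
class SiteGrouping:
    pair: tuple[str, str]
    mode: str  # segregated | aggregated
    group_1: pd.Index  # only-A sites, or both-present sites
    group_2: pd.Index  # only-B sites, or both-absent sites
    testable: bool


def site_groups(pair_row, occ) -> SiteGrouping:
    """Build the two comparison site groups for one non-random pair."""
    presence = getattr(occ, "presence", occ)
    a = presence.loc[pair_row["taxon_a"]].to_numpy() > 0
    b = presence.loc[pair_row["taxon_b"]].to_numpy() > 0
    sites = presence.columns
    mode = pair_row["classification"]
    if mode == SEGREGATED:
        g1, g2 = sites[a & ~b], sites[~a & b]
    elif mode == AGGREGATED:
        g1, g2 = sites[a & b], sites[~a & ~b]
    else:
        raise ValueError("site groups are only defined for non-random pairs")
    testable = len(g1) >= _MIN_GROUP and len(g2) >= _MIN_GROUP
    if not testable:
        warnings.warn(
            f"pair ({pair_row['taxon_a']}, {pair_row['taxon_b']}): group sizes "
            f"{len(g1)}/{len(g2)} too small; pair marked untestable")
    return SiteGrouping((pair_row["taxon_a"], pair_row["taxon_b"]), mode, g1, g2, testable)


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Two-group one-way ANOVA with explicit degenerate-variance conventions.

    Returns (F, p) with df = (1, n - 2).  Zero within-group variance with
    equal means gives p = 1; with unequal means, F = inf and p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    x1, x2 = values[labels == levels[0]], values[labels == levels[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("both groups need >= 2 members")
    F, p = _anova_columns(np.column_stack([values]), labels == levels[0])
    return float(F[0]), float(p[0])


def _anova_columns(X: np.ndarray, mask1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group one-way ANOVA over the columns of X."""
    g1, g2 = X[mask1], X[~mask1]
    n1, n2 = len(g1), len(g2)
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    dfw = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / dfw)
    p = stats.f.sf(F, 1, dfw)
    zero_w = ssw <= 0
    equal_means = zero_w & (ssb <= 0)
    sep = zero_w & (ssb > 0)
    F = np.where(equal_means, 0.0, np.where(sep, np.inf, F))
    p = np.where(equal_means, 1.0, np.where(sep, 0.0, p))
    return F, p


def one_way_manova(coords: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Two-group MANOVA of 2-D coordinates: Pillai's trace with exact F.

    With two groups Pillai's trace has a single non-zero eigenvalue and its
    F approximation is exact, equivalent to Hotelling's T^2:
        T^2 = (n1 n2 / n) d' S_pooled^{-1} d,
        F = (n - p - 1) / (p (n - 2)) * T^2  ~  F(p, n - p - 1).
    Returns (Pillai statistic, p).  Singular pooled covariance gives (nan, nan).
    """
    X = np.asarray(coords, dtype=float)
    labels = np.asarray(groups)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = X[labels == levels[0]], X[labels == levels[1]]
    n1, n2 = len(g1), len(g2)
    p_dim = X.shape[1]
    if n1 < _MIN_GROUP or n2 < _MIN_GROUP:
        raise ValueError(f"both groups need >= {_MIN_GROUP} members")
    n = n1 + n2
    d = g1.mean(axis=0) - g2.mean(axis=0)
    W = (np.atleast_2d(g1 - g1.mean(axis=0)).T @ (g1 - g1.mean(axis=0))
         + np.atleast_2d(g2 - g2.mean(axis=0)).T @ (g2 - g2.mean(axis=0)))
    S_pooled = W / (n - 2)
    try:
        sol = np.linalg.solve(S_pooled, d)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance in MANOVA")
        return float("nan"), float("nan")
    t2 = (n1 * n2 / n) * float(d @ sol)
    if t2 < 0:  # numerical noise
        t2 = 0.0
    pillai = t2 / (t2 + (n - 2))
    df2 = n - p_dim - 1
    if df2 <= 0:
        warnings.warn("too few sites for the MANOVA F approximation")
        return pillai, float("nan")
    F = t2 * df2 / (p_dim * (n - 2))
    p_val = float(stats.f.sf(F, p_dim, df2))
    return float(pillai), p_val


def attribute_pairs(
    pairs: pd.DataFrame,
    occ,
    sites: pd.DataFrame,
    alpha_attr: float = 0.05,
    env_vars: list[str] | None = None,
    env_correction: str = "none",
) -> pd.DataFrame:
    """Attribute every non-random pair to environment / dispersal / interaction.

    ``env_correction`` = "bh" applies Benjamini-Hochberg across the per-pair
    environmental ANOVA p-values before thresholding (default: none).
    Untestable pairs (either comparison group < 3 sites) keep their own
    category rather than inflating the interaction class.
    """
    if not 0 < alpha_attr < 1:
        raise ValueError("alpha_attr must be in (0, 1)")
    if env_correction not in ("none", "bh"):
        raise ValueError(f"unknown env_correction {env_correction!r}")
    env_vars = list(env_vars) if env_vars is not None else [
        v for v in ENV_VARS if v in sites.columns]
    missing = sites[env_vars].isna().any().any()
    if missing:
        raise ValueError("environmental variables must be complete for all sites")

    presence = getattr(occ, "presence", occ)
    sites = sites.loc[presence.columns]
    env_mat = sites[env_vars].to_numpy(dtype=float)
    coords = sites[["x", "y"]].to_numpy(dtype=float)
    site_pos = {s: i for i, s in enumerate(presence.columns)}

    nonrandom = pairs[(pairs["classification"] != "random") & pairs["testable"]]
    rows = []
    for _, pr in nonrandom.iterrows():
        grouping = site_groups(pr, presence)
        rec = {
            "taxon_a": pr["taxon_a"], "taxon_b": pr["taxon_b"],
            "classification": pr["classification"],
            "n_group_1": len(grouping.group_1), "n_group_2": len(grouping.group_2),
        }
        if not grouping.testable:
            rec.update({f"p_{v}": np.nan for v in env_vars})
            rec.update({"manova_p": np.nan, "explaining_vars": "",
                        "dispersal": False, "final_cause": CAUSE_UNTESTABLE,
                        "testable": False})
            rows.append(rec)
            continue
        idx = np.array([site_pos[s] for s in grouping.group_1.append(grouping.group_2)])
        mask1 = np.zeros(len(idx), dtype=bool)
        mask1[: len(grouping.group_1)] = True
        _, p_env = _anova_columns(env_mat[idx], mask1)
        p_thresh = benjamini_hochberg(p_env) if env_correction == "bh" else p_env
        explaining = sorted(v for v, pv in zip(env_vars, p_thresh) if pv < alpha_attr)
        _, manova_p = one_way_manova(coords[idx], mask1)
        dispersal = bool(np.isfinite(manova_p) and manova_p < alpha_attr)
        if explaining and dispersal:
            cause = CAUSE_ENV_DISP
        elif explaining:
            cause = CAUSE_ENV
        elif dispersal:
            cause = CAUSE_DISP
        else:
            cause = CAUSE_INTERACTION
        rec.update({f"p_{v}": p for v, p in zip(env_vars, p_env)})
        rec.update({
            "manova_p": manova_p, "explaining_vars": ",".join(explaining),
            "dispersal": dispersal, "final_cause": cause, "testable": True,
        })
        rows.append(rec)
    cols = ["taxon_a", "taxon_b", "classification", "n_group_1", "n_group_2"] + \
        [f"p_{v}" for v in env_vars] + \
        ["manova_p", "explaining_vars", "dispersal", "final_cause", "testable"]
    return pd.DataFrame(rows, columns=cols)


def attribution_summary(attributions: pd.DataFrame, n_nonrandom: int | None = None) -> dict:
    """Counts and proportions per cause and edge type (machine-readable Fig-1 analogue)."""
    counts = attributions["final_cause"].value_counts().to_dict()
    total = len(attributions)
    by_type = {}
    for cls, label in ((AGGREGATED, "cooccurrence"), (SEGREGATED, "coexclusion")):
        sub = attributions[attributions["classification"] == cls]
        by_type[label] = {
            "n": len(sub),
            "causes": sub["final_cause"].value_counts().to_dict(),
        }
    out = {
        "n_attributed": total,
        "causes": {c: counts.get(c, 0) for c in (
            CAUSE_ENV, CAUSE_DISP, CAUSE_ENV_DISP, CAUSE_INTERACTION, CAUSE_UNTESTABLE)},
        "by_edge_type": by_type,
    }
    if n_nonrandom is not None:
        out["n_nonrandom"] = n_nonrandom
        out["accounting_ok"] = bool(sum(out["causes"].values()) == total)
    return out


def rank_variables(
    attributions: pd.DataFrame,
    edge_type: str,
    alpha_attr: float = 0.05,
) -> pd.DataFrame:
    """Greedy ranking of environmental variables by newly-explained pairs.

    Mirrors the cumulative-coverage ranking: repeatedly pick the variable
    explaining the most pairs not explained by any previously chosen variable
    (ties broken by variable name).  Proportions are relative to all testable
    attributed pairs of the requested edge type; the dispersal-only proportion
    is reported alongside.
    """
    cls = {"cooccurrence": AGGREGATED, "coexclusion": SEGREGATED}[edge_type]
    sub = attributions[(attributions["classification"] == cls) & attributions["testable"]]
    if len(sub) == 0:
        warnings.warn(f"no testable {edge_type} pairs to rank")
        return pd.DataFrame(columns=[
            "variable", "n_explained", "prop_explained", "n_new",
            "cumulative_prop", "prop_dispersal_only"])
    env_cols = [c[2:] for c in sub.columns if c.startswith("p_")]
    total = len(sub)
    explained_by = {
        v: set(sub.index[sub[f"p_{v}"] < alpha_attr]) for v in env_cols}
    disp_only = int((sub["final_cause"] == CAUSE_DISP).sum())

    covered: set = set()
    order, remaining = [], sorted(env_cols)
    while remaining:
        best = max(remaining, key=lambda v: (len(explained_by[v] - covered), ))
        # deterministic tie-break: first lexicographic variable among maxima
        gain = len(explained_by[best] - covered)
        ties = sorted(v for v in remaining if len(explained_by[v] - covered) == gain)
        best = ties[0]
        covered |= explained_by[best]
        order.append((best, gain))
        remaining.remove(best)

    rows, cum = [], 0
    for v, gain in order:
        cum += gain
        rows.append({
            "variable": v,
            "n_explained": len(explained_by[v]),
            "prop_explained": len(explained_by[v]) / total,
            "n_new": gain,
            "cumulative_prop": cum / total,
            "prop_dispersal_only": disp_only / total,
        })
    return pd.DataFrame(rows)
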