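"""Signed potential-interaction network: construction, spinglass guilds, metrics.

Edges carry the signed order-of-magnitude evidence weight
``s * (log10(alpha) - log10(p))`` where p is the relevant tail probability of
the pair test; s = +1 for co-occurrences, -1 for co-exclusions.  Guilds are
found with the spinglass community algorithm in its negative-weight variant
(positive edges pulled inside modules, negative edges pushed between), and the
partition quality is the signed modularity

    Q = w+/(w+ + w-) * Q+  -  w-/(w+ + w-) * Q-

with Q+/Q- the Newman modularity of the positive/negative subgraphs.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .attribution import CAUSE_INTERACTION
from .cooccurrence import AGGREGATED, SEGREGATED

_TINY_P = 1e-320  # clamp for underflowed tail probabilities


def edge_weight(p: float, alpha: float, sign: int) -> float:
    """Signed log10 evidence weight; zero exactly at the significance boundary."""
    if p <= 0:
        warnings.warn("tail probability underflow; clamping")
        p = _TINY_P
    return sign * (math.log10(alpha) - math.log10(p))


def build_network(
    attributions: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    annotations: pd.DataFrame | None = None,
) -> ig.Graph:
    """Build the signed network from the interaction-class pairs.

    Only pairs with ``final_cause == interaction`` enter.  Positive weights are
    co-occurrences (p = upper tail), negative weights co-exclusions (p = lower
    tail).  Node annotations (occupancy, mean relative abundance, taxonomy,
    habitat labels) are attached from ``annotations`` when given.
    """
    inter = attributions[attributions["final_cause"] == CAUSE_INTERACTION]
    key = pairs.set_index(["taxon_a", "taxon_b"])
    edges, weights, pvals, etypes = [], [], [], []
    for _, row in inter.iterrows():
        pr = key.loc[(row["taxon_a"], row["taxon_b"])]
        if row["classification"] == AGGREGATED:
            p, sign, etype = float(pr["p_gt"]), 1, "cooccurrence"
        elif row["classification"] == SEGREGATED:
            p, sign, etype = float(pr["p_lt"]), -1, "coexclusion"
        else:
            continue
        if p >= alpha:  # boundary: not significant, no edge
            continue
        edges.append((row["taxon_a"], row["taxon_b"]))
        weights.append(edge_weight(p, alpha, sign))
        pvals.append(p)
        etypes.append(etype)

    nodes = sorted({t for e in edges for t in e})
    g = ig.Graph()
    g.add_vertices(nodes)
    g.vs["name"] = nodes
    if edges:
        g.add_edges(edges)
        g.es["weight"] = weights
        g.es["abs_weight"] = [abs(w) for w in weights]
        g.es["p_value"] = pvals
        g.es["edge_type"] = etypes
    if annotations is not None:
        for col in annotations.columns:
            g.vs[col] = [
                annotations[col].get(n, None) if n in annotations.index else None
                for n in nodes]
    return g


def signed_modularity(g: ig.Graph, membership, gamma_pos: float = 1.0,
                      gamma_neg: float = 1.0) -> float:
    """Signed modularity of a partition (positive within, negative between)."""
    if g.ecount() == 0:
        return 0.0
    w = np.asarray(g.es["weight"], dtype=float)
    memb = np.asarray(membership)
    src, dst = np.array([(e.source, e.target) for e in g.es]).T
    out = 0.0
    for sign_sel, gamma, coef in ((w > 0, gamma_pos, 1.0), (w < 0, gamma_neg, -1.0)):
        ww = np.abs(w[sign_sel])
        tot = ww.sum()
        if tot == 0:
            continue
        s, d = src[sign_sel], dst[sign_sel]
        strength = np.zeros(g.vcount())
        np.add.at(strength, s, ww)
        np.add.at(strength, d, ww)
        within = (memb[s] == memb[d])
        q = ww[within].sum() / tot
        for c in np.unique(memb):
            sc = strength[memb == c].sum()
            q -= gamma * (sc / (2 * tot)) ** 2
        out += coef * (tot / np.abs(w).sum()) * q
    return float(out)


@dataclass
class ModulePartition:
    membership: pd.Series  # node name -> module id
    modularity: float
    seed: int


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth membership lists."""
    memb = [0] * n

    def rec(i: int, k: int):
        if i == n:
            yield list(memb)
            return
        for c in range(k + 1):
            memb[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(0, 0)


def _exact_partition(sub: ig.Graph, gamma_pos: float, gamma_neg: float) -> list[int]:
    """Exhaustive signed-modularity maximisation for small components."""
    best_q, best = -np.inf, [0] * sub.vcount()
    for memb in _set_partitions(sub.vcount()):
        q = signed_modularity(sub, memb, gamma_pos, gamma_neg)
        if q > best_q + 1e-12:
            best_q, best = q, memb
    return best


def spinglass_partition(
    g: ig.Graph,
    seed: int = 0,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
    spins: int = 10,
    restarts: int = 25,
) -> ModulePartition:
    """Seeded signed spinglass partition; best of ``restarts`` anneals kept.

    Connected components are partitioned independently (the algorithm requires
    connectivity); module ids are offset so they are globally unique.  The
    reported Q is the signed modularity of the combined partition.
    """
    if g.vcount() == 0:
        return ModulePartition(pd.Series(dtype=int), 0.0, seed)
    membership = np.zeros(g.vcount(), dtype=int)
    offset = 0
    comps = g.connected_components()
    for comp in comps:
        sub = g.induced_subgraph(comp)
        if sub.vcount() == 1 or sub.ecount() == 0:
            for v in comp:
                membership[v] = offset
            offset += 1
            continue
        if sub.vcount() <= 8:
            # annealing is wasteful (and igraph's heuristic can stall) on tiny
            # components; the signed objective is maximised exhaustively instead
            best_memb = _exact_partition(sub, gamma_pos, gamma_neg)
            for v, m in zip(comp, best_memb):
                membership[v] = offset + m
            offset += max(best_memb) + 1
            continue
        has_neg = any(w < 0 for w in sub.es["weight"])
        best_q, best_memb = -np.inf, None
        for r in range(restarts):
            random.seed(seed * 100003 + r)
            if has_neg:
                cl = sub.community_spinglass(
                    weights="weight", spins=min(spins, sub.vcount()),
                    gamma=gamma_pos, implementation="neg", lambda_=gamma_neg)
            else:
                cl = sub.community_spinglass(
                    weights="weight", spins=min(spins, sub.vcount()),
                    gamma=gamma_pos)
            q = signed_modularity(sub, cl.membership, gamma_pos, gamma_neg)
            if q > best_q:
                best_q, best_memb = q, list(cl.membership)
        for v, m in zip(comp, best_memb):
            membership[v] = offset + m
        offset += max(best_memb) + 1
    # compact ids deterministically by first appearance
    remap: dict[int, int] = {}
    for m in membership:
        remap.setdefault(int(m), len(remap))
    membership = np.array([remap[int(m)] for m in membership])
    q_all = signed_modularity(g, membership, gamma_pos, gamma_neg)
    memb = pd.Series(membership, index=g.vs["name"], name="module")
    return ModulePartition(memb, q_all, seed)


def _hub_scores(g: ig.Graph) -> np.ndarray:
    """Principal-eigenvector hub scores on the |weight| adjacency, max-normalised.

    Computed with a dense symmetric eigendecomposition so results are exactly
    reproducible (no randomised iterative start).  Invariant to uniform
    rescaling of the weights.
    """
    n = g.vcount()
    if n == 0 or g.ecount() == 0:
        return np.zeros(n)
    A = np.zeros((n, n))
    for e, w in zip(g.es, g.es["abs_weight"]):
        A[e.source, e.target] = A[e.target, e.source] = w
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max() if v.max() > 0 else v


def module_metrics(
    g: ig.Graph,
    part: ModulePartition,
    diameter_weighted: bool = True,
    path_length_weighted: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structural metrics per module and per node.

    Per module (induced subgraph): node count, diameter (default: shortest
    paths on |weight| distances), average path length (default: hop count),
    clustering (mean local transitivity, degree<2 nodes excluded), mean and SD
    of the network-wide hub value of its nodes, and the number of disconnected
    node pairs excluded from the path statistics.  Per node: module, weighted
    degree (sum of signed weights) and hub value (principal eigenvector of the
    |weight| adjacency, max-normalised).
    """
    if g.vcount() == 0:
        return (pd.DataFrame(), pd.DataFrame())
    hub = _hub_scores(g)
    wdeg = np.asarray(g.strength(weights="weight")) if g.ecount() else np.zeros(g.vcount())
    node_df = pd.DataFrame({
        "node": g.vs["name"],
        "module": part.membership.reindex(g.vs["name"]).to_numpy(),
        "weighted_degree": wdeg,
        "hub_value": hub,
    }).set_index("node")

    rows = []
    for mod in sorted(node_df["module"].unique()):
        members = [i for i, v in enumerate(g.vs["name"]) if node_df.loc[v, "module"] == mod]
        sub = g.induced_subgraph(members)
        n = sub.vcount()
        if n == 0 or sub.ecount() == 0:
            rows.append({"module": mod, "n_nodes": n, "diameter": np.nan,
                         "clustering": np.nan, "avg_path_length": np.nan,
                         "mean_hub": np.nan, "sd_hub": np.nan,
                         "n_unconnected_pairs": 0})
            continue
        diam = sub.diameter(
            weights="abs_weight" if diameter_weighted else None, unconn=True)
        hist = sub.path_length_hist()
        n_unconn = int(hist.unconnected)
        if n_unconn:
            warnings.warn(f"module {mod}: {n_unconn} unconnected pair(s) excluded "
                          "from path statistics")
        if path_length_weighted:
            d = np.asarray(sub.distances(weights="abs_weight"))
            finite = d[np.isfinite(d) & (d > 0)]
            apl = float(finite.mean()) if finite.size else np.nan
        else:
            apl = hist.mean if hist.n else np.nan
        local = sub.transitivity_local_undirected(mode="nan")
        local = [c for c in local if c == c]  # drop NaN (degree < 2)
        hubs = node_df.loc[[g.vs["name"][i] for i in members], "hub_value"]
        rows.append({
            "module": mod, "n_nodes": n, "diameter": float(diam),
            "clustering": float(np.mean(local)) if local else np.nan,
            "avg_path_length": float(apl),
            "mean_hub": float(hubs.mean()), "sd_hub": float(hubs.std(ddof=0)),
            "n_unconnected_pairs": n_unconn,
        })
    return pd.DataFrame(rows).set_index("module"), node_df


def per_site_module_metrics(
    g: ig.Graph,
    part: ModulePartition,
    occ,
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """Local-community quantification of each module.

    Per (site, module): richness (member nodes present), completeness
    (richness / module size), abundance (summed relative abundance of present
    members) and total node weight (sum of their weighted degrees).
    """
    presence = getattr(occ, "presence", occ)
    _, node_df = module_metrics(g, part)
    rel = counts.div(counts.sum(axis=0).replace(0, np.nan), axis=1)
    rows = []
    for mod, members in node_df.groupby("module"):
        names = [n for n in members.index if n in presence.index]
        size = len(members)
        pres = presence.loc[names]
        rich = pres.sum(axis=0)
        ab = (rel.reindex(names).fillna(0.0) * pres.to_numpy()).sum(axis=0)
        wdeg = members["weighted_degree"]
        totw = pres.mul(
            wdeg.reindex(names).to_numpy(), axis=0).sum(axis=0)
        for site in presence.columns:
            rows.append({
                "site": site, "module": mod,
                "richness": int(rich[site]),
                "completeness": rich[site] / size if size else np.nan,
                "abundance": float(ab[site]),
                "total_node_weight": float(totw[site]),
            })
    return pd.DataFrame(rows)


def edge_table(g: ig.Graph) -> pd.DataFrame:
    """Tab-separated-ready edge list (node_a, node_b, weight, p, edge_type)."""
    if g.ecount() == 0:
        return pd.DataFrame(columns=["node_a", "node_b", "weight", "p_value", "edge_type"])
    names = g.vs["name"]
    return pd.DataFrame({
        "node_a": [names[e.source] for e in g.es],
        "node_b": [names[e.target] for e in g.es],
        "weight": g.es["weight"],
        "p_value": g.es["p_value"],
        "edge_type": g.es["edge_type"],
    })
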