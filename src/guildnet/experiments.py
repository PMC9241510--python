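"""Benchmark experiments: null calibration, planted-cause recovery, toy guilds.

These drivers exercise the full inference chain on data with known structure
and are shared by the test suite, the acceptance script and the analysis
notebooks.  Sizes are chosen to finish at desk cost while keeping the
statistical statements meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import igraph as ig

from . import synthetic, cooccurrence, attribution, network


def unexplained_summary(n_cooccurrence: int, n_coexclusion: int,
                        n_unexplained_cooc: int, n_unexplained_coex: int) -> dict:
    """Totals of unexplained (potential-interaction) pairs and their share.

    Inputs are the per-edge-type counts of significant pairs and of pairs left
    unexplained by every environmental variable and by space.
    """
    total = n_cooccurrence + n_coexclusion
    unexplained = n_unexplained_cooc + n_unexplained_coex
    if unexplained > total:
        raise ValueError("unexplained counts exceed significant counts")
    return {
        "n_significant": total,
        "n_unexplained": unexplained,
        "pct_unexplained": 100.0 * unexplained / total if total else float("nan"),
    }


def type_one_error(n_species: int = 50, n_sites: int = 300,
                   alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of pairs flagged non-random among independent Bernoulli(0.5) species.

    The exact hypergeometric test is discrete and therefore conservative, so
    the realised rate sits below the nominal 2-tail level.
    """
    rng = np.random.default_rng(seed)
    mat = (rng.random((n_species, n_sites)) < 0.5).astype(np.int8)
    occ = pd.DataFrame(mat,
                       index=[f"s{i}" for i in range(n_species)],
                       columns=[f"site{j}" for j in range(n_sites)])
    pairs = cooccurrence.test_all_pairs(occ, alpha=alpha, min_expected=1.0)
    testable = pairs[pairs["testable"]]
    frac = float((testable["classification"] != "random").mean())
    return {"fraction_nonrandom": frac, "n_pairs": int(len(testable))}


def _recovery_community(seed: int, n_env_pairs: int = 2, n_disp_pairs: int = 2,
                        n_inter_pairs: int = 2, strength: float = 4.0):
    """Small community with planted environment, dispersal and interaction pairs."""
    rng = np.random.default_rng(seed)
    species: list[synthetic.SpeciesSpec] = []
    interactions: list[synthetic.InteractionSpec] = []
    for k in range(n_env_pairs):
        var = ["pH", "DOC", "NO3", "SO4"][k % 4]
        lo, hi = synthetic.ENV_RANGES[var]
        center = float(rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo)))
        width = 0.10 * (hi - lo)
        for m in range(2):
            species.append(synthetic.SpeciesSpec(
                f"env{k}_{m}", baseline_logit=-0.5, niche_var=var,
                niche_center=center + float(rng.normal(0, 0.02 * (hi - lo))),
                niche_width=width, niche_height=7.0))
    for k in range(n_disp_pairs):
        center = (float(rng.uniform(15, 85)), float(rng.uniform(15, 85)))
        for m in range(2):
            species.append(synthetic.SpeciesSpec(
                f"disp{k}_{m}", baseline_logit=2.0,
                dispersal_center=center, dispersal_radius=20.0))
    for k in range(n_inter_pairs):
        a = synthetic.SpeciesSpec(f"int{k}_0", baseline_logit=0.0)
        b = synthetic.SpeciesSpec(f"int{k}_1", baseline_logit=-1.0)
        species.extend([a, b])
        interactions.append(synthetic.InteractionSpec(
            (a.species_id, b.species_id), +1, strength))
    return species, interactions


def planted_recovery(n_seeds: int = 50, seed0: int = 0, n_sites: int = 200,
                     alpha: float = 0.05, alpha_attr: float = 0.05,
                     env_correction: str = "bh") -> pd.DataFrame:
    """Recovery of planted causes over ``n_seeds`` independent metacommunities.

    Per planted class the table reports how many pairs were planted, detected
    (non-random and testable), and recovered.  Recovery criteria: environment
    pairs must have a non-empty explaining-variable set; dispersal pairs a
    significant coordinate MANOVA (the generator's environmental fields are
    spatially autocorrelated, so dispersal pairs legitimately also carry
    environmental signal); interaction pairs must end with final cause
    "interaction" exactly.  BH correction across the nine per-pair ANOVAs is
    the benchmark default: nine simultaneous null tests would otherwise
    falsely explain ~1 - 0.95^9 of true interaction pairs.
    """
    tally = {c: {"planted": 0, "detected": 0, "recovered": 0}
             for c in ("environment", "dispersal", "interaction")}
    for r in range(n_seeds):
        seed = seed0 * 1000003 + r
        sites = synthetic.generate_sites(n_sites, seed)
        species, interactions = _recovery_community(seed)
        occ, truth = synthetic.simulate_occurrence(sites, species, interactions, seed + 1)
        pairs = cooccurrence.test_all_pairs(occ, alpha=alpha)
        attrib = attribution.attribute_pairs(
            pairs, occ, sites, alpha_attr, env_correction=env_correction)
        akey = attrib.set_index(["taxon_a", "taxon_b"])
        for _, row in truth.pair_labels.iterrows():
            cause = row["cause"]
            tally[cause]["planted"] += 1
            key = (row["taxon_a"], row["taxon_b"])
            if key not in akey.index:
                continue
            arec = akey.loc[key]
            if not arec["testable"]:
                continue
            tally[cause]["detected"] += 1
            if cause == "environment":
                ok = bool(arec["explaining_vars"])
            elif cause == "dispersal":
                ok = bool(arec["dispersal"])
            else:
                ok = arec["final_cause"] == attribution.CAUSE_INTERACTION
            tally[cause]["recovered"] += int(ok)
    df = pd.DataFrame(tally).T
    df["recovery_rate"] = df["recovered"] / df["planted"]
    return df


def null_attribution_rate(n_reps: int = 200, n_sites: int = 100,
                          seed: int = 0, alpha_attr: float = 0.05) -> dict:
    """Per-variable attribution rate when environment is pure noise (~alpha).

    Each replicate is fully independent (fresh noise covariates, one fresh
    neutral species pair, forced into attribution regardless of the pair
    test), so the per-variable false-explanation rates are binomial.
    """
    hits = {v: 0 for v in synthetic.ENV_VARS}
    n_done = 0
    for rep in range(n_reps):
        rep_seed = seed * 1000003 + rep
        rng = np.random.default_rng(rep_seed)
        sites = synthetic.generate_sites(n_sites, rep_seed)
        for v in synthetic.ENV_VARS:  # destroy any env structure
            sites[v] = rng.normal(size=n_sites)
        species = [synthetic.SpeciesSpec("a"), synthetic.SpeciesSpec("b")]
        occ, _ = synthetic.simulate_occurrence(sites, species, [], rep_seed + 1)
        pairs = cooccurrence.test_all_pairs(occ)
        pairs["classification"] = np.where(
            pairs["j_obs"] >= pairs["expected_j"], "aggregated", "segregated")
        attrib = attribution.attribute_pairs(pairs, occ, sites, alpha_attr)
        attrib = attrib[attrib["testable"]]
        if len(attrib) != 1:
            continue
        n_done += 1
        for v in synthetic.ENV_VARS:
            hits[v] += int(attrib.iloc[0][f"p_{v}"] < alpha_attr)
    rates = {v: h / n_done for v, h in hits.items()}
    return {"per_variable_rates": rates, "n_pairs": n_done}


def two_clique_network(n: int = 6, w_pos: float = 1.0, w_neg: float = -1.0,
                       n_bridges: int = 4) -> ig.Graph:
    """Two positive cliques joined by negative edges: a planted 2-guild instance."""
    g = ig.Graph()
    names = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    g.add_vertices(names)
    g.vs["name"] = names
    edges, weights = [], []
    for side in (0, n):
        for i in range(n):
            for j in range(i + 1, n):
                edges.append((side + i, side + j))
                weights.append(w_pos)
    for k in range(n_bridges):
        edges.append((k % n, n + (k + 1) % n))
        weights.append(w_neg)
    g.add_edges(edges)
    g.es["weight"] = weights
    g.es["abs_weight"] = [abs(w) for w in weights]
    return g


def two_clique_recovery(n_seeds: int = 10) -> dict:
    """ARI of the spinglass partition against the planted two-clique split."""
    from sklearn.metrics import adjusted_rand_score

    g = two_clique_network()
    planted = [0] * 6 + [1] * 6
    aris = []
    for s in range(n_seeds):
        part = network.spinglass_partition(g, seed=s)
        aris.append(adjusted_rand_score(planted, part.membership.to_numpy()))
    return {"min_ari": float(min(aris)), "mean_ari": float(np.mean(aris)),
            "n_seeds": n_seeds}
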