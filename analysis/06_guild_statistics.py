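#!/usr/bin/env python
"""Downstream guild statistics on the demo run.

(1) chi-square independence of explanatory cause vs edge type with
Pearson-residual contributions; (2) PAM k-medoids clustering of taxa by the
cause profile of their pairs (optimum-silhouette k); (3) occupancy/abundance
contrast between interacting (network) and non-interacting taxa.
"""

import json
from pathlib import Path

import pandas as pd

import guildnet as gn
from guildnet.pipeline import write_tsv

OUT = Path("results/analysis")


def main() -> None:
    attrib = pd.read_csv(OUT / "attribution.tsv", sep="\t")
    annot = pd.read_csv(OUT / "taxon_annotations.tsv", sep="\t", index_col=0)
    edges = pd.read_csv(OUT / "edges.tsv", sep="\t")

    # cause x edge-type contingency
    table = pd.crosstab(attrib["final_cause"], attrib["classification"])
    res = gn.chisq_independence(table)
    write_tsv(res.contribution_pct, OUT / "chisq_contributions.tsv")
    print(f"cause x edge-type chi2 = {res.chi2:.2f} (df {res.df}, p = {res.p:.3g})")
    print("contribution % of Pearson residuals:")
    print(res.contribution_pct.round(1).to_string())

    # PAM clustering of taxa by the cause profile of their pairs
    feats = gn.genus_cause_features(
        attrib, pd.Series({t: f"d;p;c;o;f;{t};s" for t in annot.index}))
    if len(feats) >= 3:
        cl = gn.pam_cluster(feats, k_max=10)
        write_tsv(cl.assignments.to_frame(), OUT / "pam_clusters.tsv")
        print(f"PAM: optimum k = {cl.k} "
              f"(average silhouette {cl.silhouette:.2f}) over {len(feats)} taxa")

    # interacting vs non-interacting contrast
    nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    contrast = gn.interactor_contrast(nodes, annot)
    with open(OUT / "interactor_contrast.json", "w") as fh:
        json.dump(contrast, fh, indent=2)
    for metric in ("occupancy", "mean_rel_abundance"):
        m = contrast[metric]
        print(f"{metric}: interacting {m['mean_interacting']:.4g} vs "
              f"non-interacting {m['mean_noninteracting']:.4g} "
              f"(Wilcoxon p = {m['p']:.3g})")
    print(f"wrote {OUT}/chisq_contributions.tsv, pam_clusters.tsv, "
          "interactor_contrast.json")


if __name__ == "__main__":
    main()
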