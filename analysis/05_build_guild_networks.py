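#!/usr/bin/env python
"""Build the signed potential-interaction network and extract guilds.

Edges are the interaction-class pairs weighted by signed log10 evidence;
guilds are spinglass modules (positive edges within, negative between).
Writes the edge list, GraphML, module assignments, per-module structural
metrics (diameter, clustering, path length, hub values) and per-site module
metrics.
"""

import sys
from pathlib import Path

import pandas as pd

import guildnet as gn
from guildnet.pipeline import write_tsv

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    pairs = pd.read_csv(OUT / "pair_tests.tsv", sep="\t")
    attrib = pd.read_csv(OUT / "attribution.tsv", sep="\t")
    annot = pd.read_csv(OUT / "taxon_annotations.tsv", sep="\t", index_col=0)
    occ = pd.read_csv(OUT / "occurrence.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(OUT / "counts.tsv", sep="\t", index_col=0)

    g = gn.build_network(attrib, pairs, alpha=0.05, annotations=annot)
    g.write_graphml(str(OUT / "network.graphml"))
    write_tsv(gn.edge_table(g), OUT / "edges.tsv", index=False)
    pos = sum(1 for w in g.es["weight"] if w > 0)
    print(f"network: {g.vcount()} nodes, {g.ecount()} edges "
          f"({pos} positive, {g.ecount() - pos} negative)")

    part = gn.spinglass_partition(g, seed=SEED, restarts=25)
    write_tsv(part.membership.to_frame(), OUT / "modules.tsv")
    print(f"spinglass: {part.membership.nunique()} modules, "
          f"signed modularity Q = {part.modularity:.3f}")

    mod_df, node_df = gn.module_metrics(g, part)
    write_tsv(mod_df, OUT / "module_metrics.tsv")
    write_tsv(node_df, OUT / "node_metrics.tsv")
    print(mod_df[["n_nodes", "diameter", "clustering", "avg_path_length",
                  "mean_hub"]].round(3).to_string())

    site_mod = gn.per_site_module_metrics(g, part, occ, counts[occ.columns])
    write_tsv(site_mod, OUT / "per_site_module_metrics.tsv", index=False)
    print(f"wrote {OUT}/edges.tsv, network.graphml, modules.tsv, "
          "module_metrics.tsv, node_metrics.tsv, per_site_module_metrics.tsv")


if __name__ == "__main__":
    main()
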