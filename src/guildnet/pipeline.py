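"""End-to-end orchestration: synthetic generation or file input through guild stats.

All randomness is funnelled through one root seed; every artifact is written
as a tab-separated table (or JSON/GraphML) with a sha256 checksum recorded in
the run manifest, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, preprocess, cooccurrence, attribution, network, guilds

log = logging.getLogger("guildnet")


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the alpine-lake study scale."""

    output_dir: str = "results/run"
    # file-mode inputs (None => synthetic mode)
    counts_path: str | None = None
    sites_path: str | None = None
    annotations_path: str | None = None
    # synthetic-generator parameters
    n_sites: int = 224
    n_species: int = 150
    n_interaction_pairs: int = 10
    interaction_strength: float = 4.0
    depth_range: tuple[int, int] = (5000, 20000)
    # analysis parameters
    rarefaction_depth: int = 5000
    min_occurrence_fraction: float = 0.10
    alpha: float = 0.05
    alpha_attr: float = 0.05
    min_expected: float = 1.0
    pair_correction: str = "none"
    env_correction: str = "none"
    diameter_weighted: bool = True
    path_length_weighted: bool = False
    gamma_pos: float = 1.0
    gamma_neg: float = 1.0
    spinglass_restarts: int = 25
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "alpha_attr", "min_occurrence_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.pair_correction not in ("none", "bh"):
            raise ValueError("pair_correction must be 'none' or 'bh'")
        if self.env_correction not in ("none", "bh"):
            raise ValueError("env_correction must be 'none' or 'bh'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "depth_range" in data:
            data["depth_range"] = tuple(data["depth_range"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}
    t0 = time.time()

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)}

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        manifest["stages"][name] = round(time.time() - t0, 3)

    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4)
    rng_seeds = [int(s % (2**31)) for s in rng_seeds]

    stage("inputs")
    truth = None
    if config.counts_path is None:
        sites = synthetic.generate_sites(config.n_sites, rng_seeds[0])
        species, interactions = synthetic.random_community(
            config.n_species, sites, rng_seeds[0],
            n_interaction_pairs=config.n_interaction_pairs,
            interaction_strength=config.interaction_strength)
        occ_true, truth = synthetic.simulate_occurrence(
            sites, species, interactions, rng_seeds[1])
        counts = synthetic.simulate_counts(
            occ_true, species, config.depth_range, rng_seeds[2])
        write_tsv(sites, out / "sites.tsv")
        write_tsv(counts, out / "counts.tsv")
        write_tsv(truth.pair_labels, out / "truth_pairs.tsv", index=False)
        record("sites", out / "sites.tsv")
        record("counts", out / "counts.tsv")
        record("truth_pairs", out / "truth_pairs.tsv")
        annotations_extra = None
    else:
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        sites = pd.read_csv(config.sites_path, sep="\t", index_col=0)
        annotations_extra = (
            pd.read_csv(config.annotations_path, sep="\t", index_col=0)
            if config.annotations_path else None)

    stage("preprocess")
    rare = preprocess.rarefy(counts, config.rarefaction_depth, rng_seeds[3])
    occ = preprocess.filter_and_binarize(
        rare, config.min_occurrence_fraction, abundance_counts=counts[rare.columns])
    write_tsv(occ.presence, out / "occurrence.tsv")
    annot = occ.annotation_table()
    if annotations_extra is not None:
        annot = annot.join(annotations_extra, how="left")
    write_tsv(annot, out / "taxon_annotations.tsv")
    record("occurrence", out / "occurrence.tsv")
    record("taxon_annotations", out / "taxon_annotations.tsv")

    stage("pair_tests")
    pairs = cooccurrence.test_all_pairs(occ, config.alpha, config.min_expected)
    pairs = cooccurrence.apply_pair_correction(pairs, config.alpha, config.pair_correction)
    write_tsv(pairs, out / "pair_tests.tsv", index=False)
    record("pair_tests", out / "pair_tests.tsv")

    stage("attribution")
    sites_kept = sites.loc[occ.sites]
    attrib = attribution.attribute_pairs(
        pairs, occ, sites_kept, config.alpha_attr, env_correction=config.env_correction)
    write_tsv(attrib, out / "attribution.tsv", index=False)
    record("attribution", out / "attribution.tsv")
    n_nonrandom = int(((pairs["classification"] != "random") & pairs["testable"]).sum())
    summary = attribution.attribution_summary(attrib, n_nonrandom)

    stage("ranking")
    for etype in ("cooccurrence", "coexclusion"):
        rk = attribution.rank_variables(attrib, etype, config.alpha_attr)
        write_tsv(rk, out / f"ranking_{etype}.tsv", index=False)
        record(f"ranking_{etype}", out / f"ranking_{etype}.tsv")

    stage("network")
    g = network.build_network(attrib, pairs, config.alpha, annotations=annot)
    g.write_graphml(str(out / "network.graphml"))
    write_tsv(network.edge_table(g), out / "edges.tsv", index=False)
    record("network_graphml", out / "network.graphml")
    record("edges", out / "edges.tsv")

    stage("partition")
    part = network.spinglass_partition(
        g, seed=rng_seeds[0], gamma_pos=config.gamma_pos,
        gamma_neg=config.gamma_neg, restarts=config.spinglass_restarts)
    write_tsv(part.membership.to_frame(), out / "modules.tsv")
    record("modules", out / "modules.tsv")

    stage("metrics")
    mod_df, node_df = network.module_metrics(
        g, part, config.diameter_weighted, config.path_length_weighted)
    write_tsv(mod_df, out / "module_metrics.tsv")
    write_tsv(node_df, out / "node_metrics.tsv")
    record("module_metrics", out / "module_metrics.tsv")
    record("node_metrics", out / "node_metrics.tsv")
    site_mod = network.per_site_module_metrics(g, part, occ, rare)
    write_tsv(site_mod, out / "per_site_module_metrics.tsv", index=False)
    record("per_site_module_metrics", out / "per_site_module_metrics.tsv")

    stage("guild_stats")
    contrast = guilds.interactor_contrast(
        g.vs["name"] if g.vcount() else [], occ.annotation_table())

    manifest.update({
        "seed": config.seed, "derived_seeds": rng_seeds,
        "n_sites_kept": int(occ.n_sites), "n_taxa_kept": int(len(occ.taxa)),
        "n_pairs": int(len(pairs)), "n_nonrandom": n_nonrandom,
        "cause_summary": summary,
        "signed_modularity": part.modularity,
        "n_modules": int(part.membership.nunique()) if len(part.membership) else 0,
        "network": {"n_nodes": g.vcount(), "n_edges": g.ecount()},
        "interactor_contrast": contrast,
        "metric_conventions": {
            "diameter_weighted": config.diameter_weighted,
            "path_length_weighted": config.path_length_weighted,
            "abundance_annotation": "pre-rarefaction proportions",
        },
    })
    if truth is not None:
        manifest["truth_seed"] = truth.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
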