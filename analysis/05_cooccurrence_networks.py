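#!/usr/bin/env python
"""Co-occurrence networks in photic and aphotic zones.

SparCC correlations over the three microbial groups combined per zone,
network construction at |r| ≥ 0.6 and FDR-corrected p < 0.01, topology with
random-graph references, Zi/Pi keystone classification, keystone overlap
between zones, natural-connectivity attack curves, taxon-taxon-environment
edge labelling, and diversity-complexity regressions.
Reads ``results/data/``; writes to ``results/networks/``.

Run:  python analysis/05_cooccurrence_networks.py [--seed 1]
"""

import argparse
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from pelagos.containers import OtuTable
from pelagos.io import filter_for_network, load_metadata, load_otu_table, read_newick
from pelagos.network import (
    build_network,
    complexity_diversity_regression,
    detect_modules_and_roles,
    env_edge_test,
    keystone_overlap,
    robustness_attack,
    sparcc,
    topology_summary,
)
from pelagos.ordination import alpha_diversity

GROUPS = ["protist", "fl", "pa"]
ENV_COLS = ["temperature", "salinity", "dissolved_oxygen"]
TOP_OTUS_PER_GROUP = 40   # desk-scale network size
N_BOOTSTRAP = 2000        # pseudo-p resolution 1/2001 for FDR < 0.01


def zone_table(tables, ids):
    parts = []
    groups = {}
    for g in GROUPS:
        sub = tables[g].subset_samples(ids).drop_empty_otus()
        filt = filter_for_network(sub)
        top = filt.relative_abundance().mean().nlargest(
            TOP_OTUS_PER_GROUP).index
        parts.append(filt.subset_otus(top).counts)
        groups.update({o: g for o in top})
    return OtuTable(pd.concat(parts, axis=1)), groups


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/networks"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    md = load_metadata(args.data_dir / "metadata.tsv")
    tables = {g: load_otu_table(args.data_dir / f"otu_table_{g}.tsv")
              for g in GROUPS}
    zones = {"photic": md.index[md.zone == "photic"],
             "aphotic": md.index[md.zone == "aphotic"]}

    nets, roles, summary = {}, {}, {}
    for zone, ids in zones.items():
        tbl, groups = zone_table(tables, ids)
        print(f"{zone}: SparCC on {tbl.n_otus} OTUs x {tbl.n_samples} samples")
        r, p = sparcc(tbl, n_bootstrap=N_BOOTSTRAP, bootstrap_iterations=2,
                      seed=args.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g_net = build_network(r, p, node_groups=groups)
        nets[zone] = (g_net, tbl)
        print(f"{zone}: {g_net.number_of_nodes()} nodes, "
              f"{g_net.number_of_edges()} edges")
        summary[zone] = {"n_nodes": g_net.number_of_nodes(),
                         "n_edges": g_net.number_of_edges()}
        if g_net.number_of_edges() == 0:
            print(f"{zone}: no co-occurrence structure survives the "
                  "thresholds (neutral assembly leaves basis abundances "
                  "uncorrelated)")
            continue

        topo = topology_summary(g_net, n_random=10, seed=args.seed)
        pd.Series(topo).to_csv(args.out_dir / f"topology_{zone}.tsv",
                               sep="\t", header=False)
        summary[zone]["topology"] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in topo.items()}

        roles[zone] = detect_modules_and_roles(g_net, seed=args.seed)
        roles[zone].to_csv(args.out_dir / f"roles_{zone}.tsv", sep="\t")
        summary[zone]["roles"] = roles[zone]["role"].value_counts().to_dict()

        env = md.loc[list(ids), ENV_COLS]
        edges, env_sum = env_edge_test(g_net, tbl, env)
        edges.to_csv(args.out_dir / f"edges_{zone}.tsv", sep="\t", index=False)
        summary[zone]["env_edges"] = env_sum["n_env_edges"]
        summary[zone]["env_edge_fraction"] = env_sum["fraction_env"]

        for strategy in ("betweenness", "random"):
            curve = robustness_attack(
                g_net, strategy,
                n_reps=50 if strategy == "random" else None, seed=args.seed)
            pd.DataFrame({"fraction_removed": curve.fraction_removed,
                          "natural_connectivity": curve.connectivity}).to_csv(
                args.out_dir / f"attack_{zone}_{strategy}.tsv", sep="\t",
                index=False)
            auc = float(np.trapezoid(curve.normalized(),
                                     curve.fraction_removed))
            summary[zone][f"robustness_auc_{strategy}"] = auc

        tree = read_newick(args.data_dir / "tree_protist.nwk")
        prot = tables["protist"].subset_samples(ids).drop_empty_otus()
        adiv = alpha_diversity(prot, tree)
        reg = complexity_diversity_regression(g_net, tbl, adiv)
        reg.to_csv(args.out_dir / f"complexity_regression_{zone}.tsv",
                   sep="\t", index=False)

        nx.write_graphml(g_net, args.out_dir / f"network_{zone}.graphml")

    if len(roles) == 2:
        ov = keystone_overlap(roles["photic"], roles["aphotic"])
        summary["keystone_shared_fraction"] = ov["shared_fraction"]
        print(f"\nkeystones shared between zones: "
              f"{100 * ov['shared_fraction']:.2f}%")
    elif "photic" in roles:
        summary["keystone_shared_fraction"] = 0.0
        print("\nno aphotic keystones: overlap is 0")

    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    print(f"wrote outputs to {args.out_dir}")


if __name__ == "__main__":
    main()
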