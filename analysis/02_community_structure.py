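#!/usr/bin/env python
"""Community variation along the water column.

PCoA + ANOSIM of photic vs aphotic communities, homogeneity of environmental
dispersions, depth decay of community similarity, and variation partitioning
of Bray-Curtis community variation among depth, space (dbMEM), environment
and biotic-association blocks.  Reads ``results/data/``; writes tables to
``results/community_structure/``.

Run:  python analysis/02_community_structure.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from pelagos.io import load_metadata, load_otu_table
from pelagos.ordination import (
    anosim,
    bray_curtis,
    dbmem_axes,
    depth_decay,
    kaiser_guttman_axes,
    pcoa,
    permdisp,
    variation_partitioning,
)

GROUPS = ["protist", "fl", "pa"]
ENV_COLS = ["temperature", "salinity", "dissolved_oxygen"]
BIO_COLS = ["bacterial_abundance", "viral_abundance",
            "hnf_abundance", "pnf_abundance"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results/community_structure"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    md = load_metadata(args.data_dir / "metadata.tsv")
    tables = {g: load_otu_table(args.data_dir / f"otu_table_{g}.tsv")
              for g in GROUPS}
    summary: dict = {}

    # ordination + ANOSIM per group
    rows = []
    for g in GROUPS:
        dm = bray_curtis(tables[g])
        ord_res = pcoa(dm)
        coords = ord_res.samples.iloc[:, :2].set_axis(md.index)
        coords.columns = ["PCo1", "PCo2"]
        coords.join(md[["zone", "depth"]]).to_csv(
            args.out_dir / f"pcoa_{g}.tsv", sep="\t")
        for pa in (False, True):
            dm_v = bray_curtis(tables[g], presence_absence=pa)
            r, p = anosim(dm_v, md["zone"], n_perm=999, seed=args.seed)
            rows.append({"group": g,
                         "metric": "sorensen" if pa else "bray_curtis",
                         "anosim_r": r, "anosim_p": p})
    anosim_df = pd.DataFrame(rows)
    anosim_df.to_csv(args.out_dir / "anosim.tsv", sep="\t", index=False)
    print("ANOSIM photic vs aphotic:")
    print(anosim_df.round(4).to_string(index=False))
    summary["anosim_r_range"] = [float(anosim_df.anosim_r.min()),
                                 float(anosim_df.anosim_r.max())]

    # environmental homogeneity of dispersions between zones
    z = (md[ENV_COLS] - md[ENV_COLS].mean()) / md[ENV_COLS].std()
    env_d = np.linalg.norm(z.to_numpy()[:, None] - z.to_numpy()[None, :],
                           axis=2)
    f, p = permdisp(DistanceMatrix(env_d, list(md.index)), md["zone"],
                    n_perm=999, seed=args.seed)
    print(f"\nenvironmental PERMDISP: F = {f:.2f}, p = {p:.4f} "
          "(photic more heterogeneous)" if f > 1 else "")
    summary["env_permdisp"] = {"F": float(f), "p": float(p)}

    # depth decay of similarity: whole column and per zone
    rows = []
    for g in GROUPS:
        for scope, ids in (("total", md.index),
                           ("photic", md.index[md.zone == "photic"]),
                           ("aphotic", md.index[md.zone == "aphotic"])):
            sub = tables[g].subset_samples(ids).drop_empty_otus()
            dm = bray_curtis(sub)
            slope, icpt, r2, pval = depth_decay(dm, md.loc[ids, "depth"])
            rows.append({"group": g, "scope": scope, "slope": slope,
                         "intercept": icpt, "r_squared": r2, "p": pval})
    decay = pd.DataFrame(rows)
    decay.to_csv(args.out_dir / "depth_decay.tsv", sep="\t", index=False)
    print("\ndepth decay of community similarity:")
    print(decay.round(4).to_string(index=False))

    # variation partitioning per group
    mem = dbmem_axes(md["latitude"], md["longitude"], ids=md.index)
    env_pca, _ = kaiser_guttman_axes(md[ENV_COLS], max_axes=2)
    bio_pca, _ = kaiser_guttman_axes(md[BIO_COLS], max_axes=2)
    vpa_rows = []
    for g in GROUPS:
        others = [h for h in GROUPS if h != g]
        other_axes = [pcoa(bray_curtis(tables[h])).samples.iloc[:, :2]
                      .set_axis(md.index).add_prefix(h + "_")
                      for h in others]
        blocks = {"depth": md[["depth"]], "space": mem,
                  "environment": env_pca,
                  "biotic": pd.concat([bio_pca] + other_axes, axis=1)}
        res = variation_partitioning(bray_curtis(tables[g]), blocks,
                                     n_perm=199, seed=args.seed)
        row = {"group": g, "total_adj_r2": res.total_adj_r2()}
        for name in res.block_names:
            row[f"unique_{name}"] = res.fractions[(name,)]
            row[f"p_{name}"] = res.unique_p[name]
        vpa_rows.append(row)
    vpa_df = pd.DataFrame(vpa_rows)
    vpa_df.to_csv(args.out_dir / "vpa.tsv", sep="\t", index=False)
    print("\nvariation partitioning (unique adjusted R², Bonferroni p):")
    print(vpa_df.round(4).to_string(index=False))
    summary["vpa_strongest_unique_block"] = str(
        vpa_df.filter(like="unique_").mean().idxmax().removeprefix("unique_"))

    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"\nwrote tables to {args.out_dir}")


if __name__ == "__main__":
    main()
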