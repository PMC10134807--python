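#!/usr/bin/env python
"""Assembly mechanisms from photic to aphotic zones.

Sloan neutral-model fits (with bootstrap confidence bands), C-score
standardized effect sizes against the sim9 null, and the phylogenetic null
model (βNTI + RC_bray) mapped onto the five assembly processes, per zone.
Reads ``results/data/``; writes to ``results/assembly/``.

Run:  python analysis/03_assembly_mechanisms.py [--seed 1]
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pelagos.assembly import (
    beta_nti,
    c_score_ses,
    fit_sloan_ncm,
    partition_processes,
    raup_crick_bray,
)
from pelagos.io import load_metadata, load_otu_table, read_newick

GROUPS = ["protist", "fl", "pa"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/assembly"))
    ap.add_argument("--n-null", type=int, default=200,
                    help="phylogenetic-null randomizations (200 keeps the "
                         "desk-scale run fast; raise for final estimates)")
    ap.add_argument("--n-sim", type=int, default=1000,
                    help="sim9 null matrices for the C-score SES")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    md = load_metadata(args.data_dir / "metadata.tsv")
    zones = {"photic": md.index[md.zone == "photic"],
             "aphotic": md.index[md.zone == "aphotic"]}

    ncm_rows, ses_rows, proc_rows = [], [], []
    for g in GROUPS:
        tbl = load_otu_table(args.data_dir / f"otu_table_{g}.tsv")
        tree = read_newick(args.data_dir / f"tree_{g}.nwk")
        for zone, ids in zones.items():
            sub = tbl.subset_samples(ids).drop_empty_otus()

            fit = fit_sloan_ncm(sub, n_boot=200, seed=args.seed)
            ncm_rows.append({"group": g, "zone": zone, "m": fit.m,
                             "Nm": fit.Nt_m, "r_squared": fit.r_squared,
                             "m_ci_low": fit.m_ci[0], "m_ci_high": fit.m_ci[1]})
            fit.otu_stats.to_csv(
                args.out_dir / f"ncm_otus_{g}_{zone}.tsv", sep="\t")

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = c_score_ses(sub, n_sim=args.n_sim, seed=args.seed)
            ses_rows.append({"group": g, "zone": zone,
                             "c_score_obs": res.c_score_obs,
                             "c_score_sim_mean": res.c_score_sim_mean,
                             "ses": res.ses,
                             "interpretation": res.interpretation})

            z = beta_nti(sub, tree, n_null=args.n_null, seed=args.seed)
            rc = raup_crick_bray(sub, n_null=args.n_null, seed=args.seed)
            part = partition_processes(z, rc)
            proc_rows.append({"group": g, "zone": zone,
                              "n_pairs": part.n_pairs, **part.fractions})

    ncm = pd.DataFrame(ncm_rows)
    ses = pd.DataFrame(ses_rows)
    proc = pd.DataFrame(proc_rows)
    ncm.to_csv(args.out_dir / "ncm_fits.tsv", sep="\t", index=False)
    ses.to_csv(args.out_dir / "cscore_ses.tsv", sep="\t", index=False)
    proc.to_csv(args.out_dir / "process_fractions.tsv", sep="\t", index=False)

    print("Sloan neutral-model fits (higher R² = more neutral-looking):")
    print(ncm.round(4).to_string(index=False))
    print("\nC-score standardized effect sizes (|SES| > 2 = nonrandom):")
    print(ses.round(2).to_string(index=False))
    print("\nfive-process partition (fractions of sample pairs):")
    print(proc.round(3).to_string(index=False))

    piv = ncm.pivot(index="group", columns="zone", values="r_squared")
    aphotic_more_neutral = bool((piv["aphotic"] > piv["photic"]).all())
    det = proc.set_index(["group", "zone"])[
        ["heterogeneous_selection", "homogeneous_selection"]].sum(axis=1)
    print("\naphotic more neutral in all groups:", aphotic_more_neutral)
    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump({
            "aphotic_more_neutral_all_groups": aphotic_more_neutral,
            "selection_fraction": {f"{g}_{z}": float(det[g, z])
                                   for g in GROUPS for z in zones},
        }, fh, indent=2)
    print(f"wrote tables to {args.out_dir}")


if __name__ == "__main__":
    main()
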