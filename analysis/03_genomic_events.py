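#!/usr/bin/env python
"""Cohort-level genomic events from the per-tumor segmentations.

Recomputes arm-level calls and the 1p/19q co-deletion class per tumor,
extracts genomic breakpoints and clusters them into shared loci, finds
recurrent focal homozygous deletions and amplifications (>= 2 tumors),
and clusters tumors on their 1-Mb copy-number vectors (Euclidean,
average linkage).  Writes tables and the dendrogram (Newick) under
results/events/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oligocna import events as ev
from oligocna.io import (
    read_arm_table,
    read_gene_bed,
    read_probe_table,
    read_segments,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--segmentation", type=Path,
                    default=Path("results/segmentation"))
    ap.add_argument("--out", type=Path, default=Path("results/events"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    arms = read_arm_table()
    probes = read_probe_table(args.cohort / "probes.tsv")
    manifest = json.loads((args.cohort / "manifest.json").read_text())
    per_tumor = {
        sid: read_segments(args.segmentation / f"{sid}.tsv") for sid in manifest
    }

    # arm calls and codel classes
    arm_rows, codel_rows = [], []
    for sid, segs in sorted(per_tumor.items()):
        calls = ev.call_arms(segs, probes, arms)
        codel = ev.call_codel(segs, calls, arms)
        codel_rows.append(
            {
                "sample_id": sid,
                "template": manifest[sid]["template"],
                "codel_class": codel.cls,
                "breakpoint_1": codel.breakpoint_1_pos,
                "breakpoint_19": codel.breakpoint_19_pos,
            }
        )
        for a in calls:
            if a.call != "neutral":
                arm_rows.append({"sample_id": sid, "arm": a.arm, "call": a.call,
                                 "fraction": round(max(a.fraction_loss,
                                                       a.fraction_gain,
                                                       a.fraction_cnloh), 3)})
    pd.DataFrame(arm_rows).to_csv(args.out / "arm_calls.tsv", sep="\t", index=False)
    codel_df = pd.DataFrame(codel_rows)
    codel_df.to_csv(args.out / "codel_classes.tsv", sep="\t", index=False)

    n_codel = int((codel_df["codel_class"] == "codel").sum())
    print(f"co-deletion called in {n_codel}/{len(codel_df)} tumors "
          f"({100 * n_codel / len(codel_df):.0f}%)")

    # breakpoints and their co-occurrence
    per_bp = {sid: ev.extract_breakpoints(segs) for sid, segs in per_tumor.items()}
    mat, catalog = ev.cooccurrence_matrix(per_bp)
    mat.to_csv(args.out / "breakpoint_matrix.tsv", sep="\t")
    catalog.sort_values("n_tumors", ascending=False).to_csv(
        args.out / "breakpoint_loci.tsv", sep="\t", index=False
    )
    top = catalog.sort_values("n_tumors", ascending=False).head(3)
    print("most shared breakpoint loci:")
    for _, r in top.iterrows():
        print(f"  {r['locus']}  in {r['n_tumors']} tumors")

    # recurrent focal events
    gene_bed = read_gene_bed()
    for etype in ("homdel", "amp"):
        regions = ev.recurrent_regions(per_tumor, etype, k=2, gene_bed=gene_bed)
        df = pd.DataFrame(
            [
                {
                    "region": f"chr{r.chrom}_{r.start}_{r.end}",
                    "n_tumors": r.n_tumors,
                    "genes": "-".join(r.genes),
                }
                for r in regions
            ]
        )
        df.to_csv(args.out / f"recurrent_{etype}.tsv", sep="\t", index=False)
        print(f"recurrent {etype} regions (>=2 tumors): {len(df)}")

    # copy-number clustering
    vec = ev.copy_number_vectors(per_tumor, arms)
    Z, order, newick = ev.cluster_tumors(vec)
    (args.out / "dendrogram.nwk").write_text(newick + "\n")
    side_a, side_b = ev.top_split(Z, sorted(per_tumor))
    fam = lambda s: manifest[s]["template"].startswith("codel")
    pure = len({fam(s) for s in side_a}) == 1 and len({fam(s) for s in side_b}) == 1
    print(f"dendrogram top split separates codel-family from astro-like: {pure}")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
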