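#!/usr/bin/env python
"""Clinico-molecular associations and survival analysis.

Joins the per-tumor event calls (co-deletion class, aberrant arms) with
the phenotype table, tests each event against IDH status/sex (Fisher
exact) and age/KPS (Welch t) with per-variable Benjamini-Hochberg
control, compares the IDH-mutation rate between co-deleted and
non-co-deleted tumors, and draws Kaplan-Meier curves with log-rank tests
for PFS and OS by co-deletion status.  Writes tables under results/stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from oligocna.io import read_phenotypes
from oligocna.stats import (
    associate_segments,
    chi2_yates,
    fisher_exact_2x2,
    km_curve,
    logrank,
    welch_t,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--events", type=Path, default=Path("results/events"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pheno = read_phenotypes(args.cohort / "phenotypes.tsv")
    codel_df = pd.read_csv(args.events / "codel_classes.tsv", sep="\t").set_index(
        "sample_id"
    )
    arm_df = pd.read_csv(args.events / "arm_calls.tsv", sep="\t")

    events = pd.DataFrame(index=codel_df.index)
    events["codel"] = (codel_df["codel_class"] == "codel").astype(int)
    for (arm, call), grp in arm_df.groupby(["arm", "call"]):
        events[f"{arm}_{call}"] = 0
        events.loc[grp["sample_id"], f"{arm}_{call}"] = 1
    cohort = pheno.join(events, how="inner")

    assoc = associate_segments(cohort, list(events.columns))
    assoc.to_csv(args.out / "associations.tsv", sep="\t", index=False,
                 float_format="%.5g")
    hits = assoc[assoc.get("significant", False) == True]  # noqa: E712
    print(f"association tests: {len(assoc)} run, {len(hits)} significant at q<=0.05")
    for _, r in hits.iterrows():
        print(f"  {r['event']} x {r['variable']} ({r['test']}): "
              f"p={r['p']:.3g} q={r['q']:.3g}")

    # group comparison: IDH mutation by codel status
    tab = pd.crosstab(
        cohort["idh_status"] == "mutated", cohort["codel"] == 1
    ).reindex(index=[True, False], columns=[True, False], fill_value=0)
    p_idh = fisher_exact_2x2(tab.to_numpy())
    print(f"IDH-mutated in codel vs non-codel: "
          f"{tab.loc[True, True]}/{int(tab[True].sum())} vs "
          f"{tab.loc[True, False]}/{int(tab[False].sum())} (Fisher p={p_idh:.3g})")

    sex_tab = pd.crosstab(cohort["sex"], cohort["codel"]).to_numpy()
    chi2, p_sex = chi2_yates(sex_tab)
    t_age, p_age = welch_t(
        cohort.loc[cohort["codel"] == 1, "age"],
        cohort.loc[cohort["codel"] == 0, "age"],
    )
    print(f"sex by codel (Yates chi2): chi2={chi2:.3f} p={p_sex:.3f}; "
          f"age (Welch t): t={t_age:.3f} p={p_age:.3f}")

    # survival by codel status
    rows = []
    grp = cohort["codel"].map({1: "codel", 0: "non_codel"})
    for endpoint in ("pfs", "os"):
        t, e = cohort[f"{endpoint}_days"], cohort[f"{endpoint}_event"]
        chi2, p, comp = logrank(t, e, grp)
        for g in sorted(grp.unique()):
            sel = grp == g
            sf, med = km_curve(t[sel], e[sel])
            sf.assign(endpoint=endpoint, group=g).to_csv(
                args.out / f"km_{endpoint}_{g}.tsv", sep="\t", index=False,
                float_format="%.5g",
            )
            rows.append({"endpoint": endpoint, "group": g, "n": int(sel.sum()),
                         "median_days": med, "logrank_chi2": round(chi2, 4),
                         "logrank_p": round(p, 4)})
        print(f"{endpoint.upper()}: log-rank chi2={chi2:.3f} p={p:.3f}")
    surv = pd.DataFrame(rows)
    surv.to_csv(args.out / "survival.tsv", sep="\t", index=False)
    print(surv.to_string(index=False))
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
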