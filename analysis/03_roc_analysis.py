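#!/usr/bin/env python
"""ROC and prevalence-adjusted precision-recall analysis.

Computes the study's headline discriminations on the discovery-like cohort
(published AUCs are all > 0.9 for these pairs), compares EV TDP-43 against
plasma NfL for ALS-vs-HC with the paired placement-value test, and
re-expresses the ALS discrimination as a precision-recall curve at a
configurable population prevalence (prevalences are user-supplied
configuration, not published values).
"""

from pathlib import Path

import pandas as pd

import evb
from evb.pipeline import stage_seed

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "roc"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 4242

PAIRS = [
    ("PSP", "HC", "tau_ratio", "lower_is_positive"),
    ("PSP", "ALS", "tau_ratio", "lower_is_positive"),
    ("PSP", "bvFTD", "tau_ratio", "lower_is_positive"),
    ("bvFTD", "HC", "tau_ratio", "higher_is_positive"),
    ("ALS", "HC", "tdp43", "higher_is_positive"),
    ("ALS", "PSP", "tdp43", "higher_is_positive"),
    ("ALS", "bvFTD", "tdp43", "higher_is_positive"),
]

# illustrative rare-disease population prevalence for the PR re-expression
PR_PREVALENCE = {"ALS": 1e-4, "PSP": 5e-5}


def main():
    table = pd.read_csv(ROOT / "cohorts" / "DESCRIBE-2.csv")
    rows = []
    for pos_name, neg_name, marker, orientation in PAIRS:
        pos = table.loc[table["diagnosis"] == pos_name, marker].dropna()
        neg = table.loc[table["diagnosis"] == neg_name, marker].dropna()
        roc = evb.auc_mann_whitney(pos, neg, orientation=orientation)
        rows.append(
            {
                "positive": pos_name, "negative": neg_name, "marker": marker,
                "auc": roc.auc, "se": roc.se, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            }
        )
        print(f"{marker:9s} {pos_name:5s} vs {neg_name:5s}: AUC {roc.auc:.3f} (SE {roc.se:.3f}, CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
    pd.DataFrame(rows).to_csv(OUT / "auc.csv", index=False)

    # EV TDP-43 vs plasma NfL for ALS detection, same subjects -> paired test
    als = table[table["diagnosis"] == "ALS"].dropna(subset=["tdp43", "nfl"])
    hc = table[table["diagnosis"] == "HC"].dropna(subset=["tdp43", "nfl"])
    roc_tdp = evb.auc_mann_whitney(als["tdp43"], hc["tdp43"])
    roc_nfl = evb.auc_mann_whitney(als["nfl"], hc["nfl"])
    z, p = evb.compare_auc(
        roc_tdp, roc_nfl, paired=True,
        scores=(als["tdp43"].to_numpy(), hc["tdp43"].to_numpy(), als["nfl"].to_numpy(), hc["nfl"].to_numpy()),
    )
    print(f"ALS vs HC: EV TDP-43 AUC {roc_tdp.auc:.3f} vs plasma NfL AUC {roc_nfl.auc:.3f} (paired z = {z:.2f}, p = {p:.2g})")

    pr_rows = []
    for diag, rho in PR_PREVALENCE.items():
        marker = "tdp43" if diag == "ALS" else "tau_ratio"
        orientation = "higher_is_positive" if diag == "ALS" else "lower_is_positive"
        pos = table.loc[table["diagnosis"] == diag, marker].dropna()
        neg = table.loc[table["diagnosis"] == "HC", marker].dropna()
        roc = evb.auc_mann_whitney(pos, neg, orientation=orientation)
        pr = evb.pr_with_prevalence(
            roc, rho, n_boot=200, seed=stage_seed(SEED, f"pr:{diag}"), scores=(pos.to_numpy(), neg.to_numpy())
        )
        pr_rows.append({"diagnosis": diag, "marker": marker, "prevalence": rho,
                        "auprc": pr.auprc, "ci_low": pr.ci_low, "ci_high": pr.ci_high})
        print(f"{diag}: AUPRC at prevalence {rho:g} = {pr.auprc:.3f} (bootstrap CI {pr.ci_low:.3f}-{pr.ci_high:.3f})")
    pd.DataFrame(pr_rows).to_csv(OUT / "pr.csv", index=False)


if __name__ == "__main__":
    main()
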