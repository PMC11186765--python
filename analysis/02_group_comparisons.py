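#!/usr/bin/env python
"""Group-level marker comparisons and NfL correlations.

On the discovery-like cohort: Kruskal-Wallis with Dunn's correction for
both markers across the four diagnostic groups, and within-group Spearman
correlations of each marker with plasma NfL.  The published pattern this
should reproduce: tau ratio lowest in PSP and elevated in (half of) bvFTD,
TDP-43 highest in ALS, tau-NfL correlation negative in PSP and positive in
bvFTD, TDP-43-NfL strongly positive in ALS.
"""

from pathlib import Path

import pandas as pd

import evb

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stats"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    table = pd.read_csv(ROOT / "cohorts" / "DESCRIBE-2.csv")
    diagnoses = sorted(table["diagnosis"].unique())

    frames = []
    for marker in ("tau_ratio", "tdp43"):
        groups = [table.loc[table["diagnosis"] == d, marker].dropna() for d in diagnoses]
        res = evb.dunn_pairwise(groups, diagnoses)
        print(f"{marker}: Kruskal-Wallis H = {res.h_statistic:.1f} (df {res.df}), global p = {res.p_global:.3g}")
        frame = res.to_frame()
        frame.insert(0, "marker", marker)
        frames.append(frame)
        for _, row in frame.iterrows():
            print(f"  {row.group_a:7s} vs {row.group_b:7s} z = {row.z:7.2f}  adj. p = {row.p_adjusted:.3g}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "dunn_pairwise.csv", index=False)

    corr_rows = []
    for diag in diagnoses:
        sub = table[table["diagnosis"] == diag]
        if sub["nfl"].notna().sum() < 3:
            continue
        cm = evb.spearman_matrix(sub, ["tau_ratio", "tdp43", "nfl"])
        frame = cm.to_frame()
        frame.insert(0, "diagnosis", diag)
        corr_rows.append(frame)
        for _, row in frame[frame["var_b"] == "nfl"].iterrows():
            print(f"  {diag:7s} {row.var_a:9s} vs NfL: rho = {row.rho:+.2f} (p = {row.p:.2g}, n = {row.n})")
    pd.concat(corr_rows, ignore_index=True).to_csv(OUT / "spearman_nfl.csv", index=False)

    # monotone trend of NfL in tau ratio within PSP (illustrative isotonic fit)
    psp = table[table["diagnosis"] == "PSP"].dropna(subset=["tau_ratio", "nfl"])
    fit = evb.monotone_fit(psp["tau_ratio"].to_numpy(), psp["nfl"].to_numpy(), direction="auto")
    pd.DataFrame({"tau_ratio": psp["tau_ratio"], "nfl": psp["nfl"], "fit": fit}).to_csv(
        OUT / "psp_isotonic_nfl.csv", index=False
    )
    direction = "decreasing" if fit[psp["tau_ratio"].argsort().iloc[-1]] <= fit[psp["tau_ratio"].argsort().iloc[0]] else "increasing"
    print(f"  PSP isotonic NfL trend over tau ratio: {direction}")


if __name__ == "__main__":
    main()
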