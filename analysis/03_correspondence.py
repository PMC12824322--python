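"""Neural-to-behavioural correspondence with autocorrelation control.

For each network, lag-aligns the group-mean awake-story neural TTM to
the group-mean suspense TTM (3 TRs = the 6 s HRF peak), computes Kendall
Tau-A on the full and autocorrelation-masked lower triangles (k = 10 and
24), runs the timepoint-permutation test, applies BH-FDR across
networks, and traces the stabilisation curve that motivates those k
values. Tables land under results/.

Run after 02:  python analysis/03_correspondence.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ttmdyn.correspondence import fdr_bh, permutation_test, stabilisation_curve
from ttmdyn.ttm import TTM, lag_align, mean_ttm

SCRATCH = Path("scratch")
RESULTS = Path("results")
N_PERM = 2000
KS = (10, 24)


def load_ttms():
    data = np.load(SCRATCH / "ttms.npz")
    index = pd.read_csv(SCRATCH / "ttm_index.csv")
    ids = data["timepoint_ids"]
    return data, index, ids


def main() -> None:
    seed = json.loads((SCRATCH / "cohort" / "spec_seed.json").read_text())["seed"]
    data, index, ids = load_ttms()
    neural = data["neural"]  # materialise once; npz members decompress per access
    beh_mean = TTM(values=data["behavioural_mean"], kind="mean",
                   timepoint_ids=ids)
    rows = []
    group_ttms = {}
    for label, sub in index.groupby("network"):
        sel = sub[(sub["level"] == "awake") & (sub["task"] == "story")]
        stack = [
            TTM(values=neural[i], kind="neural", timepoint_ids=ids)
            for i in sel.index
        ]
        group = mean_ttm(stack)
        group.kind = "neural"
        group_ttms[label] = group
        for k in KS:
            n_al, b_al = lag_align(group, beh_mean, 3)
            res = permutation_test(n_al, b_al, k=k, n_perm=N_PERM,
                                   seed=seed + k, network_label=label)
            rows.append({"network": label, "k": k, "tau_full": res.tau_a_full,
                         "tau_masked": res.tau_a_masked, "p": res.p_perm,
                         "n_perm": N_PERM})
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for k in KS:
        sel = df["k"] == k
        df.loc[sel, "q"] = fdr_bh(df.loc[sel, "p"].to_numpy())
    df.to_csv(RESULTS / "correspondence.csv", index=False)

    k_grid = list(range(0, 29, 2))
    curves = []
    for label, group in group_ttms.items():
        n_al, b_al = lag_align(group, beh_mean, 3)
        curves.append(stabilisation_curve([n_al], b_al, k_grid).mean_similarity)
    curve_df = pd.DataFrame({"k": k_grid, "mean_tau": np.mean(curves, axis=0)})
    curve_df.to_csv(RESULTS / "stabilisation_curve.csv", index=False)

    print("correspondence (group awake-story neural TTM vs mean suspense TTM):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nhigher tau for shared-drive networks (AUD > DMN-B) indicates the "
          "pipeline recovers the planted stimulus entrainment; q = BH-FDR "
          "across networks within each k.")


if __name__ == "__main__":
    main()
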