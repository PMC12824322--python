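"""Intersubject similarity contrasts across consciousness levels.

Computes IntSS (Fisher-z TTM correlation between all 120 subject pairs)
per network x level x task, the awake-vs-deep Wilcoxon contrasts per
network (Bonferroni-corrected, bootstrap SEM n = 1000), the
3-level x network interaction ANOVA with a continuous awareness
predictor, and the per-network level x task interaction. Tables land
under results/.

Run after 02:  python analysis/04_intersubject.py
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ttmdyn.intersubject import (
    anova_level_by_network,
    anova_level_by_task,
    bonferroni,
    contrast_levels,
    intss_pairwise,
    pair_table,
)
from ttmdyn.ttm import TTM

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    seed = json.loads((SCRATCH / "cohort" / "spec_seed.json").read_text())["seed"]
    data = np.load(SCRATCH / "ttms.npz")
    neural = data["neural"]  # materialise once; npz members decompress per access
    index = pd.read_csv(SCRATCH / "ttm_index.csv")
    ids = data["timepoint_ids"]

    intss = {}
    for (label, level, task), sub in index.groupby(["network", "level", "task"]):
        sub = sub.sort_values("subject")
        stack = [
            TTM(values=neural[i], kind="neural", timepoint_ids=ids)
            for i in sub.index
        ]
        intss[(label, level, task)] = intss_pairwise(
            stack, list(sub["subject"]), label, level, task
        )
    pairs = pair_table(list(intss.values()))
    pairs.to_csv(RESULTS / "intss_pairs.csv", index=False)

    networks = sorted(index["network"].unique())
    contrasts = [
        contrast_levels(intss[(n, "awake", "story")], intss[(n, "deep", "story")],
                        n_boot=1000, seed=seed + 5)
        for n in networks
    ]
    p_bonf = bonferroni([c.p_raw for c in contrasts])
    for c, pb in zip(contrasts, p_bonf):
        c.p_bonferroni = float(pb)
    cdf = pd.DataFrame([asdict(c) for c in contrasts])
    cdf.to_csv(RESULTS / "contrasts_awake_vs_deep_story.csv", index=False)

    rows = []
    story = pairs[pairs["task"] == "story"]
    a1 = anova_level_by_network(story)
    rows.append({"design": a1.design, "network": "all", "F": a1.F_interaction,
                 "p": a1.p_interaction, "p_bonf": np.nan})
    per_net = [anova_level_by_task(pairs[pairs["network"] == n]) for n in networks]
    for n, r, pb in zip(networks, per_net,
                        bonferroni([r.p_interaction for r in per_net])):
        rows.append({"design": r.design, "network": n, "F": r.F_interaction,
                     "p": r.p_interaction, "p_bonf": float(pb)})
    adf = pd.DataFrame(rows)
    adf.to_csv(RESULTS / "anova_interactions.csv", index=False)

    print("awake-vs-deep story contrasts (positive z = higher IntSS awake):")
    print(cdf[["network_label", "z", "p_raw", "p_bonferroni", "mean_diff",
               "sem_boot"]].to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
    print("\ninteraction ANOVAs (level coded 1..3 continuous):")
    print(adf.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nexpected pattern: shared networks (AUD) lose intersubject "
          "similarity under sedation (z > 0), idiosyncratic ones (DMN-B) "
          "gain it (z < 0); the level x network interaction captures this "
          "divergence.")


if __name__ == "__main__":
    main()
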