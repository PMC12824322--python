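"""Build neural and behavioural time-by-time similarity matrices.

Reads the cohort written by 01_simulate_cohort.py, runs the band-pass ->
Hilbert phase -> cosine-IPS -> Pearson TTM chain per subject, condition
and network (edge-trimming the first/last 3 timepoints), builds the
per-rater behavioural TTMs plus their group mean and CV, and caches
everything to scratch/ttms.npz for the downstream statistics drivers.

Run after 01:  python analysis/02_build_ttms.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ttmdyn.io import PipelineConfig, networks_of, read_network_map, read_ratings, read_timeseries
from ttmdyn.pipeline import behavioural_ttms, subject_network_ttm
from ttmdyn.ttm import match_rest_length

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    cohort = SCRATCH / "cohort"
    seed = json.loads((cohort / "spec_seed.json").read_text())["seed"]
    config = PipelineConfig(seed=seed)
    netmap = read_network_map(cohort / "network_map.tsv")
    networks = networks_of(netmap)
    files = sorted(p for p in cohort.glob("*.tsv") if p.name != "network_map.tsv")
    timeseries = [read_timeseries(p) for p in files]
    story_len = min(t.n_timepoints for t in timeseries if t.task == "story")

    keys, mats = [], []
    for ts in timeseries:
        run = ts if ts.task == "story" else match_rest_length(ts, story_len)
        for label, parcels in networks.items():
            ttm = subject_network_ttm(run, parcels, label, config)
            keys.append((ts.subject_id, ts.level, ts.task, label))
            mats.append(ttm.values)
    ratings = read_ratings(cohort / "ratings.csv")
    per_rater, beh_mean, beh_cv = behavioural_ttms(ratings, config)

    index = pd.DataFrame(keys, columns=["subject", "level", "task", "network"])
    np.savez_compressed(
        SCRATCH / "ttms.npz",
        neural=np.stack(mats),
        timepoint_ids=np.arange(config.trim_head, story_len - config.trim_tail),
        behavioural_mean=beh_mean.values,
        behavioural_cv=beh_cv.values,
        behavioural_stack=np.stack([t.values for t in per_rater]),
    )
    index.to_csv(SCRATCH / "ttm_index.csv", index=False)

    RESULTS.mkdir(exist_ok=True)
    max_cv = float(beh_cv.values.max())
    summary = pd.DataFrame(
        [
            {
                "n_neural_ttms": len(mats),
                "ttm_size": mats[0].shape[0],
                "neural_diag_ok": bool(
                    np.allclose([np.diag(m) for m in mats], 1.0)
                ),
                "behavioural_max_cv": max_cv,
                "behavioural_mean_range_lo": float(beh_mean.values.min()),
                "behavioural_mean_range_hi": float(beh_mean.values.max()),
            }
        ]
    )
    summary.to_csv(RESULTS / "ttm_summary.csv", index=False)
    print(f"built {len(mats)} neural TTMs of size {mats[0].shape[0]} "
          f"(trimmed from {story_len}) across {len(networks)} networks")
    print(f"behavioural TTMs: {len(per_rater)} raters; max cell CV across "
          f"raters = {max_cv:.2f} (low values = raters largely agree)")


if __name__ == "__main__":
    main()
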