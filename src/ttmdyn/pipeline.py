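"""End-to-end orchestration: simulate -> phase -> TTM -> statistics -> report.

``run_pipeline`` executes every stage on a synthetic cohort (or on
on-disk parcel timeseries laid out per :mod:`ttmdyn.io`), writes all
intermediate artifacts and tables under the configured output directory,
and returns the report bundle in memory. Every output carries the config
hash that produced it; the run log records the master seed and all
derived stream seeds.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, ParcelTimeseries, RatingSeries, generate_cohort, network_map
from .complexity import delta_association, delta_table, ttm_entropy
from .correspondence import fdr_bh, permutation_test, stabilisation_curve
from .intersubject import (
    anova_level_by_network,
    anova_level_by_task,
    bonferroni,
    contrast_levels,
    intss_pairwise,
    pair_table,
)
from .io import (
    PipelineConfig,
    networks_of,
    read_network_map,
    read_ratings,
    read_timeseries,
    write_network_map,
    write_ratings,
    write_timeseries,
    write_ttm,
)
from .phase import bandpass, instantaneous_phase, ips_tensor
from .ttm import (
    TTM,
    behavioural_ttm,
    cv_ttm,
    lag_align,
    mean_ttm,
    neural_ttm,
    match_rest_length,
    trim_edges,
)


def subject_network_ttm(
    ts: ParcelTimeseries,
    parcels: list[str],
    network_label: str,
    config: PipelineConfig,
) -> TTM:
    """One subject/condition/network: band-pass -> IPS -> TTM -> trim."""
    filtered = bandpass(ts, *config.band)
    phases = instantaneous_phase(filtered, band=config.band)
    tensor = ips_tensor(
        phases, parcels, network_label=network_label, variant=config.ips_variant
    )
    return trim_edges(neural_ttm(tensor), config.trim_head, config.trim_tail)


def behavioural_ttms(
    ratings: list[RatingSeries], config: PipelineConfig
) -> tuple[list[TTM], TTM, TTM]:
    """Per-rater, mean and CV behavioural TTMs (trimmed like the neural)."""
    per_rater = [
        trim_edges(behavioural_ttm(r), config.trim_head, config.trim_tail)
        for r in ratings
    ]
    return per_rater, mean_ttm(per_rater), cv_ttm(per_rater)


def _load_or_simulate(
    config: PipelineConfig, out: Path
) -> tuple[list[ParcelTimeseries], list[RatingSeries], dict[str, str]]:
    if config.timeseries_dir is None:
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            n_raters=config.n_raters,
            n_timepoints=config.n_timepoints,
            tr=config.tr,
            seed=config.seed,
        )
        timeseries, ratings, truth = generate_cohort(spec)
        netmap = network_map(spec)
        cohort_dir = out / "cohort"
        cohort_dir.mkdir(parents=True, exist_ok=True)
        for ts in timeseries:
            write_timeseries(
                ts, cohort_dir / f"{ts.subject_id}_{ts.level}_{ts.task}.tsv"
            )
        write_ratings(ratings, cohort_dir / "ratings.csv")
        write_network_map(netmap, cohort_dir / "network_map.tsv")
        (cohort_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        return timeseries, ratings, netmap
    ts_dir = Path(config.timeseries_dir)
    timeseries = [read_timeseries(p) for p in sorted(ts_dir.glob("*.tsv"))]
    if not timeseries:
        raise FileNotFoundError(f"no .tsv timeseries under {ts_dir}")
    ratings = read_ratings(config.ratings_path)
    netmap = read_network_map(config.network_map_path)
    missing = [p for p in timeseries[0].parcel_ids if p not in netmap]
    if missing:
        raise ValueError(f"parcels missing from network map: {missing[:5]}")
    return timeseries, ratings, netmap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle and writes it under
    ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    stage = "setup"
    try:
        timeseries, ratings, netmap = _load_or_simulate(config, out)
        networks = networks_of(netmap)
        story_len = min(
            ts.n_timepoints for ts in timeseries if ts.task == "story"
        )

        stage = "neural TTMs"
        ttm_dir = out / "ttm"
        ttm_dir.mkdir(exist_ok=True)
        neural: dict[tuple[str, str, str, str], TTM] = {}
        for ts in timeseries:
            run = ts if ts.task == "story" else match_rest_length(ts, story_len)
            for label, parcels in networks.items():
                t = subject_network_ttm(run, parcels, label, config)
                neural[(ts.subject_id, ts.level, ts.task, label)] = t
        levels = sorted({ts.level for ts in timeseries})
        tasks = sorted({ts.task for ts in timeseries})
        subjects = sorted({ts.subject_id for ts in timeseries})

        stage = "behavioural TTMs"
        per_rater, beh_mean, beh_cv = behavioural_ttms(ratings, config)
        write_ttm(beh_mean, ttm_dir / "behavioural_mean.csv", {"config": cfg_hash})
        write_ttm(beh_cv, ttm_dir / "behavioural_cv.csv", {"config": cfg_hash})

        stage = "correspondence"
        corr_rows = []
        group_story: dict[str, TTM] = {}
        for label in networks:
            stack = [neural[(s, "awake", "story", label)] for s in subjects]
            group = mean_ttm(stack)
            group.kind = "neural"
            group_story[label] = group
            write_ttm(
                group, ttm_dir / f"neural_mean_awake_story_{label}.csv",
                {"config": cfg_hash},
            )
        for k in config.autocorr_k:
            for label, group in group_story.items():
                n_al, b_al = lag_align(group, beh_mean, config.lag_trs)
                res = permutation_test(
                    n_al, b_al, k=k, n_perm=config.n_perm,
                    seed=config.seed + 101 + k, network_label=label,
                )
                corr_rows.append(
                    {
                        "network": label,
                        "k": k,
                        "tau_full": res.tau_a_full,
                        "tau_masked": res.tau_a_masked,
                        "p": res.p_perm,
                        "n_perm": res.n_perm,
                    }
                )
        corr_df = pd.DataFrame(corr_rows)
        corr_df["q"] = np.nan
        for k in config.autocorr_k:
            sel = corr_df["k"] == k
            corr_df.loc[sel, "q"] = fdr_bh(corr_df.loc[sel, "p"].to_numpy())
        corr_df.to_csv(out / "correspondence.csv", index=False)

        stage = "stabilisation curve"
        k_grid = list(range(0, 29, 4))
        first = next(iter(group_story))
        n_al, b_al = lag_align(group_story[first], beh_mean, config.lag_trs)
        curves = []
        for label, group in group_story.items():
            n_al, b_al = lag_align(group, beh_mean, config.lag_trs)
            c = stabilisation_curve([n_al], b_al, k_grid)
            curves.append(c.mean_similarity)
        curve_df = pd.DataFrame(
            {"k": k_grid, "mean_tau": np.mean(curves, axis=0)}
        )
        curve_df.to_csv(out / "stabilisation_curve.csv", index=False)

        stage = "intersubject similarity"
        intss = {}
        for label in networks:
            for level in levels:
                for task in tasks:
                    stack = [neural[(s, level, task, label)] for s in subjects]
                    intss[(label, level, task)] = intss_pairwise(
                        stack, subjects, label, level, task
                    )
        pair_df = pair_table(list(intss.values()))
        pair_df.to_csv(out / "intss_pairs.csv", index=False)

        stage = "contrasts"
        contrast_rows = []
        if "awake" in levels and "deep" in levels:
            results = [
                contrast_levels(
                    intss[(label, "awake", "story")],
                    intss[(label, "deep", "story")],
                    n_boot=config.n_boot,
                    seed=config.seed + 202,
                )
                for label in networks
            ]
            p_bonf = bonferroni([r.p_raw for r in results])
            for r, pb in zip(results, p_bonf):
                r.p_bonferroni = float(pb)
                contrast_rows.append(asdict(r))
        contrast_df = pd.DataFrame(contrast_rows)
        contrast_df.to_csv(out / "contrasts_awake_vs_deep_story.csv", index=False)

        stage = "anova"
        anova_rows = []
        story_pairs = pair_df[pair_df["task"] == "story"]
        if len(networks) >= 2 and len(levels) == 3:
            res = anova_level_by_network(story_pairs)
            anova_rows.append(
                {"design": res.design, "network": "all",
                 "F": res.F_interaction, "p": res.p_interaction, "p_bonf": np.nan}
            )
        if len(tasks) == 2 and len(levels) == 3:
            per_net = [
                anova_level_by_task(pair_df[pair_df["network"] == label])
                for label in networks
            ]
            p_bonf = bonferroni([r.p_interaction for r in per_net])
            for label, r, pb in zip(networks, per_net, p_bonf):
                anova_rows.append(
                    {"design": r.design, "network": label,
                     "F": r.F_interaction, "p": r.p_interaction,
                     "p_bonf": float(pb)}
                )
        anova_df = pd.DataFrame(anova_rows)
        anova_df.to_csv(out / "anova_interactions.csv", index=False)

        stage = "entropy"
        ent_rows = [
            {
                "subject_id": s,
                "network": label,
                "level": level,
                "task": "story",
                "entropy": ttm_entropy(
                    neural[(s, level, "story", label)],
                    n_bins=config.n_bins,
                    scaling=config.scaling,
                ),
                "n_bins": config.n_bins,
            }
            for label in networks
            for level in levels
            for s in subjects
        ]
        ent_df = pd.DataFrame(ent_rows)
        ent_df.to_csv(out / "entropy_records.csv", index=False)

        delta_df = pd.DataFrame()
        rho = np.nan
        if {"awake", "deep"}.issubset(levels):
            summaries = (
                pair_df[pair_df["task"] == "story"]
                .groupby(["network", "level"])["value"]
                .mean()
                .rename("mean_intss")
                .reset_index()
            )
            delta_df = delta_table(ent_df, summaries)
            if len(delta_df) >= 3:
                rho = delta_association(delta_df).rho
            delta_df.to_csv(out / "delta_association.csv", index=False)

        stage = "report"
        from . import __version__ as pkg_version

        log = {
            "ttmdyn_version": pkg_version,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "config": json.loads(config.to_json()),
            "config_hash": cfg_hash,
            "master_seed": config.seed,
            "derived_seeds": {
                "permutation": [config.seed + 101 + k for k in config.autocorr_k],
                "bootstrap": config.seed + 202,
            },
            "story_length_used": story_len,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
        return {
            "correspondence": corr_df,
            "stabilisation_curve": curve_df,
            "intss_pairs": pair_df,
            "contrasts": contrast_df,
            "anova": anova_df,
            "entropy": ent_df,
            "delta_association": delta_df,
            "delta_rho": rho,
            "config_hash": cfg_hash,
            "output_dir": str(out),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
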