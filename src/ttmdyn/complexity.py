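"""Shannon entropy of TTMs and the entropy / intersubject-similarity link.

The entropy of the histogram of a subject's TTM cells indexes how rich
the individual's dynamic landscape is: a system lingering in one
similarity regime yields a concentrated histogram (low entropy), a
system visiting many similarity levels a spread one (high entropy).
Comparing the awake-minus-deep change in entropy with the corresponding
change in intersubject similarity, network by network, asks whether the
dynamics that become more idiosyncratic in consciousness are also the
ones that become more complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ttm import TTM

SCALINGS = ("minmax", "fixed", "clip")


@dataclass(frozen=True)
class EntropyRecord:
    subject_id: str
    network_label: str
    level: str
    task: str
    entropy: float
    n_bins: int


@dataclass(frozen=True)
class DeltaAssociation:
    """Per-network awake-minus-deep deltas and their rank correlation."""

    table: pd.DataFrame  # columns: network, delta_entropy, delta_intss
    rho: float
    n_networks: int


def ttm_entropy(
    ttm: TTM | np.ndarray,
    n_bins: int = 256,
    scaling: str = "minmax",
    include_diagonal: bool = True,
) -> float:
    """Shannon entropy (bits) of the histogram of TTM cells.

    Cells are mapped to [0, 1] by the chosen scaling — ``minmax`` (full
    observed range; information-preserving default), ``fixed`` (the
    neural similarity range [-1, 1]), or ``clip`` (clip to [0, 1], the
    behaviour of 8-bit image-entropy routines, which discards negative
    correlations) — then binned into ``n_bins`` equal bins; empty bins
    contribute nothing. Bounds: 0 (constant matrix, warned) to
    log2(n_bins) (uniform occupation).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    vals = ttm.values if isinstance(ttm, TTM) else np.asarray(ttm, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("TTM contains non-finite values")
    if not include_diagonal and vals.ndim == 2:
        vals = vals[~np.eye(vals.shape[0], dtype=bool)]
    flat = vals.ravel()
    if scaling == "minmax":
        lo, hi = flat.min(), flat.max()
        if hi - lo < 1e-15:
            warnings.warn("constant TTM: entropy is 0 bits", stacklevel=2)
            return 0.0
        scaled = (flat - lo) / (hi - lo)
    elif scaling == "fixed":
        scaled = (flat + 1.0) / 2.0
        if scaled.min() < 0 or scaled.max() > 1:
            raise ValueError("fixed scaling expects values in [-1, 1]")
    else:
        scaled = np.clip(flat, 0.0, 1.0)
    counts, _ = np.histogram(scaled, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def delta_table(
    entropy_records: pd.DataFrame,
    intss_summaries: pd.DataFrame,
    level_a: str = "awake",
    level_b: str = "deep",
) -> pd.DataFrame:
    """Per-network awake-minus-deep deltas of entropy and IntSS.

    ``entropy_records``: columns subject_id, network, level, entropy (one
    row per subject x network x level). ``intss_summaries``: columns
    network, level, mean_intss. Entropy deltas are taken within subject
    then averaged across subjects; IntSS deltas are differences of the
    per-network pair means.
    """
    for col in ("subject_id", "network", "level", "entropy"):
        if col not in entropy_records.columns:
            raise ValueError(f"entropy_records missing column {col!r}")
    for col in ("network", "level", "mean_intss"):
        if col not in intss_summaries.columns:
            raise ValueError(f"intss_summaries missing column {col!r}")
    ent = entropy_records.pivot_table(
        index=["network", "subject_id"], columns="level", values="entropy"
    )
    for lv in (level_a, level_b):
        if lv not in ent.columns or ent[lv].isna().any():
            raise ValueError(f"missing {lv!r} entropy for some subject/network")
    d_ent = (ent[level_a] - ent[level_b]).groupby("network").mean()

    ints = intss_summaries.pivot_table(
        index="network", columns="level", values="mean_intss"
    )
    for lv in (level_a, level_b):
        if lv not in ints.columns or ints[lv].isna().any():
            raise ValueError(f"missing {lv!r} IntSS for some network")
    d_int = ints[level_a] - ints[level_b]

    out = pd.DataFrame(
        {"delta_entropy": d_ent, "delta_intss": d_int}
    ).reset_index()
    if out.isna().any().any():
        raise ValueError("entropy and IntSS tables cover different networks")
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def delta_association(deltas: pd.DataFrame) -> DeltaAssociation:
    """Spearman correlation between per-network ΔIntSS and Δentropy."""
    rho = spearman_rho(deltas["delta_intss"], deltas["delta_entropy"])
    return DeltaAssociation(table=deltas, rho=rho, n_networks=len(deltas))
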