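"""Correspondence between neural and behavioural TTMs.

Rank agreement is measured with Kendall's Tau-A rather than Tau-B/C or
Spearman: behavioural TTMs built from Likert ratings are saturated with
ties, and Tau-A keeps tied pairs in the denominator instead of rescaling
them away, so it does not reward degenerate (constant-ish) models.

Significance comes from a permutation null that relabels the behavioural
TTM's timepoints (rows and columns jointly, preserving matrix validity)
and re-masks with the original proximity rule: because permutation
destroys the autocorrelational structure intrinsic to any TTM, cells
within |i-j| <= k of the diagonal are stripped from both the observed and
the null statistics so that autocorrelation cannot inflate significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ttm import TTM, MaskedVector, mask_autocorr


@dataclass
class CorrespondenceResult:
    network_label: str
    tau_a_full: float
    tau_a_masked: float
    p_perm: float
    k: int
    n_perm: int
    seed: int
    q_fdr: float | None = None


@dataclass(frozen=True)
class StabilisationCurve:
    """Mean Tau-A as a function of the autocorrelation band width k."""

    k_values: np.ndarray
    mean_similarity: np.ndarray


def _tie_pair_count(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def kendall_tau_a(
    x: MaskedVector | np.ndarray, y: MaskedVector | np.ndarray
) -> float:
    """Kendall's Tau-A: (concordant - discordant) / (n(n-1)/2).

    Tied pairs count in the denominator only. Computed via the O(n log n)
    Tau-B statistic un-normalised back to the raw concordant-minus-
    discordant count (an integer, recovered exactly by rounding).
    """
    xv = np.asarray(x.values if isinstance(x, MaskedVector) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, MaskedVector) else y, dtype=float)
    if xv.ndim != 1 or yv.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape[0]} vs {yv.shape[0]}")
    n = xv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    n0 = n * (n - 1) // 2
    tx, ty = _tie_pair_count(xv), _tie_pair_count(yv)
    if tx == n0 or ty == n0:
        return 0.0  # a constant input leaves no non-tied pairs
    tau_b = stats.kendalltau(xv, yv).statistic
    cd = round(float(tau_b) * float(np.sqrt((n0 - tx) * (n0 - ty))))
    return cd / n0


def permutation_test(
    neural: TTM,
    behavioural: TTM,
    k: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
    network_label: str = "",
    alternative: str = "greater",
) -> CorrespondenceResult:
    """Tau-A with a symmetry-preserving timepoint-permutation null.

    The null permutes the behavioural TTM's timepoint labels jointly over
    rows and columns, then re-masks with the ORIGINAL |i-j| <= k band
    (pre-permutation indices define proximity). One-sided by default
    (positive correspondence); ``alternative='two-sided'`` available.
    p = (1 + #{null >= observed}) / (1 + n_perm), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    full_a, full_b = mask_autocorr(neural, behavioural, 0)
    tau_full = kendall_tau_a(full_a, full_b)
    masked_a, masked_b = mask_autocorr(neural, behavioural, k)
    tau_obs = kendall_tau_a(masked_a, masked_b)

    # Positional lower-triangle indices surviving the original mask.
    T = neural.n_timepoints
    ids = neural.timepoint_ids
    il = np.tril_indices(T, k=-1)
    keep = np.abs(ids[il[0]] - ids[il[1]]) > k
    rows, cols = il[0][keep], il[1][keep]
    xv = neural.values[rows, cols]
    B = behavioural.values

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(T)
        null_tau = kendall_tau_a(xv, B[perm[rows], perm[cols]])
        if alternative == "greater":
            exceed += null_tau >= tau_obs
        else:
            exceed += abs(null_tau) >= abs(tau_obs)
    p = (1 + exceed) / (1 + n_perm)
    return CorrespondenceResult(
        network_label=network_label,
        tau_a_full=tau_full,
        tau_a_masked=tau_obs,
        p_perm=p,
        k=k,
        n_perm=n_perm,
        seed=seed,
    )


def stabilisation_curve(
    neural_stack: list[TTM], behavioural: TTM, k_values: list[int]
) -> StabilisationCurve:
    """Mean Tau-A across subjects as a function of the removed band width.

    Plateaus in this curve indicate band widths beyond which
    autocorrelation no longer drives the neural-behavioural similarity;
    they motivate the default reporting bands.
    """
    ks = np.asarray(k_values, dtype=int)
    if ks.size == 0:
        raise ValueError("k_values must be non-empty")
    if np.any(np.diff(ks) <= 0):
        raise ValueError("k_values must be strictly increasing")
    means = np.empty(ks.size)
    for i, k in enumerate(ks):
        taus = []
        for neural in neural_stack:
            ma, mb = mask_autocorr(neural, behavioural, int(k))
            taus.append(kendall_tau_a(ma, mb))
        means[i] = float(np.mean(taus))
    return StabilisationCurve(k_values=ks, mean_similarity=means)


def detect_plateau(curve: StabilisationCurve, flat_tol: float = 0.005) -> int:
    """First k at which successive mean similarities stop changing by more
    than ``flat_tol`` — a simple plateau detector for the curve above."""
    diffs = np.abs(np.diff(curve.mean_similarity))
    flat = np.flatnonzero(diffs <= flat_tol)
    if flat.size == 0:
        return int(curve.k_values[-1])
    return int(curve.k_values[flat[0] + 1])


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
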