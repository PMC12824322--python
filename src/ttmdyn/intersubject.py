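"""Intersubject similarity (IntSS) of TTMs and its condition contrasts.

Two subjects' dynamic landscapes are compared by Pearson-correlating the
Fisher-z-transformed vectorised lower triangles of their neural TTMs:
with S subjects this yields S(S-1)/2 unique pair values per network and
condition (120 for the study's 16 subjects). Contrasts across awareness
levels use the non-parametric Wilcoxon signed-rank test on the paired
pair-level differences; interaction structure across networks and tasks
uses linear-model ANOVAs with a continuous awareness-level predictor
(coded 1..3) crossed with a categorical factor.

Note the pair values are not independent (each subject contributes to
S-1 pairs); the pairs are nevertheless the test units throughout, the
convention this analysis family uses, so p-values are calibrated against
that convention rather than subject-level exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .ttm import TTM

_LEVEL_CODE = {"awake": 1, "moderate": 2, "deep": 3}


@dataclass
class IntSSMatrix:
    """S x S matrix of pairwise TTM similarities for one network/condition."""

    network_label: str
    level: str
    task: str
    values: np.ndarray
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def pair_values(self) -> np.ndarray:
        """The S(S-1)/2 unique off-diagonal values (lower triangle)."""
        il = np.tril_indices(self.n_subjects, k=-1)
        return self.values[il]

    def pair_ids(self) -> list[tuple[str, str]]:
        return [
            (self.subject_ids[i], self.subject_ids[j])
            for i, j in zip(*np.tril_indices(self.n_subjects, k=-1))
        ]


@dataclass
class ContrastResult:
    network_label: str
    z: float
    p_raw: float
    mean_diff: float
    sem_boot: float
    n_boot: int
    n_pairs: int
    method: str
    p_bonferroni: float | None = None


@dataclass
class AnovaResult:
    design: str
    F_interaction: float
    p_interaction: float
    coding: str = "level continuous 1..3, other factor categorical"


def fisher_z(r: np.ndarray, clamp: float = 1.0 - 1e-12) -> np.ndarray:
    """arctanh with inputs clamped to +/-(1 - 1e-12) to keep z finite."""
    return np.arctanh(np.clip(r, -clamp, clamp))


def intss_pairwise(
    stack: list[TTM],
    subject_ids: list[str] | None = None,
    network_label: str = "",
    level: str = "",
    task: str = "",
) -> IntSSMatrix:
    """Pairwise Pearson correlation of Fisher-z lower-triangle TTM vectors."""
    if len(stack) < 2:
        raise ValueError("need at least 2 subjects")
    shape = stack[0].values.shape
    for t in stack[1:]:
        if t.values.shape != shape:
            raise ValueError("all TTMs must share a shape")
    if subject_ids is None:
        subject_ids = [f"sub{i:02d}" for i in range(len(stack))]
    il = np.tril_indices(shape[0], k=-1)
    vecs = np.stack([fisher_z(t.values[il]) for t in stack])
    sds = vecs.std(axis=1)
    dead = sds <= 1e-10 * (np.abs(vecs.mean(axis=1)) + 1.0)
    if np.any(dead):
        bad = [subject_ids[i] for i in np.flatnonzero(dead)]
        raise ValueError(f"zero-variance TTM vector for subject(s) {bad}")
    vals = np.corrcoef(vecs)
    np.fill_diagonal(vals, 1.0)
    return IntSSMatrix(
        network_label=network_label,
        level=level,
        task=task,
        values=vals,
        subject_ids=list(subject_ids),
    )


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Two-sided exact p by enumerating all 2^n sign patterns on the ranks."""
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = 0
    extreme = 0
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    for bits in range(2**n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_signed_rank(d: np.ndarray, exact_max_n: int = 12) -> tuple[float, float, str]:
    """Signed-rank test on paired differences.

    Returns (z, p_two_sided, method). Zeros are discarded (standard
    convention); |d| ties get mid-ranks with the tie-corrected normal
    variance. For small samples (n <= ``exact_max_n`` after zero removal)
    the p comes from exact enumeration of all sign patterns; z is always
    the normal-scale statistic, signed positive when positive differences
    dominate.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, "degenerate"
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    z = 0.0 if var == 0 else (w_pos - mu) / np.sqrt(var)
    if n <= exact_max_n:
        return z, _signed_rank_exact_p(d), "exact"
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(1.0, p), "normal-approx"


def contrast_levels(
    a: IntSSMatrix, b: IntSSMatrix, n_boot: int = 1000, seed: int = 0
) -> ContrastResult:
    """Wilcoxon signed-rank contrast on paired IntSS values (a - b).

    Positive z means similarity is higher in ``a``. The SEM of the mean
    difference comes from a bootstrap over pair differences (resampled
    with replacement, seed-controlled).
    """
    if a.subject_ids != b.subject_ids:
        raise ValueError("IntSS matrices must cover the same subjects")
    d = a.pair_values() - b.pair_values()
    z, p, method = wilcoxon_signed_rank(d)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    sem = float(d[idx].mean(axis=1).std(ddof=1))
    return ContrastResult(
        network_label=a.network_label or b.network_label,
        z=float(z),
        p_raw=float(p),
        mean_diff=float(d.mean()),
        sem_boot=sem,
        n_boot=n_boot,
        n_pairs=int(d.size),
        method=method,
    )


def _coded_levels(levels: pd.Series) -> pd.Series:
    if levels.dtype.kind in "if":
        return levels.astype(float)
    try:
        return levels.map(_LEVEL_CODE).astype(float)
    except (TypeError, ValueError) as exc:  # pragma: no cover - message path
        raise ValueError(f"unknown awareness level in {set(levels)}") from exc


def _interaction_anova(df: pd.DataFrame, other: str, design: str) -> AnovaResult:
    work = df.copy()
    work["level_lin"] = _coded_levels(work["level"])
    if work[["level_lin", other, "value"]].isna().any().any():
        raise ValueError("missing cells in ANOVA table")
    model = smf.ols(f"value ~ level_lin * C({other})", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"level_lin:C({other})"]
    return AnovaResult(
        design=design,
        F_interaction=float(row["F"]),
        p_interaction=float(row["PR(>F)"]),
    )


def anova_level_by_network(records: pd.DataFrame) -> AnovaResult:
    """Awareness-level (continuous 1..3) x network (categorical) ANOVA.

    ``records`` needs columns network, level, value (one row per subject
    pair). The interaction F answers whether IntSS scales with awareness
    differently across networks — the analysis' primary outcome.
    """
    required = {"network", "level", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records["network"].nunique() < 2:
        raise ValueError("need >= 2 networks for an interaction")
    return _interaction_anova(records, "network", "level x network")


def anova_level_by_task(records: pd.DataFrame) -> AnovaResult:
    """Awareness-level x task (story vs rest) interaction for one network."""
    required = {"task", "level", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if records["task"].nunique() != 2:
        raise ValueError("need exactly 2 tasks (story, rest)")
    return _interaction_anova(records, "task", "level x task")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m); m defaults to len(p_values)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def pair_table(matrices: list[IntSSMatrix]) -> pd.DataFrame:
    """Long-format table (network, level, task, subject_i, subject_j, value)."""
    rows = []
    for m in matrices:
        for (si, sj), v in zip(m.pair_ids(), m.pair_values()):
            rows.append(
                {
                    "network": m.network_label,
                    "level": m.level,
                    "task": m.task,
                    "subject_i": si,
                    "subject_j": sj,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)
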