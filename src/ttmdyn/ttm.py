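"""Time-by-time similarity matrices (TTMs) and their bookkeeping.

A TTM redefines each timepoint of a system by its similarity to every
other timepoint, giving an individual-specific temporal landscape that
can be compared across subjects and across data domains (neural
connectivity vs subjective ratings) without ever comparing the states
themselves.

Neural TTM: Pearson correlation between the vectorised upper triangles
of the connectivity tensor's time slices. Behavioural TTM: 10 minus the
Euclidean distance between Likert ratings (for scalar ratings the
absolute difference). Group matrices: cellwise mean and coefficient of
variation across subjects or raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ParcelTimeseries, RatingSeries
from .phase import ConnectivityTensor

TTM_KINDS = ("neural", "behavioural", "mean", "cv")


@dataclass
class TTM:
    """Square symmetric similarity matrix over timepoints.

    ``timepoint_ids`` are the original TR indices and survive trimming and
    lag alignment, so masks defined on acquisition time remain valid.
    """

    values: np.ndarray
    kind: str
    timepoint_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("TTM must be square")
        if self.kind not in TTM_KINDS:
            raise ValueError(f"kind must be one of {TTM_KINDS}, got {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("TTM must be symmetric")
        if self.timepoint_ids is None:
            self.timepoint_ids = np.arange(self.values.shape[0])
        else:
            self.timepoint_ids = np.asarray(self.timepoint_ids, dtype=int)
            if self.timepoint_ids.shape != (self.values.shape[0],):
                raise ValueError("timepoint_ids length must match matrix size")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MaskedVector:
    """Lower-triangle TTM cells surviving the autocorrelation-band mask."""

    values: np.ndarray
    cell_index_pairs: np.ndarray  # (n, 2) original (i, j) timepoint ids, i > j


def _edge_vectors(tensor: ConnectivityTensor) -> np.ndarray:
    """T x E matrix of vectorised upper triangles of the time slices."""
    P = tensor.n_parcels
    iu = np.triu_indices(P, k=1)
    return tensor.values[iu[0], iu[1], :].T  # T x E


def neural_ttm(tensor: ConnectivityTensor) -> TTM:
    """Pearson-correlation TTM of a connectivity tensor's time slices."""
    P, T = tensor.n_parcels, tensor.n_timepoints
    if P < 3:
        raise ValueError(f"need >= 3 parcels for a non-degenerate edge vector, got {P}")
    if T < 2:
        raise ValueError("need >= 2 timepoints")
    edges = _edge_vectors(tensor)
    sd = edges.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(
            f"zero-variance edge vector at timepoint(s) {dead[:5].tolist()}"
        )
    vals = np.corrcoef(edges)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0
    return TTM(values=vals, kind="neural", units="pearson_r")


def behavioural_ttm(ratings: RatingSeries) -> TTM:
    """Similarity TTM from one rater: 10 - |r_t - r_s|, diagonal 10."""
    r = np.asarray(ratings.values, dtype=float)
    if r.min() < 1 or r.max() > 9:
        raise ValueError("ratings must lie in [1, 9]")
    vals = 10.0 - np.abs(r[:, None] - r[None, :])
    return TTM(values=vals, kind="behavioural", units="similarity_10_minus_dist")


def _check_stack(stack: list[TTM]) -> np.ndarray:
    if not stack:
        raise ValueError("empty TTM stack")
    shape = stack[0].values.shape
    kind = stack[0].kind
    for t in stack[1:]:
        if t.values.shape != shape:
            raise ValueError("TTM stack members differ in shape")
        if t.kind != kind:
            raise ValueError("TTM stack members differ in kind")
    return np.stack([t.values for t in stack])


def mean_ttm(stack: list[TTM]) -> TTM:
    """Cellwise arithmetic mean across a stack of same-shaped TTMs."""
    arr = _check_stack(stack)
    return TTM(
        values=arr.mean(axis=0),
        kind="mean",
        timepoint_ids=stack[0].timepoint_ids.copy(),
        units=stack[0].units,
    )


def cv_ttm(stack: list[TTM]) -> TTM:
    """Cellwise coefficient of variation (sample SD / mean) across a stack."""
    arr = _check_stack(stack)
    if arr.shape[0] < 2:
        raise ValueError("cv_ttm needs at least 2 matrices")
    mean = arr.mean(axis=0)
    zero = np.argwhere(mean == 0.0)
    if zero.size:
        raise ValueError(
            f"cellwise mean is 0 at cells {zero[:5].tolist()}; CV undefined"
        )
    sd = arr.std(axis=0, ddof=1)
    return TTM(
        values=sd / mean,
        kind="cv",
        timepoint_ids=stack[0].timepoint_ids.copy(),
        units="cv",
    )


def trim_edges(ttm: TTM, head: int = 3, tail: int = 3) -> TTM:
    """Drop the first ``head`` and last ``tail`` timepoints.

    The first and last connectivity frames of a story run tend to be
    artifactually similar (filter / analytic-transform edge effects), so
    they are removed before any statistics.
    """
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be >= 0")
    T = ttm.n_timepoints
    if T <= head + tail:
        raise ValueError(f"cannot trim {head}+{tail} timepoints from a {T}-point TTM")
    sl = slice(head, T - tail if tail else T)
    return TTM(
        values=ttm.values[sl, sl],
        kind=ttm.kind,
        timepoint_ids=ttm.timepoint_ids[sl],
        units=ttm.units,
    )


def lag_align(neural: TTM, behavioural: TTM, lag_trs: int = 3) -> tuple[TTM, TTM]:
    """Align neural to behavioural dynamics for the haemodynamic lag.

    Drops the first ``lag_trs`` timepoints of the neural TTM and the last
    ``lag_trs`` of the behavioural TTM so that neural timepoint t is
    paired with behavioural timepoint t - lag_trs. The default of 3 TRs
    (6 s at TR = 2 s) matches the canonical HRF peak.
    """
    if lag_trs < 0:
        raise ValueError("lag_trs must be >= 0")
    if neural.n_timepoints != behavioural.n_timepoints:
        raise ValueError("neural and behavioural TTMs must start equal-sized")
    if lag_trs >= neural.n_timepoints:
        raise ValueError("lag_trs must be smaller than the TTM size")
    if lag_trs == 0:
        return neural, behavioural
    return (
        trim_edges(neural, head=lag_trs, tail=0),
        trim_edges(behavioural, head=0, tail=lag_trs),
    )


def match_rest_length(rest: ParcelTimeseries, story_len: int) -> ParcelTimeseries:
    """Truncate a rest run to the story's usable length (first timepoints)."""
    if story_len <= 0:
        raise ValueError("story_len must be positive")
    if rest.n_timepoints < story_len:
        raise ValueError(
            f"rest run ({rest.n_timepoints} timepoints) shorter than story "
            f"({story_len})"
        )
    return ParcelTimeseries(
        subject_id=rest.subject_id,
        level=rest.level,
        task=rest.task,
        data=rest.data[:story_len],
        tr=rest.tr,
        parcel_ids=list(rest.parcel_ids),
    )


def usable_story_length(
    acquired_volumes: int = 156, dummy_scans: int = 5, surplus_ratings: int = 1
) -> int:
    """Common usable length of the neural and rating streams.

    The scanner acquires ``acquired_volumes`` story volumes of which the
    first ``dummy_scans`` (equilibration) are discarded; the raters give
    one surplus rating at the end relative to the neural stream, so the
    final neural volume is dropped to share a common timeline.
    """
    if acquired_volumes <= dummy_scans + surplus_ratings:
        raise ValueError("no usable timepoints left after discards")
    return acquired_volumes - dummy_scans - surplus_ratings


def mask_autocorr(ttm_a: TTM, ttm_b: TTM, k: int) -> tuple[MaskedVector, MaskedVector]:
    """Vectorise both lower triangles, dropping the autocorrelation band.

    Cells with |i - j| <= k (in original timepoint ids) are excluded so
    that trivially high similarity of temporally adjacent states cannot
    inflate correspondence statistics. Cell ordering is identical across
    the two outputs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if ttm_a.values.shape != ttm_b.values.shape:
        raise ValueError("TTMs must have the same shape")
    # After lag alignment the two matrices carry shifted timepoint ids but
    # are paired positionally; proximity is judged on the first input's ids.
    ids = ttm_a.timepoint_ids
    il = np.tril_indices(ttm_a.n_timepoints, k=-1)
    keep = np.abs(ids[il[0]] - ids[il[1]]) > k
    if not np.any(keep):
        raise ValueError(f"k = {k} leaves no cells in a {ttm_a.n_timepoints}-point TTM")
    rows, cols = il[0][keep], il[1][keep]
    pairs = np.column_stack([ids[rows], ids[cols]])
    return (
        MaskedVector(values=ttm_a.values[rows, cols], cell_index_pairs=pairs),
        MaskedVector(values=ttm_b.values[rows, cols], cell_index_pairs=pairs),
    )
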