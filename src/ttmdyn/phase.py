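"""Instantaneous phase synchrony (IPS) connectivity from parcel timeseries.

The narrowband (0.03-0.07 Hz) BOLD signal of each parcel is reduced to its
analytic-signal phase; connectivity between two parcels at timepoint t is a
function of their phase difference. The anti-phase-sensitive variant maps
the difference through cosine: in-phase pairs score +1, anti-phase pairs -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .cohort import ParcelTimeseries

IPS_VARIANTS = ("cosine", "one-minus-abs-sin")


@dataclass(frozen=True)
class PhaseMatrix:
    """Instantaneous phases (T x P, radians in (-pi, pi]) of a timeseries."""

    phases: np.ndarray
    tr: float
    band: tuple[float, float]
    parcel_ids: list[str]


@dataclass(frozen=True)
class ConnectivityTensor:
    """P x P x T phase-synchrony values in [-1, 1] for one network."""

    values: np.ndarray
    parcel_ids: list[str]
    network_label: str

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


def bandpass(
    ts: ParcelTimeseries, low: float, high: float, order: int = 2
) -> ParcelTimeseries:
    """Zero-phase Butterworth band-pass; removes DC, preserves phase."""
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0.0 < low < high < nyquist:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist} Hz for tr = {ts.tr} s"
        )
    b, a = butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr)
    filtered = filtfilt(b, a, ts.data, axis=0)
    # the filter's DC zero holds only in steady state; remove the residual
    # offset that finite-window edge transients leave behind
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return ParcelTimeseries(
        subject_id=ts.subject_id,
        level=ts.level,
        task=ts.task,
        data=filtered,
        tr=ts.tr,
        parcel_ids=list(ts.parcel_ids),
    )


def instantaneous_phase(
    ts: ParcelTimeseries, band: tuple[float, float] = (0.03, 0.07)
) -> PhaseMatrix:
    """Phase of the analytic signal per parcel.

    Input is assumed band-passed (narrowband), so the phase is
    well-defined; an all-zero column has no phase and is rejected.
    """
    norms = np.max(np.abs(ts.data), axis=0)
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:
        names = ", ".join(ts.parcel_ids[i] for i in dead[:5])
        raise ValueError(f"degenerate all-zero parcel(s), phase undefined: {names}")
    analytic = hilbert(ts.data, axis=0)
    phases = np.angle(analytic)  # in (-pi, pi]
    return PhaseMatrix(
        phases=phases, tr=ts.tr, band=band, parcel_ids=list(ts.parcel_ids)
    )


def ips_tensor(
    phases: PhaseMatrix,
    parcel_subset: list[str] | None = None,
    network_label: str = "all",
    variant: str = "cosine",
) -> ConnectivityTensor:
    """Pairwise phase-synchrony tensor for a parcel subset.

    ``cosine`` (default): values[i, j, t] = cos(phi[t, i] - phi[t, j]),
    symmetric with unit diagonal, +1 in phase / -1 anti-phase.
    ``one-minus-abs-sin``: 1 - |sin(dphi)|, the anti-phase-blind variant
    kept for comparison (range [0, 1]).
    """
    if variant not in IPS_VARIANTS:
        raise ValueError(f"unknown IPS variant {variant!r}; choose from {IPS_VARIANTS}")
    if parcel_subset is None:
        idx = np.arange(len(phases.parcel_ids))
        subset_ids = list(phases.parcel_ids)
    else:
        if not parcel_subset:
            raise ValueError("parcel_subset must be non-empty")
        lookup = {pid: i for i, pid in enumerate(phases.parcel_ids)}
        missing = [p for p in parcel_subset if p not in lookup]
        if missing:
            raise KeyError(f"unknown parcel id(s): {missing}")
        idx = np.array([lookup[p] for p in parcel_subset])
        subset_ids = list(parcel_subset)
    ph = phases.phases[:, idx]  # T x P
    dphi = ph[:, :, None] - ph[:, None, :]  # T x P x P
    if variant == "cosine":
        vals = np.cos(dphi)
    else:
        vals = 1.0 - np.abs(np.sin(dphi))
    return ConnectivityTensor(
        values=np.transpose(vals, (1, 2, 0)),
        parcel_ids=subset_ids,
        network_label=network_label,
    )
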