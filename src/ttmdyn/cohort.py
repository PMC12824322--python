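"""Synthetic multi-subject cohort with planted shared vs idiosyncratic dynamics.

Emulates the design of a propofol-sedation naturalistic-listening study:
16 subjects scanned in three awareness levels (awake, moderate, deep)
during an engaging story and at rest (TR = 2 s, ~150 usable volumes),
plus 25 independent raters giving a 1-9 suspense rating every TR.

The generative model plants the two kinds of structure the downstream
analyses are built to detect:

* a *shared* narrowband (0.03-0.07 Hz) oscillatory process, common to all
  subjects and frequency-modulated by a latent "suspense" drive — present
  only while the story plays;
* an *idiosyncratic* narrowband process per subject, modulated by a
  subject-specific smooth trajectory;
* within-network parcels are phase-coupled oscillators whose coupling
  strength follows the modulating trajectory, so the network's
  connectivity pattern (and hence its time-by-time similarity structure)
  tracks the drive.

Sedation is modelled as a multiplicative reduction of ``coupling_gain``
(gating both oscillatory amplitudes and the phase coupling) together with
an increase in additive noise: under deep sedation the planted dynamics
collapse and the signal approaches band-limited scanner noise. Activity
is convolved with a canonical double-gamma HRF and sampled at the TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import gamma as gamma_dist

LEVELS = ("awake", "moderate", "deep")
TASKS = ("story", "rest")

# Narrowband carrier range (Hz) for the planted oscillators; sits inside
# the 0.03-0.07 Hz analysis band so the band-pass stage is not load-bearing
# for signal survival.
_F_LO = 0.04
_F_HI = 0.06


@dataclass(frozen=True)
class NetworkSpec:
    """One synthetic brain network: label, size and planted amplitudes."""

    label: str
    n_parcels: int
    shared_amplitude: float
    idio_amplitude: float


@dataclass(frozen=True)
class ConditionSpec:
    """One scanning condition (awareness level x task)."""

    level: str
    task: str
    coupling_gain: float
    noise_sd: float


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma haemodynamic response parameters, in seconds."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0


def _default_networks() -> tuple[NetworkSpec, ...]:
    # Four networks spanning the shared->idiosyncratic axis, named after the
    # networks whose contrast motivates the analysis (auditory / dorsal
    # attention = stimulus-entrained; default-mode = individual-specific).
    return (
        NetworkSpec("AUD", 10, shared_amplitude=1.0, idio_amplitude=0.15),
        NetworkSpec("DAN-A", 10, shared_amplitude=0.7, idio_amplitude=0.45),
        NetworkSpec("DMN-A", 10, shared_amplitude=0.45, idio_amplitude=0.7),
        NetworkSpec("DMN-B", 10, shared_amplitude=0.15, idio_amplitude=1.0),
    )


def _default_conditions() -> tuple[ConditionSpec, ...]:
    # coupling_gain: fraction of planted (conscious) dynamics surviving;
    # noise_sd: additive scanner-like noise, rising with sedation depth.
    gains = {"awake": 1.0, "moderate": 0.5, "deep": 0.12}
    noise = {"awake": 0.4, "moderate": 0.6, "deep": 0.8}
    return tuple(
        ConditionSpec(level, task, gains[level], noise[level])
        for level in LEVELS
        for task in TASKS
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; with a seed it is reproducible."""

    n_subjects: int = 16
    n_raters: int = 25
    n_timepoints: int = 150
    tr: float = 2.0
    networks: tuple[NetworkSpec, ...] = field(default_factory=_default_networks)
    conditions: tuple[ConditionSpec, ...] = field(default_factory=_default_conditions)
    hrf: HRFParams = field(default_factory=HRFParams)
    rating_noise_sd: float = 0.08
    drive_smoothness: int = 8
    seed: int = 0
    n_timepoints_rest: int | None = None  # None -> same length as story

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_raters < 1:
            raise ValueError(f"n_raters must be >= 1, got {self.n_raters}")
        if self.n_timepoints < 20:
            raise ValueError(f"n_timepoints must be >= 20, got {self.n_timepoints}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.networks:
            raise ValueError("at least one network required")
        for net in self.networks:
            if net.n_parcels < 1:
                raise ValueError(f"network {net.label!r} has zero parcels")
            if net.shared_amplitude < 0 or net.idio_amplitude < 0:
                raise ValueError(f"network {net.label!r}: amplitudes must be >= 0")
        for cond in self.conditions:
            if cond.level not in LEVELS:
                raise ValueError(f"unknown level {cond.level!r}")
            if cond.task not in TASKS:
                raise ValueError(f"unknown task {cond.task!r}")
            if not 0.0 <= cond.coupling_gain <= 1.0:
                raise ValueError("coupling_gain must be in [0, 1]")
            if cond.noise_sd < 0:
                raise ValueError("noise_sd must be >= 0")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")


@dataclass(frozen=True)
class LatentDrive:
    """Smooth latent trajectory in [0, 1] standing in for evolving suspense."""

    values: np.ndarray
    seed: int


@dataclass
class ParcelTimeseries:
    """BOLD-like matrix for one subject x condition: T timepoints x P parcels."""

    subject_id: str
    level: str
    task: str
    data: np.ndarray
    tr: float
    parcel_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x parcels)")
        if self.data.shape[1] != len(self.parcel_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.parcel_ids)} parcel ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RatingSeries:
    """One rater's moment-to-moment suspense ratings, Likert 1-9 per TR."""

    rater_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1:
            raise ValueError("ratings must be 1-D")
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("ratings must be integers")
        if vals.min() < 1 or vals.max() > 9:
            raise ValueError("ratings must lie in {1..9}")
        object.__setattr__(self, "values", vals)


def generate_latent_drive(
    n_timepoints: int, smoothness: int, seed: int | Sequence[int]
) -> LatentDrive:
    """Smoothed uniform noise rescaled to span [0, 1].

    ``smoothness`` is a moving-average window in timepoints; a window the
    size of the series gives a (near-)constant interior, in which case the
    degenerate span is resolved by returning all 0.5.
    """
    if n_timepoints < 20:
        raise ValueError(f"n_timepoints must be >= 20, got {n_timepoints}")
    if smoothness < 1:
        raise ValueError(f"smoothness must be >= 1, got {smoothness}")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=n_timepoints)
    if smoothness >= n_timepoints:
        # full-series window: constant interior by construction
        smooth = np.full(n_timepoints, raw.mean())
    else:
        smooth = uniform_filter1d(raw, size=smoothness, mode="nearest")
    span = smooth.max() - smooth.min()
    if span < 1e-12:
        values = np.full(n_timepoints, 0.5)
    else:
        values = (smooth - smooth.min()) / span
    seed_int = seed if isinstance(seed, int) else -1
    return LatentDrive(values=values, seed=seed_int)


def generate_ratings(
    drive: LatentDrive,
    n_raters: int,
    rating_noise_sd: float,
    seed: int | Sequence[int],
) -> list[RatingSeries]:
    """Per-rater Likert ratings: round(1 + 8 * clip(drive + noise, 0, 1))."""
    if rating_noise_sd < 0:
        raise ValueError("rating_noise_sd must be >= 0")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_raters):
        noisy = drive.values + rng.normal(0.0, rating_noise_sd, size=drive.values.shape)
        vals = np.rint(1.0 + 8.0 * np.clip(noisy, 0.0, 1.0))
        vals = np.clip(vals, 1, 9).astype(int)
        out.append(RatingSeries(rater_id=f"rater{r:02d}", values=vals))
    return out


def canonical_hrf(tr: float, params: HRFParams | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, normalised to unit peak.

    Each lobe is a gamma density with unit scale whose mode sits at the
    requested delay; with the defaults (peak 6 s, undershoot 16 s, ratio
    1/6, length 32 s) and tr = 2 the sampled kernel peaks at index 3 (6 s).
    """
    if params is None:
        params = HRFParams()
    if tr <= 0:
        raise ValueError("tr must be positive")
    if params.kernel_length < params.peak_delay:
        raise ValueError(
            f"kernel_length ({params.kernel_length} s) shorter than "
            f"peak_delay ({params.peak_delay} s)"
        )
    t = np.arange(0.0, params.kernel_length + tr / 2.0, tr)
    peak = gamma_dist.pdf(t, a=params.peak_delay + 1.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=params.undershoot_delay + 1.0, scale=1.0)
    kernel = peak - params.undershoot_ratio * undershoot
    return kernel / kernel.max()


def _modulated_phase(
    modulator: np.ndarray, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Integrate a frequency trajectory f(t) = f_lo + (f_hi - f_lo) * m(t)."""
    freq = _F_LO + (_F_HI - _F_LO) * modulator
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(freq) * tr


def _coupling(gain: float, base: float, swing: float, mod: np.ndarray) -> np.ndarray:
    return np.clip(gain * (base + swing * mod), 0.0, 1.0)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ParcelTimeseries], list[RatingSeries], dict]:
    """Generate the full cohort plus rater streams and ground-truth labels.

    Returns ``(timeseries, ratings, ground_truth)`` where ``ground_truth``
    records the per-network planted amplitudes, per-condition gains, and
    the story-window latent drive, for recovery tests downstream.
    """
    kernel = canonical_hrf(spec.tr, spec.hrf)
    pad = len(kernel) - 1  # burn-in absorbed by the convolution crop

    lengths = {"story": spec.n_timepoints}
    lengths["rest"] = (
        spec.n_timepoints if spec.n_timepoints_rest is None else spec.n_timepoints_rest
    )

    # Single latent drive over the padded story timeline; output timepoint t
    # corresponds to activity index pad + t, so BOLD lags the ratings by the
    # HRF peak (~3 TRs at TR = 2 s) as in a real acquisition.
    total_story = spec.n_timepoints + pad
    drive_full = generate_latent_drive(
        total_story, spec.drive_smoothness, [spec.seed, 0]
    ).values
    drive_story = LatentDrive(values=drive_full[pad:], seed=spec.seed)

    ratings = generate_ratings(
        drive_story, spec.n_raters, spec.rating_noise_sd, [spec.seed, 4]
    )

    # Shared (network-keyed) ingredients, common to all subjects.
    shared_phase: dict[int, np.ndarray] = {}
    shared_offsets: dict[int, np.ndarray] = {}
    for ni, net in enumerate(spec.networks):
        rng_net = np.random.default_rng([spec.seed, 1, ni])
        shared_phase[ni] = _modulated_phase(drive_full, spec.tr, rng_net)
        shared_offsets[ni] = rng_net.uniform(-np.pi, np.pi, size=net.n_parcels)

    timeseries: list[ParcelTimeseries] = []
    for si in range(spec.n_subjects):
        subject_id = f"sub{si:02d}"
        for ci, cond in enumerate(spec.conditions):
            T = lengths[cond.task]
            total = T + pad
            g = cond.coupling_gain
            blocks = []
            parcel_ids: list[str] = []
            for ni, net in enumerate(spec.networks):
                rng_sub = np.random.default_rng([spec.seed, 2, si, ci, ni])
                rng_noise = np.random.default_rng([spec.seed, 3, si, ci, ni])

                # Subject-specific smooth modulator and oscillator.
                m_sub = generate_latent_drive(
                    total, spec.drive_smoothness, rng_sub.integers(2**31)
                ).values
                phi_id = _modulated_phase(m_sub, spec.tr, rng_sub)
                theta_id = rng_sub.uniform(-np.pi, np.pi, size=net.n_parcels)

                act = np.zeros((total, net.n_parcels))
                if cond.task == "story" and net.shared_amplitude > 0:
                    kap = _coupling(g, 0.15, 0.85, drive_full[:total])
                    act += (
                        g
                        * net.shared_amplitude
                        * np.cos(
                            shared_phase[ni][:total, None]
                            + (1.0 - kap)[:, None] * shared_offsets[ni][None, :]
                        )
                    )
                if net.idio_amplitude > 0:
                    kap_id = _coupling(g, 0.15, 0.85, m_sub)
                    act += (
                        g
                        * net.idio_amplitude
                        * np.cos(
                            phi_id[:, None]
                            + (1.0 - kap_id)[:, None] * theta_id[None, :]
                        )
                    )

                # Haemodynamic convolution, then crop so timepoint 0 already
                # carries a fully formed response; scanner noise is additive
                # on the sampled BOLD.
                bold = np.empty((T, net.n_parcels))
                for p in range(net.n_parcels):
                    full = np.convolve(act[:, p], kernel, mode="full")
                    bold[:, p] = full[pad : pad + T]
                bold += rng_noise.normal(0.0, cond.noise_sd, size=bold.shape)
                blocks.append(bold)
                parcel_ids.extend(
                    f"{net.label}_p{p:03d}" for p in range(net.n_parcels)
                )
            timeseries.append(
                ParcelTimeseries(
                    subject_id=subject_id,
                    level=cond.level,
                    task=cond.task,
                    data=np.hstack(blocks),
                    tr=spec.tr,
                    parcel_ids=parcel_ids,
                )
            )

    ground_truth = {
        "networks": {
            net.label: {
                "shared_amplitude": net.shared_amplitude,
                "idio_amplitude": net.idio_amplitude,
                "n_parcels": net.n_parcels,
            }
            for net in spec.networks
        },
        "conditions": {
            f"{c.level}/{c.task}": {
                "coupling_gain": c.coupling_gain,
                "noise_sd": c.noise_sd,
            }
            for c in spec.conditions
        },
        "drive_story": drive_story.values.tolist(),
        "seed": spec.seed,
    }
    return timeseries, ratings, ground_truth


def network_map(spec: CohortSpec) -> dict[str, str]:
    """Parcel id -> network label mapping for a cohort spec."""
    return {
        f"{net.label}_p{p:03d}": net.label
        for net in spec.networks
        for p in range(net.n_parcels)
    }


def gradient_networks(
    n_networks: int = 8, n_parcels: int = 10, total_amplitude: float = 1.15
) -> tuple[NetworkSpec, ...]:
    """Networks spanning a shared->idiosyncratic gradient.

    Network k gets shared fraction w_k on an even grid from 1 to 0 with
    shared + idio amplitudes summing to ``total_amplitude``; used for the
    entropy-vs-intersubject-similarity association analysis.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks for a gradient")
    ws = np.linspace(1.0, 0.0, n_networks)
    return tuple(
        NetworkSpec(
            label=f"net{k:02d}_w{w:.2f}",
            n_parcels=n_parcels,
            shared_amplitude=total_amplitude * w,
            idio_amplitude=total_amplitude * (1.0 - w),
        )
        for k, w in enumerate(ws)
    )
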