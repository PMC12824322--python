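import numpy as np
import pytest

from ttmdyn.cohort import ParcelTimeseries
from ttmdyn.experiments import calibration_experiment
from ttmdyn.phase import ConnectivityTensor
from ttmdyn.ttm import TTM


def random_connectivity_tensor(
    rng: np.random.Generator, n_parcels: int = 6, n_timepoints: int = 20
) -> ConnectivityTensor:
    """Valid IPS-like tensor from random phases."""
    phases = rng.uniform(-np.pi, np.pi, size=(n_timepoints, n_parcels))
    dphi = phases[:, :, None] - phases[:, None, :]
    return ConnectivityTensor(
        values=np.transpose(np.cos(dphi), (1, 2, 0)),
        parcel_ids=[f"p{i}" for i in range(n_parcels)],
        network_label="test",
    )


def random_neural_ttm_input(rng, n_parcels=6, n_timepoints=20):
    return random_connectivity_tensor(rng, n_parcels, n_timepoints)


def sinusoid_timeseries(
    freq: float, tr: float = 2.0, n: int = 200, phase: float = 0.0
) -> ParcelTimeseries:
    t = np.arange(n) * tr
    return ParcelTimeseries(
        subject_id="s0",
        level="awake",
        task="story",
        data=np.sin(2 * np.pi * freq * t + phase)[:, None],
        tr=tr,
        parcel_ids=["p0"],
    )


def random_symmetric_ttm(rng, T=20, kind="neural") -> TTM:
    base = rng.normal(size=(T, 10))
    vals = np.corrcoef(base)
    np.fill_diagonal(vals, 1.0)
    return TTM(values=(vals + vals.T) / 2, kind=kind)


@pytest.fixture(scope="session")
def calibration_500():
    """Shared 500-replicate null calibration of the permutation test.

    Used both for the type-I-error band and for the uniformity of null
    p-values; session-scoped because it is the slowest simulation here.
    """
    return calibration_experiment(
        n_replicates=500, n_perm=199, T=30, k=4, alpha=0.05, base_seed=11
    )
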