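"""Plain-text readers/writers and the pipeline configuration.

Conventions: parcel timeseries are TSV (rows = timepoints, columns =
parcels, header = parcel ids) with a JSON sidecar (``<file>.json``)
carrying subject, level, task and TR; ratings are CSV with one column
per rater; the network map is a two-column TSV (parcel_id, network);
TTMs are square CSV with the timepoint ids as header plus a JSON
sidecar. Timepoint indexing is 0-based everywhere; timestamps are
index * TR seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ParcelTimeseries, RatingSeries
from .ttm import TTM, MaskedVector


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_timeseries(ts: ParcelTimeseries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=ts.parcel_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "subject_id": ts.subject_id,
        "level": ts.level,
        "task": ts.task,
        "tr": ts.tr,
        "n_timepoints": ts.n_timepoints,
        "n_parcels": ts.n_parcels,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_timeseries(path: str | Path) -> ParcelTimeseries:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "level", "task", "tr"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing field {key!r}")
    ncols = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        n = len(line.split("\t"))
        if ncols is None:
            ncols = n
        elif n != ncols:
            raise ValueError(f"{path}: ragged row at line {lineno}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=float, header=0)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return ParcelTimeseries(
        subject_id=meta["subject_id"],
        level=meta["level"],
        task=meta["task"],
        data=df.to_numpy(),
        tr=float(meta["tr"]),
        parcel_ids=[str(c) for c in df.columns],
    )


def write_ratings(ratings: list[RatingSeries], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({r.rater_id: r.values for r in ratings})
    df.to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> list[RatingSeries]:
    df = pd.read_csv(path, dtype=int)
    return [RatingSeries(rater_id=str(c), values=df[c].to_numpy()) for c in df.columns]


def write_network_map(mapping: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("parcel_id\tnetwork_label\n")
        for pid, label in mapping.items():
            fh.write(f"{pid}\t{label}\n")
    return path


def read_network_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["parcel_id", "network_label"]:
        raise ValueError(
            f"{path}: expected columns parcel_id, network_label, got {list(df.columns)}"
        )
    dupes = df["parcel_id"][df["parcel_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate parcel id(s) {sorted(set(dupes))[:5]}")
    return dict(zip(df["parcel_id"], df["network_label"]))


def networks_of(mapping: dict[str, str]) -> dict[str, list[str]]:
    """Invert a parcel->network map into network -> ordered parcel list."""
    out: dict[str, list[str]] = {}
    for pid, label in mapping.items():
        out.setdefault(label, []).append(pid)
    return out


def write_ttm(ttm: TTM, path: str | Path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame(ttm.values, columns=[str(i) for i in ttm.timepoint_ids])
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"kind": ttm.kind, "units": ttm.units}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_ttm(path: str | Path) -> TTM:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    return TTM(
        values=df.to_numpy(),
        kind=meta["kind"],
        timepoint_ids=np.array([int(c) for c in df.columns]),
        units=meta.get("units", ""),
    )


def write_masked_vectors(a: MaskedVector, b: MaskedVector, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "i": a.cell_index_pairs[:, 0],
            "j": a.cell_index_pairs[:, 1],
            "value_a": a.values,
            "value_b": b.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis reproducibly."""

    output_dir: str = "results/pipeline"
    timeseries_dir: str | None = None  # None -> simulate a cohort
    network_map_path: str | None = None
    ratings_path: str | None = None
    band: tuple[float, float] = (0.03, 0.07)
    tr: float = 2.0
    trim_head: int = 3
    trim_tail: int = 3
    lag_trs: int = 3
    autocorr_k: tuple[int, ...] = (10, 24)
    n_perm: int = 1000
    n_boot: int = 1000
    n_bins: int = 256
    scaling: str = "minmax"
    ips_variant: str = "cosine"
    seed: int = 0
    granularity: str = "synthetic"
    n_subjects: int = 16
    n_raters: int = 25
    n_timepoints: int = 150

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        nyq = 1.0 / (2.0 * self.tr)
        low, high = self.band
        if not 0 < low < high < nyq:
            raise ValueError(f"band {self.band} outside (0, Nyquist={nyq})")
        if self.trim_head < 0 or self.trim_tail < 0 or self.lag_trs < 0:
            raise ValueError("trims and lag must be >= 0")
        if any(k < 0 for k in self.autocorr_k):
            raise ValueError("autocorr_k entries must be >= 0")
        if self.n_perm < 1 or self.n_boot < 1 or self.n_bins < 2:
            raise ValueError("n_perm, n_boot >= 1 and n_bins >= 2 required")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        for key in ("band", "autocorr_k"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
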