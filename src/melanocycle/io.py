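"""File formats: spike-train CSV/HDF5 round trips, simulation HDF5 output,
and run manifests."""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import InputError
from .transduction import RawTrace, SpikeTrain

SPIKE_CSV_HEADER = ("cell_id", "time_s")


def write_spikes_csv(path, trains: list[SpikeTrain]) -> None:
    """CSV `cell_id,time_s` with 6-decimal seconds; deterministic row order
    (trains sorted by cell_id, times ascending)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SPIKE_CSV_HEADER)
        for train in sorted(trains, key=lambda t: t.cell_id):
            for t in train.times_s:
                w.writerow([train.cell_id, f"{t:.6f}"])


def read_spikes_csv(path) -> list[SpikeTrain]:
    by_cell: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != SPIKE_CSV_HEADER:
            raise InputError(f"{path}: expected header {','.join(SPIKE_CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise InputError(f"{path}: malformed row at line {lineno}")
            cell, t = row
            try:
                tval = float(t)
            except ValueError:
                raise InputError(
                    f"{path}: non-numeric time at line {lineno}") from None
            if cell not in by_cell:
                by_cell[cell] = []
                order.append(cell)
            by_cell[cell].append(tval)
    return [SpikeTrain(c, np.asarray(by_cell[c])) for c in order]


def write_spikes_hdf5(path, trains: list[SpikeTrain]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("spikes")
        for train in sorted(trains, key=lambda t: t.cell_id):
            grp.create_dataset(train.cell_id, data=train.times_s)


def read_spikes_hdf5(path) -> list[SpikeTrain]:
    with h5py.File(path, "r") as f:
        grp = f["spikes"]
        return [SpikeTrain(name, grp[name][()]) for name in sorted(grp)]


def write_simulation_hdf5(path, result, trains: list[SpikeTrain] | None = None,
                          rates: np.ndarray | None = None,
                          raw: dict[str, RawTrace] | None = None) -> None:
    """HDF5 layout: /states (time x 5), /drive, optional /rates,
    /spikes/<cell_id>, /raw/<cell_id>, and /meta with all configs echoed."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=result.t)
        f.create_dataset("states", data=result.states)
        f.create_dataset("drive", data=result.drive)
        if rates is not None:
            f.create_dataset("rates", data=rates)
        if trains:
            grp = f.create_group("spikes")
            for train in sorted(trains, key=lambda tr: tr.cell_id):
                grp.create_dataset(train.cell_id, data=train.times_s)
        if raw:
            grp = f.create_group("raw")
            for cid in sorted(raw):
                ds = grp.create_dataset(cid, data=raw[cid].samples)
                ds.attrs["sampling_rate_hz"] = raw[cid].sampling_rate_hz
        f.create_group("meta").attrs["config_json"] = json.dumps(result.meta)


def read_raw_csv(path, sampling_rate_hz: float = 10_000.0) -> RawTrace:
    """Single-column CSV of voltage samples."""
    samples = np.loadtxt(path, delimiter=",", dtype=float)
    return RawTrace(samples=np.atleast_1d(samples),
                    sampling_rate_hz=sampling_rate_hz)


@dataclass
class RunManifest:
    """Provenance record tying every pipeline output to its inputs."""

    root_seed: int
    software_version: str
    config_digest: str
    stages: dict[str, dict] = field(default_factory=dict)
    created_unix: float = field(default_factory=time.time)

    @staticmethod
    def digest(config: dict) -> str:
        blob = json.dumps(config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def add_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[name] = {"inputs": inputs, "outputs": outputs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
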