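"""File formats: delimited EEG + JSON sidecar, TSV tables, HDF5 estimates.

EEG travels as a whitespace-delimited channels-by-samples matrix next to a JSON
sidecar (``<file>.json``) holding the sampling rate, channel names, events and
optional electrode positions.  Electrode and event tables are TSV.  Source
estimates are stored in an HDF5 container plus a per-vertex text export for
surface viewers.  EDF input is not supported in this build (no EDF reader in
the dependency set); convert to the delimited format first.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import EnergyMap
from .solver import SourceEstimate
from .tbf import EEGRecording

__all__ = [
    "read_eeg",
    "write_eeg",
    "read_electrodes_tsv",
    "write_electrodes_tsv",
    "read_events_tsv",
    "save_estimate",
    "load_estimate",
    "write_energy_map",
]


def write_eeg(path, eeg: EEGRecording) -> None:
    """Write a delimited EEG matrix and its JSON sidecar."""
    path = Path(path)
    np.savetxt(path, eeg.data, fmt="%.10g")
    sidecar = {
        "sfreq": eeg.sfreq,
        "channel_names": list(eeg.channel_names),
        "events": [[k, float(t)] for k, t in eeg.events],
        "reference": eeg.reference,
        "bad_channels": list(eeg.bad_channels),
    }
    if eeg.positions is not None:
        sidecar["positions"] = np.asarray(eeg.positions).tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(path, fmt: str = "delimited") -> EEGRecording:
    """Read an EEG recording (delimited matrix + JSON sidecar)."""
    if fmt == "edf":
        raise ValueError(
            "EDF input is not supported in this build; convert to the "
            "delimited+sidecar format"
        )
    if fmt != "delimited":
        raise ValueError(f"unknown EEG format {fmt!r}")
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sfreq" not in sidecar:
        raise ValueError("sidecar missing required field 'sfreq'")
    data = np.atleast_2d(np.loadtxt(path))
    names = sidecar.get("channel_names")
    if names is not None and len(names) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(names)} channels but data has {data.shape[0]} rows"
        )
    positions = sidecar.get("positions")
    return EEGRecording(
        data=data,
        sfreq=float(sidecar["sfreq"]),
        channel_names=names,
        events=[(k, float(t)) for k, t in sidecar.get("events", [])],
        reference=sidecar.get("reference", "unknown"),
        positions=None if positions is None else np.asarray(positions, float),
        bad_channels=list(sidecar.get("bad_channels", [])),
    )


def write_electrodes_tsv(path, labels, positions) -> None:
    pd.DataFrame({
        "label": labels,
        "x": np.asarray(positions)[:, 0],
        "y": np.asarray(positions)[:, 1],
        "z": np.asarray(positions)[:, 2],
    }).to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(path):
    """Electrode table: columns label, x, y, z (mm).  Returns (labels, E x 3)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"electrode TSV missing columns: {sorted(missing)}")
    return list(df["label"]), df[["x", "y", "z"]].to_numpy(dtype=float)


def read_events_tsv(path):
    """Event table: columns type, time_s.  Returns list of (type, time) tuples."""
    df = pd.read_csv(path, sep="\t")
    missing = {"type", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"event TSV missing columns: {sorted(missing)}")
    return [(row["type"], float(row["time_s"])) for _, row in df.iterrows()]


def write_leadfield(path, leadfield) -> None:
    """Whitespace-delimited gain matrix with a channel-order sidecar."""
    path = Path(path)
    np.savetxt(path, leadfield.K, fmt="%.10g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"channel_names": list(leadfield.channel_names),
                    "units": leadfield.units})
    )


def read_leadfield(path):
    from .forward import LeadField

    path = Path(path)
    K = np.atleast_2d(np.loadtxt(path))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    names = None
    units = "arb"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        names = sidecar.get("channel_names")
        units = sidecar.get("units", "arb")
    if names is None:
        names = [f"E{i:03d}" for i in range(K.shape[0])]
    if len(names) != K.shape[0]:
        raise ValueError(
            f"channel sidecar lists {len(names)} channels, matrix has {K.shape[0]} rows"
        )
    return LeadField(K=K, channel_names=names, units=units)


def save_estimate(path, estimate: SourceEstimate) -> None:
    """Serialize a source estimate (J, A, S, hyper-parameters, trace) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=estimate.J)
        f.create_dataset("A", data=estimate.A)
        f.create_dataset("S", data=estimate.S)
        f.create_dataset("objective_trace", data=np.asarray(estimate.objective_trace))
        f.attrs["converged"] = estimate.converged
        f.attrs["n_iterations"] = estimate.n_iterations
        f.attrs["alpha"] = estimate.alpha
        f.attrs["beta_sq"] = estimate.beta_sq


def load_estimate(path) -> SourceEstimate:
    with h5py.File(path, "r") as f:
        return SourceEstimate(
            J=f["J"][()],
            A=f["A"][()],
            objective_trace=list(f["objective_trace"][()]),
            converged=bool(f.attrs["converged"]),
            n_iterations=int(f.attrs["n_iterations"]),
            alpha=float(f.attrs["alpha"]),
            beta_sq=float(f.attrs["beta_sq"]),
        )


def write_energy_map(path, energy_map: EnergyMap) -> None:
    """Per-vertex scalar export (one value per line) for surface viewers."""
    np.savetxt(path, energy_map.values, fmt="%.10g",
               header=f"mode={energy_map.mode} window={energy_map.window}")
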