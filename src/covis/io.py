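"""File formats: CSV trial tables, HDF5 epoch containers, eye-tracker CSVs.

All CSVs are UTF-8, comma-delimited with a mandatory header row. EEG
epochs are stored as HDF5 with datasets ``data`` (trials x channels x
time), ``times_ms``, ``channel_names``, ``trial_ids`` and attributes
``fs_hz``, ``alignment``, ``units``. Pupil streams use an eye-tracker
export dialect: one CSV per eye with columns timestamp_s, diameter_mm,
confidence, plus a blink-event CSV with onset_s, offset_s.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from covis.containers import EpochArray, PupilEpochs, PupilStream


def write_trial_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "trial_id" not in df.columns:
        raise ValueError(f"{path}: not a trial table (missing trial_id column)")
    return df


def write_epochs(epochs: EpochArray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["alignment"] = epochs.alignment
        f.attrs["units"] = epochs.units
    return path


def read_epochs(path: str | Path) -> EpochArray:
    try:
        with h5py.File(path, "r") as f:
            for ds in ("data", "times_ms", "channel_names", "trial_ids"):
                if ds not in f:
                    raise ValueError(f"{path}: missing dataset {ds!r}")
            return EpochArray(
                data=f["data"][()],
                times_ms=f["times_ms"][()],
                channel_names=[
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["channel_names"][()]
                ],
                trial_ids=f["trial_ids"][()],
                fs_hz=float(f.attrs["fs_hz"]),
                alignment=str(f.attrs["alignment"]),
                units=str(f.attrs.get("units", "µV")),
            )
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5 epoch file ({exc})") from exc


def write_pupil_stream(stream: PupilStream, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "timestamp_s": stream.timestamp_s,
            "diameter_mm": stream.diameter_mm,
            "confidence": stream.confidence,
        }
    ).to_csv(path, index=False)
    return path


def read_pupil_stream(path: str | Path, eye: str = "left") -> PupilStream:
    df = pd.read_csv(path)
    for col in ("timestamp_s", "diameter_mm", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PupilStream(
        df["timestamp_s"].to_numpy(),
        df["diameter_mm"].to_numpy(),
        df["confidence"].to_numpy(),
        eye=eye,
    )


def write_blink_events(events: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events = np.atleast_2d(np.asarray(events, dtype=float))
    if events.size == 0:
        events = np.empty((0, 2))
    pd.DataFrame(events, columns=["onset_s", "offset_s"]).to_csv(path, index=False)
    return path


def read_blink_events(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df[["onset_s", "offset_s"]].to_numpy(dtype=float)


def write_pupil_epochs(epochs: PupilEpochs, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_s", data=epochs.time_s)
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))
        f.create_dataset("interp_frac", data=np.asarray(epochs.interp_frac))
        f.attrs["units"] = "mm"
    return path


def read_pupil_epochs(path: str | Path) -> PupilEpochs:
    try:
        with h5py.File(path, "r") as f:
            return PupilEpochs(
                data=f["data"][()],
                time_s=f["time_s"][()],
                trial_ids=f["trial_ids"][()],
                interp_frac=f["interp_frac"][()],
            )
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5 pupil-epoch file "
                         f"({exc})") from exc


def write_rsa_series(records: pd.DataFrame, path: str | Path) -> Path:
    """RsaSeries CSV: subject, time_ms, model, tau (+ optional roi)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    return path


def read_rsa_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject", "time_ms", "model", "tau"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
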