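"""In-memory containers shared across the analysis chain.

Time conventions: EEG epochs use milliseconds relative to motion onset
(or to the response for response-locked epochs); pupil streams use
seconds of recording time, matching each instrument's native scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EpochArray:
    """Epoched multichannel EEG: trials x channels x time, in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Epoch voltages in µV.
    times_ms : ndarray, shape (n_times,)
        Sample times in ms relative to the alignment event.
    channel_names : list of str
        10-20 electrode names, one per channel row.
    trial_ids : ndarray, shape (n_trials,)
        Trial identifiers linking epochs to the trial table.
    fs_hz : float
        Sampling rate of the (uniform) time grid.
    alignment : {"stimulus", "response"}
        Event the epochs are locked to.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channel_names: list[str]
    trial_ids: np.ndarray
    fs_hz: float
    alignment: str = "stimulus"
    units: str = "µV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("EpochArray data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channel_names):
            raise ValueError(
                f"{n_ch} channel rows but {len(self.channel_names)} channel names"
            )
        if n_t != self.times_ms.size:
            raise ValueError("time axis length does not match times_ms")
        if n_tr != self.trial_ids.size:
            raise ValueError("trial axis length does not match trial_ids")
        if self.alignment not in ("stimulus", "response"):
            raise ValueError(f"unknown alignment {self.alignment!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in montage {self.channel_names}"
            ) from None

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of samples in the closed interval [start_ms, end_ms]."""
        if start_ms > end_ms:
            raise ValueError("window start must not exceed end")
        half = 500.0 / self.fs_hz  # nearest-neighbour slack of half a sample
        mask = (self.times_ms >= start_ms - half) & (self.times_ms <= end_ms + half)
        if not mask.any():
            raise ValueError(
                f"window ({start_ms}, {end_ms}) ms outside epoch support "
                f"[{self.times_ms[0]}, {self.times_ms[-1]}] ms"
            )
        return mask

    def copy(self) -> "EpochArray":
        return EpochArray(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            channel_names=list(self.channel_names),
            trial_ids=self.trial_ids.copy(),
            fs_hz=self.fs_hz,
            alignment=self.alignment,
            units=self.units,
        )


@dataclass
class PupilStream:
    """One eye's pupil-diameter samples on a common time base.

    Missing samples are NaN in ``diameter_mm``; the time base itself is
    never shortened by preprocessing (missing values are interpolated,
    not dropped), so sample count is preserved through the whole chain.
    """

    timestamp_s: np.ndarray
    diameter_mm: np.ndarray
    confidence: np.ndarray
    eye: str = "left"

    def __post_init__(self) -> None:
        self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if not (
            self.timestamp_s.shape == self.diameter_mm.shape == self.confidence.shape
        ):
            raise ValueError("timestamp, diameter and confidence must align")
        if np.any(np.diff(self.timestamp_s) < 0):
            raise ValueError("timestamps must be nondecreasing")

    @property
    def n_samples(self) -> int:
        return self.timestamp_s.size

    @property
    def fs_hz(self) -> float:
        dt = np.median(np.diff(self.timestamp_s))
        return 1.0 / dt

    def copy(self) -> "PupilStream":
        return PupilStream(
            self.timestamp_s.copy(),
            self.diameter_mm.copy(),
            self.confidence.copy(),
            self.eye,
        )


@dataclass
class PupilEpochs:
    """Baseline-corrected pupil epochs: trials x time, in mm.

    The time grid is uniform (default −6…+3 s around motion onset at
    200 Hz). ``interp_frac`` records, per trial, the fraction of epoch
    samples that were interpolated during preprocessing; trials above
    0.5 are flagged in ``flagged``.
    """

    data: np.ndarray
    time_s: np.ndarray
    trial_ids: np.ndarray
    interp_frac: np.ndarray = field(default=None)  # type: ignore[assignment]
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 2:
            raise ValueError("PupilEpochs data must be trials x time")
        if self.data.shape[1] != self.time_s.size:
            raise ValueError("time axis length does not match time_s")
        if self.data.shape[0] != self.trial_ids.size:
            raise ValueError("trial axis length does not match trial_ids")
        if self.interp_frac is None:
            self.interp_frac = np.zeros(self.data.shape[0])
        if self.flagged is None:
            self.flagged = np.asarray(self.interp_frac) > 0.5

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]
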