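"""Centro-parietal positivity (CPP) amplitude extraction.

The CPP is an EEG potential over centro-parietal electrodes whose
build-up tracks accumulated perceptual evidence. Single-trial
amplitude is the mean of the baseline-corrected channel trace over a
measurement window: 400–600 ms post motion onset for stimulus-locked
epochs (baseline −200–0 ms), and a pre-response window for
response-locked epochs (baseline 0–200 ms *after* the response).
Window boundaries are closed; samples map to the grid by nearest
neighbour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from covis.containers import EpochArray


def baseline_correct(epochs: EpochArray,
                     window_ms: tuple[float, float]) -> EpochArray:
    """Subtract, per trial and channel, the mean over ``window_ms``."""
    start, end = window_ms
    if start >= end:
        raise ValueError("baseline window start must precede end")
    mask = epochs.time_mask(start, end)
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def window_mean(epochs: EpochArray, channel: str,
                window_ms: tuple[float, float]) -> np.ndarray:
    """Per-trial mean of one channel over a closed time window."""
    ch = epochs.channel_index(channel)
    mask = epochs.time_mask(*window_ms)
    return epochs.data[:, ch, mask].mean(axis=1)


def cpp_amplitude(
    epochs: EpochArray,
    channel: str = "CPz",
    window_ms: tuple[float, float] = (400.0, 600.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> pd.DataFrame:
    """Stimulus-locked single-trial CPP amplitudes.

    Returns one row per trial: trial_id, amplitude (µV), channel,
    alignment.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("cpp_amplitude expects stimulus-aligned epochs")
    corrected = baseline_correct(epochs, baseline_ms)
    amp = window_mean(corrected, channel, window_ms)
    return pd.DataFrame(
        {
            "trial_id": epochs.trial_ids,
            "amplitude": amp,
            "channel": channel,
            "alignment": "stimulus",
        }
    )


def cpp_amplitude_response(
    epochs: EpochArray,
    channel: str = "CPz",
    window_ms: tuple[float, float] = (-200.0, 0.0),
    baseline_ms: tuple[float, float] = (0.0, 200.0),
) -> pd.DataFrame:
    """Response-locked CPP amplitudes.

    The baseline sits *after* the response (0–200 ms post-response);
    the default measurement window is the 200 ms leading into it.
    """
    if epochs.alignment != "response":
        raise ValueError("cpp_amplitude_response expects response-aligned epochs")
    corrected = baseline_correct(epochs, baseline_ms)
    amp = window_mean(corrected, channel, window_ms)
    return pd.DataFrame(
        {
            "trial_id": epochs.trial_ids,
            "amplitude": amp,
            "channel": channel,
            "alignment": "response",
        }
    )
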