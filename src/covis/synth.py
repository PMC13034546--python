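"""Synthetic co-visibility RDK experiments.

Generates the three data modalities the analysis chain consumes, with
the statistical structure the analyses assume:

* a balanced trial design — 5 motion-coherence levels x 2 directions x
  2 social contexts (public / private co-visibility), 32 repeats each,
  640 trials in 4 blocks of 160;
* behavioral outcomes — accuracy following a two-parameter Weibull in
  coherence, reaction times decreasing and confidence (1–6) increasing
  with coherence, and *no* dependence of any behavioral outcome on
  social context;
* epoched EEG — spatially correlated Gaussian noise plus a
  coherence-scaled centro-parietal ramp (a CPP analog peaking
  400–600 ms) and a fixed random across-channel pattern added with
  opposite sign per social context inside a cue-locked window that
  begins before motion onset (so the univariate grand mean carries no
  context information while multivariate analyses can decode it);
* continuous binocular pupil traces at 200 Hz with blinks, spikes,
  out-of-range samples, a slow event-locked dilation, and a small
  additive public-vs-private dilation difference in an early window.

All randomness derives from one integer seed; sub-streams use fixed
offsets so each modality is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from covis.containers import EpochArray, PupilStream

COHERENCE_LEVELS: tuple[float, ...] = (3.2, 6.4, 12.8, 25.6, 51.2)
DIRECTIONS: tuple[str, str] = ("left", "right")
CONTEXTS: tuple[str, str] = ("private", "public")

RESPONSE_DEADLINE_MS = 5000.0

# sub-stream offsets for the global seed
_STREAM_DESIGN = 0
_STREAM_BEHAVIOR = 1
_STREAM_EEG = 2
_STREAM_EEG_PATTERN = 3
_STREAM_PUPIL = 4


@dataclass
class GenParams:
    """Generative parameters for one synthetic subject.

    Parameters
    ----------
    lambda_true, kappa_true : float
        Weibull threshold (percent coherence at ~82% accuracy) and slope.
    cpp_gain : float
        CPP ramp amplitude in µV per percent coherence.
    context_gain : float
        Amplitude (µV, RMS over channels) of the social-context pattern,
        added with opposite sign on public vs private trials.
    context_window_ms : (float, float)
        Window of the context pattern relative to motion onset; starts
        before 0 (the cue already signals the upcoming context).
    noise_sd : float
        EEG noise standard deviation, µV.
    pupil_context_delta : float
        Additive public-minus-private pupil dilation, mm, inside
        ``pupil_context_window_s``.
    pupil_noise_sd : float
        Per-eye white-noise SD on the pupil trace, mm.
    blink_rate, spike_rate, oor_rate : float
        Artifact rates, events per minute (blinks; single-sample spikes;
        out-of-physiological-range samples).
    seed : int
        Global seed; all sub-streams derive from it by fixed offsets.
    """

    lambda_true: float = 12.8
    kappa_true: float = 1.5
    cpp_gain: float = 0.1
    context_gain: float = 0.7
    context_window_ms: tuple[float, float] = (-900.0, 3000.0)
    noise_sd: float = 10.0
    pupil_context_delta: float = 0.02
    pupil_context_window_s: tuple[float, float] = (0.0, 1.8)
    pupil_noise_sd: float = 0.05
    blink_rate: float = 8.0
    spike_rate: float = 4.0
    oor_rate: float = 2.0
    seed: int = 0

    # behavioral nuisance parameters (not varied in the study design)
    rt_shift_ms: float = 250.0
    rt_median_base_ms: float = 950.0
    rt_median_slope_ms: float = 125.0  # per octave of coherence
    rt_sigma: float = 0.35
    conf_coherence_slope: float = 0.4  # latent-z units per octave
    conf_correct_shift: float = 0.8
    conf_cutpoints: tuple[float, ...] = (-0.8, 0.0, 0.7, 1.4, 2.1)

    def __post_init__(self) -> None:
        if self.lambda_true <= 0 or self.kappa_true <= 0:
            raise ValueError("Weibull parameters must be positive")
        for name in ("cpp_gain", "context_gain", "noise_sd", "pupil_noise_sd",
                     "pupil_context_delta", "blink_rate", "spike_rate",
                     "oor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.context_window_ms[0] >= 0:
            raise ValueError(
                "context window must start before motion onset (cue-locked)"
            )

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(offset)])


def build_design(
    n_per_type: int = 32,
    coherence_levels: tuple[float, ...] = COHERENCE_LEVELS,
    n_blocks: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced randomized trial design.

    Every (coherence, direction, context) combination appears exactly
    ``n_per_type`` times, split evenly over ``n_blocks`` blocks; trial
    order is randomized within blocks by ``seed``.
    """
    levels = [float(c) for c in coherence_levels]
    if len(levels) == 0:
        raise ValueError("coherence_levels must be nonempty")
    if len(set(levels)) != len(levels):
        raise ValueError("coherence_levels must be distinct")
    if n_per_type < 1 or n_blocks < 1:
        raise ValueError("n_per_type and n_blocks must be positive")
    if n_per_type % n_blocks != 0:
        raise ValueError(
            f"n_per_type ({n_per_type}) must be divisible by n_blocks "
            f"({n_blocks}) for per-block balance"
        )
    per_block = n_per_type // n_blocks
    rng = np.random.default_rng([int(seed), _STREAM_DESIGN])

    rows = []
    for block in range(1, n_blocks + 1):
        block_rows = [
            (coh, direction, context)
            for coh in levels
            for direction in DIRECTIONS
            for context in CONTEXTS
            for _ in range(per_block)
        ]
        order = rng.permutation(len(block_rows))
        for idx in order:
            coh, direction, context = block_rows[idx]
            rows.append((block, coh, direction, context))

    df = pd.DataFrame(rows, columns=["block", "coherence", "direction", "context"])
    df.insert(0, "trial_id", np.arange(1, len(df) + 1))
    # fixation onset precedes motion by a random 200–500 ms delay
    df["cue_onset_ms"] = -rng.uniform(200.0, 500.0, size=len(df)).round(1)
    df["motion_onset_ms"] = 0.0
    return df


def simulate_behavior(design: pd.DataFrame, gp: GenParams) -> pd.DataFrame:
    """Behavioral outcomes for a trial design.

    Accuracy is Bernoulli with the two-parameter Weibull success
    probability; RT is a shifted lognormal whose median falls linearly
    in log2(coherence); confidence is a thresholded latent Gaussian
    increasing with coherence and correctness. Social context enters
    none of the three models (the behavioral null is true by
    construction).
    """
    from covis.behavior import weibull_p

    rng = gp.rng(_STREAM_BEHAVIOR)
    coh = design["coherence"].to_numpy(dtype=float)
    n = len(design)

    p_correct = weibull_p(coh, gp.lambda_true, gp.kappa_true)
    correct = rng.random(n) < p_correct

    octaves = np.log2(coh / np.min(COHERENCE_LEVELS))
    median_ms = gp.rt_median_base_ms - gp.rt_median_slope_ms * octaves
    median_ms = np.maximum(median_ms, 100.0)
    rt = gp.rt_shift_ms + np.exp(
        rng.normal(np.log(median_ms), gp.rt_sigma)
    )
    rt = np.minimum(rt, RESPONSE_DEADLINE_MS)

    z = (
        gp.conf_coherence_slope * octaves
        + gp.conf_correct_shift * (correct.astype(float) - 0.5)
        + rng.standard_normal(n)
    )
    cuts = np.asarray(gp.conf_cutpoints)
    confidence = 1 + (z[:, None] > cuts[None, :]).sum(axis=1)

    out = design.copy()
    out["correct"] = correct
    out["rt_ms"] = rt
    out["confidence"] = confidence.astype(int)
    return out


def _cpp_waveform(times_ms: np.ndarray) -> np.ndarray:
    """Unit-amplitude evidence-accumulation ramp: rises from motion onset,
    plateaus over 400–600 ms, decays to zero by 1200 ms."""
    t = np.asarray(times_ms, dtype=float)
    w = np.zeros_like(t)
    rise = (t >= 0) & (t < 400)
    w[rise] = t[rise] / 400.0
    w[(t >= 400) & (t <= 600)] = 1.0
    decay = (t > 600) & (t < 1200)
    w[decay] = 1.0 - (t[decay] - 600.0) / 600.0
    return w


def _context_envelope(times_ms: np.ndarray,
                      window_ms: tuple[float, float]) -> np.ndarray:
    """Temporal profile of the social-context pattern: ramps from zero at
    the window start (the cue already signals the context) to full
    amplitude at motion onset, sustained to the window end — the
    representation builds up before the stimulus rather than switching
    on as a boxcar."""
    w0, w1 = window_ms
    t = np.asarray(times_ms, dtype=float)
    env = np.clip((t - w0) / (0.0 - w0), 0.0, 1.0)
    env[t > w1] = 0.0
    env[t < w0] = 0.0
    return env


def simulate_eeg(
    design: pd.DataFrame,
    behavior: pd.DataFrame,
    gp: GenParams,
    montage: tuple[str, ...] | list[str] | None = None,
    epoch_window_ms: tuple[float, float] = (-1500.0, 3000.0),
    fs_hz: float = 250.0,
    noise_corr: float = 0.3,
) -> EpochArray:
    """Stimulus-locked synthetic EEG epochs.

    Data are the sum of three sources: spatially correlated Gaussian
    noise (uniform inter-channel correlation ``noise_corr``, SD
    ``gp.noise_sd``); a coherence-proportional ramp on centro-parietal
    channels (gain ``gp.cpp_gain`` µV per percent coherence); and a
    fixed random channel pattern of RMS amplitude ``gp.context_gain``,
    added inside ``gp.context_window_ms`` with sign +1 on public and −1
    on private trials, so that the across-context grand mean is flat.
    """
    from covis.montage import CPP_WEIGHTS, DEFAULT_MONTAGE

    montage = list(montage) if montage is not None else list(DEFAULT_MONTAGE)
    if "CPz" not in montage:
        raise ValueError("montage must include CPz (CPP electrode)")
    if len(set(montage)) != len(montage):
        raise ValueError("montage contains duplicate channel names")
    start, end = epoch_window_ms
    if start >= end:
        raise ValueError("epoch window start must precede end")
    if not (start <= 0 and end >= 600):
        raise ValueError("epoch window must cover 0–600 ms post motion onset")
    if gp.context_gain > 0 and not (
        start <= gp.context_window_ms[0] and end >= gp.context_window_ms[1]
    ):
        raise ValueError("epoch window must cover the context window")

    dt = 1000.0 / fs_hz
    times_ms = np.arange(start, end + 0.5 * dt, dt)
    n_tr, n_ch, n_t = len(design), len(montage), times_ms.size

    coh = design["coherence"].to_numpy(dtype=float)
    ctx_sign = np.where(design["context"].to_numpy() == "public", 1.0, -1.0)

    rng = gp.rng(_STREAM_EEG)
    data = np.zeros((n_tr, n_ch, n_t))
    if gp.noise_sd > 0:
        shared = rng.standard_normal((n_tr, 1, n_t))
        own = rng.standard_normal((n_tr, n_ch, n_t))
        data += gp.noise_sd * (
            np.sqrt(noise_corr) * shared + np.sqrt(1.0 - noise_corr) * own
        )

    if gp.cpp_gain > 0:
        ramp = _cpp_waveform(times_ms)
        weights = np.array([CPP_WEIGHTS.get(ch, 0.0) for ch in montage])
        data += (
            (gp.cpp_gain * coh)[:, None, None]
            * weights[None, :, None]
            * ramp[None, None, :]
        )

    if gp.context_gain > 0:
        rng_pat = gp.rng(_STREAM_EEG_PATTERN)
        pattern = rng_pat.standard_normal(n_ch)
        pattern *= gp.context_gain / np.sqrt(np.mean(pattern**2))
        data += (
            ctx_sign[:, None, None]
            * pattern[None, :, None]
            * _context_envelope(times_ms, gp.context_window_ms)[None, None, :]
        )

    return EpochArray(
        data=data,
        times_ms=times_ms,
        channel_names=montage,
        trial_ids=design["trial_id"].to_numpy(),
        fs_hz=fs_hz,
        alignment="stimulus",
    )


# ---------------------------------------------------------------------------
# pupil


@dataclass
class PupilRecording:
    """Raw binocular pupil recording plus event metadata.

    ``motion_onset_s`` / ``response_s`` give, per trial, the recording
    time of motion onset and of the behavioral response.
    """

    left: PupilStream
    right: PupilStream
    blink_events: np.ndarray  # (n_blinks, 2): onset_s, offset_s
    motion_onset_s: np.ndarray
    response_s: np.ndarray
    trial_ids: np.ndarray
    fs_hz: float = 200.0
    model: dict = field(default_factory=dict)  # noiseless per-eye model traces


def _smooth_window(t: np.ndarray, start: float, end: float,
                   ramp: float = 0.1) -> np.ndarray:
    """Boxcar over [start, end] seconds with raised-cosine edges so that a
    4 Hz low-pass filter passes it essentially unchanged."""
    w = np.zeros_like(t)
    core = (t >= start + ramp) & (t <= end - ramp)
    w[core] = 1.0
    up = (t >= start) & (t < start + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    down = (t > end - ramp) & (t <= end)
    w[down] = 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp))
    return w


def _pupil_kernel(t: np.ndarray, n: float = 10.1, t_max: float = 0.93) -> np.ndarray:
    """Canonical slow pupil dilation response, peak normalized to 1."""
    tt = np.maximum(t, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (tt / t_max) ** n * np.exp(n * (1.0 - tt / t_max))
    k[t < 0] = 0.0
    return k


def pupil_model_trace(
    t: np.ndarray,
    design: pd.DataFrame,
    behavior: pd.DataFrame,
    gp: GenParams,
    motion_onset_s: np.ndarray,
) -> np.ndarray:
    """Deterministic (noise- and artifact-free) pupil diameter model, mm.

    Baseline near 3.5 mm plus a slow drift, an event-locked dilation per
    trial, coherence- and confidence-proportional components in a late
    window (1.5–3 s post onset), and the additive public-vs-private
    context component inside ``gp.pupil_context_window_s``.
    """
    t = np.asarray(t, dtype=float)
    trace = 3.5 + 0.15 * np.sin(2 * np.pi * 0.02 * t)

    coh = design["coherence"].to_numpy(dtype=float)
    zcoh = np.log2(coh / np.min(COHERENCE_LEVELS))
    zcoh = (zcoh - zcoh.mean()) / (zcoh.std() or 1.0)
    conf = behavior["confidence"].to_numpy(dtype=float)
    zconf = (conf - conf.mean()) / (conf.std() or 1.0)
    is_public = design["context"].to_numpy() == "public"

    for i, onset in enumerate(np.asarray(motion_onset_s, dtype=float)):
        rel = t - onset
        sel = (rel >= -0.2) & (rel <= 3.5)
        if not sel.any():
            continue
        r = rel[sel]
        contrib = 0.1 * _pupil_kernel(r)
        contrib += (0.03 * zcoh[i] + 0.03 * zconf[i]) * _smooth_window(r, 1.5, 3.0)
        if is_public[i]:
            contrib += gp.pupil_context_delta * _smooth_window(
                r, gp.pupil_context_window_s[0], gp.pupil_context_window_s[1]
            )
        trace[sel] += contrib
    return trace


def simulate_pupil(
    design: pd.DataFrame,
    behavior: pd.DataFrame,
    gp: GenParams,
    fs_hz: float = 200.0,
    pre_s: float = 7.0,
    post_s: float = 4.0,
    iti_s: float = 2.5,
) -> PupilRecording:
    """Continuous binocular pupil recording spanning all trials.

    Motion onsets are spaced by the trial's RT plus ``iti_s`` of
    inter-trial time; the recording starts ``pre_s`` before the first
    onset (so every trial has a full 6 s epoch history). Both eyes share
    the deterministic model trace (the right eye sits 0.15 mm smaller)
    plus independent white noise; blinks, single-sample spikes and
    out-of-range samples are injected at the configured per-minute
    rates. Per-sample confidence is ~1 for clean samples and low during
    blinks.
    """
    rng = gp.rng(_STREAM_PUPIL)
    n = len(design)
    rt_s = behavior["rt_ms"].to_numpy(dtype=float) / 1000.0

    # event schedule
    onsets = np.empty(n)
    tcur = pre_s
    for i in range(n):
        onsets[i] = tcur
        tcur += rt_s[i] + iti_s + rng.uniform(0.0, 0.3)
    duration = tcur + post_s
    t = np.arange(0.0, duration, 1.0 / fs_hz)

    base = pupil_model_trace(t, design, behavior, gp, onsets)
    eye_traces = {}
    streams = {}
    blink_events = None
    for eye, offset in (("left", 0.0), ("right", -0.15)):
        model = base + offset
        eye_traces[eye] = model
        d = model.copy()
        if gp.pupil_noise_sd > 0:
            d = d + rng.normal(0.0, gp.pupil_noise_sd, size=d.size)
        conf = np.minimum(1.0, 0.9995 + rng.normal(0.0, 0.0002, size=d.size))

        minutes = duration / 60.0
        if eye == "left":
            # blinks are binocular: one shared event list, applied to both eyes
            n_blinks = int(round(gp.blink_rate * minutes))
            b_on = np.sort(rng.uniform(1.0, duration - 1.0, size=n_blinks))
            b_dur = rng.uniform(0.15, 0.30, size=n_blinks)
            blink_events = np.column_stack([b_on, b_on + b_dur])
        for on, off in blink_events:
            sel = (t >= on) & (t <= off)
            d[sel] = 0.0
            conf[sel] = rng.uniform(0.0, 0.3)

        n_spikes = int(round(gp.spike_rate * minutes))
        if n_spikes:
            idx = rng.integers(0, d.size, size=n_spikes)
            d[idx] += rng.uniform(1.0, 2.5, size=n_spikes) * rng.choice([-1, 1], n_spikes)
        n_oor = int(round(gp.oor_rate * minutes))
        if n_oor:
            idx = rng.integers(0, d.size, size=n_oor)
            d[idx] = rng.choice([0.6, 7.4], size=n_oor)

        streams[eye] = PupilStream(t.copy(), d, conf, eye=eye)

    return PupilRecording(
        left=streams["left"],
        right=streams["right"],
        blink_events=blink_events,
        motion_onset_s=onsets,
        response_s=onsets + rt_s,
        trial_ids=design["trial_id"].to_numpy(),
        fs_hz=fs_hz,
        model={"left": eye_traces["left"], "right": eye_traces["right"], "t": t},
    )
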