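"""Pupillometry preprocessing and time-resolved regression.

The cleaning chain (canonical order, each stage also usable alone):

1. ``quality_filter`` — discard physiologically implausible diameters
   (<1.0 or >7.0 mm) and low-confidence samples (<= 0.99); discarded
   samples become missing, the time base is never shortened.
2. ``blink_interpolate`` — remove padded blink spans (from external
   blink onset/offset timestamps) and fill them linearly.
3. ``merge_eyes`` — reconstruct one eye from the other plus the
   interpolated inter-eye difference where only one eye is valid, then
   average the eyes.
4. ``mad_speed_filter`` — remove samples whose dilation speed (absolute
   derivative, two-sided maximum) exceeds median + n_mad * MAD.
5. ``smooth_lowpass`` — zero-phase fourth-order Butterworth, 4 Hz.

Epochs are 9 s (−6…+3 s around motion onset) on a uniform 200 Hz grid,
baseline-corrected by the −1000…−500 ms pre-onset mean. The
exploratory time-resolved analysis regresses the pupil value at every
time point on coherence, confidence and social context with fixed
per-subject intercepts, then applies Benjamini-Hochberg FDR across
time points separately per predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from covis.containers import PupilEpochs, PupilStream

DIAMETER_MIN_MM = 1.0
DIAMETER_MAX_MM = 7.0
CONFIDENCE_MIN = 0.99


def _fill_missing(values: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior NaN runs; initial runs are
    backward-filled from the first valid sample, trailing runs
    forward-filled (nearest-valid-value extension at the edges)."""
    out = np.asarray(values, dtype=float).copy()
    valid = np.isfinite(out)
    if not valid.any():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(out.size)
    out[~valid] = np.interp(idx[~valid], idx[valid], out[valid])
    return out


def quality_filter(stream: PupilStream) -> PupilStream:
    """Mark out-of-range and low-confidence samples missing.

    A sample is kept iff 1.0 <= diameter <= 7.0 mm *and*
    confidence > 0.99 (strict: confidence exactly 0.99 is discarded).
    """
    out = stream.copy()
    bad = (
        (out.diameter_mm < DIAMETER_MIN_MM)
        | (out.diameter_mm > DIAMETER_MAX_MM)
        | (out.confidence <= CONFIDENCE_MIN)
        | ~np.isfinite(out.diameter_mm)
    )
    out.diameter_mm[bad] = np.nan
    return out


def blink_interpolate(
    stream: PupilStream,
    blink_events: np.ndarray,
    pad_ms: float = 100.0,
) -> PupilStream:
    """Remove padded blink spans and fill them by linear interpolation.

    ``blink_events`` is (n, 2) of onset/offset seconds. Blinks touching
    the recording edge are filled by nearest-valid-value extension.
    """
    out = stream.copy()
    events = np.atleast_2d(np.asarray(blink_events, dtype=float))
    pad = pad_ms / 1000.0
    if events.size:
        if events.shape[1] != 2:
            raise ValueError("blink_events must be (n, 2) onset/offset seconds")
        t0, t1 = out.timestamp_s[0], out.timestamp_s[-1]
        for on, off in events:
            if off < on:
                raise ValueError("blink offset precedes onset")
            if off < t0 or on > t1:
                raise ValueError("blink event outside recording span")
            sel = (out.timestamp_s >= on - pad) & (out.timestamp_s <= off + pad)
            out.diameter_mm[sel] = np.nan
    out.diameter_mm = _fill_missing(out.diameter_mm)
    return out


def merge_eyes(left: PupilStream, right: PupilStream) -> PupilStream:
    """Merge two eyes into one monocular stream.

    The inter-eye difference (left − right) is computed where both eyes
    are valid and linearly interpolated elsewhere; a missing eye is
    reconstructed from the other eye plus/minus that difference; the
    output is the across-eye mean. Samples missing in both eyes stay
    missing.
    """
    if left.n_samples != right.n_samples or not np.allclose(
        left.timestamp_s, right.timestamp_s
    ):
        raise ValueError("eyes must share a common time base; resample first")
    dl, dr = left.diameter_mm, right.diameter_mm
    both = np.isfinite(dl) & np.isfinite(dr)
    if not both.any():
        raise ValueError("no sample with both eyes valid; cannot estimate "
                         "inter-eye difference")
    diff = np.full(dl.shape, np.nan)
    diff[both] = dl[both] - dr[both]
    diff = _fill_missing(diff)

    l_hat = np.where(np.isfinite(dl), dl, dr + diff)
    r_hat = np.where(np.isfinite(dr), dr, dl - diff)
    merged = 0.5 * (l_hat + r_hat)  # NaN where both eyes missing
    conf = np.fmin(left.confidence, right.confidence)
    return PupilStream(left.timestamp_s.copy(), merged, conf, eye="merged")


def dilation_speed(stream: PupilStream) -> np.ndarray:
    """Two-sided dilation speed: per sample, the larger of the backward
    and forward |Δdiameter|/Δt (mm/s). NaN next to missing samples."""
    d = stream.diameter_mm
    t = stream.timestamp_s
    with np.errstate(invalid="ignore"):
        back = np.abs(np.diff(d)) / np.diff(t)
    fwd = np.concatenate([back, [np.nan]])
    bwd = np.concatenate([[np.nan], back])
    return np.fmax(fwd, bwd)  # fmax ignores a one-sided NaN


def mad_speed_filter(stream: PupilStream, n_mad: float = 16.0) -> PupilStream:
    """Remove samples whose dilation speed exceeds median + n_mad * MAD,
    then fill them by linear interpolation."""
    valid = np.isfinite(stream.diameter_mm)
    if valid.sum() < 3:
        raise ValueError("need >= 3 valid samples for the speed filter")
    speed = dilation_speed(stream)
    finite = np.isfinite(speed)
    med = np.median(speed[finite])
    mad = np.median(np.abs(speed[finite] - med))
    threshold = med + n_mad * mad
    bad = finite & (speed > threshold)
    if bad.sum() >= valid.sum():
        raise ValueError("every sample exceeds the speed threshold; "
                         "input looks pathological")
    out = stream.copy()
    out.diameter_mm[bad] = np.nan
    out.diameter_mm = _fill_missing(out.diameter_mm)
    return out


def smooth_lowpass(
    stream: PupilStream,
    order: int = 4,
    cutoff_hz: float = 4.0,
    fs_hz: float | None = None,
) -> PupilStream:
    """Zero-phase (forward-backward) low-pass Butterworth smoothing."""
    if fs_hz is None:
        fs_hz = stream.fs_hz
    if not np.all(np.isfinite(stream.diameter_mm)):
        raise ValueError("smooth_lowpass needs a gap-free stream; "
                         "interpolate missing samples first")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    padlen = 3 * 2 * order + 1
    if stream.n_samples <= padlen:
        raise ValueError(
            f"stream of {stream.n_samples} samples shorter than filter "
            f"warm-up ({padlen})"
        )
    out = stream.copy()
    out.diameter_mm = signal.sosfiltfilt(sos, out.diameter_mm)
    return out


def preprocess(
    left: PupilStream,
    right: PupilStream,
    blink_events: np.ndarray,
    n_mad: float = 16.0,
    blink_pad_ms: float = 100.0,
    lowpass_hz: float = 4.0,
) -> tuple[PupilStream, np.ndarray]:
    """Full canonical chain: quality -> blink -> merge -> MAD -> smooth.

    Returns the cleaned monocular stream and a boolean mask of samples
    that were interpolated at any stage (used to flag epochs dominated
    by interpolation). Sample count in equals sample count out.
    """
    l1 = quality_filter(left)
    r1 = quality_filter(right)
    l2 = blink_interpolate(l1, blink_events, pad_ms=blink_pad_ms)
    r2 = blink_interpolate(r1, blink_events, pad_ms=blink_pad_ms)
    # samples interpolated in either eye before/while merging
    interp_mask = ~np.isfinite(l1.diameter_mm) | ~np.isfinite(r1.diameter_mm)
    merged = merge_eyes(l2, r2)
    merged.diameter_mm = _fill_missing(merged.diameter_mm)
    speed_in = merged.copy()
    cleaned = mad_speed_filter(merged, n_mad=n_mad)
    interp_mask |= ~np.isclose(
        cleaned.diameter_mm, speed_in.diameter_mm, equal_nan=True
    )
    smoothed = smooth_lowpass(cleaned, cutoff_hz=lowpass_hz)
    return smoothed, interp_mask


def epoch_and_baseline(
    stream: PupilStream,
    events_s: np.ndarray,
    baseline_ms: tuple[float, float] = (-1000.0, -500.0),
    pre_s: float = 6.0,
    post_s: float = 3.0,
    fs_out: float = 200.0,
    trial_ids: np.ndarray | None = None,
    interp_mask: np.ndarray | None = None,
) -> PupilEpochs:
    """9 s epochs (−6…+3 s) on a uniform 200 Hz grid, baseline-corrected
    by the per-trial mean over ``baseline_ms`` before motion onset.

    Events without full pre/post coverage are dropped with a warning.
    Epochs with > 50% interpolated samples are flagged, not dropped.
    """
    events_s = np.asarray(events_s, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(1, events_s.size + 1)
    trial_ids = np.asarray(trial_ids)
    t0, t1 = stream.timestamp_s[0], stream.timestamp_s[-1]
    keep = (events_s - pre_s >= t0) & (events_s + post_s <= t1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} event(s) too close to the "
            "recording edge",
            stacklevel=2,
        )
    events_s, trial_ids = events_s[keep], trial_ids[keep]

    grid = np.arange(-pre_s, post_s + 0.5 / fs_out, 1.0 / fs_out)
    b0, b1 = baseline_ms[0] / 1000.0, baseline_ms[1] / 1000.0
    half = 0.5 / fs_out  # half-sample slack against float grid jitter
    bmask = (grid >= b0 - half) & (grid <= b1 + half)

    data = np.empty((events_s.size, grid.size))
    frac = np.zeros(events_s.size)
    interp_f = (
        interp_mask.astype(float) if interp_mask is not None else None
    )
    for i, ev in enumerate(events_s):
        data[i] = np.interp(ev + grid, stream.timestamp_s, stream.diameter_mm)
        if interp_f is not None:
            frac[i] = np.interp(ev + grid, stream.timestamp_s, interp_f).mean()
    data -= data[:, bmask].mean(axis=1, keepdims=True)
    return PupilEpochs(
        data=data, time_s=grid, trial_ids=trial_ids, interp_frac=frac
    )


def response_locked_mean(
    stream: PupilStream,
    response_times_s: np.ndarray,
    window_s: float = 1.0,
    baseline_s: float = 0.5,
    layout: str = "pre",
) -> np.ndarray:
    """Windowed response-locked pupil size, one value (mm) per response.

    ``layout='pre'``: mean over the 1 s immediately before the response
    minus the mean over the 500 ms directly preceding that window.
    ``layout='post'``: mean over the 1 s after the response minus the
    500 ms directly before the response. Responses without full window
    coverage yield NaN.
    """
    if layout not in ("pre", "post"):
        raise ValueError("layout must be 'pre' or 'post'")
    t = stream.timestamp_s
    d = stream.diameter_mm
    out = np.full(np.asarray(response_times_s).size, np.nan)
    for i, r in enumerate(np.asarray(response_times_s, dtype=float)):
        if layout == "pre":
            w0, w1 = r - window_s, r
            b0, b1 = r - window_s - baseline_s, r - window_s
        else:
            w0, w1 = r, r + window_s
            b0, b1 = r - baseline_s, r
        if b0 < t[0] or max(w1, b1) > t[-1] or w0 < t[0]:
            continue
        wsel = (t >= w0) & (t <= w1)
        bsel = (t >= b0) & (t <= b1)
        if wsel.any() and bsel.any():
            out[i] = d[wsel].mean() - d[bsel].mean()
    return out


# ---------------------------------------------------------------------------
# statistics


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns (mask, adjusted_p); the mask is adjusted_p <= alpha, which
    matches the classical step-up rejection set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted <= alpha, adjusted


@dataclass
class GlmSeries:
    """Per-time-point regression results for the pupil time series."""

    time_s: np.ndarray
    predictors: list[str]
    beta: np.ndarray  # predictors x time
    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    alpha: float
    windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


def _contiguous_windows(time_s: np.ndarray, mask: np.ndarray):
    wins = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return wins
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        wins.append((float(time_s[s]), float(time_s[e])))
    return wins


def timewise_glm(
    epochs: PupilEpochs,
    trial_info: pd.DataFrame,
    predictors: tuple[str, ...] = ("coherence", "confidence", "context"),
    alpha: float = 0.05,
) -> GlmSeries:
    """Mass-univariate regression of pupil size on trial predictors.

    At every time point the (all-subject) trial values are regressed on
    the standardized predictors with a fixed intercept per subject
    (implemented by within-subject centering of response and
    predictors; for balanced designs the coefficients coincide with the
    random-intercept mixed-model estimates). Two-sided p-values use
    t(N − n_subjects − k). BH-FDR runs across time points separately
    per predictor; contiguous significant runs are reported as windows.
    """
    info = trial_info.reset_index(drop=True)
    if len(info) != epochs.n_trials:
        raise ValueError("trial_info must align with epochs")
    if info["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    for col in predictors:
        if info[col].isna().any():
            raise ValueError(f"predictor {col!r} has missing values")

    X = np.empty((len(info), len(predictors)))
    for j, col in enumerate(predictors):
        v = info[col]
        if col == "context":
            # +-1/2 coding: the coefficient is the public-minus-private
            # difference in mm, directly comparable to an injected delta
            X[:, j] = np.where(v.to_numpy() == "public", 0.5, -0.5)
        else:
            x = v.to_numpy(dtype=float)
            sd = x.std()
            X[:, j] = (x - x.mean()) / (sd if sd > 0 else 1.0)

    # fixed per-subject intercepts via within-subject centering
    subj = pd.Categorical(info["subject"]).codes.astype(np.int64)
    n_subj = int(subj.max()) + 1
    Y = epochs.data.copy()
    Xc = X.copy()
    for s in range(n_subj):
        sel = subj == s
        Y[sel] -= Y[sel].mean(axis=0, keepdims=True)
        Xc[sel] -= Xc[sel].mean(axis=0, keepdims=True)

    k = len(predictors)
    xtx = Xc.T @ Xc
    rank = np.linalg.matrix_rank(xtx)
    if rank < k:
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "rank-deficient design after within-subject centering; most "
            f"collinear pair: {predictors[i]!r} and {predictors[j]!r}"
        )
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ Xc.T @ Y  # k x time
    resid = Y - Xc @ beta
    dof = len(info) - n_subj - k
    if dof < 1:
        raise ValueError("not enough trials for the residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(np.isfinite(tvals), pvals, 1.0)
    tvals = np.where(np.isfinite(tvals), tvals, 0.0)

    mask = np.zeros_like(pvals, dtype=bool)
    windows: dict[str, list[tuple[float, float]]] = {}
    for j, col in enumerate(predictors):
        mask[j], _ = bh_fdr(pvals[j], alpha=alpha)
        windows[col] = _contiguous_windows(epochs.time_s, mask[j])

    return GlmSeries(
        time_s=epochs.time_s,
        predictors=list(predictors),
        beta=beta,
        t=tvals,
        p=pvals,
        fdr_mask=mask,
        alpha=alpha,
        windows=windows,
    )
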