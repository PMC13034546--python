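"""Time-resolved representational similarity analysis (RSA).

For each subject and time point, condition-specific scalp patterns
(10 conditions = 5 coherence levels x 2 social contexts) are estimated
by regression on z-scored epochs, denoised by removing the least
significant singular component, and compared pairwise with the
Mahalanobis distance whitened by the (shrunk) covariance of the
regression residuals. The resulting 10 x 10 brain RDM is rank-compared
(Kendall's Tau-A over the 45 lower-triangle entries) against model
RDMs encoding motion coherence and social context. The searchlight
variant repeats the procedure inside predefined electrode ROIs.

Condition order is canonical and shared by every RDM: context-major
(private block first), coherence ascending within context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform

from covis.containers import EpochArray
from covis.erp import baseline_correct
from covis.montage import ROI_MAP
from covis.synth import COHERENCE_LEVELS, CONTEXTS

N_CONDITIONS = 10


def condition_labels() -> list[tuple[str, float]]:
    """Canonical (context, coherence) order shared by all RDMs."""
    return [(ctx, coh) for ctx in CONTEXTS for coh in COHERENCE_LEVELS]


def condition_codes(design: pd.DataFrame) -> np.ndarray:
    """Map each trial to its 0..9 canonical condition index."""
    labels = condition_labels()
    lut = {lab: i for i, lab in enumerate(labels)}
    codes = np.empty(len(design), dtype=int)
    for i, (ctx, coh) in enumerate(
        zip(design["context"].to_numpy(), design["coherence"].to_numpy(dtype=float))
    ):
        key = (ctx, float(coh))
        if key not in lut:
            raise ValueError(f"trial condition {key} outside the 10-condition set")
        codes[i] = lut[key]
    return codes


def zscore_epochs(epochs: EpochArray) -> EpochArray:
    """Standardize each (channel, time) cell to mean 0, SD 1 across trials."""
    if epochs.n_trials < 2:
        raise ValueError("z-scoring needs >= 2 trials")
    mean = epochs.data.mean(axis=0)
    sd = epochs.data.std(axis=0, ddof=0)
    if np.any(sd == 0):
        ch, tt = np.argwhere(sd == 0)[0]
        raise ValueError(
            f"zero variance across trials at channel "
            f"{epochs.channel_names[ch]!r}, sample {tt} "
            f"({epochs.times_ms[tt]:.1f} ms)"
        )
    out = epochs.copy()
    out.data = (out.data - mean) / sd
    return out


def fit_condition_patterns(
    epochs: EpochArray, design: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Condition patterns by least squares at every (channel, time).

    The design matrix is an intercept plus the 10 condition indicators
    — rank-deficient by construction — solved with the minimum-norm
    pseudoinverse; the intercept row is discarded. Returns
    ``betas`` (time x 10 x channels) and ``residuals`` (trials x
    channels x time).
    """
    codes = condition_codes(design)
    if len(design) != epochs.n_trials:
        raise ValueError("design must align with epochs")
    counts = np.bincount(codes, minlength=N_CONDITIONS)
    if np.any(counts < 2):
        missing = [
            f"{condition_labels()[i]} (n={counts[i]})"
            for i in np.flatnonzero(counts < 2)
        ]
        raise ValueError(f"conditions with < 2 trials: {missing}")

    n = epochs.n_trials
    X = np.zeros((n, N_CONDITIONS + 1))
    X[:, 0] = 1.0
    X[np.arange(n), codes + 1] = 1.0
    P = np.linalg.pinv(X)  # (11, n) minimum-norm solve

    flat = epochs.data.reshape(n, -1)  # trials x (channels*time)
    B = P @ flat  # 11 x (channels*time)
    resid = (flat - X @ B).reshape(epochs.data.shape)
    betas = B[1:].reshape(N_CONDITIONS, epochs.n_channels, epochs.n_times)
    return np.moveaxis(betas, 2, 0), resid


def pca_denoise(betas: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Remove the least significant singular component of a pattern matrix.

    SVD of the 10 x channels beta matrix; the smallest singular value is
    zeroed and the matrix reconstructed. When the smallest singular
    value is already (numerically) zero the input is returned unchanged.
    """
    betas = np.asarray(betas, dtype=float)
    if not np.all(np.isfinite(betas)):
        raise ValueError("beta matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(betas, full_matrices=False)
    if s.size == 0 or s[-1] <= tol * max(s[0], 1.0):
        return betas.copy()
    s = s.copy()
    s[-1] = 0.0
    return (U * s) @ Vt


def noise_covariance(residuals: np.ndarray, shrinkage: float = 0.1) -> np.ndarray:
    """Shrunk residual covariance: (1−γ)·S + γ·diag(S).

    γ > 0 guarantees positive definiteness whenever every channel has
    nonzero residual variance.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    residuals = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residuals contain non-finite values")
    S = np.cov(residuals, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    return (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))


def mahalanobis_rdm(betas: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Pairwise Mahalanobis distances between condition patterns.

    Entry (i, j) = sqrt((b_i − b_j)^T cov^{-1} (b_i − b_j)); the matrix
    is symmetric with a zero diagonal.
    """
    betas = np.asarray(betas, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        L = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise ValueError(
            "covariance is not positive definite; increase shrinkage"
        ) from exc
    except Exception as exc:
        raise ValueError(
            "covariance is not positive definite; increase shrinkage"
        ) from exc
    white = solve_triangular(L, betas.T, lower=True).T
    return squareform(pdist(white, metric="euclidean"))


def model_rdm_coherence() -> np.ndarray:
    """Coherence model: |c_i − c_j| normalized by the maximum (51.2),
    identical across social contexts."""
    coh = np.array([c for _, c in condition_labels()])
    return np.abs(coh[:, None] - coh[None, :]) / max(COHERENCE_LEVELS)


def model_rdm_context(block: str = "ones") -> np.ndarray:
    """Social-context model: 0 within context, 1 between contexts.

    ``block="identity"`` gives the variant where the between-context
    block is a repeated 5 x 5 identity (dissimilar only at equal
    coherence); the 0/1 definition is the default.
    """
    ctx = np.array([0 if c == CONTEXTS[0] else 1 for c, _ in condition_labels()])
    if block == "ones":
        return (ctx[:, None] != ctx[None, :]).astype(float)
    if block == "identity":
        coh = np.array([c for _, c in condition_labels()])
        between = ctx[:, None] != ctx[None, :]
        same_coh = coh[:, None] == coh[None, :]
        return (between & same_coh).astype(float)
    raise ValueError("block must be 'ones' or 'identity'")


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """The 45 below-diagonal entries in fixed (row-major) order."""
    rdm = np.asarray(rdm)
    if rdm.shape != (N_CONDITIONS, N_CONDITIONS):
        raise ValueError("expected a 10 x 10 RDM")
    i, j = np.tril_indices(N_CONDITIONS, k=-1)
    return rdm[i, j]


def kendall_tau_a(rdm_a: np.ndarray, rdm_b: np.ndarray) -> float:
    """Kendall's Tau-A between two RDMs over lower-triangle entries.

    Tau-A uses the full pair-count denominator n(n−1)/2 (n = 45 entries,
    990 pairs); tied pairs add nothing to the numerator but stay in the
    denominator, so heavily tied model RDMs cannot reach |tau| = 1.
    """
    a = lower_triangle(rdm_a)
    b = lower_triangle(rdm_b)
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    prod = sa * sb
    iu = np.triu_indices(a.size, k=1)
    concord = prod[iu]
    n_pairs = a.size * (a.size - 1) // 2
    return float(concord.sum() / n_pairs)


@dataclass
class RsaResult:
    """Per-subject RSA time course: tau per model over (strided) time."""

    times_ms: np.ndarray
    tau: dict[str, np.ndarray]
    rdms: np.ndarray | None = field(default=None, repr=False)


def rsa_timecourse(
    epochs: EpochArray,
    design: pd.DataFrame,
    models: dict[str, np.ndarray] | None = None,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
    shrinkage: float = 0.1,
    stride: int = 1,
    keep_rdms: bool = False,
) -> RsaResult:
    """Whole-sensor RSA for one subject.

    Baseline-correct -> z-score -> condition patterns per time point ->
    PCA denoise -> residual noise covariance -> Mahalanobis RDM ->
    Tau-A against each model RDM. ``stride`` decimates the time grid
    (every stride-th sample) for desk-scale runs.
    """
    if epochs.alignment != "stimulus":
        raise ValueError("RSA expects stimulus-aligned epochs")
    if models is None:
        models = {
            "coherence": model_rdm_coherence(),
            "context": model_rdm_context(),
        }
    if stride < 1:
        raise ValueError("stride must be >= 1")

    corrected = baseline_correct(epochs, baseline_ms)
    zs = zscore_epochs(corrected)
    betas, resid = fit_condition_patterns(zs, design)

    t_idx = np.arange(0, epochs.n_times, stride)
    times = epochs.times_ms[t_idx]
    tau = {name: np.empty(t_idx.size) for name in models}
    rdms = np.empty((t_idx.size, N_CONDITIONS, N_CONDITIONS)) if keep_rdms else None

    for out_i, ti in enumerate(t_idx):
        b = pca_denoise(betas[ti])
        cov = noise_covariance(resid[:, :, ti], shrinkage=shrinkage)
        rdm = mahalanobis_rdm(b, cov)
        if rdms is not None:
            rdms[out_i] = rdm
        for name, model in models.items():
            tau[name][out_i] = kendall_tau_a(rdm, model)
    return RsaResult(times_ms=times, tau=tau, rdms=rdms)


def searchlight_rsa(
    epochs: EpochArray,
    design: pd.DataFrame,
    models: dict[str, np.ndarray] | None = None,
    roi_map: dict[str, tuple[str, ...]] | None = None,
    **kwargs,
) -> dict[str, RsaResult]:
    """Repeat the RSA procedure inside each electrode ROI."""
    if roi_map is None:
        roi_map = ROI_MAP
    out = {}
    for roi, electrodes in roi_map.items():
        if len(electrodes) == 0:
            raise ValueError(f"ROI {roi!r} is empty")
        missing = [e for e in electrodes if e not in epochs.channel_names]
        if missing:
            raise ValueError(f"ROI {roi!r} electrodes absent from montage: {missing}")
        idx = [epochs.channel_index(e) for e in electrodes]
        sub = EpochArray(
            data=epochs.data[:, idx, :],
            times_ms=epochs.times_ms,
            channel_names=list(electrodes),
            trial_ids=epochs.trial_ids,
            fs_hz=epochs.fs_hz,
            alignment=epochs.alignment,
        )
        out[roi] = rsa_timecourse(sub, design, models, **kwargs)
    return out
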