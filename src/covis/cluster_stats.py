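"""Cluster-mass permutation inference on subject x time statistic series.

One-sample t-tests against zero at every time point; clusters are
maximal contiguous runs of points with p below the entry threshold,
and cluster mass is the sum of |t| over the run. The null distribution
of the maximal cluster mass comes from random per-subject sign flips
of the whole time series — the exchangeable transformation for a
one-sample design — and corrected p-values use the add-one estimator
(b + 1) / (m + 1), so p is never below 1/(n_perm + 1) nor above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ClusterResult:
    time_range_ms: tuple[float, float]
    start_idx: int
    end_idx: int  # inclusive
    mass: float
    peak_t: float
    mean_t: float
    df: int
    p_corrected: float | None = None


@dataclass
class EffectSummary:
    mean_stat: float
    sd: float
    cohens_d: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float


def pointwise_t(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against zero across subjects, per time point.

    Zero-variance points get t = ±inf (flagged by the caller via
    isfinite) with p = 0, or t = 0, p = 1 when the mean is also zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("values must be subjects x time with >= 2 subjects")
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = np.where(
        np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), n - 1), 0.0
    )
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    return t, p


def form_clusters(
    t_series: np.ndarray,
    p_series: np.ndarray,
    alpha_entry: float = 0.05,
    times_ms: np.ndarray | None = None,
    df: int = 0,
) -> list[ClusterResult]:
    """Maximal contiguous runs of p < alpha_entry; mass = sum |t|.

    Single-point clusters are allowed.
    """
    t_series = np.asarray(t_series, dtype=float)
    p_series = np.asarray(p_series, dtype=float)
    if t_series.shape != p_series.shape:
        raise ValueError("t and p series must align")
    if times_ms is None:
        times_ms = np.arange(t_series.size, dtype=float)
    below = p_series < alpha_entry
    idx = np.flatnonzero(below)
    clusters: list[ClusterResult] = []
    if idx.size == 0:
        return clusters
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        seg = t_series[s : e + 1]
        clusters.append(
            ClusterResult(
                time_range_ms=(float(times_ms[s]), float(times_ms[e])),
                start_idx=int(s),
                end_idx=int(e),
                mass=float(np.abs(seg).sum()),
                peak_t=float(seg[np.argmax(np.abs(seg))]),
                mean_t=float(seg.mean()),
                df=df,
            )
        )
    return clusters


def _max_mass_rows(t_rows: np.ndarray, p_rows: np.ndarray,
                   alpha_entry: float) -> np.ndarray:
    """Max cluster mass per row of a (rows x time) t/p stack; 0 if none."""
    below = p_rows < alpha_entry
    out = np.zeros(t_rows.shape[0])
    absvals = np.abs(t_rows) * below
    for r in range(t_rows.shape[0]):
        idx = np.flatnonzero(below[r])
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = idx[np.concatenate([[0], breaks + 1])]
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        cum = np.concatenate([[0.0], np.cumsum(absvals[r])])
        masses = cum[ends + 1] - cum[starts]
        out[r] = masses.max()
    return out


def permutation_null(
    values: np.ndarray,
    n_perm: int = 1000,
    alpha_entry: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Max-cluster-mass null by per-subject sign flipping.

    Each permutation multiplies every subject's whole time series by an
    independent ±1 and recomputes pointwise t-tests and clusters. Sign
    flips leave the per-point sum of squares unchanged, so the flipped
    t statistic can be computed from the flipped mean and the fixed
    second moment — the permutations are exact, only faster.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("values must be subjects x time with >= 2 subjects")
    n, _ = values.shape
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    m2 = (values**2).sum(axis=0) / n  # invariant under sign flips
    means = (signs @ values) / n  # n_perm x time
    var = (m2[None, :] - means**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return _max_mass_rows(t, p, alpha_entry)


def corrected_p(observed_mass: float, null_distribution: np.ndarray) -> float:
    """Add-one permutation p: (#{null >= observed} + 1) / (m + 1)."""
    null = np.asarray(null_distribution, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((np.sum(null >= observed_mass) + 1) / (null.size + 1))


def cluster_permutation_test(
    values: np.ndarray,
    times_ms: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha_entry: float = 0.05,
    seed: int = 0,
) -> list[ClusterResult]:
    """Observed clusters with permutation-corrected p-values."""
    values = np.asarray(values, dtype=float)
    t, p = pointwise_t(values)
    clusters = form_clusters(
        t, p, alpha_entry=alpha_entry, times_ms=times_ms,
        df=values.shape[0] - 1,
    )
    if not clusters:
        return clusters
    null = permutation_null(values, n_perm=n_perm, alpha_entry=alpha_entry,
                            seed=seed)
    for c in clusters:
        c.p_corrected = corrected_p(c.mass, null)
    return clusters


def cluster_effect_size(
    values: np.ndarray,
    cluster: ClusterResult,
    times_ms: np.ndarray | None = None,
    sub_window_ms: tuple[float, float] | None = None,
    ci: str = "t",
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectSummary:
    """Within-cluster effect size: per-subject mean of the statistic over
    the cluster window (optionally a sub-window), Cohen's d = mean/sd
    across subjects, and a 95% CI (t-interval, or percentile bootstrap
    over subject resamples when ``ci='bootstrap'``)."""
    values = np.asarray(values, dtype=float)
    if times_ms is None:
        times_ms = np.arange(values.shape[1], dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = cluster.time_range_ms
    if sub_window_ms is not None:
        lo = max(lo, sub_window_ms[0])
        hi = min(hi, sub_window_ms[1])
    sel = (times_ms >= lo) & (times_ms <= hi)
    if not sel.any():
        raise ValueError("effect-size window contains no time points")
    per_subject = values[:, sel].mean(axis=1)
    n = per_subject.size
    mean = float(per_subject.mean())
    sd = float(per_subject.std(ddof=1))
    d = mean / sd if sd > 0 else 0.0
    tval = mean / (sd / np.sqrt(n)) if sd > 0 else 0.0
    pval = float(2.0 * stats.t.sf(abs(tval), n - 1)) if sd > 0 else 1.0
    if ci == "t":
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci95 = (mean - half, mean + half)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = per_subject[rng.integers(0, n, n)].mean()
        ci95 = (float(np.quantile(boots, 0.025)),
                float(np.quantile(boots, 0.975)))
    else:
        raise ValueError("ci must be 't' or 'bootstrap'")
    return EffectSummary(mean_stat=mean, sd=sd, cohens_d=float(d),
                         ci95=(float(ci95[0]), float(ci95[1])),
                         t=float(tval), df=n - 1, p=pval)


def type1_calibration(
    n_subjects: int = 20,
    n_time: int = 200,
    n_reps: int = 500,
    n_perm: int = 200,
    alpha: float = 0.05,
    alpha_entry: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical family-wise error of the cluster test on pure noise.

    Proportion of iid-Gaussian replicates yielding at least one cluster
    with corrected p < alpha. Should sit at the nominal level.
    """
    if n_reps < 1 or n_subjects < 2 or n_time < 1 or n_perm < 1:
        raise ValueError("all calibration sizes must be positive (>= 2 subjects)")
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        values = rng.standard_normal((n_subjects, n_time))
        clusters = cluster_permutation_test(
            values, n_perm=n_perm, alpha_entry=alpha_entry,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if any(c.p_corrected < alpha for c in clusters):
            hits += 1
    return hits / n_reps
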