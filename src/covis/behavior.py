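"""Psychometric fitting, type-2 ROC metacognition, and condition contrasts.

The accuracy model is the two-parameter Weibull

    P(x) = 1 - (1/2) exp(-(x / lambda)^kappa)

where x is percent motion coherence, lambda is the threshold (the
coherence at which accuracy reaches 1 - 0.5/e ≈ 82%) and kappa the
slope. Metacognitive sensitivity is the area under the type-2 ROC:
how well the 1–6 confidence rating separates the observer's own
correct from incorrect decisions. Group-level condition effects use a
two-stage summary-statistics approach: a per-subject estimate per
context, then a paired t-test across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_INIT = (25.0, 3.0)
LAMBDA_BOUNDS = (0.5, 200.0)
KAPPA_BOUNDS = (0.2, 10.0)


def weibull_p(x, lam: float, kappa: float):
    """Probability correct at coherence ``x`` under the Weibull model.

    Bounded in [0.5, 1): chance at x = 0, ~0.8161 at x = lambda,
    approaching 1 as x grows.
    """
    if lam <= 0 or kappa <= 0:
        raise ValueError("lambda and kappa must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("coherence must be nonnegative")
    return 1.0 - 0.5 * np.exp(-((x / lam) ** kappa))


@dataclass
class PsychometricFit:
    lambda_hat: float
    kappa_hat: float
    converged: bool
    sse: float
    message: str = ""


def fit_weibull(
    coherence,
    n_trials,
    n_correct,
    init: tuple[float, float] = DEFAULT_INIT,
    n_starts: int = 5,
    seed: int = 0,
) -> PsychometricFit:
    """Least-squares Weibull fit to per-level accuracy proportions.

    Multi-start nonlinear least squares from ``init`` plus perturbed
    starts; best sum of squared residuals wins (ties: first). With
    perfect accuracy at every level the threshold is not identifiable
    (any lambda below the lowest tested coherence fits); such input is
    flagged ``converged=False`` rather than raising.
    """
    coherence = np.asarray(coherence, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    if coherence.size < 3 or np.unique(coherence).size < 3:
        raise ValueError("need accuracy at >= 3 distinct coherence levels")
    if np.any(n_trials < 1):
        raise ValueError("each level needs at least one trial")
    prop = n_correct / n_trials

    if np.all(prop >= 1.0):
        return PsychometricFit(
            lambda_hat=float(min(coherence.min(), LAMBDA_BOUNDS[0])),
            kappa_hat=float(init[1]),
            converged=False,
            sse=0.0,
            message="non-identifiable: perfect accuracy at every level",
        )

    def resid(theta):
        return weibull_p(coherence, theta[0], theta[1]) - prop

    rng = np.random.default_rng(seed)
    starts = [np.asarray(init, dtype=float)]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    np.clip(init[0] * np.exp(rng.normal(0, 0.7)), *LAMBDA_BOUNDS),
                    np.clip(init[1] * np.exp(rng.normal(0, 0.5)), *KAPPA_BOUNDS),
                ]
            )
        )

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                resid,
                theta0,
                bounds=([LAMBDA_BOUNDS[0], KAPPA_BOUNDS[0]],
                        [LAMBDA_BOUNDS[1], KAPPA_BOUNDS[1]]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            if best is None:
                best = PsychometricFit(
                    float(theta0[0]), float(theta0[1]), False, np.inf, str(exc)
                )
            continue
        sse = float(2.0 * sol.cost)
        if best is None or (sol.success and sse < best.sse - 1e-15):
            best = PsychometricFit(
                lambda_hat=float(sol.x[0]),
                kappa_hat=float(sol.x[1]),
                converged=bool(sol.success),
                sse=sse,
                message=sol.message,
            )
    return best


def fit_weibull_table(behavior: pd.DataFrame, by=("subject", "context"),
                      **kwargs) -> pd.DataFrame:
    """Per-group Weibull fits from a trial-level behavior table."""
    records = []
    for keys, grp in behavior.groupby(list(by)):
        agg = grp.groupby("coherence")["correct"].agg(["size", "sum"])
        fit = fit_weibull(agg.index.to_numpy(), agg["size"].to_numpy(),
                          agg["sum"].to_numpy(), **kwargs)
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            lambda_hat=fit.lambda_hat,
            kappa_hat=fit.kappa_hat,
            converged=fit.converged,
            sse=fit.sse,
        )
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class RocCurve:
    criteria: np.ndarray  # descending confidence cutoffs
    hit_rates: np.ndarray
    fa_rates: np.ndarray
    auc: float


def type2_auc(correct, confidence) -> RocCurve:
    """Type-2 ROC: confidence as a classifier of the subject's own accuracy.

    Sweeping the criterion c = n_levels .. 1, hit rate is
    P(confidence >= c | correct) and false-alarm rate
    P(confidence >= c | incorrect); AUC is the trapezoidal area under
    the (FA, hit) polyline anchored at (0,0) and (1,1). Equals the
    pair-count statistic P(conf_correct > conf_error) + 0.5 P(tie).
    """
    correct = np.asarray(correct, dtype=bool)
    confidence = np.asarray(confidence)
    if correct.shape != confidence.shape:
        raise ValueError("correct and confidence must align")
    if correct.all() or (~correct).all():
        raise ValueError("type-2 ROC undefined with a single outcome class")

    conf_hit = confidence[correct]
    conf_fa = confidence[~correct]
    # sweep the observed rating values (descending); for 1-6 ratings this
    # equals the fixed criterion grid c = 6..1, and it makes the AUC
    # invariant under strictly monotone relabelings of the scale
    criteria = np.unique(confidence)[::-1]
    hits = np.array([(conf_hit >= c).mean() for c in criteria])
    fas = np.array([(conf_fa >= c).mean() for c in criteria])
    hit_poly = np.concatenate([[0.0], hits, [1.0]])
    fa_poly = np.concatenate([[0.0], fas, [1.0]])
    auc = float(np.trapezoid(hit_poly, fa_poly))
    return RocCurve(criteria=criteria, hit_rates=hits, fa_rates=fas, auc=auc)


@dataclass
class PairedResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    n_subjects: int
    degenerate: bool = False


def two_stage_contrast(per_subject: pd.DataFrame,
                       value: str = "value") -> PairedResult:
    """Paired public-minus-private contrast on per-subject summary values.

    ``per_subject`` needs columns subject, context and the value column.
    Subjects missing either context are dropped with a warning. A zero
    between-subject SD of the differences (no sampling variability) is
    flagged degenerate instead of reporting an infinite t.
    """
    wide = per_subject.pivot_table(index="subject", columns="context",
                                   values=value, aggfunc="mean")
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        warnings.warn(
            f"dropping subjects missing a context cell: {list(missing)}",
            stacklevel=2,
        )
        wide = wide.dropna()
    if wide.shape[0] < 2:
        raise ValueError("need >= 2 subjects with both contexts")
    for ctx in ("public", "private"):
        if ctx not in wide.columns:
            raise ValueError(f"context {ctx!r} absent from input")

    diff = (wide["public"] - wide["private"]).to_numpy(dtype=float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedResult(
            t=0.0 if diff.mean() == 0 else np.inf,
            df=n - 1,
            p=1.0 if diff.mean() == 0 else 0.0,
            cohens_d=0.0 if diff.mean() == 0 else np.inf,
            mean_diff=float(diff.mean()),
            n_subjects=n,
            degenerate=diff.mean() != 0,
        )
    tval, pval = stats.ttest_rel(wide["public"], wide["private"])
    return PairedResult(
        t=float(tval),
        df=n - 1,
        p=float(pval),
        cohens_d=float(diff.mean() / sd),
        mean_diff=float(diff.mean()),
        n_subjects=n,
    )
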