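"""Pipeline configuration: defaults, validation, TOML loading."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from covis.synth import GenParams


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Defaults describe the full study design (33 subjects, 640 trials);
    the scale fields let desk runs shrink subjects / repeats / time
    resolution without touching any analysis convention.
    """

    seed: int = 0
    out_dir: str = "results/pipeline"

    # design
    n_subjects: int = 33
    n_per_type: int = 32
    n_blocks: int = 4

    # generator (per-subject GenParams built from these)
    lambda_true: float = 12.8
    kappa_true: float = 1.5
    cpp_gain: float = 0.1
    context_gain: float = 0.7
    context_window_ms: tuple[float, float] = (-900.0, 3000.0)
    noise_sd: float = 10.0
    pupil_context_delta: float = 0.02
    pupil_noise_sd: float = 0.05
    blink_rate: float = 8.0

    # EEG epoching
    epoch_window_ms: tuple[float, float] = (-1500.0, 3000.0)
    eeg_fs_hz: float = 250.0

    # analysis windows
    cpp_window_ms: tuple[float, float] = (400.0, 600.0)
    cpp_baseline_ms: tuple[float, float] = (-200.0, 0.0)
    rsa_baseline_ms: tuple[float, float] = (-500.0, 0.0)
    pupil_baseline_ms: tuple[float, float] = (-1000.0, -500.0)

    # thresholds
    alpha: float = 0.05
    n_perm: int = 1000
    n_mad: float = 16.0
    shrinkage: float = 0.1
    rsa_stride: int = 1

    # pupil stage scale (the pupil chain is the slowest per-subject step)
    pupil_subjects: int | None = None
    pupil_n_per_type: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.rsa_stride < 1:
            raise ValueError("rsa_stride must be >= 1")
        start, end = self.epoch_window_ms
        for name in ("cpp_window_ms", "cpp_baseline_ms", "rsa_baseline_ms",
                     "context_window_ms"):
            w = getattr(self, name)
            if w[0] < start or w[1] > end:
                raise ValueError(
                    f"{name} {w} lies outside the epoch window "
                    f"{self.epoch_window_ms}"
                )

    # between-subject heterogeneity: multiplicative lognormal spread of the
    # per-subject gains and psychometric parameters (population-level
    # effect sizes come out at the order seen in human cohorts, d ~ 1,
    # instead of the near-infinite d of a perfectly homogeneous group)
    subject_gain_spread: float = 0.4
    subject_lambda_spread: float = 0.25
    subject_noise_spread: float = 0.15

    def gen_params(self, subject: int) -> GenParams:
        import numpy as np

        rng = np.random.default_rng([int(self.seed), 77, int(subject)])
        g_ctx, g_cpp = np.exp(rng.normal(0.0, self.subject_gain_spread, 2))
        g_lam = np.exp(rng.normal(0.0, self.subject_lambda_spread))
        g_kap = np.exp(rng.normal(0.0, 0.15))
        g_noise = np.exp(rng.normal(0.0, self.subject_noise_spread))
        return GenParams(
            lambda_true=self.lambda_true * g_lam,
            kappa_true=self.kappa_true * g_kap,
            cpp_gain=self.cpp_gain * g_cpp,
            context_gain=self.context_gain * g_ctx,
            context_window_ms=tuple(self.context_window_ms),
            noise_sd=self.noise_sd * g_noise,
            pupil_context_delta=self.pupil_context_delta,
            pupil_noise_sd=self.pupil_noise_sd,
            blink_rate=self.blink_rate,
            seed=(int(self.seed) * 1009 + int(subject)) % (2**31 - 1),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("context_window_ms", "epoch_window_ms", "cpp_window_ms",
                "cpp_baseline_ms", "rsa_baseline_ms", "pupil_baseline_ms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
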