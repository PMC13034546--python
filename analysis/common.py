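"""Shared desk-scale study configuration for the numbered analysis scripts.

One synthetic cohort of 16 subjects at 8 repeats per trial type
(160 trials each), RSA decimated to a 16 ms grid, 500 permutations.
These sizes keep the full chain at a few minutes on one CPU while
preserving every analysis convention of the full 33-subject,
640-trial design (which `covis.config.PipelineConfig()` gives
unchanged).
"""

from covis.config import PipelineConfig

OUT_DIR = "results/study"


def study_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        n_subjects=16,
        n_per_type=8,
        rsa_stride=4,
        n_perm=500,
        pupil_subjects=8,
        pupil_n_per_type=4,
        out_dir=OUT_DIR,
    )
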