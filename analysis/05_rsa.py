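"""Time-resolved RSA: Mahalanobis brain RDMs vs model RDMs.

Per subject and time point: baseline-correct, z-score, estimate the
10 condition patterns by regression, denoise with PCA, whiten by the
shrunk residual covariance, build the 10x10 Mahalanobis RDM, and
rank-compare (Kendall Tau-A) against the coherence and social-context
model RDMs. Writes the per-subject tau time courses.
"""

from pathlib import Path

from common import OUT_DIR, study_config
from covis.pipeline import stage_rsa


def main() -> None:
    cfg = study_config()
    info = stage_rsa(cfg, Path(OUT_DIR))
    print(f"wrote {info['rsa_csv']} ({info['n_subjects']} subjects, "
          f"stride {cfg.rsa_stride} -> {1000 * cfg.rsa_stride / cfg.eeg_fs_hz:.0f} ms grid)")


if __name__ == "__main__":
    main()
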