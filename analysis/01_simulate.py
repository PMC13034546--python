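"""Simulate the synthetic co-visibility cohort.

Generates each subject's balanced RDK design (5 coherence levels x 2
directions x 2 social contexts) and behavioral outcomes, and writes
the pooled trial table to results/study/behavior.csv. Downstream
scripts regenerate EEG and pupil data from the same seeds on demand.
"""

from pathlib import Path

from common import OUT_DIR, study_config
from covis.pipeline import stage_simulate


def main() -> None:
    cfg = study_config()
    out = Path(OUT_DIR)
    out.mkdir(parents=True, exist_ok=True)
    info = stage_simulate(cfg, out)
    print(f"wrote {info['behavior_csv']} ({info['n_trials']} trials, "
          f"{cfg.n_subjects} subjects x {cfg.n_per_type * 20} trials)")


if __name__ == "__main__":
    main()
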