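"""Behavioral analysis: psychometric fits, metacognition, context contrasts.

Fits the two-parameter Weibull per subject and context, computes
type-2 ROC AUCs, and runs paired public-vs-private contrasts on
accuracy, RT, confidence, AUC and threshold. The generative model has
no context effect on behavior, so every contrast should come out
non-significant — the behavioral null.
"""

from pathlib import Path

from common import OUT_DIR, study_config
from covis.pipeline import stage_behavior


def main() -> None:
    cfg = study_config()
    info = stage_behavior(cfg, Path(OUT_DIR))
    print(f"wrote {info['fits_csv']}")
    print("public - private contrasts (paired t):")
    for measure, res in info["contrasts"].items():
        flag = "  <- unexpected" if res["p"] < 0.05 else ""
        print(f"  {measure:12s} t({res['df']}) = {res['t']:+.2f}, "
              f"p = {res['p']:.3f}, d = {res['d']:+.2f}{flag}")


if __name__ == "__main__":
    main()
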