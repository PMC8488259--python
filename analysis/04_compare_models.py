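"""Statistical model comparison: ANOVA + Tukey HSD hypothesis batteries.

H1 — are the models better than a uniform dummy?  H2 — do the novel tasks
(pupil calibration, memory description) match the established tasks
(picture description, reading)?  H3 — does task fusion beat the individual
tasks?  Writes comparisons.csv.
"""

import argparse
from pathlib import Path

from gazespeech.pipeline import RunConfig, run_compare


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=str(args.out))
    batteries = run_compare(cfg, args.out)
    for b in ("H1", "H2", "H3"):
        sub = batteries[batteries["battery"] == b]
        print(f"{b}: {int(sub['significant'].sum())}/{len(sub)} "
              "Tukey-adjusted pairwise comparisons significant at 0.05")


if __name__ == "__main__":
    main()
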