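"""Logistic-regression feature importance per (task, modality).

Fits the L2 logistic regression on the full cohort after correlation
feature selection, ranks features by Wald t-statistics, and writes the
top rows with odds ratios and 95% CIs to importance.csv.
"""

import argparse
from pathlib import Path

from gazespeech.pipeline import RunConfig, run_importance


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    ap.add_argument("--top", type=int, default=5)
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=str(args.out))
    table = run_importance(cfg, args.out, top_n=args.top)
    for (task, modality), sub in table.groupby(["task", "modality"], sort=False):
        print(f"{task} / {modality}:")
        for _, r in sub.iterrows():
            print(f"  [{r['direction']}] {r['feature']}  OR={r['odds_ratio']:.3g}")


if __name__ == "__main__":
    main()
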