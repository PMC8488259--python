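"""Generate the synthetic memory-clinic cohort.

Writes per-participant gaze streams, transcripts and acoustic frame
matrices for 79 patients and 83 controls (the study's cohort composition),
with ~36 participants carrying degraded gaze, to <out>/cohort/.
"""

import argparse
from pathlib import Path

import pandas as pd

from gazespeech.pipeline import RunConfig, run_simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=str(args.out))
    args.out.mkdir(parents=True, exist_ok=True)
    run_simulate(cfg, args.out)

    labels = pd.read_csv(args.out / "cohort" / "labels.csv")
    counts = labels["group"].value_counts()
    print(f"cohort written to {args.out / 'cohort'}")
    print(f"  patients: {counts.get('patient', 0)}, controls: {counts.get('control', 0)}")


if __name__ == "__main__":
    main()
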