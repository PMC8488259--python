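"""Render the human-readable markdown report from the run artifacts."""

import argparse
from pathlib import Path

from gazespeech.pipeline import write_report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    args = ap.parse_args()
    print(write_report(args.out))


if __name__ == "__main__":
    main()
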