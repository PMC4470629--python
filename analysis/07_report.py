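#!/usr/bin/env python
"""Print the human-readable summary of a completed study bundle,
cross-checking the summary totals against the raw projection table."""

import argparse
from pathlib import Path

from parkclim.pipeline import report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0, help="unused; kept so every "
                    "stage script shares one invocation")
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    print(report(args.out))


if __name__ == "__main__":
    main()
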