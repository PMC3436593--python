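#!/usr/bin/env python
"""Re-derive the saturation critical-value table by simulation and overwrite
the copy shipped with the package (slow: a few minutes).

Usage: python scripts/regenerate_isscrit.py [--seed N] [--out PATH]
"""

import argparse
from pathlib import Path

from barcodelim.saturation import regenerate_critical_table

DEFAULT_OUT = (Path(__file__).resolve().parent.parent
               / "src" / "barcodelim" / "data" / "iss_critical_synthetic.tsv")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20120824)
    parser.add_argument("--out", type=Path, default=DEFAULT_OUT)
    args = parser.parse_args()
    rows = regenerate_critical_table(seed=args.seed, out_path=args.out)
    print(f"wrote {len(rows)} rows to {args.out}")


if __name__ == "__main__":
    main()
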