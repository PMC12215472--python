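"""Regenerate the simulator's confidence-calibration reference table.

For a grid of class counts and mean-confidence targets, solve for the
Dirichlet peak concentration whose expected top probability matches the
target (the same seeded Monte-Carlo bisection the simulator uses at run
time) and print the table as JSON.  Useful for inspecting the calibration
curve or pinning values in downstream configs.

Usage:  python scripts/calibrate_confidence.py [--out table.json]
"""

from __future__ import annotations

import argparse
import json
import sys

from avifuse.simulate import calibrate_concentration


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--classes", type=int, nargs="+", default=[5, 10, 20])
    parser.add_argument("--targets", type=float, nargs="+",
                        default=[0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95])
    parser.add_argument("--out", default=None)
    args = parser.parse_args()

    table: dict[str, dict[str, float]] = {}
    for k in args.classes:
        table[str(k)] = {}
        for t in args.targets:
            try:
                table[str(k)][f"{t:.2f}"] = round(calibrate_concentration(k, t), 4)
            except ValueError:
                table[str(k)][f"{t:.2f}"] = None  # below the attainable floor
    out = json.dumps(table, indent=1)
    if args.out:
        with open(args.out, "w", encoding="utf-8") as fh:
            fh.write(out)
    else:
        sys.stdout.write(out + "\n")


if __name__ == "__main__":
    main()
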