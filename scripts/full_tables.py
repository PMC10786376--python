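#!/usr/bin/env python
"""Reproduce the full published type-I-error / power grids (k = 3, 5, 7).

Not part of CI (each of the 63 cells runs 10,000 replicates); writes one TSV
per k under the chosen output directory.

Usage:  python scripts/full_tables.py --seed 1 --out scratch/tables [--reps 10000]
"""

from __future__ import annotations

import argparse
import os
import sys

import varctrl as vc

SIZE_PATTERNS = {
    3: [(5,) * 4, (15,) * 4, (30,) * 4,
        (5, 10, 10, 10), (10, 20, 20, 20), (20, 30, 30, 30),
        (10, 5, 5, 5), (20, 10, 10, 10), (30, 20, 20, 20),
        (5, 6, 7, 8), (15, 16, 17, 18), (25, 26, 27, 28),
        (8, 7, 6, 5), (18, 17, 16, 15), (28, 27, 26, 25),
        (5, 5, 10, 10), (10, 10, 20, 20), (15, 15, 30, 30),
        (10, 10, 5, 5), (20, 20, 10, 10), (30, 30, 15, 15)],
    5: [(5,) * 6, (15,) * 6, (30,) * 6,
        (5,) + (10,) * 5, (10,) + (20,) * 5, (20,) + (30,) * 5,
        (10,) + (5,) * 5, (20,) + (10,) * 5, (30,) + (20,) * 5,
        (5, 6, 7, 8, 9, 10), (15, 16, 17, 18, 19, 20), (25, 26, 27, 28, 29, 30),
        (10, 9, 8, 7, 6, 5), (20, 19, 18, 17, 16, 15), (30, 29, 28, 27, 26, 25),
        (5, 5, 5, 10, 10, 10), (10, 10, 10, 20, 20, 20), (15, 15, 15, 30, 30, 30),
        (10, 10, 10, 5, 5, 5), (20, 20, 20, 10, 10, 10), (30, 30, 30, 15, 15, 15)],
    7: [(5,) * 8, (15,) * 8, (30,) * 8,
        (5,) + (10,) * 7, (10,) + (20,) * 7, (20,) + (30,) * 7,
        (10,) + (5,) * 7, (20,) + (10,) * 7, (30,) + (20,) * 7,
        (5, 6, 7, 8, 9, 10, 11, 12), (15, 16, 17, 18, 19, 20, 21, 22),
        (25, 26, 27, 28, 29, 30, 31, 32),
        (12, 11, 10, 9, 8, 7, 6, 5), (22, 21, 20, 19, 18, 17, 16, 15),
        (32, 31, 30, 29, 28, 27, 26, 25),
        (5, 5, 5, 5, 10, 10, 10, 10), (10, 10, 10, 10, 20, 20, 20, 20),
        (15, 15, 15, 15, 30, 30, 30, 30),
        (10, 10, 10, 10, 5, 5, 5, 5), (20, 20, 20, 20, 10, 10, 10, 10),
        (30, 30, 30, 30, 15, 15, 15, 15)],
}

VARIANCE_PATTERNS = {
    3: [(2, 2, 2, 2), (2, 2, 2, 1), (2, 1, 1, 1)],
    5: [(2,) * 6, (2, 2, 2, 2, 1, 1), (2, 2, 1, 1, 1, 1)],
    7: [(2,) * 8, (2, 2, 2, 2, 2, 2, 1, 1), (2, 2, 2, 1, 1, 1, 1, 1)],
}


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=10_000)
    parser.add_argument("--out", default="scratch/tables")
    parser.add_argument("--k", type=int, choices=(3, 5, 7), default=None,
                        help="run a single grid instead of all three")
    args = parser.parse_args(argv)
    os.makedirs(args.out, exist_ok=True)

    ks = [args.k] if args.k else [3, 5, 7]
    for k in ks:
        specs = []
        for i, sizes in enumerate(SIZE_PATTERNS[k]):
            equal = len(set(sizes[1:])) == 1
            methods = ("MIM", "Spurrier") if equal else ("MIM",)
            for j, variances in enumerate(VARIANCE_PATTERNS[k]):
                specs.append(vc.SimulationSpec(
                    sizes=sizes, variances=variances, reps=args.reps,
                    alpha=0.05, seed=args.seed * 100_000 + k * 1000 + i * 10 + j,
                    methods=methods,
                ))
        frame = vc.run_scenarios(specs)
        path = os.path.join(args.out, f"rates_k{k}.tsv")
        frame.to_csv(path, sep="\t", index=False)
        print(f"k={k}: {len(specs)} cells -> {path}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
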