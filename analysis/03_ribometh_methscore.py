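#!/usr/bin/env python
"""MethScore stoichiometry recovery across the f grid.

Finding (seed 1): at 50,000 hydrolysed molecules and 3 replicates the
mean MethScore recovers the planted methylated fraction to within ~0.01
at every f in {0, 0.25, 0.5, 0.75, 1.0}; the analytic fixed points hold
exactly (uniform profile -> 0, fully protected bond -> 1).
"""

import argparse
from pathlib import Path

import pandas as pd

from nm_atlas import experiments as ex


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rec = ex.methscore_recovery(seed=args.seed)
    fixed = ex.methscore_fixed_points()
    rows = [
        {"f_true": f, "abs_error": float(err)} for f, err in rec["per_f_abs_error"].items()
    ]
    pd.DataFrame(rows).to_csv(args.out / "methscore_recovery.tsv", sep="\t", index=False)

    for row in rows:
        print(f"f = {row['f_true']:.2f}: |MethScore - f| = {row['abs_error']:.4f}")
    print(f"max error: {float(rec['max_abs_error']):.4f} "
          f"({rec['depth']} molecules, {rec['n_replicates']} replicates)")
    print(f"uniform-profile score (pre-clamp): {fixed['uniform_score']}")
    print(f"fully-protected score: {fixed['protected_score']}")
    print(f"worked example S=[10,10,4,10,10], w=(1.0,0.9): {ex.methscore_worked_example()}")


if __name__ == "__main__":
    main()
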