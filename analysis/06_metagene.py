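#!/usr/bin/env python
"""Metagene composition of planted sites.

Finding (seed 1): 500 sites planted at the observed mRNA region mix
(5% 5'UTR / 55% CDS / 40% 3'UTR) are recovered by the annotator with a
maximum region-fraction error of less than 0.01.
"""

import argparse
from pathlib import Path

import pandas as pd

from nm_atlas import experiments as ex
from nm_atlas.simulate import REGIONS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    result = ex.metagene_recovery(seed=args.seed)
    pd.DataFrame(
        {
            "region": REGIONS,
            "count": result["counts"],
            "fraction": result["fractions"],
            "target": (0.05, 0.55, 0.40),
        }
    ).to_csv(args.out / "metagene_fractions.tsv", sep="\t", index=False)

    for region, frac, target in zip(REGIONS, result["fractions"], (0.05, 0.55, 0.40)):
        print(f"{region}: {frac:.3f} (target {target:.2f})")
    print(f"max fraction error: {result['max_fraction_error']:.4f} ({result['n_sites']} sites)")


if __name__ == "__main__":
    main()
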