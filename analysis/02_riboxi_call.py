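#!/usr/bin/env python
"""RibOxi-seq2 site calling on planted truth: sensitivity, specificity,
and the consecutive-site masking artefact.

Finding (seed 1): all 50 planted sites of f >= 0.5 are recovered at the
depth-scaled threshold with zero off-target calls, and a fully methylated
site immediately 5' of another retains only ~4% of its neighbour's
signal — only the 3'-most site of a tandem is observed.
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

    calling = ex.riboxi_calling(seed=args.seed)
    masking = ex.masking_experiment(seed=args.seed)
    frame = pd.DataFrame(
        [
            {"metric": "sensitivity", "value": calling["sensitivity"], "n": calling["n_sites"]},
            {"metric": "off_target_calls", "value": calling["off_target_calls"], "n": calling["n_sites"]},
            {"metric": "masked_site_signal_ratio", "value": masking["ratio"], "n": masking["depth"]},
            {"metric": "masked_site_called", "value": masking["p_called"], "n": 1},
            {"metric": "distal_site_called", "value": masking["p1_called"], "n": 1},
        ]
    )
    frame.to_csv(args.out / "riboxi_calling.tsv", sep="\t", index=False)
    print(f"sensitivity: {calling['sensitivity']:.3f} ({calling['n_sites']} planted sites)")
    print(f"off-target calls: {calling['off_target_calls']}")
    print(
        f"tandem-site masking: upstream/downstream signal ratio "
        f"{masking['ratio']:.3f} (called: p={masking['p_called']}, p+1={masking['p1_called']})"
    )


if __name__ == "__main__":
    main()
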