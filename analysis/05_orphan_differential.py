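#!/usr/bin/env python
"""Four-sample WT-vs-smDEL differential: orphan snoRNA target nomination.

Finding (seed 1): in a design with 100 guide-independent sites present in
all four samples and 10 guide-dependent sites methylated only where the
snoRNA cluster is expressed, the presence/absence logic plus canonical
+5 matching recovers exactly the 10 planted targets with no false
positives; guide-independent sites are overwhelmingly shared across all
four samples.
"""

import argparse
from pathlib import Path

import pandas as pd

from nm_atlas import experiments as ex
from nm_atlas import orphan
from nm_atlas.orphan import CompareParams


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    result = ex.orphan_design(seed=args.seed)
    frame = orphan.candidates_to_frame(result.candidates)
    frame.to_csv(args.out / "orphan_candidates.tsv", sep="\t", index=False)

    shared, venn = orphan.shared_specific(
        result.tables, CompareParams(top_n=500, tau_on=150, tau_off=50)
    )
    shared.to_csv(args.out / "shared_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"samples": ",".join(k), "count": v} for k, v in sorted(venn.items())]
    ).to_csv(args.out / "venn_counts.tsv", sep="\t", index=False)

    n_shared = int(shared["shared"].sum())
    print(f"canonical candidates recovered: {result.n_true_positive}/{len(result.planted)}")
    print(f"false positives: {result.n_false_positive}")
    print(f"sites shared by all four samples: {n_shared}/{len(shared)}")


if __name__ == "__main__":
    main()
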