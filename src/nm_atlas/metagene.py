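"""Region assignment (5'UTR / CDS / 3'UTR) and normalized metagene coordinates.

Each transcript region is scaled onto its own unit interval, giving a
metagene coordinate in [0, 3): [0,1) 5'UTR, [1,2) CDS, [2,3) 3'UTR.
Region boundaries are half-open; the boundary nucleotide belongs to the
downstream region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .simulate import NmSite, REGIONS, Transcript


@dataclass(frozen=True)
class RegionAssignment:
    site: NmSite
    region: str
    metagene_x: float


def assign_region(site: NmSite, transcript: Transcript) -> RegionAssignment:
    if site.seq_id != transcript.id:
        raise MalformedInputError(f"site {site.seq_id} does not lie on {transcript.id}")
    if not 0 <= site.pos < transcript.length:
        raise MalformedInputError(f"position {site.pos} outside {transcript.id}")
    bounds = [(0, transcript.cut1), (transcript.cut1, transcript.cut2),
              (transcript.cut2, transcript.length)]
    for idx, (a, b) in enumerate(bounds):
        if a <= site.pos < b:
            return RegionAssignment(site, REGIONS[idx], idx + (site.pos - a) / (b - a))
    raise MalformedInputError(f"position {site.pos} not covered by any region of {transcript.id}")


def region_fractions(
    assignments: Sequence[RegionAssignment],
) -> tuple[np.ndarray, np.ndarray]:
    """(fractions, counts) over (5'UTR, CDS, 3'UTR); fractions sum to 1."""
    if not assignments:
        raise MalformedInputError("no assignments given")
    counts = np.array([sum(a.region == r for a in assignments) for r in REGIONS])
    return counts / counts.sum(), counts


def assignments_to_frame(assignments: Sequence[RegionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [a.site.seq_id for a in assignments],
            "pos": [a.site.pos for a in assignments],
            "region": [a.region for a in assignments],
            "metagene_x": [a.metagene_x for a in assignments],
        }
    )


def metagene_histogram(
    assignments: Sequence[RegionAssignment], bins_per_region: int = 20
) -> pd.DataFrame:
    """Binned site density along the metagene axis, for plotting."""
    x = np.array([a.metagene_x for a in assignments])
    edges = np.linspace(0.0, 3.0, 3 * bins_per_region + 1)
    hist, _ = np.histogram(x, bins=edges)
    return pd.DataFrame({"x_left": edges[:-1], "x_right": edges[1:], "count": hist})
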