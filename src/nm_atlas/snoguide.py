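"""Box C/D snoRNA motif finding, antisense elements and canonical matching.

Box C/D snoRNAs guide 2'-O-methylation through a 10-15 nt antisense
element (ASE) immediately 5' of a D or D' box (CUGA); the methylated
target nucleotide pairs with the guide nucleotide exactly five positions
upstream of the box ("+5 rule", counted from the box's 5' nucleotide with
the adjacent position as 1).

Conventions used for box assignment (deterministic):

* box C  = the 5'-most RUGAUGA (R = A/G) instance;
* box D  = the 3'-most CUGA instance;
* box D' = the 3'-most CUGA strictly upstream of box D and at least 10 nt
  downstream of box C (keeps the guide region adjacent to its box even
  when the guide itself happens to contain a CUGA);
* box C' = the 5'-most remaining RUGAUGA between box C and box D.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex import WC_PAIRS, DuplexParams, DuplexResult, DEFAULT_PARAMS, duplex_mfe
from .errors import InvalidConfigError, MalformedInputError, PlacementError
from .simulate import NmSite, RNA_ALPHABET, Transcript, revcomp

BOX_C_RE = re.compile("(?=[AG]UGAUGA)")
BOX_D_RE = re.compile("(?=CUGA)")

Interval = tuple[int, int]

MATCH_COLUMNS = [
    "sno_id", "box", "seq_id", "site_pos", "energy", "n_pairs",
    "offset", "canonical", "passes", "pairing",
]


@dataclass
class SnoRNA:
    """A box C/D snoRNA with located boxes and extracted antisense elements.

    Intervals are 0-based half-open; ``ase_D``/``ase_Dprime`` end at the
    first nucleotide of their box.
    """

    id: str
    sequence: str
    boxC: Interval | None = None
    boxD: Interval | None = None
    boxCprime: Interval | None = None
    boxDprime: Interval | None = None
    ase_D: Interval | None = None
    ase_Dprime: Interval | None = None


@dataclass
class ScanParams:
    """Significance gates for guide/target matches.

    ``min_pairs`` is the minimum length of the contiguous helix containing
    the site pair: the methyltransferase is positioned by a rigid duplex
    over the target nucleotide, so scattered pairs across interior loops
    do not count toward canonical significance.
    """

    window: int = 7            # half-width of the Nm region scanned
    min_pairs: int = 9
    energy_cutoff: float = -8.0
    wobble: bool = True

    def validate(self) -> None:
        if self.window < 1:
            raise InvalidConfigError("window must be >= 1")
        if self.energy_cutoff > 0:
            raise InvalidConfigError("energy_cutoff must be <= 0")
        if self.min_pairs < 1:
            raise InvalidConfigError("min_pairs must be >= 1")


@dataclass
class GuideMatch:
    sno_id: str
    box_used: str              # "D" or "D'"
    target_seq_id: str
    site_pos: int
    duplex: DuplexResult
    offset: int | None         # box 5' nt minus guide nt paired to the site
    canonical: bool
    passes: bool               # clears min_pairs / energy / site-pairing gates


def find_boxes(seq: str) -> dict[str, list[Interval]]:
    """All RUGAUGA (C-type) and CUGA (D-type) motif instances."""
    if set(seq) - set(RNA_ALPHABET):
        raise MalformedInputError("snoRNA sequence must be RNA (ACGU)")
    c = [(m.start(), m.start() + 7) for m in BOX_C_RE.finditer(seq)]
    d = [(m.start(), m.start() + 4) for m in BOX_D_RE.finditer(seq)]
    return {"C": c, "D": d}


def extract_ase(
    seq_len: int,
    box: Interval,
    upstream_boundary: int = 0,
    len_range: tuple[int, int] = (10, 15),
) -> Interval | None:
    """Guide interval ending immediately 5' of ``box``; up to ``len_range[1]``
    nt, truncated at ``upstream_boundary``; None if shorter than the
    minimum guide length."""
    lo, hi = len_range
    end = box[0]
    start = max(0, upstream_boundary, end - hi)
    if end - start < lo:
        return None
    return (start, end)


def annotate_snorna(sno_id: str, seq: str) -> SnoRNA | None:
    """Locate boxes and ASEs; None when the C/D architecture is absent."""
    boxes = find_boxes(seq)
    if not boxes["C"] or not boxes["D"]:
        return None
    boxC = boxes["C"][0]
    boxD = boxes["D"][-1]
    if boxC[1] > boxD[0]:
        return None
    # a D' box must leave >= 10 nt of guide room on both sides: downstream of
    # box C and upstream of box D
    dprime_candidates = [
        d for d in boxes["D"] if d[1] <= boxD[0] - 10 and d[0] >= boxC[1] + 10
    ]
    boxDprime = dprime_candidates[-1] if dprime_candidates else None
    cprime_candidates = [
        c for c in boxes["C"][1:] if c[0] >= boxC[1] and c[1] <= boxD[0]
    ]
    boxCprime = cprime_candidates[0] if cprime_candidates else None

    def boundary(box: Interval) -> int:
        # guides truncate at box C or an upstream D' box (C' is decorative)
        ends = [b[1] for b in (boxC, boxDprime) if b is not None and b[1] <= box[0]]
        return max(ends, default=0)

    ase_D = extract_ase(len(seq), boxD, boundary(boxD))
    ase_Dprime = (
        extract_ase(len(seq), boxDprime, boundary(boxDprime)) if boxDprime else None
    )
    return SnoRNA(
        id=sno_id, sequence=seq, boxC=boxC, boxD=boxD,
        boxCprime=boxCprime, boxDprime=boxDprime,
        ase_D=ase_D, ase_Dprime=ase_Dprime,
    )


def site_helix_length(pairing: list[tuple[int, int]], site_pair: tuple[int, int]) -> int:
    """Length of the contiguous helix (no loops on either strand) that
    contains ``site_pair``; pairing is (i ascending, j descending)."""
    pairs = sorted(pairing)
    k = pairs.index(site_pair)
    run = 1
    for a, b in zip(pairs[k::-1], pairs[k - 1 :: -1] if k else []):
        if b[0] == a[0] - 1 and b[1] == a[1] + 1:
            run += 1
        else:
            break
    for a, b in zip(pairs[k:], pairs[k + 1 :]):
        if b[0] == a[0] + 1 and b[1] == a[1] - 1:
            run += 1
        else:
            break
    return run


def canonical_match(
    sno: SnoRNA,
    window: str,
    window_start: int,
    site_pos: int,
    target_seq_id: str = "",
    params: ScanParams | None = None,
    duplex_params: DuplexParams = DEFAULT_PARAMS,
) -> GuideMatch | None:
    """Best guide/target duplex over the site's Nm window, D then D'.

    A match requires the site nucleotide to be Watson-Crick paired to the
    guide inside a contiguous helix of at least ``min_pairs`` base pairs,
    with duplex energy <= the cutoff; ``canonical`` additionally requires
    the guide nucleotide paired to the site to sit exactly 5 nt upstream
    of the box.  When both boxes yield a passing match the lower-energy
    one is returned.
    """
    params = params or ScanParams()
    params.validate()
    site_local = site_pos - window_start
    if not 0 <= site_local < len(window):
        raise MalformedInputError("window does not cover the site")

    best: GuideMatch | None = None
    for box_name, box, ase in (("D", sno.boxD, sno.ase_D), ("D'", sno.boxDprime, sno.ase_Dprime)):
        if box is None or ase is None:
            continue
        ase_seq = sno.sequence[ase[0]:ase[1]]
        res = duplex_mfe(ase_seq, window, wobble=params.wobble, params=duplex_params)
        site_pair = next((p for p in res.pairing if p[1] == site_local), None)
        offset = None
        site_wc = False
        helix = 0
        if site_pair is not None:
            guide_abs = ase[0] + site_pair[0]
            offset = box[0] - guide_abs
            site_wc = (ase_seq[site_pair[0]], window[site_local]) in WC_PAIRS
            helix = site_helix_length(res.pairing, site_pair)
        passes = (
            site_pair is not None
            and site_wc
            and helix >= params.min_pairs
            and res.energy <= params.energy_cutoff
        )
        if not passes:
            continue
        match = GuideMatch(
            sno_id=sno.id, box_used=box_name, target_seq_id=target_seq_id,
            site_pos=site_pos, duplex=res, offset=offset,
            canonical=(offset == 5), passes=True,
        )
        if best is None or match.duplex.energy < best.duplex.energy:
            best = match
    return best


def site_window(sequence: str, pos: int, half_width: int) -> tuple[str, int]:
    """The +-half_width Nm region around ``pos``, clipped to the sequence."""
    start = max(0, pos - half_width)
    end = min(len(sequence), pos + half_width + 1)
    return sequence[start:end], start


def scan_targets(
    snornas: Sequence[SnoRNA],
    sites: Sequence[NmSite],
    sequences: Mapping[str, str],
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Evaluate every (snoRNA, site) pair over the site's Nm window.

    Rows carry the best duplex per pair (lower-energy box), sorted by
    energy ascending with (energy, sno_id, seq_id, pos) tie-break; pairs
    with no duplex at all are reported at energy 0.
    """
    params = params or ScanParams()
    rows = []
    for site in sites:
        seq = sequences[site.seq_id]
        window, start = site_window(seq, site.pos, params.window)
        for sno in snornas:
            entry = {
                "sno_id": sno.id, "box": "", "seq_id": site.seq_id,
                "site_pos": site.pos, "energy": 0.0, "n_pairs": 0,
                "offset": np.nan, "canonical": False, "passes": False, "pairing": "",
            }
            best_energy = 0.0
            for box_name, box, ase in (("D", sno.boxD, sno.ase_D), ("D'", sno.boxDprime, sno.ase_Dprime)):
                if box is None or ase is None:
                    continue
                res = duplex_mfe(sno.sequence[ase[0]:ase[1]], window, wobble=params.wobble)
                if res.energy < best_energy:
                    best_energy = res.energy
                    entry.update(box=box_name, energy=res.energy,
                                 n_pairs=len(res.pairing), pairing=res.structure)
            match = canonical_match(sno, window, start, site.pos, site.seq_id, params)
            if match is not None:
                entry.update(
                    box=match.box_used, energy=match.duplex.energy,
                    n_pairs=len(match.duplex.pairing), offset=match.offset,
                    canonical=match.canonical, passes=True,
                    pairing=match.duplex.structure,
                )
            rows.append(entry)
    frame = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    return frame.sort_values(
        ["energy", "sno_id", "seq_id", "site_pos"], kind="mergesort"
    ).reset_index(drop=True)


_SAFE_FILL = "AC"  # cannot form CUGA or RUGAUGA motifs


def _safe_rand(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_FILL[k] for k in rng.integers(0, 2, n))


def make_guided_snoRNA(
    target: Transcript,
    site: NmSite,
    ase_len: int = 12,
    which_box: str = "D",
    seed: int = 0,
    misplace_ase: int = 0,
    sno_id: str | None = None,
) -> SnoRNA:
    """Construct a box C/D snoRNA that canonically guides ``site``.

    The ASE is the reverse complement of the target window placed so the
    site nucleotide pairs with the guide position exactly 5 nt upstream of
    the chosen box (D or D').  ``misplace_ase`` shifts the window by that
    many nt, deliberately breaking the +5 geometry (debugging/decoys).
    The result is self-checked with :func:`canonical_match`.
    """
    if not 10 <= ase_len <= 15:
        raise InvalidConfigError("ase_len must be in [10, 15]")
    if which_box not in ("D", "D'"):
        raise InvalidConfigError("which_box must be 'D' or \"D'\"")
    w0 = site.pos - 4 + misplace_ase
    if w0 < 0 or w0 + ase_len > target.length:
        raise PlacementError(
            f"site {site.seq_id}:{site.pos} too close to a transcript end for ase_len={ase_len}"
        )
    ase = revcomp(target.sequence[w0 : w0 + ase_len])
    rng = np.random.default_rng(seed)
    sno_id = sno_id or f"sno_{site.seq_id}_{site.pos}"

    for _attempt in range(50):
        box_c = ("A" if rng.integers(0, 2) else "G") + "UGAUGA"
        leader = _safe_rand(rng, 5)
        spacer1 = _safe_rand(rng, 6)
        tail = _safe_rand(rng, 3)
        if which_box == "D":
            seq = leader + box_c + spacer1 + ase + "CUGA" + tail
        else:
            filler = _safe_rand(rng, 12)
            seq = leader + box_c + spacer1 + ase + "CUGA" + filler + "CUGA" + tail
        sno = annotate_snorna(sno_id, seq)
        if sno is None:
            continue
        window, start = site_window(target.sequence, site.pos, ScanParams().window)
        match = canonical_match(sno, window, start, site.pos, target.id)
        if misplace_ase != 0:
            if match is None or not match.canonical:
                return sno
            continue
        if match is not None and match.canonical and match.box_used == which_box:
            return sno
    raise PlacementError(
        f"could not assemble a canonical guide for {site.seq_id}:{site.pos} "
        f"(ase_len={ase_len}, box={which_box})"
    )
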