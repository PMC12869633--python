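"""Synthetic transcriptomes, planted Nm sites, and read-end simulators.

Two assay simulators share a common planted truth:

* :func:`simulate_riboxi_reads` emulates RibOxi-seq2 libraries, in which
  iterative periodate oxidation / beta-elimination trims unmodified
  nucleotides from fragment 3' ends so that (almost) only fragments ending
  on a 2'-O-methylated nucleotide survive linker ligation.  Read 3' ends
  therefore mark Nm positions directly.
* :func:`simulate_ribometh_ends` emulates RiboMeth-seq alkaline hydrolysis,
  in which the phosphodiester bond 3' of a methylated ribose is protected
  from cleavage in proportion to the methylation stoichiometry, depleting
  fragment ends at that bond.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, PlacementError

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

REGIONS = ("5UTR", "CDS", "3UTR")

#: minimum distance of a planted site from either transcript end.  Positions
#: closer to an end are not measurable: a 3' end at position p supports reads
#: of at most p + 1 nt, so the > 20 nt read filter blinds the first ~21 nt of
#: a transcript; MethScore needs informative +-(flank+1) windows and guide
#: matching a +-7 nt window.  The generator never plants in the blind zone.
EDGE_MARGIN = 25


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A single-isoform transcript with 5'UTR/CDS/3'UTR cut points.

    ``cut1`` is the first CDS position, ``cut2`` the first 3'UTR position,
    both 0-based; ``0 <= cut1 <= cut2 <= len(sequence)``.
    """

    id: str
    sequence: str
    cut1: int
    cut2: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidConfigError(f"{self.id}: empty sequence")
        if set(self.sequence) - set(RNA_ALPHABET):
            raise InvalidConfigError(f"{self.id}: non-ACGU characters in sequence")
        if not (0 <= self.cut1 <= self.cut2 <= len(self.sequence)):
            raise InvalidConfigError(
                f"{self.id}: region cut points ({self.cut1}, {self.cut2}) "
                f"out of order for length {len(self.sequence)}"
            )
        if self.strand not in "+-":
            raise InvalidConfigError(f"{self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def region_bounds(self) -> tuple[int, int]:
        return (self.cut1, self.cut2)


@dataclass(frozen=True)
class NmSite:
    """A 2'-O-methylated position with stoichiometry ``f`` in [0, 1]."""

    seq_id: str
    pos: int
    base: str
    f: float
    guide_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise InvalidConfigError(f"site {self.seq_id}:{self.pos}: f={self.f} outside [0,1]")
        if self.base not in RNA_ALPHABET:
            raise InvalidConfigError(f"site {self.seq_id}:{self.pos}: base {self.base!r}")


@dataclass
class SimulationConfig:
    """Knobs of both read-end simulators.

    depth
        RibOxi: fragmentation endpoints drawn per transcript (molecules
        attempted).  RiboMeth: input molecules subjected to hydrolysis.
    background_rate
        Per-nucleotide probability that an unmethylated 3' end survives
        oxidation and is ligated anyway (incomplete oxidation).
    cleavage_rate
        Per-bond alkaline hydrolysis probability at an unprotected bond.
    pcr_dup_mean
        Mean PCR duplicate count per molecule (geometric, support >= 1).
    max_trim
        Number of nucleotides the oxidation/beta-elimination cycles can
        resect from a fragment 3' end before the fragment is lost.
    """

    depth: int = 50_000
    background_rate: float = 1e-3
    cleavage_rate: float = 0.1
    pcr_dup_mean: float = 1.5
    umi_len: int = 10
    max_trim: int = 25
    read_len_range: tuple[int, int] = (15, 60)
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise InvalidConfigError("depth must be positive")
        if not 0.0 <= self.background_rate <= 1.0:
            raise InvalidConfigError("background_rate outside [0,1]")
        if not 0.0 < self.cleavage_rate < 1.0:
            raise InvalidConfigError("cleavage_rate outside (0,1)")
        if self.pcr_dup_mean < 1.0:
            raise InvalidConfigError("pcr_dup_mean must be >= 1")
        if self.umi_len < 1:
            raise InvalidConfigError("umi_len must be >= 1")
        if self.max_trim < 0:
            raise InvalidConfigError("max_trim must be >= 0")
        lo, hi = self.read_len_range
        if not 1 <= lo <= hi:
            raise InvalidConfigError("read_len_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned, UMI-tagged read (0-based half-open interval)."""

    seq_id: str
    start: int
    end: int
    strand: str
    umi: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidConfigError(f"read {self.seq_id}:{self.start}-{self.end}: empty interval")


READ_COLUMNS = ["seq_id", "start", "end", "strand", "umi"]


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = RNA_ALPHABET) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def umi_code_to_str(code: int, umi_len: int) -> str:
    out = []
    for _ in range(umi_len):
        out.append(RNA_ALPHABET[code & 3])
        code >>= 2
    return "".join(out)


def make_transcriptome(
    n_tx: int,
    length_range: tuple[int, int] = (400, 800),
    region_fractions: tuple[float, float, float] = (0.05, 0.55, 0.40),
    seed: int = 0,
) -> list[Transcript]:
    """Generate random transcripts whose region sizes follow ``region_fractions``
    in expectation (per-transcript fractions are Dirichlet-jittered)."""
    if n_tx < 1:
        raise InvalidConfigError("n_tx must be >= 1")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise InvalidConfigError(f"invalid length_range {length_range}")
    fr = np.asarray(region_fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-6:
        raise InvalidConfigError("region_fractions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    concentration = 60.0  # keeps per-transcript jitter moderate around the target mix
    out = []
    for i in range(n_tx):
        length = int(rng.integers(lo, hi + 1))
        fracs = rng.dirichlet(fr * concentration)
        cut1 = int(round(length * fracs[0]))
        cut2 = min(length, cut1 + int(round(length * fracs[1])))
        out.append(
            Transcript(
                id=f"tx{i:04d}",
                sequence=_rand_seq(rng, length),
                cut1=cut1,
                cut2=cut2,
            )
        )
    return out


def _apportion(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` into len(weights) bins."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(rem):
        base[order[k]] += 1
    return base.tolist()


def plant_sites(
    transcripts: Sequence[Transcript],
    n_sites: int,
    f_values: Sequence[float],
    region_weights: tuple[float, float, float] = (0.05, 0.55, 0.40),
    seed: int = 0,
    edge_margin: int = EDGE_MARGIN,
    max_per_transcript: int | None = None,
) -> list[NmSite]:
    """Plant ``n_sites`` Nm sites, apportioned over regions by ``region_weights``.

    Region counts are apportioned deterministically (largest remainder);
    positions within a region are uniform.  Sites stay >= ``edge_margin`` nt
    from transcript ends.  Duplicate (seq_id, pos) pairs are never produced;
    adjacent positions are allowed.
    """
    if n_sites < 0:
        raise InvalidConfigError("n_sites must be >= 0")
    if n_sites == 0:
        return []
    if not f_values:
        raise InvalidConfigError("f_values must be non-empty")

    rng = np.random.default_rng(seed)
    by_region = _apportion(n_sites, region_weights)
    tx_list = list(transcripts)
    used: set[tuple[str, int]] = set()
    per_tx_count: dict[str, int] = {}
    sites: list[NmSite] = []

    def region_interval(tx: Transcript, region: int) -> tuple[int, int]:
        bounds = [(0, tx.cut1), (tx.cut1, tx.cut2), (tx.cut2, tx.length)]
        a, b = bounds[region]
        return max(a, edge_margin), min(b, tx.length - edge_margin)

    for region, count in enumerate(by_region):
        for _ in range(count):
            placed = False
            for _attempt in range(2000):
                tx = tx_list[int(rng.integers(0, len(tx_list)))]
                if max_per_transcript is not None and per_tx_count.get(tx.id, 0) >= max_per_transcript:
                    continue
                a, b = region_interval(tx, region)
                if b <= a:
                    continue
                pos = int(rng.integers(a, b))
                if (tx.id, pos) in used:
                    continue
                used.add((tx.id, pos))
                per_tx_count[tx.id] = per_tx_count.get(tx.id, 0) + 1
                f = float(f_values[int(rng.integers(0, len(f_values)))])
                sites.append(NmSite(tx.id, pos, tx.sequence[pos], f))
                placed = True
                break
            if not placed:
                raise InvalidConfigError(
                    f"could not place {n_sites} sites (region {REGIONS[region]} exhausted)"
                )
    return sorted(sites, key=lambda s: (s.seq_id, s.pos))


def simulate_riboxi_reads(
    transcripts: Sequence[Transcript],
    sites: Sequence[NmSite],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Simulate UMI-tagged RibOxi-seq2 reads; columns :data:`READ_COLUMNS`.

    Per molecule a fragmentation endpoint ``e`` is drawn uniformly; the 3'
    end is resected toward 5' for at most ``cfg.max_trim`` nt.  Each scanned
    position stops the resection independently: with probability ``f`` at a
    methylated site (ligatable Nm 3' end) and ``background_rate`` anywhere
    (incomplete oxidation).  No stop within the trim window -> the molecule
    is lost.  Surviving molecules get a random UMI and a geometric number of
    PCR duplicates sharing UMI and coordinates.
    """
    cfg.validate()
    tx_by_id = {t.id: t for t in transcripts}
    site_map: dict[str, list[NmSite]] = {t.id: [] for t in transcripts}
    for s in sites:
        if s.seq_id not in tx_by_id:
            raise InvalidConfigError(f"site on unknown transcript {s.seq_id}")
        site_map[s.seq_id].append(s)

    rng = np.random.default_rng(cfg.seed)
    eps = cfg.background_rate
    frames = []
    for tx in transcripts:
        length = tx.length
        e = rng.integers(0, length, cfg.depth)
        ends = np.full(cfg.depth, -1, dtype=np.int64)
        if eps > 0.0:
            # highest background-surviving position within the trim window
            d = rng.geometric(eps, cfg.depth)  # 1 == stop at e itself
            bg = e - (d - 1)
            ok = (d <= cfg.max_trim + 1) & (bg >= 0)
            ends[ok] = bg[ok]
        for s in sorted(site_map[tx.id], key=lambda x: x.pos):
            if s.f <= 0.0:
                continue
            fired = (e >= s.pos) & (e - s.pos <= cfg.max_trim) & (rng.random(cfg.depth) < s.f)
            ends[fired & (ends < s.pos)] = s.pos
        keep = ends >= 0
        n = int(keep.sum())
        if n == 0:
            continue
        end3 = ends[keep]
        rlen = rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1, n)
        start = np.maximum(0, end3 + 1 - rlen)
        codes = rng.integers(0, 4**cfg.umi_len, n)
        dups = rng.geometric(1.0 / cfg.pcr_dup_mean, n)
        idx = np.repeat(np.arange(n), dups)
        umis = np.array([umi_code_to_str(int(c), cfg.umi_len) for c in codes])
        frames.append(
            pd.DataFrame(
                {
                    "seq_id": tx.id,
                    "start": start[idx],
                    "end": end3[idx] + 1,
                    "strand": "+",
                    "umi": umis[idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.concat(frames, ignore_index=True)[READ_COLUMNS]


def simulate_ribometh_ends(
    transcripts: Sequence[Transcript],
    sites: Sequence[NmSite],
    cfg: SimulationConfig,
) -> dict[str, "EndProfile"]:
    """Simulate alkaline-hydrolysis end profiles, one per transcript.

    The bond 3' of position ``n`` is cleaved with probability
    ``cleavage_rate * (1 - f_n)`` in each of ``cfg.depth`` molecules; every
    cleavage leaves a fragment 3' end at ``n`` and a 5' end at ``n + 1``.
    Transcript terminal ends are not cleavage events and never counted.
    """
    from .riboxi import EndProfile  # local import to avoid a cycle

    cfg.validate()
    f_by_tx: dict[str, dict[int, float]] = {t.id: {} for t in transcripts}
    for s in sites:
        if s.seq_id not in f_by_tx:
            raise InvalidConfigError(f"site on unknown transcript {s.seq_id}")
        f_by_tx[s.seq_id][s.pos] = s.f

    rng = np.random.default_rng(cfg.seed)
    profiles: dict[str, EndProfile] = {}
    for tx in transcripts:
        length = tx.length
        f = np.zeros(length)
        for pos, val in f_by_tx[tx.id].items():
            f[pos] = val
        p = cfg.cleavage_rate * (1.0 - f[: length - 1])
        cuts = rng.binomial(cfg.depth, p)
        counts3 = np.concatenate([cuts, [0]]).astype(np.int64)
        counts5 = np.concatenate([[0], cuts]).astype(np.int64)
        profiles[tx.id] = EndProfile(tx.id, "+", counts3, counts5)
    return profiles


def reads_to_records(reads: pd.DataFrame) -> list[ReadRecord]:
    """Materialise a reads table as :class:`ReadRecord` objects."""
    return [
        ReadRecord(r.seq_id, int(r.start), int(r.end), r.strand, r.umi)
        for r in reads.itertuples(index=False)
    ]


def sites_with_f(sites: Sequence[NmSite], f: float, guide_id: str | None = None) -> list[NmSite]:
    """Copy of ``sites`` with stoichiometry replaced — used to switch planted
    guide-dependent sites on/off per sample."""
    return [NmSite(s.seq_id, s.pos, s.base, f, guide_id or s.guide_id) for s in sites]
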