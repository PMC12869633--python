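"""Strand-aware single-nucleotide 3'-end profiles and Nm-score peak calling.

The Nm score of a position is the summed, UMI-deduplicated 3'-end read
count across a condition's replicates.  A position is called when its Nm
score clears an absolute threshold *and* a local-background enrichment
gate (median of the surrounding window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MalformedInputError

CALL_COLUMNS = ["seq_id", "pos", "strand", "base", "nm_score", "enrichment"]


@dataclass
class EndProfile:
    """Per-position 3' and 5' end counts on one strand of one sequence."""

    seq_id: str
    strand: str
    counts3: np.ndarray
    counts5: np.ndarray

    def __post_init__(self) -> None:
        self.counts3 = np.asarray(self.counts3, dtype=np.int64)
        self.counts5 = np.asarray(self.counts5, dtype=np.int64)
        if self.counts3.shape != self.counts5.shape or self.counts3.ndim != 1:
            raise MalformedInputError(f"{self.seq_id}: 3'/5' count arrays differ in shape")
        if (self.counts3 < 0).any() or (self.counts5 < 0).any():
            raise MalformedInputError(f"{self.seq_id}: negative end counts")
        if self.strand not in "+-":
            raise MalformedInputError(f"{self.seq_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return int(self.counts3.shape[0])


@dataclass
class PeakParams:
    """Thresholds for Nm-score peak calling.

    ``score_threshold`` defaults to the high-confidence value used at full
    sequencing depth; scale it to the depth actually simulated or sequenced.
    """

    score_threshold: int = 1000
    background_window: int = 50
    min_enrichment: float = 5.0
    min_read_len: int = 20

    def validate(self) -> None:
        if self.score_threshold <= 0:
            raise InvalidConfigError("score_threshold must be > 0")
        if self.background_window < 1:
            raise InvalidConfigError("background_window must be >= 1")
        if self.min_enrichment <= 1:
            raise InvalidConfigError("min_enrichment must be > 1")


@dataclass(frozen=True)
class PeakCall:
    seq_id: str
    pos: int
    strand: str
    base: str
    nm_score: int
    enrichment: float


def filter_reads(reads: pd.DataFrame, min_read_len: int = 20) -> pd.DataFrame:
    """Keep reads strictly longer than ``min_read_len`` nt, order preserved."""
    if reads.empty:
        return reads
    return reads[(reads["end"] - reads["start"]) > min_read_len].reset_index(drop=True)


def dedup_umi(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one representative per
    (seq_id, strand, 3'-end position, UMI) equivalence class."""
    if reads.empty:
        return reads
    if reads["umi"].isna().any() or (reads["umi"] == "").any():
        raise MalformedInputError("reads without a UMI cannot be deduplicated")
    end3 = np.where(reads["strand"] == "+", reads["end"] - 1, reads["start"])
    key = reads.assign(_end3=end3)
    out = key.drop_duplicates(subset=["seq_id", "strand", "_end3", "umi"], keep="first")
    return out.drop(columns="_end3").reset_index(drop=True)


def end3_profile(
    reads: pd.DataFrame, seq_lengths: Mapping[str, int]
) -> dict[tuple[str, str], EndProfile]:
    """Tally read 3' ends (and 5' ends) per (sequence, strand).

    A plus-strand read [start, end) ends at ``end - 1``; a minus-strand
    read ends at ``start``.
    """
    profiles: dict[tuple[str, str], EndProfile] = {}
    if reads.empty:
        return profiles
    bad = ~reads["seq_id"].isin(seq_lengths)
    if bad.any():
        raise MalformedInputError(f"reads on unknown sequence {reads.loc[bad, 'seq_id'].iloc[0]!r}")
    for (seq_id, strand), grp in reads.groupby(["seq_id", "strand"], sort=True):
        length = seq_lengths[seq_id]
        if (grp["start"] < 0).any() or (grp["end"] > length).any():
            raise MalformedInputError(f"read outside bounds of {seq_id} (length {length})")
        if strand == "+":
            e3, e5 = grp["end"].to_numpy() - 1, grp["start"].to_numpy()
        else:
            e3, e5 = grp["start"].to_numpy(), grp["end"].to_numpy() - 1
        counts3 = np.bincount(e3, minlength=length)
        counts5 = np.bincount(e5, minlength=length)
        profiles[(seq_id, strand)] = EndProfile(seq_id, strand, counts3, counts5)
    return profiles


def _summed_track(profiles: Sequence[EndProfile]) -> np.ndarray:
    if not profiles:
        raise MalformedInputError("no replicate profiles given")
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise MalformedInputError("replicate profiles have inconsistent lengths")
    return np.sum([p.counts3 for p in profiles], axis=0)


def nm_score(profiles: Sequence[EndProfile], pos: int) -> int:
    """Summed deduplicated 3'-end count across replicates at ``pos``."""
    track = _summed_track(profiles)
    if not 0 <= pos < track.shape[0]:
        raise MalformedInputError(f"position {pos} outside profile")
    return int(track[pos])


def local_background(track: np.ndarray, pos: int, half_width: int) -> float:
    """max(1, median of the +-half_width window around pos, pos excluded)."""
    lo = max(0, pos - half_width)
    hi = min(track.shape[0], pos + half_width + 1)
    window = np.concatenate([track[lo:pos], track[pos + 1 : hi]])
    if window.size == 0:
        return 1.0
    return max(1.0, float(np.median(window)))


def call_nm_sites(
    profiles: Sequence[EndProfile],
    params: PeakParams,
    sequence: str | None = None,
) -> list[PeakCall]:
    """Call Nm sites on one (sequence, strand)'s replicate profiles.

    A position is called iff its Nm score is >= the score threshold and
    >= min_enrichment times the local background.  Adjacent super-threshold
    positions are reported independently (sites are single-nucleotide).
    """
    params.validate()
    track = _summed_track(profiles)
    seq_id, strand = profiles[0].seq_id, profiles[0].strand
    calls = []
    for pos in np.flatnonzero(track >= params.score_threshold):
        pos = int(pos)
        bg = local_background(track, pos, params.background_window)
        enrichment = track[pos] / bg
        if enrichment >= params.min_enrichment:
            base = sequence[pos] if sequence is not None else "N"
            calls.append(PeakCall(seq_id, pos, strand, base, int(track[pos]), float(enrichment)))
    return sorted(calls, key=lambda c: (c.seq_id, c.pos))


def call_all(
    replicate_profiles: Sequence[Mapping[tuple[str, str], EndProfile]],
    params: PeakParams,
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Run :func:`call_nm_sites` over every (sequence, strand) group present
    in any replicate; returns a tidy calls table."""
    keys = sorted({k for rep in replicate_profiles for k in rep})
    rows = []
    for key in keys:
        group = [rep[key] for rep in replicate_profiles if key in rep]
        seq = sequences.get(key[0]) if sequences else None
        rows.extend(call_nm_sites(group, params, seq))
    return pd.DataFrame([r.__dict__ for r in rows], columns=CALL_COLUMNS)
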