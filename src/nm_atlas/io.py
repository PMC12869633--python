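"""Readers and writers for the text formats the pipeline speaks.

All coordinates on disk are 0-based half-open (BED/bedGraph convention).
Readers validate rather than coerce: duplicate FASTA ids, non-nucleotide
characters, overlapping bedGraph intervals and schema mismatches raise
:class:`~nm_atlas.errors.MalformedInputError`.  TSV tables carry a
versioned schema comment line so downstream tools can check what they
are reading.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import MalformedInputError
from .riboxi import EndProfile
from .simulate import NmSite, RNA_ALPHABET, Transcript

SCHEMA_PREFIX = "#nm-atlas v1 schema="

SITE_SCHEMA = "sites.1"        # planted truth: seq_id pos base f guide_id
CALL_SCHEMA = "calls.1"        # called peaks: seq_id pos strand base nm_score enrichment
DESIGN_SCHEMA = "design.1"     # sample_id genotype background expresses_cluster sites_path
ANNOT_SCHEMA = "regions.1"     # transcript annotation: id cut1 cut2 length


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id -> sequence mapping; DNA is transcribed (T -> U), case
    normalised to upper."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise MalformedInputError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise MalformedInputError(f"{path}: empty record {rec.id!r}")
        bad = set(seq) - set(RNA_ALPHABET)
        if bad:
            raise MalformedInputError(f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}")
        out[rec.id] = seq
    if not out:
        raise MalformedInputError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(seq_id: str, counts: np.ndarray, path: str | Path) -> None:
    """Run-length encoded bedGraph of one count track; zero runs omitted."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, counts.shape[0] + 1):
            if i == counts.shape[0] or counts[i] != counts[start]:
                if counts[start] != 0:
                    fh.write(f"{seq_id}\t{start}\t{i}\t{int(counts[start])}\n")
                start = i


def read_bedgraph(path: str | Path, seq_id: str, length: int) -> np.ndarray:
    counts = np.zeros(length, dtype=np.int64)
    covered = np.zeros(length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise MalformedInputError(f"{path}:{lineno}: expected 4 bedGraph columns")
            name, start, end, value = fields
            if name != seq_id:
                continue
            start, end, value = int(start), int(end), int(value)
            if not 0 <= start < end <= length:
                raise MalformedInputError(f"{path}:{lineno}: interval outside [0, {length})")
            if covered[start:end].any():
                raise MalformedInputError(f"{path}:{lineno}: overlapping intervals")
            covered[start:end] = True
            counts[start:end] = value
    return counts


def write_end_profile(profile: EndProfile, path3: str | Path, path5: str | Path) -> None:
    write_bedgraph(profile.seq_id, profile.counts3, path3)
    write_bedgraph(profile.seq_id, profile.counts5, path5)


def read_end_profile(
    path3: str | Path, path5: str | Path, seq_id: str, length: int, strand: str = "+"
) -> EndProfile:
    return EndProfile(
        seq_id, strand,
        read_bedgraph(path3, seq_id, length),
        read_bedgraph(path5, seq_id, length),
    )


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """BED6 with the UMI in the name column and score 0."""
    bed = pd.DataFrame(
        {
            "chrom": reads["seq_id"], "start": reads["start"], "end": reads["end"],
            "name": reads["umi"], "score": 0, "strand": reads["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    try:
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedInputError(f"{path}: not a readable BED6 file ({exc})") from exc
    if bed[["start", "end"]].isna().any().any() or (bed["start"] >= bed["end"]).any():
        raise MalformedInputError(f"{path}: malformed read intervals")
    if (~bed["strand"].isin(["+", "-"])).any():
        raise MalformedInputError(f"{path}: strand column must be +/-")
    return pd.DataFrame(
        {
            "seq_id": bed["chrom"], "start": bed["start"].astype(int),
            "end": bed["end"].astype(int), "strand": bed["strand"], "umi": bed["name"],
        }
    )


def _write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX}{schema}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_table(path: str | Path, schema: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"{SCHEMA_PREFIX}{schema}":
            raise MalformedInputError(
                f"{path}: expected schema line {SCHEMA_PREFIX}{schema!s}, got {header!r}"
            )
        return pd.read_csv(fh, sep="\t")


def write_sites_tsv(sites: Sequence[NmSite], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "seq_id": [s.seq_id for s in sites], "pos": [s.pos for s in sites],
            "base": [s.base for s in sites], "f": [s.f for s in sites],
            "guide_id": [s.guide_id or "" for s in sites],
        }
    )
    _write_table(frame, path, SITE_SCHEMA)


def read_sites_tsv(path: str | Path) -> list[NmSite]:
    frame = _read_table(path, SITE_SCHEMA)
    frame["guide_id"] = frame.get("guide_id", "").fillna("")
    return [
        NmSite(r.seq_id, int(r.pos), r.base, float(r.f), r.guide_id or None)
        for r in frame.itertuples(index=False)
    ]


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    _write_table(calls, path, CALL_SCHEMA)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, CALL_SCHEMA)
    if frame.empty:
        return frame
    frame["pos"] = frame["pos"].astype(int)
    frame["nm_score"] = frame["nm_score"].astype(int)
    return frame


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    _write_table(design, path, DESIGN_SCHEMA)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, DESIGN_SCHEMA)
    required = {"sample_id", "genotype", "background", "expresses_cluster"}
    missing = required - set(frame.columns)
    if missing:
        raise MalformedInputError(f"{path}: design table missing columns {sorted(missing)}")
    frame["expresses_cluster"] = frame["expresses_cluster"].astype(bool)
    return frame


def write_annotation_tsv(transcripts: Sequence[Transcript], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "id": [t.id for t in transcripts], "cut1": [t.cut1 for t in transcripts],
            "cut2": [t.cut2 for t in transcripts], "length": [t.length for t in transcripts],
        }
    )
    _write_table(frame, path, ANNOT_SCHEMA)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, ANNOT_SCHEMA)
    bad = ~((0 <= frame["cut1"]) & (frame["cut1"] <= frame["cut2"]) & (frame["cut2"] <= frame["length"]))
    if bad.any():
        raise MalformedInputError(f"{path}: inconsistent region cut points")
    return frame
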