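"""Shared/specific site classification and orphan snoRNA target nomination.

The four-sample design mirrors two isogenic stem-cell backgrounds, each
with a wild-type line and a line carrying a small paternal deletion
(smDEL) of the SNORD116 orphan snoRNA cluster; one background's smDEL
line additionally silences the SNORD113/114 clusters.  Target nomination
is presence/absence logic over Nm scores, not a statistical test:

* SNORD113/114 style — a site must be present in the single cluster-
  expressing sample and absent from the three non-expressing samples.
* SNORD116 style — present in both wild-type samples, absent from both
  smDEL samples.

Surviving sites are then required to pair canonically (+5 rule) with a
snoRNA of the deleted cluster to be nominated as canonical candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidDesignError
from .snoguide import GuideMatch, ScanParams, SnoRNA, canonical_match, site_window

SiteKey = tuple[str, int, str]  # (seq_id, pos, strand)

VERDICTS = ("canonical_candidate", "non_canonical", "rejected")


@dataclass
class ConditionSiteTable:
    """Called sites for one sample, plus the design metadata."""

    sample_id: str
    genotype: str                  # "WT" or "smDEL"
    background: str                # isogenic line label
    calls: pd.DataFrame            # columns as riboxi.CALL_COLUMNS
    expresses_cluster: bool = False

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "smDEL"):
            raise InvalidDesignError(f"{self.sample_id}: genotype must be WT or smDEL")
        if not self.calls.empty:
            dup = self.calls.duplicated(subset=["seq_id", "pos", "strand"])
            if dup.any():
                raise InvalidDesignError(f"{self.sample_id}: duplicate site keys in calls")

    def score_map(self) -> dict[SiteKey, int]:
        return {
            (r.seq_id, int(r.pos), r.strand): int(r.nm_score)
            for r in self.calls.itertuples(index=False)
        }


@dataclass
class CompareParams:
    top_n: int = 500
    tau_on: int = 500
    tau_off: int = 50

    def validate(self) -> None:
        if self.top_n < 1:
            raise InvalidConfigError("top_n must be >= 1")
        if not self.tau_off < self.tau_on:
            raise InvalidConfigError("tau_off must be < tau_on")


@dataclass
class OrphanCandidate:
    site: SiteKey
    scores: dict[str, int]         # per sample_id
    guide_match: GuideMatch | None
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise InvalidConfigError(f"unknown verdict {self.verdict!r}")


def _top_sites(table: ConditionSiteTable, top_n: int) -> set[SiteKey]:
    calls = table.calls
    if calls.empty:
        return set()
    ranked = calls.sort_values(
        ["nm_score", "seq_id", "pos"], ascending=[False, True, True], kind="mergesort"
    ).head(top_n)
    return {(r.seq_id, int(r.pos), r.strand) for r in ranked.itertuples(index=False)}


def shared_specific(
    tables: Sequence[ConditionSiteTable], params: CompareParams | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Classify each top-N site by the subset of samples containing it.

    Returns a per-site table (columns seq_id, pos, strand, samples, shared)
    and Venn-style counts keyed by the sorted tuple of sample ids.
    """
    params = params or CompareParams()
    params.validate()
    if len(tables) < 2:
        raise InvalidDesignError("need at least two samples to compare")
    if any(t.calls.empty for t in tables):
        raise InvalidDesignError("every sample must have at least one call")
    tops = {t.sample_id: _top_sites(t, params.top_n) for t in tables}
    all_sites = sorted(set().union(*tops.values()))
    n_samples = len(tables)
    rows = []
    counts: dict[tuple[str, ...], int] = {}
    for site in all_sites:
        members = tuple(sorted(s for s, top in tops.items() if site in top))
        counts[members] = counts.get(members, 0) + 1
        rows.append(
            {
                "seq_id": site[0], "pos": site[1], "strand": site[2],
                "samples": ",".join(members),
                "shared": len(members) == n_samples,
            }
        )
    return pd.DataFrame(rows), counts


def _score_of(score_maps: Mapping[str, dict[SiteKey, int]], sample: str, site: SiteKey) -> int:
    return score_maps[sample].get(site, 0)


def _evaluate_candidates(
    candidate_sites: Sequence[SiteKey],
    absence_ok: Mapping[SiteKey, bool],
    score_maps: Mapping[str, dict[SiteKey, int]],
    snornas: Sequence[SnoRNA],
    sequences: Mapping[str, str],
    scan: ScanParams,
) -> list[OrphanCandidate]:
    out = []
    for site in candidate_sites:
        scores = {s: _score_of(score_maps, s, site) for s in score_maps}
        if not absence_ok[site]:
            out.append(OrphanCandidate(site, scores, None, "rejected"))
            continue
        seq_id, pos, _strand = site
        window, start = site_window(sequences[seq_id], pos, scan.window)
        best: GuideMatch | None = None
        for sno in snornas:
            m = canonical_match(sno, window, start, pos, seq_id, scan)
            if m is None:
                continue
            if best is None or (m.canonical, -m.duplex.energy) > (best.canonical, -best.duplex.energy):
                best = m
        if best is not None and best.canonical:
            verdict = "canonical_candidate"
        else:
            verdict = "non_canonical"
        out.append(OrphanCandidate(site, scores, best, verdict))
    return out


def snord113_114_style(
    tables: Sequence[ConditionSiteTable],
    snornas: Sequence[SnoRNA],
    sequences: Mapping[str, str],
    compare: CompareParams | None = None,
    scan: ScanParams | None = None,
) -> list[OrphanCandidate]:
    """One expressing sample vs three non-expressing samples.

    Candidate sites score >= tau_on in the expressing sample; they are
    rejected unless <= tau_off in every non-expressing sample.
    """
    compare = compare or CompareParams()
    scan = scan or ScanParams()
    compare.validate()
    expressing = [t for t in tables if t.expresses_cluster]
    others = [t for t in tables if not t.expresses_cluster]
    if len(expressing) != 1 or not others:
        raise InvalidDesignError("need exactly one cluster-expressing sample")
    score_maps = {t.sample_id: t.score_map() for t in tables}
    on = expressing[0]
    candidates = sorted(
        k for k, v in score_maps[on.sample_id].items() if v >= compare.tau_on
    )
    absence = {
        site: all(_score_of(score_maps, t.sample_id, site) <= compare.tau_off for t in others)
        for site in candidates
    }
    return _evaluate_candidates(candidates, absence, score_maps, snornas, sequences, scan)


def snord116_style(
    tables: Sequence[ConditionSiteTable],
    snornas: Sequence[SnoRNA],
    sequences: Mapping[str, str],
    compare: CompareParams | None = None,
    scan: ScanParams | None = None,
) -> list[OrphanCandidate]:
    """Two WT vs two smDEL samples.

    Candidate sites score >= tau_on in both WT samples; rejected unless
    <= tau_off in both smDEL samples.
    """
    compare = compare or CompareParams()
    scan = scan or ScanParams()
    compare.validate()
    wt = [t for t in tables if t.genotype == "WT"]
    dele = [t for t in tables if t.genotype == "smDEL"]
    if len(wt) != 2 or len(dele) != 2:
        raise InvalidDesignError("SNORD116-style comparison needs 2 WT and 2 smDEL samples")
    score_maps = {t.sample_id: t.score_map() for t in tables}
    keys = sorted(set(score_maps[wt[0].sample_id]) & set(score_maps[wt[1].sample_id]))
    candidates = [
        k for k in keys
        if all(_score_of(score_maps, t.sample_id, k) >= compare.tau_on for t in wt)
    ]
    absence = {
        site: all(_score_of(score_maps, t.sample_id, site) <= compare.tau_off for t in dele)
        for site in candidates
    }
    return _evaluate_candidates(candidates, absence, score_maps, snornas, sequences, scan)


def candidates_to_frame(candidates: Sequence[OrphanCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "seq_id": c.site[0], "pos": c.site[1], "strand": c.site[2],
            "verdict": c.verdict,
            "sno_id": c.guide_match.sno_id if c.guide_match else "",
            "box": c.guide_match.box_used if c.guide_match else "",
            "energy": c.guide_match.duplex.energy if c.guide_match else np.nan,
            "offset": c.guide_match.offset if c.guide_match else np.nan,
            "canonical": bool(c.guide_match.canonical) if c.guide_match else False,
        }
        for sample, score in sorted(c.scores.items()):
            row[f"score_{sample}"] = score
        rows.append(row)
    return pd.DataFrame(rows)
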