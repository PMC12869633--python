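"""End-to-end pipeline: simulate -> profile -> call -> score -> scan -> compare.

The pipeline is the demo-scale composition of every stage over one
synthetic four-sample experiment.  All outputs are plain text, all
randomness flows from one seed, and a manifest with SHA-256 content
hashes of every artifact is written so reruns can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, metagene, orphan, riboxi, ribometh, simulate, snoguide
from .errors import InvalidConfigError
from .experiments import _sub_seed
from .orphan import CompareParams, ConditionSiteTable
from .riboxi import PeakParams
from .ribometh import MethScoreParams
from .simulate import SimulationConfig
from .snoguide import ScanParams

log = logging.getLogger("nm_atlas.pipeline")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    n_transcripts: int = 40
    length_range: tuple[int, int] = (350, 450)
    region_fractions: tuple[float, float, float] = (0.05, 0.55, 0.40)
    n_background_sites: int = 25
    n_guide_targets: int = 5
    f_values: tuple[float, ...] = (0.6, 0.8, 1.0)
    guide_f: float = 0.9
    depth: int = 8000
    background_rate: float = 0.0
    call_tau: int = 20
    tau_on: int = 60
    tau_off: int = 20
    methscore_depth: int = 20000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.tau_off < self.tau_on:
            raise InvalidConfigError("tau_off must be < tau_on")
        if self.n_transcripts < self.n_background_sites + self.n_guide_targets:
            raise InvalidConfigError("need at least one transcript per planted site")
        SimulationConfig(depth=self.depth, background_rate=self.background_rate).validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns {'outputs': {name: sha256}, ...}."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    log.info("pipeline start: %s", asdict(config))

    # --- synthetic truth -------------------------------------------------
    transcripts = simulate.make_transcriptome(
        config.n_transcripts, config.length_range, config.region_fractions,
        seed=_sub_seed(seed, 1),
    )
    n_bg = config.n_background_sites
    bg_sites = simulate.plant_sites(
        transcripts[:n_bg], n_bg, list(config.f_values),
        seed=_sub_seed(seed, 2), max_per_transcript=1,
    )
    guide_sites = simulate.plant_sites(
        transcripts[n_bg : n_bg + config.n_guide_targets], config.n_guide_targets,
        [config.guide_f], seed=_sub_seed(seed, 3), max_per_transcript=1,
    )
    tx_by_id = {t.id: t for t in transcripts}
    snornas = [
        snoguide.make_guided_snoRNA(
            tx_by_id[s.seq_id], s, ase_len=10 + k % 6,
            which_box="D" if k % 2 == 0 else "D'",
            seed=_sub_seed(seed, 50 + k), sno_id=f"guide{k + 1}",
        )
        for k, s in enumerate(guide_sites)
    ]
    sequences = {t.id: t.sequence for t in transcripts}
    lengths = {t.id: t.length for t in transcripts}

    io.write_fasta(sequences, out / "transcripts.fa")
    io.write_fasta({s.id: s.sequence for s in snornas}, out / "snornas.fa")
    io.write_annotation_tsv(transcripts, out / "transcripts.regions.tsv")
    io.write_sites_tsv(bg_sites + guide_sites, out / "planted_sites.tsv")

    # --- RibOxi arm: four samples ---------------------------------------
    design_rows = []
    tables = []
    for k, (sample, genotype, background, expresses) in enumerate(
        [("H9", "WT", "H9", True), ("H9-smDEL", "smDEL", "H9", False),
         ("CT2", "WT", "CT2", True), ("CT2-smDEL", "smDEL", "CT2", False)]
    ):
        sample_sites = bg_sites + (guide_sites if expresses else [])
        cfg = SimulationConfig(
            depth=config.depth, background_rate=config.background_rate,
            seed=_sub_seed(seed, 100 + k),
        )
        reads = simulate.simulate_riboxi_reads(transcripts, sample_sites, cfg)
        io.write_reads_bed(reads, out / f"{sample}.reads.bed")
        reads = riboxi.dedup_umi(riboxi.filter_reads(reads, 20))
        profiles = riboxi.end3_profile(reads, lengths)
        calls = riboxi.call_all([profiles], PeakParams(score_threshold=config.call_tau), sequences)
        io.write_calls_tsv(calls, out / f"{sample}.sites.tsv")
        tables.append(ConditionSiteTable(sample, genotype, background, calls, expresses))
        design_rows.append(
            {"sample_id": sample, "genotype": genotype, "background": background,
             "expresses_cluster": expresses, "sites_path": f"{sample}.sites.tsv"}
        )
        if k == 0 and profiles:
            first = profiles[sorted(profiles)[0]]
            io.write_bedgraph(first.seq_id, first.counts3, out / f"{sample}.{first.seq_id}.3p.bg")
    io.write_design_tsv(pd.DataFrame(design_rows), out / "design.tsv")

    # --- RiboMeth arm on the WT truth ------------------------------------
    meth_profiles = [
        simulate.simulate_ribometh_ends(
            transcripts, bg_sites + guide_sites,
            SimulationConfig(depth=config.methscore_depth, seed=_sub_seed(seed, 200 + r)),
        )
        for r in range(3)
    ]
    meth_rows = []
    for s in bg_sites + guide_sites:
        track = ribometh.methscore_track([rep[s.seq_id] for rep in meth_profiles])
        meth_rows.append(
            {"seq_id": s.seq_id, "pos": s.pos, "f_true": s.f,
             "methscore": track.scores[s.pos], "sd": track.replicate_sd[s.pos]}
        )
    pd.DataFrame(meth_rows).to_csv(out / "methscore.sites.tsv", sep="\t", index=False)

    # --- guide scan and differential -------------------------------------
    matches = snoguide.scan_targets(snornas, guide_sites, sequences)
    matches.to_csv(out / "guide_matches.tsv", sep="\t", index=False)
    compare = CompareParams(top_n=500, tau_on=config.tau_on, tau_off=config.tau_off)
    candidates = orphan.snord116_style(tables, snornas, sequences, compare)
    orphan.candidates_to_frame(candidates).to_csv(out / "orphan_candidates.tsv", sep="\t", index=False)
    shared, venn = orphan.shared_specific(tables, compare)
    shared.to_csv(out / "shared_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"samples": ",".join(k), "count": v} for k, v in sorted(venn.items())]
    ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)

    # --- metagene ---------------------------------------------------------
    assignments = [metagene.assign_region(s, tx_by_id[s.seq_id]) for s in bg_sites + guide_sites]
    metagene.assignments_to_frame(assignments).to_csv(out / "site_regions.tsv", sep="\t", index=False)
    fractions, counts = metagene.region_fractions(assignments)
    pd.DataFrame(
        {"region": simulate.REGIONS, "count": counts, "fraction": fractions}
    ).to_csv(out / "region_fractions.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    outputs = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    manifest = {"config": asdict(config), "outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("pipeline done: %d artifacts in %s", len(outputs), out)

    n_candidates = sum(c.verdict == "canonical_candidate" for c in candidates)
    return {
        "outputs": outputs,
        "n_planted_sites": len(bg_sites) + len(guide_sites),
        "n_canonical_candidates": n_candidates,
        "candidates": candidates,
    }
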