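"""Self-contained simulation experiments exercising the whole pipeline.

Each function generates its own synthetic data at the study conditions
documented in ``docs/methods.md``, runs the relevant pipeline stage, and
returns summary numbers.  The analysis drivers, the test suite and the
acceptance script all call these; nothing here reads external data.

Depth-dependent thresholds: the peak-calling score threshold used at full
sequencing depth (1000 high-confidence / 500 permissive at ~30M reads per
sample) is scaled to the simulated depths here as tau = 150 at 50,000
fragmentation attempts per transcript, which detects stoichiometries
f >~ 0.3 anywhere on a transcript body under the bounded-resection read
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import duplex, io, metagene, orphan, riboxi, ribometh, simulate, snoguide
from .orphan import CompareParams, ConditionSiteTable
from .riboxi import PeakParams
from .ribometh import MethScoreParams
from .simulate import NmSite, SimulationConfig
from .snoguide import ScanParams


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


#: transcript region-length mix used by the experiments.  Distinct from the
#: site region weights (5%/55%/40%, where sites fall): real mRNA 5'UTRs are
#: ~100 nt, long enough to carry measurable sites, even though they host only
#: ~5% of them.
TX_GEOMETRY = (0.15, 0.50, 0.35)


# ---------------------------------------------------------------------------
# MethScore


def methscore_recovery(
    seed: int = 0,
    f_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    depth: int = 50_000,
    n_replicates: int = 3,
) -> dict:
    """Parameter recovery: plant one site per stoichiometry on a single
    transcript, simulate hydrolysis profiles, recover f as the MethScore."""
    length = 40 * (len(f_grid) + 1)
    rng = np.random.default_rng(_sub_seed(seed, 1))
    seq = simulate._rand_seq(rng, length)
    tx = simulate.Transcript("meth_tx", seq, 0, length)
    positions = [40 * (i + 1) for i in range(len(f_grid))]
    sites = [NmSite("meth_tx", p, seq[p], f) for p, f in zip(positions, f_grid)]
    profiles = [
        simulate.simulate_ribometh_ends(
            [tx], sites, SimulationConfig(depth=depth, seed=_sub_seed(seed, 10 + r))
        )["meth_tx"]
        for r in range(n_replicates)
    ]
    track = ribometh.methscore_track(profiles, MethScoreParams())
    errors = {f: abs(track.scores[p] - f) for p, f in zip(positions, f_grid)}
    return {
        "per_f_abs_error": errors,
        "max_abs_error": max(errors.values()),
        "depth": depth,
        "n_replicates": n_replicates,
    }


def methscore_fixed_points() -> dict:
    """Analytic fixed points: uniform profile scores exactly 0 pre-clamp,
    a fully protected centre scores exactly 1."""
    uniform = riboxi.EndProfile("u", "+", np.full(9, 7), np.zeros(9, dtype=int))
    protected = riboxi.EndProfile(
        "p", "+", np.array([8, 8, 8, 0, 8, 8, 8, 0]), np.zeros(8, dtype=int)
    )
    params = MethScoreParams(clamp=False)
    return {
        "uniform_score": ribometh.methscore(uniform, 4, params),
        "protected_score": ribometh.methscore(protected, 3, params),
    }


def methscore_worked_example() -> float:
    """Hand-checkable arithmetic: S = [10,10,4,10,10], weights (1.0, 0.9)."""
    counts3 = np.array([0, 10, 10, 4, 10, 10, 0])
    profile = riboxi.EndProfile("w", "+", counts3, np.zeros(7, dtype=int))
    return ribometh.methscore(profile, 3, MethScoreParams())


# ---------------------------------------------------------------------------
# RibOxi site calling


def riboxi_calling(
    seed: int = 0,
    n_sites: int = 50,
    depth: int = 50_000,
    background_rate: float = 1e-3,
    tau: int = 150,
) -> dict:
    """Sensitivity / off-target calls on planted sites of f >= 0.5.

    One site per transcript so that planted truth is unambiguous; depth-
    scaled threshold tau; 5-fold local-background enrichment gate.
    """
    transcripts = simulate.make_transcriptome(
        n_sites, length_range=(400, 600), region_fractions=TX_GEOMETRY, seed=_sub_seed(seed, 1)
    )
    sites = simulate.plant_sites(
        transcripts, n_sites, f_values=[0.5, 0.75, 1.0],
        seed=_sub_seed(seed, 2), max_per_transcript=1,
    )
    cfg = SimulationConfig(depth=depth, background_rate=background_rate, seed=_sub_seed(seed, 3))
    reads = simulate.simulate_riboxi_reads(transcripts, sites, cfg)
    reads = riboxi.dedup_umi(riboxi.filter_reads(reads, 20))
    profiles = riboxi.end3_profile(reads, {t.id: t.length for t in transcripts})
    params = PeakParams(score_threshold=tau)
    calls = riboxi.call_all([profiles], params, {t.id: t.sequence for t in transcripts})
    truth = {(s.seq_id, s.pos) for s in sites}
    called = {(r.seq_id, int(r.pos)) for r in calls.itertuples(index=False)}
    return {
        "sensitivity": len(called & truth) / len(truth),
        "off_target_calls": len(called - truth),
        "n_sites": len(truth),
        "n_calls": len(called),
        "depth": depth,
    }


def masking_experiment(seed: int = 0, depth: int = 20_000) -> dict:
    """Tandem fully methylated sites at p, p+1 with no oxidation background:
    ligation selects the 3'-most methylated terminus, so signal at p is a
    small fraction of signal at p+1 and only p+1 is called."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    seq = simulate._rand_seq(rng, 300)
    tx = simulate.Transcript("mask_tx", seq, 0, 300)
    p = 150
    sites = [NmSite("mask_tx", p, seq[p], 1.0), NmSite("mask_tx", p + 1, seq[p + 1], 1.0)]
    cfg = SimulationConfig(depth=depth, background_rate=0.0, seed=_sub_seed(seed, 2))
    reads = riboxi.dedup_umi(
        simulate.simulate_riboxi_reads([tx], sites, cfg)
    )
    profiles = riboxi.end3_profile(reads, {"mask_tx": 300})
    track = profiles[("mask_tx", "+")].counts3
    calls = riboxi.call_all([profiles], PeakParams(score_threshold=150), {"mask_tx": seq})
    called_pos = set(calls["pos"].astype(int))
    return {
        "count_p": int(track[p]),
        "count_p1": int(track[p + 1]),
        "ratio": track[p] / max(1, track[p + 1]),
        "p_called": p in called_pos,
        "p1_called": (p + 1) in called_pos,
        "depth": depth,
    }


# ---------------------------------------------------------------------------
# Duplex DP vs exhaustive enumeration


def duplex_oracle_check(seed: int = 0, n_pairs: int = 200, max_len: int = 12) -> dict:
    """DP energy vs brute-force enumeration over all admissible pairings."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    agree = 0
    for _ in range(n_pairs):
        a = simulate._rand_seq(rng, int(rng.integers(3, max_len + 1)))
        b = simulate._rand_seq(rng, int(rng.integers(3, max_len + 1)))
        e_dp = duplex.duplex_mfe(a, b).energy
        e_bf = duplex.brute_force_mfe(a, b)
        if abs(e_dp - e_bf) < 1e-9:
            agree += 1
    return {"n_pairs": n_pairs, "n_agree": agree, "agreement": agree / n_pairs}


# ---------------------------------------------------------------------------
# Guided snoRNA construction and decoys


def guided_canonical_recovery(seed: int = 0, n_guides: int = 20, n_decoys: int = 100) -> dict:
    """Constructed guides must all satisfy the +5 rule; shuffled-guide
    decoys almost never should."""
    transcripts = simulate.make_transcriptome(
        n_guides, length_range=(300, 500), region_fractions=TX_GEOMETRY, seed=_sub_seed(seed, 1)
    )
    sites = simulate.plant_sites(
        transcripts, n_guides, f_values=[1.0], seed=_sub_seed(seed, 2), max_per_transcript=1
    )
    tx_by_id = {t.id: t for t in transcripts}
    n_canonical = 0
    snos = []
    for k, site in enumerate(sites):
        ase_len = 10 + k % 6
        box = "D" if k % 2 == 0 else "D'"
        sno = snoguide.make_guided_snoRNA(
            tx_by_id[site.seq_id], site, ase_len=ase_len, which_box=box,
            seed=_sub_seed(seed, 100 + k),
        )
        snos.append(sno)
        tx = tx_by_id[site.seq_id]
        window, start = snoguide.site_window(tx.sequence, site.pos, 7)
        m = snoguide.canonical_match(sno, window, start, site.pos, site.seq_id)
        if m is not None and m.canonical:
            n_canonical += 1

    # decoy null: shuffle the D-box guide of the first snoRNA, same window
    rng = np.random.default_rng(_sub_seed(seed, 3))
    target = tx_by_id[sites[0].seq_id]
    window, start = snoguide.site_window(target.sequence, sites[0].pos, 7)
    base = snos[0]
    a0, a1 = base.ase_D
    false_canonical = 0
    for d in range(n_decoys):
        shuffled = "".join(rng.permutation(list(base.sequence[a0:a1])))
        seq = base.sequence[:a0] + shuffled + base.sequence[a1:]
        decoy = snoguide.annotate_snorna(f"decoy{d}", seq)
        if decoy is None:
            continue
        m = snoguide.canonical_match(decoy, window, start, sites[0].pos)
        if m is not None and m.canonical:
            false_canonical += 1
    return {
        "n_guides": n_guides,
        "n_canonical": n_canonical,
        "n_decoys": n_decoys,
        "false_canonical": false_canonical,
        "false_canonical_rate": false_canonical / n_decoys,
    }


# ---------------------------------------------------------------------------
# Orphan differential design


@dataclass
class OrphanExperiment:
    candidates: list
    planted: set
    n_true_positive: int
    n_false_positive: int
    tables: list
    snornas: list
    sequences: dict


def orphan_design(
    seed: int = 0,
    n_guide_targets: int = 10,
    n_background_sites: int = 100,
    depth: int = 20_000,
) -> OrphanExperiment:
    """Four-sample SNORD116-style design over synthetic data.

    ``n_background_sites`` guide-independent sites are methylated in all
    four samples; ``n_guide_targets`` guide-dependent sites (each with a
    constructed canonical snoRNA) are methylated at f = 0.9 in the two WT
    samples and unmethylated in the two smDEL samples.  Oxidation
    background is off, matching the idealised presence/absence setting.
    """
    n_tx = n_guide_targets + n_background_sites
    transcripts = simulate.make_transcriptome(
        n_tx, length_range=(350, 450), region_fractions=TX_GEOMETRY, seed=_sub_seed(seed, 1)
    )
    bg_tx, guide_tx = transcripts[:n_background_sites], transcripts[n_background_sites:]
    bg_sites = simulate.plant_sites(
        bg_tx, n_background_sites, f_values=[0.6, 0.8, 1.0],
        seed=_sub_seed(seed, 2), max_per_transcript=1,
    )
    guide_sites = simulate.plant_sites(
        guide_tx, n_guide_targets, f_values=[0.9],
        seed=_sub_seed(seed, 3), max_per_transcript=1,
    )
    tx_by_id = {t.id: t for t in transcripts}
    snornas = [
        snoguide.make_guided_snoRNA(
            tx_by_id[s.seq_id], s, ase_len=10 + k % 6,
            which_box="D" if k % 2 == 0 else "D'",
            seed=_sub_seed(seed, 200 + k), sno_id=f"SNORD116-like-{k + 1}",
        )
        for k, s in enumerate(guide_sites)
    ]

    lengths = {t.id: t.length for t in transcripts}
    sequences = {t.id: t.sequence for t in transcripts}
    design = [
        ("H9", "WT", "H9", True),
        ("H9-smDEL", "smDEL", "H9", False),
        ("CT2", "WT", "CT2", True),
        ("CT2-smDEL", "smDEL", "CT2", False),
    ]
    tables = []
    for k, (sample, genotype, background, expresses) in enumerate(design):
        sample_sites = list(bg_sites)
        if expresses:
            sample_sites += guide_sites
        cfg = SimulationConfig(
            depth=depth, background_rate=0.0, seed=_sub_seed(seed, 300 + k)
        )
        reads = riboxi.dedup_umi(
            riboxi.filter_reads(simulate.simulate_riboxi_reads(transcripts, sample_sites, cfg), 20)
        )
        profiles = riboxi.end3_profile(reads, lengths)
        # permissive call threshold: keeps sub-tau_on scores visible to the
        # absence test downstream
        calls = riboxi.call_all([profiles], PeakParams(score_threshold=20), sequences)
        tables.append(
            ConditionSiteTable(sample, genotype, background, calls, expresses_cluster=expresses)
        )

    compare = CompareParams(top_n=500, tau_on=150, tau_off=50)
    candidates = orphan.snord116_style(tables, snornas, sequences, compare, ScanParams())
    planted = {(s.seq_id, s.pos, "+") for s in guide_sites}
    hits = {c.site for c in candidates if c.verdict == "canonical_candidate"}
    return OrphanExperiment(
        candidates=candidates,
        planted=planted,
        n_true_positive=len(hits & planted),
        n_false_positive=len(hits - planted),
        tables=tables,
        snornas=snornas,
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# Metagene recovery


def metagene_recovery(
    seed: int = 0,
    n_sites: int = 500,
    region_weights: tuple[float, float, float] = (0.05, 0.55, 0.40),
) -> dict:
    """Plant sites with the observed mRNA region mix (5% 5'UTR / 40% 3'UTR)
    and recover the fractions through the annotator."""
    transcripts = simulate.make_transcriptome(
        200, length_range=(400, 800), region_fractions=TX_GEOMETRY, seed=_sub_seed(seed, 1)
    )
    sites = simulate.plant_sites(
        transcripts, n_sites, f_values=[0.5, 1.0],
        region_weights=region_weights, seed=_sub_seed(seed, 2),
    )
    tx_by_id = {t.id: t for t in transcripts}
    assignments = [metagene.assign_region(s, tx_by_id[s.seq_id]) for s in sites]
    fractions, counts = metagene.region_fractions(assignments)
    errors = np.abs(fractions - np.asarray(region_weights))
    return {
        "fractions": fractions,
        "counts": counts,
        "max_fraction_error": float(errors.max()),
        "n_sites": n_sites,
    }
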