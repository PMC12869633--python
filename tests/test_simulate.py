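"""Generator behaviour: determinism, planted composition, assay signatures."""

import numpy as np
import pandas as pd
import pytest

from nm_atlas import riboxi, simulate
from nm_atlas.errors import InvalidConfigError
from nm_atlas.simulate import NmSite, SimulationConfig, Transcript


class TestTranscriptome:
    def test_fixed_seed_reproducible(self):
        a = simulate.make_transcriptome(5, seed=7)
        b = simulate.make_transcriptome(5, seed=7)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert [t.region_bounds for t in a] == [t.region_bounds for t in b]

    def test_region_fractions_recovered_in_expectation(self):
        txs = simulate.make_transcriptome(
            1000, length_range=(400, 800), region_fractions=(0.05, 0.55, 0.40), seed=3
        )
        fracs = np.array(
            [[t.cut1 / t.length, (t.cut2 - t.cut1) / t.length, (t.length - t.cut2) / t.length]
             for t in txs]
        ).mean(axis=0)
        assert np.abs(fracs - (0.05, 0.55, 0.40)).max() < 0.02

    def test_invalid_lengths_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate.make_transcriptome(3, length_range=(0, 10))

    def test_transcript_invariants_enforced(self):
        with pytest.raises(InvalidConfigError):
            Transcript("x", "ACGT", 0, 4)  # DNA alphabet
        with pytest.raises(InvalidConfigError):
            Transcript("x", "ACGU", 3, 2)


class TestPlantSites:
    def test_zero_sites(self, small_transcriptome):
        assert simulate.plant_sites(small_transcriptome, 0, [1.0]) == []

    def test_base_matches_sequence_and_no_duplicates(self, planted):
        txs, sites = planted
        by_id = {t.id: t for t in txs}
        assert len({(s.seq_id, s.pos) for s in sites}) == len(sites)
        for s in sites:
            assert by_id[s.seq_id].sequence[s.pos] == s.base
            assert s.f in (0.5, 1.0)

    def test_deterministic_for_seed(self, small_transcriptome):
        a = simulate.plant_sites(small_transcriptome, 5, [1.0], seed=4)
        b = simulate.plant_sites(small_transcriptome, 5, [1.0], seed=4)
        assert a == b

    def test_overfull_request_rejected(self, small_transcriptome):
        with pytest.raises(InvalidConfigError):
            simulate.plant_sites(
                small_transcriptome, 50, [1.0], max_per_transcript=1
            )

    def test_region_apportionment_is_exact(self, small_transcriptome):
        txs = simulate.make_transcriptome(100, seed=8)
        sites = simulate.plant_sites(txs, 200, [1.0], region_weights=(0.05, 0.55, 0.40), seed=9)
        by_id = {t.id: t for t in txs}
        counts = [0, 0, 0]
        for s in sites:
            t = by_id[s.seq_id]
            counts[0 if s.pos < t.cut1 else 1 if s.pos < t.cut2 else 2] += 1
        assert counts == [10, 110, 80]


class TestRiboxiSimulator:
    def test_no_background_all_ends_on_sites(self, planted):
        txs, sites = planted
        cfg = SimulationConfig(depth=3000, background_rate=0.0, seed=5)
        reads = simulate.simulate_riboxi_reads(txs, sites, cfg)
        site_pos = {(s.seq_id, s.pos) for s in sites}
        ends = set(zip(reads["seq_id"], reads["end"] - 1))
        assert ends <= site_pos

    def test_unmethylated_transcriptome_emits_nothing(self, small_transcriptome):
        cfg = SimulationConfig(depth=2000, background_rate=0.0, seed=5)
        reads = simulate.simulate_riboxi_reads(small_transcriptome, [], cfg)
        assert reads.empty

    def test_dedup_counts_scale_with_stoichiometry(self):
        # two equal-length transcripts, one site each at the same position:
        # deduplicated 3'-end counts should be ~2:1 for f = 1.0 vs 0.5
        rng = np.random.default_rng(0)
        seq = simulate._rand_seq(rng, 500)
        txs = [Transcript("a", seq, 0, 500), Transcript("b", seq, 0, 500)]
        sites = [NmSite("a", 250, seq[250], 1.0), NmSite("b", 250, seq[250], 0.5)]
        cfg = SimulationConfig(depth=50_000, background_rate=1e-3, seed=6)
        reads = riboxi.dedup_umi(simulate.simulate_riboxi_reads(txs, sites, cfg))
        at_site = reads[reads["end"] - 1 == 250].groupby("seq_id").size()
        ratio = at_site["a"] / at_site["b"]
        assert 1.85 < ratio < 2.15

    def test_duplicates_share_umi_and_coordinates(self, planted):
        txs, sites = planted
        cfg = SimulationConfig(depth=2000, pcr_dup_mean=3.0, background_rate=0.0, seed=7)
        reads = simulate.simulate_riboxi_reads(txs, sites, cfg)
        deduped = riboxi.dedup_umi(reads)
        assert len(deduped) < len(reads)
        assert (reads["umi"].str.len() == cfg.umi_len).all()


class TestRibomethSimulator:
    def test_fully_protected_bond_has_no_ends(self):
        rng = np.random.default_rng(1)
        seq = simulate._rand_seq(rng, 100)
        tx = Transcript("t", seq, 0, 100)
        site = NmSite("t", 50, seq[50], 1.0)
        prof = simulate.simulate_ribometh_ends(
            [tx], [site], SimulationConfig(depth=50_000, seed=2)
        )["t"]
        assert prof.counts3[50] == 0 and prof.counts5[51] == 0

    def test_end_totals_equal_cleavage_events(self):
        rng = np.random.default_rng(1)
        seq = simulate._rand_seq(rng, 80)
        tx = Transcript("t", seq, 0, 80)
        prof = simulate.simulate_ribometh_ends(
            [tx], [], SimulationConfig(depth=5000, seed=3)
        )["t"]
        assert prof.counts3.sum() == prof.counts5.sum()
        assert prof.counts5[0] == 0 and prof.counts3[-1] == 0

    def test_unmethylated_profile_roughly_uniform(self):
        rng = np.random.default_rng(1)
        seq = simulate._rand_seq(rng, 60)
        tx = Transcript("t", seq, 0, 60)
        prof = simulate.simulate_ribometh_ends(
            [tx], [], SimulationConfig(depth=100_000, cleavage_rate=0.1, seed=4)
        )["t"]
        internal = prof.counts3[:-1]
        assert internal.min() > 0.8 * internal.mean()
        assert internal.max() < 1.2 * internal.mean()

    def test_config_validation(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(depth=0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(cleavage_rate=1.0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(pcr_dup_mean=0.5).validate()
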