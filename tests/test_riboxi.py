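"""Read filtering, UMI collapse, 3'-end profiling and peak calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nm_atlas import riboxi, simulate
from nm_atlas.errors import MalformedInputError
from nm_atlas.riboxi import EndProfile, PeakParams
from nm_atlas.simulate import SimulationConfig


def reads_frame(rows):
    return pd.DataFrame(rows, columns=simulate.READ_COLUMNS)


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,kept",
        [(20, False), (21, True), (1, False), (60, True)],
        ids=["at-threshold-removed", "just-longer-kept", "tiny", "long"],
    )
    def test_strictly_longer_required(self, length, kept):
        reads = reads_frame([("t", 0, length, "+", "A" * 10)])
        out = riboxi.filter_reads(reads, 20)
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        out = riboxi.filter_reads(reads_frame([]), 20)
        assert out.empty


class TestDedupUmi:
    def test_same_key_collapses(self):
        reads = reads_frame(
            [("t", 0, 30, "+", "ACGUACGUAC"), ("t", 5, 30, "+", "ACGUACGUAC")]
        )
        assert len(riboxi.dedup_umi(reads)) == 1  # same (seq, strand, 3' end, UMI)

    def test_different_end_kept(self):
        reads = reads_frame(
            [("t", 0, 30, "+", "ACGUACGUAC"), ("t", 0, 31, "+", "ACGUACGUAC")]
        )
        assert len(riboxi.dedup_umi(reads)) == 2

    def test_missing_umi_rejected(self):
        reads = reads_frame([("t", 0, 30, "+", "")])
        with pytest.raises(MalformedInputError):
            riboxi.dedup_umi(reads)

    def test_idempotent_and_matches_key_set_oracle(self, planted):
        txs, sites = planted
        cfg = SimulationConfig(depth=5000, pcr_dup_mean=2.5, seed=21)
        reads = simulate.simulate_riboxi_reads(txs, sites, cfg)
        once = riboxi.dedup_umi(reads)
        twice = riboxi.dedup_umi(once)
        assert len(once) == len(twice)
        # independent oracle: distinct (seq, strand, 3'-end, umi) tuples
        keys = {
            (r.seq_id, r.strand, r.end - 1 if r.strand == "+" else r.start, r.umi)
            for r in reads.itertuples(index=False)
        }
        assert len(once) == len(keys)


class TestEnd3Profile:
    def test_plus_strand_convention(self):
        profs = riboxi.end3_profile(reads_frame([("t", 10, 40, "+", "A" * 10)]), {"t": 50})
        assert profs[("t", "+")].counts3[39] == 1
        assert profs[("t", "+")].counts3.sum() == 1

    def test_minus_strand_convention(self):
        profs = riboxi.end3_profile(reads_frame([("t", 10, 40, "-", "A" * 10)]), {"t": 50})
        assert profs[("t", "-")].counts3[10] == 1

    def test_read_count_conserved(self, planted):
        txs, sites = planted
        reads = simulate.simulate_riboxi_reads(
            txs, sites, SimulationConfig(depth=2000, seed=22)
        )
        profs = riboxi.end3_profile(reads, {t.id: t.length for t in txs})
        total = sum(p.counts3.sum() for p in profs.values())
        assert total == len(reads)

    def test_out_of_bounds_read_rejected(self):
        with pytest.raises(MalformedInputError):
            riboxi.end3_profile(reads_frame([("t", 10, 60, "+", "A" * 10)]), {"t": 50})

    def test_unknown_sequence_rejected(self):
        with pytest.raises(MalformedInputError):
            riboxi.end3_profile(reads_frame([("u", 0, 10, "+", "A" * 10)]), {"t": 50})


class TestNmScore:
    def test_sums_across_replicates(self):
        a = EndProfile("t", "+", [0, 600, 0], [0, 0, 0])
        b = EndProfile("t", "+", [0, 500, 0], [0, 0, 0])
        assert riboxi.nm_score([a, b], 1) == 1100
        assert riboxi.nm_score([a, b], 0) == 0

    def test_replicate_length_mismatch_rejected(self):
        a = EndProfile("t", "+", [0, 1], [0, 0])
        b = EndProfile("t", "+", [0, 1, 2], [0, 0, 0])
        with pytest.raises(MalformedInputError):
            riboxi.nm_score([a, b], 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equals_elementwise_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = rng.integers(0, 100, (2, 30))
        reps = [
            EndProfile("t", "+", c1, np.zeros(30, int)),
            EndProfile("t", "+", c2, np.zeros(30, int)),
        ]
        pos = int(rng.integers(0, 30))
        assert riboxi.nm_score(reps, pos) == int(c1[pos]) + int(c2[pos])


class TestCallNmSites:
    def test_all_zero_profile_no_calls(self):
        prof = EndProfile("t", "+", np.zeros(200, int), np.zeros(200, int))
        assert riboxi.call_nm_sites([prof], PeakParams()) == []

    def test_single_spike_called_once(self):
        counts = np.zeros(300, int)
        counts[150] = 2000
        prof = EndProfile("t", "+", counts, np.zeros(300, int))
        calls = riboxi.call_nm_sites([prof], PeakParams(score_threshold=1000), "A" * 300)
        assert [(c.pos, c.nm_score, c.base) for c in calls] == [(150, 2000, "A")]

    def test_enrichment_gate_blocks_flat_high_coverage(self):
        # uniformly high track: everything passes tau but nothing is enriched
        prof = EndProfile("t", "+", np.full(300, 1500), np.zeros(300, int))
        assert riboxi.call_nm_sites([prof], PeakParams(score_threshold=1000)) == []

    def test_adjacent_peaks_reported_independently(self):
        counts = np.zeros(300, int)
        counts[[150, 151]] = 2000
        prof = EndProfile("t", "+", counts, np.zeros(300, int))
        calls = riboxi.call_nm_sites([prof], PeakParams(score_threshold=1000))
        assert [c.pos for c in calls] == [150, 151]


class TestNmScoreMonotonicity:
    def test_expected_score_nondecreasing_in_stoichiometry(self):
        rng = np.random.default_rng(5)
        seq = simulate._rand_seq(rng, 400)
        tx = simulate.Transcript("t", seq, 0, 400)
        scores = []
        for k, f in enumerate((0.25, 0.5, 0.75, 1.0)):
            site = simulate.NmSite("t", 200, seq[200], f)
            reads = riboxi.dedup_umi(
                simulate.simulate_riboxi_reads(
                    [tx], [site], SimulationConfig(depth=30_000, seed=30 + k)
                )
            )
            profs = riboxi.end3_profile(reads, {"t": 400})
            scores.append(riboxi.nm_score([profs[("t", "+")]], 200))
        assert scores == sorted(scores)
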