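"""Shared/specific classification and presence/absence target nomination."""

import numpy as np
import pandas as pd
import pytest

from nm_atlas import orphan, simulate, snoguide
from nm_atlas.errors import InvalidConfigError, InvalidDesignError
from nm_atlas.orphan import CompareParams, ConditionSiteTable
from nm_atlas.riboxi import CALL_COLUMNS


def calls(rows):
    return pd.DataFrame(
        [dict(zip(CALL_COLUMNS, (seq, pos, "+", "A", score, 10.0))) for seq, pos, score in rows],
        columns=CALL_COLUMNS,
    )


def table(sample, genotype, rows, background="B", expresses=False):
    return ConditionSiteTable(sample, genotype, background, calls(rows), expresses)


class TestSharedSpecific:
    def test_identical_tables_all_shared(self):
        rows = [("t", 5, 900), ("t", 9, 800)]
        frame, counts = orphan.shared_specific(
            [table("a", "WT", rows), table("b", "WT", rows)]
        )
        assert frame["shared"].all()
        assert counts == {("a", "b"): 2}

    def test_disjoint_tables_nothing_shared(self):
        frame, counts = orphan.shared_specific(
            [table("a", "WT", [("t", 5, 900)]), table("b", "WT", [("t", 7, 900)])]
        )
        assert not frame["shared"].any()
        assert counts == {("a",): 1, ("b",): 1}

    def test_counts_match_set_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        samples = {}
        for name in "abc":
            keys = rng.choice(60, size=25, replace=False)
            samples[name] = [("t", int(k), int(rng.integers(100, 1000))) for k in keys]
        tables = [table(n, "WT", rows) for n, rows in samples.items()]
        frame, counts = orphan.shared_specific(tables, CompareParams(top_n=15, tau_on=99, tau_off=1))
        # oracle: brute-force set ops over each sample's top-15 scores
        tops = {}
        for n, rows in samples.items():
            tops[n] = {
                ("t", p, "+")
                for _, p, _ in sorted(rows, key=lambda r: (-r[2], r[1]))[:15]
            }
        union = set().union(*tops.values())
        assert sum(counts.values()) == len(union)
        for site in union:
            members = tuple(sorted(n for n in tops if site in tops[n]))
            row = frame[(frame.pos == site[1])].iloc[0]
            assert row.samples == ",".join(members)

    def test_every_site_gets_exactly_one_label(self):
        tables = [
            table("a", "WT", [("t", 1, 500), ("t", 2, 400)]),
            table("b", "WT", [("t", 2, 300), ("t", 3, 200)]),
        ]
        frame, counts = orphan.shared_specific(tables)
        assert len(frame) == 3 == sum(counts.values())
        assert frame.duplicated(subset=["seq_id", "pos", "strand"]).sum() == 0

    def test_needs_two_samples(self):
        with pytest.raises(InvalidDesignError):
            orphan.shared_specific([table("a", "WT", [("t", 1, 5)])])


def four_sample_fixture(guided=True):
    """Synthetic four-sample design with one guide-dependent planted site."""
    txs = simulate.make_transcriptome(6, length_range=(300, 400), seed=30)
    sites = simulate.plant_sites(txs, 6, [0.8], seed=31, max_per_transcript=1)
    target, background_sites = sites[0], sites[1:]
    by_id = {t.id: t for t in txs}
    sno = snoguide.make_guided_snoRNA(by_id[target.seq_id], target, seed=32) if guided else None
    sequences = {t.id: t.sequence for t in txs}

    def rows(include_target):
        out = [(s.seq_id, s.pos, 700) for s in background_sites]
        if include_target:
            out.append((target.seq_id, target.pos, 650))
        return out

    tables = [
        table("H9", "WT", rows(True), "H9", expresses=True),
        table("H9-smDEL", "smDEL", rows(False), "H9"),
        table("CT2", "WT", rows(True), "CT2", expresses=True),
        table("CT2-smDEL", "smDEL", rows(False), "CT2"),
    ]
    return tables, sno, sequences, target


class TestSnord116Style:
    def test_guide_dependent_site_nominated(self):
        tables, sno, sequences, target = four_sample_fixture()
        cands = orphan.snord116_style(tables, [sno], sequences, CompareParams(tau_on=500))
        verdicts = {c.site: c.verdict for c in cands}
        assert verdicts[(target.seq_id, target.pos, "+")] == "canonical_candidate"
        # guide-independent sites are present everywhere, so never candidates
        assert list(verdicts.values()).count("canonical_candidate") == 1

    def test_site_present_in_one_wt_only_not_a_candidate(self):
        tables, sno, sequences, target = four_sample_fixture()
        # drop the target from CT2: no longer >= tau_on in both WT samples
        ct2 = tables[2]
        pruned = ct2.calls[~((ct2.calls.seq_id == target.seq_id) & (ct2.calls.pos == target.pos))]
        tables[2] = ConditionSiteTable("CT2", "WT", "CT2", pruned.reset_index(drop=True), True)
        cands = orphan.snord116_style(tables, [sno], sequences, CompareParams(tau_on=500))
        assert (target.seq_id, target.pos, "+") not in {c.site for c in cands}

    def test_site_present_in_all_samples_rejected(self):
        tables, sno, sequences, target = four_sample_fixture()
        for k in (1, 3):  # add the target back into the smDEL samples
            extra = calls([(target.seq_id, target.pos, 600)])
            merged = pd.concat([tables[k].calls, extra], ignore_index=True)
            tables[k] = ConditionSiteTable(
                tables[k].sample_id, "smDEL", tables[k].background, merged
            )
        cands = orphan.snord116_style(tables, [sno], sequences, CompareParams(tau_on=500))
        verdicts = {c.site: c.verdict for c in cands}
        assert verdicts[(target.seq_id, target.pos, "+")] == "rejected"

    def test_no_matching_snorna_gives_non_canonical(self):
        tables, _, sequences, target = four_sample_fixture(guided=False)
        cands = orphan.snord116_style(tables, [], sequences, CompareParams(tau_on=500))
        verdicts = {c.site: c.verdict for c in cands}
        assert verdicts[(target.seq_id, target.pos, "+")] == "non_canonical"

    def test_wrong_design_rejected(self):
        tables, sno, sequences, _ = four_sample_fixture()
        with pytest.raises(InvalidDesignError):
            orphan.snord116_style(tables[:3], [sno], sequences)

    def test_threshold_monotonicity(self):
        tables, sno, sequences, _ = four_sample_fixture()
        base = orphan.snord116_style(tables, [sno], sequences, CompareParams(tau_on=500, tau_off=50))
        n_base = sum(c.verdict != "rejected" for c in base)
        stricter_on = orphan.snord116_style(
            tables, [sno], sequences, CompareParams(tau_on=660, tau_off=50)
        )
        lower_off = orphan.snord116_style(
            tables, [sno], sequences, CompareParams(tau_on=500, tau_off=10)
        )
        assert sum(c.verdict != "rejected" for c in stricter_on) <= n_base
        assert sum(c.verdict != "rejected" for c in lower_off) <= n_base


class TestSnord113_114Style:
    def test_single_expressing_sample_logic(self):
        tables, sno, sequences, target = four_sample_fixture()
        # re-label: only CT2 expresses the 113/114 cluster and carries the site
        h9 = tables[0]
        pruned = h9.calls[~((h9.calls.seq_id == target.seq_id) & (h9.calls.pos == target.pos))]
        tables[0] = ConditionSiteTable("H9", "WT", "H9", pruned.reset_index(drop=True), False)
        cands = orphan.snord113_114_style(
            tables, [sno], sequences, CompareParams(tau_on=500)
        )
        verdicts = {c.site: c.verdict for c in cands}
        assert verdicts[(target.seq_id, target.pos, "+")] == "canonical_candidate"

    def test_requires_exactly_one_expressing_sample(self):
        tables, sno, sequences, _ = four_sample_fixture()  # two expressing samples
        with pytest.raises(InvalidDesignError):
            orphan.snord113_114_style(tables, [sno], sequences)

    def test_tau_ordering_enforced(self):
        with pytest.raises(InvalidConfigError):
            CompareParams(tau_on=50, tau_off=50).validate()
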