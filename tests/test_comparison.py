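from __future__ import annotations

import itertools
import math

import pytest

from otunet.amplicon_io import Amplicon, ENVIRONMENTAL, REFERENCE
from otunet.clustering import OTU, ClusteringResult
from otunet.comparison import (
    divergence_profile,
    misclassification_audit,
    novel_amplicon_sets,
    overlap_counts,
    summarize,
    write_summary,
    write_venn_counts,
)
from otunet.novelty import ENV_ONLY, MIXED, NoveltyRecord, novelty_report
from otunet.alignment import pairwise_identity

from oracles import mutate, random_dna


def record(amp_id, otu_class, otu_id="o1"):
    return NoveltyRecord(
        amplicon_id=amp_id,
        otu_id=otu_id,
        otu_class=otu_class,
        path_distance=math.inf if otu_class == ENV_ONLY else 1,
        best_hit_identity=None,
        novelty_class="novel" if otu_class == ENV_ONLY else "covered",
    )


class TestNovelSets:
    def test_no_env_only_gives_empty_sets(self):
        reports = {ap: [record("e1", MIXED)] for ap in ("a", "b", "c")}
        assert novel_amplicon_sets(reports) == {"a": set(), "b": set(), "c": set()}

    def test_random_reports_match_filter_oracle(self, rng):
        ids = [f"e{i:02d}" for i in range(40)]
        reports = {}
        for ap in ("greedy", "network", "swarm"):
            reports[ap] = [
                record(i, ENV_ONLY if rng.random() < 0.3 else MIXED) for i in ids
            ]
        sets = novel_amplicon_sets(reports)
        for ap in reports:
            assert sets[ap] == {
                r.amplicon_id for r in reports[ap] if r.otu_class == ENV_ONLY
            }


class TestOverlapCounts:
    def test_disjoint_sets(self):
        counts = overlap_counts({"a": {1}, "b": {2, 3}, "c": {4, 5, 6}})
        assert counts[frozenset({"a"})] == 1
        assert counts[frozenset({"b"})] == 2
        assert counts[frozenset({"c"})] == 3
        assert all(
            counts[k] == 0 for k in counts if len(k) > 1
        )

    def test_identical_sets_all_in_triple_region(self):
        s = set(range(7))
        counts = overlap_counts({"a": set(s), "b": set(s), "c": set(s)})
        assert counts[frozenset({"a", "b", "c"})] == 7
        assert sum(counts.values()) == 7

    def test_wrong_number_of_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_counts({"a": set(), "b": set()})

    def test_matches_membership_pattern_tally(self, rng):
        universe = [f"u{i:04d}" for i in range(1000)]
        sets = {
            ap: {u for u in universe if rng.random() < p}
            for ap, p in (("a", 0.3), ("b", 0.2), ("c", 0.4))
        }
        counts = overlap_counts(sets)
        tally: dict[frozenset, int] = {}
        for u in universe:
            pattern = frozenset(ap for ap in sets if u in sets[ap])
            if pattern:
                tally[pattern] = tally.get(pattern, 0) + 1
        for region, n in counts.items():
            assert n == tally.get(region, 0)
        assert sum(counts.values()) == len(set().union(*sets.values()))


class TestAudit:
    def test_empty_set_counts_zero(self, small_community):
        n, flagged = misclassification_audit(
            set(), small_community["combined"], small_community["refs"], 0.97
        )
        assert (n, flagged) == (0, [])

    def test_network_novel_set_audits_to_zero(self, small_community):
        reports = {
            ap: novelty_report(res, small_community["combined"], small_community["refs"])
            for ap, res in small_community["results"].items()
        }
        sets = novel_amplicon_sets(reports)
        n, _ = misclassification_audit(
            sets["network"], small_community["combined"], small_community["refs"], 0.97
        )
        assert n == 0

    def test_radius_cap_scenario_flags_greedy(self, small_community):
        reports = {
            ap: novelty_report(res, small_community["combined"], small_community["refs"])
            for ap, res in small_community["results"].items()
        }
        sets = novel_amplicon_sets(reports)
        n, flagged = misclassification_audit(
            sets["greedy"], small_community["combined"], small_community["refs"], 0.97
        )
        assert n >= 1
        assert all(f in sets["greedy"] for f in flagged)

    def test_count_monotone_nonincreasing_in_t(self, small_community):
        reports = {
            ap: novelty_report(res, small_community["combined"], small_community["refs"])
            for ap, res in small_community["results"].items()
        }
        novel = novel_amplicon_sets(reports)["greedy"]
        counts = [
            misclassification_audit(
                novel, small_community["combined"], small_community["refs"], t
            )[0]
            for t in (0.90, 0.95, 0.97, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strict_inequality_switch(self, rng):
        seq = random_dna(rng, 100)
        amps = [
            Amplicon(id="e1", sequence=seq, origin=ENVIRONMENTAL),
            Amplicon(id="r1", sequence=seq, origin=REFERENCE),
        ]
        n_ge, _ = misclassification_audit({"e1"}, amps, [amps[1]], 1.0)
        n_gt, _ = misclassification_audit({"e1"}, amps, [amps[1]], 1.0, strict=True)
        assert (n_ge, n_gt) == (1, 0)


def _single_mixed_setup():
    amps = [
        Amplicon(id="e1", sequence="ACGTACGT", origin=ENVIRONMENTAL),
        Amplicon(id="e2", sequence="ACGTACGA", origin=ENVIRONMENTAL),
        Amplicon(id="r1", sequence="ACGTACGC", origin=REFERENCE),
    ]
    otu = OTU(
        otu_id="network_00000",
        approach="network",
        member_ids=frozenset({"e1", "e2", "r1"}),
        internal_edges=frozenset({("e1", "r1"), ("e2", "r1")}),
    )
    res = ClusteringResult(approach="network", parameters={}, otus=(otu,))
    return amps, res


class TestSummarize:
    def test_single_mixed_otu_counts(self):
        amps, res = _single_mixed_setup()
        results = {"network": res}
        reports = {"network": novelty_report(res, amps, [amps[2]])}
        summary = summarize(results, reports, amps)
        counts = summary.per_approach["network"]
        assert counts == {
            "total_otus": 1,
            "mixed_otus": 1,
            "mixed_env_amplicons": 2,
            "mixed_ref_amplicons": 1,
            "ref_only_otus": 0,
            "ref_only_ref_amplicons": 0,
            "env_only_otus": 0,
            "env_only_env_amplicons": 0,
        }

    def test_counts_match_tally_oracle_and_are_consistent(self, small_community):
        combined = small_community["combined"]
        refs = small_community["refs"]
        results = small_community["results"]
        reports = {
            ap: novelty_report(res, combined, refs) for ap, res in results.items()
        }
        summary = summarize(results, reports, combined, refs, 0.97)
        origin = {a.id: a.origin for a in combined}
        for ap, res in results.items():
            counts = summary.per_approach[ap]
            assert counts["total_otus"] == len(res.otus)
            # amplicon counts across the three classes sum to retained total
            total = (
                counts["mixed_env_amplicons"]
                + counts["mixed_ref_amplicons"]
                + counts["ref_only_ref_amplicons"]
                + counts["env_only_env_amplicons"]
            )
            assert total == len(res.retained_ids())
            # independent tally
            n_env_mixed = sum(
                1
                for otu in res.otus
                if {origin[m] for m in otu.member_ids} == {ENVIRONMENTAL, REFERENCE}
                for m in otu.member_ids
                if origin[m] == ENVIRONMENTAL
            )
            assert counts["mixed_env_amplicons"] == n_env_mixed
        assert summary.misclassified["network"] == 0
        assert sum(summary.venn.values()) == len(
            set().union(*novel_amplicon_sets(reports).values())
        )

    def test_mismatched_universes_rejected(self):
        amps, res = _single_mixed_setup()
        other = ClusteringResult(
            approach="greedy",
            parameters={},
            otus=(
                OTU(
                    otu_id="greedy_00000",
                    approach="greedy",
                    member_ids=frozenset({"e1"}),
                    seed_id="e1",
                ),
            ),
        )
        reports = {"network": [], "greedy": []}
        with pytest.raises(ValueError, match="different amplicon sets"):
            summarize({"network": res, "greedy": other}, reports, amps)


class TestDivergenceProfile:
    def test_identical_amplicon_tops_out(self, rng):
        seq = random_dna(rng, 80)
        amps = [
            Amplicon(id="e1", sequence=seq, abundance=9, origin=ENVIRONMENTAL),
            Amplicon(id="r1", sequence=seq, origin=REFERENCE),
        ]
        df = divergence_profile({"e1"}, amps, [amps[1]])
        assert df.loc[0, "best_hit_identity"] == pytest.approx(1.0)
        assert df.loc[0, "abundance"] == 9
        assert not df.loc[0, "below_floor"]

    def test_empty_set_gives_empty_table(self, small_community):
        df = divergence_profile(
            set(), small_community["combined"], small_community["refs"]
        )
        assert df.empty

    def test_rows_match_best_hit_oracle(self, rng):
        refs = [
            Amplicon(id=f"r{i}", sequence=random_dna(rng, 50), origin=REFERENCE)
            for i in range(5)
        ]
        amps = [
            Amplicon(
                id=f"e{i}",
                sequence=mutate(refs[i % 5].sequence, int(rng.integers(1, 6)), rng),
                origin=ENVIRONMENTAL,
            )
            for i in range(10)
        ]
        df = divergence_profile({a.id for a in amps}, amps + refs, refs, floor=0.0)
        for row in df.itertuples():
            amp = next(a for a in amps if a.id == row.amplicon_id)
            expected = max(
                pairwise_identity(amp.sequence, r.sequence) for r in refs
            )
            assert row.best_hit_identity == pytest.approx(expected)


def test_summary_and_venn_serialization(tmp_path, small_community):
    combined = small_community["combined"]
    refs = small_community["refs"]
    results = small_community["results"]
    reports = {ap: novelty_report(r, combined, refs) for ap, r in results.items()}
    summary = summarize(results, reports, combined, refs, 0.97)
    sp = tmp_path / "summary.tsv"
    write_summary(summary, sp)
    text = sp.read_text()
    assert text.startswith("metric\tgreedy\tnetwork\tswarm\n")
    assert "misclassified_novel" in text
    vp = tmp_path / "venn.tsv"
    write_venn_counts(summary.venn, vp)
    assert len(vp.read_text().splitlines()) == 8  # header + 7 regions
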