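"""Dual-caller consensus matching and cross-individual merge clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcohort.consensus import (
    apply_cohort_filters,
    dual_caller_consensus,
    merge_cohort,
    mergeable,
    type_counts,
)
from svcohort.sv_io import ConsensusSV, MergedSV, SVCall


def _call(caller="A", sample="S1", chrom="1", start=1000, end=1500, svtype="DEL",
          support=5, length=None):
    if length is None:
        length = 100 if svtype == "INS" else end - start
    return SVCall(caller, sample, chrom, start, end, svtype, length, support)


def brute_force_clusters(records, min_overlap=25, ins_window=25):
    """Independent oracle: union-find over all O(n^2) mergeable pairs."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    for i, j in itertools.combinations(range(len(records)), 2):
        if mergeable(records[i], records[j], min_overlap, ins_window):
            graph.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(graph)}


class TestMergeable:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # overlap 100 > 25
            (_call(start=1000, end=1500), _call(start=1400, end=1900), True),
            # same interval, different type never merges
            (_call(svtype="DEL"), _call(svtype="DUP"), False),
            # overlap exactly 25: strict inequality, no merge
            (_call(start=1000, end=1030), _call(start=1005, end=1035), False),
            (_call(start=1000, end=1031), _call(start=1005, end=1036), True),
            # different chromosome
            (_call(chrom="1"), _call(chrom="2"), False),
            # insertions match by breakpoint distance <= 25
            (_call(svtype="INS", start=500, end=500), _call(svtype="INS", start=525, end=525), True),
            (_call(svtype="INS", start=500, end=500), _call(svtype="INS", start=526, end=526), False),
        ],
    )
    def test_merge_rule(self, a, b, expected):
        assert mergeable(a, b) is expected

    @given(
        s1=st.integers(1, 5000), l1=st.integers(26, 400),
        s2=st.integers(1, 5000), l2=st.integers(26, 400),
    )
    def test_symmetry(self, s1, l1, s2, l2):
        a = _call(start=s1, end=s1 + l1)
        b = _call(start=s2, end=s2 + l2)
        assert mergeable(a, b) == mergeable(b, a)


class TestDualCallerConsensus:
    def test_identical_call_takes_max_support(self):
        a = [_call(caller="A", support=5)]
        b = [_call(caller="B", support=7)]
        (cons,) = dual_caller_consensus(a, b)
        assert cons.support == 7
        assert {c.caller_id for c in cons.source_pair} == {"A", "B"}

    def test_single_caller_call_dropped(self):
        a = [_call(caller="A", start=1000, end=1500)]
        b = [_call(caller="B", start=9000, end=9500)]
        assert dual_caller_consensus(a, b) == []

    def test_support_filter_applies_per_caller_before_matching(self):
        a = [_call(caller="A", support=2)]
        b = [_call(caller="B", support=10)]
        assert dual_caller_consensus(a, b) == []
        assert len(dual_caller_consensus(a, b, min_support=2)) == 1

    def test_mixed_samples_fatal(self):
        with pytest.raises(ValueError, match="mixed sample"):
            dual_caller_consensus([_call(sample="S1")], [_call(caller="B", sample="S2")])

    def test_each_record_used_at_most_once(self):
        # two A-records both overlap one B-record; only the best pair forms
        a = [_call(caller="A", start=1000, end=1500), _call(caller="A", start=1100, end=1600)]
        b = [_call(caller="B", start=1080, end=1580)]
        cons = dual_caller_consensus(a, b)
        assert len(cons) == 1

    def test_jittered_pairs_match_exhaustive_assignment(self):
        """Greedy matching equals the exhaustive max-overlap assignment."""
        rng = np.random.default_rng(11)
        truth = [(1000, 1500), (1600, 2100), (2300, 2800), (3100, 3600)]
        a_calls, b_calls = [], []
        for s, e in truth:
            ja, jb = rng.integers(-10, 11, size=2)
            a_calls.append(_call(caller="A", start=s + ja, end=e + ja))
            b_calls.append(_call(caller="B", start=s + jb, end=e + jb))
        cons = dual_caller_consensus(a_calls, b_calls)
        assert len(cons) == 4
        # exhaustive: best total-overlap one-to-one assignment over all pairings
        def total(perm):
            return sum(
                min(a.end, b_calls[j].end) - max(a.start, b_calls[j].start)
                for a, j in zip(a_calls, perm)
            )
        best = max(itertools.permutations(range(4)), key=total)
        got = {
            (c.source_pair[0].start, c.source_pair[1].start) for c in cons
        }
        expected = {(a_calls[i].start, b_calls[j].start) for i, j in enumerate(best)}
        assert got == expected


class TestMergeCohort:
    def _cons(self, sample="S1", chrom="1", start=1000, end=1500, svtype="DEL", support=5):
        length = 100 if svtype == "INS" else end - start
        return ConsensusSV(sample, chrom, start, end, svtype, length, support)

    def test_identical_intervals_from_three_samples_collapse(self):
        records = [self._cons(sample=s) for s in ("S1", "S2", "S3")]
        (merged,) = merge_cohort(records)
        assert merged.carriers == {"S1", "S2", "S3"}
        assert merged.id == "sv_00001"

    def test_type_mismatch_never_clusters(self):
        records = [self._cons(svtype="DEL"), self._cons(sample="S2", svtype="INV")]
        assert len(merge_cohort(records)) == 2

    def test_transitive_chains_cluster_like_union_find(self):
        # two chains of three on one chromosome
        coords = [(1000, 1400), (1300, 1700), (1600, 2000), (5000, 5400), (5300, 5700), (5600, 6000)]
        records = [self._cons(sample=f"S{i}", start=s, end=e) for i, (s, e) in enumerate(coords)]
        merged = merge_cohort(records)
        assert len(merged) == 2
        assert {len(m.member_calls) for m in merged} == {3}

    def test_representative_is_highest_support_member(self):
        records = [
            self._cons(sample="S1", start=1000, end=1500, support=4),
            self._cons(sample="S2", start=1050, end=1550, support=9),
        ]
        (merged,) = merge_cohort(records)
        assert (merged.start, merged.end, merged.length) == (1050, 1550, 500)

    def test_matches_brute_force_union_find(self, random_consensus_calls):
        rng = np.random.default_rng(3)
        for _ in range(20):
            records = random_consensus_calls(rng, int(rng.integers(2, 50)))
            merged = merge_cohort(records)
            got = {
                frozenset((m.chrom, m.svtype, c.start, c.end, c.sample_id) for c in m.member_calls)
                for m in merged
            }
            oracle = brute_force_clusters(records)
            expected = {
                frozenset(
                    (records[i].chrom, records[i].svtype, records[i].start,
                     records[i].end, records[i].sample_id)
                    for i in cluster
                )
                for cluster in oracle
            }
            assert got == expected

    def test_order_invariance(self, random_consensus_calls):
        rng = np.random.default_rng(5)
        records = random_consensus_calls(rng, 40)
        base = merge_cohort(records)
        for seed in range(3):
            perm = list(records)
            np.random.default_rng(seed).shuffle(perm)
            again = merge_cohort(perm)
            assert [(m.chrom, m.start, m.end, m.svtype, m.carriers) for m in base] == [
                (m.chrom, m.start, m.end, m.svtype, m.carriers) for m in again
            ]

    def test_idempotence_on_representatives(self, random_consensus_calls):
        rng = np.random.default_rng(9)
        records = random_consensus_calls(rng, 40)
        merged = merge_cohort(records)
        reps = [
            ConsensusSV(sorted(m.carriers)[0], m.chrom, m.start, m.end, m.svtype, m.length, 5)
            for m in merged
        ]
        assert len(merge_cohort(reps)) == len(merged)

    def test_raising_min_overlap_never_merges_more(self, random_consensus_calls):
        rng = np.random.default_rng(13)
        records = random_consensus_calls(rng, 40)
        counts = [len(merge_cohort(records, min_overlap=o)) for o in (0, 25, 50, 100, 200)]
        assert counts == sorted(counts)

    def test_every_consensus_record_lands_in_exactly_one_cluster(self, random_consensus_calls):
        rng = np.random.default_rng(17)
        records = random_consensus_calls(rng, 45)
        merged = merge_cohort(records)
        assert sum(len(m.member_calls) for m in merged) == len(records)


class TestCohortFilters:
    def _sv(self, chrom="1", carriers=("a", "b")):
        return MergedSV(chrom=chrom, start=100, end=400, svtype="DEL", length=300,
                        carriers=frozenset(carriers))

    def test_retention_rules(self):
        svs = [
            self._sv(carriers=("a",)),            # singleton: removed
            self._sv(chrom="Y", carriers=("a", "b", "c", "d", "e")),  # Y: removed
            self._sv(chrom="18", carriers=("a", "b")),  # kept
        ]
        kept = apply_cohort_filters(svs)
        assert len(kept) == 1 and kept[0].chrom == "18"

    def test_thresholds_configurable(self):
        svs = [self._sv(carriers=("a",)), self._sv(chrom="Y")]
        assert len(apply_cohort_filters(svs, min_individuals=1, drop_chroms=())) == 2


class TestTypeCounts:
    def test_cohort_scale_example(self):
        class R:  # minimal record with an svtype
            def __init__(self, t):
                self.svtype = t

        svs = [R("DEL")] * 3 + [R("DUP")] * 2 + [R("INS")] + [R("INV")]
        counts = type_counts(svs)
        assert counts.as_dict() == {"DEL": 3, "DUP": 2, "INS": 1, "INV": 1, "total": 7}

    def test_empty(self):
        assert type_counts([]).total == 0
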