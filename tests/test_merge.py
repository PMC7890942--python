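"""Consensus-merge rules: reciprocal overlap, matching, clustering,
median resolution, and size filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svsweep import (
    ConsensusSV,
    MergeParams,
    SVCall,
    apply_size_filters,
    cluster_calls,
    matches,
    merge_callsets,
    reciprocal_overlap,
    resolve_consensus,
)
from svsweep.merge import CallCluster


def make_del(start, end, caller="c1", chrom="chr1", svtype="DEL"):
    return SVCall(chrom, start, end, svtype, 0, caller)


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        assert reciprocal_overlap(make_del(1001, 2000), make_del(1001, 2000)) == 1.0

    def test_disjoint_intervals(self):
        assert reciprocal_overlap(make_del(1, 100), make_del(201, 300)) == 0.0

    def test_partial_overlap_arithmetic(self):
        # len 1000 vs len 900, shared 800 bp -> min(0.800, 0.888...) = 0.800
        ro = reciprocal_overlap(make_del(1001, 2000), make_del(1201, 2100))
        assert ro == pytest.approx(0.800, abs=1e-12)
        assert ro > 0.75

    def test_cross_chrom_and_cross_type_are_zero(self):
        assert reciprocal_overlap(make_del(1, 100), make_del(1, 100, chrom="chr2")) == 0.0
        assert reciprocal_overlap(make_del(1, 100), make_del(1, 100, svtype="DUP")) == 0.0


@given(
    st.integers(1, 10_000), st.integers(0, 5_000),
    st.integers(1, 10_000), st.integers(0, 5_000),
)
def test_reciprocal_overlap_symmetric_and_bounded(s1, l1, s2, l2):
    a, b = make_del(s1, s1 + l1), make_del(s2, s2 + l2)
    ro_ab, ro_ba = reciprocal_overlap(a, b), reciprocal_overlap(b, a)
    assert ro_ab == ro_ba
    assert 0.0 <= ro_ab <= 1.0


class TestMatches:
    def test_exact_75_percent_is_not_a_match(self):
        # RO exactly 0.75: the rule is strictly greater than
        a, b = make_del(1, 1000), make_del(251, 1250)
        assert reciprocal_overlap(a, b) == pytest.approx(0.75)
        assert not matches(a, b)

    def test_ins_window_and_length_ratio(self):
        a = SVCall("chr1", 5000, 5000, "INS", 300, "c1")
        b = SVCall("chr1", 5050, 5050, "INS", 280, "c2")
        assert matches(a, b)  # distance 50 <= 100; ratio 0.933 >= 0.75
        far = SVCall("chr1", 5101, 5101, "INS", 300, "c2")
        assert not matches(a, far)
        short = SVCall("chr1", 5050, 5050, "INS", 200, "c2")
        assert not matches(a, short)

    def test_type_partition(self):
        assert not matches(make_del(100, 500), make_del(100, 500, svtype="DUP"))

    def test_tra_dual_breakend_proximity(self):
        a = SVCall("chr1", 100, 100, "TRA", 0, "c1", mate_chrom="chr2", mate_pos=5000)
        b = SVCall("chr1", 150, 150, "TRA", 0, "c2", mate_chrom="chr2", mate_pos=5080)
        c = SVCall("chr1", 150, 150, "TRA", 0, "c2", mate_chrom="chr3", mate_pos=5080)
        d = SVCall("chr1", 150, 150, "TRA", 0, "c2", mate_chrom="chr2", mate_pos=5500)
        assert matches(a, b)
        assert not matches(a, c)
        assert not matches(a, d)


def _brute_force_partition(calls, params=MergeParams()):
    """Independent oracle: exhaustive pairwise match matrix + connected
    components (networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if matches(calls[i], calls[j], params):
                g.add_edge(i, j)
    return _canonical(
        [[calls[i] for i in comp] for comp in nx.connected_components(g)]
    )


def _canonical(clusters):
    def key(c):
        return (c.chrom, c.start, c.end, c.svtype, c.svlen, c.caller,
                c.mate_chrom or "", c.mate_pos or 0)

    return sorted(sorted(key(c) for c in cluster) for cluster in clusters)


def _random_instance(rng):
    n = int(rng.integers(1, 13))
    calls = []
    for _ in range(n):
        svtype = ["DEL", "INS", "INV", "DUP", "TRA"][int(rng.integers(5))]
        caller = f"c{int(rng.integers(3)) + 1}"
        chrom = f"chr{int(rng.integers(2)) + 1}"
        start = int(rng.integers(1, 3000))
        if svtype == "INS":
            calls.append(SVCall(chrom, start, start, "INS", int(rng.integers(50, 500)), caller))
        elif svtype == "TRA":
            calls.append(SVCall(chrom, start, start, "TRA", 0, caller,
                                mate_chrom=f"chr{int(rng.integers(2)) + 1}",
                                mate_pos=int(rng.integers(1, 3000))))
        else:
            calls.append(SVCall(chrom, start, start + int(rng.integers(0, 1500)), svtype, 0, caller))
    return calls


class TestClusterCalls:
    def test_three_identical_calls_one_cluster(self):
        calls = [make_del(100, 600, c) for c in ("c1", "c2", "c3")]
        (cluster,) = cluster_calls(calls)
        assert cluster.support == 3

    def test_chaining_is_single_linkage(self):
        # A-B and B-C match but A-C does not: one cluster of three
        a, b, c = make_del(1, 1000, "c1"), make_del(150, 1150, "c2"), make_del(300, 1300, "c3")
        assert matches(a, b) and matches(b, c) and not matches(a, c)
        (cluster,) = cluster_calls([a, b, c])
        assert len(cluster.members) == 3

    def test_type_partition_gives_singletons(self):
        clusters = cluster_calls([make_del(100, 500), make_del(100, 500, svtype="INV")])
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_matches_random_instances_against_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            calls = _random_instance(rng)
            assert _canonical(
                [c.members for c in cluster_calls(calls)]
            ) == _brute_force_partition(calls)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(99)
        calls = _random_instance(rng)
        base = _canonical([c.members for c in cluster_calls(calls)])
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            assert _canonical([c.members for c in cluster_calls(perm)]) == base


class TestResolveConsensus:
    def test_odd_count_median(self):
        cluster = CallCluster([
            make_del(100, 200, "c1"), make_del(110, 220, "c2"), make_del(120, 240, "c3"),
        ])
        sv = resolve_consensus(cluster)
        assert (sv.start, sv.end) == (110, 220)
        assert sv.callers == ("c1", "c2", "c3")

    def test_even_count_median_floors(self):
        cluster = CallCluster([make_del(100, 200, "c1"), make_del(111, 220, "c2")])
        sv = resolve_consensus(cluster)
        assert sv.start == 105  # floor of 105.5

    def test_single_caller_duplicates_do_not_reach_support(self):
        cluster = CallCluster([make_del(100, 200, "c1"), make_del(102, 202, "c1")])
        assert resolve_consensus(cluster) is None

    def test_same_caller_members_count_once_but_shift_the_median(self):
        cluster = CallCluster([
            make_del(100, 200, "c1"), make_del(100, 200, "c1"), make_del(130, 230, "c2"),
        ])
        sv = resolve_consensus(cluster)
        assert sv.callers == ("c1", "c2")
        assert sv.start == 100  # median of {100, 100, 130}

    @given(st.lists(st.tuples(st.integers(1, 10_000), st.integers(0, 2_000)), min_size=2, max_size=9))
    def test_consensus_breakpoints_inside_member_envelope(self, coords):
        members = [
            make_del(s, s + l, caller=f"c{i % 3}") for i, (s, l) in enumerate(coords)
        ]
        sv = resolve_consensus(CallCluster(members))
        if sv is None:
            assert len({m.caller for m in members}) < 2
        else:
            assert min(m.start for m in members) <= sv.start <= max(m.start for m in members)
            assert min(m.end for m in members) <= sv.end <= max(m.end for m in members)


class TestSizeFilters:
    def _cons(self, svtype, svlen):
        if svtype == "TRA":
            return ConsensusSV("chr1", 100, 100, "TRA", 0, ("a", "b"),
                               mate_chrom="chr2", mate_pos=5)
        if svtype == "INS":
            return ConsensusSV("chr1", 100, 100, "INS", svlen, ("a", "b"))
        return ConsensusSV("chr1", 100, 100 + svlen - 1, svtype, svlen, ("a", "b"))

    def test_boundaries(self):
        kept = apply_size_filters([
            self._cons("DEL", 40),          # removed: <= 50 bp
            self._cons("DEL", 50),          # removed: boundary, rule is > 50
            self._cons("DEL", 51),          # kept
            self._cons("DEL", 10_000_000),  # removed: rule is < 10 Mb
            self._cons("INS", 87),          # kept
            self._cons("INV", 11_000_000),  # removed
            self._cons("DUP", 4_668),       # kept
            self._cons("TRA", 0),           # kept unconditionally
        ])
        assert [(sv.svtype, sv.svlen) for sv in kept] == [
            ("DEL", 51), ("INS", 87), ("DUP", 4_668), ("TRA", 0),
        ]


class TestMergeCallsets:
    def test_fewer_than_two_callers_rejected(self):
        with pytest.raises(ValueError, match=">=2 callers"):
            merge_callsets({"only": [make_del(1, 100)]})

    def test_two_agreeing_callers_give_one_consensus(self):
        out = merge_callsets({
            "c1": [make_del(100, 599, "c1")],
            "c2": [make_del(100, 599, "c2")],
        })
        assert len(out) == 1 and out[0].n_callers == 2

    def test_caller_private_calls_are_dropped(self):
        out = merge_callsets({
            "c1": [make_del(100, 599, "c1")],
            "c2": [make_del(5_000, 5_499, "c2")],
        })
        assert out == []

    def test_noise_free_merge_recovers_truth(self, noiseless_truth, noiseless_callsets):
        merged = merge_callsets(noiseless_callsets)
        truth_kept = apply_size_filters(
            ConsensusSV(sv.chrom, sv.start, sv.end, sv.svtype, sv.svlen, ("x", "y"),
                        mate_chrom=sv.mate_chrom, mate_pos=sv.mate_pos)
            for sv in noiseless_truth.svs
        )
        assert [
            (sv.chrom, sv.start, sv.end, sv.svtype, sv.svlen) for sv in merged
        ] == [
            (sv.chrom, sv.start, sv.end, sv.svtype, sv.svlen) for sv in truth_kept
        ]
        assert all(sv.n_callers == 3 for sv in merged)
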