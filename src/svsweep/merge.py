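"""Multi-caller consensus merging.

The merge follows three consensus principles: spanning calls of the same
type belong to the same locus when they show >75% reciprocal overlap
(translocations are exempt and matched by breakend proximity instead); a
locus is retained only when two or more distinct callers detected it; and
the merged breakpoints are the medians of the member calls' start and end
positions. Size filters are applied after support resolution: deletions and
insertions must be >50 bp and <10 Mb, inversions and duplications <10 Mb;
translocations are kept unconditionally.

Clustering is single-linkage: within each (chromosome, type) partition the
clusters are the connected components of the pairwise match graph. Chaining
across a long run of partially overlapping calls is therefore possible but
bounded by the per-type partition and the strict >0.75 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import SPANNING_TYPES, ConsensusSV, SVCall


@dataclass(frozen=True)
class MergeParams:
    """Tunable thresholds for call matching.

    ro_threshold: reciprocal-overlap fraction that must be *exceeded* for
        two spanning calls to match (strict >, so 0.75 exactly fails).
    ins_window: maximum breakpoint distance in bp for INS (and TRA breakend)
        matching.
    ins_len_ratio: minimum min/max insertion-length ratio for INS matching.
    """

    ro_threshold: float = 0.75
    ins_window: int = 100
    ins_len_ratio: float = 0.75


@dataclass
class CallCluster:
    """Calls of one (chromosome, type) partition linked by pairwise matches."""

    members: list[SVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        chroms = {m.chrom for m in self.members}
        types = {m.svtype for m in self.members}
        if len(chroms) > 1 or len(types) > 1:
            raise ValueError("cluster members must share chrom and svtype")

    @property
    def callers(self) -> set[str]:
        return {m.caller for m in self.members}

    @property
    def support(self) -> int:
        return len(self.callers)


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """min(overlap/len(a), overlap/len(b)) for two 1-based inclusive spans.

    Defined as 0 for disjoint intervals and for calls on different
    chromosomes or of different types (never an error).
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return min(overlap / a.span, overlap / b.span)


def matches(a: SVCall, b: SVCall, params: MergeParams = MergeParams()) -> bool:
    """Do two same-type calls describe the same locus?

    DEL/INV/DUP: reciprocal overlap strictly above ``ro_threshold``.
    INS: start positions within ``ins_window`` bp and inserted-length ratio
    (min/max) >= ``ins_len_ratio``. TRA: both breakends within
    ``ins_window`` bp on the same ordered chromosome pair.
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if a.svtype in SPANNING_TYPES:
        return reciprocal_overlap(a, b) > params.ro_threshold
    if a.svtype == "INS":
        if abs(a.start - b.start) > params.ins_window:
            return False
        lo, hi = sorted((a.svlen, b.svlen))
        return lo / hi >= params.ins_len_ratio
    # TRA
    return (
        a.mate_chrom == b.mate_chrom
        and abs(a.start - b.start) <= params.ins_window
        and abs(a.mate_pos - b.mate_pos) <= params.ins_window
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_calls(
    calls: Sequence[SVCall], params: MergeParams = MergeParams()
) -> list[CallCluster]:
    """Single-linkage clusters (connected components of the match graph),
    computed within (chrom, svtype) partitions.

    Every input call lands in exactly one cluster; the result is invariant
    under permutation of the input order.
    """
    partitions: dict[tuple, list[SVCall]] = {}
    for call in calls:
        key: tuple = (call.chrom, call.svtype)
        if call.svtype == "TRA":
            key = (call.chrom, call.svtype, call.mate_chrom)
        partitions.setdefault(key, []).append(call)

    clusters: list[CallCluster] = []
    for key in sorted(partitions, key=lambda k: tuple(map(str, k))):
        group = sorted(
            partitions[key], key=lambda c: (c.start, c.end, c.svlen, c.caller)
        )
        uf = _UnionFind(len(group))
        svtype = key[1]
        # sweep: a match needs overlapping spans (spanning types) or starts
        # within ins_window (INS/TRA), so only a bounded look-ahead is needed
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if svtype in SPANNING_TYPES:
                    if b.start > a.end:
                        break
                elif b.start - a.start > params.ins_window:
                    break
                if matches(a, b, params):
                    uf.union(i, j)
        comps: dict[int, list[SVCall]] = {}
        for i, call in enumerate(group):
            comps.setdefault(uf.find(i), []).append(call)
        for root in sorted(comps):
            clusters.append(CallCluster(comps[root]))
    return clusters


def _median_int(values: Sequence[int]) -> int:
    """Median keeping integer coordinates: floor of the midpoint mean for
    even counts."""
    vs = sorted(values)
    n = len(vs)
    if n % 2:
        return vs[n // 2]
    return (vs[n // 2 - 1] + vs[n // 2]) // 2


def resolve_consensus(cluster: CallCluster) -> Optional[ConsensusSV]:
    """Collapse a cluster to a consensus site, or ``None`` when fewer than
    two distinct callers support it.

    All member calls contribute to the medians (duplicates from one caller
    included) but each caller counts once toward support.
    """
    if cluster.support < 2:
        return None
    members = tuple(
        sorted(cluster.members, key=lambda c: (c.start, c.end, c.svlen, c.caller))
    )
    first = members[0]
    start = _median_int([m.start for m in members])
    if first.svtype == "TRA":
        return ConsensusSV(
            first.chrom, start, start, "TRA", 0, tuple(cluster.callers),
            members=members, mate_chrom=first.mate_chrom,
            mate_pos=_median_int([m.mate_pos for m in members]),
        )
    if first.svtype == "INS":
        return ConsensusSV(
            first.chrom, start, start, "INS",
            _median_int([m.svlen for m in members]),
            tuple(cluster.callers), members=members,
        )
    end = _median_int([m.end for m in members])
    return ConsensusSV(
        first.chrom, start, end, first.svtype, end - start + 1,
        tuple(cluster.callers), members=members,
    )


def apply_size_filters(svs: Iterable[ConsensusSV]) -> list[ConsensusSV]:
    """Type-specific size filters: DEL/INS kept when 50 bp < svlen < 10 Mb,
    INV/DUP when svlen < 10 Mb, TRA kept unconditionally."""
    out = []
    for sv in svs:
        if sv.svtype in ("DEL", "INS"):
            if 50 < sv.svlen < 10_000_000:
                out.append(sv)
        elif sv.svtype in ("INV", "DUP"):
            if sv.svlen < 10_000_000:
                out.append(sv)
        else:
            out.append(sv)
    return out


def merge_callsets(
    callsets: Mapping[str, Sequence[SVCall]],
    params: MergeParams = MergeParams(),
) -> list[ConsensusSV]:
    """Full merge: cluster across callers, resolve >=2-caller consensus
    sites, apply size filters, and sort by (chrom, start)."""
    if len(callsets) < 2:
        raise ValueError(f"merging needs >=2 callers, got {len(callsets)}")
    calls = [call for caller_calls in callsets.values() for call in caller_calls]
    clusters = cluster_calls(calls, params)
    consensus = [sv for sv in map(resolve_consensus, clusters) if sv is not None]
    consensus = apply_size_filters(consensus)
    consensus.sort(key=lambda sv: (sv.chrom, sv.start, sv.end, sv.svtype))
    return consensus
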