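"""Within-sample filtering and two-caller consensus.

A raw call survives filtering when it has paired-end support from at least
three read pairs and does not sit on an excluded chromosome (Y by default,
to remove the gender effect in a mixed-sex cohort).  Calls from the two
callers are then pooled and clustered by single linkage under the merge
rule: same chromosome, same SV type, and >= 25 bp of overlap (for
zero-width insertion breakpoints, a 25 bp breakpoint-distance window
substitutes for bp overlap).  Only clusters containing every required
caller survive; each becomes one consensus SV spanning the union of its
members.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sv_io import SvCall, normalize_chrom, sv_sort_key

DEFAULT_MIN_OVERLAP = 25
DEFAULT_INS_WINDOW = 25
DEFAULT_MIN_SUPPORT = 3
DEFAULT_EXCLUDED_CHROMS = frozenset({"y"})


@dataclass
class FilterResult:
    kept: list[SvCall]
    removed: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.kept)

    def __len__(self):
        return len(self.kept)


def filter_calls(calls: Iterable[SvCall], min_support: int = DEFAULT_MIN_SUPPORT,
                 excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS) -> FilterResult:
    """Drop calls below the support threshold or on excluded chromosomes.

    Each removal is tallied under its reason; a call failing both tests is
    counted once, under the support reason (checked first).
    """
    excluded = {normalize_chrom(c) for c in excluded_chroms}
    result = FilterResult(kept=[])
    for call in calls:
        if call.support < min_support:
            result.removed["low_support"] += 1
        elif normalize_chrom(call.chrom) in excluded:
            result.removed["excluded_chrom"] += 1
        else:
            result.kept.append(call)
    return result


def overlap_length(a, b) -> int:
    """Basepairs shared by two calls; 0 on different chromosomes."""
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def mergeable(a, b, min_overlap: int = DEFAULT_MIN_OVERLAP,
              ins_window: int = DEFAULT_INS_WINDOW) -> bool:
    """True when two calls satisfy the merge rule (same chrom, same type,
    >= ``min_overlap`` bp shared; insertions within ``ins_window`` bp)."""
    if a.sv_type != b.sv_type:
        return False
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return False
    if a.sv_type == "INS":
        return abs(a.start - b.start) <= ins_window
    return overlap_length(a, b) >= min_overlap


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_calls(calls: Sequence, min_overlap: int = DEFAULT_MIN_OVERLAP,
                  ins_window: int = DEFAULT_INS_WINDOW) -> list[list]:
    """Single-linkage clustering of calls under the merge rule.

    Calls are partitioned by (chromosome, type) and swept in start order;
    within a partition each call is unioned with every still-active earlier
    call it can merge with, which is exactly the transitive closure of the
    pairwise rule.  Output is independent of input order: clusters are
    returned sorted by their leftmost member, members in genomic order.
    """
    calls = list(calls)
    uf = _UnionFind(len(calls))
    partitions: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        partitions[(normalize_chrom(c.chrom), c.sv_type)].append(i)

    for (_, sv_type), idxs in partitions.items():
        idxs.sort(key=lambda i: (calls[i].start, calls[i].end))
        if sv_type == "INS":
            # points on a line: single linkage = chain adjacent breakpoints
            for prev, cur in zip(idxs, idxs[1:]):
                if calls[cur].start - calls[prev].start <= ins_window:
                    uf.union(prev, cur)
        else:
            active: list[int] = []
            for i in idxs:
                start_i, end_i = calls[i].start, calls[i].end
                # an active call j can never reach min_overlap once
                # end_j < start_i + min_overlap (starts only increase)
                active = [j for j in active
                          if calls[j].end >= start_i + min_overlap]
                for j in active:
                    if min(calls[j].end, end_i) - start_i >= min_overlap:
                        uf.union(j, i)
                active.append(i)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(calls)):
        groups[uf.find(i)].append(i)
    clusters = [sorted((calls[i] for i in members), key=sv_sort_key)
                for members in groups.values()]
    clusters.sort(key=lambda cl: sv_sort_key(cl[0]))
    return clusters


@dataclass(frozen=True)
class ConsensusSv:
    """One within-sample SV supported by every required caller.

    The span is the union of member calls (min start, max end); for
    insertions the breakpoint is the leftmost member breakpoint and the
    length the maximum member length.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    callers_present: frozenset[str]
    member_calls: tuple[SvCall, ...]
    truth_ids: frozenset[str] = frozenset()

    @property
    def support(self) -> int:
        return max(c.support for c in self.member_calls)


def _consensus_from_cluster(sample_id: str, cluster: Sequence[SvCall]) -> ConsensusSv:
    sv_type = cluster[0].sv_type
    chrom = normalize_chrom(cluster[0].chrom)
    if sv_type == "INS":
        start = end = min(c.start for c in cluster)
        length = max(c.length for c in cluster)
    else:
        start = min(c.start for c in cluster)
        end = max(c.end for c in cluster)
        length = end - start
    return ConsensusSv(
        sample_id=sample_id, chrom=chrom, start=start, end=end,
        sv_type=sv_type, length=length,
        callers_present=frozenset(c.caller_id for c in cluster),
        member_calls=tuple(cluster),
        truth_ids=frozenset(c.truth_id for c in cluster if c.truth_id),
    )


def caller_consensus(calls_by_caller: Mapping[str, Sequence[SvCall]],
                     required_callers: Iterable[str],
                     min_overlap: int = DEFAULT_MIN_OVERLAP,
                     ins_window: int = DEFAULT_INS_WINDOW) -> list[ConsensusSv]:
    """Intersect the callers of one sample: keep clusters seen by all.

    Raises if a required caller has no entry in ``calls_by_caller`` — that
    is a configuration error, not an empty result.
    """
    required = set(required_callers)
    if len(required) < 2:
        raise ValueError("consensus needs at least two required callers")
    missing = required - set(calls_by_caller)
    if missing:
        raise ValueError(f"required caller(s) absent from input: {sorted(missing)}")

    pooled: list[SvCall] = []
    sample_ids = set()
    for caller_id, calls in calls_by_caller.items():
        for c in calls:
            pooled.append(c)
            sample_ids.add(c.sample_id)
    if len(sample_ids) > 1:
        raise ValueError(f"caller_consensus is per-sample; got {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    out = []
    for cluster in cluster_calls(pooled, min_overlap=min_overlap,
                                 ins_window=ins_window):
        present = {c.caller_id for c in cluster}
        if required.issubset(present):
            out.append(_consensus_from_cluster(sample_id, cluster))
    return out
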