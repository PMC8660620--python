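"""Dual-caller consensus and cross-individual merging into a non-redundant call set.

Two call sets per individual (one per calling program) are first reduced to a
per-individual consensus: a call is kept only when it has read-pair support of
at least ``min_support`` in *both* callers and the two callers' records match
(same type, same chromosome, interval overlap strictly greater than
``min_overlap`` bp; insertion breakpoints within ``ins_window`` bp).

Consensus records from all individuals are then clustered by single-linkage
under the same matching rule; each cluster becomes one cohort-level record
whose representative interval is the highest-support member and whose carrier
set is the distinct samples in the cluster. Finally the cohort filters retain
records seen in at least ``min_individuals`` individuals and drop the sex
chromosome Y.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Sequence

from .sv_io import ConsensusSV, MergedSV, SVCall, SVTypeCounts, chrom_sort_key

__all__ = [
    "mergeable",
    "overlap_score",
    "dual_caller_consensus",
    "merge_cohort",
    "apply_cohort_filters",
    "type_counts",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 25
DEFAULT_INS_WINDOW = 25
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_INDIVIDUALS = 2
DEFAULT_DROP_CHROMS = frozenset({"Y"})


def overlap_score(a, b) -> int:
    """Matching score for two same-type, same-chromosome records.

    For interval types this is the overlap length ``min(end) - max(start)``
    (possibly negative when disjoint); for insertions it is minus the
    breakpoint distance, so that closer breakpoints score higher.
    """
    if a.svtype == "INS":
        return -abs(a.start - b.start)
    return min(a.end, b.end) - max(a.start, b.start)


def mergeable(
    a,
    b,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    ins_window: int = DEFAULT_INS_WINDOW,
) -> bool:
    """True iff two records describe the same variant under the merge rule.

    Same type and chromosome are required. Interval types must overlap by
    strictly more than ``min_overlap`` bp (an overlap of exactly
    ``min_overlap`` does not merge). Insertions, which have zero-width
    intervals, match when their breakpoints lie within ``ins_window`` bp.
    """
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype == "INS":
        return abs(a.start - b.start) <= ins_window
    return overlap_score(a, b) > min_overlap


def _interval_key(rec):
    return (rec.start, rec.length)


def dual_caller_consensus(
    calls_a: Sequence[SVCall],
    calls_b: Sequence[SVCall],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    ins_window: int = DEFAULT_INS_WINDOW,
) -> list[ConsensusSV]:
    """Match one individual's two call sets into consensus records.

    Each caller record passing the per-record support filter participates in
    at most one consensus. Matching is greedy on the best overlap score, ties
    broken by leftmost position then smallest length; the representative
    interval comes from the member with the higher support (ties favour
    ``calls_a``).
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"mixed sample_ids in consensus input: {sorted(samples)}")
    a_pass = [c for c in calls_a if c.support >= min_support]
    b_pass = [c for c in calls_b if c.support >= min_support]

    by_bucket: dict[tuple[str, str], list[tuple[int, SVCall]]] = defaultdict(list)
    for j, cb in enumerate(b_pass):
        by_bucket[(cb.chrom, cb.svtype)].append((j, cb))

    candidates: list[tuple[int, int, int, int, int, int]] = []
    for i, ca in enumerate(a_pass):
        for j, cb in by_bucket.get((ca.chrom, ca.svtype), ()):
            if mergeable(ca, cb, min_overlap, ins_window):
                score = overlap_score(ca, cb)
                candidates.append(
                    (-score, min(ca.start, cb.start), min(ca.length, cb.length), i, j, score)
                )
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[ConsensusSV] = []
    for _, _, _, i, j, _score in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ca, cb = a_pass[i], b_pass[j]
        rep = cb if cb.support > ca.support else ca
        out.append(
            ConsensusSV(
                sample_id=rep.sample_id,
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                svtype=rep.svtype,
                length=rep.length,
                support=max(ca.support, cb.support),
                source_pair=(ca, cb),
            )
        )
    out.sort(key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end, c.svtype))
    return out


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def merge_cohort(
    consensus: Sequence[ConsensusSV],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    ins_window: int = DEFAULT_INS_WINDOW,
) -> list[MergedSV]:
    """Single-linkage clustering of consensus records across individuals.

    Transitive closure of the pairwise :func:`mergeable` relation within each
    (chromosome, type) bucket; each cluster becomes one :class:`MergedSV`. The
    representative interval is the member with the highest support (ties:
    leftmost, then smallest length), carriers are the distinct samples of the
    cluster, and output order/IDs follow (chrom, start). The result is
    invariant to input order.
    """
    # canonical order makes cluster membership independent of caller order
    records = sorted(
        consensus,
        key=lambda c: (chrom_sort_key(c.chrom), c.svtype, c.start, c.end, c.sample_id, -c.support),
    )
    dsu = _DisjointSet(len(records))
    by_bucket: dict[tuple[str, str], list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        by_bucket[(rec.chrom, rec.svtype)].append(idx)

    for (chrom, svtype), idxs in by_bucket.items():
        if svtype == "INS":
            # sorted by start; a sliding window over the breakpoint distance
            prev: list[int] = []
            for i in idxs:
                start_i = records[i].start
                prev = [j for j in prev if start_i - records[j].start <= ins_window]
                for j in prev:
                    dsu.union(i, j)
                prev.append(i)
        else:
            # active list: earlier records whose end still reaches far enough
            active: list[int] = []
            for i in idxs:
                s_i, e_i = records[i].start, records[i].end
                active = [j for j in active if records[j].end > s_i + min_overlap]
                for j in active:
                    if min(records[j].end, e_i) - max(records[j].start, s_i) > min_overlap:
                        dsu.union(i, j)
                active.append(i)

    clusters: dict[int, list[ConsensusSV]] = defaultdict(list)
    for idx, rec in enumerate(records):
        clusters[dsu.find(idx)].append(rec)

    merged: list[MergedSV] = []
    for members in clusters.values():
        rep = min(members, key=lambda m: (-m.support, m.start, m.length, m.sample_id))
        merged.append(
            MergedSV(
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                svtype=rep.svtype,
                length=rep.length,
                carriers=frozenset(m.sample_id for m in members),
                member_calls=tuple(members),
            )
        )
    merged.sort(key=lambda m: (chrom_sort_key(m.chrom), m.start, m.end, m.svtype))
    return [replace(sv, id=f"sv_{i:05d}") for i, sv in enumerate(merged, start=1)]


def apply_cohort_filters(
    svs: Sequence[MergedSV],
    min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
    drop_chroms: Iterable[str] = DEFAULT_DROP_CHROMS,
) -> list[MergedSV]:
    """Cohort retention filters: recurrence across individuals and chromosome drop.

    Keeps records carried by at least ``min_individuals`` individuals whose
    chromosome is not in ``drop_chroms`` (default: Y, to remove the influence
    of sex on detection). Per-rule removal counts are logged.
    """
    drop = set(drop_chroms)
    kept: list[MergedSV] = []
    n_few = n_chrom = 0
    for sv in svs:
        if sv.chrom in drop:
            n_chrom += 1
        elif sv.n_carriers < min_individuals:
            n_few += 1
        else:
            kept.append(sv)
    log.info(
        "cohort filters: %d in, %d kept, %d removed on chromosome filter (%s), "
        "%d removed with < %d carriers",
        len(svs), len(kept), n_chrom, ",".join(sorted(drop)) or "-", n_few, min_individuals,
    )
    return kept


def type_counts(svs: Sequence) -> SVTypeCounts:
    """Tally records per SV type; ``.total`` is their sum."""
    counts = {t: 0 for t in ("DEL", "DUP", "INS", "INV")}
    for sv in svs:
        counts[sv.svtype] += 1
    return SVTypeCounts(**counts)
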