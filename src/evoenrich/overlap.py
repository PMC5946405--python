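"""Marker sharing between annotation-derived SNP sets.

Different evolutionary annotations (methylation-change regions, selective
sweep markers, accelerated regions) should tag largely different markers;
this module quantifies that with pairwise overlaps and a full Venn
partition over the binned SNP-id sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Set, Tuple

from .model import AnnotationSet

MAX_SETS = 5


@dataclass
class OverlapReport:
    set_names: list
    set_sizes: Dict[str, int]
    pairwise: Dict[Tuple[str, str], Tuple[int, float, float]]  # shared, %of a, %of b
    partition: Dict[Tuple[str, ...], int]  # Venn cell (sorted member names) -> count
    union_size: int


def marker_overlap(sets: Dict[str, Set[str]]) -> OverlapReport:
    """Exact set arithmetic over 2..5 named SNP-id sets.

    ``pairwise[(a, b)]`` reports the shared count and the percentages of
    each set it represents; ``partition`` holds every non-empty Venn cell,
    keyed by the sorted tuple of sets the cell belongs to.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("marker_overlap needs at least two sets")
    if len(names) > MAX_SETS:
        raise ValueError(f"marker_overlap supports at most {MAX_SETS} sets")
    for name, s in sets.items():
        if not s:
            raise ValueError(f"set {name!r} is empty")

    sizes = {n: len(sets[n]) for n in names}
    pairwise = {}
    for a, b in combinations(names, 2):
        shared = len(sets[a] & sets[b])
        pairwise[(a, b)] = (shared, 100.0 * shared / sizes[a], 100.0 * shared / sizes[b])

    union = set().union(*sets.values())
    partition: Dict[Tuple[str, ...], int] = {}
    for marker in union:
        cell = tuple(sorted(n for n in names if marker in sets[n]))
        partition[cell] = partition.get(cell, 0) + 1
    return OverlapReport(
        set_names=names,
        set_sizes=sizes,
        pairwise=pairwise,
        partition=partition,
        union_size=len(union),
    )


def interval_bp_jaccard(a: AnnotationSet, b: AnnotationSet) -> float:
    """Base-pair Jaccard index between two interval annotations (supplementary)."""
    if a.kind != "interval" or b.kind != "interval":
        raise TypeError("interval_bp_jaccard requires interval annotations")

    def merged(ann):
        by_chrom: Dict[str, list] = {}
        for iv in ann.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out = {}
        for c, spans in by_chrom.items():
            spans.sort()
            acc = [list(spans[0])]
            for s, e in spans[1:]:
                if s <= acc[-1][1]:
                    acc[-1][1] = max(acc[-1][1], e)
                else:
                    acc.append([s, e])
            out[c] = acc
        return out

    ma, mb = merged(a), merged(b)
    inter = 0
    for c in set(ma) & set(mb):
        for s1, e1 in ma[c]:
            for s2, e2 in mb[c]:
                inter += max(0, min(e1, e2) - max(s1, s2))
    total = sum(e - s for m in (ma, mb) for spans in m.values() for s, e in spans)
    union = total - inter
    return inter / union if union else 1.0
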