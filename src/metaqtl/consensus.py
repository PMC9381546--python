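"""Coordinate transfer between genetic maps via shared anchor markers.

A study map is expressed in reference ("consensus") coordinates by
piecewise-linear interpolation between markers present on both maps.
Anchors whose order disagrees between the maps are resolved by keeping a
longest order-consistent subsequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .errors import DegenerateIntervalError, InsufficientAnchorsError
from .types import GeneticMap


@dataclass
class AnchorSet:
    """Shared-marker correspondences for one chromosome.

    ``pairs`` holds (source_cM, consensus_cM), sorted by source position.
    A filtered AnchorSet additionally has strictly increasing coordinates on
    both sides, which is what projection requires.
    """

    chromosome: int
    pairs: list[tuple[float, float]]
    markers: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def shared_anchors(
    source: GeneticMap, reference: GeneticMap, chromosome: int
) -> AnchorSet:
    """Raw anchor pairs: markers present on both maps, ordered by source cM."""
    ref_pos = {m: p for m, p in reference.markers_on(chromosome)}
    pairs: list[tuple[float, float, str]] = []
    for marker, pos in source.markers_on(chromosome):
        if marker in ref_pos:
            pairs.append((pos, ref_pos[marker], marker))
    if len(pairs) < 2:
        raise InsufficientAnchorsError(
            f"maps {source.map_id!r} and {reference.map_id!r} share "
            f"{len(pairs)} marker(s) on chromosome {chromosome}; need >= 2"
        )
    pairs.sort(key=lambda t: (t[0], t[1]))
    return AnchorSet(
        chromosome=chromosome,
        pairs=[(s, c) for s, c, _ in pairs],
        markers=[m for _, _, m in pairs],
    )


def monotone_filter(anchors: AnchorSet) -> AnchorSet:
    """Keep a longest subsequence of anchors that is strictly increasing in
    both source and consensus position.

    Ties between equally long subsequences are broken toward the one with the
    smallest total rank displacement |rank_source - rank_consensus| over its
    members, then toward the leftmost (lexicographically smallest index set).
    """
    pairs = anchors.pairs
    n = len(pairs)
    if n < 2:
        raise InsufficientAnchorsError("need >= 2 raw anchor pairs")

    cons_rank = {
        i: r for r, i in enumerate(sorted(range(n), key=lambda i: (pairs[i][1], i)))
    }
    cost = [abs(i - cons_rank[i]) for i in range(n)]

    def compatible(i: int, j: int) -> bool:
        return pairs[i][0] < pairs[j][0] and pairs[i][1] < pairs[j][1]

    # best[i] = (max length, min cost) of a chain starting at i
    best: list[tuple[int, int]] = [(1, cost[i]) for i in range(n)]
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if compatible(i, j):
                cand = (best[j][0] + 1, best[j][1] + cost[i])
                if (-cand[0], cand[1]) < (-best[i][0], best[i][1]):
                    best[i] = cand

    target = min((-l, c) for l, c in best)
    chain: list[int] = []
    # greedy left-to-right reconstruction gives the leftmost optimal chain
    need_len, need_cost = -target[0], target[1]
    prev = -1
    while need_len > 0:
        for i in range(prev + 1, n):
            if prev >= 0 and not compatible(prev, i):
                continue
            if best[i][0] == need_len and best[i][1] == need_cost:
                chain.append(i)
                need_len -= 1
                need_cost -= cost[i]
                prev = i
                break
        else:  # pragma: no cover - the DP guarantees a witness exists
            raise AssertionError("chain reconstruction failed")

    if len(chain) < 2:
        raise InsufficientAnchorsError(
            f"chromosome {anchors.chromosome}: fewer than 2 order-consistent anchors"
        )
    return AnchorSet(
        chromosome=anchors.chromosome,
        pairs=[pairs[i] for i in chain],
        markers=[anchors.markers[i] for i in chain] if anchors.markers else [],
    )


def _interval_index(anchors: AnchorSet, pos: float) -> int:
    """Index of the anchor interval used for pos (terminal when outside)."""
    sources = [s for s, _ in anchors.pairs]
    i = bisect.bisect_right(sources, pos) - 1
    return min(max(i, 0), len(sources) - 2)


def project_position(pos: float, anchors: AnchorSet) -> float:
    """Map a source-cM position into consensus coordinates.

    Piecewise-linear between bracketing anchors; beyond the terminal anchors
    the slope of the nearest interval is extended (linear extrapolation), so
    off-end positions keep their ordering instead of piling up at the ends.
    """
    i = _interval_index(anchors, pos)
    (s0, c0), (s1, c1) = anchors.pairs[i], anchors.pairs[i + 1]
    if s1 == s0:
        raise DegenerateIntervalError(
            f"zero-length source interval at {s0} cM on chromosome {anchors.chromosome}"
        )
    return c0 + (pos - s0) * (c1 - c0) / (s1 - s0)


def local_expansion(pos: float, anchors: AnchorSet) -> float:
    """Expansion ratio λ = consensus span / source span of the anchor
    interval containing pos (terminal interval when extrapolating)."""
    i = _interval_index(anchors, pos)
    (s0, c0), (s1, c1) = anchors.pairs[i], anchors.pairs[i + 1]
    if s1 == s0:
        raise DegenerateIntervalError(
            f"zero-length source interval at {s0} cM on chromosome {anchors.chromosome}"
        )
    return (c1 - c0) / (s1 - s0)


def build_anchor_sets(
    source: GeneticMap, reference: GeneticMap
) -> dict[int, AnchorSet]:
    """Filtered anchor sets for every chromosome projectable between the maps."""
    out: dict[int, AnchorSet] = {}
    for chrom in source.chromosomes:
        if not reference.markers_on(chrom):
            continue
        try:
            out[chrom] = monotone_filter(shared_anchors(source, reference, chrom))
        except InsufficientAnchorsError:
            continue
    return out
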