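"""Removal of sequencing-error structures: low-coverage nodes/links, tips
and bubbles.

Tips and bubbles are found with a Dijkstra-like breadth-first search
ordered by distance in bases (the sum of link label lengths along a path).
A tip is an unbranched dead-end chain hanging off a branching node; a
bubble is a pair of paths leaving the same node side and meeting again at
the same node in the same orientation, in which case the branch with the
lower mean node coverage is deleted.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .seqio import FORWARD, REVERSE, reverse_complement
from .sparse_graph import LEFT, RIGHT, GraphParams, SparseKmerGraph

__all__ = [
    "CleaningParams",
    "remove_low_coverage",
    "clip_tips",
    "pop_bubbles",
    "clean_graph",
]

_MAX_WALK = 100_000  # hard bound on walk length, guards pathological graphs


@dataclass(frozen=True)
class CleaningParams:
    """Thresholds for graph simplification.

    Defaults scale with the graph's effective node span ``k + g``:
    tips up to ``2(k+g)`` bp are clipped and bubbles are searched up to a
    ``3(k+g)`` bp horizon (a Velvet-style "2k" rule adapted to the sparse
    graph).
    """

    max_tip_bp: int
    max_bubble_bp: int
    link_min_cov: int = 1

    def __post_init__(self) -> None:
        if min(self.max_tip_bp, self.max_bubble_bp, self.link_min_cov) < 0:
            raise ValueError("cleaning thresholds must be >= 0")

    @classmethod
    def from_graph_params(
        cls, params: GraphParams, link_min_cov: Optional[int] = None
    ) -> "CleaningParams":
        span = params.k + params.g
        return cls(
            max_tip_bp=2 * span,
            max_bubble_bp=3 * span,
            link_min_cov=params.link_min_cov
            if link_min_cov is None
            else link_min_cov,
        )


def remove_low_coverage(
    graph: SparseKmerGraph, node_min_cov: int, link_min_cov: int
) -> Tuple[int, int]:
    """Delete nodes below *node_min_cov* and links below *link_min_cov*.

    Reciprocal link records are scrubbed consistently.  Returns
    ``(nodes_removed, links_removed)``.
    """
    nodes_removed = 0
    for code in sorted(graph.nodes):
        node = graph.nodes[code]
        if not node.deleted and node.cov < node_min_cov:
            graph.delete_node(code)
            nodes_removed += 1
    links_removed = 0
    for code in sorted(graph.nodes):
        node = graph.nodes[code]
        if node.deleted:
            continue
        for side in (RIGHT, LEFT):
            for (label, strand), mult in list(node.side_view(side).items()):
                if mult < link_min_cov:
                    graph.remove_link(code, side, label, strand)
                    links_removed += 1
    return nodes_removed, links_removed


# ---------------------------------------------------------------------------
# tips
# ---------------------------------------------------------------------------


def clip_tips(graph: SparseKmerGraph, params: CleaningParams) -> int:
    """Remove short dead-end chains attached to branching nodes.

    Repeats until no further chain qualifies; returns the number of tips
    (not nodes) removed.
    """
    removed = 0
    changed = True
    while changed:
        changed = False
        for code in sorted(graph.nodes):
            node = graph.nodes[code]
            if node.deleted:
                continue
            for orient in (FORWARD, REVERSE):
                if graph.outgoing(code, orient):
                    continue  # not a dead end on this side
                tip = _tip_chain(graph, code, 1 - orient, params.max_tip_bp)
                if tip:
                    for c in tip:
                        if not graph.nodes[c].deleted:
                            graph.delete_node(c)
                    removed += 1
                    changed = True
                    break  # this node is gone; move on
    return removed


def _tip_chain(
    graph: SparseKmerGraph, code: int, inward: int, max_tip_bp: int
) -> Optional[List[int]]:
    """Walk inward from a dead end; return the chain of tip nodes if the
    walk reaches a branching point within the length budget, else None."""
    k = graph.params.k
    chain = [code]
    labels: List[int] = []
    seen: Set[int] = {code}
    cur = (code, inward)
    for _ in range(_MAX_WALK):
        outs = graph.outgoing(*cur)
        if len(outs) == 0:
            return None  # other end is also dead: a pure linear chain
        if len(outs) > 1:
            # the chain dead-ends *into* a fork: it is unique sequence
            # leading up to a branch point, not a spurious stub
            return None
        label, dest, dorient, _ = outs[0]
        if dest in seen:
            return None  # loop
        dnode = graph.nodes.get(dest)
        if dnode is None or dnode.deleted:
            return None
        entered = dnode.side_view(LEFT if dorient == FORWARD else RIGHT)
        if len(entered) > 1:
            break  # dest is the branching node the tip hangs off
        chain.append(dest)
        labels.append(len(label))
        seen.add(dest)
        cur = (dest, dorient)
    if not chain:
        return None
    if k + sum(labels) > max_tip_bp:
        return None
    return chain


# ---------------------------------------------------------------------------
# bubbles
# ---------------------------------------------------------------------------


def pop_bubbles(graph: SparseKmerGraph, params: CleaningParams) -> int:
    """Detect and pop bubbles; returns the number popped.

    From every branching node side, paths are expanded in ascending bp
    distance up to ``max_bubble_bp``.  When two paths from the same source
    meet at the same node in the same orientation, the branch with lower
    mean interior-node coverage is deleted (ties keep the lexicographically
    smaller path sequence).  The search restarts after each removal.
    """
    popped = 0
    for _ in range(_MAX_WALK):
        if not _pop_one_bubble(graph, params.max_bubble_bp):
            break
        popped += 1
    return popped


def _pop_one_bubble(graph: SparseKmerGraph, horizon: int) -> bool:
    for code in sorted(graph.nodes):
        node = graph.nodes[code]
        if node.deleted:
            continue
        for orient in (FORWARD, REVERSE):
            if len(graph.outgoing(code, orient)) < 2:
                continue
            if _search_and_pop(graph, code, orient, horizon):
                return True
    return False


def _search_and_pop(
    graph: SparseKmerGraph, src: int, orient: int, horizon: int
) -> bool:
    counter = itertools.count()
    start = (src, orient)
    # state -> (distance, node path, walk sequence past the source k-mer)
    finalized: Dict[Tuple[int, int], Tuple[int, Tuple[int, ...], str]] = {
        start: (0, (src,), "")
    }
    heap: list = []
    for label, dest, dorient, _ in sorted(graph.outgoing(src, orient)):
        heapq.heappush(
            heap,
            (len(label), label, next(counter), (dest, dorient), (src, dest), label),
        )
    while heap:
        dist, seq, _, state, path, first = heapq.heappop(heap)
        if dist > horizon:
            break
        if state in finalized:
            d0, path0, seq0 = finalized[state]
            if _resolve_bubble(graph, orient, path0, seq0, path, seq):
                return True
            continue
        finalized[state] = (dist, path, seq)
        code, o = state
        for label, dest, dorient, _ in sorted(graph.outgoing(code, o)):
            heapq.heappush(
                heap,
                (
                    dist + len(label),
                    seq + label,
                    next(counter),
                    (dest, dorient),
                    path + (dest,),
                    first,
                ),
            )
    return False


def _branch_strength(graph: SparseKmerGraph, path: Tuple[int, ...]) -> float:
    interior = path[1:-1]
    if not interior:
        return float("inf")
    return sum(graph.nodes[c].cov for c in interior) / len(interior)


def _resolve_bubble(graph, orient, path_a, seq_a, path_b, seq_b) -> bool:
    """Delete the weaker of two parallel branches; True if anything changed."""
    sa, sb = _branch_strength(graph, path_a), _branch_strength(graph, path_b)
    if sa > sb or (sa == sb and seq_a <= seq_b):
        stronger, weaker, wseq = path_a, path_b, seq_b
    else:
        stronger, weaker, wseq = path_b, path_a, seq_a
    keep = set(stronger)
    doomed = [
        c
        for c in weaker[1:-1]
        if c not in keep and not graph.nodes[c].deleted
    ]
    if doomed:
        for c in doomed:
            graph.delete_node(c)
        return True
    # no interior of its own (e.g. two parallel direct links): drop the
    # weaker branch's first link record instead
    return _remove_first_hop(graph, weaker[0], orient, weaker, wseq)


def _remove_first_hop(graph, src, orient, path, seq) -> bool:
    """Remove the first link of a path (identified by walk label prefix)."""
    if len(path) < 2:
        return False
    target = path[1]
    for label, dest, dorient, _ in graph.outgoing(src, orient):
        if dest != target or not seq.startswith(label):
            continue
        if orient == FORWARD:
            graph.remove_link(src, RIGHT, label, dorient)
        else:
            graph.remove_link(
                src, LEFT, reverse_complement(label), 1 - dorient
            )
        return True
    return False


def clean_graph(
    graph: SparseKmerGraph,
    node_min_cov: int,
    cleaning: CleaningParams,
) -> Dict[str, int]:
    """Full cleaning pass: low-coverage removal, tip clipping, bubble
    popping.  Returns per-stage removal counts."""
    nodes_removed, links_removed = remove_low_coverage(
        graph, node_min_cov, cleaning.link_min_cov
    )
    tips = bubbles = 0
    while True:  # bubble popping can expose new tips and vice versa
        t = clip_tips(graph, cleaning)
        b = pop_bubbles(graph, cleaning)
        tips += t
        bubbles += b
        if t == 0 and b == 0:
            break
    return {
        "low_cov_nodes_removed": nodes_removed,
        "low_cov_links_removed": links_removed,
        "tips_clipped": tips,
        "bubbles_popped": bubbles,
    }
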