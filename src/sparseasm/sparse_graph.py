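"""The sparse k-mer graph: two-round construction and the memory model.

Round 1 walks each read and keeps roughly one of every ``g`` k-mers as a
node: from the last selected position ``a`` it queries the ``g`` subsequent
k-mer positions ``a+1 .. a+g``; the nearest position whose canonical k-mer
is already a node re-anchors the scan, otherwise a new node is created at
``a+g`` (at the very first k-mer for a fresh read, mirroring the construction
rule).  This guarantees consecutive selected positions within a read are at
most ``g`` apart, so every pair of selected neighbours can later be joined
by a link label of at most ``g`` bases.

Round 2 re-scans the reads, matches *every* position whose canonical k-mer
is a node, recounts node coverage from those matches, and records a link
for each consecutive pair of matches at distance 1..g.  Links are stored
twice (once per endpoint, mirrored between node sides) so the graph can be
walked in either direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

import numpy as np

from . import seqio
from .seqio import FORWARD, REVERSE, Read, reverse_complement

__all__ = [
    "GraphParams",
    "Node",
    "SparseKmerGraph",
    "MemoryEstimate",
    "select_nodes",
    "filter_low_coverage_nodes",
    "build_links",
    "node_count",
    "link_count",
    "estimate_memory",
    "write_graph_tsv",
    "load_graph_tsv",
    "COVERAGE_CAP",
]

#: node coverage and link multiplicity saturate at this value (16-bit spirit)
COVERAGE_CAP = 65535

#: a link record: (label, dest_strand) -> multiplicity
LinkKey = Tuple[str, int]


@dataclass(frozen=True)
class GraphParams:
    """Parameters governing one assembly run."""

    k: int
    g: int
    node_min_cov: int = 2
    link_min_cov: int = 1
    allow_even_k: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        if not 0 < self.g < self.k:
            raise ValueError(f"need 0 < g < k, got g={self.g}, k={self.k}")
        if self.node_min_cov < 0 or self.link_min_cov < 0:
            raise ValueError("coverage thresholds must be >= 0")
        seqio.check_odd_k(self.k, self.allow_even_k)


class Node:
    """A stored canonical k-mer.

    ``left``/``right`` map ``(label, dest_strand) -> multiplicity``.  The
    right side is the 3' end of the canonical orientation; a right label is
    appended after the k-mer, a left label is prepended before it (both
    written 5'->3').  ``dest_strand`` is FORWARD when the k-mer reached by
    shifting through the label reads in its canonical orientation.
    """

    __slots__ = ("cov", "left", "right", "visited", "deleted")

    def __init__(self, cov: int = 1):
        self.cov = cov
        self.left: Optional[Dict[LinkKey, int]] = None
        self.right: Optional[Dict[LinkKey, int]] = None
        self.visited = False
        self.deleted = False

    def side(self, which: int) -> Dict[LinkKey, int]:
        if which == 0:
            if self.right is None:
                self.right = {}
            return self.right
        if self.left is None:
            self.left = {}
        return self.left

    def side_view(self, which: int) -> Dict[LinkKey, int]:
        d = self.right if which == 0 else self.left
        return d if d is not None else {}


RIGHT = 0
LEFT = 1


class SparseKmerGraph:
    """Node table keyed by canonical k-mer code, plus parameters."""

    def __init__(self, params: GraphParams):
        self.params = params
        self.nodes: Dict[int, Node] = {}
        self.n_short_reads = 0  # reads shorter than k, skipped in round 1

    # -- basic queries ----------------------------------------------------

    def __contains__(self, code: int) -> bool:
        return code in self.nodes

    def kmer(self, code: int) -> str:
        return seqio.decode_kmer(code, self.params.k)

    def oriented_kmer(self, code: int, orient: int) -> str:
        s = self.kmer(code)
        return s if orient == FORWARD else reverse_complement(s)

    def iter_codes(self) -> Iterator[int]:
        """Non-deleted node codes in ascending canonical-code order."""
        for code in sorted(self.nodes):
            if not self.nodes[code].deleted:
                yield code

    # -- link arithmetic --------------------------------------------------

    def outgoing(self, code: int, orient: int) -> List[Tuple[str, int, int, int]]:
        """Links leaving a node when walking it in *orient*.

        Returns ``[(walk_label, dest_code, dest_orient, multiplicity)]``
        where *walk_label* is written in the walking orientation.
        """
        node = self.nodes[code]
        out = []
        if orient == FORWARD:
            for (label, strand), mult in node.side_view(RIGHT).items():
                seq = self.kmer(code) + label
                dest, dorient = self._locate(seq[-self.params.k :])
                out.append((label, dest, dorient, mult))
        else:
            for (label, strand), mult in node.side_view(LEFT).items():
                wlabel = reverse_complement(label)
                seq = label + self.kmer(code)
                dest, dorient = self._locate(seq[: self.params.k])
                out.append((wlabel, dest, 1 - dorient, mult))
        return out

    def _locate(self, kmer: str) -> Tuple[int, int]:
        code, strand = seqio.canonical(kmer)
        return code.bits, strand

    def add_link(
        self, code: int, side: int, label: str, strand: int, mult: int = 1
    ) -> None:
        """Add (or strengthen) one link record plus its mirror record."""
        self._add_record(code, side, label, strand, mult)
        mcode, mside, mlabel, mstrand = self.mirror(code, side, label, strand)
        self._add_record(mcode, mside, mlabel, mstrand, mult)

    def _add_record(self, code, side, label, strand, mult):
        d = self.nodes[code].side(side)
        key = (label, strand)
        d[key] = min(d.get(key, 0) + mult, COVERAGE_CAP)

    def mirror(
        self, code: int, side: int, label: str, strand: int
    ) -> Tuple[int, int, str, int]:
        """The reciprocal record stored on the destination node."""
        k = self.params.k
        if side == RIGHT:
            orient = FORWARD
            seq = self.kmer(code) + label
        else:
            orient = REVERSE
            seq = reverse_complement(label + self.kmer(code))
        # seq = oriented source k-mer + walk label; destination at its tail
        dest, t = self._locate(seq[-k:])
        wlabel_m = reverse_complement(seq[: len(label)])
        if t == REVERSE:  # walking back from dest starts on its right side
            return dest, RIGHT, wlabel_m, 1 - orient
        return dest, LEFT, reverse_complement(wlabel_m), orient

    def remove_link(self, code: int, side: int, label: str, strand: int) -> None:
        """Drop one link record and its mirror."""
        self._pop_record(code, side, label, strand)
        mcode, mside, mlabel, mstrand = self.mirror(code, side, label, strand)
        self._pop_record(mcode, mside, mlabel, mstrand)

    def _pop_record(self, code, side, label, strand):
        node = self.nodes.get(code)
        if node is None:
            return
        d = node.side_view(side)
        d.pop((label, strand), None)

    def delete_node(self, code: int) -> None:
        """Flag a node deleted and scrub all link records touching it."""
        node = self.nodes[code]
        for side in (RIGHT, LEFT):
            for (label, strand) in list(node.side_view(side)):
                mcode, mside, mlabel, mstrand = self.mirror(
                    code, side, label, strand
                )
                if mcode != code:
                    self._pop_record(mcode, mside, mlabel, mstrand)
            node.side_view(side).clear()
        node.deleted = True
        node.left = None
        node.right = None


@dataclass(frozen=True)
class MemoryEstimate:
    """Closed-form graph memory model (bits)."""

    genome_size: float
    k: int
    g: int
    ptr_sz: int
    s1_bits: float
    s2_bits: float


def estimate_memory(
    params: GraphParams, genome_size: float, ptr_sz: int = 64
) -> MemoryEstimate:
    """Dense-graph lower bound vs sparse-graph estimate.

    ``s1 = G * (2k + 8)`` (2 bits per base plus 4 edge-presence bits per
    side); ``s2 = (N/g) * (2k + 4g + ptr_sz)`` (one node per g bases, each
    storing the packed k-mer, up to g 2-bit label bases per side, and
    pointer overhead).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if ptr_sz < 0:
        raise ValueError("ptr_sz must be >= 0")
    k, g = params.k, params.g
    s1 = genome_size * (2 * k + 8)
    s2 = (genome_size / g) * (2 * k + 4 * g + ptr_sz)
    return MemoryEstimate(genome_size, k, g, ptr_sz, s1, s2)


# ---------------------------------------------------------------------------
# round 1: node selection
# ---------------------------------------------------------------------------


def _reads_iter(reads: Union[Iterable[Read], str]) -> Iterator[Read]:
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        return seqio.read_sequences(reads)
    return iter(reads)


def select_nodes(
    reads: Union[Iterable[Read], str], params: GraphParams
) -> SparseKmerGraph:
    """Round 1: choose the k-mers that become graph nodes.

    Reads are processed independently in input order.  Selection within a
    read follows the anchored scan described in the module docstring; each
    anchored or newly created node gains one unit of coverage.  k-mers
    containing non-ACGT characters are never formed: the scan restarts
    after the ambiguous base.
    """
    graph = SparseKmerGraph(params)
    k, g = params.k, params.g
    nodes = graph.nodes
    if g == 1:
        _select_nodes_g1(reads, params, graph)
        return graph
    for read in _reads_iter(reads):
        if len(read.seq) < k:
            graph.n_short_reads += 1
            continue
        codes_a, _, valid_a = seqio.canonical_codes(read.seq, k)
        codes = codes_a.tolist()
        valid = valid_a.tolist()
        n = len(codes)
        lo, hi = 0, min(g, n)  # current query window [lo, hi)
        last = -2 * g  # position of the previous selection
        while lo < n:
            a = -1
            for i in range(lo, hi):
                if valid[i] and codes[i] in nodes:
                    a = i
                    break
            if a < 0:
                # no existing node: create one, keeping g-spacing when the
                # window directly follows a selection, else (fresh start /
                # after an N gap) as early as possible
                if lo == last + 1:
                    if hi < lo + g:
                        break  # window truncated by the read end: stop
                    rng = range(hi - 1, lo - 1, -1)
                else:
                    rng = range(lo, hi)
                for i in rng:
                    if valid[i]:
                        a = i
                        nodes[codes[i]] = Node(cov=1)
                        break
            else:
                node = nodes[codes[a]]
                node.cov = min(node.cov + 1, COVERAGE_CAP)
            if a < 0:  # window had no usable k-mer at all
                lo, hi = hi, min(hi + g, n)
            else:
                last = a
                lo, hi = a + 1, min(a + 1 + g, n)
    return graph


def _select_nodes_g1(reads, params: GraphParams, graph: SparseKmerGraph) -> None:
    """g=1 fast path: every k-mer position is selected, so the node table is
    exactly the multiset of canonical k-mers.  Equivalent to the generic
    scan (verified by tests) but vectorised."""
    k = params.k
    chunks: List[np.ndarray] = []
    for read in _reads_iter(reads):
        if len(read.seq) < k:
            graph.n_short_reads += 1
            continue
        codes, _, valid = seqio.canonical_codes(read.seq, k)
        chunks.append(codes[valid])
    if not chunks:
        return
    allcodes = np.concatenate(chunks)
    uniq, counts = np.unique(allcodes, return_counts=True)
    nodes = graph.nodes
    counts = np.minimum(counts, COVERAGE_CAP)
    for code, cnt in zip(uniq.tolist(), counts.tolist()):
        nodes[code] = Node(cov=cnt)


def filter_low_coverage_nodes(graph: SparseKmerGraph, node_min_cov: int) -> int:
    """Drop round-1 nodes below the coverage threshold; returns count removed."""
    doomed = [c for c, n in graph.nodes.items() if n.cov < node_min_cov]
    for code in doomed:
        del graph.nodes[code]
    return len(doomed)


# ---------------------------------------------------------------------------
# round 2: link building
# ---------------------------------------------------------------------------


def build_links(
    reads: Union[Iterable[Read], str], graph: SparseKmerGraph
) -> SparseKmerGraph:
    """Round 2: re-scan the reads and connect surviving nodes.

    Every position whose canonical k-mer is a node counts as a match; node
    coverage is reset and recounted from these matches.  Each consecutive
    pair of matches at distance ``1..g`` produces a link labelled with the
    intervening bases (recorded on both endpoints); wider gaps produce no
    link, effectively splitting the read.
    """
    params = graph.params
    k, g = params.k, params.g
    nodes = graph.nodes
    for node in nodes.values():
        node.cov = 0
    for read in _reads_iter(reads):
        if len(read.seq) < k:
            continue
        codes_a, strands_a, valid_a = seqio.canonical_codes(read.seq, k)
        codes = codes_a.tolist()
        strands = strands_a.tolist()
        valid = valid_a.tolist()
        seq = read.seq
        prev_pos = -1
        prev_code = -1
        prev_strand = FORWARD
        for i, code in enumerate(codes):
            if not valid[i] or code not in nodes:
                continue
            node = nodes[code]
            node.cov = min(node.cov + 1, COVERAGE_CAP)
            if prev_pos >= 0 and 1 <= i - prev_pos <= g:
                _add_read_link(
                    graph,
                    seq,
                    prev_pos,
                    prev_code,
                    prev_strand,
                    i,
                    code,
                    strands[i],
                )
            prev_pos, prev_code, prev_strand = i, code, strands[i]
    return graph


def _add_read_link(graph, seq, p, code_p, s, q, code_q, t):
    """Record the p->q adjacency on both nodes, in canonical coordinates."""
    k = graph.params.k
    label_r = seq[p + k : q + k]  # bases after the source k-mer
    label_l = seq[p:q]  # bases before the destination k-mer
    if s == FORWARD:
        graph._add_record(code_p, RIGHT, label_r, t, 1)
    else:
        graph._add_record(
            code_p, LEFT, reverse_complement(label_r), 1 - t, 1
        )
    if t == FORWARD:
        graph._add_record(code_q, LEFT, label_l, s, 1)
    else:
        graph._add_record(
            code_q, RIGHT, reverse_complement(label_l), 1 - s, 1
        )


# ---------------------------------------------------------------------------
# counters
# ---------------------------------------------------------------------------


def node_count(graph: SparseKmerGraph) -> int:
    return sum(1 for n in graph.nodes.values() if not n.deleted)


def link_count(graph: SparseKmerGraph) -> int:
    """Number of links, counting each once (every link owns two mirrored
    records, one per endpoint)."""
    records = 0
    for n in graph.nodes.values():
        if n.deleted:
            continue
        records += len(n.side_view(RIGHT)) + len(n.side_view(LEFT))
    return records // 2


# ---------------------------------------------------------------------------
# dump / load
# ---------------------------------------------------------------------------


def _fmt_side(d: Dict[LinkKey, int]) -> str:
    if not d:
        return "."
    parts = [
        f"{label}:{'F' if strand == FORWARD else 'R'}:{mult}"
        for (label, strand), mult in sorted(d.items())
    ]
    return ",".join(parts)


def _parse_side(s: str) -> Dict[LinkKey, int]:
    if s == ".":
        return {}
    out: Dict[LinkKey, int] = {}
    for part in s.split(","):
        label, strand, mult = part.split(":")
        out[(label, FORWARD if strand == "F" else REVERSE)] = int(mult)
    return out


def write_graph_tsv(graph: SparseKmerGraph, path) -> None:
    """Dump: one row per node, ascending canonical code; columns are the
    k-mer, coverage, then left and right links as label:strand:mult triples."""
    with open(path, "wt") as fh:
        fh.write(f"#k={graph.params.k}\tg={graph.params.g}\n")
        fh.write("#kmer\tcoverage\tleft_links\tright_links\n")
        for code in graph.iter_codes():
            node = graph.nodes[code]
            fh.write(
                f"{graph.kmer(code)}\t{node.cov}\t"
                f"{_fmt_side(node.side_view(LEFT))}\t"
                f"{_fmt_side(node.side_view(RIGHT))}\n"
            )


def load_graph_tsv(path) -> SparseKmerGraph:
    with open(path, "rt") as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: missing graph header")
        kpart, gpart = header[1:].split("\t")
        k = int(kpart.split("=")[1])
        g = int(gpart.split("=")[1])
        graph = SparseKmerGraph(GraphParams(k=k, g=g, allow_even_k=True))
        for line in fh:
            if line.startswith("#"):
                continue
            kmer, cov, left, right = line.rstrip("\n").split("\t")
            code = seqio.encode_kmer(kmer).bits
            node = Node(cov=int(cov))
            ld, rd = _parse_side(left), _parse_side(right)
            node.left = ld or None
            node.right = rd or None
            graph.nodes[code] = node
    return graph
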