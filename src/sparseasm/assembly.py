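"""Contig generation by unitig traversal, and the end-to-end pipeline."""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import cleaning as _cleaning
from . import sparse_graph as sg
from .cleaning import CleaningParams
from .seqio import FORWARD, REVERSE, Read, reverse_complement
from .sparse_graph import LEFT, RIGHT, GraphParams, SparseKmerGraph

__all__ = ["Contig", "AssemblyError", "traverse_contigs", "assemble"]


class AssemblyError(RuntimeError):
    pass


@dataclass
class Contig:
    """One unbranched traversal of the cleaned graph."""

    seq: str
    node_path_len: int
    mean_cov: float

    def __len__(self) -> int:
        return len(self.seq)


def traverse_contigs(
    graph: SparseKmerGraph, min_contig_len: int = 100
) -> List[Contig]:
    """Emit contigs by walking maximal unbranched chains.

    Unvisited nodes are seeded in ascending canonical-code order (making
    the output deterministic) and extended right then left while the
    current side has exactly one link and the entered side of the
    destination has exactly one link.  Every non-deleted node is visited
    exactly once; contigs shorter than *min_contig_len* are dropped after
    their nodes are marked.
    """
    contigs: List[Contig] = []
    nodes = graph.nodes
    for code in sorted(nodes):
        node = nodes[code]
        if node.deleted or node.visited:
            continue
        node.visited = True
        ext_r, path_r = _walk(graph, code, FORWARD)
        ext_l, path_l = _walk(graph, code, REVERSE)
        seq = reverse_complement(ext_l) + graph.kmer(code) + ext_r
        path = [code] + path_r + path_l
        mean_cov = sum(nodes[c].cov for c in path) / len(path)
        if len(seq) >= min_contig_len:
            contigs.append(Contig(seq, len(path), mean_cov))
    return contigs


def _walk(graph: SparseKmerGraph, code: int, orient: int):
    """Extend a unitig walk from (code, orient); marks nodes visited."""
    ext: List[str] = []
    path: List[int] = []
    cur = (code, orient)
    while True:
        outs = graph.outgoing(*cur)
        if len(outs) != 1:
            break
        label, dest, dorient, _ = outs[0]
        dnode = graph.nodes.get(dest)
        if dnode is None or dnode.deleted or dnode.visited:
            break
        entered = dnode.side_view(LEFT if dorient == FORWARD else RIGHT)
        if len(entered) != 1:
            break
        ext.append(label)
        path.append(dest)
        dnode.visited = True
        cur = (dest, dorient)
    return "".join(ext), path


def assemble(
    reads: Union[str, Path, Sequence[Read]],
    params: GraphParams,
    cleaning_params: Optional[CleaningParams] = None,
    min_contig_len: int = 100,
) -> Tuple[List[Contig], Dict]:
    """Run the full pipeline: two-round graph construction, cleaning,
    traversal.  *reads* may be a FASTA/FASTQ path (scanned twice) or an
    in-memory sequence of reads.

    Returns ``(contigs, report)`` where the report carries node/link counts
    at each stage and the wall time.
    """
    if cleaning_params is None:
        cleaning_params = CleaningParams.from_graph_params(params)
    if not isinstance(reads, (str, Path)) and not isinstance(reads, list):
        reads = list(reads)

    t0 = time.monotonic()
    report: Dict = {"k": params.k, "g": params.g}

    graph = sg.select_nodes(reads, params)
    report["round1_nodes"] = sg.node_count(graph)
    report["reads_shorter_than_k"] = graph.n_short_reads
    if not graph.nodes:
        raise AssemblyError(
            "no k-mers collected: input empty or every read shorter than k"
        )
    report["peak_nodes"] = report["round1_nodes"]

    report["round1_filtered"] = sg.filter_low_coverage_nodes(
        graph, params.node_min_cov
    )
    sg.build_links(reads, graph)
    report["round2_nodes"] = sg.node_count(graph)
    report["round2_links"] = sg.link_count(graph)

    stats = _cleaning.clean_graph(graph, params.node_min_cov, cleaning_params)
    report.update(stats)
    report["cleaned_nodes"] = sg.node_count(graph)
    report["cleaned_links"] = sg.link_count(graph)

    contigs = traverse_contigs(graph, min_contig_len)
    report["n_contigs"] = len(contigs)
    report["total_bp"] = sum(len(c) for c in contigs)
    report["wall_time_s"] = time.monotonic() - t0
    return contigs, report
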