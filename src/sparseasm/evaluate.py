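"""Assembly metrics (N50/NG50 family), reference-based validation of
contigs by exact matching, and the node-count experiment harness.

Misjoin detection greedily decomposes each contig into maximal exact
matches against the reference (either strand).  This replaces
alignment-based misjoin calling and is valid for simulated data where the
reference is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import simulate as sim
from . import sparse_graph as sg
from .seqio import Read, reverse_complement
from .sparse_graph import GraphParams

__all__ = [
    "AssemblyStats",
    "nxx",
    "ngxx",
    "validate_contigs",
    "compute_stats",
    "node_count_experiment",
]


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    mean_bp: float
    n50: int
    n95: int
    longest: int
    ng50: Optional[int] = None
    ng95: Optional[int] = None
    genome_coverage: Optional[float] = None
    misjoins: Optional[int] = None


def nxx(lengths: Sequence[int], x: float) -> int:
    """Largest L such that contigs of length >= L sum to >= x% of the total
    assembly length; 0 for an empty assembly."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if not lengths:
        return 0
    target = x / 100.0 * sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= target:
            return L
    return 0  # unreachable: full sum always meets the target


def ngxx(lengths: Sequence[int], genome_size: int, x: float) -> int:
    """Like :func:`nxx` but against x% of *genome_size*; 0 when the assembly
    never reaches the target."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    target = x / 100.0 * genome_size
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= target:
            return L
    return 0


def _longest_prefix_in(hay: str, s: str) -> int:
    """Length of the longest prefix of *s* occurring in *hay* (binary
    search over the monotone prefix-occurrence property)."""
    if not s or s[0] not in hay:
        return 0
    lo, hi = 1, len(s)  # invariant: prefix of length lo occurs
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if s[:mid] in hay:
            lo = mid
        else:
            hi = mid - 1
    return lo


def validate_contigs(
    contigs, reference: str, min_match: Optional[int] = None
) -> Tuple[int, List[int], float]:
    """Exact-match validation against a known reference.

    Each contig is greedily decomposed into maximal exact matches to the
    reference or its reverse complement.  A single full-length match means
    0 misjoins; every extra segment adds one.  Returns
    ``(misjoins, corrected_lengths, genome_coverage)`` where corrected
    lengths exclude segments shorter than *min_match* (default 31) and
    genome coverage is the fraction of reference positions covered by at
    least one segment on either strand.
    """
    if min_match is None:
        min_match = 31
    rc_ref = reverse_complement(reference)
    hay = reference + "#" + rc_ref
    covered = np.zeros(len(reference), dtype=bool)
    misjoins = 0
    corrected: List[int] = []
    for contig in contigs:
        seq = contig.seq if hasattr(contig, "seq") else str(contig)
        segments = 0
        good_segments = 0
        rest = seq
        while rest:
            L = _longest_prefix_in(hay, rest)
            if L == 0:
                rest = rest[1:]
                continue
            segments += 1
            if L >= min_match:
                good_segments += 1
                corrected.append(L)
                _mark_coverage(covered, reference, rc_ref, rest[:L])
            rest = rest[L:]
        if good_segments == 0:
            misjoins += 1  # nowhere placeable
        else:
            misjoins += segments - 1
    coverage = float(covered.sum()) / len(reference) if len(reference) else 0.0
    return misjoins, corrected, coverage


def _mark_coverage(covered, reference, rc_ref, segment):
    pos = reference.find(segment)
    if pos >= 0:
        covered[pos : pos + len(segment)] = True
        return
    pos = rc_ref.find(segment)
    if pos >= 0:  # map rc coordinates back to forward strand
        start = len(reference) - pos - len(segment)
        covered[start : start + len(segment)] = True


def compute_stats(
    contigs,
    genome_size: Optional[int] = None,
    reference: Optional[str] = None,
    min_contig_len: int = 100,
) -> AssemblyStats:
    """Summary metrics for a contig set, optionally validated against a
    reference (misjoins are detected first and NG values use the corrected
    segment lengths)."""
    kept = [c for c in contigs if len(c.seq if hasattr(c, "seq") else c) >= min_contig_len]
    lengths = [len(c.seq if hasattr(c, "seq") else c) for c in kept]
    stats = AssemblyStats(
        n_contigs=len(lengths),
        total_bp=sum(lengths),
        mean_bp=sum(lengths) / len(lengths) if lengths else 0.0,
        n50=nxx(lengths, 50),
        n95=nxx(lengths, 95),
        longest=max(lengths, default=0),
    )
    if reference is not None:
        misjoins, corrected, coverage = validate_contigs(kept, reference)
        stats.misjoins = misjoins
        stats.genome_coverage = coverage
        gsize = genome_size if genome_size is not None else len(reference)
        stats.ng50 = ngxx(corrected, gsize, 50)
        stats.ng95 = ngxx(corrected, gsize, 95)
    elif genome_size is not None:
        stats.ng50 = ngxx(lengths, genome_size, 50)
        stats.ng95 = ngxx(lengths, genome_size, 95)
    return stats


def node_count_experiment(
    reference: str,
    k: int,
    g_values: Sequence[int],
    coverage: float = 30.0,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    node_min_cov: int = 0,
) -> List[Dict]:
    """Round-1 node counts across g, with fold reduction relative to g=1.

    Counts are raw round-1 counts by default (``node_min_cov=0``); set a
    threshold to count post-filter nodes instead.  One read set is
    simulated and reused for every g.
    """
    reads = sim.simulate_reads(
        reference,
        sim.SimulationConfig(
            coverage=coverage,
            read_len=read_len,
            error_rate=error_rate,
            seed=seed,
        ),
    )
    baseline = None
    rows: List[Dict] = []
    all_g = sorted(set(g_values) | {1})
    counts: Dict[int, int] = {}
    for g in all_g:
        params = GraphParams(k=k, g=g, node_min_cov=node_min_cov)
        graph = sg.select_nodes(reads, params)
        if node_min_cov > 0:
            sg.filter_low_coverage_nodes(graph, node_min_cov)
        counts[g] = sg.node_count(graph)
    baseline = counts[1]
    for g in g_values:
        rows.append(
            {
                "g": g,
                "node_count": counts[g],
                "fold_reduction": baseline / counts[g] if counts[g] else float("nan"),
            }
        )
    return rows
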