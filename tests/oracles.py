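"""Independent reference implementations used to cross-check the package.

Everything here is written with plain Python strings and dicts, avoiding
the package's vectorised code paths, so the two routes stay independent.
"""

from typing import Dict, List, Optional, Sequence

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical_str(kmer: str) -> Optional[str]:
    """Lexicographically smaller of kmer / reverse complement; None if the
    window contains a non-ACGT character."""
    if set(kmer) - set("ACGT"):
        return None
    other = rc(kmer)
    return kmer if kmer <= other else other


def distinct_canonical_kmers(seqs: Sequence[str], k: int) -> set:
    """Brute-force set of canonical k-mers over a collection of strings."""
    out = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            c = canonical_str(seq[i : i + k])
            if c is not None:
                out.add(c)
    return out


def canonical_kmer_counts(seqs: Sequence[str], k: int) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            c = canonical_str(seq[i : i + k])
            if c is not None:
                out[c] = out.get(c, 0) + 1
    return out


def select_nodes_oracle(seqs: Sequence[str], k: int, g: int) -> Dict[str, int]:
    """Step-by-step execution of the round-1 scan.

    From the last selected position a, the g subsequent k-mer positions
    a+1..a+g are queried for an existing node (nearest wins); if none and
    the window is complete, a node is created at a+g.  A fresh scan (read
    start, or after an ambiguous-base gap) creates its node at the first
    usable position instead.  Returns canonical k-mer -> coverage.
    """
    table: Dict[str, int] = {}
    for seq in seqs:
        n = len(seq) - k + 1
        if n <= 0:
            continue

        def canon(i):
            return canonical_str(seq[i : i + k])

        lo, hi = 0, min(g, n)
        last = None
        while lo < n:
            a = None
            for i in range(lo, hi):
                c = canon(i)
                if c is not None and c in table:
                    a = i
                    break
            if a is None:
                fresh = last is None or lo != last + 1
                if fresh:
                    candidates = range(lo, hi)
                else:
                    if hi < lo + g:
                        break  # truncated by the read end
                    candidates = range(hi - 1, lo - 1, -1)
                for i in candidates:
                    c = canon(i)
                    if c is not None:
                        a = i
                        table[c] = 1
                        break
            else:
                table[canon(a)] += 1
            if a is None:
                lo, hi = hi, min(hi + g, n)
            else:
                last = a
                lo, hi = a + 1, min(a + 1 + g, n)
    return table


def match_positions(seq: str, table, k: int) -> List[int]:
    """Round-2 rule: every position whose canonical k-mer is a node."""
    out = []
    for i in range(len(seq) - k + 1):
        c = canonical_str(seq[i : i + k])
        if c is not None and c in table:
            out.append(i)
    return out


def nxx_oracle(lengths: Sequence[int], x: float, total: Optional[int] = None) -> int:
    """Exhaustive N-statistic: try every candidate L from large to small and
    return the first satisfying the definition."""
    if total is None:
        total = sum(lengths)
    target = x / 100.0 * total
    for L in sorted(set(lengths), reverse=True):
        if sum(v for v in lengths if v >= L) >= target:
            return L
    return 0


def enumerate_paths(graph, src, orient, horizon: int):
    """All simple link paths up to *horizon* bp leaving (src, orient), as
    (dest_state, node_tuple, bp) triples.  Brute-force DFS for small graphs."""
    results = []

    def dfs(state, path, bp):
        code, o = state
        for label, dest, dorient, _ in graph.outgoing(code, o):
            nbp = bp + len(label)
            if nbp > horizon or dest in path:
                continue
            nstate = (dest, dorient)
            results.append((nstate, path + (dest,), nbp))
            dfs(nstate, path + (dest,), nbp)

    dfs((src, orient), (src,), 0)
    return results
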