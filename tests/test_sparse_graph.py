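import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
import sparseasm as sa
from sparseasm import seqio
from sparseasm import sparse_graph as sg
from sparseasm.seqio import FORWARD, REVERSE

from conftest import TOY_READ


def kmer_table(graph):
    return {graph.kmer(c): graph.nodes[c].cov for c in graph.iter_codes()}


# -- parameters -------------------------------------------------------------


def test_params_validation():
    with pytest.raises(ValueError):
        sa.GraphParams(k=31, g=31)  # need g < k
    with pytest.raises(ValueError):
        sa.GraphParams(k=31, g=0)
    with pytest.raises(ValueError):
        sa.GraphParams(k=31, g=5, node_min_cov=-1)


# -- round 1 ----------------------------------------------------------------


def test_toy_node_selection(toy_params):
    # hand-traced anchored scan of ACGTACGGATT with k=3, g=2: nodes are
    # created at read positions 0 (ACG), 3 (TAC->GTA), 6 (GGA), 8 (ATT->AAT);
    # ACG is re-anchored at positions 1 and 4
    graph = sa.select_nodes([sa.Read("t", TOY_READ)], toy_params)
    assert kmer_table(graph) == {"ACG": 3, "GTA": 1, "GGA": 1, "AAT": 1}


def test_toy_matches_oracle(toy_params):
    got = kmer_table(sa.select_nodes([sa.Read("t", TOY_READ)], toy_params))
    assert got == oracles.select_nodes_oracle([TOY_READ], 3, 2)


@given(
    st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=60), min_size=1, max_size=8),
    st.integers(3, 9).filter(lambda k: k % 2 == 1),
    st.integers(1, 6),
)
@settings(max_examples=150, deadline=None)
def test_select_nodes_equals_oracle(seqs, k, g):
    if g >= k:
        g = k - 1
    reads = [sa.Read(f"r{i}", s) for i, s in enumerate(seqs)]
    params = sa.GraphParams(k=k, g=g, node_min_cov=0)
    got = kmer_table(sa.select_nodes(reads, params))
    assert got == oracles.select_nodes_oracle(seqs, k, g)


def test_same_read_twice_doubles_coverage(toy_params):
    # the second pass may re-anchor at extra positions (the table is no
    # longer empty), so round-1 coverage can exceed an exact doubling; the
    # node set is unchanged and the recounted round-2 coverage doubles
    reads = [sa.Read("a", TOY_READ), sa.Read("b", TOY_READ)]
    graph = sa.select_nodes(reads, toy_params)
    single = sa.select_nodes([reads[0]], toy_params)
    assert set(kmer_table(graph)) == set(kmer_table(single))
    assert all(
        kmer_table(graph)[k] >= 2 * v for k, v in kmer_table(single).items()
    )
    sa.build_links(reads, graph)
    sa.build_links([reads[0]], single)
    assert kmer_table(graph) == {k: 2 * v for k, v in kmer_table(single).items()}


def test_g1_equals_distinct_canonical_kmers(small_reads):
    params = sa.GraphParams(k=31, g=1, node_min_cov=0)
    graph = sa.select_nodes(small_reads, params)
    expected = oracles.distinct_canonical_kmers([r.seq for r in small_reads], 31)
    assert set(kmer_table(graph)) == expected
    # and coverage equals the occurrence count
    counts = oracles.canonical_kmer_counts([r.seq for r in small_reads], 31)
    assert kmer_table(graph) == counts


def test_short_reads_skipped_and_counted():
    params = sa.GraphParams(k=5, g=2, node_min_cov=0)
    graph = sa.select_nodes([sa.Read("short", "ACG"), sa.Read("ok", "ACGTACG")], params)
    assert graph.n_short_reads == 1
    assert sg.node_count(graph) > 0


def test_n_containing_kmers_never_formed():
    params = sa.GraphParams(k=3, g=2, node_min_cov=0)
    graph = sa.select_nodes([sa.Read("r", "ACGTNNACGT")], params)
    for code in graph.iter_codes():
        assert "N" not in graph.kmer(code)
    assert kmer_table(graph) == oracles.select_nodes_oracle(["ACGTNNACGT"], 3, 2)


def test_filter_low_coverage_nodes(toy_params):
    graph = sa.select_nodes([sa.Read("t", TOY_READ)], toy_params)
    assert sa.filter_low_coverage_nodes(graph, 0) == 0  # identity
    n_before = sg.node_count(graph)
    removed = sa.filter_low_coverage_nodes(graph, 2)
    assert removed == 3 and sg.node_count(graph) == n_before - 3
    assert set(kmer_table(graph)) == {"ACG"}


def test_errors_create_more_low_coverage_nodes(small_genome):
    cfg0 = sa.SimulationConfig(coverage=30, read_len=100, error_rate=0.0, seed=3)
    cfg1 = sa.SimulationConfig(coverage=30, read_len=100, error_rate=0.01, seed=3)
    params = sa.GraphParams(k=31, g=15)
    frac = []
    for cfg in (cfg0, cfg1):
        graph = sa.select_nodes(sa.simulate_reads(small_genome, cfg), params)
        n = sg.node_count(graph)
        frac.append(sa.filter_low_coverage_nodes(graph, 2) / n)
    assert frac[1] > 10 * frac[0]


# -- round 2 ----------------------------------------------------------------


def test_toy_links(toy_graph):
    # frozen from hand-execution of the round-2 rule (every position whose
    # canonical k-mer is a node; consecutive pairs at distance <= g)
    def side(kmer, which):
        code = sa.encode_kmer(kmer).bits
        return dict(toy_graph.nodes[code].side_view(which))

    R, L = sg.RIGHT, sg.LEFT
    assert side("AAT", R) == {("CC", REVERSE): 1}
    assert side("AAT", L) == {}
    assert side("ACG", R) == {("T", REVERSE): 2, ("GA", FORWARD): 1}
    assert side("ACG", L) == {("T", REVERSE): 2}
    assert side("GGA", R) == {("TT", REVERSE): 1}
    assert side("GGA", L) == {("AC", FORWARD): 1}
    assert side("GTA", R) == {("C", REVERSE): 2}
    assert side("GTA", L) == {("C", REVERSE): 2}
    # coverage recounted from every-position matches
    assert kmer_table(toy_graph) == {"ACG": 3, "GTA": 2, "GGA": 1, "AAT": 1}


def test_toy_counts(toy_graph):
    assert sg.node_count(toy_graph) == 4
    assert sg.link_count(toy_graph) == 4


def test_empty_graph_counts():
    graph = sg.SparseKmerGraph(sa.GraphParams(k=3, g=2))
    assert sg.node_count(graph) == 0 and sg.link_count(graph) == 0


def test_two_identical_reads_double_multiplicity(toy_params):
    reads = [sa.Read("a", TOY_READ), sa.Read("b", TOY_READ)]
    graph = sa.select_nodes(reads, toy_params)
    sa.build_links(reads, graph)
    single = sa.select_nodes([reads[0]], toy_params)
    sa.build_links([reads[0]], single)
    for code in graph.iter_codes():
        for which in (sg.RIGHT, sg.LEFT):
            got = graph.nodes[code].side_view(which)
            want = {
                k: 2 * v for k, v in single.nodes[code].side_view(which).items()
            }
            assert got == want


def test_read_plus_rc_mirrors(toy_params):
    fwd = sa.Read("f", TOY_READ)
    rev = sa.Read("r", sa.reverse_complement(TOY_READ))
    both = sa.select_nodes([fwd, rev], toy_params)
    only = sa.select_nodes([fwd], toy_params)
    # the rc read anchors on existing nodes: the node table is unchanged
    assert set(kmer_table(both)) == set(kmer_table(only))
    sa.build_links([fwd, rev], both)
    sa.build_links([fwd], only)
    for code in both.iter_codes():
        for which in (sg.RIGHT, sg.LEFT):
            got = both.nodes[code].side_view(which)
            want = {k: 2 * v for k, v in only.nodes[code].side_view(which).items()}
            assert got == want


def _assert_mirror_consistent(graph):
    for code in graph.iter_codes():
        node = graph.nodes[code]
        for which in (sg.RIGHT, sg.LEFT):
            for (label, strand), mult in node.side_view(which).items():
                m = graph.mirror(code, which, label, strand)
                mcode, mwhich, mlabel, mstrand = m
                back = graph.mirror(mcode, mwhich, mlabel, mstrand)
                assert back == (code, which, label, strand)
                assert (
                    graph.nodes[mcode].side_view(mwhich).get((mlabel, mstrand))
                    == mult
                )


@given(
    st.lists(st.text(alphabet="ACGT", min_size=8, max_size=60), min_size=1, max_size=6),
    st.integers(3, 7).filter(lambda k: k % 2 == 1),
    st.integers(1, 4),
)
@settings(max_examples=100, deadline=None)
def test_links_mirror_consistent(seqs, k, g):
    if g >= k:
        g = k - 1
    reads = [sa.Read(f"r{i}", s) for i, s in enumerate(seqs)]
    params = sa.GraphParams(k=k, g=g, node_min_cov=0)
    graph = sa.select_nodes(reads, params)
    sa.build_links(reads, graph)
    _assert_mirror_consistent(graph)


@given(
    st.lists(st.text(alphabet="ACGT", min_size=10, max_size=60), min_size=1, max_size=5),
    st.integers(3, 7).filter(lambda k: k % 2 == 1),
    st.integers(1, 4),
)
@settings(max_examples=100, deadline=None)
def test_link_labels_reproduce_read_substrings(seqs, k, g):
    if g >= k:
        g = k - 1
    reads = [sa.Read(f"r{i}", s) for i, s in enumerate(seqs)]
    params = sa.GraphParams(k=k, g=g, node_min_cov=0)
    graph = sa.select_nodes(reads, params)
    sa.build_links(reads, graph)
    haystack = "#".join(seqs) + "#" + "#".join(oracles.rc(s) for s in seqs)
    for code in graph.iter_codes():
        for orient in (FORWARD, REVERSE):
            for label, dest, dorient, mult in graph.outgoing(code, orient):
                assert graph.oriented_kmer(code, orient) + label in haystack


def test_round2_coverage_recount(small_reads):
    params = sa.GraphParams(k=31, g=15, node_min_cov=0)
    graph = sa.select_nodes(small_reads, params)
    sa.build_links(small_reads, graph)
    counts = oracles.canonical_kmer_counts([r.seq for r in small_reads], 31)
    for code in list(graph.iter_codes())[:200]:
        assert graph.nodes[code].cov == counts[graph.kmer(code)]


def test_sparsity_band(small_reads):
    counts = {}
    for g in (1, 5, 10):
        params = sa.GraphParams(k=31, g=g, node_min_cov=0)
        counts[g] = sg.node_count(sa.select_nodes(small_reads, params))
    for g in (5, 10):
        ratio = counts[g] / counts[1]
        assert 1 / (1.2 * g) <= ratio <= 1 / (0.8 * g)


def test_overlap_capture(small_genome, small_reads):
    k, g = 31, 15
    params = sa.GraphParams(k=k, g=g, node_min_cov=0)
    graph = sa.select_nodes(small_reads, params)
    by_start = sorted(
        (int(r.id.split("_pos_")[1].split("_")[0]), r.id) for r in small_reads
    )
    checked = 0
    for (s1, _), (s2, _) in zip(by_start, by_start[1:]):
        overlap = s1 + 100 - s2
        if overlap < k + g:
            continue
        window = small_genome[s2 : s1 + 100]
        codes, _, valid = seqio.canonical_codes(window, k)
        assert any(int(c) in graph.nodes for c, v in zip(codes, valid) if v)
        checked += 1
        if checked >= 200:
            break
    assert checked >= 100


# -- memory model -----------------------------------------------------------


def test_estimate_memory_values():
    est = sa.estimate_memory(sa.GraphParams(k=31, g=16), 3e9)
    assert est.s1_bits == 3e9 * 70  # 2.1e11
    est = sa.estimate_memory(sa.GraphParams(k=31, g=16), 1e6, ptr_sz=64)
    assert est.s2_bits == 11_875_000  # 62_500 * 190


def test_estimate_memory_dense_limit():
    est = sa.estimate_memory(sa.GraphParams(k=31, g=1), 1e6, ptr_sz=4)
    assert est.s2_bits == est.s1_bits == 1e6 * 70


def test_estimate_memory_decreasing_in_g():
    vals = [
        sa.estimate_memory(sa.GraphParams(k=31, g=g), 1e8).s2_bits
        for g in range(1, 31)
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_estimate_memory_validation():
    with pytest.raises(ValueError):
        sa.estimate_memory(sa.GraphParams(k=31, g=4), 0)
    with pytest.raises(ValueError):
        sa.estimate_memory(sa.GraphParams(k=31, g=4), 1e6, ptr_sz=-1)


# -- dump / load ------------------------------------------------------------


def test_graph_dump_roundtrip(toy_graph, tmp_path):
    p = tmp_path / "graph.tsv"
    sg.write_graph_tsv(toy_graph, p)
    back = sg.load_graph_tsv(p)
    assert back.params.k == 3 and back.params.g == 2
    assert set(back.nodes) == set(toy_graph.nodes)
    for code in toy_graph.iter_codes():
        a, b = toy_graph.nodes[code], back.nodes[code]
        assert a.cov == b.cov
        assert a.side_view(sg.LEFT) == b.side_view(sg.LEFT)
        assert a.side_view(sg.RIGHT) == b.side_view(sg.RIGHT)


def test_graph_dump_deterministic_order(toy_graph, tmp_path):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    sg.write_graph_tsv(toy_graph, p1)
    sg.write_graph_tsv(toy_graph, p2)
    assert p1.read_text() == p2.read_text()
    kmers = [line.split("\t")[0] for line in p1.read_text().splitlines()[2:]]
    assert kmers == sorted(kmers)
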