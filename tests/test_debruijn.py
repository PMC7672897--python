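import pytest

from cloverasm.consensus_split import ConsensusNode, build_consensus_set
from cloverasm.debruijn import (
    AssemblyGraph,
    build_graph,
    compact,
    pop_bubbles,
    prune_tips,
    remove_erroneous_connections,
    trim_low_frequency_edges,
)
from cloverasm.kmer_clustering import canonical, cluster_kmers, extract_kmers
from cloverasm.pipeline import RunConfig, assemble
from cloverasm.read_io import ReadRecord, reverse_complement
from cloverasm.simulate import SimConfig, pairs_to_records, random_genome, simulate_pair_records

from oracles import textbook_debruijn


def nodes_of(*seqs):
    return [ConsensusNode(s, members=[(canonical(s)[0], canonical(s)[1], 1)]) for s in seqs]


def graph_edges_as_seq_pairs(graph):
    pairs = set()
    for a, _sa, b, _sb in graph.edges:
        sa_, sb_ = graph.nodes[a].seq, graph.nodes[b].seq
        pairs.add((sa_, sb_) if sa_ <= sb_ else (sb_, sa_))
    return pairs


class TestBuildGraph:
    def test_simple_overlap_edge(self):
        graph = build_graph(nodes_of("GGTCT", "GTCTA"))
        assert len(graph.nodes) == 2
        assert len(graph.edges) == 1

    def test_homopolymer_self_loop(self):
        graph = build_graph(nodes_of("AAAAA"))
        assert len(graph.edges) == 1
        ((a, _sa, b, _sb),) = graph.edges
        assert a == b

    def test_matches_textbook_construction(self):
        sim = SimConfig(genome_length=300, seed=5, error_rate=0.0)
        genome = random_genome(sim)
        k = 7
        table = extract_kmers([ReadRecord("g", genome)], k)
        nodes, _ = build_consensus_set(cluster_kmers(table, 0), 0.6)
        graph = build_graph(nodes, table)
        oracle_kmers, oracle_edges = textbook_debruijn([genome], k)
        assert {n.seq for n in graph.nodes.values()} == oracle_kmers
        assert graph_edges_as_seq_pairs(graph) == oracle_edges


class TestCompact:
    def test_chain_merges_to_single_node(self):
        graph = build_graph(nodes_of("ACCTG", "CCTGA", "CTGAG"))
        merged = compact(graph)
        assert len(merged.nodes) == 1
        (node,) = merged.nodes.values()
        assert node.seq in ("ACCTGAG", reverse_complement("ACCTGAG"))

    def test_branch_blocks_merge(self):
        graph = build_graph(nodes_of("ACCTG", "CCTGA", "CCTGT"))
        merged = compact(graph)
        assert len(merged.nodes) == 3

    def test_idempotent(self):
        graph = build_graph(nodes_of("ACCTG", "CCTGA", "CTGAG", "CCTGT"))
        once = compact(graph)
        twice = compact(once)
        assert once.sequences() == twice.sequences()
        assert len(once.edges) == len(twice.edges)

    def test_cycle_compacts_with_self_loop(self):
        # circular 8-mer: k-mers of seq+seq wrap around
        cyc = "ACGGTCAT"
        k = 5
        table = extract_kmers([ReadRecord("c", cyc + cyc[: k - 1])], k)
        nodes, _ = build_consensus_set(cluster_kmers(table, 0), 0.6)
        merged = compact(build_graph(nodes, table))
        assert len(merged.nodes) == 1
        assert len(merged.edges) == 1

    def test_coverage_is_kmer_weighted_mean(self):
        graph = AssemblyGraph(5)
        a = graph.add_node("ACGTA", cov=10, nk=1)
        b = graph.add_node("CGTAC", cov=30, nk=1)
        # orient explicitly: ACGTA forward ends with CGTA = prefix of CGTAC
        graph.add_edge(a, "ACGTA" == graph.nodes[a].seq, b, "CGTAC" == graph.nodes[b].seq)
        merged = compact(graph)
        (node,) = merged.nodes.values()
        assert node.cov == pytest.approx(20.0)


class TestTrim:
    def make(self, freq, cs):
        graph = AssemblyGraph(5)
        a = graph.add_node("ACGTA", cov=10)
        b = graph.add_node("CGTAC", cov=10)
        graph.add_edge(a, True, b, True, freq=freq)
        return trim_low_frequency_edges(graph, cs)

    def test_below_cutoff_removed(self):
        assert len(self.make(freq=4, cs=5).edges) == 0

    def test_at_cutoff_kept(self):
        assert len(self.make(freq=5, cs=5).edges) == 1

    def test_cs_zero_is_noop(self):
        assert len(self.make(freq=0, cs=0).edges) == 1

    def test_isolated_low_coverage_nodes_dropped(self):
        graph = AssemblyGraph(5)
        graph.add_node("ACGTA", cov=2)
        graph.add_node("CGTAC", cov=9)
        trim_low_frequency_edges(graph, 5)
        assert graph.sequences() == [min("CGTAC", reverse_complement("CGTAC"))]


def snp_spur_graph():
    """Genome path with one low-frequency dead-end spur at a junction."""
    sim = SimConfig(genome_length=400, seed=9, error_rate=0.0)
    genome = random_genome(sim)
    k = 15
    # 30 perfect copies plus one read carrying a final-base mutation
    pos = 200
    mutated = genome[pos : pos + k - 1] + ("A" if genome[pos + k - 1] != "A" else "C")
    reads = [ReadRecord(f"r{i}", genome) for i in range(30)]
    reads.append(ReadRecord("err", mutated))
    table = extract_kmers(reads, k)
    nodes, _ = build_consensus_set(cluster_kmers(table, 0), 0.6)
    return compact(build_graph(nodes, table)), genome


class TestPruneTips:
    def test_spur_removed(self):
        graph, genome = snp_spur_graph()
        assert len(graph.nodes) > 1
        cleaned = prune_tips(graph, max_tip_len=2 * 15)
        assert len(cleaned.nodes) == 1
        (node,) = cleaned.nodes.values()
        assert node.seq in (genome, reverse_complement(genome))

    def test_linear_chain_untouched(self):
        graph = compact(build_graph(nodes_of("ACCTG", "CCTGA", "CTGAG")))
        assert prune_tips(graph, 100).sequences() == graph.sequences()

    def test_equal_frequency_tie_removes_smaller_sequence(self):
        graph = AssemblyGraph(5)
        j = graph.add_node("AACGT", cov=10)
        t1 = graph.add_node("ACGTA", cov=10)  # canonical ACGTA
        t2 = graph.add_node("ACGTC", cov=10)
        jf = graph.nodes[j].seq == "AACGT"
        graph.add_edge(j, jf, t1, graph.nodes[t1].seq == "ACGTA", freq=3)
        graph.add_edge(j, jf, t2, graph.nodes[t2].seq == "ACGTC", freq=3)
        cleaned = prune_tips(graph, 100)
        survivors = cleaned.sequences()
        # the lexicographically smaller tip (ACGTA) goes; ACGTC path remains
        assert any("ACGTC" in s or reverse_complement("ACGTC") in s for s in survivors)
        assert not any(s == "ACGTA" for s in survivors)


def manual_bubble():
    """S branches into near-identical A/B (freqs 20 vs 2) reconverging at T;
    stubs keep S and T as junctions so the popped edges stay observable."""
    g = AssemblyGraph(5)
    seqs = {"S": "AACGT", "A": "ACGTCTGCA", "B": "ACGTGTGCA", "T": "TGCAA",
            "C": "ACGTT", "D": "TTGCA"}
    ids = {}
    orient = {}
    for name, seq in seqs.items():
        ids[name] = g.add_node(seq, cov=10, nk=len(seq) - 4)
        orient[name] = g.nodes[ids[name]].seq == seq
    def edge(x, y, freq):
        g.add_edge(ids[x], orient[x], ids[y], orient[y], freq=freq)
    edge("S", "A", 20)
    edge("A", "T", 20)
    edge("S", "B", 2)
    edge("B", "T", 2)
    edge("S", "C", 30)
    edge("D", "T", 30)
    return g, ids


class TestPopBubbles:
    def test_snp_bubble_pops_onto_survivor(self):
        g, ids = manual_bubble()
        out = pop_bubbles(g, max_bubble_len=20, min_identity=0.85)
        seqs = out.sequences()
        assert not any("ACGTGTGCA" in s or reverse_complement("ACGTGTGCA") in s
                       for s in seqs)
        # survivor's edges absorbed the popped path's frequency: 20 + 2
        freqs = sorted(e.freq for e in out.edges.values())
        assert 22 in freqs

    def test_low_identity_keeps_both(self):
        g, _ = manual_bubble()
        out = pop_bubbles(g, max_bubble_len=20, min_identity=0.95)
        assert len(out.nodes) == 6

    def test_no_parallel_paths_unchanged(self):
        graph = build_graph(nodes_of("ACCTG", "CCTGA", "CTGAG"))
        out = pop_bubbles(graph, 100, 0.9)
        assert out.sequences() == graph.sequences()


class TestErroneousConnections:
    def test_chimeric_link_removed(self):
        g = AssemblyGraph(5)
        a = g.add_node("AAACCCGGGTTTACG", cov=30, nk=11)
        b = g.add_node("CATGGATCCATGCAT", cov=30, nk=11)
        g.add_edge(a, True, b, True, freq=1)
        out = remove_erroneous_connections(g, cs=5)
        assert len(out.edges) == 0
        assert len(out.nodes) == 2

    def test_uniform_support_unchanged(self):
        g = AssemblyGraph(5)
        a = g.add_node("ACGTA", cov=30)
        b = g.add_node("CGTAC", cov=30)
        g.add_edge(a, g.nodes[a].seq == "ACGTA", b, g.nodes[b].seq == "CGTAC", freq=30)
        out = remove_erroneous_connections(g, cs=5)
        assert len(out.edges) == 1


class TestPipelineLevelInvariants:
    def test_cleaning_is_monotone(self):
        sim = SimConfig(genome_length=2000, read_length=100, coverage=30,
                        error_rate=0.01, insert_mean=300, seed=13)
        genome = random_genome(sim)
        reads = pairs_to_records(simulate_pair_records(genome, sim))
        k = 21
        table = extract_kmers(reads, k)
        nodes, _ = build_consensus_set(cluster_kmers(table, 0), 0.6)
        graph = compact(build_graph(nodes, table))
        counts = [(len(graph.nodes), len(graph.edges))]
        graph = trim_low_frequency_edges(graph, 5)
        counts.append((len(graph.nodes), len(graph.edges)))
        graph = compact(graph)
        graph = prune_tips(graph, 2 * k)
        counts.append((len(graph.nodes), len(graph.edges)))
        graph = pop_bubbles(graph, 3 * k, 0.9)
        counts.append((len(graph.nodes), len(graph.edges)))
        for (n0, e0), (n1, e1) in zip(counts, counts[1:]):
            assert n1 <= n0 and e1 <= e0

    def test_strand_symmetry(self):
        sim = SimConfig(genome_length=2000, read_length=100, coverage=30,
                        error_rate=0.0, insert_mean=300, seed=17)
        genome = random_genome(sim)
        reads = pairs_to_records(simulate_pair_records(genome, sim))
        flipped = [ReadRecord(r.id, reverse_complement(r.sequence)) for r in reads]
        res_fwd = assemble(reads, RunConfig(k=31, p=0, cs=0))
        res_rev = assemble(flipped, RunConfig(k=31, p=0, cs=0))
        canon = lambda seqs: sorted(min(s, reverse_complement(s)) for s in seqs)
        assert canon(res_fwd.contigs) == canon(res_rev.contigs)

    def test_end_to_end_single_unitig(self, errorfree_20kb):
        scenario = errorfree_20kb
        assert len(scenario.result.contigs) == 1
        contig = scenario.result.contigs[0]
        assert contig in scenario.genome or reverse_complement(contig) in scenario.genome
        assert len(contig) >= 0.995 * len(scenario.genome)
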