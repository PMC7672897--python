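"""End-to-end assembly pipeline.

extract k-mers -> cluster (skipped when p = 0) -> consensus + split ->
de Bruijn graph -> clean (spectral trim, tips, bubbles, erroneous
connections) -> sub-k extension -> read threading -> contigs ->
paired-end links -> scaffolds.  The run is fully deterministic: re-running
with the same configuration and inputs is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from cloverasm import debruijn, scaffolding
from cloverasm.consensus_split import build_consensus_set
from cloverasm.extension import default_m, extend_graph
from cloverasm.kmer_clustering import cluster_kmers, extract_kmers
from cloverasm.read_io import LibrarySpec, ReadRecord, parse_libraries, write_fasta
from cloverasm.stats import AssemblyStats, summarize

logger = logging.getLogger("cloverasm")


@dataclass
class RunConfig:
    """All assembly parameters with their defaults.

    k: k-mer length; p: Hamming error allowance on k-mers; sp: node-split
    threshold; cs: spectral low-frequency cutoff; ss: scaffold support;
    m: minimum extension overlap (defaults to floor(k/2)+1); ml: minimum
    output sequence length.
    """

    k: int
    p: int = 0
    sp: float = 0.6
    cs: int = 5
    ss: int = 5
    m: Optional[int] = None
    ml: int = 0
    libraries: List[LibrarySpec] = field(default_factory=list)
    seed: int = 0
    out_prefix: str = "out"
    genome_size: Optional[int] = None
    max_tip_len: Optional[int] = None       # default 2k
    max_bubble_len: Optional[int] = None    # default 3k
    min_bubble_identity: float = 0.9

    def validate(self, require_libraries: bool = True) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.p < 0 or self.k < self.p + 1:
            raise ValueError("need 0 <= p <= k - 1")
        if not 0 < self.sp <= 1:
            raise ValueError("sp must be in (0, 1]")
        m = self.m if self.m is not None else default_m(self.k)
        if m > self.k - 1:
            raise ValueError("minimum overlap m must be <= k - 1")
        if require_libraries and not self.libraries:
            raise ValueError("at least one input library is required")


@dataclass
class PipelineResult:
    contigs: List[str]
    scaffolds: List[str]
    contig_stats: AssemblyStats
    scaffold_stats: AssemblyStats
    contig_path: Optional[Path] = None
    scaffold_path: Optional[Path] = None
    graph: Optional[debruijn.AssemblyGraph] = None
    coverages: List[float] = field(default_factory=list)


def _log_stage(name: str, started: float, graph: Optional[debruijn.AssemblyGraph] = None) -> None:
    extra = ""
    if graph is not None:
        extra = f" nodes={len(graph.nodes)} edges={len(graph.edges)}"
    logger.info("%s done in %.2fs%s", name, time.perf_counter() - started, extra)


def assemble(reads: Sequence[ReadRecord], config: RunConfig) -> PipelineResult:
    """Assemble an in-memory read set (the library files already parsed)."""
    config.validate(require_libraries=False)
    k = config.k
    t = time.perf_counter()
    table = extract_kmers(reads, k)
    logger.info("extracted %d distinct k-mers (%d occurrences)",
                len(table.counts), table.total_occurrences)

    t = time.perf_counter()
    clusters = cluster_kmers(table, config.p)
    logger.info("clustering (p=%d): %d clusters from %d k-mers in %.2fs",
                config.p, len(clusters), len(table.counts), time.perf_counter() - t)

    t = time.perf_counter()
    nodes, _member_map = build_consensus_set(clusters, config.sp)
    logger.info("consensus set: %d k-mers (sp=%s) in %.2fs",
                len(nodes), config.sp, time.perf_counter() - t)

    t = time.perf_counter()
    graph = debruijn.build_graph(nodes, table)
    _log_stage("graph construction", t, graph)

    t = time.perf_counter()
    graph = debruijn.compact(graph)
    graph = debruijn.trim_low_frequency_edges(graph, config.cs)
    graph = debruijn.compact(graph)
    graph = debruijn.prune_tips(graph, config.max_tip_len or 2 * k)
    graph = debruijn.pop_bubbles(graph, config.max_bubble_len or 3 * k,
                                 config.min_bubble_identity)
    graph = debruijn.remove_erroneous_connections(graph, config.cs)
    _log_stage("cleaning", t, graph)

    t = time.perf_counter()
    m = config.m if config.m is not None else default_m(k)
    graph = extend_graph(graph, m)
    _log_stage(f"extension to m={m}", t, graph)

    t = time.perf_counter()
    votes = scaffolding.thread_reads(graph, reads)
    graph = scaffolding.resolve_junctions(graph, votes)
    _log_stage("read threading", t, graph)

    contig_map: Dict[int, str] = {nid: graph.nodes[nid].seq for nid in sorted(graph.nodes)}

    t = time.perf_counter()
    anchors = scaffolding.map_reads(reads, graph)
    pairs = scaffolding.pair_anchors(list(reads), anchors)
    insert_sizes = [lib.insert_size for lib in config.libraries] or [0]
    # shortest-insert libraries first, then stronger support first
    links: List[scaffolding.ScaffoldLink] = []
    for lib_index, _ in sorted(enumerate(insert_sizes), key=lambda x: x[1]):
        lib_pairs = [pr for pr in pairs if pr[0].library_index == lib_index]
        if lib_pairs:
            links.extend(scaffolding.infer_links(lib_pairs, graph, insert_sizes, config.ss))
    logger.info("scaffolding: %d anchors, %d anchored pairs, %d links in %.2fs",
                len(anchors), len(pairs), len(links), time.perf_counter() - t)

    scaffolds = scaffolding.build_scaffolds(contig_map, links, config.ml)
    cov_by_seq = {graph.nodes[nid].seq: graph.nodes[nid].cov for nid in graph.nodes}
    contigs = sorted((s for s in contig_map.values() if len(s) >= config.ml),
                     key=lambda s: (-len(s), s))
    coverages = [cov_by_seq.get(s, 0.0) for s in contigs]

    contig_stats = summarize([len(c) for c in contigs], config.genome_size)
    scaffold_stats = summarize([len(s) for s in scaffolds], config.genome_size)
    return PipelineResult(contigs, scaffolds, contig_stats, scaffold_stats,
                          graph=graph, coverages=coverages)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Parse the configured libraries, assemble, and write the outputs."""
    config.validate()
    reads = list(parse_libraries(config.libraries))
    logger.info("parsed %d reads from %d libraries", len(reads), len(config.libraries))
    result = assemble(reads, config)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True) if prefix.parent != Path(".") else None
    contig_path = prefix.parent / (prefix.name + "_contig.fasta")
    scaffold_path = prefix.parent / (prefix.name + "_scaffold.fasta")
    write_fasta(contig_path,
                ((f"contig_{i + 1} length={len(c)} cov={cov:.1f}", c)
                 for i, (c, cov) in enumerate(zip(result.contigs, result.coverages))))
    write_fasta(scaffold_path,
                ((f"scaffold_{i + 1} length={len(s)}", s)
                 for i, s in enumerate(result.scaffolds)))
    result.contig_path = contig_path
    result.scaffold_path = scaffold_path
    print(result.contig_stats.table("Contigs"))
    print(result.scaffold_stats.table("Scaffolds"))
    return result
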