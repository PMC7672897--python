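"""Sub-k overlap extension of unitig ends.

After cleaning, contiguity is often limited by junctions that spectral
trimming removed entirely, leaving free unitig ends whose sequences still
overlap exactly — just by less than k - 1 bases.  Extension joins such
ends greedily from the longest overlap (k - 1) down to a minimum overlap
``m``, defaulting to floor(k/2) + 1, and only when the match is mutually
unique: an end with two equally good partners (or a partner wanted by two
ends) is never joined.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from cloverasm.debruijn import AssemblyGraph, compact


def default_m(k: int) -> int:
    """Default minimum extension overlap, floor(k/2) + 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return k // 2 + 1


def extend_graph(graph: AssemblyGraph, m: int) -> AssemblyGraph:
    """Join free unitig ends sharing a unique exact overlap in [m, k-1].

    Overlap lengths are tried longest first; after each round the graph is
    re-compacted so newly merged nodes can participate in shorter-overlap
    joins.  Self-joins are forbidden.
    """
    k = graph.k
    if m > k - 1:
        return graph
    for overlap in range(k - 1, m - 1, -1):
        tails: Dict[str, List[Tuple[int, bool]]] = {}
        heads: Dict[str, List[Tuple[int, bool]]] = {}
        for nid in graph.node_ids():
            seq_len = len(graph.nodes[nid].seq)
            if seq_len < overlap:
                continue
            for fwd in (True, False):
                if graph.degree(nid, fwd) == 0:
                    oseq = graph.seq(nid, fwd)
                    # a free (nid, fwd) end can emit (tail flank) and the
                    # opposite orientation can accept (head flank)
                    tails.setdefault(oseq[-overlap:], []).append((nid, fwd))
                    heads.setdefault(graph.seq(nid, not fwd)[:overlap], []).append((nid, not fwd))
        joined = False
        for flank in sorted(tails):
            tail_ends = tails[flank]
            head_ends = heads.get(flank, [])
            if len(tail_ends) != 1 or len(head_ends) != 1:
                continue
            (a, sa), (b, sb) = tail_ends[0], head_ends[0]
            if a == b:
                continue
            if graph.degree(a, sa) or graph.degree(b, not sb):
                continue  # consumed by an earlier join this round
            graph.add_edge(a, sa, b, sb, freq=0, overlap=overlap)
            joined = True
        if joined:
            graph = compact(graph)
    return graph
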