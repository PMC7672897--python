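"""Paired-end scaffolding and read-threaded contig prediction.

Both mates of a pair are anchored to unitigs by exact k-mer seeding plus a
near-exact full-length check; pairs whose mates land on different unitigs
vote for an oriented link between them.  A link is accepted when its
support reaches the scaffold-support threshold ``ss``; its gap estimate is
the median of the per-pair inferred gaps (library insert minus the
distance covered on both unitigs).  Separately, reads that thread across
graph junctions vote for in-edge/out-edge pairings; junctions where the
spanning reads are unanimous (and at least two per pairing) are split so
each genome copy of the junction sequence gets its own node — the
read-coherent walks of the graph that contigs are read off from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from cloverasm.debruijn import AssemblyGraph, EdgeKey, _norm_edge, compact
from cloverasm.read_io import ReadRecord, reverse_complement


@dataclass(frozen=True)
class Anchor:
    """A full-length placement of one read on one node."""

    read_id: str
    node_id: int
    offset: int       # 0-based start on the node's forward strand
    forward: bool     # read sequence matches the forward strand?
    length: int
    library_index: int = 0


@dataclass(frozen=True)
class ScaffoldLink:
    """An oriented pairing of two nodes: sa-oriented a precedes sb-oriented b."""

    node_a: int
    side_a: bool
    node_b: int
    side_b: bool
    support: int
    gap: int
    library_index: int = 0


def _node_kmer_index(graph: AssemblyGraph) -> Dict[str, List[Tuple[int, int]]]:
    index: Dict[str, List[Tuple[int, int]]] = {}
    k = graph.k
    for nid in sorted(graph.nodes):
        seq = graph.nodes[nid].seq
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((nid, i))
    return index


def _mismatches(a: str, b: str, cap: int) -> Optional[int]:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return None
    return d


def map_reads(reads: Iterable[ReadRecord], graph: AssemblyGraph,
              max_mismatch_frac: float = 0.05,
              index: Optional[Dict[str, List[Tuple[int, int]]]] = None) -> List[Anchor]:
    """Place each read wholly on a single node, or not at all.

    Seeding uses the first and last k-mer of the read (both orientations);
    a seeded placement is accepted when at least 95% of the read's bases
    match the node at the implied offset and the read fits entirely on the
    node.  Reads with accepted placements on more than one node are
    repeat-ambiguous and dropped.
    """
    if index is None:
        index = _node_kmer_index(graph)
    k = graph.k
    anchors: List[Anchor] = []
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            continue
        cap = int(max_mismatch_frac * len(seq))
        rc = reverse_complement(seq)
        placements = set()
        for oriented_read, fwd in ((seq, True), (rc, False)):
            for probe in (0, len(oriented_read) - k):
                for nid, i in index.get(oriented_read[probe : probe + k], ()):
                    off = i - probe
                    node_seq = graph.nodes[nid].seq
                    if off < 0 or off + len(seq) > len(node_seq):
                        continue
                    if _mismatches(node_seq[off : off + len(seq)], oriented_read, cap) is None:
                        continue
                    placements.add((nid, off, fwd))
        if not placements:
            continue
        nodes_hit = {nid for nid, _, _ in placements}
        if len(nodes_hit) > 1:
            continue
        nid, off, fwd = min(placements)
        anchors.append(Anchor(read.id, nid, off, fwd, len(seq), read.library_index))
    return anchors


def pair_anchors(reads: Sequence[ReadRecord], anchors: Sequence[Anchor]
                 ) -> List[Tuple[Anchor, Anchor]]:
    """Join anchors of mate-1/mate-2 reads, preserving read order."""
    by_id = {a.read_id: a for a in anchors}
    pairs: List[Tuple[Anchor, Anchor]] = []
    seen = set()
    for read in reads:
        if read.mate is None or read.id in seen:
            continue
        seen.add(read.id)
        seen.add(read.mate.id)
        a1 = by_id.get(read.id)
        a2 = by_id.get(read.mate.id)
        if a1 is not None and a2 is not None:
            pairs.append((a1, a2))
    return pairs


def infer_links(anchor_pairs: Sequence[Tuple[Anchor, Anchor]],
                graph: AssemblyGraph, insert_sizes: Sequence[int],
                ss: int) -> List[ScaffoldLink]:
    """Tally oriented link votes from anchor pairs and keep the consistent ones.

    A pair anchored on nodes A and B implies A oriented along the fragment,
    then a gap, then B; the implied gap is the library insert minus the
    fragment distance consumed on each node.  Votes for the same node pair
    but inconsistent orientations are tallied separately.  Links need
    support >= ss; when two links claim the same node end, only the
    strongest survives (ties drop the lexicographically later key).
    """
    if ss < 1:
        raise ValueError("ss must be >= 1")
    votes: Dict[Tuple[int, EdgeKey], List[int]] = {}
    for a1, a2 in anchor_pairs:
        if a1.node_id == a2.node_id:
            continue
        insert = insert_sizes[a1.library_index]
        len_a = len(graph.nodes[a1.node_id].seq)
        len_b = len(graph.nodes[a2.node_id].seq)
        o_a = a1.forward
        o_b = not a2.forward
        span_a = (len_a - a1.offset) if o_a else (a1.offset + a1.length)
        span_b = (a2.offset + a2.length) if o_b else (len_b - a2.offset)
        gap = insert - span_a - span_b
        key = _norm_edge(a1.node_id, o_a, a2.node_id, o_b)
        votes.setdefault((a1.library_index, key), []).append(gap)

    links: List[ScaffoldLink] = []
    for (lib, key), gaps in sorted(votes.items()):
        if len(gaps) < ss:
            continue
        gaps_sorted = sorted(gaps)
        gap = gaps_sorted[(len(gaps_sorted) - 1) // 2]  # lower median
        a, sa, b, sb = key
        links.append(ScaffoldLink(a, sa, b, sb, len(gaps), gap, lib))

    # resolve end conflicts: strongest link per physical node end
    links.sort(key=lambda l: (-l.support, l.node_a, l.side_a, l.node_b, l.side_b))
    used_ends = set()
    kept: List[ScaffoldLink] = []
    for link in links:
        end_a = (link.node_a, link.side_a)
        end_b = (link.node_b, not link.side_b)
        if end_a in used_ends or end_b in used_ends:
            continue
        used_ends.add(end_a)
        used_ends.add(end_b)
        kept.append(link)
    return kept


# ---------------------------------------------------------------------
# read threading / Eulerian contig prediction


def _walk_read(graph: AssemblyGraph, read: str, nid: int, fwd: bool,
               offset: int) -> Optional[List[EdgeKey]]:
    """Follow ``read`` exactly through the graph from a seeded placement;
    return the edges crossed, or None if the walk fails or is ambiguous."""
    seq = graph.seq(nid, fwd)
    avail = len(seq) - offset
    if avail >= len(read):
        return [] if seq[offset : offset + len(read)] == read else None
    if seq[offset:] != read[:avail]:
        return None
    rpos = avail
    cur = (nid, fwd)
    edges: List[EdgeKey] = []
    while rpos < len(read):
        candidates = []
        for key, b, sb, _freq, ov in graph.out_edges(*cur):
            bseq = graph.seq(b, sb)
            need = min(len(bseq) - ov, len(read) - rpos)
            if need > 0 and bseq[ov : ov + need] == read[rpos : rpos + need]:
                candidates.append((key, b, sb, need))
        if len(candidates) != 1:
            return None
        key, b, sb, need = candidates[0]
        edges.append(key)
        cur = (b, sb)
        rpos += need
    return edges


def thread_reads(graph: AssemblyGraph, reads: Iterable[ReadRecord]
                 ) -> Dict[Tuple[int, FrozenSet[EdgeKey]], int]:
    """Count, per junction node, how often a read links two of its edges."""
    index = _node_kmer_index(graph)
    k = graph.k
    votes: Dict[Tuple[int, FrozenSet[EdgeKey]], int] = {}
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            continue
        for oriented_read in (seq, reverse_complement(seq)):
            placements = index.get(oriented_read[:k], ())
            if len(placements) != 1:
                continue
            nid, i = placements[0]
            # the seed k-mer fixes the node orientation: forward placement
            edges = _walk_read(graph, oriented_read, nid, True, i)
            if not edges or len(edges) < 2:
                continue
            # walk path: nid -> via edges; middle nodes get pairing votes
            path_nodes = [nid]
            cur = (nid, True)
            for key in edges:
                for ekey, b, sb, _f, _ov in graph.out_edges(*cur):
                    if ekey == key:
                        cur = (b, sb)
                        break
                path_nodes.append(cur[0])
            for j in range(1, len(edges)):
                mid = path_nodes[j]
                pair = frozenset((edges[j - 1], edges[j]))
                if len(pair) == 2:
                    vkey = (mid, pair)
                    votes[vkey] = votes.get(vkey, 0) + 1
            break  # one orientation placed is enough
    return votes


def resolve_junctions(graph: AssemblyGraph,
                      votes: Dict[Tuple[int, FrozenSet[EdgeKey]], int],
                      min_reads: int = 2) -> AssemblyGraph:
    """Split junction nodes whose crossings are unanimously read-supported.

    A junction with in-edges I (head side) and out-edges O (tail side) is
    resolved only when the voted pairings form a perfect I<->O matching
    with every pairing seen in >= ``min_reads`` reads; the node is then
    duplicated once per pairing.  Anything less leaves the junction intact,
    which cuts contigs there.
    """
    by_node: Dict[int, List[Tuple[FrozenSet[EdgeKey], int]]] = {}
    for (nid, pair), count in votes.items():
        by_node.setdefault(nid, []).append((pair, count))

    for nid in sorted(by_node):
        if nid not in graph.nodes:
            continue
        head = {key for key, *_ in graph.out_edges(nid, False)}
        tail = {key for key, *_ in graph.out_edges(nid, True)}
        if len(head) < 2 and len(tail) < 2:
            continue
        if any(a == b for (a, _sa, b, _sb) in head | tail):
            continue  # self-loops: leave alone
        pairings = [(p, c) for p, c in by_node[nid] if c >= min_reads]
        if any(c < min_reads for _p, c in by_node[nid]):
            continue  # conflicting weakly-supported crossing: not unanimous
        pair_edges = [tuple(sorted(p)) for p, _c in pairings]
        flat = [e for p in pair_edges for e in p]
        if len(flat) != len(set(flat)):
            continue  # an edge voted into two pairings
        if len(pairings) != len(head) or len(pairings) != len(tail):
            continue  # not a perfect matching over all edges
        if not all((p & head) and (p & tail) for p, _c in pairings):
            continue
        node = graph.nodes[nid]
        stale = False
        for p, _c in pairings:
            if any(e not in graph.edges for e in p):
                stale = True
        if stale:
            continue
        for p, _c in sorted(pairings, key=lambda x: tuple(sorted(x[0]))):
            copy_id = graph.add_node(node.seq, cov=node.cov / len(pairings), nk=node.nk)
            for ekey in sorted(p):
                a, sa, b, sb = ekey
                edge = graph.edges[ekey]
                na, nb = a, b
                if na == nid:
                    na = copy_id
                elif nb == nid:
                    nb = copy_id
                graph.add_edge(na, sa, nb, sb, freq=edge.freq, overlap=edge.overlap)
        graph.remove_node(nid)
    return compact(graph)


def eulerian_contigs(graph: AssemblyGraph, reads: Sequence[ReadRecord]
                     ) -> Tuple[AssemblyGraph, List[str]]:
    """Thread reads through junctions, then read contigs off the graph."""
    votes = thread_reads(graph, reads)
    resolved = resolve_junctions(graph.copy(), votes)
    return resolved, resolved.sequences()


# ---------------------------------------------------------------------
# scaffold construction


def build_scaffolds(contigs: Dict[int, str], links: Sequence[ScaffoldLink],
                    ml: int = 0) -> List[str]:
    """Chain contigs along links (strongest first) into scaffold sequences.

    Gaps are rendered as runs of N of length max(gap, 1); negative gaps are
    not merged — a single N marks the junction.  Scaffolds and standalone
    contigs shorter than ``ml`` are not emitted.
    """
    chains: Dict[int, List] = {}
    chain_of: Dict[int, int] = {}
    gaps: Dict[int, List[int]] = {}
    for idx, nid in enumerate(sorted(contigs)):
        chains[idx] = [(nid, True)]
        gaps[idx] = []
        chain_of[nid] = idx

    def reverse_chain(idx: int) -> None:
        chains[idx] = [(n, not o) for n, o in reversed(chains[idx])]
        gaps[idx] = list(reversed(gaps[idx]))

    ordered = sorted(links, key=lambda l: (-l.support, l.node_a, l.side_a,
                                           l.node_b, l.side_b))
    for link in ordered:
        ca = chain_of.get(link.node_a)
        cb = chain_of.get(link.node_b)
        if ca is None or cb is None or ca == cb:
            continue
        # orient chain a so its tail end is (node_a, side_a)
        last, o_last = chains[ca][-1]
        first, o_first = chains[ca][0]
        if last == link.node_a and o_last == link.side_a:
            pass
        elif first == link.node_a and o_first == (not link.side_a):
            reverse_chain(ca)
        else:
            continue  # the needed end is interior: conflicting link, drop
        first, o_first = chains[cb][0]
        last, o_last = chains[cb][-1]
        if first == link.node_b and o_first == link.side_b:
            pass
        elif last == link.node_b and o_last == (not link.side_b):
            reverse_chain(cb)
        else:
            continue
        chains[ca].extend(chains[cb])
        gaps[ca].append(link.gap)
        gaps[ca].extend(gaps[cb])
        for n, _o in chains[cb]:
            chain_of[n] = ca
        del chains[cb]
        del gaps[cb]

    out: List[str] = []
    for idx in sorted(chains):
        parts = []
        for j, (nid, fwd) in enumerate(chains[idx]):
            seq = contigs[nid] if fwd else reverse_complement(contigs[nid])
            if j > 0:
                parts.append("N" * max(gaps[idx][j - 1], 1))
            parts.append(seq)
        scaffold = "".join(parts)
        if len(scaffold) >= ml:
            out.append(scaffold)
    out.sort(key=lambda s: (-len(s), s))
    return out
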