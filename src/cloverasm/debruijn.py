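"""Bidirected de Bruijn graph: construction, unitig compaction, cleaning.

Each double-stranded sequence is stored once, in canonical orientation
(lexicographic min of the sequence and its reverse complement).  An edge
records an oriented adjacency ``(a, sa) -> (b, sb)`` meaning the
``sa``-oriented sequence of node ``a`` is followed by the ``sb``-oriented
sequence of node ``b`` with a stated overlap; the edge and its
reverse-complement twin ``(b, !sb) -> (a, !sa)`` are the same object, kept
under a normalized key, so traversing a node "flipped" reads its reverse
complement for free.

Edge frequencies come from read adjacencies projected through the k-mer
clusters: an edge's frequency is the number of times two consecutive read
k-mers mapped onto its two consensus nodes.  The spectral cleaning step
trims edges below a frequency cutoff; the structural steps prune tips,
pop bubbles and cut chimera-like low-support connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from cloverasm.consensus_split import ConsensusNode
from cloverasm.kmer_clustering import KmerTable
from cloverasm.read_io import reverse_complement

# an oriented edge: sa/sb True = forward (stored) orientation
EdgeKey = Tuple[int, bool, int, bool]


def _norm_edge(a: int, sa: bool, b: int, sb: bool) -> EdgeKey:
    key = (a, sa, b, sb)
    twin = (b, not sb, a, not sa)
    return key if key <= twin else twin


@dataclass
class _Node:
    seq: str          # canonical orientation
    cov: float        # mean per-k-mer count
    nk: int           # number of k-mer positions folded into the node


@dataclass
class _Edge:
    freq: int
    overlap: int


class AssemblyGraph:
    """Nodes (unitigs) plus bidirected overlap edges."""

    def __init__(self, k: int):
        self.k = k
        self.nodes: Dict[int, _Node] = {}
        self.edges: Dict[EdgeKey, _Edge] = {}
        self._out: Dict[Tuple[int, bool], Set[EdgeKey]] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add_node(self, seq: str, cov: float = 0.0, nk: Optional[int] = None) -> int:
        canon = min(seq, reverse_complement(seq))
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = _Node(canon, cov, nk if nk is not None else max(1, len(seq) - self.k + 1))
        self._out[(nid, True)] = set()
        self._out[(nid, False)] = set()
        return nid

    def add_edge(self, a: int, sa: bool, b: int, sb: bool, freq: int = 0,
                 overlap: Optional[int] = None) -> EdgeKey:
        key = _norm_edge(a, sa, b, sb)
        if key not in self.edges:
            self.edges[key] = _Edge(freq, overlap if overlap is not None else self.k - 1)
            ka, ksa, kb, ksb = key
            self._out[(ka, ksa)].add(key)
            self._out[(kb, not ksb)].add(key)
        else:
            self.edges[key].freq = max(self.edges[key].freq, freq)
        return key

    def remove_edge(self, key: EdgeKey) -> None:
        if key not in self.edges:
            return
        del self.edges[key]
        a, sa, b, sb = key
        self._out[(a, sa)].discard(key)
        self._out[(b, not sb)].discard(key)

    def remove_node(self, nid: int) -> None:
        for fwd in (True, False):
            for key in list(self._out[(nid, fwd)]):
                self.remove_edge(key)
        del self._out[(nid, True)]
        del self._out[(nid, False)]
        del self.nodes[nid]

    def copy(self) -> "AssemblyGraph":
        g = AssemblyGraph(self.k)
        g._next_id = self._next_id
        g.nodes = {i: _Node(n.seq, n.cov, n.nk) for i, n in self.nodes.items()}
        g.edges = {key: _Edge(e.freq, e.overlap) for key, e in self.edges.items()}
        g._out = {end: set(keys) for end, keys in self._out.items()}
        return g

    # -- queries ------------------------------------------------------

    def seq(self, nid: int, forward: bool = True) -> str:
        s = self.nodes[nid].seq
        return s if forward else reverse_complement(s)

    def out_edges(self, nid: int, forward: bool) -> List[Tuple[EdgeKey, int, bool, int, int]]:
        """Edges leaving the oriented end (nid, forward), as
        (key, target, target_orientation, freq, overlap), deterministically ordered."""
        result = []
        for key in sorted(self._out.get((nid, forward), ())):
            a, sa, b, sb = key
            edge = self.edges[key]
            if (a, sa) == (nid, forward):
                result.append((key, b, sb, edge.freq, edge.overlap))
            if (b, not sb) == (nid, forward) and (a, sa) != (nid, forward):
                result.append((key, a, not sa, edge.freq, edge.overlap))
        return result

    def degree(self, nid: int, forward: bool) -> int:
        return len(self.out_edges(nid, forward))

    def node_ids(self) -> List[int]:
        """Node ids in lexicographic order of their canonical sequences."""
        return sorted(self.nodes, key=lambda i: (self.nodes[i].seq, i))

    def sequences(self) -> List[str]:
        return sorted(n.seq for n in self.nodes.values())


# ---------------------------------------------------------------------
# construction from the consensus k-mer set


def build_graph(nodes: Sequence[ConsensusNode], table: Optional[KmerTable] = None) -> AssemblyGraph:
    """De Bruijn graph over consensus k-mers: an edge wherever a
    (k-1)-suffix of one oriented k-mer equals a (k-1)-prefix of another.

    Edge frequencies count the read adjacencies (from ``table``) whose two
    raw k-mers map onto the edge's two consensus nodes; an overlap edge
    with no read support keeps frequency 0.
    """
    if not nodes:
        raise ValueError("empty consensus set")
    k = len(nodes[0].sequence)
    graph = AssemblyGraph(k)
    member_map: Dict[str, Tuple[int, bool]] = {}
    ids: List[int] = []
    for node in nodes:
        if len(node.sequence) != k:
            raise ValueError("all consensus sequences must have equal length")
        nid = graph.add_node(node.sequence, cov=float(node.total_count) or 1.0, nk=1)
        ids.append(nid)
        if node.members:
            for kmer, fwd, _count in node.members:
                member_map[kmer] = (nid, fwd)
        else:
            member_map[graph.nodes[nid].seq] = (nid, True)

    prefix_index: Dict[str, List[Tuple[int, bool]]] = {}
    for nid in ids:
        for fwd in (True, False):
            prefix = graph.seq(nid, fwd)[: k - 1]
            prefix_index.setdefault(prefix, []).append((nid, fwd))

    support: Dict[EdgeKey, int] = {}
    if table is not None:
        for (ca, fa, cb, fb), count in table.adjacencies.items():
            ma = member_map.get(ca)
            mb = member_map.get(cb)
            if ma is None or mb is None:
                continue
            a, oa = ma
            b, ob = mb
            key = _norm_edge(a, fa == oa, b, fb == ob)
            support[key] = support.get(key, 0) + count

    for nid in ids:
        for fwd in (True, False):
            suffix = graph.seq(nid, fwd)[1:]
            for b, sb in prefix_index.get(suffix, ()):
                key = _norm_edge(nid, fwd, b, sb)
                graph.add_edge(*key, freq=support.get(key, 0))
    return graph


# ---------------------------------------------------------------------
# unitig compaction


def _unique_next(graph: AssemblyGraph, nid: int, fwd: bool) -> Optional[Tuple[int, bool, int]]:
    outs = graph.out_edges(nid, fwd)
    if len(outs) != 1:
        return None
    _key, b, sb, _freq, ov = outs[0]
    if b == nid:
        return None
    if len(graph.out_edges(b, not sb)) != 1:
        return None
    return b, sb, ov


def compact(graph: AssemblyGraph) -> AssemblyGraph:
    """Merge every maximal unbranched path into a single unitig node.

    Coverage of a merged node is the k-mer-count-weighted mean of its
    parts; edge topology outside merged paths is preserved.  Idempotent.
    """
    assigned: Dict[int, int] = {}           # old node -> chain index
    chains: List[List[Tuple[int, bool]]] = []
    cyclic: List[bool] = []

    for start in sorted(graph.nodes):
        if start in assigned:
            continue
        chain = [(start, True)]
        members = {start}
        is_cycle = False
        # walk backward from the start
        while True:
            nid, fwd = chain[0]
            prev = _unique_next(graph, nid, not fwd)
            if prev is None:
                break
            pnid, psb, _ov = prev
            if pnid in members:
                is_cycle = pnid == chain[-1][0]
                break
            chain.insert(0, (pnid, not psb))
            members.add(pnid)
        if not is_cycle:
            while True:
                nid, fwd = chain[-1]
                nxt = _unique_next(graph, nid, fwd)
                if nxt is None:
                    break
                nnid, nsb, _ov = nxt
                if nnid in members:
                    is_cycle = nnid == chain[0][0]
                    break
                chain.append((nnid, nsb))
                members.add(nnid)
        idx = len(chains)
        chains.append(chain)
        cyclic.append(is_cycle)
        for nid, _ in chain:
            assigned[nid] = idx

    new = AssemblyGraph(graph.k)
    # endmap: old oriented end -> new oriented end (for surviving chain ends)
    endmap: Dict[Tuple[int, bool], Tuple[int, bool]] = {}
    internal: Set[EdgeKey] = set()

    for chain, is_cycle in zip(chains, cyclic):
        seq_parts = [graph.seq(*chain[0])]
        cov_sum = 0.0
        nk_sum = 0
        for i, (nid, fwd) in enumerate(chain):
            node = graph.nodes[nid]
            cov_sum += node.cov * node.nk
            nk_sum += node.nk
            if i > 0:
                pn, pf = chain[i - 1]
                outs = graph.out_edges(pn, pf)
                (_key, _b, _sb, _f, ov) = outs[0]
                internal.add(_key)
                seq_parts.append(graph.seq(nid, fwd)[ov:])
        merged = "".join(seq_parts)
        canon = min(merged, reverse_complement(merged))
        stored_fwd = merged == canon
        new_id = new.add_node(canon, cov=cov_sum / max(1, nk_sum), nk=nk_sum)
        head = chain[0]
        tail = chain[-1]
        # edges leaving the chain's forward tail now leave (new, stored_fwd);
        # edges leaving the chain's reversed head leave (new, !stored_fwd)
        endmap[(tail[0], tail[1])] = (new_id, stored_fwd)
        endmap[(head[0], not head[1])] = (new_id, not stored_fwd)
        if is_cycle:
            # the closing edge stays external and becomes a self-loop below
            pass

    for key, edge in graph.edges.items():
        if key in internal:
            continue
        a, sa, b, sb = key
        src = endmap.get((a, sa))
        dst_src = endmap.get((b, not sb))  # target end expressed as a source end
        if src is None or dst_src is None:
            # an edge touching a consumed interior end can only be the second
            # registration of an internal chain edge; skip defensively
            continue
        new.add_edge(src[0], src[1], dst_src[0], not dst_src[1], freq=edge.freq,
                     overlap=edge.overlap)
    return new


# ---------------------------------------------------------------------
# cleaning operations


def trim_low_frequency_edges(graph: AssemblyGraph, cs: int) -> AssemblyGraph:
    """Spectral cleaning: drop every edge with frequency < cs, then drop
    nodes left edgeless whose coverage is also < cs."""
    if cs <= 0:
        return graph
    for key in sorted(graph.edges):
        if graph.edges[key].freq < cs:
            graph.remove_edge(key)
    for nid in sorted(graph.nodes):
        if graph.degree(nid, True) == 0 and graph.degree(nid, False) == 0 \
                and graph.nodes[nid].cov < cs:
            graph.remove_node(nid)
    return graph


def _tips(graph: AssemblyGraph, max_tip_len: int):
    """Yield (tip_node, edge_key, junction_end, edge_freq) for dead-end nodes."""
    for nid in graph.node_ids():
        if len(graph.nodes[nid].seq) > max_tip_len:
            continue
        deg_f = graph.degree(nid, True)
        deg_r = graph.degree(nid, False)
        if deg_f == 0 and deg_r == 1:
            attached = False
        elif deg_r == 0 and deg_f == 1:
            attached = True
        else:
            continue
        key, j, sj, freq, _ov = graph.out_edges(nid, attached)[0]
        if j == nid:
            continue
        yield nid, key, (j, not sj), freq


def prune_tips(graph: AssemblyGraph, max_tip_len: int) -> AssemblyGraph:
    """Clip short dead-end branches that compete with a stronger edge.

    A tip is removed when, at its junction end, some alternative edge has
    higher frequency — or equal frequency with a lexicographically larger
    competing sequence (low-frequency edges go first; the residual tie
    break is deterministic).  Iterates to a fixed point, re-compacting
    between rounds.
    """
    while True:
        removed = []
        for nid, key, junction_end, freq in list(_tips(graph, max_tip_len)):
            if nid not in graph.nodes or key not in graph.edges:
                continue
            alternatives = [
                (akey, t, f)
                for akey, t, _st, f, _ov in graph.out_edges(*junction_end)
                if akey != key
            ]
            if not alternatives:
                continue
            myseq = graph.nodes[nid].seq
            for _akey, t, f in alternatives:
                if f > freq or (f == freq and graph.nodes[t].seq > myseq):
                    removed.append(nid)
                    graph.remove_node(nid)
                    break
        if not removed:
            return graph
        graph = compact(graph)


def _identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if _HAVE_EDLIB:
        dist = edlib.align(a, b)["editDistance"]
    else:
        dist = sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))
    return 1.0 - dist / max(len(a), len(b))


def pop_bubbles(graph: AssemblyGraph, max_bubble_len: int,
                min_identity: float = 0.9) -> AssemblyGraph:
    """Collapse simple bubbles: two parallel single-node paths between the
    same pair of junction ends whose sequences are near-identical.  The
    lower-support path is deleted and its edge frequencies and coverage
    fold onto the survivor."""
    while True:
        changed = False
        # entries: key (pair of junction ends) -> list of
        # (node, total path freq, edge key at key[0] side, edge key at key[1]
        # side, freq at key[0], freq at key[1], forward-in-key orientation)
        groups: Dict[Tuple, List[Tuple]] = {}
        for nid in graph.node_ids():
            if len(graph.nodes[nid].seq) > max_bubble_len:
                continue
            outs_f = graph.out_edges(nid, True)
            outs_r = graph.out_edges(nid, False)
            if len(outs_f) != 1 or len(outs_r) != 1:
                continue
            kf, bf, sbf, ff, _ = outs_f[0]
            kr, br, sbr, fr, _ = outs_r[0]
            if bf == nid or br == nid:
                continue
            end_in = (br, not sbr)    # junction end on the node's head side
            end_out = (bf, not sbf)   # junction end on the node's tail side
            if end_in == end_out:
                continue
            key = tuple(sorted((end_in, end_out)))
            fwd_in_key = key[0] == end_in
            if fwd_in_key:
                entry = (nid, ff + fr, kr, kf, fr, ff, True)
            else:
                entry = (nid, ff + fr, kf, kr, ff, fr, False)
            groups.setdefault(key, []).append(entry)
        for key in sorted(groups):
            entries = groups[key]
            if len(entries) < 2:
                continue
            entries.sort(key=lambda e: (-e[1], graph.nodes[e[0]].seq))
            surv = entries[0]
            surv_id = surv[0]
            surv_seq = graph.seq(surv_id, surv[6])
            for loser in entries[1:]:
                nid = loser[0]
                if nid not in graph.nodes or surv_id not in graph.nodes:
                    continue
                if _identity(surv_seq, graph.seq(nid, loser[6])) < min_identity:
                    continue
                graph.remove_node(nid)
                if surv[2] in graph.edges:
                    graph.edges[surv[2]].freq += loser[4]
                if surv[3] in graph.edges:
                    graph.edges[surv[3]].freq += loser[5]
                graph.nodes[surv_id].cov += loser[1] / 2.0
                changed = True
        if not changed:
            return graph
        graph = compact(graph)


def remove_erroneous_connections(graph: AssemblyGraph, cs: int) -> AssemblyGraph:
    """Cut chimera-like connections: an edge whose frequency is below cs
    and below half the median support around both of its endpoints (node
    coverages stand in when the endpoints have no other edges)."""
    if cs <= 0:
        return graph
    removed = False
    for key in sorted(graph.edges):
        if key not in graph.edges:
            continue
        edge = graph.edges[key]
        if edge.freq >= cs:
            continue
        a, _sa, b, _sb = key
        neighbours = []
        for nid in {a, b}:
            for fwd in (True, False):
                for nkey, _t, _st, f, _ov in graph.out_edges(nid, fwd):
                    if nkey != key:
                        neighbours.append(f)
        values = neighbours if neighbours else [graph.nodes[a].cov, graph.nodes[b].cov]
        if edge.freq < 0.5 * median(values):
            graph.remove_edge(key)
            removed = True
    return compact(graph) if removed else graph


def to_gfa(graph: AssemblyGraph) -> str:
    """GFA1 dump (S and L records) for external inspection."""
    lines = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        lines.append(f"S\t{nid}\t{node.seq}\tRC:i:{int(node.cov * node.nk)}")
    for (a, sa, b, sb), edge in sorted(graph.edges.items()):
        lines.append(
            f"L\t{a}\t{'+' if sa else '-'}\t{b}\t{'+' if sb else '-'}\t{edge.overlap}M"
        )
    return "\n".join(lines) + "\n"
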