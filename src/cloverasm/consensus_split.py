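"""Consensus k-mers for clusters, with recursive over-merge splitting.

Each cluster collapses to the column-wise majority sequence of its oriented
members, weighted by occurrence counts.  A cluster that merged genuinely
distinct k-mers shows a column where a minority nucleotide x is nearly as
frequent as the consensus nucleotide y; when occ(x) >= sp * occ(y) the
members carrying x are pulled into their own node and both halves are
re-examined recursively.  The surviving consensus sequences form the k-mer
set on which the de Bruijn graph is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

from cloverasm.kmer_clustering import FWD, Cluster, canonical, oriented
from cloverasm.read_io import reverse_complement

_BASES = "ACGT"

# a member is (canonical k-mer, orientation relative to the node, count)
Member = Tuple[str, bool, int]


@dataclass
class ConsensusNode:
    """One consensus k-mer with the cluster members that produced it."""

    sequence: str
    members: List[Member] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(count for _, _, count in self.members)


def _column_tallies(members: Sequence[Member], k: int) -> List[Dict[str, int]]:
    tallies: List[Dict[str, int]] = [dict.fromkeys(_BASES, 0) for _ in range(k)]
    for kmer, fwd, count in members:
        seq = oriented(kmer, fwd)
        for i, base in enumerate(seq):
            tallies[i][base] += count
    return tallies


def consensus(members: Sequence[Member]) -> str:
    """Column-wise majority of the oriented members, weighted by occurrence.

    A tied column goes to the lexicographically smallest nucleotide.
    """
    if not members:
        raise ValueError("cannot take the consensus of an empty member list")
    k = len(members[0][0])
    tallies = _column_tallies(members, k)
    # max() scans A<C<G<T and keeps the first maximum, i.e. the smallest base
    return "".join(max(_BASES, key=lambda b: col[b]) for col in tallies)


def split_node(node: ConsensusNode, sp: Fraction | float | str) -> List[ConsensusNode]:
    """Recursively split ``node`` wherever a minority column is too strong.

    Columns are scanned left to right and, within a column, non-consensus
    nucleotides in order A<C<G<T; the first (column, x) with
    occ(x) >= sp * occ(y) (y the consensus nucleotide there) partitions the
    members into those carrying x (new node v1) and the rest (v2), and both
    are retried.  The comparison is exact rational arithmetic, so a decimal
    sp like 0.6 behaves as 3/5 rather than its float approximation.
    """
    sp = Fraction(str(sp)) if not isinstance(sp, Fraction) else sp
    if sp <= 0:
        raise ValueError("sp must be positive")
    out: List[ConsensusNode] = []
    stack = [node.members]
    while stack:
        members = stack.pop()
        seq = consensus(members)
        hit = _find_split_column(members, seq, sp)
        if hit is None:
            out.append(ConsensusNode(sequence=seq, members=list(members)))
            continue
        column, x = hit
        v1 = [m for m in members if oriented(m[0], m[1])[column] == x]
        v2 = [m for m in members if oriented(m[0], m[1])[column] != x]
        stack.append(v2)
        stack.append(v1)
    return out


def _find_split_column(
    members: Sequence[Member], seq: str, sp: Fraction
) -> Tuple[int, str] | None:
    tallies = _column_tallies(members, len(seq))
    for column, col in enumerate(tallies):
        y = seq[column]
        occ_y = col[y]
        for x in _BASES:
            if x == y or col[x] == 0:
                continue
            if Fraction(col[x]) >= sp * occ_y:
                return column, x
    return None


def build_consensus_set(
    clusters: Sequence[Cluster], sp: Fraction | float | str
) -> Tuple[List[ConsensusNode], Dict[str, Tuple[int, bool]]]:
    """Consensus + splitting over every cluster.

    Returns the final consensus nodes (sequences stored canonically,
    duplicates merged with summed counts) and a map from each member
    canonical k-mer to ``(node index, orientation)`` — the orientation that
    aligns the member with the stored node sequence.  Every original k-mer
    occurrence lands in exactly one node.
    """
    raw: List[ConsensusNode] = []
    for cluster in sorted(clusters, key=lambda c: c.members[0][0]):
        node = ConsensusNode(sequence="", members=list(cluster.members))
        raw.extend(split_node(node, sp))

    by_seq: Dict[str, int] = {}
    nodes: List[ConsensusNode] = []
    member_map: Dict[str, Tuple[int, bool]] = {}
    for node in raw:
        canon_seq, was_fwd = canonical(node.sequence)
        idx = by_seq.get(canon_seq)
        if idx is None:
            idx = len(nodes)
            by_seq[canon_seq] = idx
            nodes.append(ConsensusNode(sequence=canon_seq))
        target = nodes[idx]
        for kmer, fwd, count in node.members:
            # flip member orientation when the consensus itself was flipped
            # to reach canonical form
            rel = fwd if was_fwd else not fwd
            target.members.append((kmer, rel, count))
            member_map[kmer] = (idx, rel)
    return nodes, member_map
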