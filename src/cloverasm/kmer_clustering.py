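"""Error-tolerant k-mer clustering via the Hamming graph.

Two k-mers are neighbours when the Hamming distance between them — or
between one and the reverse complement of the other — is at most ``p``.
Connected components of that graph are the clusters that later collapse to
consensus k-mers.

Candidate neighbour pairs are found with a pigeonhole index: each k-mer is
partitioned into ``p + 1`` contiguous substrings and indexed in ``p + 1``
hash tables, one per substring position.  Any pair within distance ``p``
must agree exactly on at least one substring (p mismatches cannot hit all
p + 1 spans), so scanning the hash buckets yields a superset of the true
neighbour pairs; an early-exit Hamming check then verifies each candidate.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from cloverasm.read_io import ReadRecord, clean_fragments, reverse_complement

# orientation flags: True = the k-mer as stored, False = reverse complement
FWD = True
REV = False

# adjacency key: (canon_a, a_is_forward, canon_b, b_is_forward) meaning the raw
# k-mer orient(canon_a, a_is_forward) was immediately followed in a read by
# orient(canon_b, b_is_forward); stored under a strand-normalized key.
AdjKey = Tuple[str, bool, str, bool]


def canonical(kmer: str) -> Tuple[str, bool]:
    """Return (canonical form, True if the input was already canonical)."""
    rc = reverse_complement(kmer)
    if kmer <= rc:
        return kmer, FWD
    return rc, REV


def oriented(kmer: str, forward: bool) -> str:
    return kmer if forward else reverse_complement(kmer)


def _norm_adjacency(a: str, fa: bool, b: str, fb: bool) -> AdjKey:
    # an adjacency x->y is the same event as revcomp(y)->revcomp(x)
    key = (a, fa, b, fb)
    twin = (b, not fb, a, not fa)
    return key if key <= twin else twin


@dataclass
class KmerTable:
    """Canonical k-mer multiset with read-adjacency counts."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)
    adjacencies: Dict[AdjKey, int] = field(default_factory=dict)

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())

    def add_fragment(self, fragment: str) -> None:
        k = self.k
        prev: Optional[Tuple[str, bool]] = None
        for i in range(len(fragment) - k + 1):
            kmer = fragment[i : i + k]
            canon, fwd = canonical(kmer)
            self.counts[canon] = self.counts.get(canon, 0) + 1
            if prev is not None:
                key = _norm_adjacency(prev[0], prev[1], canon, fwd)
                self.adjacencies[key] = self.adjacencies.get(key, 0) + 1
            prev = (canon, fwd)


def extract_kmers(reads: Iterable[ReadRecord], k: int) -> KmerTable:
    """Count every k-mer window of every N-free read fragment.

    Counts are folded onto canonical forms (lexicographic min of the k-mer
    and its reverse complement); consecutive windows are recorded as
    adjacencies for edge-frequency accounting later.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    table = KmerTable(k)
    for read in reads:
        for fragment in clean_fragments(read.sequence, k):
            table.add_fragment(fragment)
    return table


def partition_positions(k: int, p: int) -> List[Tuple[int, int]]:
    """Split [0, k) into p + 1 contiguous balanced spans, longer spans first."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if k < p + 1:
        raise ValueError(f"k={k} too small to partition into {p + 1} non-empty substrings")
    n = p + 1
    base, extra = divmod(k, n)
    spans = []
    start = 0
    for i in range(n):
        length = base + (1 if i < extra else 0)
        spans.append((start, length))
        start += length
    return spans


@dataclass
class PartitionIndex:
    """(p + 1) hash tables keyed by the i-th substring of each indexed k-mer.

    Both the forward and reverse-complement substrings of each k-mer are
    indexed so that reverse-complement neighbours fall into the same
    buckets.
    """

    k: int
    p: int
    spans: List[Tuple[int, int]] = field(default_factory=list)
    tables: List[Dict[str, List[str]]] = field(default_factory=list)

    @classmethod
    def build(cls, kmers: Iterable[str], k: int, p: int) -> "PartitionIndex":
        spans = partition_positions(k, p)
        index = cls(k=k, p=p, spans=spans, tables=[{} for _ in spans])
        for kmer in kmers:
            index.add(kmer)
        return index

    def add(self, kmer: str) -> None:
        rc = reverse_complement(kmer)
        for table, (start, length) in zip(self.tables, self.spans):
            for seq in (kmer, rc):
                sub = seq[start : start + length]
                bucket = table.get(sub)
                if bucket is None:
                    table[sub] = [kmer]
                elif bucket[-1] != kmer:  # cheap de-dup of fwd==rc substrings
                    bucket.append(kmer)

    def candidates_of(self, kmer: str) -> Iterator[str]:
        """All indexed k-mers sharing at least one substring with ``kmer``
        (or with its reverse complement)."""
        rc = reverse_complement(kmer)
        seen = set()
        for table, (start, length) in zip(self.tables, self.spans):
            for seq in (kmer, rc):
                for other in table.get(seq[start : start + length], ()):
                    if other != kmer and other not in seen:
                        seen.add(other)
                        yield other


def verified_distance(a: str, b: str, p: int) -> Optional[Tuple[int, bool]]:
    """Hamming distance of ``a`` vs ``b`` and vs revcomp(b), capped at ``p``.

    Returns (distance, orientation) for the closer comparison (forward
    preferred on ties) or None when both exceed ``p``.  Mismatch counting
    exits early once p + 1 differences are seen.
    """
    if len(a) != len(b):
        raise ValueError("k-mer length mismatch")
    d_fwd = _hamming_capped(a, b, p)
    if d_fwd == 0:
        return 0, FWD
    d_rev = _hamming_capped(a, reverse_complement(b), p)
    if d_fwd is None and d_rev is None:
        return None
    if d_rev is None or (d_fwd is not None and d_fwd <= d_rev):
        return d_fwd, FWD  # type: ignore[return-value]
    return d_rev, REV


def _hamming_capped(a: str, b: str, p: int) -> Optional[int]:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > p:
                return None
    return d


def candidate_pairs(table: KmerTable, p: int) -> Iterator[Tuple[str, str]]:
    """Stream candidate neighbour pairs from the pigeonhole index.

    Guaranteed to contain every pair within Hamming distance p (in either
    orientation); may contain false positives, which verification rejects.
    """
    if p < 1:
        raise ValueError("candidate generation is only meaningful for p >= 1")
    kmers = sorted(table.counts)
    index = PartitionIndex.build(kmers, table.k, p)
    emitted = set()
    for kmer in kmers:
        for other in index.candidates_of(kmer):
            key = (kmer, other) if kmer <= other else (other, kmer)
            if key not in emitted:
                emitted.add(key)
                yield key


@dataclass
class Cluster:
    """A connected component of the Hamming graph.

    ``members`` are (canonical k-mer, orientation, occurrence count); the
    orientation is relative to the BFS root (root = forward) so that the
    oriented member sequences are mutually alignable column by column.
    """

    members: List[Tuple[str, bool, int]]
    component_id: int
    orientation_conflicts: int = 0


def cluster_kmers(table: KmerTable, p: int) -> List[Cluster]:
    """Connected components of the distance-<=p Hamming graph, via BFS.

    With p = 0 clustering is skipped entirely: every distinct canonical
    k-mer becomes its own singleton cluster.  BFS roots are taken in
    lexicographic order so the output is independent of hash iteration
    order.  A member reachable with both orientations (palindrome-like
    conflict) keeps the orientation assigned first; conflicts are counted.
    """
    kmers = sorted(table.counts)
    if p == 0:
        return [
            Cluster(members=[(kmer, FWD, table.counts[kmer])], component_id=i)
            for i, kmer in enumerate(kmers)
        ]

    index = PartitionIndex.build(kmers, table.k, p)
    orientation: Dict[str, bool] = {}
    clusters: List[Cluster] = []
    for root in kmers:
        if root in orientation:
            continue
        orientation[root] = FWD
        members: List[Tuple[str, bool, int]] = []
        conflicts = 0
        queue = deque([root])
        while queue:
            cur = queue.popleft()
            cur_orient = orientation[cur]
            members.append((cur, cur_orient, table.counts[cur]))
            for other in sorted(index.candidates_of(cur)):
                hit = verified_distance(cur, other, p)
                if hit is None:
                    continue
                # orientation of `other` relative to the root: flip when the
                # match itself is a reverse-complement match
                implied = cur_orient if hit[1] == FWD else not cur_orient
                if other in orientation:
                    if orientation[other] != implied:
                        conflicts += 1
                    continue
                orientation[other] = implied
                queue.append(other)
        clusters.append(
            Cluster(members=members, component_id=len(clusters), orientation_conflicts=conflicts)
        )
    return clusters
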