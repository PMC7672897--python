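"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's indexed/BFS code paths: distances
are computed all-pairs with numpy and components with scipy's union-find
based connected_components, so agreement is a genuine cross-check.
"""

from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from cloverasm.read_io import reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _encode(kmers: List[str]) -> np.ndarray:
    return np.array([list(k) for k in kmers], dtype="U1")


def brute_force_pairs(kmers: List[str], p: int) -> Set[Tuple[str, str]]:
    """All unordered pairs within Hamming distance p, directly or via
    reverse complement."""
    n = len(kmers)
    if n < 2:
        return set()
    fwd = _encode(kmers)
    rev = _encode([reverse_complement(k) for k in kmers])
    d_fwd = (fwd[:, None, :] != fwd[None, :, :]).sum(axis=2)
    d_rev = (fwd[:, None, :] != rev[None, :, :]).sum(axis=2)
    close = (np.minimum(d_fwd, d_rev) <= p)
    out = set()
    for i, j in zip(*np.nonzero(np.triu(close, k=1))):
        a, b = kmers[i], kmers[j]
        out.add((a, b) if a <= b else (b, a))
    return out


def brute_force_components(kmers: List[str], p: int) -> Set[FrozenSet[str]]:
    """Connected components of the Hamming graph as sets of k-mers."""
    n = len(kmers)
    index = {k: i for i, k in enumerate(kmers)}
    rows, cols = [], []
    for a, b in brute_force_pairs(kmers, p):
        rows.append(index[a])
        cols.append(index[b])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _ncomp, labels = connected_components(adj, directed=False)
    comps: Dict[int, Set[str]] = {}
    for kmer, label in zip(kmers, labels):
        comps.setdefault(label, set()).add(kmer)
    return {frozenset(v) for v in comps.values()}


def textbook_debruijn(sequences: List[str], k: int):
    """Classic de Bruijn construction: distinct canonical k-mers as nodes,
    an edge between two k-mers when some orientation pair overlaps by k-1."""
    from cloverasm.kmer_clustering import canonical

    kmers = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmers.add(canonical(seq[i : i + k])[0])
    edges = set()
    for a in kmers:
        for a_seq in (a, reverse_complement(a)):
            suffix = a_seq[1:]
            for b in kmers:
                for b_seq in (b, reverse_complement(b)):
                    if b_seq[: k - 1] == suffix:
                        edges.add((a, b) if a <= b else (b, a))
    return kmers, edges
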