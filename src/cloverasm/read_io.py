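"""Reading sequencing libraries (FASTQ/FASTA, paired or single).

Sequences are uppercased on input.  Bases outside {A, C, G, T} (most
commonly N) split a read into clean fragments before k-mer extraction;
fragments shorter than k are dropped, because Hamming-distance clustering
is defined only over the four-letter alphabet.  Quality strings are parsed
and discarded — nothing downstream uses them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement; N maps to N."""
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A single read; ``mate`` points at the other end of the pair."""

    id: str
    sequence: str
    library_index: int = 0
    mate: Optional["ReadRecord"] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.id!r}")


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: a file (or pair of files) plus its insert size."""

    path_1: str
    path_2: Optional[str] = None
    insert_size: int = 0
    library_index: int = 0

    def __post_init__(self) -> None:
        if self.path_2 is not None and self.insert_size <= 0:
            raise ValueError(
                f"paired library {self.path_1}/{self.path_2} needs a positive insert size"
            )


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _records(handle: IO[str], path: str) -> Iterator[Tuple[str, str]]:
    """Yield (id, sequence) from FASTQ or FASTA, auto-detected by leader char."""
    first = handle.readline()
    while first and not first.strip():
        first = handle.readline()
    if not first:
        return
    leader = first[0]
    if leader == "@":
        yield from _fastq_records(first, handle, path)
    elif leader == ">":
        yield from _fasta_records(first, handle)
    else:
        raise ValueError(f"{path}: unrecognized format (first char {leader!r})")


def _fastq_records(first: str, handle: IO[str], path: str) -> Iterator[Tuple[str, str]]:
    idx = 0
    header = first
    while header:
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"{path}: malformed FASTQ record at record index {idx}")
        yield header[1:].split()[0], seq.strip().upper()
        idx += 1
        header = handle.readline()
        while header and not header.strip():
            header = handle.readline()


def _fasta_records(first: str, handle: IO[str]) -> Iterator[Tuple[str, str]]:
    name = first[1:].split()[0] if len(first) > 1 else ""
    chunks: List[str] = []
    for line in handle:
        if line.startswith(">"):
            yield name, "".join(chunks).upper()
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        else:
            chunks.append(line.strip())
    yield name, "".join(chunks).upper()


def parse_library(spec: LibrarySpec) -> Iterator[ReadRecord]:
    """Stream the reads of one library.

    For a paired library both files are read in lockstep and mates are
    joined positionally; both records of a pair are yielded (mate 1 first).
    A count mismatch between the two files is a hard error.
    """
    with open_maybe_gzip(spec.path_1) as h1:
        if spec.path_2 is None:
            for name, seq in _records(h1, spec.path_1):
                yield ReadRecord(name, seq, spec.library_index)
            return
        with open_maybe_gzip(spec.path_2) as h2:
            it1 = _records(h1, spec.path_1)
            it2 = _records(h2, spec.path_2)
            sentinel = object()
            while True:
                r1 = next(it1, sentinel)
                r2 = next(it2, sentinel)
                if r1 is sentinel and r2 is sentinel:
                    return
                if r1 is sentinel or r2 is sentinel:
                    raise ValueError(
                        f"paired files {spec.path_1} and {spec.path_2} "
                        "contain different numbers of records"
                    )
                a = ReadRecord(r1[0], r1[1], spec.library_index)
                b = ReadRecord(r2[0], r2[1], spec.library_index)
                a.mate, b.mate = b, a
                yield a
                yield b


def parse_libraries(specs: Sequence[LibrarySpec]) -> Iterator[ReadRecord]:
    for spec in specs:
        yield from parse_library(spec)


def clean_fragments(sequence: str, k: int) -> List[str]:
    """Split a sequence at non-ACGT characters; keep fragments of length >= k."""
    out: List[str] = []
    start = 0
    n = len(sequence)
    for i, ch in enumerate(sequence):
        if ch not in "ACGT":
            if i - start >= k:
                out.append(sequence[start:i])
            start = i + 1
    if n - start >= k:
        out.append(sequence[start:n])
    return out


def write_fasta(path: str | Path, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    """Write (header, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Iterable[Tuple[str, str]], quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as 4-line FASTQ with constant quality."""
    path = str(path)
    fh: IO[str]
    if path.endswith(".gz"):
        fh = gzip.open(path, "wt")
    else:
        fh = open(path, "w")
    with fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
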