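"""Synthetic genomes and Illumina-like paired-end reads.

The simulator emulates a fragment library from a short-read instrument:
fixed read length, inward-facing pairs, normally distributed insert sizes,
and substitution-only errors (the dominant error mode of the platform,
typically at 0.5-2.5%).  Indels, quality profiles, coverage bias and PCR
duplicates are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from cloverasm.read_io import reverse_complement, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library."""

    genome_length: int = 20_000
    gc: float = 0.5
    repeat_spec: Optional[Tuple[int, int]] = None  # (unit length, copies)
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.01
    insert_mean: int = 300
    insert_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")


@dataclass
class SimulatedPair:
    """One read pair plus its ground-truth placement."""

    name: str
    read_1: str
    read_2: str
    start: int          # fragment start on the forward genome strand
    fragment_length: int
    forward: bool       # fragment drawn from the forward strand?


def random_genome(config: SimConfig) -> str:
    """An i.i.d. random genome at the requested GC fraction.

    With ``repeat_spec = (unit, copies)`` a sampled unit sequence is pasted
    at uniformly chosen non-overlapping positions, ``copies`` times.
    """
    if config.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rng = np.random.default_rng(config.seed)
    probs = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    genome = rng.choice(_BASES, size=config.genome_length, p=probs)
    if config.repeat_spec is not None:
        unit_len, copies = config.repeat_spec
        if unit_len * copies > config.genome_length:
            raise ValueError("repeats do not fit in the genome")
        unit = rng.choice(_BASES, size=unit_len, p=probs)
        positions: List[int] = []
        for _ in range(10_000):
            if len(positions) == copies:
                break
            pos = int(rng.integers(0, config.genome_length - unit_len + 1))
            if all(abs(pos - q) >= unit_len for q in positions):
                positions.append(pos)
        if len(positions) < copies:
            raise ValueError("could not place non-overlapping repeat copies")
        for pos in positions:
            genome[pos : pos + unit_len] = unit
    return genome.tobytes().decode()


def _add_errors(read: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_pair_records(genome: str, config: SimConfig,
                          orientation: str = "fr") -> List[SimulatedPair]:
    """Draw read pairs from ``genome`` under the library model.

    Fragment lengths are normal(insert_mean, insert_sd) rounded and clamped
    to [read_length, genome length]; starts are uniform; strands uniform.
    Mate 1 is the fragment prefix and mate 2 the reverse complement of the
    fragment suffix ("fr", inward).  ``orientation="rf"`` flips both mates
    for outward-facing mate-pair dialects.  The pair count is
    ceil(coverage * genome_length / (2 * read_length)).
    """
    rng = np.random.default_rng(config.seed + 1)
    g = len(genome)
    rl = config.read_length
    n_pairs = int(np.ceil(config.coverage * g / (2 * rl)))
    pairs: List[SimulatedPair] = []
    for i in range(n_pairs):
        frag_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        frag_len = max(rl, min(frag_len, g))
        start = int(rng.integers(0, g - frag_len + 1))
        forward = bool(rng.integers(0, 2))
        fragment = genome[start : start + frag_len]
        if not forward:
            fragment = reverse_complement(fragment)
        r1 = fragment[:rl]
        r2 = reverse_complement(fragment[-rl:])
        if orientation == "rf":
            r1, r2 = reverse_complement(r1), reverse_complement(r2)
        r1 = _add_errors(r1, rng, config.error_rate)
        r2 = _add_errors(r2, rng, config.error_rate)
        pairs.append(SimulatedPair(f"sim_{i}", r1, r2, start, frag_len, forward))
    return pairs


def mate_spans(pair: SimulatedPair, read_length: int) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Genomic [start, end) intervals covered by each mate."""
    s, e = pair.start, pair.start + pair.fragment_length
    left = (s, min(e, s + read_length))
    right = (max(s, e - read_length), e)
    return (left, right) if pair.forward else (right, left)


def censor_pairs(pairs: List[SimulatedPair], intervals: List[Tuple[int, int]],
                 read_length: int) -> List[SimulatedPair]:
    """Drop whole pairs in which either mate overlaps a censored interval.

    Used to carve unassemblable low-coverage gaps into a simulated genome
    while keeping gap-spanning pairs for the scaffolder.
    """
    kept = []
    for pair in pairs:
        spans = mate_spans(pair, read_length)
        if any(s < iv_end and iv_start < e for s, e in spans
               for iv_start, iv_end in intervals):
            continue
        kept.append(pair)
    return kept


def pairs_to_records(pairs: List[SimulatedPair], library_index: int = 0):
    """Materialize simulated pairs as mate-linked ReadRecords."""
    from cloverasm.read_io import ReadRecord

    reads = []
    for pair in pairs:
        r1 = ReadRecord(f"{pair.name}/1", pair.read_1, library_index)
        r2 = ReadRecord(f"{pair.name}/2", pair.read_2, library_index)
        r1.mate, r2.mate = r2, r1
        reads.extend((r1, r2))
    return reads


def simulate_pairs(genome: str, config: SimConfig, path_1: str, path_2: str,
                   orientation: str = "fr") -> List[SimulatedPair]:
    """Simulate pairs and write them as two 4-line FASTQ files."""
    pairs = simulate_pair_records(genome, config, orientation)
    write_fastq(path_1, ((f"{p.name}/1", p.read_1) for p in pairs))
    write_fastq(path_2, ((f"{p.name}/2", p.read_2) for p in pairs))
    return pairs
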