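"""Assembly summary statistics.

N50 here follows the assembler's own reporting convention: the minimum
sequence length needed, taking sequences longest first, to cover half of
the *total sequence produced*.  Passing an explicit denominator (e.g. a
known genome size) reproduces the reference-based convention instead; the
two differ whenever assembly total != genome size.  E-size is the expected
length of the sequence containing a uniformly random base of the
denominator: sum(L_i^2) / denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence


def n50(lengths: Sequence[int], denominator: Optional[int] = None) -> int:
    """Minimum length covering half the denominator, longest-first."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if denominator is None:
        denominator = sum(lengths)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    half = denominator / 2
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running >= half:
            return length
    return min(lengths)  # denominator larger than the assembly total


def e_size(lengths: Sequence[int], denominator: Optional[int] = None) -> float:
    """Expected length of the sequence containing a random base."""
    if not lengths:
        raise ValueError("e_size of an empty length list is undefined")
    if denominator is None:
        denominator = sum(lengths)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return sum(length * length for length in lengths) / denominator


@dataclass(frozen=True)
class AssemblyStats:
    num: int
    total: int
    max: int
    n50: int
    e_size: float

    def table(self, label: str) -> str:
        return (
            f"{label}\n"
            f"  Num    {self.num}\n"
            f"  Total  {self.total}\n"
            f"  Max    {self.max}\n"
            f"  N50    {self.n50}\n"
            f"  E-size {self.e_size:.1f}\n"
        )


def summarize(lengths: Sequence[int], denominator: Optional[int] = None) -> AssemblyStats:
    if not lengths:
        return AssemblyStats(0, 0, 0, 0, 0.0)
    return AssemblyStats(
        num=len(lengths),
        total=sum(lengths),
        max=max(lengths),
        n50=n50(lengths, denominator),
        e_size=e_size(lengths, denominator),
    )
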