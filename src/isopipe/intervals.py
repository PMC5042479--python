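"""Genomic coordinate primitives.

All internal coordinates are 0-based, half-open ``[start, end)``.  GTF I/O
converts to/from the on-disk 1-based inclusive convention at the boundary
(:mod:`isopipe.io`), and SAM positions are handled by pysam.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: ``donor`` is the first intronic base, ``acceptor`` one past
    the last (half-open like everything else), on the given strand.

    ``status`` is ``known`` (annotated, J labels) or ``novel`` (N labels).
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str = "+"
    status: str = "known"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"invalid junction donor={self.donor} acceptor={self.acceptor}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.status not in ("known", "novel"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.label and self.label[0] not in {"known": "J", "novel": "N"}[self.status]:
            raise ValueError(f"label {self.label!r} does not match status {self.status!r}")

    @property
    def key(self) -> tuple:
        """Exact-match identity used for counting and classification."""
        return (self.chrom, self.donor, self.acceptor)
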