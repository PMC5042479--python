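"""Open-reading-frame annotation for transcript sequences.

Scans the three forward frames for complete ATG..stop ORFs, reports the
largest one, and annotates translation-initiation (Kozak) context and
protein-domain coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class ORFAnnotation:
    """Largest complete ORF of a transcript.

    ``start`` is the transcript offset of the ATG, ``end`` one past the stop
    codon; ``aa_length`` excludes the stop but includes the initial Met.
    ``aa_length == 0`` with ``start == end == 0`` is the no-ORF sentinel.
    """

    start: int = 0
    end: int = 0
    aa_length: int = 0
    kozak_ok: bool = False
    domain_count: int | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be a whole number of codons")
        if self.aa_length and self.aa_length != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_length inconsistent with ORF span")

    @property
    def found(self) -> bool:
        return self.aa_length > 0


def find_largest_orf(seq: str) -> ORFAnnotation:
    """Largest complete ORF across the three forward frames.

    Ties on length are broken toward the most 5' start.  Returns the no-ORF
    sentinel when no ATG reaches an in-frame stop.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    best: tuple[int, int] | None = None  # (start, end)
    for frame in range(3):
        orf_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - orf_start
                if best is None or length > best[1] - best[0] or (
                    length == best[1] - best[0] and orf_start < best[0]
                ):
                    best = (orf_start, pos + 3)
                orf_start = None
    if best is None:
        return ORFAnnotation()
    start, end = best
    return ORFAnnotation(
        start=start,
        end=end,
        aa_length=(end - start) // 3 - 1,
        kozak_ok=check_kozak(seq, start),
    )


def check_kozak(seq: str, orf_start: int) -> bool:
    """Minimal Kozak consensus: purine at -3 and G at +4 relative to the A of
    the ATG.  False when the context extends past either sequence end."""
    seq = seq.upper()
    if orf_start < 3 or orf_start + 4 > len(seq):
        return False
    if seq[orf_start : orf_start + 3] != "ATG":
        raise ValueError(f"no ATG at offset {orf_start}")
    return seq[orf_start - 3] in "AG" and seq[orf_start + 3] == "G"


def domain_coverage(
    orf_span: tuple[int, int], domains: list[tuple[int, int]]
) -> int:
    """Number of protein domains fully contained in the ORF's translated span.

    Both the span and the domains are half-open intervals in amino-acid
    coordinates of the reference protein; the caller supplies the mapping of
    this ORF onto the reference frame.
    """
    lo, hi = orf_span
    return sum(1 for d_lo, d_hi in domains if lo <= d_lo and d_hi <= hi)
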