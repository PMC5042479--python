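"""Sequence extraction from a genome: spliced transcripts and splice motifs."""

from __future__ import annotations

from collections.abc import Mapping, Sequence

from .gene_model import TheoreticalIsoform
from .intervals import GenomicInterval, SpliceJunction, revcomp


def _contig(genome: Mapping[str, object], chrom: str) -> str:
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not in genome") from exc
    return str(seq)


def extract_interval(genome: Mapping[str, object], interval: GenomicInterval) -> str:
    """Plus-strand text of one interval (no strand handling here)."""
    contig = _contig(genome, interval.chrom)
    if interval.end > len(contig):
        raise ValueError(
            f"exon {interval.chrom}:{interval.start}-{interval.end} outside contig "
            f"(length {len(contig)})"
        )
    return contig[interval.start : interval.end].upper()


def extract_sequence(
    genome: Mapping[str, object],
    exon_chain: Sequence[GenomicInterval],
    strand: str | None = None,
) -> str:
    """Spliced transcript sequence: exon texts concatenated in genomic order,
    reverse-complemented as a whole for the minus strand."""
    if not exon_chain:
        return ""
    if strand is None:
        strand = exon_chain[0].strand
    seq = "".join(extract_interval(genome, iv) for iv in exon_chain)
    return revcomp(seq) if strand == "-" else seq


def isoform_sequence(genome: Mapping[str, object], isoform: TheoreticalIsoform) -> str:
    return extract_sequence(genome, isoform.exon_chain, isoform.strand)


def junction_motif(
    genome: Mapping[str, object], junction: SpliceJunction
) -> tuple[str, str, bool]:
    """Donor and acceptor dinucleotides of an intron, strand-aware.

    Returns ``(donor, acceptor, canonical)`` where canonical means GT-AG on
    the transcribed strand.
    """
    if junction.acceptor - junction.donor < 4:
        raise ValueError(
            f"intron {junction.donor}-{junction.acceptor} shorter than 4 nt"
        )
    contig = _contig(genome, junction.chrom)
    if junction.acceptor > len(contig):
        raise ValueError("junction outside contig")
    left = contig[junction.donor : junction.donor + 2].upper()
    right = contig[junction.acceptor - 2 : junction.acceptor].upper()
    if junction.strand == "-":
        donor, acceptor = revcomp(right), revcomp(left)
    else:
        donor, acceptor = left, right
    return donor, acceptor, (donor, acceptor) == ("GT", "AG")
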