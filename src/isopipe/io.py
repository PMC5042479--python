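"""File-format boundary: GTF, FASTA, and the package's TSV tables.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read (and back on write).  All writes are atomic
(write to a temp file in the same directory, then rename).
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_model import RegionTable, SubVariant, TheoreticalIsoform
from .intervals import GenomicInterval


@dataclass
class Transcript:
    """A transcript read from (or destined for) a GTF file."""

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w"):
    """Write-then-rename so partial outputs never land at the final path."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> list[Transcript]:
    """Read exon features from a GTF into transcripts (internal coordinates).

    Malformed lines are reported with their line number before parsing.
    """
    path = os.fspath(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line (expected 9 fields)")
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, Transcript] = {}
    for feature in db.features_of_type("exon", order_by=("seqid", "start")):
        tx_id = feature.attributes["transcript_id"][0]
        gene_id = feature.attributes.get("gene_id", [tx_id])[0]
        tx = transcripts.setdefault(
            tx_id, Transcript(tx_id, gene_id, feature.seqid, feature.strand)
        )
        tx.exons.append(
            GenomicInterval(feature.seqid, feature.start - 1, feature.end, feature.strand)
        )
    for tx in transcripts.values():
        tx.exons.sort()
    return list(transcripts.values())


def write_gtf(transcripts: list[Transcript], path: str | os.PathLike) -> None:
    with atomic_write(path) as out:
        for tx in transcripts:
            for exon in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}";'
                out.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "isopipe",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def isoforms_to_transcripts(isoforms: list[TheoreticalIsoform]) -> list[Transcript]:
    return [
        Transcript(iso.name, iso.gene_id, iso.chrom, iso.strand, list(iso.exon_chain))
        for iso in isoforms
    ]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with atomic_write(path) as out:
        SeqIO.write(records, out, "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


# ---------------------------------------------------------------------------
# Region table TSV
# ---------------------------------------------------------------------------

_REGION_COLUMNS = [
    "region_id",
    "subvariant_id",
    "kind",
    "chain",
    "requires",
    "excludes",
    "major",
]


def _format_chain(chain: tuple[GenomicInterval, ...]) -> str:
    return ",".join(f"{iv.chrom}:{iv.start}-{iv.end}" for iv in chain)


def _parse_chain(text: str, strand: str) -> tuple[GenomicInterval, ...]:
    if not text or text == ".":
        return ()
    intervals = []
    for token in text.split(","):
        chrom, span = token.split(":")
        start, end = span.split("-")
        intervals.append(GenomicInterval(chrom, int(start), int(end), strand))
    return tuple(intervals)


def write_region_table(table: RegionTable, path: str | os.PathLike) -> None:
    rows = []
    for region_id, subs in table.regions:
        for sv in subs:
            rows.append(
                {
                    "region_id": region_id,
                    "subvariant_id": sv.id,
                    "kind": sv.kind,
                    "chain": _format_chain(sv.chain) or ".",
                    "requires": ",".join(sorted(sv.requires)) or ".",
                    "excludes": ",".join(sorted(sv.excludes)) or ".",
                    "major": int(sv.major),
                }
            )
    frame = pd.DataFrame(rows, columns=_REGION_COLUMNS)
    with atomic_write(path) as out:
        out.write(f"# gene_id={table.gene_id} chrom={table.chrom} strand={table.strand}\n")
        frame.to_csv(out, sep="\t", index=False)


def read_region_table(path: str | os.PathLike) -> RegionTable:
    path = os.fspath(path)
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# gene_id=... chrom=... strand=...' header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        frame = pd.read_csv(handle, sep="\t", dtype=str)
    strand = meta["strand"]
    regions: dict[str, list[SubVariant]] = {}
    order: list[str] = []
    for row in frame.itertuples(index=False):
        if row.region_id not in regions:
            regions[row.region_id] = []
            order.append(row.region_id)
        regions[row.region_id].append(
            SubVariant(
                id=row.subvariant_id,
                region_id=row.region_id,
                chain=_parse_chain(row.chain, strand),
                kind=row.kind,
                requires=frozenset() if row.requires == "." else frozenset(row.requires.split(",")),
                excludes=frozenset() if row.excludes == "." else frozenset(row.excludes.split(",")),
                major=bool(int(row.major)),
            )
        )
    return RegionTable(
        meta["gene_id"], meta["chrom"], strand, [(rid, regions[rid]) for rid in order]
    )


# ---------------------------------------------------------------------------
# Primer and design TSVs
# ---------------------------------------------------------------------------

def write_primer_table(primers: list, path: str | os.PathLike) -> None:
    rows = [
        {
            "pair_id": p.id,
            "forward": p.forward,
            "reverse": p.reverse,
            "fwd_anchor": p.fwd_anchor,
            "rev_anchor": p.rev_anchor,
        }
        for p in primers
    ]
    with atomic_write(path) as out:
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)


def read_primer_table(path: str | os.PathLike):
    from .longread import PrimerPair  # local import: avoids a cycle

    frame = pd.read_csv(os.fspath(path), sep="\t", dtype={"pair_id": str})
    return [
        PrimerPair(
            id=str(row.pair_id),
            forward=row.forward,
            reverse=row.reverse,
            fwd_anchor=int(row.fwd_anchor),
            rev_anchor=int(row.rev_anchor),
        )
        for row in frame.itertuples(index=False)
    ]


def read_design_table(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(os.fspath(path), sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required <= set(frame.columns):
        raise ValueError(f"design table must contain columns {sorted(required)}")
    return frame


def write_count_matrix(matrix, path: str | os.PathLike) -> None:
    """Serialise a :class:`isopipe.feature_counting.CountMatrix` to TSV."""
    with atomic_write(path) as out:
        matrix.to_frame().to_csv(out, sep="\t", index=False)


def read_count_matrix(path: str | os.PathLike):
    from .feature_counting import CountMatrix

    return CountMatrix.from_frame(pd.read_csv(os.fspath(path), sep="\t"))
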