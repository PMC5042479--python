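"""Flattened gene models and feature counting from spliced alignments.

Transcript annotations are flattened into disjoint exonic regions plus
deduplicated known junctions; spliced short-read alignments then contribute
novel junctions and per-feature read-pair counts.  Feature labels follow a
single numbering that runs across types within a gene: exonic regions first
(``E001..``), then known junctions (``J..``), then novel junctions (``N..``).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .intervals import GenomicInterval, SpliceJunction
from .io import Transcript

EXONIC = "exonic_region"
KNOWN_J = "known_junction"
NOVEL_J = "novel_junction"


@dataclass
class FlatGeneModel:
    """Disjoint exonic regions and (known + novel) junctions of one gene."""

    gene_id: str
    chrom: str
    strand: str
    exonic_regions: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    junctions: list[SpliceJunction] = field(default_factory=list)

    @property
    def known_junctions(self) -> list[SpliceJunction]:
        return [j for j in self.junctions if j.status == "known"]

    @property
    def novel_junctions(self) -> list[SpliceJunction]:
        return [j for j in self.junctions if j.status == "novel"]

    @property
    def span(self) -> GenomicInterval:
        starts = [iv.start for _, iv in self.exonic_regions] + [j.donor for j in self.junctions]
        ends = [iv.end for _, iv in self.exonic_regions] + [j.acceptor for j in self.junctions]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def features(self) -> list[tuple[str, str, object]]:
        out: list[tuple[str, str, object]] = []
        out.extend((label, EXONIC, iv) for label, iv in self.exonic_regions)
        out.extend(
            (j.label, KNOWN_J if j.status == "known" else NOVEL_J, j) for j in self.junctions
        )
        return out

    def junction_keys(self) -> set[tuple]:
        return {j.key for j in self.junctions}


def flatten_annotation(transcripts: list[Transcript]) -> FlatGeneModel:
    """Flatten one gene's transcripts into disjoint exonic regions plus
    deduplicated known junctions.

    Exon breakpoints from every transcript split overlapping exons, so the
    regions exactly partition the union of the input exons.  Regions are
    numbered 5'->3' on the coding strand.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    gene_id = transcripts[0].gene_id
    strands = {tx.strand for tx in transcripts}
    if len(strands) > 1:
        raise ValueError(f"gene {gene_id}: transcripts on mixed strands {sorted(strands)}")
    strand = strands.pop()
    chrom = transcripts[0].chrom

    boundaries: set[int] = set()
    exons = [exon for tx in transcripts for exon in tx.exons]
    for exon in exons:
        boundaries.update((exon.start, exon.end))
    cuts = sorted(boundaries)
    regions: list[GenomicInterval] = []
    for lo, hi in zip(cuts, cuts[1:]):
        if any(exon.start <= lo and hi <= exon.end for exon in exons):
            regions.append(GenomicInterval(chrom, lo, hi, strand))
    if strand == "-":
        regions = regions[::-1]

    junction_keys: set[tuple[int, int]] = set()
    for tx in transcripts:
        for a, b in zip(tx.exons, tx.exons[1:]):
            if b.start > a.end:
                junction_keys.add((a.end, b.start))
    ordered = sorted(junction_keys, reverse=(strand == "-"))

    model = FlatGeneModel(gene_id, chrom, strand)
    counter = 1
    for iv in regions:
        model.exonic_regions.append((f"E{counter:03d}", iv))
        counter += 1
    for donor, acceptor in ordered:
        model.junctions.append(
            SpliceJunction(chrom, donor, acceptor, strand, "known", f"J{counter:03d}")
        )
        counter += 1
    return model


# ---------------------------------------------------------------------------
# Spliced read pairs from SAM
# ---------------------------------------------------------------------------

@dataclass
class SplicedReadPair:
    """Aligned block/gap structure of one read pair (or single-end read)."""

    sample_id: str
    qname: str
    chrom: str
    fragment_strand: str
    blocks: list[GenomicInterval]  # all mates pooled, sorted
    gaps: set[tuple[int, int]]  # (donor, acceptor) of N operations


def _cigar_blocks(read: pysam.AlignedSegment, min_intron: int):
    """Reference blocks and N gaps from a CIGAR; D shorter than ``min_intron``
    stays inside its block, N gaps shorter than ``min_intron`` are bridged."""
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start = pos
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            pos += length
        elif op == 2:  # D
            pos += length
        elif op == 3:  # N
            if length >= min_intron:
                if pos > block_start:
                    blocks.append((block_start, pos))
                gaps.append((pos, pos + length))
                block_start = pos + length
            pos += length
        # I, S, H, P consume no reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks, gaps


def read_sam_pairs(
    path: str,
    sample_id: str,
    min_intron: int = 20,
) -> list[SplicedReadPair]:
    """Read primary alignments from a SAM file and pool them into pairs.

    Secondary, supplementary and unmapped records are ignored.  The fragment
    strand follows the fr-secondstrand convention (read 1 carries the
    transcript strand).
    """
    grouped: dict[tuple[str, str], list[pysam.AlignedSegment]] = defaultdict(list)
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            grouped[(read.query_name, read.reference_name)].append(read)
    pairs: list[SplicedReadPair] = []
    for (qname, chrom), reads in grouped.items():
        blocks: list[GenomicInterval] = []
        gaps: set[tuple[int, int]] = set()
        strand = "+"
        for read in reads:
            if read.is_read1 or not read.is_paired:
                strand = "-" if read.is_reverse else "+"
            raw_blocks, raw_gaps = _cigar_blocks(read, min_intron)
            blocks.extend(GenomicInterval(chrom, lo, hi) for lo, hi in raw_blocks)
            gaps.update(raw_gaps)
        blocks.sort()
        pairs.append(SplicedReadPair(sample_id, qname, chrom, strand, blocks, gaps))
    pairs.sort(key=lambda p: (p.qname,))
    return pairs


def discover_novel_junctions(
    pairs: list[SplicedReadPair],
    model: FlatGeneModel,
    min_support: int = 5,
    stranded: bool = True,
) -> FlatGeneModel:
    """Append an N-labelled feature for every unannotated gap supported by at
    least ``min_support`` distinct read pairs across all samples."""
    known = {(j.donor, j.acceptor) for j in model.junctions}
    support: dict[tuple[int, int], set[tuple[str, str]]] = defaultdict(set)
    for pair in pairs:
        if pair.chrom != model.chrom:
            continue
        if stranded and pair.fragment_strand != model.strand:
            continue
        for gap in pair.gaps:
            if gap not in known:
                support[gap].add((pair.sample_id, pair.qname))
    novel = sorted(
        (gap for gap, supp in support.items() if len(supp) >= min_support),
        reverse=(model.strand == "-"),
    )
    if not novel:
        return model
    counter = 1 + len(model.exonic_regions) + len(model.junctions)
    augmented = replace(model, junctions=list(model.junctions))
    for donor, acceptor in novel:
        augmented.junctions.append(
            SpliceJunction(model.chrom, donor, acceptor, model.strand, "novel", f"N{counter:03d}")
        )
        counter += 1
    return augmented


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Feature x sample integer counts plus per-gene totals.

    Junction and exon counts overlap by design (one pair can support several
    features), so feature counts need not sum to the gene total.
    """

    feature_info: pd.DataFrame  # label, type, gene_id, chrom, start, end
    counts: pd.DataFrame  # index label, columns sample ids
    gene_totals: pd.DataFrame  # index gene_id, columns sample ids
    size_factors: pd.Series | None = None
    off_target: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        feat = self.feature_info.copy()
        feat = feat.join(self.counts, on="label")
        gene_rows = self.gene_totals.reset_index().rename(columns={"index": "gene_id"})
        gene_rows.insert(0, "label", gene_rows["gene_id"] + ":total")
        gene_rows.insert(1, "type", "gene_total")
        for col in ("chrom", "start", "end"):
            gene_rows[col] = ""
        return pd.concat(
            [feat, gene_rows[feat.columns]], ignore_index=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        meta_cols = ["label", "type", "gene_id", "chrom", "start", "end"]
        sample_cols = [c for c in frame.columns if c not in meta_cols]
        features = frame[frame["type"] != "gene_total"]
        genes = frame[frame["type"] == "gene_total"]
        counts = features.set_index("label")[sample_cols].astype(int)
        gene_totals = genes.set_index("gene_id")[sample_cols].astype(int)
        gene_totals.index.name = None
        return cls(
            feature_info=features[meta_cols].reset_index(drop=True),
            counts=counts,
            gene_totals=gene_totals,
        )


def count_features(
    pairs: list[SplicedReadPair],
    models: list[FlatGeneModel],
    samples: list[str],
    stranded: bool = True,
) -> CountMatrix:
    """Count read pairs over flattened features.

    A pair increments an exonic region when any block overlaps it by at least
    one base, and a junction when one of its gaps equals the junction exactly;
    each pair increments each feature at most once.  The gene total counts
    pairs with any overlap of the gene span.  Reads on contigs absent from
    every model are tallied as off-target.
    """
    info_rows = []
    counts: dict[str, dict[str, int]] = {}
    gene_totals: dict[str, dict[str, int]] = {}
    for model in models:
        for label, ftype, feat in model.features():
            if ftype == EXONIC:
                row = dict(chrom=feat.chrom, start=feat.start, end=feat.end)
            else:
                row = dict(chrom=feat.chrom, start=feat.donor, end=feat.acceptor)
            info_rows.append(dict(label=label, type=ftype, gene_id=model.gene_id, **row))
            counts[label] = {s: 0 for s in samples}
        gene_totals[model.gene_id] = {s: 0 for s in samples}

    known_chroms = {model.chrom for model in models}
    off_target: dict[str, int] = {s: 0 for s in samples}
    for pair in pairs:
        if pair.chrom not in known_chroms:
            off_target[pair.sample_id] = off_target.get(pair.sample_id, 0) + 1
            continue
        for model in models:
            if pair.chrom != model.chrom:
                continue
            if stranded and pair.fragment_strand != model.strand:
                continue
            span = model.span
            touched = False
            for label, iv in model.exonic_regions:
                if any(b.start < iv.end and iv.start < b.end for b in pair.blocks):
                    counts[label][pair.sample_id] += 1
                    touched = True
            for junction in model.junctions:
                if (junction.donor, junction.acceptor) in pair.gaps:
                    counts[junction.label][pair.sample_id] += 1
                    touched = True
            if touched or any(b.start < span.end and span.start < b.end for b in pair.blocks):
                gene_totals[model.gene_id][pair.sample_id] += 1
    if any(off_target.values()):
        warnings.warn(f"off-target read pairs per sample: {off_target}")

    feature_info = pd.DataFrame(
        info_rows, columns=["label", "type", "gene_id", "chrom", "start", "end"]
    )
    count_frame = pd.DataFrame(counts).T.reindex(feature_info["label"])[samples]
    totals = pd.DataFrame(gene_totals).T[samples]
    return CountMatrix(feature_info, count_frame, totals, off_target=off_target)


def estimate_size_factors(gene_totals: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes nonzero in every sample,
    rescaled to geometric mean one.  Falls back to total-count ratios (with a
    warning) when no gene is nonzero everywhere."""
    if gene_totals.shape[1] < 2:
        raise ValueError("need at least two samples")
    if not (gene_totals.to_numpy() > 0).any():
        raise ValueError("all gene totals are zero")
    usable = gene_totals[(gene_totals > 0).all(axis=1)]
    if usable.empty:
        warnings.warn("no gene nonzero in all samples; falling back to total-count ratios")
        factors = gene_totals.sum(axis=0).astype(float)
    else:
        log_ref = np.log(usable).mean(axis=1)
        factors = np.exp(np.median(np.log(usable).sub(log_ref, axis=0), axis=0))
        factors = pd.Series(factors, index=gene_totals.columns)
    factors = factors / np.exp(np.log(factors).mean())
    return factors
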