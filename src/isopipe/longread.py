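"""Classification of long consensus reads (reads of insert, ROI).

The classifier reproduces an amplicon-sequencing workflow: each ROI is first
matched to the PCR primer pairs by semi-global edit distance (full-length =
both ends match the same pair consistently), then compared to the theoretical
isoform amplicons, first as an exact base-for-base string (perfect match) and
then through its spliced genomic alignment (alignment match: the read covers
all of an isoform's exonic regions, splices across all of its junctions,
covers nothing else, and both alignment ends fall within a small tolerance of
the primer endpoints).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd
import pysam

from .feature_counting import FlatGeneModel, _cigar_blocks
from .intervals import GenomicInterval, revcomp

CATEGORIES = (
    "perfect_major",
    "alignment_major",
    "intron_retention_match",
    "minor_variant_match",
    "full_length_unmatched",
    "one_end",
    "no_primer",
    "off_target_alignment",
    "unaligned",
)


@dataclass(frozen=True)
class ReadOfInsert:
    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"ROI {self.id}: sequence must be non-empty over ACGTN")


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; anchors are the genomic endpoints of the amplicon
    (forward primer 5' start, reverse primer 5' anchor, half-open)."""

    id: str
    forward: str
    reverse: str
    fwd_anchor: int
    rev_anchor: int

    def __post_init__(self) -> None:
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError(f"pair {self.id}: primers must be >=15 nt")


@dataclass(frozen=True)
class PrimerMatchResult:
    status: str  # full_length | one_end | none
    pair_id: str | None = None
    orientation: str | None = None  # sense | antisense
    edits: tuple[int, int] | None = None
    normalized: str | None = None  # sense-orientation ROI sequence


def _edit_distance(query: str, target: str, limit: int) -> int:
    """Best semi-global (infix) edit distance of query within target."""
    if not target:
        return limit + 1
    res = edlib.align(query, target, mode="HW", task="distance", k=limit)
    dist = res["editDistance"]
    return dist if dist >= 0 else limit + 1


def match_primers(
    roi: ReadOfInsert, pairs: list[PrimerPair], max_edits: int = 3
) -> PrimerMatchResult:
    """Match both ROI ends against every primer pair in both orientations.

    Each primer (or its reverse complement) is aligned semi-globally against
    a terminal window of twice its length; a full-length call requires both
    ends to match the same pair in a consistent orientation within
    ``max_edits`` per primer.  Primers are not clipped.
    """
    seq = roi.sequence.upper()
    best: tuple[int, PrimerPair, str, tuple[int, int]] | None = None
    single_end = False
    for pair in pairs:
        w5_f = seq[: 2 * len(pair.forward)]
        w3_r = seq[-2 * len(pair.reverse):]
        w5_r = seq[: 2 * len(pair.reverse)]
        w3_f = seq[-2 * len(pair.forward):]
        for orientation in ("sense", "antisense"):
            if orientation == "sense":
                d5 = _edit_distance(pair.forward, w5_f, max_edits)
                d3 = _edit_distance(revcomp(pair.reverse), w3_r, max_edits)
            else:
                d5 = _edit_distance(pair.reverse, w5_r, max_edits)
                d3 = _edit_distance(revcomp(pair.forward), w3_f, max_edits)
            if d5 <= max_edits and d3 <= max_edits:
                cand = (d5 + d3, pair, orientation, (d5, d3))
                if best is None or cand[0] < best[0]:
                    best = cand
            elif d5 <= max_edits or d3 <= max_edits:
                single_end = True
    if best is not None:
        _, pair, orientation, edits = best
        normalized = seq if orientation == "sense" else revcomp(seq)
        return PrimerMatchResult("full_length", pair.id, orientation, edits, normalized)
    if single_end:
        return PrimerMatchResult("one_end")
    return PrimerMatchResult("none")


# ---------------------------------------------------------------------------
# Amplicons and structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    """A theoretical-isoform amplicon: sequence plus genomic block structure."""

    name: str  # unique per (isoform, primer pair)
    isoform: str
    set_name: str  # major | retention | minor
    pair_id: str
    chrom: str
    strand: str
    sequence: str
    blocks: tuple[GenomicInterval, ...]

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


@dataclass(frozen=True)
class Structure:
    """Covered exonic regions, splice-junction chain and end positions of an
    alignment or an amplicon, relative to one flattened gene model."""

    regions: frozenset[str]
    junctions: frozenset[tuple[int, int]]
    start: int
    end: int


def structure_of_blocks(
    blocks: list[GenomicInterval] | tuple[GenomicInterval, ...],
    gaps: set[tuple[int, int]] | None,
    model: FlatGeneModel,
) -> Structure:
    if gaps is None:
        gaps = {(a.end, b.start) for a, b in zip(blocks, blocks[1:])}
    regions = frozenset(
        label
        for label, iv in model.exonic_regions
        if any(b.start < iv.end and iv.start < b.end for b in blocks)
    )
    return Structure(regions, frozenset(gaps), blocks[0].start, blocks[-1].end)


def structure_from_alignment(
    read: pysam.AlignedSegment, model: FlatGeneModel, min_intron: int = 20
) -> Structure:
    raw_blocks, raw_gaps = _cigar_blocks(read, min_intron)
    blocks = [GenomicInterval(read.reference_name, lo, hi) for lo, hi in raw_blocks]
    return structure_of_blocks(blocks, set(raw_gaps), model)


def amplicon_structure(amplicon: Amplicon, model: FlatGeneModel) -> Structure:
    return structure_of_blocks(amplicon.blocks, None, model)


def classify_alignment(
    read_structure: Structure, isoform_structure: Structure, end_tolerance: int = 3
) -> bool:
    """The four-part alignment-match rule: same exonic regions, same junction
    chain, nothing extra, and both ends within ``end_tolerance`` bases of the
    isoform's primer endpoints (boundary inclusive)."""
    return (
        read_structure.regions == isoform_structure.regions
        and read_structure.junctions == isoform_structure.junctions
        and abs(read_structure.start - isoform_structure.start) <= end_tolerance
        and abs(read_structure.end - isoform_structure.end) <= end_tolerance
    )


def detect_intron_retention(
    blocks: list[GenomicInterval] | tuple[GenomicInterval, ...],
    model: FlatGeneModel,
) -> list[tuple[int, int]]:
    """Introns (from the model's junctions) spanned contiguously by a single
    aligned block, i.e. retained rather than spliced."""
    retained = []
    for junction in model.junctions:
        for block in blocks:
            if block.start < junction.donor and block.end > junction.acceptor:
                retained.append((junction.donor, junction.acceptor))
                break
    return sorted(set(retained))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class AmpliconIndex:
    """All theoretical amplicons, indexed for perfect and alignment matching."""

    amplicons: list[Amplicon]
    model: FlatGeneModel
    by_sequence: dict[str, Amplicon] = field(init=False)
    structures: dict[str, Structure] = field(init=False)

    def __post_init__(self) -> None:
        self.by_sequence = {}
        for amp in self.amplicons:
            other = self.by_sequence.get(amp.sequence)
            if other is not None and other.isoform != amp.isoform:
                raise ValueError(
                    f"isoforms {other.isoform} and {amp.isoform} have identical "
                    f"amplicon sequences; the theoretical set is ambiguous"
                )
            self.by_sequence.setdefault(amp.sequence, amp)
        self.structures = {amp.name: amplicon_structure(amp, self.model) for amp in self.amplicons}

    def of_set(self, set_name: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.set_name == set_name]


def classify_perfect(normalized: str, index: AmpliconIndex) -> Amplicon | None:
    return index.by_sequence.get(normalized)


@dataclass
class ROIClassification:
    roi_id: str
    category: str
    isoforms: tuple[str, ...] = ()
    pair_id: str | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_roi(
    roi: ReadOfInsert,
    primer_result: PrimerMatchResult,
    alignment: Structure | None,
    aligned_chrom: str | None,
    index: AmpliconIndex,
    end_tolerance: int = 3,
) -> ROIClassification:
    """Assign exactly one category following the precedence: primer status,
    alignment status, then perfect > alignment-to-major > retention > minor
    variant > full-length-unmatched."""
    if primer_result.status == "none":
        return ROIClassification(roi.id, "no_primer")
    if primer_result.status == "one_end":
        return ROIClassification(roi.id, "one_end")
    if alignment is None:
        return ROIClassification(roi.id, "unaligned")
    if aligned_chrom != index.model.chrom or not (
        alignment.start < index.model.span.end and index.model.span.start < alignment.end
    ):
        return ROIClassification(roi.id, "off_target_alignment")
    perfect = classify_perfect(primer_result.normalized, index)
    if perfect is not None and perfect.set_name == "major":
        return ROIClassification(
            roi.id, "perfect_major", (perfect.isoform,), perfect.pair_id
        )
    for set_name, category in (
        ("major", "alignment_major"),
        ("retention", "intron_retention_match"),
        ("minor", "minor_variant_match"),
    ):
        hits = [
            amp
            for amp in index.of_set(set_name)
            if classify_alignment(alignment, index.structures[amp.name], end_tolerance)
        ]
        if hits:
            isoforms = tuple(sorted({amp.isoform for amp in hits}))
            return ROIClassification(
                roi.id,
                category,
                isoforms,
                hits[0].pair_id if len(isoforms) == 1 else None,
                ambiguous=len(isoforms) > 1,
            )
    return ROIClassification(roi.id, "full_length_unmatched")


def load_roi_alignments(
    sam_path: str, model: FlatGeneModel, min_intron: int = 20
) -> dict[str, tuple[Structure, str]]:
    """Primary ROI alignments from a SAM file, as structures keyed by read id."""
    out: dict[str, tuple[Structure, str]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            out[read.query_name] = (
                structure_from_alignment(read, model, min_intron),
                read.reference_name,
            )
    return out


def classify_cohort(
    rois: list[ReadOfInsert],
    pairs: list[PrimerPair],
    alignments: dict[str, tuple[Structure, str]],
    index: AmpliconIndex,
    max_edits: int = 3,
    end_tolerance: int = 3,
) -> list[ROIClassification]:
    results = []
    for roi in rois:
        primer_result = match_primers(roi, pairs, max_edits)
        aln = alignments.get(roi.id)
        structure, chrom = aln if aln is not None else (None, None)
        results.append(
            classify_roi(roi, primer_result, structure, chrom, index, end_tolerance)
        )
    return results


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def tabulate(
    classifications: list[ROIClassification],
    perfect_tiers: tuple[int, ...] = (1000, 500, 50, 1),
) -> dict[str, pd.DataFrame]:
    """Category summary, per-isoform tallies, and the perfect-match tier
    report (how many isoforms exceed each threshold).

    Ambiguous matches count toward their category but toward no single
    isoform.
    """
    total = len(classifications)
    cat_counts = {cat: 0 for cat in CATEGORIES}
    for c in classifications:
        cat_counts[c.category] += 1
    summary = pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "n_roi": [cat_counts[c] for c in CATEGORIES],
            "pct_roi": [
                100.0 * cat_counts[c] / total if total else 0.0 for c in CATEGORIES
            ],
        }
    )

    perfect: dict[str, int] = defaultdict(int)
    alignment: dict[str, int] = defaultdict(int)
    for c in classifications:
        if c.ambiguous or not c.isoforms:
            continue
        if c.category == "perfect_major":
            perfect[c.isoforms[0]] += 1
        elif c.category == "alignment_major":
            alignment[c.isoforms[0]] += 1
    isoform_ids = sorted(set(perfect) | set(alignment))
    per_isoform = pd.DataFrame(
        {
            "isoform": isoform_ids,
            "perfect_matches": [perfect[i] for i in isoform_ids],
            "alignment_matches": [alignment[i] for i in isoform_ids],
        }
    )

    tiers = pd.DataFrame(
        {
            "min_perfect_matches": list(perfect_tiers),
            "n_isoforms": [
                sum(1 for v in perfect.values() if v >= t) for t in perfect_tiers
            ],
        }
    )
    return {"summary": summary, "per_isoform": per_isoform, "tiers": tiers}
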