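"""Region/sub-variant gene representation and theoretical-isoform enumeration.

A gene is modelled as an ordered series of *variable regions*; each region
holds one or more alternative *sub-variants* (chains of exon fragments).  A
theoretical isoform is one choice of sub-variant per region, subject to
optional ``requires``/``excludes`` compatibility constraints.  Enumerating
every valid combination yields the theoretical isoform set against which
long consensus reads are later classified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .intervals import GenomicInterval, SpliceJunction


class ConstraintError(ValueError):
    """Raised when a sub-variant constraint set is contradictory."""


@dataclass(frozen=True)
class SubVariant:
    """One alternative structure for a variable region.

    ``chain`` lists the exon fragments (5'->3', non-overlapping); an empty
    chain encodes a skip.  ``kind`` is ``start``, ``internal`` or ``end``.
    ``requires``/``excludes`` name sub-variants that must / must not co-occur.
    """

    id: str
    region_id: str
    chain: tuple[GenomicInterval, ...]
    kind: str = "internal"
    requires: frozenset[str] = frozenset()
    excludes: frozenset[str] = frozenset()
    major: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("start", "internal", "end"):
            raise ValueError(f"invalid kind {self.kind!r}")
        for a, b in itertools.pairwise(self.chain):
            if b.start < a.end:
                raise ValueError(f"sub-variant {self.id}: chain not 5'->3' ordered")
        overlap = self.requires & self.excludes
        if overlap:
            raise ConstraintError(
                f"sub-variant {self.id}: {sorted(overlap)} both required and excluded"
            )


@dataclass
class RegionTable:
    """Ordered variable regions of one gene, each with its sub-variants."""

    gene_id: str
    chrom: str
    strand: str
    regions: list[tuple[str, list[SubVariant]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for region_id, subs in self.regions:
            for sv in subs:
                if sv.region_id != region_id:
                    raise ValueError(
                        f"sub-variant {sv.id} declares region {sv.region_id}, "
                        f"listed under {region_id}"
                    )
        kinds = {sv.kind for _, subs in self.regions for sv in subs}
        if self.regions and not {"start", "end"} <= kinds:
            raise ValueError("table must contain at least one start and one end sub-variant")

    @property
    def subvariants(self) -> list[SubVariant]:
        return [sv for _, subs in self.regions for sv in subs]

    def majors_only(self) -> "RegionTable":
        """Restrict each region to its major-flagged sub-variants."""
        regions = []
        for region_id, subs in self.regions:
            majors = [sv for sv in subs if sv.major]
            if not majors:
                raise ValueError(f"region {region_id} has no major sub-variant")
            regions.append((region_id, majors))
        return RegionTable(self.gene_id, self.chrom, self.strand, regions)

    def unconstrained(self) -> "RegionTable":
        """Drop all cross-region constraints (full combinatorial space)."""
        regions = [
            (rid, [replace(sv, requires=frozenset(), excludes=frozenset()) for sv in subs])
            for rid, subs in self.regions
        ]
        return RegionTable(self.gene_id, self.chrom, self.strand, regions)


@dataclass
class TheoreticalIsoform:
    """One enumerated combination: an exon chain plus derived junctions."""

    id: int
    gene_id: str
    chrom: str
    strand: str
    subvariant_ids: tuple[str, ...]
    exon_chain: tuple[GenomicInterval, ...]
    junction_chain: tuple[SpliceJunction, ...]
    sequence: str | None = None

    @property
    def name(self) -> str:
        return f"{self.gene_id}-iso{self.id:02d}"


def derive_junctions(
    exon_chain: tuple[GenomicInterval, ...] | list[GenomicInterval],
) -> list[SpliceJunction]:
    """One junction per adjacent exon pair: donor = upstream end, acceptor =
    downstream start.  Touching or overlapping exons are rejected (merge them
    first)."""
    junctions = []
    for a, b in itertools.pairwise(exon_chain):
        if b.start <= a.end:
            raise ValueError(
                f"exons {a.start}-{a.end} and {b.start}-{b.end} touch or overlap; "
                "no intron between them"
            )
        junctions.append(SpliceJunction(a.chrom, a.end, b.start, a.strand))
    return junctions


def merge_chain(fragments: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Merge adjacent (touching) exon fragments into single exons; the input
    must already be strictly ordered and non-overlapping."""
    merged: list[GenomicInterval] = []
    for frag in fragments:
        if merged and frag.start < merged[-1].end:
            raise ValueError(
                f"exon fragments overlap at {frag.chrom}:{frag.start}-{frag.end}"
            )
        if merged and frag.start == merged[-1].end:
            prev = merged.pop()
            merged.append(GenomicInterval(prev.chrom, prev.start, frag.end, prev.strand))
        else:
            merged.append(frag)
    return tuple(merged)


def _validate_constraints(table: RegionTable) -> None:
    by_id = {sv.id: sv for sv in table.subvariants}
    for sv in table.subvariants:
        for other_id in sv.requires:
            other = by_id.get(other_id)
            if other is not None and sv.id in other.excludes:
                raise ConstraintError(
                    f"contradictory constraints: {sv.id} requires {other_id} "
                    f"but {other_id} excludes {sv.id}"
                )


def _combination_valid(chosen: tuple[SubVariant, ...]) -> bool:
    ids = {sv.id for sv in chosen}
    for sv in chosen:
        if sv.requires and not sv.requires <= ids:
            return False
        if sv.excludes & ids:
            return False
    return True


def enumerate_isoforms(
    table: RegionTable, majors_only: bool = False
) -> list[TheoreticalIsoform]:
    """Enumerate every valid combination, one sub-variant per region.

    Ordering is deterministic: regions iterate 5'->3' with the last region
    varying fastest and sub-variants in their declared order, so the first
    region (the start sites, in declared order) is the outermost key.
    Surviving combinations are numbered from 1.
    """
    if majors_only:
        table = table.majors_only()
    for region_id, subs in table.regions:
        if not subs:
            raise ValueError(f"region {region_id} holds no sub-variants")
    _validate_constraints(table)

    isoforms: list[TheoreticalIsoform] = []
    next_id = 1
    for chosen in itertools.product(*(subs for _, subs in table.regions)):
        if not _combination_valid(chosen):
            continue
        fragments = [iv for sv in chosen for iv in sv.chain]
        exon_chain = merge_chain(fragments)
        junctions = tuple(derive_junctions(exon_chain))
        isoforms.append(
            TheoreticalIsoform(
                id=next_id,
                gene_id=table.gene_id,
                chrom=table.chrom,
                strand=table.strand,
                subvariant_ids=tuple(sv.id for sv in chosen),
                exon_chain=exon_chain,
                junction_chain=junctions,
            )
        )
        next_id += 1
    return isoforms
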