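"""Synthetic data with complete truth: a toy multi-region gene, NB count
matrices with condition-specific usage shifts, spliced short-read pairs, and
error-injected long-read (ROI) cohorts.

The toy gene emulates the structure of a neurally regulated, multi-region
ciliopathy-type gene: an annotated start plus two alternative
start exons that share a downstream in-frame ATG in Kozak context, a 30-nt
frame-preserving cassette exon, a skippable 86-nt exon whose removal
frame-shifts into an early stop, two novel terminal exons with short ORFs, a
retainable intron carrying a stop a few codons in, and low-usage internal
variants (a late donor, an alternative acceptor, two stop-introducing
cassettes).  All introns are GT-AG.

Sequence content is built codon-by-codon so the designed reading frames are
guaranteed: coding codons come from a stop-free, ATG-free pool; "stamp"
codon pairs placed every few codons put stop codons into both shifted
frames; non-coding stretches carry stop stamps in all three frames and are
scrubbed of ATG.  Every designed claim (ORF starts, stop placements, GT-AG)
is re-verified after construction and raises ``ToyGeneError`` on violation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .feature_counting import CountMatrix, FlatGeneModel, flatten_annotation
from .gene_model import (
    RegionTable,
    SubVariant,
    TheoreticalIsoform,
    enumerate_isoforms,
    merge_chain,
    derive_junctions,
)
from .intervals import GenomicInterval, revcomp
from .io import Transcript, atomic_write, isoforms_to_transcripts, write_fasta, write_gtf, write_primer_table, write_region_table
from .longread import Amplicon, AmpliconIndex, PrimerPair
from .orf import find_largest_orf
from .sequences import extract_sequence, junction_motif


class ToyGeneError(ValueError):
    """The requested geometry cannot satisfy the GT-AG / ORF constraints."""


# Codon pool: no stops, no ATG, and no codon starting with TA/TG (so no codon
# boundary can seed a frame-shifted stop) or ending in AT (no cross-codon ATG).
_POOL = [
    "GCT", "GCC", "GCA", "GAA", "GAG", "CTG", "CTC", "TTC",
    "AAC", "AAA", "GGA", "GGC", "CAG", "CAC", "TCC", "ACC",
]
# Stamp pairs: pair A puts TAA in frame +1 at the codon boundary, pair B puts
# TAA in frame +2.
_STAMP_A = ("TTA", "AGT")
_STAMP_B = ("CTT", "AAT")
_NONCODING_STAMP = "TAAGTAAGTAA"  # stop in all three frames, ATG-free

PRIMER_LEN = 20


def _pool_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_POOL[i] for i in rng.integers(0, len(_POOL), size=n)]


def _scrub_atg(seq: str) -> str:
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[: i + 2] + "C" + seq[i + 3 :]
    return seq


def _noncoding(rng: np.random.Generator, length: int, stamp_every: int = 40) -> str:
    chars = rng.choice(list("ACGT"), size=length)
    seq = "".join(chars)
    out = []
    pos = 0
    while pos < length:
        chunk = seq[pos : pos + stamp_every]
        out.append(chunk)
        pos += stamp_every
        if pos < length - len(_NONCODING_STAMP):
            out.append(_NONCODING_STAMP)
            pos += len(_NONCODING_STAMP)
    return _scrub_atg("".join(out)[:length].ljust(length, "C"))


@dataclass
class ToyGeneConfig:
    seed: int = 0
    contig: str = "chrT"
    gene_id: str = "toygene"
    intron_length: int = 120
    cassette_length: int = 30  # frame-preserving cassette (10 codons)
    skip_exon_length: int = 86  # frame-shifting when skipped
    n_domains: int = 8


@dataclass
class ToyGene:
    """A fully specified toy gene: genome, region table, annotation, primers,
    domains and designed-truth bookkeeping."""

    config: ToyGeneConfig
    genome: dict[str, str]
    region_table: RegionTable  # all 21 sub-variants, constraint on the cassette
    annotation: list[Transcript]  # "known" transcripts
    primers: list[PrimerPair]
    domains: list[tuple[int, int]]  # aa coordinates on the reference protein
    exons: dict[str, GenomicInterval]
    reference_orf_aa: int
    alt_start_codon_offset: int  # aa offset of the internal ATG on the reference

    # -- enumeration helpers ------------------------------------------------
    def major_isoforms(self) -> list[TheoreticalIsoform]:
        return enumerate_isoforms(self.region_table, majors_only=True)

    def all_isoforms(self) -> list[TheoreticalIsoform]:
        return enumerate_isoforms(self.region_table.unconstrained())

    def retention_isoforms(self) -> list[TheoreticalIsoform]:
        """Major combinations with the two-exon b-terminal replaced by its
        intron-retained single-block form."""
        tb1, tb2 = self.exons["Tb1"], self.exons["Tb2"]
        retained_block = GenomicInterval(tb1.chrom, tb1.start, tb2.end, tb1.strand)
        out = []
        for iso in self.major_isoforms():
            if "end-9b" not in iso.subvariant_ids:
                continue
            chain = [iv for iv in iso.exon_chain if iv not in (tb1, tb2)] + [retained_block]
            chain.sort()
            exon_chain = merge_chain(chain)
            subs = tuple(
                "end-9b-retained" if s == "end-9b" else s for s in iso.subvariant_ids
            )
            out.append(
                TheoreticalIsoform(
                    id=iso.id,
                    gene_id=iso.gene_id + "-ret",
                    chrom=iso.chrom,
                    strand=iso.strand,
                    subvariant_ids=subs,
                    exon_chain=exon_chain,
                    junction_chain=tuple(derive_junctions(exon_chain)),
                )
            )
        return out

    # -- amplicons and classification index ---------------------------------
    def pair_for(self, iso: TheoreticalIsoform) -> PrimerPair:
        start = iso.subvariant_ids[0]
        end = iso.subvariant_ids[-1]
        fwd = {"exon1-start": "1", "exon3a-start": "2", "exon3b-start": "3"}[start]
        rev = {"end-9a": "a", "end-9b": "b", "end-9b-retained": "b"}.get(end, "k")
        pair_id = f"P{fwd}{rev}"
        return next(p for p in self.primers if p.id == pair_id)

    def amplicons(self) -> list[Amplicon]:
        majors = self.major_isoforms()
        retentions = self.retention_isoforms()
        claimed = {iso.subvariant_ids for iso in majors + retentions}
        minors = [
            iso for iso in self.all_isoforms() if iso.subvariant_ids not in claimed
        ]
        records: list[Amplicon] = []
        for set_name, isoforms in (
            ("major", majors),
            ("retention", retentions),
            ("minor", minors),
        ):
            for iso in isoforms:
                name = f"{set_name}-{iso.id:03d}"
                pair = self.pair_for(iso)
                records.append(
                    Amplicon(
                        name=name,
                        isoform=name,
                        set_name=set_name,
                        pair_id=pair.id,
                        chrom=iso.chrom,
                        strand=iso.strand,
                        sequence=extract_sequence(self.genome, iso.exon_chain, iso.strand),
                        blocks=iso.exon_chain,
                    )
                )
        return records

    def classification_model(self) -> FlatGeneModel:
        """Flattened model over the complete theoretical set (used to define
        regions/junctions for the alignment-match rule)."""
        txs = isoforms_to_transcripts(self.all_isoforms() + self.retention_isoforms())
        return flatten_annotation(txs)

    def amplicon_index(self) -> AmpliconIndex:
        return AmpliconIndex(self.amplicons(), self.classification_model())

    # -- output -------------------------------------------------------------
    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "regions": os.path.join(outdir, "regions.tsv"),
            "annotation": os.path.join(outdir, "annotation.gtf"),
            "primers": os.path.join(outdir, "primers.tsv"),
        }
        write_fasta(self.genome, paths["genome"])
        write_region_table(self.region_table, paths["regions"])
        write_gtf(self.annotation, paths["annotation"])
        write_primer_table(self.primers, paths["primers"])
        return paths


def make_toy_gene(config: ToyGeneConfig | int = 0) -> ToyGene:
    """Build the toy gene deterministically from a seed (or full config)."""
    if isinstance(config, int):
        config = ToyGeneConfig(seed=config)
    rng = np.random.default_rng(config.seed)
    if config.cassette_length % 3 or config.cassette_length < 12:
        raise ToyGeneError("cassette length must be a multiple of 3 and >= 12")
    if config.skip_exon_length % 3 == 0:
        raise ToyGeneError("skippable exon length must not be a multiple of 3")

    # --- reference coding stream -------------------------------------------
    coding_lengths = {
        "S1": 90, "E2": 90, "E3": 120, "E4": 90, "E5": 90, "E6": 90,
        "E7": config.skip_exon_length, "E8": 90, "E9": 90,
        "E10": 90, "E11": 90, "E12": 90, "E13": 90, "E14": 46,
    }
    total = sum(coding_lengths.values())
    pad = (3 - total % 3) % 3
    coding_lengths["E14"] += pad
    total += pad
    n_codons = total // 3
    codons = _pool_codons(rng, n_codons)
    stamp_toggle = True
    for k in range(4, n_codons - 1, 8):
        if k in (69, 70, 71) or k + 1 in (69, 70, 71):
            continue
        pair = _STAMP_A if stamp_toggle else _STAMP_B
        codons[k], codons[k + 1] = pair
        stamp_toggle = not stamp_toggle
    codons[0] = "ATG"  # annotated start (exon 1)
    codons[1] = "GCT"  # +4 G for the Kozak context
    codons[69] = "GCA"  # -3 purine for the internal ATG
    codons[70] = "ATG"  # shared downstream start used by the alternative TSSs
    codons[71] = "GCT"  # +4 G
    stream = "".join(codons)

    seg: dict[str, str] = {}
    offset = 0
    offsets: dict[str, int] = {}
    for name, length in coding_lengths.items():
        offsets[name] = offset
        seg[name] = stream[offset : offset + length]
        offset += length

    # frame-shift stop for the skip of E7: TAA at the skip-frame codon that
    # starts at E8 offset 9 (ref-frame codons there straddle it harmlessly)
    seg["E8"] = seg["E8"][:9] + "TAA" + seg["E8"][12:]
    # AG acceptor inside E9 for the alternative acceptor variant
    seg["E9"] = seg["E9"][:7] + "AG" + seg["E9"][9:]

    # --- non-stream exon content -------------------------------------------
    c2a = _scrub_atg("".join(_pool_codons(rng, config.cassette_length // 3)))
    ta = "C" + "".join(_pool_codons(rng, 2)) + "TAA" + _noncoding(rng, 110)
    tb1 = "C" + "".join(_pool_codons(rng, 19)) + "CC"
    intron_b = (
        "GT" + "CC" + "".join(_pool_codons(rng, 3)) + "TAA" + _noncoding(rng, 72) + "AG"
    )
    tb2 = "C" + "".join(_pool_codons(rng, 1)) + "TAA" + _noncoding(rng, 73)
    c10a = "C" + "".join(_pool_codons(rng, 1)) + "TAA" + _noncoding(rng, 26)
    c11a = "C" + "".join(_pool_codons(rng, 1)) + "TAA" + _noncoding(rng, 26)
    ext4 = "GTC" + "".join(_pool_codons(rng, 1)) + "TAA" + _noncoding(rng, 15)
    utr5 = _noncoding(rng, 23) + "C" + "GCCACC"
    utr3 = _noncoding(rng, 41)
    s2a = _noncoding(rng, 80)
    s2b = _noncoding(rng, 70)

    exon_seqs = {
        "S1": utr5 + seg["S1"],
        "S2a": s2a,
        "S2b": s2b,
        "E2": seg["E2"],
        "C2a": c2a,
        "E3": seg["E3"],
        "E4": seg["E4"],
        "E5": seg["E5"],
        "E6": seg["E6"],
        "E7": seg["E7"],
        "E8": seg["E8"],
        "E9": seg["E9"],
        "Ta": ta,
        "Tb1": tb1,
        "Tb2": tb2,
        "E10": seg["E10"],
        "C10a": c10a,
        "E11": seg["E11"],
        "C11a": c11a,
        "E12": seg["E12"],
        "E13": seg["E13"],
        "E14": seg["E14"] + "TAA" + utr3,
    }

    # --- genome assembly ----------------------------------------------------
    gil = config.intron_length
    order = [
        "S1", "S2a", "S2b", "E2", "C2a", "E3", "E4", "E5", "E6", "E7", "E8",
        "E9", "Ta", "Tb1", "Tb2", "E10", "C10a", "E11", "C11a", "E12", "E13", "E14",
    ]
    donors = {
        "S1", "S2a", "S2b", "E2", "C2a", "E3", "E4", "E5", "E6", "E7", "E8",
        "E9", "Tb1", "E10", "C10a", "E11", "C11a", "E12", "E13",
    }
    acceptors = {
        "E2", "C2a", "E3", "E4", "E5", "E6", "E7", "E8", "E9", "Ta", "Tb1",
        "Tb2", "E10", "C10a", "E11", "C11a", "E12", "E13", "E14",
    }
    parts: list[str] = [_noncoding(rng, 50)]
    exons: dict[str, GenomicInterval] = {}
    pos = 50
    for i, name in enumerate(order):
        body = exon_seqs[name]
        exons[name] = GenomicInterval(config.contig, pos, pos + len(body))
        parts.append(body)
        pos += len(body)
        if i == len(order) - 1:
            parts.append(_noncoding(rng, 60))
            pos += 60
            break
        nxt = order[i + 1]
        if name == "E4":
            gap = "GT" + ext4[2:] + "GT" + _noncoding(rng, gil - 28) + "AG"
        elif name == "Tb1":
            gap = intron_b
        else:
            gap = _noncoding(rng, gil)
            if name in donors:
                gap = "GT" + gap[2:]
            if nxt in acceptors:
                gap = gap[:-2] + "AG"
        parts.append(gap)
        pos += len(gap)
    genome = {config.contig: "".join(parts)}

    ext4_interval = GenomicInterval(config.contig, exons["E4"].start, exons["E4"].end + 24)
    e9alt = GenomicInterval(config.contig, exons["E9"].start + 9, exons["E9"].end)
    retained = GenomicInterval(config.contig, exons["Tb1"].start, exons["Tb2"].end)

    def sv(sid, rid, chain, kind="internal", requires=(), major=False):
        return SubVariant(
            id=sid, region_id=rid, chain=tuple(chain), kind=kind,
            requires=frozenset(requires), major=major,
        )

    E = exons
    long_tail = [E["E10"], E["E11"], E["E12"], E["E13"], E["E14"]]
    regions = [
        ("R1-start", [
            sv("exon1-start", "R1-start", [E["S1"], E["E2"]], "start", major=True),
            sv("exon3a-start", "R1-start", [E["S2a"], E["E2"]], "start", major=True),
            sv("exon3b-start", "R1-start", [E["S2b"], E["E2"]], "start", major=True),
        ]),
        ("R2-cassette", [
            sv("c2a-include", "R2-cassette", [E["C2a"]], requires={"exon1-start"}, major=True),
            sv("c2a-skip", "R2-cassette", [], major=True),
        ]),
        ("R3-exon4", [
            sv("exon4-normal", "R3-exon4", [E["E3"], E["E4"]], major=True),
            sv("exon4-late-donor", "R3-exon4", [E["E3"], ext4_interval]),
            sv("exon4-skip", "R3-exon4", [E["E3"]]),
        ]),
        ("R4-exon5-6", [sv("exon5-6", "R4-exon5-6", [E["E5"], E["E6"]], major=True)]),
        ("R5-exon7", [
            sv("exon7-include", "R5-exon7", [E["E7"]], major=True),
            sv("exon7-skip", "R5-exon7", [], major=True),
        ]),
        ("R6-exon8", [sv("exon8", "R6-exon8", [E["E8"]], major=True)]),
        ("R7-exon9", [
            sv("exon9-normal", "R7-exon9", [E["E9"]], major=True),
            sv("exon9-alt-acceptor", "R7-exon9", [e9alt]),
            sv("exon9-skip", "R7-exon9", []),
        ]),
        ("R8-terminal", [
            sv("end-9a", "R8-terminal", [E["Ta"]], "end", major=True),
            sv("end-9b", "R8-terminal", [E["Tb1"], E["Tb2"]], "end", major=True),
            sv("end-known", "R8-terminal", long_tail, "end", major=True),
            sv("end-9b-retained", "R8-terminal", [retained], "end"),
            sv("end-known-10a", "R8-terminal",
               [E["E10"], E["C10a"], E["E11"], E["E12"], E["E13"], E["E14"]], "end"),
            sv("end-known-11a", "R8-terminal",
               [E["E10"], E["E11"], E["C11a"], E["E12"], E["E13"], E["E14"]], "end"),
        ]),
    ]
    table = RegionTable(config.gene_id, config.contig, "+", regions)

    # --- known annotation (three transcripts) --------------------------------
    s1_short = GenomicInterval(config.contig, E["S1"].start + 15, E["S1"].end)
    e14_trunc = GenomicInterval(config.contig, E["E14"].start, E["E14"].end - 30)
    annotation = [
        Transcript("tx-standard", config.gene_id, config.contig, "+",
                   [E["S1"], E["E2"], E["E3"], E["E4"], E["E5"], E["E6"], E["E7"],
                    E["E8"], E["E9"]] + long_tail),
        Transcript("tx-retina", config.gene_id, config.contig, "+",
                   [s1_short, E["E2"], E["C2a"], E["E3"], E["E4"], E["E5"], E["E6"],
                    E["E7"], E["E8"], E["E9"], E["Tb1"]]),
        Transcript("tx-fragment", config.gene_id, config.contig, "+",
                   [E["E13"], e14_trunc]),
    ]

    # --- primers --------------------------------------------------------------
    contig_seq = genome[config.contig]

    def exon_seq(name):
        iv = exons[name]
        return contig_seq[iv.start : iv.end]

    fwd = {"1": exon_seq("S1")[:PRIMER_LEN], "2": exon_seq("S2a")[:PRIMER_LEN],
           "3": exon_seq("S2b")[:PRIMER_LEN]}
    rev = {"a": revcomp(exon_seq("Ta")[-PRIMER_LEN:]),
           "b": revcomp(exon_seq("Tb2")[-PRIMER_LEN:]),
           "k": revcomp(exon_seq("E14")[-PRIMER_LEN:])}
    rev_anchor = {"a": E["Ta"].end, "b": E["Tb2"].end, "k": E["E14"].end}
    fwd_anchor = {"1": E["S1"].start, "2": E["S2a"].start, "3": E["S2b"].start}
    primers = [
        PrimerPair(f"P{f}{r}", fwd[f], rev[r], fwd_anchor[f], rev_anchor[r])
        for f in "123" for r in "abk"
    ]

    n_dom = config.n_domains
    domains = [(280 + 16 * k, 292 + 16 * k) for k in range(n_dom)]

    gene = ToyGene(
        config=config,
        genome=genome,
        region_table=table,
        annotation=annotation,
        primers=primers,
        domains=domains,
        exons=exons,
        reference_orf_aa=n_codons,
        alt_start_codon_offset=70,
    )
    _verify_toy_gene(gene)
    return gene


def _verify_toy_gene(gene: ToyGene) -> None:
    """Re-check the designed constraints; raise ToyGeneError on violation."""
    majors = gene.major_isoforms()
    if len(majors) != 24:
        raise ToyGeneError(f"major enumeration produced {len(majors)} isoforms")
    for iso in majors:
        for junction in iso.junction_chain:
            _, _, canonical = junction_motif(gene.genome, junction)
            if not canonical:
                raise ToyGeneError(
                    f"non-GT-AG intron {junction.donor}-{junction.acceptor} "
                    f"in isoform {iso.id}"
                )
        seq = extract_sequence(gene.genome, iso.exon_chain, iso.strand)
        orf = find_largest_orf(seq)
        start_sv = iso.subvariant_ids[0]
        if start_sv == "exon1-start":
            if orf.start != 30:
                raise ToyGeneError(f"isoform {iso.id}: ORF start {orf.start}, expected 30")
        else:
            start_len = {"exon3a-start": 80, "exon3b-start": 70}[start_sv]
            expected = start_len + 90 + 30  # start exon + E2 + into E3
            if orf.start != expected:
                raise ToyGeneError(
                    f"isoform {iso.id}: ORF start {orf.start}, expected {expected}"
                )
        if not orf.kozak_ok:
            raise ToyGeneError(f"isoform {iso.id}: start codon lacks Kozak context")
    # cassette adds exactly cassette_length/3 amino acids
    by_subs = {iso.subvariant_ids: iso for iso in majors}
    with_c = by_subs[("exon1-start", "c2a-include", "exon4-normal", "exon5-6",
                      "exon7-include", "exon8", "exon9-normal", "end-known")]
    without_c = by_subs[("exon1-start", "c2a-skip", "exon4-normal", "exon5-6",
                         "exon7-include", "exon8", "exon9-normal", "end-known")]
    gain = (
        find_largest_orf(extract_sequence(gene.genome, with_c.exon_chain)).aa_length
        - find_largest_orf(extract_sequence(gene.genome, without_c.exon_chain)).aa_length
    )
    if gain != gene.config.cassette_length // 3:
        raise ToyGeneError(f"cassette changes ORF by {gain} aa")


# ---------------------------------------------------------------------------
# NB count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    seed: int = 0
    n_replicates: int = 3  # per condition, as in the study design
    conditions: tuple[str, str] = ("day", "night")
    gene_mean: float = 300.0
    dispersion: float = 0.05
    baseline_usage: float = 0.1  # per-feature mean as a fraction of gene mean
    usage_shift: dict[str, float] = field(default_factory=dict)  # label -> fold in condition B
    n_null_genes: int = 0
    # One tested feature per null gene makes the gene-rest an independent NB
    # draw with the feature's dispersion -- exactly the model the usage test
    # assumes -- so null filler genes are calibrated by construction.
    features_per_null_gene: int = 1
    library_factors: tuple[float, ...] | None = None  # true per-sample factors


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    model: FlatGeneModel | None,
    config: CountSimConfig,
    baseline_weights: dict[str, float] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw an NB count matrix over a flattened model plus optional null
    filler genes.

    Each feature count is drawn NB(gene_mean * usage * library_factor,
    dispersion); a usage shift multiplies the affected feature's mean in the
    second condition, so the realized between-condition mean ratio equals the
    shift.  The gene total is the sum of the gene's exonic feature draws plus
    an independent NB background draw covering the rest of the gene (mean
    gene_mean * (1 - total exonic usage), zero when the exonic usages already
    reach 1).  With one feature per gene the gene-rest is therefore exactly
    an independent NB count with the feature's dispersion -- the model the
    usage test assumes -- which is the configuration calibration studies
    should use (and the default for null filler genes).  Junction features
    are not added to the total: a junction-supporting fragment is already
    inside the exonic bins it spans.  ``baseline_weights`` overrides the
    per-feature usage fraction (default ``baseline_usage``) by label.

    Returns the matrix and a per-feature truth table.
    """
    rng = np.random.default_rng(config.seed)
    samples = [
        f"{cond}{i+1}" for cond in config.conditions for i in range(config.n_replicates)
    ]
    cond_b = np.array(
        [s.startswith(config.conditions[1]) for s in samples], dtype=bool
    )
    if config.library_factors is None:
        lib = np.exp(rng.uniform(-0.3, 0.3, size=len(samples)))
        lib /= np.exp(np.mean(np.log(lib)))
    else:
        lib = np.array(config.library_factors, dtype=float)

    features: list[dict] = []
    if model is not None:
        for label, ftype, feat in model.features():
            coords = (
                (feat.start, feat.end) if ftype == "exonic_region" else (feat.donor, feat.acceptor)
            )
            features.append(
                dict(label=label, type=ftype, gene_id=model.gene_id,
                     chrom=model.chrom, start=coords[0], end=coords[1])
            )
    for g in range(config.n_null_genes):
        for f in range(config.features_per_null_gene):
            features.append(
                dict(label=f"null{g:03d}:F{f:02d}", type="exonic_region",
                     gene_id=f"null{g:03d}", chrom="chrN", start=f * 100, end=f * 100 + 99)
            )

    by_gene: dict[str, list[dict]] = {}
    for feat in features:
        by_gene.setdefault(feat["gene_id"], []).append(feat)

    truth_rows = []
    counts: dict[str, np.ndarray] = {}
    totals: dict[str, np.ndarray] = {}
    for gene_id, feats in by_gene.items():
        exonic_sum = np.zeros(len(samples), dtype=np.int64)
        exonic_usage = 0.0
        for feat in feats:
            usage = (baseline_weights or {}).get(feat["label"], config.baseline_usage)
            shift = config.usage_shift.get(feat["label"], 1.0)
            mean = config.gene_mean * usage * lib * np.where(cond_b, shift, 1.0)
            counts[feat["label"]] = _nb_draw(rng, mean, config.dispersion)
            if feat["type"] == "exonic_region":
                exonic_sum += counts[feat["label"]]
                exonic_usage += usage
            truth_rows.append(
                dict(label=feat["label"], gene_id=gene_id,
                     baseline_mean=config.gene_mean * usage,
                     true_shift=shift, shifted=shift != 1.0)
            )
        background_mean = config.gene_mean * max(1.0 - exonic_usage, 0.0)
        background = (
            _nb_draw(rng, background_mean * lib, config.dispersion)
            if background_mean > 0
            else np.zeros(len(samples), dtype=np.int64)
        )
        totals[gene_id] = exonic_sum + background

    feature_info = pd.DataFrame(features)
    count_frame = pd.DataFrame(counts, index=samples).T
    gene_totals = pd.DataFrame(totals, index=samples).T
    matrix = CountMatrix(
        feature_info[["label", "type", "gene_id", "chrom", "start", "end"]],
        count_frame,
        gene_totals,
    )
    truth = pd.DataFrame(truth_rows)
    truth["samples"] = [",".join(samples)] * len(truth)
    return matrix, truth


# ---------------------------------------------------------------------------
# Short spliced read-pair simulation (SAM)
# ---------------------------------------------------------------------------

def _transcript_to_blocks(
    exon_chain: tuple[GenomicInterval, ...], t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Map a transcript-coordinate interval onto genomic blocks."""
    blocks = []
    offset = 0
    for exon in exon_chain:
        length = len(exon)
        lo = max(t_start - offset, 0)
        hi = min(t_end - offset, length)
        if lo < hi:
            blocks.append(GenomicInterval(exon.chrom, exon.start + lo, exon.start + hi))
        offset += length
    return blocks


def _blocks_to_cigar(blocks: list[GenomicInterval]) -> str:
    parts = []
    for i, block in enumerate(blocks):
        if i:
            gap = block.start - blocks[i - 1].end
            parts.append(f"{gap}N")
        parts.append(f"{len(block)}M")
    return "".join(parts)


def simulate_read_pairs(
    isoforms: list[TheoreticalIsoform],
    genome: dict[str, str],
    sam_path: str | os.PathLike,
    n_pairs: int = 2000,
    weights: dict[int, float] | None = None,
    read_length: int = 76,
    fragment_range: tuple[int, int] = (160, 300),
    sample_id: str = "sim",
    seed: int = 0,
) -> pd.DataFrame:
    """Emit error-free paired spliced alignments drawn from the given
    isoforms; returns a truth table of per-pair blocks and gaps."""
    rng = np.random.default_rng(seed)
    seqs = [extract_sequence(genome, iso.exon_chain, iso.strand) for iso in isoforms]
    if weights is None:
        w = np.ones(len(isoforms))
    else:
        w = np.array([weights.get(iso.id, 0.0) for iso in isoforms], dtype=float)
    w = w / w.sum()
    chrom = isoforms[0].chrom
    contig_len = len(genome[chrom])

    truth_rows = []
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": contig_len}, {"SN": "chrN", "LN": 1000}],
    }
    path = os.fspath(sam_path)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in range(n_pairs):
            idx = rng.choice(len(isoforms), p=w)
            iso = isoforms[idx]
            length = len(seqs[idx])
            frag = int(rng.integers(*fragment_range))
            frag = min(frag, length)
            start = int(rng.integers(0, length - frag + 1))
            mate_spans = [(start, start + read_length), (start + frag - read_length, start + frag)]
            qname = f"pair{i:06d}"
            pair_blocks = []
            pair_gaps = set()
            for mate_idx, (lo, hi) in enumerate(mate_spans):
                lo, hi = max(lo, 0), min(hi, length)
                blocks = _transcript_to_blocks(iso.exon_chain, lo, hi)
                pair_blocks.extend(blocks)
                pair_gaps.update(
                    (a.end, b.start) for a, b in zip(blocks, blocks[1:])
                )
                read = pysam.AlignedSegment()
                read.query_name = qname
                read.reference_id = 0
                read.reference_start = blocks[0].start
                read.cigarstring = _blocks_to_cigar(blocks)
                seq = seqs[idx][lo:hi]
                read.query_sequence = seq if mate_idx == 0 else revcomp(seq)
                read.flag = (0x1 | 0x2 | 0x40 | 0x20) if mate_idx == 0 else (0x1 | 0x2 | 0x80 | 0x10)
                read.mapping_quality = 60
                out.write(read)
            truth_rows.append(
                dict(
                    qname=qname, isoform=iso.id, sample_id=sample_id,
                    blocks=";".join(f"{b.start}-{b.end}" for b in sorted(pair_blocks)),
                    gaps=";".join(f"{d}-{a}" for d, a in sorted(pair_gaps)),
                )
            )
    return pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ROI simulation
# ---------------------------------------------------------------------------

@dataclass
class ROISimConfig:
    """ROI cohort settings.  The default mixture proportions are calibrated to
    the composition reported for the real sequencing run they emulate
    (full-length fraction 62.5%, retention 5.9%, minor variants 0.4%)."""

    seed: int = 0
    n_rois: int = 10_000
    error_rate: float = 0.01  # per-base; 80% substitutions, 10% ins, 10% del
    # Consensus reads vary in pass count, so a sizable fraction carry no
    # residual errors at all; 0.368 reproduces the reported perfect vs
    # alignment-match split among full-length major matches.
    error_free_fraction: float = 0.368
    full_length_fraction: float = 0.625
    both_end_truncation_fraction: float = 0.515  # of non-full-length ROIs
    retention_fraction: float = 0.059
    minor_fraction: float = 0.004
    abundance: dict[str, float] | None = None  # major amplicon name -> weight
    random_orientation: bool = True


def _inject_errors(
    rng: np.random.Generator, seq: str, blocks: list[GenomicInterval], error_rate: float
) -> tuple[str, list[tuple[str, int]], int, int]:
    """Mutate a read and return (sequence, cigar ops, n_edits, ref_offset).

    Ops are (op, length) over the original read coordinates with M runs split
    by N gaps supplied via ``blocks``; substitutions keep M, insertions add I,
    deletions add D.
    """
    bases = "ACGT"
    ops: list[tuple[str, int]] = []
    out: list[str] = []
    n_edits = 0
    block_lengths = [len(b) for b in blocks]
    gaps = [b.start - a.end for a, b in zip(blocks, blocks[1:])]
    pos = 0
    for bi, blen in enumerate(block_lengths):
        if bi:
            ops.append(("N", gaps[bi - 1]))
        for j in range(blen):
            base = seq[pos]
            pos += 1
            if error_rate > 0 and rng.random() < error_rate:
                n_edits += 1
                kind = rng.random()
                if kind < 0.8:  # substitution
                    base = bases[(bases.index(base) + int(rng.integers(1, 4))) % 4]
                    out.append(base)
                    ops.append(("M", 1))
                elif kind < 0.9 and 0 < j:  # insertion before this base
                    out.append(bases[int(rng.integers(0, 4))])
                    out.append(base)
                    ops.append(("I", 1))
                    ops.append(("M", 1))
                else:  # deletion of this base
                    ops.append(("D", 1))
            else:
                out.append(base)
                ops.append(("M", 1))
    # collapse runs
    collapsed: list[tuple[str, int]] = []
    for op, length in ops:
        if collapsed and collapsed[-1][0] == op:
            collapsed[-1] = (op, collapsed[-1][1] + length)
        else:
            collapsed.append((op, length))
    # alignments cannot start/end with D; leading trims shift the ref start
    ref_offset = 0
    while collapsed and collapsed[0][0] in "DN":
        ref_offset += collapsed.pop(0)[1]
    while collapsed and collapsed[-1][0] in "DN":
        collapsed.pop()
    return "".join(out), collapsed, n_edits, ref_offset


def _truncate(
    rng: np.random.Generator,
    seq: str,
    blocks: list[GenomicInterval],
    left: bool,
    right: bool,
    primer_len: int = PRIMER_LEN,
) -> tuple[str, list[GenomicInterval]]:
    """Cut past the primer at the chosen end(s) so the primer is absent."""
    lo, hi = 0, len(seq)
    if left:
        lo = primer_len + int(rng.integers(5, 60))
    if right:
        hi = len(seq) - primer_len - int(rng.integers(5, 60))
    lo = min(lo, len(seq) // 3)
    hi = max(hi, 2 * len(seq) // 3)
    new_blocks = []
    offset = 0
    for b in blocks:
        blen = len(b)
        s = max(lo - offset, 0)
        e = min(hi - offset, blen)
        if s < e:
            new_blocks.append(GenomicInterval(b.chrom, b.start + s, b.start + e))
        offset += blen
    return seq[lo:hi], new_blocks


def simulate_rois(
    amplicons: list[Amplicon],
    config: ROISimConfig,
    fasta_path: str | os.PathLike,
    sam_path: str | os.PathLike,
    contig_lengths: dict[str, int],
) -> pd.DataFrame:
    """Draw an ROI cohort from theoretical amplicons with truncation and
    per-base errors; writes the reads (FASTA), their truth alignments (SAM)
    and returns the truth table."""
    rng = np.random.default_rng(config.seed)
    majors = [a for a in amplicons if a.set_name == "major"]
    retentions = [a for a in amplicons if a.set_name == "retention"]
    minors = [a for a in amplicons if a.set_name == "minor"]
    if not majors:
        raise ValueError("no major amplicons supplied")
    if config.abundance:
        w = np.array([config.abundance.get(a.name, 0.0) for a in majors])
    else:
        # skewed mixture: a handful of dominant isoforms, a long tail
        w = 1.0 / (1.0 + np.arange(len(majors))) ** 1.3
    w = w / w.sum()

    records: list[tuple[str, str]] = []
    truth_rows = []
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()],
    }
    with pysam.AlignmentFile(os.fspath(sam_path), "w", header=header) as out:
        for i in range(config.n_rois):
            u = rng.random()
            if retentions and u < config.retention_fraction:
                amp = retentions[int(rng.integers(0, len(retentions)))]
            elif minors and u < config.retention_fraction + config.minor_fraction:
                amp = minors[int(rng.integers(0, len(minors)))]
            else:
                amp = majors[int(rng.choice(len(majors), p=w))]
            seq = amp.sequence
            blocks = list(amp.blocks)
            full_length = rng.random() < config.full_length_fraction
            trunc_left = trunc_right = False
            if not full_length:
                if rng.random() < config.both_end_truncation_fraction:
                    trunc_left = trunc_right = True
                else:
                    if rng.random() < 0.5:
                        trunc_left = True
                    else:
                        trunc_right = True
                seq, blocks = _truncate(rng, seq, blocks, trunc_left, trunc_right)
            error_free = rng.random() < config.error_free_fraction
            read_seq, ops, n_edits, ref_offset = _inject_errors(
                rng, seq, blocks, 0.0 if error_free else config.error_rate
            )

            roi_id = f"roi{i:06d}"
            antisense = config.random_orientation and rng.random() < 0.5
            records.append((roi_id, revcomp(read_seq) if antisense else read_seq))

            aln = pysam.AlignedSegment()
            aln.query_name = roi_id
            aln.reference_id = list(contig_lengths).index(amp.chrom)
            aln.reference_start = (blocks[0].start if blocks else 0) + ref_offset
            aln.cigarstring = "".join(f"{ln}{op}" for op, ln in ops)
            aln.query_sequence = read_seq
            aln.flag = 16 if antisense else 0
            aln.mapping_quality = 60
            out.write(aln)

            if trunc_left and trunc_right:
                category = "no_primer"
            elif trunc_left or trunc_right:
                category = "one_end"
            elif n_edits == 0 and amp.set_name == "major":
                category = "perfect_major"
            elif amp.set_name == "major":
                category = "alignment_major"
            elif amp.set_name == "retention":
                category = "intron_retention_match"
            else:
                category = "minor_variant_match"
            truth_rows.append(
                dict(
                    roi_id=roi_id, isoform=amp.isoform, set_name=amp.set_name,
                    pair_id=amp.pair_id, n_edits=n_edits,
                    truncated_left=trunc_left, truncated_right=trunc_right,
                    antisense=antisense, category=category,
                )
            )
    with atomic_write(fasta_path) as handle:
        for roi_id, seq in records:
            handle.write(f">{roi_id}\n{seq}\n")
    return pd.DataFrame(truth_rows)


def validate_roi_truth(
    fasta: dict[str, str], truth: pd.DataFrame, sam_path: str | os.PathLike
) -> None:
    """Cross-check that the truth table is complete and consistent with the
    emitted FASTA/SAM; raises ValueError on any mismatch."""
    truth_ids = set(truth["roi_id"])
    if truth_ids != set(fasta):
        raise ValueError("truth table and FASTA read ids differ")
    sam_ids = set()
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            sam_ids.add(read.query_name)
            if len(read.query_sequence) != len(fasta[read.query_name]):
                raise ValueError(f"{read.query_name}: SAM/FASTA length mismatch")
    if sam_ids != truth_ids:
        raise ValueError("truth table and SAM read ids differ")
    from .longread import CATEGORIES

    bad = set(truth["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in truth table: {sorted(bad)}")
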