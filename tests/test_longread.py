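import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopipe.feature_counting import FlatGeneModel
from isopipe.intervals import GenomicInterval, SpliceJunction, revcomp
from isopipe.longread import (
    Amplicon,
    AmpliconIndex,
    PrimerMatchResult,
    PrimerPair,
    ROIClassification,
    ReadOfInsert,
    Structure,
    _edit_distance,
    classify_alignment,
    classify_roi,
    detect_intron_retention,
    match_primers,
    structure_of_blocks,
    tabulate,
)


def iv(start, end, chrom="c"):
    return GenomicInterval(chrom, start, end)


MODEL = FlatGeneModel(
    "g",
    "c",
    "+",
    exonic_regions=[("E001", iv(0, 100)), ("E002", iv(200, 300))],
    junctions=[SpliceJunction("c", 100, 200, "+", "known", "J003")],
)


def oracle_semiglobal_edit(query: str, target: str) -> int:
    """Brute-force infix (HW) edit distance: query anywhere within target."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)  # free leading gap in target
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev)  # free trailing gap in target


class TestEditDistance:
    @settings(max_examples=200, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=0, max_size=30),
        st.integers(min_value=0, max_value=5),
    )
    def test_matches_dp_oracle(self, query, target, limit):
        expected = oracle_semiglobal_edit(query, target) if target else limit + 1
        got = _edit_distance(query, target, limit)
        if expected <= limit:
            assert got == expected
        else:
            assert got == limit + 1

    def test_exact_substring_is_zero(self):
        assert _edit_distance("ACGT", "TTACGTTT", 3) == 0


FWD = "ACGTACGTACGTACGT"  # 16 nt
REV = "TTGGCCAATTGGCCAA"  # 16 nt, the primer as written 5'->3' on the bottom strand
PAIR = PrimerPair("P1", FWD, REV, 0, 400)
INSERT = "GATTACA" * 20


def sense_read(fwd=FWD, rev=REV, insert=INSERT):
    return fwd + insert + revcomp(rev)


class TestMatchPrimers:
    def test_exact_sense(self):
        res = match_primers(ReadOfInsert("r", sense_read()), [PAIR])
        assert res.status == "full_length"
        assert res.pair_id == "P1"
        assert res.orientation == "sense"
        assert res.edits == (0, 0)
        assert res.normalized == sense_read()

    def test_antisense_normalizes(self):
        res = match_primers(ReadOfInsert("r", revcomp(sense_read())), [PAIR])
        assert res.status == "full_length"
        assert res.orientation == "antisense"
        assert res.normalized == sense_read()

    def test_edited_primer_within_budget(self):
        mutated = "ACGAACGTACGTACGT"  # one substitution in FWD
        res = match_primers(ReadOfInsert("r", mutated + INSERT + revcomp(REV)), [PAIR])
        assert res.status == "full_length"
        assert res.edits == (1, 0)

    def test_one_end_only(self):
        res = match_primers(ReadOfInsert("r", FWD + INSERT), [PAIR])
        assert res.status == "one_end"

    def test_no_primer(self):
        res = match_primers(ReadOfInsert("r", INSERT), [PAIR])
        assert res.status == "none"

    def test_best_pair_wins(self):
        other = PrimerPair("P2", "GGGTTTGGGTTTGGG", "CCCAAACCCAAACCC", 0, 400)
        res = match_primers(ReadOfInsert("r", sense_read()), [other, PAIR])
        assert res.pair_id == "P1"

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("bad", "ACGT", REV, 0, 10)


class TestClassifyAlignment:
    ISO = Structure(frozenset({"E001", "E002"}), frozenset({(100, 200)}), 0, 300)

    def offset_structure(self, start_off=0, end_off=0):
        return Structure(
            self.ISO.regions, self.ISO.junctions,
            self.ISO.start + start_off, self.ISO.end + end_off,
        )

    def test_end_offset_three_matches(self):
        assert classify_alignment(self.offset_structure(3, -3), self.ISO)
        assert classify_alignment(self.offset_structure(-3, 3), self.ISO)

    def test_end_offset_four_fails(self):
        assert not classify_alignment(self.offset_structure(4, 0), self.ISO)
        assert not classify_alignment(self.offset_structure(0, -4), self.ISO)

    def test_region_set_must_match(self):
        read = Structure(frozenset({"E001"}), self.ISO.junctions, 0, 300)
        assert not classify_alignment(read, self.ISO)

    def test_junction_chain_must_match(self):
        read = Structure(self.ISO.regions, frozenset({(100, 250)}), 0, 300)
        assert not classify_alignment(read, self.ISO)


class TestIntronRetention:
    def test_spanning_block_detected(self):
        assert detect_intron_retention([iv(50, 250)], MODEL) == [(100, 200)]

    def test_touching_block_not_retention(self):
        assert detect_intron_retention([iv(50, 200)], MODEL) == []
        assert detect_intron_retention([iv(100, 250)], MODEL) == []


def make_amplicons():
    major_a = Amplicon(
        "major-001", "iso01", "major", "P1", "c", "+",
        "AAACCC" * 10, (iv(0, 100), iv(200, 300)),
    )
    retention = Amplicon(
        "retention-001", "iso01r", "retention", "P1", "c", "+",
        "GGGTTT" * 10, (iv(0, 300),),
    )
    minor = Amplicon(
        "minor-001", "iso77", "minor", "P1", "c", "+",
        "ACACAC" * 10, (iv(0, 100), iv(250, 300)),
    )
    return [major_a, retention, minor]


@pytest.fixture
def index():
    return AmpliconIndex(make_amplicons(), MODEL)


def full_length(normalized):
    return PrimerMatchResult("full_length", "P1", "sense", (0, 0), normalized)


class TestClassifyROI:
    def roi(self):
        return ReadOfInsert("r", "ACGT" * 10)

    def test_no_primer_first(self, index):
        res = classify_roi(self.roi(), PrimerMatchResult("none"), None, None, index)
        assert res.category == "no_primer"

    def test_one_end(self, index):
        res = classify_roi(self.roi(), PrimerMatchResult("one_end"), None, None, index)
        assert res.category == "one_end"

    def test_unaligned(self, index):
        res = classify_roi(self.roi(), full_length("ACGT" * 10), None, None, index)
        assert res.category == "unaligned"

    def test_off_target_chrom(self, index):
        structure = structure_of_blocks([iv(0, 300, chrom="other")], None, MODEL)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "other", index)
        assert res.category == "off_target_alignment"

    def test_off_target_no_span_overlap(self, index):
        structure = Structure(frozenset(), frozenset(), 5000, 5200)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "c", index)
        assert res.category == "off_target_alignment"

    def test_perfect_major_beats_alignment(self, index):
        # sequence identical to the major amplicon: perfect even though the
        # alignment also satisfies the alignment-match rule
        structure = structure_of_blocks([iv(0, 100), iv(200, 300)], None, MODEL)
        res = classify_roi(self.roi(), full_length("AAACCC" * 10), structure, "c", index)
        assert res.category == "perfect_major"
        assert res.isoforms == ("iso01",)

    def test_alignment_major(self, index):
        structure = structure_of_blocks([iv(2, 100), iv(200, 298)], None, MODEL)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "c", index)
        assert res.category == "alignment_major"
        assert res.isoforms == ("iso01",)
        assert not res.ambiguous

    def test_intron_retention_match(self, index):
        structure = structure_of_blocks([iv(0, 300)], None, MODEL)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "c", index)
        assert res.category == "intron_retention_match"
        assert res.isoforms == ("iso01r",)

    def test_minor_variant_match(self, index):
        structure = structure_of_blocks([iv(0, 100), iv(250, 300)], None, MODEL)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "c", index)
        assert res.category == "minor_variant_match"

    def test_full_length_unmatched(self, index):
        # novel junction matching no theoretical amplicon
        structure = structure_of_blocks([iv(0, 50), iv(270, 300)], None, MODEL)
        res = classify_roi(self.roi(), full_length("ACGT" * 10), structure, "c", index)
        assert res.category == "full_length_unmatched"

    def test_ambiguous_alignment_hit(self):
        twin = Amplicon(
            "major-002", "iso02", "major", "P1", "c", "+",
            "TTTAAA" * 10, (iv(0, 100), iv(200, 300)),
        )
        index = AmpliconIndex(make_amplicons() + [twin], MODEL)
        structure = structure_of_blocks([iv(1, 100), iv(200, 300)], None, MODEL)
        res = classify_roi(
            ReadOfInsert("r", "ACGT" * 10), full_length("ACGT" * 10),
            structure, "c", index,
        )
        assert res.category == "alignment_major"
        assert res.ambiguous
        assert res.isoforms == ("iso01", "iso02")
        assert res.pair_id is None


class TestAmpliconIndex:
    def test_cross_isoform_duplicate_sequence_rejected(self):
        amps = make_amplicons()
        dup = Amplicon(
            "major-009", "isoXX", "major", "P2", "c", "+",
            amps[0].sequence, amps[0].blocks,
        )
        with pytest.raises(ValueError, match="identical"):
            AmpliconIndex(amps + [dup], MODEL)


class TestTabulate:
    def test_counts_tiers_and_ambiguous_exclusion(self):
        classifications = (
            [ROIClassification(f"a{i}", "perfect_major", ("isoX",)) for i in range(1200)]
            + [ROIClassification(f"b{i}", "perfect_major", ("isoY",)) for i in range(600)]
            + [ROIClassification(f"c{i}", "perfect_major", ("isoZ",)) for i in range(60)]
            + [ROIClassification("d0", "perfect_major", ("isoW",))]
            + [ROIClassification("e0", "alignment_major", ("isoX", "isoY"), ambiguous=True)]
            + [ROIClassification("f0", "no_primer")]
        )
        tables = tabulate(classifications)
        summary = tables["summary"].set_index("category")["n_roi"]
        assert summary["perfect_major"] == 1861
        assert summary["alignment_major"] == 1
        assert summary["no_primer"] == 1

        per_isoform = tables["per_isoform"].set_index("isoform")
        # the ambiguous alignment hit is excluded from every isoform tally
        assert per_isoform["alignment_matches"].sum() == 0
        assert per_isoform.loc["isoX", "perfect_matches"] == 1200

        tiers = tables["tiers"].set_index("min_perfect_matches")["n_isoforms"]
        assert tiers.loc[1000] == 1
        assert tiers.loc[500] == 2
        assert tiers.loc[50] == 3
        assert tiers.loc[1] == 4

    def test_empty_input(self):
        tables = tabulate([])
        assert tables["summary"]["n_roi"].sum() == 0


class TestCohort:
    def test_order_invariance(self, gene, amplicon_index, tmp_path):
        from isopipe.longread import classify_cohort, load_roi_alignments
        from isopipe.io import read_fasta
        from isopipe.simulate import ROISimConfig, simulate_rois

        config = ROISimConfig(seed=17, n_rois=300)
        fasta_path = tmp_path / "rois.fa"
        sam_path = tmp_path / "rois.sam"
        chrom = amplicon_index.model.chrom
        contig_lengths = {chrom: len(gene.genome[chrom])}
        simulate_rois(gene.amplicons(), config, fasta_path, sam_path, contig_lengths)
        rois = [ReadOfInsert(name, seq) for name, seq in read_fasta(fasta_path).items()]
        pairs = gene.primers
        alignments = load_roi_alignments(str(sam_path), amplicon_index.model)

        fwd = classify_cohort(rois, pairs, alignments, amplicon_index)
        rev = classify_cohort(rois[::-1], pairs, alignments, amplicon_index)
        by_id_fwd = {c.roi_id: (c.category, c.isoforms) for c in fwd}
        by_id_rev = {c.roi_id: (c.category, c.isoforms) for c in rev}
        assert by_id_fwd == by_id_rev
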