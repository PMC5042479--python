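import numpy as np
import pandas as pd
import pytest

from isopipe.feature_counting import (
    FlatGeneModel,
    SplicedReadPair,
    count_features,
    discover_novel_junctions,
    estimate_size_factors,
    flatten_annotation,
    read_sam_pairs,
)
from isopipe.intervals import GenomicInterval, SpliceJunction
from isopipe.io import Transcript, isoforms_to_transcripts


def iv(start, end, chrom="c", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestFlatten:
    def test_boundary_splitting(self):
        # two transcripts whose exons overlap partially force a split
        tx = [
            Transcript("t1", "g", "c", "+", [iv(0, 100), iv(200, 300)]),
            Transcript("t2", "g", "c", "+", [iv(0, 150), iv(200, 300)]),
        ]
        model = flatten_annotation(tx)
        spans = [(r.start, r.end) for _, r in model.exonic_regions]
        assert spans == [(0, 100), (100, 150), (200, 300)]
        assert [(j.donor, j.acceptor) for j in model.junctions] == [
            (100, 200),
            (150, 200),
        ]

    def test_regions_partition_exon_union(self):
        tx = [
            Transcript("t1", "g", "c", "+", [iv(0, 100), iv(50, 160), iv(200, 300)]),
        ]
        model = flatten_annotation(tx)
        covered = sorted((r.start, r.end) for _, r in model.exonic_regions)
        # contiguous, non-overlapping, covering [0,160) and [200,300)
        assert covered[0][0] == 0 and covered[-1][1] == 300
        for (a, b), (c, d) in zip(covered, covered[1:]):
            assert b <= c

    def test_label_numbering_continues_into_junctions(self):
        tx = [Transcript("t1", "g", "c", "+", [iv(0, 10), iv(20, 30)])]
        model = flatten_annotation(tx)
        assert [label for label, _ in model.exonic_regions] == ["E001", "E002"]
        assert [j.label for j in model.junctions] == ["J003"]

    def test_mixed_strands_rejected(self):
        tx = [
            Transcript("t1", "g", "c", "+", [iv(0, 10)]),
            Transcript("t2", "g", "c", "-", [iv(0, 10, strand="-")]),
        ]
        with pytest.raises(ValueError):
            flatten_annotation(tx)

    def test_toy_gene_annotation(self, gene):
        model = flatten_annotation(gene.annotation)
        assert len(model.exonic_regions) == 18
        assert len(model.known_junctions) == 16
        assert model.novel_junctions == []


def write_sam(path, records, chrom="c", length=10_000):
    header = f"@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:{chrom}\tLN:{length}\n"
    path.write_text(header + "".join(records))


def sam_line(qname, flag, pos, cigar, chrom="c"):
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
    )


class TestSamReading:
    def test_blocks_and_gaps(self, tmp_path):
        sam = tmp_path / "a.sam"
        # 1-based pos 11 -> 0-based 10; 30M 100N 20M
        write_sam(sam, [sam_line("r1", 0, 11, "30M100N20M")])
        pairs = read_sam_pairs(str(sam), "s1")
        assert len(pairs) == 1
        p = pairs[0]
        assert [(b.start, b.end) for b in p.blocks] == [(10, 40), (140, 160)]
        assert p.gaps == {(40, 140)}
        assert p.fragment_strand == "+"

    def test_short_gap_bridged(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [sam_line("r1", 0, 11, "10M5N10M")])
        p = read_sam_pairs(str(sam), "s1", min_intron=20)[0]
        assert [(b.start, b.end) for b in p.blocks] == [(10, 35)]
        assert p.gaps == set()

    def test_deletion_stays_in_block(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [sam_line("r1", 0, 11, "10M3D10M")])
        p = read_sam_pairs(str(sam), "s1")[0]
        assert [(b.start, b.end) for b in p.blocks] == [(10, 33)]

    def test_pair_pooled_and_strand_from_read1(self, tmp_path):
        sam = tmp_path / "a.sam"
        # read1 reverse (flag 81 = paired + reverse + first), read2 forward (161)
        write_sam(
            sam,
            [
                sam_line("r1", 81, 11, "20M"),
                sam_line("r1", 161, 101, "20M"),
            ],
        )
        p = read_sam_pairs(str(sam), "s1")[0]
        assert p.fragment_strand == "-"
        assert len(p.blocks) == 2

    def test_secondary_and_unmapped_ignored(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(
            sam,
            [
                sam_line("r1", 0, 11, "20M"),
                sam_line("r2", 256, 11, "20M"),  # secondary
                sam_line("r3", 4, 0, "*"),  # unmapped
            ],
        )
        pairs = read_sam_pairs(str(sam), "s1")
        assert [p.qname for p in pairs] == ["r1"]


def make_pair(qname, blocks, gaps=(), sample="s1", strand="+", chrom="c"):
    return SplicedReadPair(
        sample,
        qname,
        chrom,
        strand,
        [GenomicInterval(chrom, a, b) for a, b in blocks],
        set(gaps),
    )


BASE_MODEL = FlatGeneModel(
    "g",
    "c",
    "+",
    exonic_regions=[("E001", iv(0, 100)), ("E002", iv(200, 300))],
    junctions=[SpliceJunction("c", 100, 200, "+", "known", "J003")],
)


class TestDiscovery:
    def test_min_support_threshold(self):
        novel_gap = (100, 250)
        pairs = [
            make_pair(f"q{i}", [(50, 100), (250, 290)], gaps=[novel_gap])
            for i in range(5)
        ]
        model = discover_novel_junctions(pairs, BASE_MODEL, min_support=5)
        assert [(j.donor, j.acceptor) for j in model.novel_junctions] == [novel_gap]
        assert model.novel_junctions[0].label == "N004"

        below = discover_novel_junctions(pairs[:4], BASE_MODEL, min_support=5)
        assert below.novel_junctions == []

    def test_duplicate_qname_counts_once(self):
        # same (sample, qname) seen twice contributes a single unit of support
        pairs = [
            make_pair("q0", [(50, 100), (250, 290)], gaps=[(100, 250)])
            for _ in range(10)
        ]
        model = discover_novel_junctions(pairs, BASE_MODEL, min_support=2)
        assert model.novel_junctions == []

    def test_known_junction_not_rediscovered(self):
        pairs = [
            make_pair(f"q{i}", [(50, 100), (200, 240)], gaps=[(100, 200)])
            for i in range(20)
        ]
        model = discover_novel_junctions(pairs, BASE_MODEL)
        assert model.novel_junctions == []

    def test_toy_gene_discovery_matches_source_junctions(self, gene, tmp_path):
        from isopipe.simulate import simulate_read_pairs

        model = flatten_annotation(gene.annotation)
        sources = gene.major_isoforms()
        # expected novel set: junctions used by the sources but absent from
        # the flattened annotation
        known_keys = {(j.donor, j.acceptor) for j in model.known_junctions}
        expected = {
            (j.donor, j.acceptor)
            for iso in sources
            for j in iso.junction_chain
        } - known_keys

        sam = tmp_path / "x.sam"
        simulate_read_pairs(sources, gene.genome, sam, n_pairs=6000, seed=11)
        pairs = read_sam_pairs(str(sam), "s1")
        augmented = discover_novel_junctions(pairs, model, min_support=5)
        novel_keys = {(j.donor, j.acceptor) for j in augmented.novel_junctions}
        assert not (known_keys & novel_keys)
        assert novel_keys == expected


class TestCounting:
    def test_semantics(self):
        pairs = [
            # overlaps E001 only
            make_pair("a", [(10, 50)]),
            # spans the junction: both exons + J003
            make_pair("b", [(80, 100), (200, 230)], gaps=[(100, 200)]),
            # intronic only: gene total only
            make_pair("c", [(120, 180)]),
            # wrong strand: nothing
            make_pair("d", [(10, 50)], strand="-"),
            # off-target contig
            make_pair("e", [(10, 50)], chrom="other"),
        ]
        with pytest.warns(UserWarning, match="off-target"):
            matrix = count_features(pairs, [BASE_MODEL], ["s1"])
        got = matrix.counts["s1"]
        assert got["E001"] == 2
        assert got["E002"] == 1
        assert got["J003"] == 1
        assert matrix.gene_totals.loc["g", "s1"] == 3
        assert matrix.off_target["s1"] == 1

    def test_pair_counted_once_per_feature(self):
        # both mates overlap E001; it still counts once
        pairs = [make_pair("a", [(10, 40), (60, 90)])]
        matrix = count_features(pairs, [BASE_MODEL], ["s1"])
        assert matrix.counts.loc["E001", "s1"] == 1


class TestSizeFactors:
    def test_recovers_library_scaling(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(200, size=50).astype(float) + 1
        factors_true = np.array([0.5, 1.0, 2.0])
        totals = pd.DataFrame(
            {f"s{i}": rng.poisson(base * f) for i, f in enumerate(factors_true)}
        )
        est = estimate_size_factors(totals + 1)
        ratio = est.to_numpy() / factors_true
        # recovered up to a constant, with geometric mean one
        assert np.allclose(ratio / ratio[0], 1.0, atol=0.15)
        assert np.isclose(np.exp(np.log(est).mean()), 1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_size_factors(pd.DataFrame({"s1": [5, 6]}))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_size_factors(pd.DataFrame({"s1": [0, 0], "s2": [0, 0]}))

    def test_fallback_warns(self):
        totals = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with pytest.warns(UserWarning, match="falling back"):
            est = estimate_size_factors(totals)
        assert np.isclose(np.exp(np.log(est).mean()), 1.0)
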