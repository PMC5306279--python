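"""Coordinate contract: FASTA/GFF3/SAM/BED parsing and the uniqueness flag."""

import pytest
from hypothesis import given, settings, strategies as st

import srnapipe as sp
from conftest import random_genome

SAM_OPS_REF = set("MD=X")  # reference-consuming CIGAR operations


def write(path, text):
    path.write_text(text)
    return str(path)


class TestReadGenome:
    def test_single_record(self, tmp_path):
        p = write(tmp_path / "g.fa", ">chr\nACGT\n")
        g = sp.read_genome(p)
        assert len(g.replicons) == 1 and g["chr"].length == 4

    def test_multi_replicon_with_plasmids(self, tmp_path):
        recs = [">chr chromosome\n" + "ACGT" * 10]
        recs += [f">p{i} plasmid\n" + "ACGT" * 5 for i in range(1, 5)]
        g = sp.read_genome(write(tmp_path / "g.fa", "\n".join(recs) + "\n"))
        assert len(g.replicons) == 5
        assert [r.kind for r in g.replicons] == ["chromosome"] + ["plasmid"] * 4

    def test_case_and_rna_normalization(self, tmp_path):
        g = sp.read_genome(write(tmp_path / "g.fa", ">chr\nacgu\n"))
        assert g["chr"].sequence == "ACGT"

    def test_duplicate_ids_error(self, tmp_path):
        p = write(tmp_path / "g.fa", ">chr\nAC\n>chr\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            sp.read_genome(p)

    def test_empty_file_error(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA records"):
            sp.read_genome(write(tmp_path / "g.fa", ""))

    def test_roundtrip(self, tmp_path):
        g = random_genome(seed=3, length=500, n_plasmids=2)
        sp.write_genome(g, tmp_path / "g.fa")
        g2 = sp.read_genome(tmp_path / "g.fa")
        assert [(r.id, r.sequence, r.kind) for r in g.replicons] == \
               [(r.id, r.sequence, r.kind) for r in g2.replicons]


GFF_HEADER = "##gff-version 3\n"


class TestReadAnnotation:
    def test_type_mapping(self, tmp_path):
        genome = random_genome(length=6000)
        gff = GFF_HEADER + "\n".join([
            "chr\tsrc\tCDS\t100\t400\t.\t+\t.\tID=orf1",
            "chr\tsrc\ttRNA\t1000\t1080\t.\t-\t.\tID=t1",
            "chr\tsrc\trRNA\t2000\t3500\t.\t+\t.\tID=r1",
        ]) + "\n"
        feats = sp.read_annotation(write(tmp_path / "a.gff3", gff), genome)
        assert [(f.kind, f.start, f.end, f.strand) for f in feats] == [
            ("ORF", 100, 400, "+"), ("tRNA", 1000, 1080, "-"), ("rRNA", 2000, 3500, "+")]

    def test_unknown_type_skipped(self, tmp_path):
        genome = random_genome()
        gff = GFF_HEADER + "chr\tsrc\tregion\t1\t2000\t.\t+\t.\tID=x\n"
        assert sp.read_annotation(write(tmp_path / "a.gff3", gff), genome) == []

    def test_out_of_bounds_error(self, tmp_path):
        genome = random_genome(length=500)
        gff = GFF_HEADER + "chr\tsrc\tCDS\t100\t900\t.\t+\t.\tID=orf1\n"
        with pytest.raises(ValueError, match="outside replicon"):
            sp.read_annotation(write(tmp_path / "a.gff3", gff), genome)

    def test_unknown_replicon_error(self, tmp_path):
        genome = random_genome()
        gff = GFF_HEADER + "chrX\tsrc\tCDS\t1\t10\t.\t+\t.\tID=orf1\n"
        with pytest.raises(ValueError, match="unknown replicon"):
            sp.read_annotation(write(tmp_path / "a.gff3", gff), genome)

    def test_annotation_roundtrip(self, tmp_path):
        genome = random_genome(length=6000)
        feats = [sp.Feature("orf1", "chr", 100, 400, "+", "ORF"),
                 sp.Feature("t1", "chr", 1000, 1080, "-", "tRNA")]
        sp.write_annotation(feats, tmp_path / "a.gff3")
        back = sp.read_annotation(tmp_path / "a.gff3", genome)
        assert [(f.id, f.start, f.end, f.strand, f.kind) for f in back] == \
               [(f.id, f.start, f.end, f.strand, f.kind) for f in feats]


def sam_text(records, replicon_len=5000):
    head = f"@HD\tVN:1.6\n@SQ\tSN:chr\tLN:{replicon_len}\n"
    return head + "".join(
        f"{name}\t{flag}\tchr\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
        for name, flag, pos, cigar in records)


class TestReadSam:
    def test_pos_cigar_arithmetic(self, tmp_path):
        genome = random_genome(length=5000)
        p = write(tmp_path / "a.sam", sam_text([("r1", 0, 100, "50M")]))
        (a,) = sp.read_alignments(p, genome)
        assert (a.start, a.end, a.strand, a.is_unique) == (100, 149, "+", True)

    def test_reverse_flag(self, tmp_path):
        genome = random_genome(length=5000)
        p = write(tmp_path / "a.sam", sam_text([("r1", 16, 200, "30M")]))
        (a,) = sp.read_alignments(p, genome)
        assert a.strand == "-"

    def test_multi_mapper_not_unique(self, tmp_path):
        """A read id appearing in two primary records is flagged non-unique,
        matching a brute-force count of placements per read id."""
        genome = random_genome(length=5000)
        recs = [("r1", 0, 100, "20M"), ("r1", 0, 900, "20M"), ("r2", 0, 50, "20M")]
        p = write(tmp_path / "a.sam", sam_text(recs))
        alignments = sp.read_alignments(p, genome)
        placements = {}
        for name, *_ in recs:
            placements[name] = placements.get(name, 0) + 1
        for a in alignments:
            assert a.is_unique == (placements[a.read_id] == 1)

    def test_indel_cigar(self, tmp_path):
        genome = random_genome(length=5000)
        # 10M2D5M consumes 17 reference bases; 3I consumes none
        p = write(tmp_path / "a.sam", sam_text([("r1", 0, 100, "10M3I2D5M")]))
        (a,) = sp.read_alignments(p, genome)
        assert a.end == 100 + 10 + 2 + 5 - 1

    @settings(max_examples=60, deadline=None)
    @given(ops=st.lists(
        st.tuples(st.sampled_from("MIDS=X"), st.integers(1, 30)),
        min_size=1, max_size=6))
    def test_cigar_end_matches_brute_force_walk(self, ops, tmp_path_factory):
        """SAM end coordinates agree with an independent CIGAR walker."""
        ref_len = sum(n for op, n in ops if op in SAM_OPS_REF)
        if ref_len == 0:
            return
        # soft clips are only legal at the ends; rebuild a legal CIGAR
        clips = [f"{n}S" for op, n in ops if op == "S"]
        middle = "".join(f"{n}{op}" for op, n in ops if op != "S")
        cigar = (clips[0] if clips else "") + middle + (clips[1] if len(clips) > 1 else "")
        genome = random_genome(length=5000)
        tmp = tmp_path_factory.mktemp("sam")
        p = write(tmp / "a.sam", sam_text([("r1", 0, 100, cigar)]))
        (a,) = sp.read_alignments(p, genome)
        assert a.end == 100 + ref_len - 1

    def test_alignment_inside_replicon_enforced(self, tmp_path):
        genome = random_genome(length=120)
        p = write(tmp_path / "a.sam", sam_text([("r1", 0, 100, "50M")], replicon_len=120))
        with pytest.raises(ValueError, match="outside replicon"):
            sp.read_alignments(p, genome)


class TestBed6:
    def test_bed_conversion_roundtrip(self, tmp_path):
        genome = random_genome(length=5000)
        alns = [sp.Alignment("r1", "chr", 101, 150, "+"),
                sp.Alignment("r2", "chr", 51, 80, "-")]
        sp.write_bed6(alns, tmp_path / "a.bed")
        back = sp.read_alignments(tmp_path / "a.bed", genome)
        assert {(a.read_id, a.start, a.end, a.strand) for a in back} == \
               {(a.read_id, a.start, a.end, a.strand) for a in alns}
        # on-disk representation is 0-based half-open
        line = (tmp_path / "a.bed").read_text().splitlines()[1]
        assert line.split("\t")[1:3] == ["100", "150"]

    def test_bad_strand_error(self, tmp_path):
        genome = random_genome()
        p = write(tmp_path / "a.bed", "chr\t0\t10\tr1\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            sp.read_alignments(p, genome)


def test_fetch_reverse_complement():
    g = sp.Genome([sp.Replicon("chr", "AACGTT")])
    assert g.fetch("chr", 1, 4, "+") == "AACG"
    assert g.fetch("chr", 1, 4, "-") == "CGTT"
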