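import pytest

from plastokit.model import (
    FormatError,
    GeneFeature,
    GenomeInterval,
    RegionPartition,
    SequenceRecord,
    ValidationError,
    extract_feature_sequence,
    gc_content,
    read_annotation,
    read_fasta,
    revcomp,
    write_annotation,
    write_fasta,
)


class TestSequenceRecord:
    def test_uppercases(self):
        assert SequenceRecord("x", "acgt").residues == "ACGT"

    def test_rejects_empty(self):
        with pytest.raises(ValidationError, match="empty"):
            SequenceRecord("x", "")

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValidationError, match="position 2"):
            SequenceRecord("x", "ACRT")

    def test_slice_plus_minus(self):
        rec = SequenceRecord("x", "AACGTT")
        iv = GenomeInterval(1, 4)
        assert rec.slice(iv) == "ACG"
        assert rec.slice(GenomeInterval(1, 4, strand="-")) == "CGT"

    def test_slice_wrapping_requires_circular(self):
        rec = SequenceRecord("x", "AACGTT")
        wrap = GenomeInterval(4, 2, wraps_origin=True)
        with pytest.raises(ValidationError, match="linear"):
            rec.slice(wrap)
        circ = SequenceRecord("x", "AACGTT", circular=True)
        assert circ.slice(wrap) == "TTAA"

    def test_slice_out_of_bounds(self):
        with pytest.raises(ValidationError, match="outside"):
            SequenceRecord("x", "ACGT").slice(GenomeInterval(2, 9))


class TestGenomeInterval:
    def test_length_and_segments(self):
        iv = GenomeInterval(2, 5)
        assert iv.length() == 3
        assert iv.segments() == [(2, 5)]

    def test_wrapping_length_and_segments(self):
        iv = GenomeInterval(8, 3, wraps_origin=True)
        assert iv.length(10) == 5
        assert iv.segments(10) == [(8, 10), (0, 3)]

    def test_wrapping_validation(self):
        with pytest.raises(ValidationError):
            GenomeInterval(2, 5, wraps_origin=True)
        with pytest.raises(ValidationError):
            GenomeInterval(5, 5)

    def test_contains_and_overlaps_across_origin(self):
        wrap = GenomeInterval(8, 3, wraps_origin=True)
        assert wrap.contains(GenomeInterval(9, 10), 10)
        assert wrap.contains(GenomeInterval(0, 2), 10)
        assert not wrap.contains(GenomeInterval(3, 4), 10)
        assert wrap.overlaps(GenomeInterval(2, 6), 10)
        assert not wrap.overlaps(GenomeInterval(4, 7), 10)


class TestGeneFeature:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="overlapping"):
            GeneFeature("g", "protein",
                        (GenomeInterval(0, 10), GenomeInterval(5, 15)))

    def test_anticodon_only_on_trna(self):
        with pytest.raises(ValidationError, match="anticodon"):
            GeneFeature("g", "protein", (GenomeInterval(0, 9),), anticodon="TAA")
        f = GeneFeature("t", "tRNA", (GenomeInterval(0, 70),), anticodon="TAA")
        assert f.anticodon == "TAA"

    def test_intron_count(self):
        f = GeneFeature("g", "protein",
                        (GenomeInterval(0, 9), GenomeInterval(20, 29)))
        assert f.intron_count == 1


class TestRegionPartition:
    def test_valid_partition(self):
        part = RegionPartition(
            lsc=GenomeInterval(0, 50), irb=GenomeInterval(50, 60),
            ssc=GenomeInterval(60, 70), ira=GenomeInterval(70, 80),
            genome_length=80,
        )
        assert part.ir_length == 10
        assert part.region_of(GenomeInterval(62, 65)) == "SSC"
        assert part.region_of(GenomeInterval(45, 55)) is None  # straddles JLB

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError, match="sum"):
            RegionPartition(
                lsc=GenomeInterval(0, 50), irb=GenomeInterval(50, 60),
                ssc=GenomeInterval(60, 70), ira=GenomeInterval(70, 80),
                genome_length=81,
            )

    def test_rejects_unequal_irs(self):
        with pytest.raises(ValidationError, match="IR"):
            RegionPartition(
                lsc=GenomeInterval(0, 50), irb=GenomeInterval(50, 61),
                ssc=GenomeInterval(61, 71), ira=GenomeInterval(71, 80),
                genome_length=80,
            )


class TestSequenceOps:
    def test_revcomp(self):
        assert revcomp("AACGTN") == "NACGTT"
        assert revcomp(revcomp("ACGTACGT")) == "ACGTACGT"

    def test_gc_content_excludes_n(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("GCATNN") == 50.0
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_extract_multi_exon_minus_strand(self):
        #            0123456789
        rec = SequenceRecord("x", "ATGCCGGTAA")
        # minus-strand two-exon gene: 5' exon is the rightmost on the genome
        f = GeneFeature("g", "protein", (
            GenomeInterval(6, 10, strand="-"),   # revcomp(GTAA) = TTAC
            GenomeInterval(0, 3, strand="-"),    # revcomp(ATG) = CAT
        ))
        assert extract_feature_sequence(rec, f) == "TTACCAT"


class TestFastaIO:
    def test_roundtrip(self, tmp_path):
        recs = [SequenceRecord("a", "ACGT" * 40), SequenceRecord("b", "TTTT")]
        p = tmp_path / "x.fasta"
        write_fasta(p, recs)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [
            (r.id, r.residues) for r in recs
        ]

    def test_u_mapped_to_t_with_warning(self, tmp_path):
        p = tmp_path / "u.fasta"
        p.write_text(">r\nACGU\n")
        with pytest.warns(UserWarning, match="U residues"):
            recs = read_fasta(p)
        assert recs[0].residues == "ACGT"

    def test_illegal_residue_position_reported(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">r\nACGX\n")
        with pytest.raises(FormatError, match="position 3"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)


class TestAnnotationIO:
    def _features(self):
        return [
            GeneFeature("psbA", "protein", (GenomeInterval(10, 70),)),
            GeneFeature("trnX", "tRNA", (GenomeInterval(100, 172),),
                        anticodon="TAA"),
            GeneFeature("split", "protein", (
                GenomeInterval(300, 330), GenomeInterval(350, 380))),
            GeneFeature("pseudoG", "protein", (GenomeInterval(400, 460),),
                        pseudo=True),
        ]

    @pytest.mark.parametrize("dialect", ["gff3", "feature_table"])
    def test_roundtrip(self, tmp_path, dialect):
        p = tmp_path / f"ann.{dialect}"
        write_annotation(p, self._features(), dialect=dialect)
        back = read_annotation(p, dialect=dialect, genome_length=500)
        assert back == self._features()

    def test_gff3_is_one_based_inclusive(self, tmp_path):
        p = tmp_path / "a.gff3"
        write_annotation(p, [GeneFeature("g", "protein", (GenomeInterval(0, 9),))])
        line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        cols = line.split("\t")
        assert (cols[3], cols[4]) == ("1", "9")

    def test_ir_copy_suffix_splits_copies(self, tmp_path):
        feats = [
            GeneFeature("rrn16", "rRNA", (GenomeInterval(0, 100),)),
            GeneFeature("rrn16", "rRNA", (GenomeInterval(200, 300, strand="-"),)),
        ]
        p = tmp_path / "a.gff3"
        write_annotation(p, feats)
        back = read_annotation(p, genome_length=300)
        assert len(back) == 2
        assert {f.name for f in back} == {"rrn16"}

    def test_out_of_bounds_exon_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        write_annotation(p, [GeneFeature("g", "protein", (GenomeInterval(0, 9),))])
        with pytest.raises(ValidationError, match="outside"):
            read_annotation(p, genome_length=5)
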