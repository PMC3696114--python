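import numpy as np
import pytest

from oracles import naive_union_size

from plastokit.model import (
    GenomeInterval,
    RegionPartition,
    SequenceRecord,
    ValidationError,
    revcomp,
)
from plastokit.nupt import (
    InsertionHit,
    chromosome_summary,
    find_insertions,
    insertion_profile,
    map_back_to_full,
    merge_intervals,
    read_blast6,
    strip_one_ir,
    write_blast6,
)
from plastokit.reference import NUCLEAR_INSERTIONS
from plastokit.simulate import PlastomeSimSpec, make_nuclear_with_nupts, make_plastome


def _hit(ps, pe, chrom="chr01", ns=0, ne=None, e=1e-30):
    ne = ns + (pe - ps) if ne is None else ne
    return InsertionHit(GenomeInterval(ps, pe), chrom, GenomeInterval(ns, ne),
                        identity=100.0, evalue=e, bit_score=100.0)


class TestStripping:
    def test_strip_removes_exactly_one_ir(self, default_plastome):
        record, _, truth = default_plastome
        stripped = strip_one_ir(record, truth.partition)
        assert len(stripped) == len(record) - truth.partition.ir_length
        assert stripped.residues == record.residues[: truth.partition.ssc.end]
        assert stripped.id.endswith("|IR-stripped")

    def test_double_strip_rejected(self, default_plastome):
        record, _, truth = default_plastome
        stripped = strip_one_ir(record, truth.partition)
        with pytest.raises(ValidationError, match="stripped"):
            strip_one_ir(stripped, truth.partition)

    def test_non_canonical_partition_rejected(self):
        rec = SequenceRecord("x", "ACGT" * 50, circular=True)
        part = RegionPartition(
            lsc=GenomeInterval(10, 110), irb=GenomeInterval(110, 145),
            ssc=GenomeInterval(145, 175),
            ira=GenomeInterval(175, 10, wraps_origin=True),
            genome_length=200,
        )
        with pytest.raises(ValidationError, match="canonical"):
            strip_one_ir(rec, part)


class TestMapBack:
    PART = RegionPartition(
        lsc=GenomeInterval(0, 100), irb=GenomeInterval(100, 140),
        ssc=GenomeInterval(140, 160), ira=GenomeInterval(160, 200),
        genome_length=200,
    )

    def test_lsc_maps_to_itself(self):
        out = map_back_to_full(GenomeInterval(10, 60), self.PART)
        assert out == [GenomeInterval(10, 60)]

    def test_irb_maps_to_both_copies(self):
        out = map_back_to_full(GenomeInterval(110, 120), self.PART)
        assert len(out) == 2
        assert out[0] == GenomeInterval(110, 120)
        # mirror: offsets 10..20 from IRb start → 20..30 from IRa end
        assert (out[1].start, out[1].end, out[1].strand) == (180, 190, "-")

    def test_mirror_preserves_sequence(self, default_plastome):
        record, _, truth = default_plastome
        part = truth.partition
        iv = GenomeInterval(part.irb.start + 5, part.irb.start + 55)
        full, mirror = map_back_to_full(iv, part)
        assert record.slice(mirror) == record.slice(full)


class TestFindInsertions:
    def test_planted_recall_and_precision(self, default_plastome):
        record, _, truth = default_plastome
        chroms, planted = make_nuclear_with_nupts(
            record, truth.partition, n_chrom=3, n_insertions=8,
            divergence_rate=0.0, seed=13,
        )
        query = strip_one_ir(record, truth.partition)
        hits = find_insertions(nuclear=chroms, query=query)
        expected = [t for t in planted if t["length"] > 100]
        # recall: every planted insertion > 100 bp is found at its position
        for t in expected:
            assert any(
                h.chromosome == t["chromosome"]
                and h.nuclear_interval.start <= t["nuclear_interval"].start
                and h.nuclear_interval.end >= t["nuclear_interval"].end
                for h in hits
            ), t
        # precision: every hit overlaps some planted insertion
        for h in hits:
            assert any(
                h.chromosome == t["chromosome"]
                and h.nuclear_interval.overlaps(t["nuclear_interval"])
                for t in planted
            ), h

    def test_length_filter_is_strict(self, tmp_path):
        hits = [_hit(0, 100), _hit(200, 301)]  # lengths 100 (excluded) and 101
        p = tmp_path / "hits.tsv"
        write_blast6(p, hits)
        kept = find_insertions(hits_file=str(p))
        assert [h.length for h in kept] == [101]

    def test_evalue_filter_is_strict(self, tmp_path):
        hits = [_hit(0, 200, e=1e-5), _hit(300, 501, e=9e-6)]
        p = tmp_path / "hits.tsv"
        write_blast6(p, hits)
        kept = find_insertions(hits_file=str(p))
        assert [h.plastome_interval.start for h in kept] == [300]

    def test_requires_some_input(self):
        with pytest.raises(ValueError):
            find_insertions()


class TestProfile:
    PART = TestMapBack.PART

    def test_per_base_counts_and_coverage(self):
        rec = SequenceRecord("p", "A" * 200, circular=True)
        hits = [_hit(0, 120), _hit(110, 130)]
        prof = insertion_profile(hits, rec, self.PART)
        assert prof.stripped_values.sum() == 140
        assert prof.stripped_values[115] == 2
        assert prof.covered_fraction == pytest.approx(100.0 * 130 / 160)

    def test_ir_display_halved_and_mirrored(self):
        rec = SequenceRecord("p", "A" * 200, circular=True)
        hits = [_hit(100, 140)]  # exactly IRb
        prof = insertion_profile(hits, rec, self.PART)
        assert np.all(prof.display_values[100:140] == 0.5)
        assert np.all(prof.display_values[160:200] == 0.5)
        assert prof.display_values.sum() == pytest.approx(40.0)

    def test_hit_outside_stripped_coordinates_rejected(self):
        rec = SequenceRecord("p", "A" * 200, circular=True)
        with pytest.raises(ValidationError, match="outside"):
            insertion_profile([_hit(150, 170)], rec, self.PART)


class TestSummary:
    def test_merge_intervals_matches_naive_union(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ivs = []
            for _ in range(15):
                s = int(rng.integers(0, 500))
                ivs.append((s, s + int(rng.integers(1, 80))))
            merged = merge_intervals(ivs)
            assert sum(e - s for s, e in merged) == naive_union_size(ivs)
            # merged intervals are disjoint and sorted
            for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
                assert e1 < s2

    def test_summary_counts_overlaps_once(self):
        hits = [_hit(0, 150, ns=100), _hit(200, 350, ns=200),
                _hit(400, 520, "chr02", ns=50)]
        df = chromosome_summary(hits, {"chr01": 1000, "chr02": 500})
        row1 = df[df.chromosome == "chr01"].iloc[0]
        assert row1.n_hits == 2
        assert row1.n_bases == 250  # [100,250)+[200,350) merge to [100,350)
        total = df[df.chromosome == "total"].iloc[0]
        assert total.n_hits == 3
        assert total.n_bases == 370
        assert total.pct_of_insertions == pytest.approx(100.0)
        assert total.permille_of_chromosome == pytest.approx(1000 * 370 / 1500)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            chromosome_summary([_hit(0, 150, chrom="chrX")], {"chr01": 1000})

    def test_reference_table_totals(self):
        assert sum(n for n, _ in NUCLEAR_INSERTIONS.values()) == 563
        assert sum(b for _, b in NUCLEAR_INSERTIONS.values()) == 134491


class TestBlast6IO:
    def test_roundtrip(self, tmp_path):
        hits = [_hit(5, 210, ns=40), _hit(300, 480, "chr02", ns=10, e=1e-12)]
        p = tmp_path / "hits.tsv"
        write_blast6(p, hits)
        back = read_blast6(p)
        assert len(back) == 2
        for a, b in zip(hits, back):
            assert a.plastome_interval == b.plastome_interval
            assert a.chromosome == b.chromosome
            assert a.nuclear_interval == b.nuclear_interval
            assert a.evalue == pytest.approx(b.evalue)
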