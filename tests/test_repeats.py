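import pytest

from oracles import naive_microsatellites, naive_minisatellites

from plastokit.model import GenomeInterval, RegionPartition
from plastokit.repeats import (
    MICRO_MIN_REPEATS,
    RepeatLocus,
    assign_regions,
    canonical_motif,
    dedup_ir,
    extract_flanks,
    find_microsatellites,
    find_minisatellites,
    is_primitive,
)
from plastokit.simulate import PlastomeSimSpec, make_plastome, _random_seq, _rng


class TestMotifs:
    def test_primitive(self):
        assert is_primitive("ACT")
        assert not is_primitive("ATAT")
        assert not is_primitive("AAA")
        assert is_primitive("AAT")

    def test_canonical_motif_over_rotations_and_revcomp(self):
        # rotations of GA: {GA, AG}; of its revcomp TC: {TC, CT} → min AG
        assert canonical_motif("GA") == "AG"
        assert canonical_motif("TC") == "AG"
        # strand symmetry always holds
        from plastokit.model import revcomp

        for m in ("ACT", "GAT", "TTAGGC"):
            assert canonical_motif(m) == canonical_motif(revcomp(m))


class TestRepeatLocus:
    def test_micro_unit_bounds(self):
        with pytest.raises(ValueError):
            RepeatLocus(GenomeInterval(0, 70), "ACTGACT", 10.0, "micro")

    def test_mini_unit_bounds(self):
        with pytest.raises(ValueError):
            RepeatLocus(GenomeInterval(0, 18), "ACTGACTGA", 2.0, "mini")

    def test_copies_consistent_with_span(self):
        with pytest.raises(ValueError):
            RepeatLocus(GenomeInterval(0, 10), "AC", 3.0, "micro")


class TestMicrosatellites:
    def test_mononucleotide_threshold(self):
        pad = "GCTGCGTCGC"
        assert find_microsatellites(pad + "A" * 9 + pad) == []
        loci = find_microsatellites(pad + "A" * 10 + pad)
        assert len(loci) == 1
        (loc,) = loci
        assert (loc.unit, loc.copies) == ("A", 10.0)
        assert (loc.interval.start, loc.interval.end) == (10, 20)

    @pytest.mark.parametrize("motif", ["AT", "ACT", "AATC", "AACGT", "AACGTC"])
    def test_threshold_boundary(self, motif):
        u = len(motif)
        need = MICRO_MIN_REPEATS[u - 1]
        pad1, pad2 = "GCCGGCGGCG", "CGGCGCCGCG"
        below = pad1 + motif * (need - 1) + pad2
        at = pad1 + motif * need + pad2
        assert all(l.unit != motif for l in find_microsatellites(below))
        assert any(
            l.unit == motif and l.copies >= need
            for l in find_microsatellites(at)
        )

    def test_non_primitive_motif_reported_at_base_unit(self):
        # (ATAT)x5 is really (AT)x10
        loci = find_microsatellites("GCCGGCGGCG" + "AT" * 10 + "CGGCGCCGCG")
        assert len(loci) == 1
        assert loci[0].unit == "AT"

    def test_agrees_with_naive_oracle_random(self):
        for seed in range(8):
            seq = _random_seq(_rng(seed, "plastome"), 2000,
                              probs=(0.4, 0.1, 0.1, 0.4))  # AT-rich → many SSRs
            got = [
                (l.interval.start, l.interval.end, l.unit, l.copies)
                for l in sorted(find_microsatellites(seq),
                                key=lambda l: l.interval.start)
            ]
            assert got == naive_microsatellites(seq), seed

    def test_planted_recovery(self):
        spec = PlastomeSimSpec(seed=21, planted_repeats=(
            ("A", 12, "LSC"), ("AT", 6, "SSC"), ("ACT", 4, "LSC"),
            ("AATC", 3, "IRb"),
        ))
        record, _, truth = make_plastome(spec)
        loci = find_microsatellites(record.residues)
        for t in truth.repeats:
            assert any(
                l.unit == t.unit
                and l.interval.start <= t.interval.start
                and l.interval.end >= t.interval.end
                for l in loci
            ), t


class TestMinisatellites:
    def test_fractional_copies(self):
        motif = "ACGGTTCAGT"  # 10 bp primitive
        seq = "GCCGGCGGCG" + motif * 2 + motif[:5] + "CGGCGCCGCG"
        loci = find_minisatellites(seq)
        assert len(loci) == 1
        assert loci[0].unit == motif
        assert loci[0].copies == pytest.approx(2.5)

    def test_below_two_copies_not_reported(self):
        motif = "ACGGTTCAGT"
        seq = "GCCGGCGGCG" + motif + motif[:9] + "CGGCGCCGCG"
        assert find_minisatellites(seq) == []

    def test_agrees_with_naive_oracle_random(self):
        for seed in range(4):
            rng = _rng(seed + 50, "plastome")
            seq = _random_seq(rng, 1500)
            # plant one minisatellite to make the comparison non-vacuous
            motif = "GATCCTGAAT"
            seq = seq[:400] + motif * 3 + seq[400:]
            got = [
                (l.interval.start, l.interval.end, l.unit, l.copies)
                for l in sorted(find_minisatellites(seq),
                                key=lambda l: l.interval.start)
            ]
            assert got == naive_minisatellites(seq), seed


class TestRegionsAndDedup:
    def _partition(self):
        return RegionPartition(
            lsc=GenomeInterval(0, 100), irb=GenomeInterval(100, 140),
            ssc=GenomeInterval(140, 160), ira=GenomeInterval(160, 200),
            genome_length=200,
        )

    def test_region_labels_and_junction_flag(self):
        part = self._partition()
        inside = RepeatLocus(GenomeInterval(10, 22), "A", 12.0, "micro")
        spanning = RepeatLocus(GenomeInterval(95, 107), "A", 12.0, "micro")
        out = assign_regions([inside, spanning], part)
        assert out[0].region == "LSC" and not out[0].junction_spanning
        assert out[1].junction_spanning

    def test_mirrored_ir_twin_dropped(self):
        part = self._partition()
        # IRb locus at offset 10..22 from IRb start → IRa twin mirrored
        irb_loc = RepeatLocus(GenomeInterval(110, 122), "A", 12.0, "micro")
        ira_loc = RepeatLocus(GenomeInterval(178, 190), "T", 12.0, "micro")
        out = dedup_ir(assign_regions([irb_loc, ira_loc], part), part)
        assert len(out) == 1
        assert out[0].interval == irb_loc.interval

    def test_unmirrored_ira_locus_kept(self):
        part = self._partition()
        ira_only = RepeatLocus(GenomeInterval(178, 190), "T", 12.0, "micro")
        out = dedup_ir(assign_regions([ira_only], part), part)
        assert len(out) == 1

    def test_planted_ir_repeat_appears_twice_then_once(self):
        spec = PlastomeSimSpec(seed=33, planted_repeats=(("AATC", 3, "IRb"),))
        record, _, truth = make_plastome(spec)
        loci = assign_regions(find_microsatellites(record.residues),
                              truth.partition)
        ir_loci = [l for l in loci if l.region in ("IRb", "IRa")]
        assert len(ir_loci) == 2
        assert len(dedup_ir(loci, truth.partition)) == len(loci) - 1


class TestFlanks:
    def test_linear_flanks(self):
        seq = "A" * 50 + "GT" * 10 + "C" * 50
        loc = RepeatLocus(GenomeInterval(50, 70), "GT", 10.0, "micro")
        left, right = extract_flanks(loc, seq, flank_len=20)
        assert left == "A" * 20
        assert right == "C" * 20

    def test_linear_flank_truncated_at_edge(self):
        seq = "AAA" + "GT" * 10 + "CCC"
        loc = RepeatLocus(GenomeInterval(3, 23), "GT", 10.0, "micro")
        left, right = extract_flanks(loc, seq, flank_len=20)
        assert (left, right) == ("AAA", "CCC")

    def test_circular_flank_wraps(self):
        seq = "GT" * 10 + "A" * 30 + "CCC"
        loc = RepeatLocus(GenomeInterval(0, 20), "GT", 10.0, "micro")
        left, right = extract_flanks(loc, seq, flank_len=5, circular=True)
        assert left == seq[-5:]
        assert right == "AAAAA"
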