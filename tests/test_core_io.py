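import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from polymirts.core_io import (
    MatureMiRNA,
    SNPRecord,
    UTRRecord,
    apply_variant,
    deduplicate_utrs,
    extract_utr_sequences,
    nucleotide_variation,
    read_fasta,
    read_utr_annotation,
    read_vcf,
    reverse_complement,
    write_bed6_utrs,
    write_fasta,
    write_vcf,
)


def make_utr(seq, start=100, strand="+", contig="chr1", tid="tx1"):
    return UTRRecord(gene_id="g1", transcript_id=tid, contig=contig,
                     start=start, end=start + len(seq), strand=strand,
                     sequence=seq)


class TestMatureMiRNA:
    def test_seed_slices(self, let7a):
        assert let7a.seed6 == "GAGGUA"
        assert let7a.seed7 == "GAGGUAG"
        assert let7a.family_key == let7a.seed7

    def test_dna_input_transcribed(self):
        m = MatureMiRNA("m", "TGAGGTAGTAGGTTGTATAGTT")
        assert m.sequence == "UGAGGUAGUAGGUUGUAUAGUU"

    @pytest.mark.parametrize("seq", ["ACGU" * 4, "A" * 26, "ACGX" + "A" * 18])
    def test_invalid_rejected(self, seq):
        with pytest.raises(ValueError):
            MatureMiRNA("bad", seq)


class TestExtractUTRs:
    def test_plus_strand_slice(self):
        [utr] = extract_utr_sequences(
            {"c": "AACCGGTT"}, [("c", 2, 6, "g", "t", "+")])
        assert utr.sequence == "CCGG"

    def test_minus_strand_reverse_complement(self):
        [utr] = extract_utr_sequences(
            {"c": "AACCGGTT"}, [("c", 0, 4, "g", "t", "-")])
        assert utr.sequence == "GGTT"

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="t"):
            extract_utr_sequences({"c": "ACGTACGT"}, [("c", 5, 12, "g", "t", "+")])


class TestApplyVariant:
    def test_plus_strand_substitution(self):
        utr = make_utr("AAAAAAAAAA")
        snp = SNPRecord("chr1", 106, "A", "G")  # 1-based = offset 5
        assert apply_variant(utr, snp).sequence == "AAAAAGAAAA"

    def test_minus_strand_matches_reextraction(self, rng):
        # oracle: edit the genome, re-extract, compare
        genome = {"c": random_dna(rng, 60)}
        [utr] = extract_utr_sequences(genome, [("c", 10, 50, "g", "t", "-")])
        pos0 = 23
        ref = genome["c"][pos0]
        alt = next(b for b in "ACGT" if b != ref)
        snp = SNPRecord("c", pos0 + 1, ref, alt)
        edited = {"c": genome["c"][:pos0] + alt + genome["c"][pos0 + 1:]}
        [expected] = extract_utr_sequences(edited, [("c", 10, 50, "g", "t", "-")])
        assert apply_variant(utr, snp).sequence == expected.sequence

    def test_outside_utr_raises(self):
        utr = make_utr("AAAAAAAAAA")
        with pytest.raises(ValueError, match="outside"):
            apply_variant(utr, SNPRecord("chr1", 100, "A", "G"))

    def test_ref_mismatch_raises(self):
        utr = make_utr("AAAAAAAAAA")
        with pytest.raises(ValueError, match="expected"):
            apply_variant(utr, SNPRecord("chr1", 105, "C", "G"))

    def test_involution(self, rng):
        utr = make_utr(random_dna(rng, 30))
        pos0 = 110
        ref = utr.sequence[10]
        alt = next(b for b in "ACGT" if b != ref)
        variant = apply_variant(utr, SNPRecord("chr1", pos0 + 1, ref, alt))
        back = apply_variant(variant, SNPRecord("chr1", pos0 + 1, alt, ref))
        assert back.sequence == utr.sequence

    def test_known_mask_unchanged(self):
        utr = UTRRecord("g", "t", "chr1", 100, 110, "+", "AAAAAAAAAA",
                        known_mask=frozenset({8, 9}))
        variant = apply_variant(utr, SNPRecord("chr1", 103, "A", "T"))
        assert variant.known_mask == frozenset({8, 9})


class TestDeduplicate:
    def test_collapses_identical(self):
        records = [make_utr("ACGTGA", tid=f"t{i}") for i in range(2)]
        records.append(make_utr("ACGAGA", tid="t2"))
        unique, mult = deduplicate_utrs(records)
        assert [u.sequence for u in unique] == ["ACGTGA", "ACGAGA"]
        assert mult == {"t0": 2, "t2": 1}

    def test_all_distinct_identity(self, rng):
        records = [make_utr(random_dna(rng, 20), tid=f"t{i}") for i in range(5)]
        unique, mult = deduplicate_utrs(records)
        assert len(unique) == 5 and all(v == 1 for v in mult.values())

    def test_planted_duplicate_count(self, rng):
        # 44 alleles with 12 planted duplicates collapse to 32 uniques
        base = [random_dna(rng, 50) for _ in range(32)]
        seqs = base + [base[i % 32] for i in range(12)]
        records = [make_utr(s, tid=f"t{i}") for i, s in enumerate(seqs)]
        unique, mult = deduplicate_utrs(records)
        assert len(unique) == 32
        assert sum(mult.values()) == 44

    def test_multiplicities_sum(self, rng):
        seqs = [random_dna(rng, 8) for _ in range(10)]
        picks = [seqs[i] for i in rng.integers(0, 10, size=25)]
        records = [make_utr(s, tid=f"t{i}") for i, s in enumerate(picks)]
        unique, mult = deduplicate_utrs(records)
        assert sum(mult.values()) == 25
        assert len(unique) <= 25
        assert len({u.sequence for u in unique}) == len(unique)


class TestNucleotideVariation:
    def test_identical_is_zero(self):
        assert nucleotide_variation(["ACGTACGTAC", "ACGTACGTAC"]) == 0.0

    def test_single_polymorphic_column(self):
        assert nucleotide_variation(["ACGTACGTAC", "ACGTACGTAT"]) == pytest.approx(0.10)

    def test_matches_column_scan_oracle(self, rng):
        seqs = []
        for _ in range(5):
            chars = rng.choice(list("ACGT-N"), size=40, p=[.22, .22, .22, .22, .06, .06])
            seqs.append("".join(chars))
        eligible = polymorphic = 0
        for col in zip(*seqs):
            residues = [c for c in col if c not in "-."]
            if len(residues) >= 2:
                eligible += 1
                if len({c for c in residues if c != "N"}) >= 2:
                    polymorphic += 1
        expected = polymorphic / eligible if eligible else 0.0
        assert nucleotide_variation(seqs) == pytest.approx(expected)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="alignment"):
            nucleotide_variation(["ACGT", "ACG"])

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant(self, data):
        seqs = data.draw(st.lists(
            st.text(alphabet="ACGT-N", min_size=12, max_size=12),
            min_size=2, max_size=5))
        perm = data.draw(st.permutations(seqs))
        assert nucleotide_variation(seqs) == nucleotide_variation(list(perm))


class TestRoundTrips:
    def test_fasta(self, tmp_path, rng):
        seqs = {f"s{i}": random_dna(rng, 40) for i in range(4)}
        write_fasta(tmp_path / "x.fa", seqs)
        assert read_fasta(tmp_path / "x.fa") == seqs

    def test_bed6(self, tmp_path, rng):
        genome = {"c1": random_dna(rng, 120)}
        ann = [("c1", 5, 50, "gA", "txA", "+"), ("c1", 60, 100, "gB", "txB", "-")]
        utrs = extract_utr_sequences(genome, ann)
        write_bed6_utrs(tmp_path / "u.bed", utrs)
        assert read_utr_annotation(tmp_path / "u.bed") == ann

    def test_gff3(self, tmp_path):
        gff = ("##gff-version 3\n"
               "c1\tsrc\tthree_prime_UTR\t6\t50\t.\t+\t.\tID=txA;gene_id=gA\n"
               "c1\tsrc\texon\t1\t50\t.\t+\t.\tID=e1\n")
        (tmp_path / "a.gff3").write_text(gff)
        assert read_utr_annotation(tmp_path / "a.gff3") == [("c1", 5, 50, "gA", "txA", "+")]

    def test_vcf(self, tmp_path):
        snps = [
            SNPRecord("c1", 10, "A", "G", quality=77.0, depth=42,
                      allele_counts={"s1": (12, 30), "s2": (5, 0)},
                      provenance="both", snp_id="rs1"),
            SNPRecord("c1", 44, "C", "T", quality=50.0, depth=15,
                      allele_counts={"s1": (7, 8), "s2": (1, 2)}),
        ]
        write_vcf(tmp_path / "x.vcf", snps, contig_lengths={"c1": 100})
        back = read_vcf(tmp_path / "x.vcf")
        assert len(back) == 2
        for a, b in zip(snps, back):
            assert a.key == b.key
            assert a.quality == b.quality
            assert a.depth == b.depth
            assert dict(a.allele_counts) == dict(b.allele_counts)
            assert a.provenance == b.provenance


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement("") == ""
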