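"""Bisulfite conversion, read generation, trimming and end-composition QC."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rrbsim as R
from rrbsim.reads import _adapter_trim_pos, _quality_trim_end


def _states(n, top=False, bottom=False):
    return {"top": np.full(n, top), "bottom": np.full(n, bottom)}


class TestBisulfiteConvert:
    def test_fully_methylated_is_identity(self):
        seq = "ACGTCCGGAC"
        top, bottom = R.bisulfite_convert(
            seq, _states(len(seq), top=True, bottom=True),
            R.ConversionParams(conversion_rate=1.0, inappropriate_conversion_rate=0.0))
        assert top == seq
        assert bottom == "GTCCGGACGT"  # reverse complement, untouched

    def test_unmethylated_forced_conversion(self):
        top, bottom = R.bisulfite_convert(
            "ACGT", _states(4), R.ConversionParams(conversion_rate=1.0))
        assert top == "ATGT"
        assert bottom == "ATGT"  # revcomp ACGT = ACGT, its C converts too

    def test_conversion_rate_recovered_binomially(self):
        n = 10_000
        rate = 0.99
        rng = np.random.default_rng(3)
        top, _ = R.bisulfite_convert(
            "C" * n, _states(n), R.ConversionParams(conversion_rate=rate), rng)
        converted = top.count("T")
        se = math.sqrt(n * rate * (1 - rate))
        assert abs(converted - n * rate) < 3 * se

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80), st.integers(0, 5))
    def test_length_conservation(self, seq, seed):
        top, bottom = R.bisulfite_convert(
            seq, _states(len(seq)), R.ConversionParams(rng_seed=seed))
        assert len(top) == len(seq) and len(bottom) == len(seq)

    def test_state_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            R.bisulfite_convert("ACGT", _states(3), R.ConversionParams())


@pytest.fixture(scope="module")
def digest_pairs(small_reference):
    genome, _, methylome = small_reference
    library = R.rrbs_library(genome, R.SizeWindow(150, 250))
    return R.generate_reads(
        library, genome, methylome, 800,
        params=R.ConversionParams(sequencing_error_rate=0.0), seed=17)


class TestGenerateReads:
    def test_long_insert_reads_are_pure_template(self, digest_pairs, small_reference):
        """Insert >= read length: every base is genomic (C->T aside), never adapter."""
        genome, _, _ = small_reference
        for p in digest_pairs[:100]:
            chrom, s, e, strand = p.origin
            if strand == "top":
                template = genome.sequences[chrom][s:s + len(p.read1)]
            else:
                tail = genome.sequences[chrom][e - len(p.read1):e]
                template = tail.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            # error-free, so reads match the template wherever no C was converted
            assert all(rb == tb or (tb == "C" and rb == "T")
                       for rb, tb in zip(p.read1, template))

    def test_error_free_read1_begins_at_mspi_site(self, digest_pairs):
        table = R.end_composition(digest_pairs)
        r1 = table[table["read"] == "read1"]
        frac = r1[r1["pattern"].isin(["CGG", "TGG"])]["fraction"].sum()
        assert frac == pytest.approx(1.0)

    def test_short_insert_reads_into_adapter(self, small_reference):
        genome, _, methylome = small_reference
        library = R.rrbs_library(genome, R.SizeWindow(60, 90))
        pairs = R.generate_reads(
            library, genome, methylome, 20,
            params=R.ConversionParams(sequencing_error_rate=0.0), seed=2)
        for p in pairs:
            insert = p.origin[2] - p.origin[1]
            assert p.read1[insert:insert + 10] == R.DEFAULT_ADAPTER[:10]

    def test_duplicate_seed_byte_identical_fastq(self, small_reference, tmp_path):
        genome, _, methylome = small_reference
        library = R.rrbs_library(genome, R.SizeWindow(150, 250))
        for run in ("a", "b"):
            pairs = R.generate_reads(library, genome, methylome, 50, seed=9)
            R.write_fastq_pairs(pairs, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_fastq_round_trip_preserves_pairs_and_origin(self, digest_pairs, tmp_path):
        R.write_fastq_pairs(digest_pairs[:30], tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        back = R.read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert back == list(digest_pairs[:30])

    def test_read2_is_g_depleted_when_methylation_low(self, small_reference):
        genome, features, _ = small_reference
        methylome = R.simulate_methylome(
            genome, features,
            R.MethylomeParams(island_fixed=0.05, background_fixed=0.05,
                              repeat_fixed=0.05, non_cpg_methylation=0.0))
        library = R.rrbs_library(genome, R.SizeWindow(150, 250))
        pairs = R.generate_reads(library, genome, methylome, 300, seed=6)
        read2 = "".join(p.read2 for p in pairs)
        genome_g = sum(s.count("G") for s in genome.sequences.values()) / genome.total_length
        assert read2.count("G") / len(read2) < genome_g / 2


class TestTrimming:
    def test_clean_read_unchanged(self):
        pair = R.ReadPair("p", "ACGTACGTAC" * 10, "I" * 100,
                          "TGCATGCATG" * 10, "I" * 100)
        out = R.trim_read_pair(pair, R.TrimConfig(rrbs_mode=False))
        assert out == pair

    def test_low_quality_tail_removed_exactly(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp
        qual = chr(33 + 30) * 20 + chr(33 + 10) * 20
        pair = R.ReadPair("p", seq, qual, seq, qual)
        out = R.trim_read_pair(pair, R.TrimConfig(rrbs_mode=False))
        assert out.read1 == seq[:20] and out.read2 == seq[:20]

    def test_adapter_suffix_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp
        seq = insert + R.DEFAULT_ADAPTER[:20]
        pair = R.ReadPair("p", seq, "I" * len(seq), seq, "I" * len(seq))
        out = R.trim_read_pair(pair, R.TrimConfig(rrbs_mode=False))
        assert out.read1 == insert

    def test_rrbs_mode_trims_two_extra_and_clips_read2_start(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"
        seq = insert + R.DEFAULT_ADAPTER[:20]
        pair = R.ReadPair("p", seq, "I" * len(seq), seq, "I" * len(seq))
        out = R.trim_read_pair(pair, R.TrimConfig(rrbs_mode=True))
        assert out.read1 == insert[:-2]          # adapter + 2 bp fill-in
        assert out.read2 == insert[2:-2]         # additionally 5'-clipped

    def test_short_pairs_rejected(self):
        pair = R.ReadPair("p", "ACGTACGTAC", "I" * 10, "ACGTACGTAC", "I" * 10)
        assert R.trim_read_pair(pair, R.TrimConfig(min_length_after_trim=20)) is None

    @given(st.text(alphabet="ACGT", min_size=25, max_size=120),
           st.integers(0, 40), st.booleans())
    def test_trimming_only_shortens_and_keeps_lengths_consistent(
            self, seq, qual_offset, rrbs):
        qual = "".join(chr(33 + min(41, qual_offset + (i % 11)))
                       for i in range(len(seq)))
        pair = R.ReadPair("p", seq, qual, seq, qual)
        out = R.trim_read_pair(pair, R.TrimConfig(rrbs_mode=rrbs,
                                                  min_length_after_trim=1))
        if out is not None:
            assert len(out.read1) == len(out.qual1) <= len(seq)
            assert len(out.read2) == len(out.qual2) <= len(seq)
            assert seq.startswith(out.read1)
            assert out.read2 in seq

    def test_quality_trim_helper_boundary(self):
        assert _quality_trim_end("IIII", 20) == 4
        assert _quality_trim_end("II!!", 20) == 2
        assert _quality_trim_end("!!!!", 20) == 0

    def test_adapter_helper_requires_one_base_overlap(self):
        assert _adapter_trim_pos("ACGTACGTA", "AGATCGGAAGAGC") == 8  # trailing A
        assert _adapter_trim_pos("ACGTACGTC", "AGATCGGAAGAGC") is None


class TestEndComposition:
    def test_empty_input_empty_table(self):
        assert R.end_composition([]).empty

    def test_sonication_on_uniform_genome_is_uniform(self):
        config = R.GenomeConfig(chromosome_lengths=(80_000,), background_gc=0.5,
                                n_islands=0, n_genes=0, n_repeat_loci=0, rng_seed=8)
        genome, features = R.simulate_genome(config)
        # fully methylated: bisulfite leaves the sequence untouched
        methylome = R.simulate_methylome(
            genome, features,
            R.MethylomeParams(island_fixed=1.0, background_fixed=1.0,
                              repeat_fixed=1.0, non_cpg_methylation=1.0))
        frags = R.sonicate(genome, 10_000, seed=10)
        pairs = R.generate_reads(
            frags, genome, methylome, 10_000,
            params=R.ConversionParams(inappropriate_conversion_rate=0.0,
                                      sequencing_error_rate=0.0), seed=11)
        table = R.end_composition(pairs)
        r1 = table[table["read"] == "read1"]
        p = 1 / 64
        se = math.sqrt(p * (1 - p) / 10_000)
        assert len(r1) == 64
        assert (np.abs(r1["fraction"] - p) < 3.5 * se).all()
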