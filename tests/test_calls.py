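"""Methylation calling: evidence orientation, QC arithmetic, fill-in bias."""

from __future__ import annotations

import math

import pytest

import rrbsim as R
from rrbsim.calls import MethylationCallTable


def _uniform_reference(level: float, non_cpg: float = 0.0, seed: int = 41):
    genome, features = R.simulate_genome(
        R.GenomeConfig(chromosome_lengths=(20_000,), n_islands=3, n_genes=3,
                       n_repeat_loci=0, rng_seed=seed))
    methylome = R.simulate_methylome(
        genome, features,
        R.MethylomeParams(island_fixed=level, background_fixed=level,
                          repeat_fixed=level, non_cpg_methylation=non_cpg))
    return genome, features, methylome


class TestCallMethylation:
    def test_fully_methylated_molecule_gives_pure_methylated_calls(self):
        genome, _, methylome = _uniform_reference(1.0)
        frag = R.Fragment("chr1", 1_000, 1_200, "sonication")
        pairs = R.generate_reads(
            [frag], genome, methylome, 4,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=1)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        frame = table.to_frame()
        cpg = frame[frame["context"] == "CpG"]
        assert len(cpg) > 0
        assert (cpg["unmethylated"] == 0).all()
        assert (cpg["methylated"] >= 1).all()

    def test_unmethylated_genome_full_conversion_gives_pure_unmethylated(self):
        genome, _, methylome = _uniform_reference(0.0)
        frag = R.Fragment("chr1", 1_000, 1_200, "sonication")
        pairs = R.generate_reads(
            [frag], genome, methylome, 4,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=2)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        frame = table.to_frame()
        assert (frame["methylated"] == 0).all()
        assert (frame["unmethylated"] >= 1).all()

    def test_count_conservation_against_independent_tally(self):
        genome, _, methylome = _uniform_reference(0.7)
        frags = R.sonicate(genome, 30, 160, 10, R.SizeWindow(140, 180), seed=3)
        pairs = R.generate_reads(
            [f for f in frags], genome, methylome, 60, read_length=100,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=4)
        alignments = R.truth_alignments(pairs)
        table = R.call_methylation(alignments, pairs, genome)
        # independent tally: count reference cytosines (on the molecule's
        # strand) under read 1 plus the non-overlapping tail of read 2
        expected = 0
        seq = genome.sequences["chr1"]
        for p in pairs:
            chrom, s, e, strand = p.origin
            L1, L2 = len(p.read1), len(p.read2)
            base = "C" if strand == "top" else "G"
            if strand == "top":
                spans = [(s, s + L1), (max(e - L2, s + L1), e)]
            else:
                spans = [(e - L1, e), (s, min(s + L2, e - L1))]
            for a, b in spans:
                expected += seq[a:b].count(base)
        assert table.total_calls() == expected

    def test_mate_overlap_counted_once(self):
        genome, _, methylome = _uniform_reference(1.0)
        frag = R.Fragment("chr1", 500, 600, "sonication")  # insert == read length
        pairs = R.generate_reads(
            [frag], genome, methylome, 1, read_length=100,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=5)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        frame = table.to_frame()
        assert (frame["depth"] == 1).all()  # read 2 fully overlaps read 1

    def test_unknown_chromosome_rejected(self):
        genome, _, _ = _uniform_reference(0.5)
        pair = R.ReadPair("p", "A" * 100, "I" * 100, "A" * 100, "I" * 100)
        bad = R.Alignment("p", "unique", "chrX", 0, 200, "top", 0, 0)
        with pytest.raises(ValueError, match="chrX"):
            R.call_methylation([bad], [pair], genome)

    def test_strand_merge_preserves_counts(self, rrbs_run):
        table = rrbs_run["table"]
        genome = rrbs_run["genome"]
        merged = table.merged_cpg_frame()
        for row in merged.head(50).itertuples(index=False):
            p = row.pos
            assert row.methylated == (table.meth_fwd[row.chrom][p]
                                      + table.meth_rev[row.chrom][p + 1])
            assert row.depth == (table.meth_fwd[row.chrom][p]
                                 + table.unmeth_fwd[row.chrom][p]
                                 + table.meth_rev[row.chrom][p + 1]
                                 + table.unmeth_rev[row.chrom][p + 1])


class TestConversionQC:
    def test_perfect_conversion_zero_non_cpg(self):
        genome, _, methylome = _uniform_reference(1.0, non_cpg=0.0)
        frag = R.Fragment("chr1", 2_000, 2_200, "sonication")
        pairs = R.generate_reads(
            [frag], genome, methylome, 10,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=6)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        non_cpg, efficiency = R.conversion_qc(table)
        assert non_cpg == 0.0 and efficiency == 100.0

    def test_qc_recovers_conversion_failure_rate(self):
        genome, _, methylome = _uniform_reference(0.8, non_cpg=0.0)
        frags = R.sonicate(genome, 300, 350, 50, seed=7)
        pairs = R.generate_reads(
            frags, genome, methylome, 600,
            params=R.ConversionParams(conversion_rate=0.99, sequencing_error_rate=0.0),
            seed=8)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        non_cpg, efficiency = R.conversion_qc(table)
        meth, unmeth = table.context_totals("non-CpG")
        n = meth + unmeth
        se = 100 * math.sqrt(0.01 * 0.99 / n)
        assert abs(non_cpg - 1.0) < 3 * se
        assert non_cpg + efficiency == 100.0

    def test_no_non_cpg_calls_is_an_error(self):
        genome, _, _ = _uniform_reference(0.5)
        with pytest.raises(ValueError, match="non-CpG"):
            R.conversion_qc(MethylationCallTable(genome))


class TestMeanMethylation:
    def test_fully_methylated_is_100(self):
        genome, _, methylome = _uniform_reference(1.0)
        frag = R.Fragment("chr1", 3_000, 3_200, "sonication")
        pairs = R.generate_reads(
            [frag], genome, methylome, 5,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=9)
        table = R.call_methylation(R.truth_alignments(pairs), pairs, genome)
        assert R.mean_methylation(table) == 100.0

    def test_hand_arithmetic_two_sites(self):
        genome = R.ReferenceGenome({"c": "ACGTACGTAT"})
        table = MethylationCallTable(genome)
        table.meth_fwd["c"][1], table.unmeth_fwd["c"][1] = 3, 1
        table.meth_fwd["c"][5], table.unmeth_fwd["c"][5] = 1, 3
        assert R.mean_methylation(table) == 50.0
        assert R.mean_methylation(table, weighted=False) == 50.0

    def test_min_depth_filter_and_error(self):
        genome = R.ReferenceGenome({"c": "ACGTACGTAT"})
        table = MethylationCallTable(genome)
        table.meth_fwd["c"][1] = 2
        assert R.mean_methylation(table, min_depth=2) == 100.0
        with pytest.raises(ValueError, match="depth"):
            R.mean_methylation(table, min_depth=5)


class TestFillInArtifact:
    """Short-insert RRBS: the repaired (fill-in) cytosines are unmethylated
    regardless of the methylome; RRBS-mode trimming must excise them."""

    def _short_insert_calls(self, rrbs_mode: bool):
        genome, features = R.simulate_genome(
            R.GenomeConfig(chromosome_lengths=(60_000,), rng_seed=51))
        methylome = R.simulate_methylome(
            genome, features,
            R.MethylomeParams(island_fixed=1.0, background_fixed=1.0,
                              repeat_fixed=1.0, non_cpg_methylation=0.0))
        library = R.rrbs_library(genome, R.SizeWindow(60, 95))
        pairs = R.generate_reads(
            library, genome, methylome, 400,
            params=R.ConversionParams(conversion_rate=1.0, sequencing_error_rate=0.0),
            seed=52)
        trimmed = R.trim_pairs(
            pairs, R.TrimConfig(rrbs_mode=rrbs_mode, min_length_after_trim=20))
        index = R.build_index(genome, 50)
        config = R.MapperConfig(insert_min_bp=40, insert_max_bp=115)
        alignments = R.map_pairs(trimmed, index, config)
        assert sum(a.status == "unique" for a in alignments) > 100
        table = R.call_methylation(alignments, trimmed, genome)
        return library, table

    def test_rrbs_mode_removes_fill_in_bias(self):
        library, table = self._short_insert_calls(rrbs_mode=True)
        frame = table.to_frame()
        cpg = frame[frame["context"] == "CpG"]
        # truth is fully methylated; with the artifact excised, no
        # unmethylated CpG evidence can remain anywhere
        assert len(cpg) > 100
        assert int(cpg["unmethylated"].sum()) == 0

    def test_without_rrbs_mode_fragment_end_cpgs_are_depressed(self):
        library, table = self._short_insert_calls(rrbs_mode=False)
        fill_unmeth = 0
        for f in library:
            for p in f.fill_in_positions:
                fill_unmeth += int(table.unmeth_fwd[f.chrom][p]
                                   + table.unmeth_rev[f.chrom][p])
        assert fill_unmeth > 50  # strong negative bias at the repaired CpGs
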