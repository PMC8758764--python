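"""Synthetic locus, cohort and read generation behave as constructed."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goldmapper import (
    CohortConfig,
    ReadSimConfig,
    build_locus,
    revcomp,
    simulate_cohort,
    simulate_reads,
    write_sam,
)
from goldmapper.simulate import read_cohort_table, read_fasta, write_cohort_table


class TestLocusConstruction:
    def test_full_size_geometry(self, big_locus):
        # insertion = 2 * 4100 + 50 - 2 deletions
        assert big_locus.insertion_length == 8_248
        assert len(big_locus.alt_sequence) == 18_248
        assert abs(len(big_locus.alt_sequence) - 18_250) <= 2

    def test_empty_insertion_gives_identical_haplotypes(self):
        locus = build_locus(1_000, 0, 0, 0, 500, seed=1)
        assert locus.alt_sequence == locus.ref_sequence

    def test_arms_are_reverse_complementary(self):
        locus = build_locus(1_000, 100, 10, 0, 500, seed=7)
        alt = locus.alt_sequence
        assert alt[500:600] == revcomp(alt[610:710])

    @pytest.mark.parametrize("breakpoint", [0, 1_000, 2_000, -5])
    def test_breakpoint_outside_sequence_rejected(self, breakpoint):
        with pytest.raises(ValueError, match="breakpoint"):
            build_locus(1_000, 50, 10, 0, breakpoint, seed=1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        arm=st.integers(40, 120),
        loop=st.integers(0, 30),
        edits=st.integers(0, 3),
        bp=st.integers(100, 400),
        seed=st.integers(0, 10_000),
    )
    def test_alt_haplotype_composition_invariant(self, arm, loop, edits, bp, seed):
        locus = build_locus(500, arm, loop, edits, bp, seed=seed)
        expected = (
            locus.ref_sequence[:bp]
            + locus.arm_sequence
            + locus.loop_sequence
            + locus.arm2_sequence
            + locus.ref_sequence[bp:]
        )
        assert locus.alt_sequence == expected
        assert len(locus.arm2_sequence) == arm - edits
        assert abs(locus.insertion_length - (2 * arm + loop)) <= edits


class TestCohortModel:
    def test_no_g_allele_means_all_dark_dd(self, small_locus):
        config = CohortConfig(n_individuals=200, g_allele_freq=0.0,
                              phenocopy_rate=0.0, n_background_markers=5, seed=3)
        sim = simulate_cohort(config, small_locus)
        assert (sim.cohort["true_genotype"] == "dd").all()
        assert (sim.cohort["phenotype"] == "dark").all()

    def test_fixed_g_allele_means_all_gold_gg(self, small_locus):
        config = CohortConfig(n_individuals=200, g_allele_freq=1.0,
                              p_untransformed_hom=0.0, p_untransformed_het=0.0,
                              n_background_markers=5, seed=3)
        sim = simulate_cohort(config, small_locus)
        assert (sim.cohort["true_genotype"] == "GG").all()
        assert (sim.cohort["phenotype"] == "gold").all()

    def test_hardy_weinberg_fractions(self, small_locus):
        n, g = 10_000, 0.1
        config = CohortConfig(n_individuals=n, g_allele_freq=g,
                              n_background_markers=0, seed=11)
        sim = simulate_cohort(config, small_locus)
        counts = sim.cohort["true_genotype"].value_counts()
        for genotype, p in [("dd", 0.81), ("Gd", 0.18), ("GG", 0.01)]:
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(genotype, 0) - n * p) < 3 * sd

    def test_dosage_dependence_constraint_enforced(self):
        with pytest.raises(ValueError, match="dosage"):
            CohortConfig(p_untransformed_het=0.01, p_untransformed_hom=0.1)

    def test_marker_matrix_shape_and_missingness(self, small_locus):
        config = CohortConfig(n_individuals=50, n_background_markers=200,
                              missing_rate=0.1, seed=4)
        sim = simulate_cohort(config, small_locus)
        assert sim.dosages.shape == (200, 50)
        observed = sim.dosages.isna().to_numpy().mean()
        assert abs(observed - 0.1) < 0.02
        assert sim.variants["pos"].is_monotonic_increasing

    def test_cohort_table_roundtrip(self, small_locus, tmp_path):
        config = CohortConfig(n_individuals=30, n_background_markers=0, seed=5)
        sim = simulate_cohort(config, small_locus)
        path = tmp_path / "cohort.tsv"
        write_cohort_table(sim.cohort, path)
        back = read_cohort_table(path)
        pd.testing.assert_frame_equal(back, sim.cohort)


class TestReadSimulation:
    def test_read_count_matches_coverage(self, big_locus):
        config = ReadSimConfig(coverage=30, read_length=100)
        reads = simulate_reads("dd", big_locus, config, seed=9)
        expected = 30 * 10_000 / 100
        assert abs(len(reads) - expected) < 3 * np.sqrt(expected)

    def test_dd_reads_never_clipped_near_breakpoint(self, small_locus):
        config = ReadSimConfig(coverage=30, read_length=100)
        reads = simulate_reads("dd", small_locus, config, seed=9)
        assert all(all(op == "M" for op, _ in r.cigar) for r in reads)

    def test_gg_junction_reads_clip_exactly_at_breakpoint(self, small_locus):
        bp = small_locus.breakpoint
        config = ReadSimConfig(coverage=30, read_length=100)
        reads = simulate_reads("GG", small_locus, config, seed=9)
        clipped = [r for r in reads if any(op == "S" for op, _ in r.cigar)]
        assert clipped
        for read in clipped:
            if read.cigar[-1][0] == "S":     # trailing clip: match ends at bp
                matched = sum(n for op, n in read.cigar if op == "M")
                assert read.pos + matched - 1 == bp
            else:                            # leading clip: match starts at bp+1
                assert read.pos == bp + 1

    def test_het_split_fraction_matches_construction(self, small_locus):
        # among classifiable reads: 2*(rl-1) split start positions per alt
        # haplotype vs (rl-9) spanning positions on the ref haplotype
        from goldmapper.genotyper import collect_evidence

        rl = 100
        config = ReadSimConfig(coverage=60, read_length=rl)
        reads = simulate_reads("Gd", small_locus, config, seed=21)
        ev = collect_evidence(reads, "x", small_locus.breakpoint)
        expected = 2 * (rl - 1) / (2 * (rl - 1) + (rl - 9))
        sd = np.sqrt(expected * (1 - expected) / ev.n_total)
        assert abs(ev.ratio - expected) < 4 * sd

    def test_sam_output_byte_identical_across_runs(self, small_locus, tmp_path):
        config = ReadSimConfig(coverage=20, read_length=100, duplicate_rate=0.05)
        for name in ("a", "b"):
            reads = simulate_reads("Gd", small_locus, config, seed=13, sample_id="s")
            write_sam(reads, small_locus, tmp_path / f"{name}.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_substitutions_never_move_clip_boundaries(self, small_locus):
        clean = simulate_reads(
            "GG", small_locus, ReadSimConfig(coverage=20, read_length=100), seed=17)
        noisy = simulate_reads(
            "GG", small_locus,
            ReadSimConfig(coverage=20, read_length=100, substitution_rate=0.05),
            seed=17)
        assert [(r.pos, r.cigar) for r in clean] == [(r.pos, r.cigar) for r in noisy]

    def test_read_longer_than_locus_rejected(self):
        locus = build_locus(50, 0, 0, 0, 25, seed=1)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads("dd", locus, ReadSimConfig(coverage=10, read_length=60))

    def test_fasta_normalizes_case_preserves_n(self, tmp_path):
        path = tmp_path / "x.fa"
        path.write_text(">s\nacgTNna\n")
        assert read_fasta(path) == {"s": "ACGTNNA"}
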