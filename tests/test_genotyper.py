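"""Split-read classification and genotype calling at a known breakpoint."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goldmapper import (
    AlignedReadRecord,
    BreakpointEvidence,
    ReadSimConfig,
    call_genotype,
    classify_read,
    collect_evidence,
    genotype_cohort,
    simulate_reads,
    write_sam,
)
from goldmapper.genotyper import EXCLUDED, REFERENCE, SPLIT

BP = 1_000


def read(start, cigar, unmapped=False, duplicate=False, name="r"):
    return AlignedReadRecord(name=name, unmapped=unmapped, duplicate=duplicate,
                             ref_start=start, operations=tuple(cigar))


class TestClassifyRead:
    @pytest.mark.parametrize(
        "record, expected",
        [
            # full match spanning [bp-50, bp+49]: reference support
            (read(BP - 50, [("M", 100)]), REFERENCE),
            # 50M50S with the clip boundary at the breakpoint: split
            (read(BP - 49, [("M", 50), ("S", 50)]), SPLIT),
            # leading clip starting at bp+1: split (either junction accepted)
            (read(BP + 1, [("S", 40), ("M", 60)]), SPLIT),
            # hard clips carry the same boundary signal as soft clips
            (read(BP - 49, [("M", 50), ("H", 50)]), SPLIT),
            # duplicate-flagged spanning read: excluded
            (read(BP - 50, [("M", 100)], duplicate=True), EXCLUDED),
            # unmapped: excluded
            (read(0, [], unmapped=True), EXCLUDED),
            # ends only 3 bases past the breakpoint: too little overlap
            (read(BP - 96, [("M", 100)]), EXCLUDED),
            # clip boundary far from the breakpoint, good overlap: reference
            (read(BP - 50, [("M", 90), ("S", 10)]), REFERENCE),
            # clip boundary just outside the +/-5 window: not split
            (read(BP - 55, [("M", 50), ("S", 50)]), EXCLUDED),
            # deletions consume reference: span still covers both sides
            (read(BP - 20, [("M", 10), ("D", 5), ("M", 30)]), REFERENCE),
        ],
    )
    def test_classification_rules(self, record, expected):
        assert classify_read(record, BP) == expected

    def test_malformed_operations_excluded_with_warning(self, caplog):
        bad = read(BP - 10, [("Q", 50)])
        with caplog.at_level("WARNING"):
            assert classify_read(bad, BP) == EXCLUDED
        assert "unknown operations" in caplog.text


class TestCallGenotype:
    @pytest.mark.parametrize(
        "n_total, n_split, expected",
        [
            (100, 0, "dd"),      # ratio 0
            (40, 20, "Gd"),      # ratio 0.5, between thresholds
            (30, 2, "dd"),       # absolute split count <= 2
            (30, 28, "GG"),      # total - split <= 2
            (30, 29, "GG"),      # ratio above 0.9
            (100, 9, "dd"),      # ratio 0.09 < 0.1
            (100, 10, "Gd"),     # ratio 0.10 not strictly below threshold
            (100, 90, "Gd"),     # ratio 0.90 not strictly above threshold
            (3, 2, "no-call"),   # both absolute conditions fire
            (0, 0, "no-call"),   # no classifiable reads
        ],
    )
    def test_threshold_and_absolute_rules(self, n_total, n_split, expected):
        evidence = BreakpointEvidence("s", n_total=n_total, n_split=n_split)
        assert call_genotype(evidence).call == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BreakpointEvidence("s", n_total=-1, n_split=0)
        with pytest.raises(ValueError):
            BreakpointEvidence("s", n_total=3, n_split=5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n_total=st.integers(1, 60))
    def test_increasing_split_reads_never_move_call_toward_dd(self, n_total):
        order = {"dd": 0, "Gd": 1, "GG": 2}
        calls = [
            call_genotype(BreakpointEvidence("s", n_total, n_split)).call
            for n_split in range(n_total + 1)
        ]
        ranks = [order[c] for c in calls if c != "no-call"]
        assert ranks == sorted(ranks)


class TestCohortGenotyping:
    def _cohort(self, locus, seed, coverage=40, duplicate_rate=0.0):
        config = ReadSimConfig(coverage=coverage, read_length=100,
                               duplicate_rate=duplicate_rate)
        rng = np.random.SeedSequence(seed).spawn(60)
        truth, alignments = {}, {}
        for i, child in enumerate(rng):
            genotype = ("dd", "Gd", "GG")[i % 3]
            sample = f"s{i:03d}"
            truth[sample] = genotype
            alignments[sample] = simulate_reads(
                genotype, locus, config,
                seed=int(child.generate_state(1)[0] % 2**31), sample_id=sample)
        return truth, alignments

    def test_exact_recovery_on_clean_simulations(self, small_locus):
        for seed in (1, 2):
            truth, alignments = self._cohort(small_locus, seed)
            calls = genotype_cohort(alignments, small_locus.breakpoint)
            assert all(calls[s].call == truth[s] for s in truth)

    def test_duplicate_flags_do_not_change_calls(self, small_locus):
        truth, clean = self._cohort(small_locus, 3, duplicate_rate=0.0)
        _, noisy = self._cohort(small_locus, 3, duplicate_rate=0.1)
        calls_clean = genotype_cohort(clean, small_locus.breakpoint)
        calls_noisy = genotype_cohort(noisy, small_locus.breakpoint)
        assert {s: c.call for s, c in calls_clean.items()} == {
            s: c.call for s, c in calls_noisy.items()}

    def test_empty_alignments_yield_no_call(self):
        calls = genotype_cohort({"a": [], "b": []}, BP)
        assert all(c.call == "no-call" for c in calls.values())

    def test_read_order_and_distant_reads_irrelevant(self, small_locus):
        config = ReadSimConfig(coverage=30, read_length=100)
        reads = simulate_reads("Gd", small_locus, config, seed=5)
        baseline = collect_evidence(reads, "s", small_locus.breakpoint)

        shuffled = list(reads)
        random.Random(0).shuffle(shuffled)
        far = [read(1, [("M", 100)], name="far1"),
               read(len(small_locus.ref_sequence) - 100, [("M", 100)], name="far2")]
        perturbed = collect_evidence(shuffled + far, "s", small_locus.breakpoint)
        assert (baseline.n_split, baseline.n_total) == (
            perturbed.n_split, perturbed.n_total)

    def test_sam_file_and_in_memory_paths_agree(self, small_locus, tmp_path):
        config = ReadSimConfig(coverage=30, read_length=100)
        reads = simulate_reads("Gd", small_locus, config, seed=8, sample_id="s")
        path = tmp_path / "s.sam"
        write_sam(reads, small_locus, path)
        from_file = genotype_cohort({"s": path}, small_locus.breakpoint)
        from_memory = genotype_cohort({"s": reads}, small_locus.breakpoint)
        assert from_file["s"] == from_memory["s"]
        assert from_file["s"].call == "Gd"
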