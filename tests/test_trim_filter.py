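import filecmp

import pytest

from ampliclean.config_io import ReadRecord, StepReport
from ampliclean.simulate_reads import (
    default_demo_config,
    manifest_step_counts,
    simulate_sample_set,
)
from ampliclean.trim_filter import (
    BoundaryConsensusError,
    boundary_offset_filter,
    compute_boundary_consensus,
    demultiplex,
    dereplicate,
    filter_ambiguous,
    filter_length,
    mean_quality,
    quality_filter,
    remove_low_frequency,
    run_pipeline,
    run_pipeline_files,
    strip_adapter_b,
    strip_primers,
)


def make_read(seq, rid="r1", q=30):
    return ReadRecord(rid, seq, [q] * len(seq))


ADAPTER = "CTGAGACTGCCAAGGCACAC"  # 20 bp


class TestAdapterTrimming:
    def test_exact_adapter_trimmed_with_qualities(self):
        read = make_read("ACGTACGTACGT" + ADAPTER)
        out = strip_adapter_b(read, ADAPTER, 0.1)
        assert out.sequence == "ACGTACGTACGT"
        assert len(out.qualities) == 12

    def test_one_mismatch_in_20mer_within_fraction(self):
        # brute-force check: mismatch count 1 <= ceil(0.1 * 20) = 2
        noisy = ADAPTER[:7] + "A" + ADAPTER[8:]
        assert noisy != ADAPTER
        out = strip_adapter_b(make_read("ACGTACGTACGT" + noisy), ADAPTER, 0.1)
        assert out.sequence == "ACGTACGTACGT"

    def test_three_mismatches_rejected(self):
        noisy = "AAA" + ADAPTER[3:]
        assert sum(a != b for a, b in zip(noisy, ADAPTER)) == 3
        assert strip_adapter_b(make_read("ACGTACGTACGT" + noisy), ADAPTER, 0.1) is None

    def test_no_adapter_rejected(self):
        assert strip_adapter_b(make_read("ACGTACGTACGTACGTACGTACGT"), ADAPTER, 0.1) is None

    def test_truncated_adapter_prefix_at_read_end(self):
        # 12 of 20 adapter bases survive at the 3' end (>= half the adapter)
        out = strip_adapter_b(make_read("ACGTACGTACGT" + ADAPTER[:12]), ADAPTER, 0.1)
        assert out.sequence == "ACGTACGTACGT"

    def test_adapter_at_position_zero_leaves_nothing(self):
        assert strip_adapter_b(make_read(ADAPTER + "ACGT"), ADAPTER, 0.1) is None


class TestAmbiguityFilter:
    @pytest.mark.parametrize(
        "seq, keep", [("ACGTACGT", True), ("ACNT", False), ("NNNN", False)]
    )
    def test_reads_with_any_n_discarded(self, seq, keep):
        assert filter_ambiguous(make_read(seq)) is keep


class TestLowFrequencyRemoval:
    def test_pooled_counting(self):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(["AAAA", "AAAA", "CCCC"])]
        kept, discarded = remove_low_frequency(reads, 2)
        assert [r.sequence for r in kept] == ["AAAA", "AAAA"]
        assert [r.sequence for r in discarded] == ["CCCC"]

    def test_min_copy_one_is_identity(self):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(["AAAA", "CCCC", "GGGG"])]
        kept, discarded = remove_low_frequency(reads, 1)
        assert kept == reads and discarded == []

    def test_brute_force_count_three_survivors(self):
        seqs = ["AAAA"] * 3 + ["CCCC", "GGGG"]
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(seqs)]
        kept, _ = remove_low_frequency(reads, 2)
        assert len(kept) == 3


class TestDemultiplex:
    BARCODES = {"S1": "ACGT", "S2": "TGCA"}

    def test_assignment_strips_barcode_and_qualities(self):
        read = ReadRecord("r1", "ACGT" + "GGGGCCCC", list(range(12)))
        samples, unassigned = demultiplex([read], self.BARCODES)
        (out,) = samples["S1"]
        assert out.sequence == "GGGGCCCC" and out.qualities == list(range(4, 12))
        assert unassigned == []

    def test_unmatched_read_unassigned(self):
        samples, unassigned = demultiplex([make_read("GGGGCCCCAAAA")], self.BARCODES)
        assert len(unassigned) == 1 and not samples["S1"] and not samples["S2"]

    def test_partition_sums_to_input(self):
        reads = [
            make_read(bc + "GGGGCCCC", rid=f"r{i}")
            for i, bc in enumerate(["ACGT", "TGCA", "ACGT", "TTTT"])
        ]
        samples, unassigned = demultiplex(reads, self.BARCODES)
        assert sum(len(v) for v in samples.values()) + len(unassigned) == len(reads)


class TestLengthFilter:
    @pytest.mark.parametrize("length, keep", [(250, True), (99, False), (100, True), (500, True), (501, False)])
    def test_inclusive_window(self, length, keep):
        assert filter_length(make_read("A" * length), 100, 500) is keep


class TestBoundaryConsensus:
    PRIMER = "GGCC"

    def reads_with_windows(self, windows):
        return [
            make_read(self.PRIMER + w + "ACGTACGTACGT", rid=f"r{i}")
            for i, w in enumerate(windows)
        ]

    def test_modal_window_wins(self):
        windows = ["ACGTACGT"] * 6 + ["TTTTAAAA"] * 4
        c = compute_boundary_consensus(self.reads_with_windows(windows), self.PRIMER)
        assert (c.motif, c.support) == ("ACGTACGT", 6)

    def test_tie_broken_lexicographically(self):
        windows = ["TTTTAAAA"] * 5 + ["ACGTACGT"] * 5
        c = compute_boundary_consensus(self.reads_with_windows(windows), self.PRIMER)
        assert c.motif == "ACGTACGT"

    def test_no_full_window_raises(self):
        short = [make_read(self.PRIMER + "ACG")]
        with pytest.raises(BoundaryConsensusError):
            compute_boundary_consensus(short, self.PRIMER)


class TestBoundaryOffsetFilter:
    PRIMER = "GGCG"  # ends in G
    CONSENSUS = "GTACGTAC"  # junction target starts with primer's last base

    def test_plus_one_insertion_matches_consensus_and_is_discarded(self):
        # an extra G duplicated from the primer's last base shifts the target
        read = make_read(self.PRIMER + "G" + self.CONSENSUS + "TTTTAAAACCCC")
        assert read.sequence[5:13] == self.CONSENSUS  # +1 window == consensus
        assert not boundary_offset_filter(read, self.CONSENSUS, len(self.PRIMER))

    def test_minus_one_deletion_matches_consensus_and_is_discarded(self):
        read = make_read(self.PRIMER + self.CONSENSUS[1:] + "TTTTAAAACCCC")
        assert not boundary_offset_filter(read, self.CONSENSUS, len(self.PRIMER))

    def test_clean_read_with_divergent_offsets_kept(self):
        read = make_read(self.PRIMER + self.CONSENSUS + "TTTTAAAACCCC")
        assert boundary_offset_filter(read, self.CONSENSUS, len(self.PRIMER))

    def test_offset_window_past_read_end_is_skipped(self):
        # read exactly primer + 8 bases: no +1 window exists
        read = make_read(self.PRIMER + self.CONSENSUS)
        assert boundary_offset_filter(read, self.CONSENSUS, len(self.PRIMER))

    def test_exempt_exact_flag_spares_tandem_repeat_reads(self):
        # offset-0 window equals the consensus but the repeat also matches at +1
        repeat = "GGGGGGGG"
        read = make_read(self.PRIMER + repeat + "G" + "TTTTAAAA")
        assert not boundary_offset_filter(read, repeat, len(self.PRIMER))
        assert boundary_offset_filter(read, repeat, len(self.PRIMER), exempt_exact=True)


class TestPrimerStripping:
    FWD = "GTGCCAGC"
    REV = "GAATTACC"  # rc = GGTAATTC

    def test_exact_primers_removed(self):
        read = make_read(self.FWD + "ACGTACGTACGT" + "GGTAATTC")
        out = strip_primers(read, self.FWD, self.REV)
        assert out.sequence == "ACGTACGTACGT" and len(out.qualities) == 12

    def test_one_mismatch_in_forward_rejected(self):
        bad = "ATGCCAGC"
        read = make_read(bad + "ACGTACGTACGT" + "GGTAATTC")
        assert strip_primers(read, self.FWD, self.REV) is None

    def test_missing_reverse_complement_tail_rejected(self):
        read = make_read(self.FWD + "ACGTACGTACGT")
        assert strip_primers(read, self.FWD, self.REV) is None

    def test_literal_orientation_switch(self):
        read = make_read(self.FWD + "ACGTACGTACGT" + self.REV)
        assert strip_primers(read, self.FWD, self.REV) is None
        out = strip_primers(read, self.FWD, self.REV, reverse_literal=True)
        assert out.sequence == "ACGTACGTACGT"


class TestQualityFilter:
    def test_mean_is_arithmetic(self):
        assert mean_quality(ReadRecord("r", "AAA", [20, 30, 40])) == 30.0

    def test_mean_equal_to_threshold_is_kept(self):
        read = ReadRecord("r", "AAA", [20, 30, 40])
        assert quality_filter(read, 30.0)
        assert not quality_filter(read, 30.0001)

    def test_empty_quality_vector_raises(self):
        read = ReadRecord("r", "AAA", [20, 30, 40])
        read.qualities = []
        with pytest.raises(ValueError):
            mean_quality(read)


class TestDereplication:
    def test_frequency_and_rank(self):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(["ACAC", "ACAC", "AGAG"])]
        recs = dereplicate(reads, "S1")
        assert [(r.sequence, r.frequency, r.rank) for r in recs] == [
            ("ACAC", 2, 1),
            ("AGAG", 1, 2),
        ]

    def test_indel_variants_stay_distinct(self):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(["ACGT", "ACGGT"])]
        assert len(dereplicate(reads, "S1")) == 2

    def test_equal_frequencies_ordered_lexicographically(self):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(["TTTT", "AAAA"])]
        recs = dereplicate(reads, "S1")
        assert [r.sequence for r in recs] == ["AAAA", "TTTT"]

    def test_mass_conservation(self, simulated_dataset):
        config, records, _ = simulated_dataset
        result = run_pipeline(config, records)
        for sample, reads in result.samples.items():
            assert sum(r.frequency for r in result.nonredundant[sample]) == len(reads)
            freqs = [r.frequency for r in result.nonredundant[sample]]
            assert freqs == sorted(freqs, reverse=True)


class TestRunPipeline:
    def test_all_clean_reads_discard_nothing(self, demo_config):
        rates = {cat: 0.0 for cat in ("no_adapter", "low_quality")}
        records, truths = simulate_sample_set(demo_config, 30, rates, seed=3)
        assert all(t.expected_fate == "kept" for t in truths)
        result = run_pipeline(demo_config, records)
        assert all(rep.n_discarded == 0 for rep in result.reports)

    def test_step_counts_match_manifest(self, simulated_dataset):
        config, records, truths = simulated_dataset
        result = run_pipeline(config, records)
        assert result.reports == manifest_step_counts(truths)

    def test_conservation_invariants(self, simulated_dataset):
        config, records, _ = simulated_dataset
        result = run_pipeline(config, records)
        for rep in result.reports:
            assert rep.n_in == rep.n_kept + rep.n_discarded
        total_discarded = sum(rep.n_discarded for rep in result.reports)
        assert result.reports[0].n_in == result.reports[-1].n_kept + total_discarded

    def test_single_sample_mode_skips_demultiplexing(self, demo_config):
        config = default_demo_config(barcodes={})
        records, truths = simulate_sample_set(config, 40, seed=5)
        result = run_pipeline(config, records)
        assert list(result.samples) == ["all"]
        demux = next(r for r in result.reports if r.step_name == "demultiplexing")
        assert demux.n_discarded == 0

    def test_outputs_byte_identical_across_runs(self, tmp_path, demo_config):
        records, _ = simulate_sample_set(demo_config, 40, seed=9, out_dir=tmp_path / "sim")
        for run in ("a", "b"):
            run_pipeline_files(
                demo_config,
                tmp_path / "sim" / "reads.fasta",
                tmp_path / "sim" / "reads.qual",
                tmp_path / run,
            )
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == [] and set(match) == set(names)

    def test_invalid_step_report_rejected(self):
        with pytest.raises(ValueError):
            StepReport("broken", 10, 5, 4)
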