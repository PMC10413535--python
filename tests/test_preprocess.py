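import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covplot import preprocess
from covplot.errors import EmptyLibraryError, ParameterError
from covplot.io import Peak, PeakSet
from covplot.preprocess import (ConsensusParams, LibraryStats, bin_signal,
                                compute_library_stats, consensus_peaks,
                                count_reads_per_bin, fisher_combine,
                                normalize_bins, normalize_many,
                                normalize_track)
from covplot.regions import BinnedSignal, GenomicRegion, SignalTrack, \
    make_region
from covplot.simulate import SimSpec, simulate_alignments, simulate_reference

from conftest import write_bam


def fisher_oracle(p_values):
    """Closed-form chi-square survival at even df:
    exp(-x/2) * sum_{j<k} (x/2)^j / j!  with x = -2 sum(ln p)."""
    x = -2.0 * sum(math.log(p) for p in p_values)
    k = len(p_values)
    half = x / 2.0
    return math.exp(-half) * sum(half ** j / math.factorial(j)
                                 for j in range(k))


class TestBinSignal:
    def _track(self, values):
        return SignalTrack(make_region("chr1", 0, len(values)),
                           np.asarray(values, dtype=float))

    def test_mean(self):
        b = bin_signal(self._track([1, 1, 1, 3, 3, 3]), 3, "mean")
        assert list(b.values) == [1.0, 3.0]

    def test_short_terminal_bin(self):
        b = bin_signal(self._track(range(7)), 3, "mean")
        assert len(b) == 3
        assert b.values[-1] == 6.0  # the single position of the last bin

    def test_sum(self):
        b = bin_signal(self._track([1.0] * 10), 10, "sum")
        assert list(b.values) == [10.0]

    def test_bad_binsize(self):
        with pytest.raises(ParameterError):
            bin_signal(self._track([1.0]), 0)


class TestLibraryStats:
    def test_counts_written_reads(self, tmp_path):
        reads = [[(i * 3, i * 3 + 50)] for i in range(1000)]
        bam = write_bam(tmp_path / "t.bam", "chr1", 5000, reads)
        stats = compute_library_stats(bam)
        assert stats.total_mapped_reads == 1000
        assert stats.mean_read_length == 50.0

    def test_duplicates_excluded(self, tmp_path):
        import pysam
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        path = tmp_path / "d.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for i in range(10):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 20
                a.flag = 1024 if i < 4 else 0  # 4 duplicates
                a.reference_id = 0
                a.reference_start = 100
                a.mapping_quality = 60
                a.cigar = [(0, 20)]
                out.write(a)
        pysam.index(str(path))
        assert compute_library_stats(path).total_mapped_reads == 6

    def test_empty_library(self, tmp_path):
        import pysam
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100}]}
        path = tmp_path / "e.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header):
            pass
        pysam.index(str(path))
        with pytest.raises(EmptyLibraryError):
            compute_library_stats(path)


class TestNormalization:
    def test_cpm_closed_form(self):
        binned = BinnedSignal(make_region("chr1", 0, 100), 100, [10.0])
        stats = LibraryStats(1_000_000, 100.0)
        out = normalize_bins(binned, "CPM", stats)
        assert out.values[0] == pytest.approx(10.0, rel=1e-12)

    def test_rpkm_closed_form(self):
        binned = BinnedSignal(make_region("chr1", 0, 500), 500, [20.0])
        stats = LibraryStats(2_000_000, 100.0)
        out = normalize_bins(binned, "RPKM", stats)
        assert out.values[0] == pytest.approx(20.0, rel=1e-12)

    def test_bpm_closed_form(self):
        binned = BinnedSignal(make_region("chr1", 0, 300), 100,
                              [2.0, 3.0, 5.0])
        out = normalize_bins(binned, "BPM")
        assert list(out.values) == [200000.0, 300000.0, 500000.0]

    def test_bpm_sums_to_one_million(self):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 500, size=200).astype(float)
        values[0] += 1  # guard against all-zero
        binned = BinnedSignal(make_region("chr1", 0, 200 * 50), 50, values)
        out = normalize_bins(binned, "BPM")
        assert out.values.sum() == pytest.approx(1e6, rel=1e-6)

    def test_rpgc_uniform_mean_is_one(self, tmp_path):
        # 1000 reads x 100 bp on a 50 kb effective genome -> scale 2.0
        spec = SimSpec(seed=2)
        ref = simulate_reference(spec, tmp_path / "ref.fa")
        bam = simulate_alignments(spec, ref, tmp_path / "u.bam")
        stats = compute_library_stats(bam, effective_genome_size=50_000)
        assert stats.total_mapped_reads == 1000
        assert stats.mean_read_length == 100.0
        out = normalize_track(bam, spec.region, 50, "RPGC", stats)
        # genome-wide mean per-base RPGC depth is exactly 1x
        assert out.values.mean() == pytest.approx(1.0, rel=1e-6)

    def test_rpgc_requires_genome_size(self):
        binned = BinnedSignal(make_region("chr1", 0, 100), 100, [4.0])
        with pytest.raises(ParameterError):
            normalize_bins(binned, "RPGC", LibraryStats(1000, 100.0))

    @pytest.mark.parametrize("method", ["CPM", "RPKM", "BPM", "RPGC"])
    def test_linearity(self, method):
        rng = np.random.default_rng(9)
        values = rng.integers(1, 100, size=20).astype(float)
        binned = BinnedSignal(make_region("chr1", 0, 1000), 50, values)
        scaled = binned.with_values(values * 3.0, "raw")
        stats = LibraryStats(10_000, 80.0, effective_genome_size=100_000)
        out1 = normalize_bins(binned, method, stats).values
        out3 = normalize_bins(scaled, method, stats).values
        if method == "BPM":  # scale-invariant by construction
            assert np.allclose(out3, out1)
        else:
            assert np.allclose(out3, 3.0 * out1)

    def test_count_reads_by_five_prime_position(self, tmp_path):
        import pysam
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        path = tmp_path / "s.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for i, (start, flag) in enumerate([(95, 0), (95, 16)]):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 10
                a.flag = flag
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigar = [(0, 10)]
                out.write(a)
        pysam.index(str(path))
        binned = count_reads_per_bin(path, make_region("chr1", 0, 1000), 100)
        # forward read 5' end at 95 (bin 0); reverse read 5' end at 104
        assert binned.values[0] == 1
        assert binned.values[1] == 1


class TestNormalizeMany:
    def test_identical_inputs_identical_outputs(self, tmp_path):
        spec = SimSpec(seed=4, region=make_region("chr1", 0, 5000),
                       n_reads=200)
        ref = simulate_reference(spec, tmp_path / "ref.fa")
        b1 = simulate_alignments(spec, ref, tmp_path / "a.bam")
        b2 = simulate_alignments(spec, ref, tmp_path / "b.bam")
        results, failures = normalize_many([b1, b2], spec.region, 100, "CPM")
        assert not failures
        assert np.array_equal(results[0].values, results[1].values)

    def test_partial_failure_isolated(self, tmp_path):
        spec = SimSpec(seed=4, region=make_region("chr1", 0, 5000),
                       n_reads=200)
        ref = simulate_reference(spec, tmp_path / "ref.fa")
        good = simulate_alignments(spec, ref, tmp_path / "a.bam")
        bad = tmp_path / "corrupt.bam"
        bad.write_text("not a bam")
        results, failures = normalize_many([good, bad, good], spec.region,
                                           100, "raw")
        assert results[0] is not None and results[2] is not None
        assert results[1] is None
        assert len(failures) == 1 and "corrupt" in failures[0].path


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.001, 0.2, 0.85, 1.0):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_worked_example(self):
        # x = -2(ln 0.01 + ln 0.04) = 15.648...; df 4
        assert fisher_combine([0.01, 0.04]) == pytest.approx(
            fisher_oracle([0.01, 0.04]), rel=1e-12)
        assert fisher_combine([0.01, 0.04]) == pytest.approx(3.53e-3,
                                                             rel=0.01)

    def test_matches_even_df_closed_form(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            k = int(rng.integers(1, 7))
            p = rng.uniform(1e-8, 1.0, size=k)
            assert fisher_combine(p) == pytest.approx(
                fisher_oracle(p), abs=1e-12, rel=1e-9)

    def test_order_invariant(self):
        p = [0.3, 0.01, 0.77, 0.05]
        assert fisher_combine(p) == fisher_combine(p[::-1])

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.2], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterError):
            fisher_combine(bad)


def _peak(start, end, p=None, chrom="chr1"):
    return Peak(region=GenomicRegion(chrom, start, end), p_value=p)


class TestConsensusPeaks:
    def test_three_replicates_recovered(self):
        sets = [PeakSet([_peak(100, 600, 1e-6)], source=f"rep{i}")
                for i in range(3)]
        out = consensus_peaks(sets, ConsensusParams(gamma=1e-8,
                                                    min_support=2))
        assert len(out) == 1
        expected = fisher_oracle([1e-6] * 3)
        assert out.peaks[0].p_value == pytest.approx(expected, rel=1e-6)
        assert expected < 1e-8  # passes the stringent threshold

    def test_low_support_discarded(self):
        sets = [PeakSet([_peak(100, 600, 1e-9)]), PeakSet([]), PeakSet([])]
        out = consensus_peaks(sets, ConsensusParams(gamma=0.5,
                                                    min_support=2))
        assert len(out) == 0

    def test_weak_evidence_discarded(self):
        sets = [PeakSet([_peak(100, 600, 0.04)]),
                PeakSet([_peak(150, 650, 0.05)])]
        combined = fisher_oracle([0.04, 0.05])
        assert combined > 1e-4  # ~0.016
        out = consensus_peaks(sets, ConsensusParams(gamma=1e-4,
                                                    min_support=2))
        assert len(out) == 0

    def test_merged_interval_is_span_union(self):
        sets = [PeakSet([_peak(100, 600, 1e-9)]),
                PeakSet([_peak(300, 800, 1e-9)])]
        out = consensus_peaks(sets, ConsensusParams(gamma=1e-4,
                                                    min_support=2))
        assert len(out) == 1
        assert (out.peaks[0].region.start, out.peaks[0].region.end) \
            == (100, 800)

    def test_output_sorted_non_overlapping(self):
        rng = np.random.default_rng(3)
        sets = []
        for _ in range(3):
            peaks = []
            for k in range(6):
                start = int(rng.integers(k * 1000, k * 1000 + 300))
                peaks.append(_peak(start, start + 400,
                                   float(rng.uniform(1e-10, 1e-6))))
            sets.append(PeakSet(sorted(peaks,
                                       key=lambda p: p.region.start)))
        out = consensus_peaks(sets, ConsensusParams(gamma=1e-4,
                                                    min_support=2))
        regions = [p.region for p in out]
        for a, b in zip(regions, regions[1:]):
            assert a.start <= b.start
            assert a.end <= b.start  # non-overlapping

    def test_gamma_monotonicity(self):
        rng = np.random.default_rng(8)
        sets = []
        for _ in range(3):
            peaks = [_peak(int(k * 500), int(k * 500 + 300),
                           float(rng.uniform(1e-8, 0.5)))
                     for k in range(8)]
            sets.append(PeakSet(peaks))
        counts = [len(consensus_peaks(
            sets, ConsensusParams(gamma=g, min_support=2)))
            for g in (1e-12, 1e-8, 1e-4, 1e-2, 0.5)]
        assert counts == sorted(counts)  # less stringent -> never fewer

    def test_min_support_exceeds_replicates(self):
        sets = [PeakSet([_peak(0, 10, 0.1)]), PeakSet([_peak(0, 10, 0.1)])]
        with pytest.raises(ParameterError):
            consensus_peaks(sets, ConsensusParams(gamma=0.5, min_support=3))
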