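"""Coverage preprocessing: binning, per-bin read normalization, and
consensus-peak generation from replicate peak sets.

Normalization follows the standard per-bin definitions used throughout
the NGS world:

    CPM_i  = reads_i / (total_mapped / 1e6)
    RPKM_i = reads_i / ((width_i / 1000) * (total_mapped / 1e6))
    BPM_i  = reads_i / (sum_j reads_j / 1e6)          (bins per million)
    RPGC_i = depth_i / (total_mapped * mean_read_len / effective_genome)

RPGC scales mean per-base depth to 1x genomic coverage; the other three
operate on per-bin read counts, where a read is counted in the bin that
contains its 5'-most reference position.

Consensus peaks combine replicate evidence with Fisher's method
(X^2 = -2 * sum(ln p) ~ chi-square with 2k df): a peak survives when it is
supported by at least `min_support` replicates and its combined p-value is
at or below the stringency threshold `gamma`; surviving peaks that overlap
across replicates are merged into one consensus interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pysam
from scipy import stats

from .errors import EmptyLibraryError, ParameterError
from .io import Peak, PeakSet, _read_passes, read_coverage_bam
from .regions import BinnedSignal, GenomicRegion, SignalTrack, overlaps

__all__ = [
    "LibraryStats",
    "ConsensusParams",
    "EFFECTIVE_GENOME_SIZES",
    "DEFAULT_BINSIZE",
    "bin_signal",
    "compute_library_stats",
    "count_reads_per_bin",
    "normalize_bins",
    "normalize_track",
    "normalize_many",
    "fisher_combine",
    "consensus_peaks",
]

DEFAULT_BINSIZE = 50

# deeptools-style effective (mappable) genome sizes, overridable everywhere
EFFECTIVE_GENOME_SIZES: dict[str, int] = {
    "hg19": 2_864_785_220,
    "hg38": 2_913_022_398,
    "mm10": 2_652_783_500,
}

_BIN_STATS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "sum": np.sum,
    "max": np.max,
}


@dataclass
class LibraryStats:
    """Per-library quantities the normalization formulas require."""

    total_mapped_reads: int
    mean_read_length: float
    effective_genome_size: int | None = None

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ParameterError("total_mapped_reads must be positive")
        if self.mean_read_length <= 0:
            raise ParameterError("mean_read_length must be positive")
        if (self.effective_genome_size is not None
                and self.effective_genome_size <= 0):
            raise ParameterError("effective_genome_size must be positive")


def bin_signal(track: SignalTrack, binsize: int,
               stat: str = "mean") -> BinnedSignal:
    """Aggregate a per-base track into bins tiling the region from its
    start; the short terminal bin aggregates only its own positions."""
    if binsize < 1:
        raise ParameterError(f"binsize must be >= 1, got {binsize}")
    if stat not in _BIN_STATS:
        raise ParameterError(
            f"stat must be one of {sorted(_BIN_STATS)}, got {stat!r}"
        )
    fn = _BIN_STATS[stat]
    n = len(track.values)
    values = np.array([
        fn(track.values[i:min(i + binsize, n)])
        for i in range(0, n, binsize)
    ], dtype=float)
    return BinnedSignal(region=track.region, binsize=binsize, values=values,
                        sample=track.sample, group=track.group)


def compute_library_stats(path: str | Path,
                          effective_genome_size: int | None = None,
                          max_length_sample: int = 100_000) -> LibraryStats:
    """Whole-library statistics from an indexed BAM.

    Counts primary mapped non-duplicate reads; mean read length is averaged
    over at most `max_length_sample` reads from the start of the file.
    """
    total = 0
    length_sum = 0
    length_n = 0
    with pysam.AlignmentFile(str(path), "rb") as af:
        for read in af.fetch(until_eof=True):
            if not _read_passes(read, 0):
                continue
            total += 1
            if length_n < max_length_sample:
                length_sum += read.query_length or read.infer_query_length() or 0
                length_n += 1
    if total == 0:
        raise EmptyLibraryError(f"{path}: no usable mapped reads")
    return LibraryStats(
        total_mapped_reads=total,
        mean_read_length=length_sum / length_n,
        effective_genome_size=effective_genome_size,
    )


def _read_5prime_position(read: "pysam.AlignedSegment") -> int:
    """5'-most reference position of the read (strand-aware)."""
    if read.is_reverse:
        return read.reference_end - 1
    return read.reference_start


def count_reads_per_bin(path: str | Path, region: GenomicRegion,
                        binsize: int, min_mapq: int = 0,
                        sample: str | None = None,
                        group: str | None = None) -> BinnedSignal:
    """Per-bin read counts: each passing read is counted once, in the bin
    containing its 5'-most reference position (no fractional assignment)."""
    if binsize < 1:
        raise ParameterError(f"binsize must be >= 1, got {binsize}")
    n_bins = -(-len(region) // binsize)
    counts = np.zeros(n_bins, dtype=float)
    with pysam.AlignmentFile(str(path), "rb") as af:
        for read in af.fetch(region.chrom, region.start, region.end):
            if not _read_passes(read, min_mapq):
                continue
            pos = _read_5prime_position(read)
            if region.start <= pos < region.end:
                counts[(pos - region.start) // binsize] += 1
    name = sample if sample is not None else Path(path).stem
    return BinnedSignal(region=region, binsize=binsize, values=counts,
                        sample=name, group=group)


def normalize_bins(binned: BinnedSignal, method: str,
                   stats_: LibraryStats | None = None) -> BinnedSignal:
    """Apply one of the per-bin normalizations (see module docstring).

    For CPM/RPKM/BPM, `binned.values` are per-bin read counts; for RPGC
    they are mean per-base depths. BPM and raw need no library stats.
    """
    if method == "raw":
        return binned.with_values(binned.values.copy(), "raw")
    if method == "BPM":
        total = binned.values.sum()
        if total == 0:
            raise ParameterError("BPM undefined for an all-zero track")
        return binned.with_values(binned.values * 1e6 / total, "BPM")
    if stats_ is None:
        raise ParameterError(f"{method} normalization requires LibraryStats")
    if method == "CPM":
        return binned.with_values(
            binned.values / (stats_.total_mapped_reads / 1e6), "CPM")
    if method == "RPKM":
        per_kb = binned.bin_widths / 1000.0
        return binned.with_values(
            binned.values / (per_kb * (stats_.total_mapped_reads / 1e6)),
            "RPKM")
    if method == "RPGC":
        if stats_.effective_genome_size is None:
            raise ParameterError(
                "RPGC requires an effective_genome_size in LibraryStats"
            )
        scale = (stats_.total_mapped_reads * stats_.mean_read_length
                 / stats_.effective_genome_size)
        return binned.with_values(binned.values / scale, "RPGC")
    raise ParameterError(f"unknown normalization method {method!r}")


def normalize_track(path: str | Path, region: GenomicRegion, binsize: int,
                    method: str, stats_: LibraryStats | None = None,
                    min_mapq: int = 0, sample: str | None = None,
                    group: str | None = None) -> BinnedSignal:
    """Bin + normalize a BAM over a region in one step.

    RPGC bins mean per-base depth; all other methods bin 5'-position read
    counts. Library stats are computed from the file when not supplied and
    the method needs them.
    """
    if method == "RPGC":
        track = read_coverage_bam(path, region, min_mapq=min_mapq,
                                  sample=sample, group=group)
        binned = bin_signal(track, binsize, stat="mean")
    else:
        binned = count_reads_per_bin(path, region, binsize,
                                     min_mapq=min_mapq, sample=sample,
                                     group=group)
    if method in ("CPM", "RPKM", "RPGC") and stats_ is None:
        stats_ = compute_library_stats(path)
    return normalize_bins(binned, method, stats_)


@dataclass
class NormalizeError:
    path: str
    error: Exception


def normalize_many(bam_paths: Sequence[str | Path], region: GenomicRegion,
                   binsize: int, method: str,
                   effective_genome_size: int | None = None,
                   min_mapq: int = 0
                   ) -> tuple[list[BinnedSignal | None], list[NormalizeError]]:
    """Normalize several libraries over the same region.

    Results are independent per input and returned in input order; a
    failing input yields ``None`` in its slot plus an error record, and
    does not affect the others.
    """
    if not bam_paths:
        raise ParameterError("need at least one alignment file")
    results: list[BinnedSignal | None] = []
    failures: list[NormalizeError] = []
    for path in bam_paths:
        try:
            stats_ = None
            if method in ("CPM", "RPKM", "RPGC"):
                stats_ = compute_library_stats(
                    path, effective_genome_size=effective_genome_size)
            results.append(normalize_track(path, region, binsize, method,
                                           stats_, min_mapq=min_mapq))
        except Exception as exc:  # error contract: isolate per input
            results.append(None)
            failures.append(NormalizeError(path=str(path), error=exc))
    return results, failures


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability over k p-values.

    X^2 = -2 * sum(ln p_k); returns the chi-square(2k) upper-tail
    probability at X^2. The k = 1 case returns the input p unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


@dataclass
class ConsensusParams:
    """Stringency threshold and replicate-support requirement for
    consensus peak calling."""

    gamma: float = 1e-8
    min_support: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.gamma < 1):
            raise ParameterError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.min_support < 1:
            raise ParameterError("min_support must be >= 1")


def _peak_p(peak: Peak) -> float:
    # peaks without p-values are treated as weakest possible evidence
    return peak.p_value if peak.p_value is not None else 1.0


def consensus_peaks(replicate_sets: Sequence[PeakSet],
                    params: ConsensusParams | None = None) -> PeakSet:
    """Consensus peaks from >= 2 replicate peak sets.

    For each peak: collect the single best (smallest-p) overlapping peak
    from every other replicate; support = 1 + number of contributing
    replicates; peaks with support below `min_support` are discarded.
    The peak's own p-value and the collected ones are combined with
    Fisher's method and the peak survives iff combined p <= gamma.
    Surviving peaks overlapping across replicates are merged into one
    consensus interval (union of spans; combined p = group minimum).
    """
    params = params or ConsensusParams()
    if len(replicate_sets) < 2:
        raise ParameterError("consensus requires at least 2 replicates")
    if params.min_support > len(replicate_sets):
        raise ParameterError(
            f"min_support={params.min_support} exceeds number of "
            f"replicates ({len(replicate_sets)})"
        )

    surviving: list[tuple[Peak, float]] = []  # (peak, combined p)
    for i, peak_set in enumerate(replicate_sets):
        for peak in peak_set:
            collected = [_peak_p(peak)]
            support = 1
            for j, other_set in enumerate(replicate_sets):
                if j == i:
                    continue
                best = None
                for other in other_set:
                    if overlaps(peak.region, other.region):
                        if best is None or _peak_p(other) < _peak_p(best):
                            best = other
                if best is not None:
                    support += 1
                    collected.append(_peak_p(best))
            if support < params.min_support:
                continue
            # clamp away from 0 so -log10 scores and the (0,1] peak
            # invariant stay well-defined under extreme evidence
            combined = max(fisher_combine(collected), 1e-300)
            if combined <= params.gamma:
                surviving.append((peak, combined))

    # merge overlapping survivors into consensus intervals
    surviving.sort(key=lambda pc: (pc[0].region.chrom, pc[0].region.start,
                                   pc[0].region.end, pc[1]))
    merged: list[Peak] = []
    for peak, combined in surviving:
        if merged and overlaps(merged[-1].region, peak.region):
            prev = merged[-1]
            merged[-1] = Peak(
                region=GenomicRegion(
                    prev.region.chrom, prev.region.start,
                    max(prev.region.end, peak.region.end)),
                name=prev.name,
                score=max(prev.score, -np.log10(combined)),
                p_value=min(prev.p_value, combined),
            )
        else:
            merged.append(Peak(
                region=peak.region,
                name=f"consensus_{len(merged) + 1}",
                score=float(-np.log10(combined)),
                p_value=combined,
            ))
    return PeakSet(peaks=merged, source="consensus")
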