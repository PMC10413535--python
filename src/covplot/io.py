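"""Readers and writers for every supported track and annotation format.

All readers honor the region-subset contract: only the requested region is
fetched or materialized, never the whole file (for indexed formats this is
delegated to the index; text formats are filtered while streaming).

Coordinate conventions on disk: BED / BedGraph / narrowPeak are 0-based
half-open and pass through unchanged; GTF and cytoband files follow their
published conventions and are converted to the internal 0-based half-open
system on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pyBigWig
import pysam
from gffutils.feature import feature_from_line
from pyfaidx import Fasta

from .errors import (
    ChromosomeNotFoundError,
    FormatError,
    IndexRequiredError,
    NotFoundError,
    ReferenceUnavailableError,
    SchemaError,
)
from .regions import BinnedSignal, GenomicRegion, SignalTrack

__all__ = [
    "LocusBaseCounts",
    "GenePart",
    "TranscriptModel",
    "GeneModel",
    "GeneModelSet",
    "Peak",
    "PeakSet",
    "CytobandSet",
    "ContactMatrix",
    "PeptideRecord",
    "PeptideTable",
    "read_coverage_bam",
    "read_base_counts_bam",
    "read_coverage_bigwig",
    "read_coverage_bedgraph",
    "read_track_tsv",
    "read_gene_models_gtf",
    "read_peaks",
    "read_cytoband",
    "read_contact_matrix",
    "read_peptides",
    "read_fasta_region",
    "write_bedgraph",
    "write_bigwig",
]

BASES = "ACGTN"

# SAM flag filters for conventional coverage semantics
_EXCLUDE_FLAGS = dict(unmapped=True, secondary=True, supplementary=True,
                      qcfail=True, duplicate=True)


def _read_passes(read: "pysam.AlignedSegment", min_mapq: int) -> bool:
    if (read.is_unmapped or read.is_secondary or read.is_supplementary
            or read.is_qcfail or read.is_duplicate):
        return False
    return read.mapping_quality >= min_mapq


def _covered_blocks(read: "pysam.AlignedSegment") -> list[tuple[int, int]]:
    """Reference spans this read covers: M/=/X and D count, N (spliced
    introns) does not."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    cur_start = None
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference and cover it
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 3:  # N: consumes reference, not covered
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def _open_indexed_bam(path: str | Path) -> pysam.AlignmentFile:
    af = pysam.AlignmentFile(str(path), "rb")
    if not af.has_index():
        af.close()
        raise IndexRequiredError(
            f"{path}: alignment file must be indexed (.bai) for "
            "region-subset loading"
        )
    return af


def _check_chrom(af: pysam.AlignmentFile, chrom: str, path) -> None:
    if chrom not in af.references:
        raise ChromosomeNotFoundError(
            f"{path}: chromosome {chrom!r} not in header "
            f"(has {list(af.references)[:5]}...)"
        )


def read_coverage_bam(path: str | Path, region: GenomicRegion,
                      min_mapq: int = 0, sample: str | None = None,
                      group: str | None = None) -> SignalTrack:
    """Per-base read depth over `region` from an indexed BAM.

    Depth at a position is the number of passing reads whose aligned
    reference span covers it. Unmapped, secondary, supplementary, QC-fail
    and duplicate reads are excluded; deletions within a read count as
    covered, spliced skips (N CIGAR) do not.
    """
    depth = np.zeros(len(region), dtype=float)
    with _open_indexed_bam(path) as af:
        _check_chrom(af, region.chrom, path)
        for read in af.fetch(region.chrom, region.start, region.end):
            if not _read_passes(read, min_mapq):
                continue
            for bstart, bend in _covered_blocks(read):
                lo = max(bstart, region.start) - region.start
                hi = min(bend, region.end) - region.start
                if lo < hi:
                    depth[lo:hi] += 1
    name = sample if sample is not None else Path(path).stem
    return SignalTrack(region=region, values=depth, sample=name, group=group)


@dataclass
class LocusBaseCounts:
    """Per-position A/C/G/T/N pileup counts plus the reference base."""

    region: GenomicRegion
    counts: np.ndarray  # shape (len(region), 5), columns A C G T N
    ref_bases: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.region), len(BASES)):
            raise FormatError(
                f"counts must be ({len(self.region)}, {len(BASES)}), "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise FormatError("negative pileup count")
        if len(self.ref_bases) != len(self.region):
            raise FormatError("one reference base required per position")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def read_fasta_region(fasta_path: str | Path, region: GenomicRegion) -> str:
    """Uppercased reference sequence for `region` (indexed FASTA access)."""
    fa = Fasta(str(fasta_path))
    if region.chrom not in fa:
        raise ReferenceUnavailableError(
            f"{fasta_path}: no sequence named {region.chrom!r}"
        )
    if region.end > len(fa[region.chrom]):
        raise ReferenceUnavailableError(
            f"{fasta_path}: {region} extends past end of "
            f"{region.chrom} ({len(fa[region.chrom])} bp)"
        )
    return str(fa[region.chrom][region.start:region.end]).upper()


def read_base_counts_bam(path: str | Path, region: GenomicRegion,
                         fasta_path: str | Path, min_mapq: int = 0,
                         min_baseq: int = 0) -> LocusBaseCounts:
    """Pileup base counts per position, with quality filters, plus the
    reference base from the FASTA."""
    ref = read_fasta_region(fasta_path, region)
    counts = np.zeros((len(region), len(BASES)), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    with _open_indexed_bam(path) as af:
        _check_chrom(af, region.chrom, path)
        for read in af.fetch(region.chrom, region.start, region.end):
            if not _read_passes(read, min_mapq):
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos < region.start or rpos >= region.end:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                b = seq[qpos].upper()
                counts[rpos - region.start, base_index.get(b, 4)] += 1
    return LocusBaseCounts(region=region, counts=counts, ref_bases=ref)


def read_coverage_bigwig(path: str | Path, region: GenomicRegion,
                         sample: str | None = None,
                         group: str | None = None) -> SignalTrack:
    """Per-base values from a BigWig; positions with no interval are 0."""
    try:
        bw = pyBigWig.open(str(path))
    except RuntimeError as exc:
        raise FormatError(f"{path}: cannot open as BigWig ({exc})") from exc
    try:
        chroms = bw.chroms()
        if region.chrom not in chroms:
            raise ChromosomeNotFoundError(
                f"{path}: chromosome {region.chrom!r} not present"
            )
        end = min(region.end, chroms[region.chrom])
        values = np.zeros(len(region), dtype=float)
        if end > region.start:
            vals = bw.values(region.chrom, region.start, end, numpy=True)
            vals = np.nan_to_num(vals, nan=0.0)
            values[: end - region.start] = vals
    finally:
        bw.close()
    name = sample if sample is not None else Path(path).stem
    return SignalTrack(region=region, values=values, sample=name, group=group)


def read_coverage_bedgraph(path: str | Path, region: GenomicRegion,
                           sample: str | None = None,
                           group: str | None = None) -> SignalTrack:
    """Per-base values from a BedGraph (0-based half-open, 4 columns)."""
    values = np.zeros(len(region), dtype=float)
    seen: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if (not line or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BedGraph needs 4 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, value = fields[0], int(fields[1]), \
                int(fields[2]), float(fields[3])
            if chrom != region.chrom:
                continue
            if end <= region.start or start >= region.end:
                # still remember the interval for overlap checking on chrom
                seen.append((start, end))
                continue
            seen.append((start, end))
            lo = max(start, region.start) - region.start
            hi = min(end, region.end) - region.start
            values[lo:hi] = value
    seen.sort()
    for (s1, e1), (s2, e2) in zip(seen, seen[1:]):
        if s2 < e1:
            raise FormatError(
                f"{path}: overlapping BedGraph intervals "
                f"[{s1},{e1}) and [{s2},{e2}) on {region.chrom}"
            )
    name = sample if sample is not None else Path(path).stem
    return SignalTrack(region=region, values=values, sample=name, group=group)


_TSV_ALIASES = {
    "chrom": {"chrom", "chromosome", "chr", "seqnames", "seqname"},
    "start": {"start", "chromstart"},
    "end": {"end", "chromend", "stop"},
    "score": {"score", "value", "signal", "count"},
    "sample": {"sample", "type", "sample_type", "sampletype"},
    "group": {"group", "sample_group", "samplegroup"},
}


def read_track_tsv(path: str | Path) -> list[BinnedSignal]:
    """Pre-binned tracks from a TSV with chromosome / start / end / score /
    sample type / group columns (case-insensitive aliases accepted).

    Returns one :class:`BinnedSignal` per sample, rows sorted by start.
    """
    df = pd.read_csv(path, sep="\t")
    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    for canon, aliases in _TSV_ALIASES.items():
        hit = next((lowered[a] for a in aliases if a in lowered), None)
        if hit is None:
            raise SchemaError(
                f"{path}: missing required column {canon!r} "
                f"(accepted aliases: {sorted(aliases)})"
            )
        colmap[canon] = hit
    out: list[BinnedSignal] = []
    for sample, sub in df.groupby(colmap["sample"], sort=True):
        sub = sub.sort_values(colmap["start"])
        chroms = sub[colmap["chrom"]].unique()
        if len(chroms) != 1:
            raise FormatError(
                f"{path}: sample {sample!r} spans multiple chromosomes"
            )
        starts = sub[colmap["start"]].to_numpy(dtype=np.int64)
        ends = sub[colmap["end"]].to_numpy(dtype=np.int64)
        if not (starts[1:] == ends[:-1]).all():
            raise FormatError(
                f"{path}: bins of sample {sample!r} do not tile contiguously"
            )
        groups = sub[colmap["group"]].unique()
        region = GenomicRegion(str(chroms[0]), int(starts[0]), int(ends[-1]))
        out.append(BinnedSignal(
            region=region,
            binsize=int(ends[0] - starts[0]),
            values=sub[colmap["score"]].to_numpy(dtype=float),
            sample=str(sample),
            group=str(groups[0]),
        ))
    return out


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

PART_KINDS = ("exon", "UTR", "intron")


@dataclass
class GenePart:
    region: GenomicRegion
    kind: str  # exon | UTR | intron


@dataclass
class TranscriptModel:
    transcript_id: str
    transcript_name: str
    strand: str
    parts: list[GenePart]

    @property
    def span(self) -> GenomicRegion:
        return GenomicRegion(self.parts[0].region.chrom,
                             min(p.region.start for p in self.parts),
                             max(p.region.end for p in self.parts))


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    strand: str
    group: str | None
    parts: list[GenePart]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> GenomicRegion:
        return GenomicRegion(self.parts[0].region.chrom,
                             min(p.region.start for p in self.parts),
                             max(p.region.end for p in self.parts))


@dataclass
class GeneModelSet:
    genes: list[GeneModel]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id or g.gene_name == gene_id:
                return g
        raise NotFoundError(f"no gene with id or name {gene_id!r}")


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract_intervals(base: list[tuple[int, int]],
                        cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """base minus cut, both merged; result sorted non-overlapping."""
    out: list[tuple[int, int]] = []
    cut = _merge_intervals(cut)
    for s, e in _merge_intervals(base):
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def _build_parts(chrom: str, exons: list[tuple[int, int]],
                 cds: list[tuple[int, int]],
                 utrs: list[tuple[int, int]]) -> list[GenePart]:
    """Assemble exon/UTR/intron parts from feature intervals (0-based)."""
    exons_m = _merge_intervals(exons)
    if not exons_m:
        return []
    if utrs:
        utr_iv = _merge_intervals(utrs)
    elif cds:
        utr_iv = _subtract_intervals(exons_m, cds)
    else:
        utr_iv = []
    exon_iv = _subtract_intervals(exons_m, utr_iv)
    span = (exons_m[0][0], exons_m[-1][1])
    intron_iv = _subtract_intervals([span], exons_m)
    parts = (
        [GenePart(GenomicRegion(chrom, s, e), "exon") for s, e in exon_iv]
        + [GenePart(GenomicRegion(chrom, s, e), "UTR") for s, e in utr_iv]
        + [GenePart(GenomicRegion(chrom, s, e), "intron") for s, e in intron_iv]
    )
    parts.sort(key=lambda p: (p.region.start, p.region.end))
    return parts


_UTR_TYPES = {"utr", "five_prime_utr", "three_prime_utr", "5utr", "3utr"}


def read_gene_models_gtf(path: str | Path, region: GenomicRegion,
                         group_attr: str | None = None) -> GeneModelSet:
    """Gene models overlapping `region` from a GTF file.

    A gene partially overlapping the region is included whole (clipping
    happens at draw time). Introns are inferred as gaps between a gene's
    merged exons; UTR parts come from UTR features when present, otherwise
    they are derived as exon minus CDS.
    """
    # raw per-gene / per-transcript feature interval pools
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            ftype = feat.featuretype.lower()
            if feat.seqid != region.chrom:
                continue
            if ftype not in ("exon", "cds") and ftype not in _UTR_TYPES:
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
            except KeyError:
                raise FormatError(
                    f"{path}:{lineno}: feature lacks gene_id attribute"
                ) from None
            tx_id = (feat.attributes["transcript_id"][0]
                     if "transcript_id" in feat.attributes else gene_id)
            iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
            g = genes.setdefault(gene_id, {
                "name": gene_id, "strand": feat.strand, "group": None,
                "exons": [], "cds": [], "utrs": [], "tx": {},
            })
            if "gene_name" in feat.attributes:
                g["name"] = feat.attributes["gene_name"][0]
            if group_attr and group_attr in feat.attributes:
                g["group"] = feat.attributes[group_attr][0]
            t = g["tx"].setdefault(tx_id, {
                "name": tx_id, "exons": [], "cds": [], "utrs": []})
            if "transcript_name" in feat.attributes:
                t["name"] = feat.attributes["transcript_name"][0]
            key = ("exons" if ftype == "exon"
                   else "cds" if ftype == "cds" else "utrs")
            g[key].append(iv)
            t[key].append(iv)

    out: list[GeneModel] = []
    for gene_id, g in genes.items():
        if not g["exons"]:
            continue
        span = (min(s for s, _ in g["exons"]), max(e for _, e in g["exons"]))
        if span[1] <= region.start or span[0] >= region.end:
            continue
        if g["strand"] not in ("+", "-"):
            g["strand"] = "+"
        transcripts = []
        for tx_id, t in sorted(g["tx"].items()):
            tparts = _build_parts(region.chrom, t["exons"], t["cds"], t["utrs"])
            if tparts:
                transcripts.append(TranscriptModel(
                    transcript_id=tx_id, transcript_name=t["name"],
                    strand=g["strand"], parts=tparts))
        out.append(GeneModel(
            gene_id=gene_id, gene_name=g["name"], strand=g["strand"],
            group=g["group"],
            parts=_build_parts(region.chrom, g["exons"], g["cds"], g["utrs"]),
            transcripts=transcripts,
        ))
    out.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
    return GeneModelSet(genes=out)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass
class Peak:
    region: GenomicRegion
    name: str = "."
    score: float = 0.0
    p_value: float | None = None
    summit: int | None = None  # offset from region.start

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise FormatError(
                f"peak p-value must be in (0, 1], got {self.p_value}"
            )


@dataclass
class PeakSet:
    peaks: list[Peak]
    source: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def read_peaks(path: str | Path) -> PeakSet:
    """BED3+ or ENCODE narrowPeak. narrowPeak column 8 holds -log10(p);
    the ENCODE missing-value sentinel -1 yields an absent p-value."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if (not line or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}: peak line with <3 columns")
            region = GenomicRegion(f[0], int(f[1]), int(f[2]))
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            p_value = None
            summit = None
            if len(f) >= 10:  # narrowPeak
                neglog_p = float(f[7])
                if neglog_p >= 0:
                    p_value = min(1.0, 10.0 ** (-neglog_p))
                summit_val = int(f[9])
                if summit_val >= 0:
                    summit = summit_val
            peaks.append(Peak(region=region, name=name, score=score,
                              p_value=p_value, summit=summit))
    peaks.sort(key=lambda p: (p.region.chrom, p.region.start, p.region.end))
    return PeakSet(peaks=peaks, source=str(path))


# ---------------------------------------------------------------------------
# Cytobands, contact matrices, peptides
# ---------------------------------------------------------------------------


@dataclass
class CytobandSet:
    """UCSC cytoband table; 'acen' stain marks centromere bands."""

    bands: pd.DataFrame  # columns chrom, start, end, name, stain

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "name", "stain"]
        if list(self.bands.columns[:5]) != required:
            self.bands.columns = required + list(self.bands.columns[5:])
        self.bands = self.bands.sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in self.bands.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise FormatError(f"cytobands overlap on {chrom}")

    def chromosomes(self) -> list[str]:
        return list(self.bands["chrom"].unique())

    def chrom_length(self, chrom: str) -> int:
        sub = self.bands[self.bands["chrom"] == chrom]
        if sub.empty:
            raise NotFoundError(f"no cytobands for chromosome {chrom!r}")
        return int(sub["end"].max())

    def bands_for(self, chrom: str) -> pd.DataFrame:
        sub = self.bands[self.bands["chrom"] == chrom]
        if sub.empty:
            raise NotFoundError(f"no cytobands for chromosome {chrom!r}")
        return sub

    def centromere(self, chrom: str) -> GenomicRegion | None:
        sub = self.bands_for(chrom)
        acen = sub[sub["stain"] == "acen"]
        if acen.empty:
            return None
        return GenomicRegion(chrom, int(acen["start"].min()),
                             int(acen["end"].max()))


def read_cytoband(path: str | Path) -> CytobandSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "stain"])
    return CytobandSet(bands=df)


@dataclass
class ContactMatrix:
    """Dense symmetric chromatin contact matrix over a region's bin grid."""

    region: GenomicRegion
    binsize: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = -(-len(self.region) // self.binsize)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise FormatError(
                f"contact matrix must be square, got {self.matrix.shape}"
            )
        if self.matrix.shape[0] != n:
            raise FormatError(
                f"{len(self.region)} bp region at binsize {self.binsize} "
                f"needs a {n}x{n} matrix, got {self.matrix.shape[0]}x"
                f"{self.matrix.shape[1]}"
            )
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-6 * scale:
            warnings.warn("contact matrix is asymmetric; symmetrizing as "
                          "(M + M.T)/2", stacklevel=2)
        self.matrix = (self.matrix + self.matrix.T) / 2.0


def read_contact_matrix(path: str | Path, region: GenomicRegion,
                        binsize: int) -> ContactMatrix:
    matrix = np.loadtxt(path, ndmin=2)
    return ContactMatrix(region=region, binsize=binsize, matrix=matrix)


@dataclass
class PeptideRecord:
    sequence: str
    abundance: float | None = None
    count: int | None = None


@dataclass
class PeptideTable:
    records: list[PeptideRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


_PEPTIDE_ABUNDANCE_ALIASES = {"abundance", "intensity", "area"}
_PEPTIDE_COUNT_ALIASES = {"count", "psms", "# psms", "spectral_count"}


def read_peptides(path: str | Path,
                  sequence_column: str = "Sequence") -> PeptideTable:
    """Peptide table from an analyzer spreadsheet (XLSX) or TSV.

    Only a peptide-sequence column is required; abundance/count columns are
    picked up opportunistically and everything else is ignored, since
    analyzer export layouts vary widely.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    lowered = {c.lower(): c for c in df.columns}
    seq_col = lowered.get(sequence_column.lower())
    if seq_col is None:
        raise SchemaError(
            f"{path}: no peptide sequence column {sequence_column!r} "
            f"(columns: {list(df.columns)})"
        )
    ab_col = next((lowered[a] for a in _PEPTIDE_ABUNDANCE_ALIASES
                   if a in lowered), None)
    ct_col = next((lowered[a] for a in _PEPTIDE_COUNT_ALIASES
                   if a in lowered), None)
    records = []
    for _, row in df.iterrows():
        seq = str(row[seq_col]).strip().upper()
        if not seq or seq == "NAN":
            continue
        records.append(PeptideRecord(
            sequence=seq,
            abundance=float(row[ab_col]) if ab_col is not None
            and pd.notna(row[ab_col]) else None,
            count=int(row[ct_col]) if ct_col is not None
            and pd.notna(row[ct_col]) else None,
        ))
    return PeptideTable(records=records)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_bedgraph(binned: BinnedSignal, path: str | Path) -> None:
    """Write a binned track as BedGraph; float formatting uses Python's
    shortest round-trip repr, so read(write(x)) reproduces the values
    exactly."""
    with open(path, "w") as fh:
        for start, end, value in zip(binned.bin_starts, binned.bin_ends,
                                     binned.values):
            fh.write(f"{binned.region.chrom}\t{start}\t{end}\t"
                     f"{float(value)!r}\n")


def write_bigwig(binned: BinnedSignal, chrom_sizes: dict[str, int],
                 path: str | Path) -> None:
    chrom = binned.region.chrom
    if chrom not in chrom_sizes:
        raise ChromosomeNotFoundError(
            f"chromosome {chrom!r} missing from chrom sizes"
        )
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(sorted(chrom_sizes.items()))
        bw.addEntries([chrom] * len(binned),
                      [int(s) for s in binned.bin_starts],
                      ends=[int(e) for e in binned.bin_ends],
                      values=[float(v) for v in binned.values])
    finally:
        bw.close()
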