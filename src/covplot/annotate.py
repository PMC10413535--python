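"""Computational annotations for coverage figures.

This module turns raw substrates (sequence, pileups, gene models, peptide
tables) into the derived quantities the annotation panels draw: per-bin GC
content, per-position base frequencies and variant calls, amino-acid
reading frames, packed gene/transcript glyph rows, per-residue protein
coverage, and display-ready CNV tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import NotFoundError, ParameterError, SequenceError
from .io import (BASES, GeneModel, GeneModelSet, GenePart, LocusBaseCounts,
                 PeptideTable, TranscriptModel)
from .regions import BinnedSignal, GenomicRegion

__all__ = [
    "SnvCall",
    "GlyphPart",
    "GlyphRow",
    "ProteinCoverage",
    "CnvTrack",
    "TranslatedFrame",
    "gc_content_bins",
    "base_frequencies",
    "call_snvs",
    "translate_frames",
    "assign_rows",
    "build_gene_glyphs",
    "build_transcript_glyphs",
    "protein_coverage",
    "build_cnv_track",
    "reverse_complement",
]

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")

# relative draw heights within a glyph lane: exon > UTR > intron
PART_HEIGHTS = {"exon": 1.0, "UTR": 0.6, "intron": 0.15}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def gc_content_bins(sequence: str, binsize: int
                    ) -> tuple[np.ndarray, float]:
    """Per-bin GC fraction plus the region-wide mean GC.

    GC = (#G + #C) / (#A + #C + #G + #T); N and ambiguity codes are
    excluded from both numerator and denominator. A bin with no A/C/G/T
    at all yields NaN and is excluded from the mean.
    """
    if binsize < 1:
        raise ParameterError(f"binsize must be >= 1, got {binsize}")
    seq = sequence.upper()
    bad = set(seq) - _IUPAC_DNA
    if bad:
        raise SequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    fractions = []
    for i in range(0, len(seq), binsize):
        gc = int(is_gc[i:i + binsize].sum())
        acgt = int(is_acgt[i:i + binsize].sum())
        fractions.append(gc / acgt if acgt else np.nan)
    total_acgt = int(is_acgt.sum())
    mean = float(is_gc.sum() / total_acgt) if total_acgt else float("nan")
    return np.array(fractions, dtype=float), mean


def base_frequencies(counts: LocusBaseCounts) -> np.ndarray:
    """Per-position fraction of each base (columns A C G T N).

    Zero-depth positions yield all-zero fractions rather than NaN.
    """
    depth = counts.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts.counts / depth[:, None]
    freq[depth == 0] = 0.0
    return freq


@dataclass
class SnvCall:
    """A single-nucleotide variant candidate from pileup frequencies."""

    position: int  # 0-based genomic position
    ref: str
    alt: str
    alt_freq: float
    depth: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ParameterError("alt base must differ from ref")
        if not (0.0 <= self.alt_freq <= 1.0):
            raise ParameterError(f"alt_freq out of [0,1]: {self.alt_freq}")


def call_snvs(counts: LocusBaseCounts, min_alt_freq: float = 0.2,
              min_depth: int = 10) -> list[SnvCall]:
    """Frequency-rule variant candidates.

    A position is reported iff its depth reaches `min_depth` and the most
    frequent non-reference base (among A/C/G/T) reaches `min_alt_freq` of
    the total depth. This is a display-oriented rule, not a genotyper.
    """
    if not (0 < min_alt_freq <= 1):
        raise ParameterError("min_alt_freq must be in (0, 1]")
    calls: list[SnvCall] = []
    acgt = counts.counts[:, :4]
    depth = counts.depth
    for i in range(len(counts.region)):
        if depth[i] < min_depth:
            continue
        ref = counts.ref_bases[i]
        best_base, best_count = None, -1
        for j, base in enumerate(BASES[:4]):
            if base == ref:
                continue
            if acgt[i, j] > best_count:
                best_base, best_count = base, int(acgt[i, j])
        if best_base is None or best_count <= 0:
            continue
        freq = best_count / int(depth[i])
        if freq >= min_alt_freq:
            calls.append(SnvCall(
                position=counts.region.start + i, ref=ref, alt=best_base,
                alt_freq=freq, depth=int(depth[i])))
    return calls


@dataclass
class TranslatedFrame:
    """Amino acids of one forward reading frame with genomic spans."""

    offset: int  # 0, 1 or 2
    residues: str
    spans: list[tuple[int, int]]  # 0-based genomic [start, end) per residue


def translate_frames(sequence: str, region_start: int = 0,
                     offsets: Sequence[int] = (0, 1, 2)
                     ) -> list[TranslatedFrame]:
    """Translate forward reading frames with the standard genetic code.

    Codons containing N translate to 'X'; trailing 1-2 nt are dropped.
    Each residue carries its 3-bp genomic span (offset from `region_start`)
    for drawing under the coverage axis.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise SequenceError("frame translation expects an A/C/G/T/N sequence")
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    frames: list[TranslatedFrame] = []
    for offset in offsets:
        if offset not in (0, 1, 2):
            raise ParameterError(f"frame offset must be 0, 1 or 2: {offset}")
        residues = []
        spans = []
        for i in range(offset, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                aa = "X"
            elif codon in stops:
                aa = "*"
            else:
                aa = table[codon]
            residues.append(aa)
            spans.append((region_start + i, region_start + i + 3))
        frames.append(TranslatedFrame(offset=offset,
                                      residues="".join(residues),
                                      spans=spans))
    return frames


def assign_rows(extents: Sequence[tuple[float, float]],
                min_gap: float = 0.0) -> list[int]:
    """Greedy first-fit interval packing for glyph lanes.

    Extents are processed in order of start (ties: longer first); each goes
    to the lowest row where it stays >= `min_gap` away from everything
    already in that row. For interval graphs this greedy order uses exactly
    as many rows as the maximum overlap depth.
    """
    order = sorted(range(len(extents)),
                   key=lambda i: (extents[i][0], -extents[i][1]))
    rows: list[list[tuple[float, float]]] = []
    assignment = [0] * len(extents)
    for idx in order:
        start, end = extents[idx]
        placed = False
        for r, occupied in enumerate(rows):
            if all(start >= e + min_gap or end + min_gap <= s
                   for s, e in occupied):
                occupied.append((start, end))
                assignment[idx] = r
                placed = True
                break
        if not placed:
            rows.append([(start, end)])
            assignment[idx] = len(rows) - 1
    return assignment


@dataclass
class GlyphPart:
    start: int
    end: int
    kind: str  # exon | UTR | intron
    height: float


@dataclass
class GlyphRow:
    """One drawable gene/transcript glyph with its packed row index."""

    feature_id: str
    label: str
    row: int
    strand: str
    color_key: str
    parts: list[GlyphPart]

    @property
    def start(self) -> int:
        return min(p.start for p in self.parts)

    @property
    def end(self) -> int:
        return max(p.end for p in self.parts)


def _clip_parts(parts: Sequence[GenePart],
                region: GenomicRegion) -> list[GlyphPart]:
    out = []
    for part in parts:
        start = max(part.region.start, region.start)
        end = min(part.region.end, region.end)
        if start < end:
            out.append(GlyphPart(start=start, end=end, kind=part.kind,
                                 height=PART_HEIGHTS[part.kind]))
    return out


def _default_min_gap(region: GenomicRegion) -> float:
    # packing operates in display space: keep 1% of the window between
    # neighbours so labels do not collide
    return 0.01 * len(region)


def build_gene_glyphs(models: GeneModelSet, region: GenomicRegion,
                      min_gap: float | None = None) -> list[GlyphRow]:
    """Drawable glyphs for all genes in the region, packed into rows.

    Arrows point right on '+' and left on '-'; color is keyed by strand
    ("plus"/"minus") unless the gene carries a user group label.
    """
    if min_gap is None:
        min_gap = _default_min_gap(region)
    visible: list[tuple[GeneModel, list[GlyphPart]]] = []
    for gene in models.genes:
        clipped = _clip_parts(gene.parts, region)
        if clipped:
            visible.append((gene, clipped))
    extents = [(min(p.start for p in parts), max(p.end for p in parts))
               for _, parts in visible]
    rows = assign_rows(extents, min_gap=min_gap)
    glyphs = []
    for (gene, parts), row in zip(visible, rows):
        color_key = gene.group if gene.group is not None else (
            "plus" if gene.strand == "+" else "minus")
        glyphs.append(GlyphRow(feature_id=gene.gene_id, label=gene.gene_name,
                               row=row, strand=gene.strand,
                               color_key=color_key, parts=parts))
    return glyphs


def build_transcript_glyphs(models: GeneModelSet, gene_id: str,
                            region: GenomicRegion,
                            min_gap: float | None = None) -> list[GlyphRow]:
    """One glyph per transcript of a gene, each packed via assign_rows."""
    gene = models.gene(gene_id)  # raises NotFoundError for unknown ids
    if min_gap is None:
        min_gap = _default_min_gap(region)
    visible: list[tuple[TranscriptModel, list[GlyphPart]]] = []
    for tx in gene.transcripts:
        clipped = _clip_parts(tx.parts, region)
        if clipped:
            visible.append((tx, clipped))
    extents = [(min(p.start for p in parts), max(p.end for p in parts))
               for _, parts in visible]
    rows = assign_rows(extents, min_gap=min_gap)
    color_key = gene.group if gene.group is not None else (
        "plus" if gene.strand == "+" else "minus")
    return [GlyphRow(feature_id=tx.transcript_id, label=tx.transcript_name,
                     row=row, strand=tx.strand, color_key=color_key,
                     parts=parts)
            for (tx, parts), row in zip(visible, rows)]


_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinCoverage:
    """Per-residue peptide coverage of one protein."""

    protein_id: str
    length: int
    depth: np.ndarray
    matches: list[tuple[str, int, int]]  # (peptide, start residue, end)
    skipped: list[str] = field(default_factory=list)

    @property
    def covered_fraction(self) -> float:
        return float((self.depth > 0).sum() / self.length)


def protein_coverage(protein_sequence: str, peptides: PeptideTable,
                     protein_id: str = "protein") -> ProteinCoverage:
    """Map peptides onto a protein by exact substring occurrence.

    Every occurrence of every peptide adds +1 depth over its residues (a
    peptide found at several positions contributes at each). Leucine and
    isoleucine are NOT equated. Peptides with characters outside the
    20-letter alphabet are skipped and recorded with a warning.
    """
    protein = protein_sequence.strip().upper()
    if not protein:
        raise SequenceError("protein sequence must be non-empty")
    depth = np.zeros(len(protein), dtype=np.int64)
    matches: list[tuple[str, int, int]] = []
    skipped: list[str] = []
    for record in peptides:
        pep = record.sequence
        if not pep or set(pep) - _AA20:
            skipped.append(pep)
            warnings.warn(f"skipping peptide with illegal characters: {pep!r}",
                          stacklevel=2)
            continue
        pos = protein.find(pep)
        while pos != -1:
            depth[pos:pos + len(pep)] += 1
            matches.append((pep, pos, pos + len(pep)))
            pos = protein.find(pep, pos + 1)
    return ProteinCoverage(protein_id=protein_id, length=len(protein),
                           depth=depth, matches=matches, skipped=skipped)


@dataclass
class CnvSegment:
    region: GenomicRegion
    copy_number: float


@dataclass
class CnvTrack:
    """Display-ready copy-number panel: bin dots, segment step line, ploidy
    reference line. Copy-number estimates are inputs, never computed here."""

    bins: BinnedSignal
    segments: list[CnvSegment]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ParameterError("ploidy must be >= 1")
        segs = sorted(self.segments, key=lambda s: s.region.start)
        for a, b in zip(segs, segs[1:]):
            if a.region.end > b.region.start:
                raise ParameterError(
                    f"CNV segments overlap: {a.region} and {b.region}"
                )
        for seg in segs:
            if not self.bins.region.contains(seg.region):
                raise ParameterError(
                    f"segment {seg.region} outside track region "
                    f"{self.bins.region}"
                )
        self.segments = segs


def build_cnv_track(bins: BinnedSignal,
                    segments: Sequence[tuple[GenomicRegion, float]],
                    ploidy: int = 2) -> CnvTrack:
    """Assemble a CNV display track from normalized bins and externally
    estimated copy-number segments."""
    return CnvTrack(bins=bins,
                    segments=[CnvSegment(region=r, copy_number=cn)
                              for r, cn in segments],
                    ploidy=ploidy)
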