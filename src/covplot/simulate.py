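"""Synthetic data generation for every pipeline stage.

The generators emulate the data types a coverage figure consumes — a
reference with controllable GC, aligned single-end reads (uniform,
enriched, or exon-restricted/spliced profiles, optionally carrying a
planted SNV at a target allele frequency), gene models on both strands,
replicate peak sets with planned shared/noise structure, peptide tables
with decoys — so that the full plotting gallery and all preprocessing is
testable without any downloads.

Every generator draws from its own seeded random stream (derived from the
spec seed plus a per-generator tag), so changing one plan leaves the other
outputs unchanged, and outputs are byte-reproducible under a fixed seed.
The ground-truth plan is emitted alongside each dataset in a manifest;
downstream assertions should read truth from there, never re-derive it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .regions import GenomicRegion

__all__ = [
    "PlantedSnv",
    "PeakPlan",
    "PeptidePlan",
    "SimSpec",
    "simulate_reference",
    "simulate_alignments",
    "simulate_gene_models",
    "simulate_replicate_peaks",
    "simulate_peptides",
    "simulate_cytobands",
    "simulate_contact_matrix",
    "make_demo_bundle",
    "DEMO_GENES",
]

_STREAMS = {"reference": 1, "reads": 2, "peaks": 3, "peptides": 4,
            "contacts": 5}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class PlantedSnv:
    """A variant planted into the reads at a target allele frequency."""

    position: int  # 0-based
    ref: str = "T"
    alt: str = "A"
    vaf: float = 1.0


@dataclass
class PeakPlan:
    """Replicate peak-set plan: shared (true) peaks plus per-replicate
    noise peaks placed in disjoint zones so they can never gain support."""

    n_replicates: int = 3
    n_shared: int = 3
    n_noise: int = 2
    shared_p_range: tuple[float, float] = (1e-10, 1e-6)
    noise_p_range: tuple[float, float] = (0.01, 0.5)
    peak_width: int = 500
    jitter: int = 100


@dataclass
class PeptidePlan:
    protein_length: int = 200
    n_peptides: int = 10
    length_range: tuple[int, int] = (8, 15)
    decoy_fraction: float = 0.2


@dataclass
class SimSpec:
    """Study conditions for the synthetic datasets."""

    seed: int = 0
    region: GenomicRegion = field(
        default_factory=lambda: GenomicRegion("chr1", 0, 50_000))
    n_reads: int = 1_000
    read_length: int = 100
    gc_target: float = 0.5
    gc_windows: tuple = ()  # (start, end, gc) overrides over the region
    n_block: tuple[int, int] | None = None  # (start, length) run of N
    snv: PlantedSnv | None = None
    peak_plan: PeakPlan = field(default_factory=PeakPlan)
    peptide_plan: PeptidePlan = field(default_factory=PeptidePlan)


def simulate_reference(spec: SimSpec, path: str | Path) -> Path:
    """Random reference FASTA (+ .fai) with per-window GC control."""
    rng = _rng(spec.seed, "reference")
    n = len(spec.region)
    gc = np.full(n, spec.gc_target)
    for start, end, target in spec.gc_windows:
        gc[start - spec.region.start:end - spec.region.start] = target
    u = rng.random(n)
    pick = rng.random(n)
    seq = np.where(u < gc,
                   np.where(pick < 0.5, "G", "C"),
                   np.where(pick < 0.5, "A", "T"))
    if spec.n_block is not None:
        s, length = spec.n_block
        seq[s - spec.region.start:s - spec.region.start + length] = "N"
    if spec.snv is not None:
        seq[spec.snv.position - spec.region.start] = spec.snv.ref
    sequence = "".join(seq)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{spec.region.chrom}\n")
        for i in range(0, n, 60):
            fh.write(sequence[i:i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def _position_weights(spec: SimSpec, enrichment_regions) -> np.ndarray:
    max_start = len(spec.region) - spec.read_length
    w = np.ones(max_start + 1)
    for reg, factor in enrichment_regions or ():
        lo = max(reg.start - spec.region.start - spec.read_length + 1, 0)
        hi = min(reg.end - spec.region.start, max_start + 1)
        if lo < hi:
            w[lo:hi] *= factor
    return w / w.sum()


def _exon_blocks(read_start_tx: int, read_length: int,
                 exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Map a transcript-space read onto genomic exon blocks (for spliced
    N-CIGAR reads)."""
    blocks = []
    remaining = read_length
    offset = read_start_tx
    for s, e in exons:
        length = e - s
        if offset >= length:
            offset -= length
            continue
        take = min(remaining, length - offset)
        blocks.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return blocks


def simulate_alignments(spec: SimSpec, reference_fasta: str | Path,
                        path: str | Path, profile: str = "uniform",
                        enrichment_regions=None,
                        exons: list[tuple[int, int]] | None = None,
                        n_reads: int | None = None,
                        sample_tag: str = "") -> Path:
    """Sorted, indexed BAM of perfect-match single-end reads.

    Profiles: ``uniform`` places read starts uniformly; ``enriched``
    multiplies placement weight inside `enrichment_regions`;
    ``exons`` places reads in transcript space over `exons` and emits
    spliced (N CIGAR) alignments, leaving introns at zero depth. Reads
    overlapping a planted SNV carry the alt base with probability = VAF.
    """
    rng = _rng(spec.seed, "reads")
    if sample_tag:  # independent, process-stable stream per library
        tag = zlib.crc32(sample_tag.encode()) % (2**31)
        rng = np.random.default_rng([spec.seed, _STREAMS["reads"], tag])
    n_reads = n_reads if n_reads is not None else spec.n_reads
    path = Path(path)
    ref = pysam.FastaFile(str(reference_fasta))
    chrom = spec.region.chrom
    ref_seq = ref.fetch(chrom).upper()
    ref.close()

    if profile == "exons":
        if not exons:
            raise ValueError("exon profile requires an exon list")
        tx_len = sum(e - s for s, e in exons)
        starts = rng.integers(0, tx_len - spec.read_length + 1, size=n_reads)
    elif profile in ("uniform", "enriched"):
        weights = _position_weights(
            spec, enrichment_regions if profile == "enriched" else None)
        starts = rng.choice(len(weights), size=n_reads, p=weights) \
            + spec.region.start
    else:
        raise ValueError(f"unknown profile {profile!r}")
    starts = np.sort(starts)
    snv_draws = rng.random(n_reads)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": spec.region.end}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        records = []
        for i, start in enumerate(starts):
            if profile == "exons":
                blocks = _exon_blocks(int(start), spec.read_length, exons)
            else:
                blocks = [(int(start), int(start) + spec.read_length)]
            seq = "".join(ref_seq[s:e] for s, e in blocks)
            if spec.snv is not None and snv_draws[i] < spec.snv.vaf:
                qoff = 0
                for s, e in blocks:
                    if s <= spec.snv.position < e:
                        j = qoff + (spec.snv.position - s)
                        seq = seq[:j] + spec.snv.alt + seq[j + 1:]
                        break
                    qoff += e - s
            a = pysam.AlignedSegment()
            a.query_name = f"read{sample_tag}_{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = blocks[0][0]
            a.mapping_quality = 60
            cigar = []
            for k, (s, e) in enumerate(blocks):
                if k > 0:
                    cigar.append((3, s - blocks[k - 1][1]))  # N skip
                cigar.append((0, e - s))  # M
            a.cigar = cigar
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(seq))
            records.append(a)
        records.sort(key=lambda r: r.reference_start)
        for a in records:
            out.write(a)
    pysam.index(str(path))
    return path


# Fixed demo gene plan: strands, multi-exon transcripts, CDS-bearing and
# non-coding genes; positions in 0-based half-open coordinates on chr1.
DEMO_GENES = [
    {"gene_id": "gene1", "gene_name": "GENE1", "strand": "+",
     "biotype": "protein_coding",
     "transcripts": {
         "gene1.t1": {"exons": [(5000, 6000), (8000, 9000), (12000, 15000)],
                      "cds": [(5500, 6000), (8000, 9000), (12000, 13500)]},
         "gene1.t2": {"exons": [(5000, 6000), (12000, 15000)],
                      "cds": [(5500, 6000), (12000, 13000)]},
     }},
    {"gene_id": "gene2", "gene_name": "GENE2", "strand": "-",
     "biotype": "protein_coding",
     "transcripts": {
         "gene2.t1": {"exons": [(16000, 17500), (20000, 21000),
                                (23000, 24000)],
                      "cds": [(16500, 17500), (20000, 21000),
                              (23000, 23500)]},
     }},
    {"gene_id": "gene3", "gene_name": "GENE3", "strand": "+",
     "biotype": "lncRNA",
     "transcripts": {
         "gene3.t1": {"exons": [(30000, 32000), (35000, 40000)], "cds": []},
         "gene3.t2": {"exons": [(30000, 32000), (37000, 40000)], "cds": []},
     }},
]


def simulate_gene_models(spec: SimSpec, path: str | Path,
                         genes=None) -> Path:
    """Write the demo gene plan (or a custom one) as a GTF file."""
    genes = genes if genes is not None else DEMO_GENES
    chrom = spec.region.chrom
    lines = []
    for gene in genes:
        tx_items = sorted(gene["transcripts"].items())
        g_start = min(s for _, t in tx_items for s, _e in t["exons"])
        g_end = max(e for _, t in tx_items for _s, e in t["exons"])
        attrs = (f'gene_id "{gene["gene_id"]}"; '
                 f'gene_name "{gene["gene_name"]}"; '
                 f'gene_biotype "{gene["biotype"]}";')
        lines.append(f"{chrom}\tsim\tgene\t{g_start + 1}\t{g_end}\t.\t"
                     f"{gene['strand']}\t.\t{attrs}")
        for tx_id, tx in tx_items:
            t_start = min(s for s, _ in tx["exons"])
            t_end = max(e for _, e in tx["exons"])
            tattrs = attrs + f' transcript_id "{tx_id}";'
            lines.append(f"{chrom}\tsim\ttranscript\t{t_start + 1}\t{t_end}"
                         f"\t.\t{gene['strand']}\t.\t{tattrs}")
            for s, e in tx["exons"]:
                lines.append(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                             f"{gene['strand']}\t.\t{tattrs}")
            for s, e in tx["cds"]:
                lines.append(f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{gene['strand']}\t0\t{tattrs}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _loguniform(rng, low: float, high: float, size=None):
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def simulate_replicate_peaks(spec: SimSpec, outdir: str | Path
                             ) -> tuple[list[Path], list[GenomicRegion]]:
    """narrowPeak files for each replicate plus the planned true peaks.

    Shared peaks appear (with small positional jitter) in every replicate
    with p-values from the shared range; noise peaks are unique to one
    replicate, placed in disjoint zones so no two noise peaks can ever
    overlap across replicates.
    """
    plan = spec.peak_plan
    rng = _rng(spec.seed, "peaks")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = spec.region
    usable = len(region)
    shared_centers = [region.start + usable * (k + 1) // (plan.n_shared + 2)
                      for k in range(plan.n_shared)]
    truth = [GenomicRegion(region.chrom, c - plan.peak_width // 2,
                           c + plan.peak_width // 2)
             for c in shared_centers]
    # disjoint noise zones in the last third of the region
    noise_zone_start = region.start + (2 * usable) // 3
    n_zones = plan.n_replicates * plan.n_noise
    zone_w = (region.end - noise_zone_start) // max(n_zones, 1)
    paths = []
    for r in range(plan.n_replicates):
        rows = []
        for k, center in enumerate(shared_centers):
            jitter = int(rng.integers(-plan.jitter, plan.jitter + 1))
            start = center - plan.peak_width // 2 + jitter
            end = start + plan.peak_width
            p = float(_loguniform(rng, *plan.shared_p_range))
            rows.append((start, end, f"rep{r + 1}_shared{k + 1}", p))
        for k in range(plan.n_noise):
            zone = r * plan.n_noise + k
            z0 = noise_zone_start + zone * zone_w
            width = min(plan.peak_width, zone_w - 2)
            start = int(rng.integers(z0, z0 + zone_w - width))
            p = float(rng.uniform(*plan.noise_p_range))
            rows.append((start, start + width, f"rep{r + 1}_noise{k + 1}", p))
        rows.sort()
        path = outdir / f"rep{r + 1}.narrowPeak"
        with open(path, "w") as fh:
            for start, end, name, p in rows:
                neglog = -np.log10(p)
                fh.write(f"{region.chrom}\t{start}\t{end}\t{name}\t"
                         f"{min(1000, int(10 * neglog))}\t.\t"
                         f"{neglog:.4f}\t{neglog:.4f}\t-1\t"
                         f"{(end - start) // 2}\n")
        paths.append(path)
    return paths, truth


def simulate_peptides(spec: SimSpec, outdir: str | Path,
                      formats: tuple[str, ...] = ("tsv", "xlsx")
                      ) -> dict:
    """Protein FASTA plus a peptide table with exact-substring peptides and
    a planned fraction of decoys (never matching the protein)."""
    plan = spec.peptide_plan
    rng = _rng(spec.seed, "peptides")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein = "".join(rng.choice(list(_AA20), size=plan.protein_length))
    n_decoys = int(round(plan.decoy_fraction * plan.n_peptides))
    n_true = plan.n_peptides - n_decoys
    records = []
    for i in range(n_true):
        length = int(rng.integers(plan.length_range[0],
                                  plan.length_range[1] + 1))
        start = int(rng.integers(0, plan.protein_length - length + 1))
        records.append(("true", protein[start:start + length]))
    for i in range(n_decoys):
        while True:
            length = int(rng.integers(plan.length_range[0],
                                      plan.length_range[1] + 1))
            pep = "".join(rng.choice(list(_AA20), size=length))
            if pep not in protein:
                break
        records.append(("decoy", pep))
    abundances = _loguniform(rng, 1e4, 1e8, size=len(records))
    df = pd.DataFrame({
        "Sequence": [pep for _, pep in records],
        "Abundance": abundances.round(1),
        "PSMs": rng.integers(1, 20, size=len(records)),
    })
    fasta_path = outdir / "protein.fa"
    fasta_path.write_text(">demo_protein\n" + protein + "\n")
    out = {"protein_fasta": fasta_path, "protein": protein,
           "peptides": [pep for kind, pep in records if kind == "true"],
           "decoys": [pep for kind, pep in records if kind == "decoy"]}
    if "tsv" in formats:
        tsv = outdir / "peptides.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        out["tsv"] = tsv
    if "xlsx" in formats:
        xlsx = outdir / "peptides.xlsx"
        df.to_excel(xlsx, index=False)
        out["xlsx"] = xlsx
    return out


def simulate_cytobands(spec: SimSpec, path: str | Path) -> Path:
    """A plausible cytoband table for the simulated chromosome: stained
    arms around a central 'acen' centromere pair."""
    chrom = spec.region.chrom
    n = spec.region.end
    bands = [
        (0, int(n * 0.2), "p13", "gneg"),
        (int(n * 0.2), int(n * 0.35), "p12", "gpos50"),
        (int(n * 0.35), int(n * 0.45), "p11", "gneg"),
        (int(n * 0.45), int(n * 0.50), "p11.1", "acen"),
        (int(n * 0.50), int(n * 0.55), "q11.1", "acen"),
        (int(n * 0.55), int(n * 0.7), "q11", "gpos25"),
        (int(n * 0.7), int(n * 0.85), "q12", "gpos100"),
        (int(n * 0.85), n, "q13", "gneg"),
    ]
    with open(path, "w") as fh:
        for start, end, name, stain in bands:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{stain}\n")
    return Path(path)


def simulate_contact_matrix(spec: SimSpec, path: str | Path,
                            region: GenomicRegion, binsize: int,
                            n_domains: int = 3) -> Path:
    """Symmetric contact matrix with block-diagonal domains and a
    distance-decay background."""
    rng = _rng(spec.seed, "contacts")
    n = -(-len(region) // binsize)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    decay = 100.0 / (1.0 + np.abs(i - j))
    bounds = np.linspace(0, n, n_domains + 1).astype(int)
    domain_bonus = np.zeros((n, n))
    for d in range(n_domains):
        lo, hi = bounds[d], bounds[d + 1]
        domain_bonus[lo:hi, lo:hi] += 60.0
    noise = rng.random((n, n)) * 5.0
    m = decay + domain_bonus + (noise + noise.T) / 2.0
    np.savetxt(path, m, fmt="%.4f", delimiter="\t")
    return Path(path)


def make_demo_bundle(outdir: str | Path, seed: int = 0) -> dict:
    """Generate the full demo dataset plus plot configs and a manifest.

    Emulates the classic multi-omics gallery: a WGS library with a planted
    100%-VAF T>A variant and a copy-gain segment, a ChIP/input pair with
    enrichment at the planned peaks, a spliced RNA library restricted to
    one gene's exons, replicate peak calls, a cytoband table, a contact
    matrix, and a peptide table over a synthetic protein.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = GenomicRegion("chr1", 0, 50_000)
    snv = PlantedSnv(position=25_000, ref="T", alt="A", vaf=1.0)
    spec = SimSpec(seed=seed, region=region, n_reads=1_000, read_length=100,
                   gc_windows=((10_000, 20_000, 0.6),), snv=snv)

    ref = simulate_reference(spec, outdir / "ref.fa")
    gain = GenomicRegion("chr1", 20_000, 35_000)
    wgs = simulate_alignments(
        spec, ref, outdir / "wgs.bam", profile="enriched",
        enrichment_regions=[(gain, 2.0)], n_reads=15_000, sample_tag="wgs")
    peak_regions = [(GenomicRegion("chr1", c - 250, c + 250), 8.0)
                    for c in (10_000, 20_000, 30_000)]
    chip = simulate_alignments(
        spec, ref, outdir / "chip.bam", profile="enriched",
        enrichment_regions=peak_regions, n_reads=4_000, sample_tag="chip")
    ctrl = simulate_alignments(
        spec, ref, outdir / "input.bam", profile="uniform",
        n_reads=4_000, sample_tag="input")
    gene1_exons = DEMO_GENES[0]["transcripts"]["gene1.t1"]["exons"]
    rna = simulate_alignments(
        spec, ref, outdir / "rna.bam", profile="exons",
        exons=gene1_exons, n_reads=2_000, sample_tag="rna")
    gtf = simulate_gene_models(spec, outdir / "genes.gtf")
    peak_paths, true_peaks = simulate_replicate_peaks(spec, outdir / "peaks")
    cytoband = simulate_cytobands(spec, outdir / "cytoband.txt")
    chip_region = GenomicRegion("chr1", 5_000, 35_000)
    contacts = simulate_contact_matrix(spec, outdir / "contacts.tsv",
                                       chip_region, binsize=1_500)
    pept = simulate_peptides(spec, outdir)

    configs = _write_demo_configs(outdir, snv, gain, chip_region)

    manifest = {
        "seed": seed,
        "region": {"chrom": region.chrom, "start": region.start,
                   "end": region.end},
        "files": {
            "reference": ref.name, "wgs_bam": wgs.name,
            "chip_bam": chip.name, "input_bam": ctrl.name,
            "rna_bam": rna.name, "gtf": gtf.name,
            "cytoband": cytoband.name, "contacts": contacts.name,
            "peak_replicates": [str(p.relative_to(outdir))
                                for p in peak_paths],
            "protein_fasta": pept["protein_fasta"].name,
            "peptides_tsv": pept["tsv"].name,
            "peptides_xlsx": pept["xlsx"].name,
            "configs": [c.name for c in configs],
        },
        "truth": {
            "snv": asdict(snv),
            "copy_gain": {"chrom": gain.chrom, "start": gain.start,
                          "end": gain.end, "copy_number": 4.0},
            "ploidy": 2,
            "shared_peaks": [{"chrom": p.chrom, "start": p.start,
                              "end": p.end} for p in true_peaks],
            "n_noise_per_replicate": spec.peak_plan.n_noise,
            "gene1_exons": gene1_exons,
            "protein": pept["protein"],
            "true_peptides": pept["peptides"],
            "decoy_peptides": pept["decoys"],
            "reads": {"wgs": 15_000, "chip": 4_000, "input": 4_000,
                      "rna": 2_000, "read_length": spec.read_length},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_demo_configs(outdir: Path, snv: PlantedSnv, gain: GenomicRegion,
                        chip_region: GenomicRegion) -> list[Path]:
    import yaml

    cn_segments = [["chr1", gain.start, gain.end, 4.0]]
    configs = {
        "wgs_cnv.yaml": {
            "region": "chr1:1-50,000",
            "style": "facet",
            "tracks": [{"path": "wgs.bam", "format": "bam", "sample": "WGS",
                        "group": "tumor", "normalization": "CPM",
                        "binsize": 500}],
            "layers": [
                {"kind": "gc", "fasta": "ref.fa", "binsize": 500},
                {"kind": "cnv", "bam": "wgs.bam", "binsize": 500,
                 "normalization": "CPM", "segments": cn_segments,
                 "ploidy": 2},
                {"kind": "ideogram", "cytoband": "cytoband.txt"},
            ],
            "output": {"path": "wgs_cnv.svg"},
        },
        "wgs_snv.yaml": {
            "region": f"chr1:{snv.position - 99:,}-{snv.position + 100:,}",
            "tracks": [{"path": "wgs.bam", "format": "bam", "sample": "WGS",
                        "group": "tumor"}],
            "layers": [
                {"kind": "base", "bam": "wgs.bam", "fasta": "ref.fa",
                 "frames": [0, 1, 2], "snv_style": "twill"},
            ],
            "output": {"path": "wgs_snv.svg"},
        },
        "chip.yaml": {
            "region": "chr1:5,001-35,000",
            "style": "facet",
            "highlights": ["chr1:9,501-10,500"],
            "tracks": [
                {"path": "chip.bam", "format": "bam", "sample": "ChIP",
                 "group": "ChIP", "normalization": "CPM", "binsize": 100},
                {"path": "input.bam", "format": "bam", "sample": "Input",
                 "group": "Input", "normalization": "CPM", "binsize": 100},
            ],
            "layers": [
                {"kind": "gene", "gtf": "genes.gtf"},
                {"kind": "peak",
                 "paths": ["peaks/rep1.narrowPeak", "peaks/rep2.narrowPeak",
                           "peaks/rep3.narrowPeak"]},
                {"kind": "link",
                 "anchors": [[9_750, 10_250, 5_000, 5_001],
                             [19_750, 20_250, 16_000, 16_001]]},
                {"kind": "tad", "matrix": "contacts.tsv", "binsize": 1_500},
                {"kind": "feature",
                 "features": [[9_500, 10_500, "promoter", "box"]]},
            ],
            "output": {"path": "chip.svg"},
        },
        "rna.yaml": {
            "region": "chr1:4,001-16,000",
            "tracks": [{"path": "rna.bam", "format": "bam", "sample": "RNA",
                        "group": "KD"}],
            "layers": [
                {"kind": "transcript", "gtf": "genes.gtf", "gene": "gene1"},
            ],
            "output": {"path": "rna.svg"},
        },
        "protein.yaml": {
            "protein": {"fasta": "protein.fa", "peptides": "peptides.tsv"},
            "layers": [
                {"kind": "feature",
                 "features": [[20, 80, "domain A", "domain"],
                              [120, 160, "domain B", "domain"]]},
            ],
            "output": {"path": "protein.svg"},
        },
    }
    paths = []
    for name, cfg in configs.items():
        p = outdir / name
        p.write_text(yaml.safe_dump(cfg, sort_keys=False))
        paths.append(p)
    return paths
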