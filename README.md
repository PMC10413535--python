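# covplot

Composable genome and protein coverage visualization for NGS and
proteomics data, with built-in preprocessing.

Inspecting read coverage next to the right annotations is the everyday
sanity check of sequencing analysis: CNV work needs normalized bin counts
alongside GC content and centromere position; variant inspection needs
per-locus base frequencies over the reference and reading frames; ChIP-seq
needs ChIP-vs-input tracks over gene models and called peaks; RNA-seq
needs exon-resolved coverage over transcript structure; mass-spectrometry
proteomics needs per-residue peptide coverage over protein domains.
`covplot` serves all of these with one grammar: a figure starts from a
coverage panel and grows by adding annotation layers with `+`, each layer
becoming one panel of a shared-axis stack.

## What it computes

- **Coverage**: per-base depth from indexed BAM (flag- and MAPQ-filtered,
  splice-aware: `N` CIGAR gaps contribute no depth), or per-base/binned
  signal from BigWig, BedGraph and TSV tracks. Every reader loads only the
  requested region, never the whole file.
- **Per-bin read normalization** with the standard definitions, for bin
  count `r_i`, bin width `w_i`, library size `N`, mean read length `L`
  and effective genome size `G`:
  - CPM: `r_i / (N / 10^6)`
  - RPKM: `r_i / ((w_i/1000) · (N/10^6))`
  - BPM: `r_i / (Σ_j r_j / 10^6)` (sums to 10^6 over the track)
  - RPGC: `d_i / (N·L/G)` on per-base depth `d_i` (1× genome scaling)
- **Consensus peaks** from replicate peak sets: for each peak, the best
  overlapping peak per other replicate is collected, replicate support is
  enforced, and evidence is combined with Fisher's method
  (`X² = −2 Σ ln p ~ χ²(2k)`); surviving overlapping peaks merge into one
  consensus interval. The stringency `gamma` bounds the combined p-value.
- **Annotations**: per-bin GC content with a mean/reference line; pileup
  base frequencies with frequency-rule SNV candidates (min depth, min
  alternate-allele fraction) highlighted in three styles (twill hatch,
  color strip, colored letters); amino acids of the 0/1/2 forward frames;
  gene and transcript glyphs packed by first-fit interval rows (exon >
  UTR > intron heights, strand-colored arrows); chromosome ideograms with
  green centromeres and a red region marker; 45°-rotated contact-map
  triangles; anchor-to-anchor arc links; per-residue protein coverage by
  exact peptide substring matching.

A `fixtures`-style module (`covplot.simulate`) generates all of the input
formats synthetically — references with controllable GC, aligned reads
with a planted SNV at a target allele frequency, spliced RNA-seq reads,
ChIP enrichment, replicate peaks with planned shared/noise structure,
peptide tables with decoys — so the whole gallery runs with zero
downloads.

## Worked example

Generate three replicate peak sets (3 shared peaks with p ∈ [1e−10, 1e−6],
plus 2 weak noise peaks unique to each replicate) and combine them:

```python
from covplot import read_peaks, consensus_peaks, ConsensusParams
from covplot.simulate import SimSpec, simulate_replicate_peaks

spec = SimSpec(seed=0)
paths, truth = simulate_replicate_peaks(spec, "peaks_demo")
sets = [read_peaks(p) for p in paths]
result = consensus_peaks(sets, ConsensusParams(gamma=1e-4, min_support=2))
for peak in result:
    print(f"{peak.region}  combined p = {peak.p_value:.3g}  "
          f"score = {peak.score:.1f}")
```

prints

```
chr1:9,691-10,251  combined p = 1.37e-22  score = 21.9
chr1:19,741-20,329  combined p = 2.25e-21  score = 20.6
chr1:29,684-30,267  combined p = 1.71e-22  score = 21.8
```

— exactly the three planned shared peaks (the merged interval is the span
union across replicates; the score is the combined −log10 p), and none of
the six noise peaks, whose replicate support and combined evidence both
fail. A figure over the same data is a one-liner chain:

```python
from covplot import coverage_plot, read_coverage_bam, save
from covplot.plotting import gc_layer, gene_layer, ideogram_layer

fig = coverage_plot(tracks) + gc + genes + ideogram   # one panel each
save(fig, "figure.svg")                                # deterministic SVG
```

The same figure is available without writing Python:

```sh
covplot demo --outdir demo --seed 0       # synthetic bundle + configs
covplot plot demo/chip.yaml               # render a declarative config
covplot normalize --bam demo/wgs.bam --region chr1:1-50,000 \
    --method BPM --binsize 500 --out wgs.bedgraph
covplot consensus --peaks demo/peaks/rep1.narrowPeak \
    --peaks demo/peaks/rep2.narrowPeak --peaks demo/peaks/rep3.narrowPeak \
    --gamma 1e-4 --min-support 2 --out consensus.bed
```

## Layout

- `src/covplot/regions.py` — coordinate types and region arithmetic
- `src/covplot/io.py` — BAM/BigWig/BedGraph/TSV/GTF/peak/cytoband/
  contact-matrix/peptide readers, BedGraph/BigWig writers
- `src/covplot/preprocess.py` — binning, normalization, consensus peaks
- `src/covplot/annotate.py` — GC, base/SNV, frames, glyph layout, protein
  coverage, CNV track assembly
- `src/covplot/plotting.py` — the layer grammar and matplotlib rendering
- `src/covplot/simulate.py` — synthetic data generators and demo bundle
- `src/covplot/cli.py` — `covplot plot|normalize|consensus|demo`

See `docs/methods.md` for the underlying models, defaults and known
limitations.
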