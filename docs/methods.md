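# Methods

This note documents the models and procedures `covplot` implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic data does and does not emulate.

## Coordinates

Internally every interval is 0-based half-open on a named chromosome (BED
convention), which keeps lengths, slicing and abutment arithmetic
ambiguity-free. Anything user-facing — region strings accepted by
`parse_region` and the CLI, axis tick labels — is 1-based inclusive, the
way genome browsers print positions, with thousands separators accepted on
input. Chromosome names are matched exactly: silently adding or stripping
a `chr` prefix is a classic source of wrong-region figures, so any naming
mismatch must be resolved explicitly by the caller.

## Coverage semantics

Per-base depth from a BAM counts, at each reference position, the reads
whose aligned span covers it, after excluding unmapped, secondary,
supplementary, QC-fail and duplicate records and applying a MAPQ floor
(default 0; the flag set matches the conventional definition used across
coverage tools). Within a read, `M`/`=`/`X` and `D` (deletion) operations
count as covering the reference; `N` skips (spliced introns) do not. The
splice-awareness matters for RNA-seq: exon-restricted coverage with
zero-depth introns is only reproducible if `N` gaps are excluded.
Insertions and clips consume no reference and are ignored.

All readers honor a region-subset contract: loading region *R* must equal
loading any superset and slicing to *R*. For BAM and BigWig this is
delegated to their indexes; BedGraph and TSV are filtered while streamed.
The contract is enforced by tests comparing both paths on random
sub-regions, and it is what makes plotting large files interactive-fast:
nothing outside the displayed window is ever materialized.

## Per-bin normalization

Bins tile the displayed region from its start; the terminal bin may be
short and aggregates only its own positions. For the count-based methods a
read is assigned to the single bin containing its 5′-most reference
position (`reference_start` on the forward strand, `reference_end − 1` on
the reverse) — unambiguous, strand-aware, and trivially checkable by an
independent oracle; no fractional assignment is attempted. Definitions,
with `r_i` the bin count, `w_i` the actual bin width, `N` primary mapped
non-duplicate reads, `L` mean read length, `G` effective genome size:

| method | value | needs |
|---|---|---|
| raw  | `r_i` | — |
| CPM  | `r_i / (N/10⁶)` | `N` |
| RPKM | `r_i / ((w_i/1000)(N/10⁶))` | `N` |
| BPM  | `r_i / (Σ_j r_j/10⁶)` | nothing (track-internal) |
| RPGC | `d_i / (N·L/G)` | `N`, `L`, `G` |

RPGC operates on mean per-base depth `d_i` rather than counts, because it
is defined as scaling to 1× genomic coverage; on uniform data the
genome-wide mean of normalized depth is exactly 1. `N` and `L` come from a
single pass over the library (`compute_library_stats`); mean read length
is averaged over at most 100,000 reads, which bounds the pass on very
large libraries while leaving the estimate exact for the homogeneous read
lengths of typical short-read data. Effective genome sizes for hg19, hg38
and mm10 ship as overridable constants; any other value can be passed
directly. BPM is invariant to global scaling of the counts and sums to
10⁶ by construction; the other methods are linear in the counts. These
properties are asserted in the test suite rather than assumed.

Normalizing several libraries is embarrassingly parallel; the
implementation runs inputs independently in input order and isolates
failures (a corrupt file yields an error record for its path, not an
aborted batch). Concurrency is an internal freedom, not an API promise:
outputs are defined to be identical to serial execution.

## Consensus peaks from replicates

Replicate peak calls are combined by evidence, not by voting alone. For
each peak in each replicate set: (1) from every *other* replicate, the
single best (smallest-p) peak overlapping it by ≥ 1 bp is collected;
(2) support = 1 + number of contributing replicates, and peaks with
support below `min_support` are discarded; (3) the peak's own p-value and
the collected ones are combined with Fisher's method — `X² = −2 Σ ln p`
referred to a chi-square distribution with `2k` degrees of freedom — and
the peak survives iff the combined p ≤ `gamma`; (4) surviving peaks that
overlap across replicates merge into one consensus interval spanning
their union, carrying the group's minimum combined p (ties in merging are
broken by leftmost start, so output is deterministic and sorted
non-overlapping). Peaks lacking p-values (plain BED input) are treated as
the weakest possible evidence, p = 1.

This is deliberately a simplification of the full multi-stage
replicate-combination machinery used by dedicated consensus callers
(weak/stringent peak classes and an FDR stage are out of scope): the
single `gamma` + `min_support` surface captures the combine-evidence core
in a form whose every decision is testable against the closed form. For
even degrees of freedom the chi-square survival function has the exact
form `exp(−x/2) Σ_{j<k} (x/2)^j/j!`, which the tests use as an
independent oracle against the scipy-based implementation; combined
p-values are clamped at 1e−300 so scores (−log10 p) stay finite under
extreme evidence. `fisher_combine` is order-invariant and reduces to the
identity at k = 1. Note that combined evidence is *not* monotone in the
number of inputs (adding a p < 1 can raise the combined p because the
degrees of freedom grow); the tests assert the properties that actually
hold.

## Annotations

**GC content.** Per bin, GC = (#G + #C) / (#A + #C + #G + #T); N and
ambiguity codes are excluded from both numerator and denominator, and a
bin with no unambiguous base yields NaN and is excluded from the mean.
The reference line defaults to the displayed region's mean; a user
constant (e.g. a genome-wide average) can replace it — the constant is
taken at face value, the package does not attempt to interpret it.

**Base frequencies and SNV candidates.** Pileup counts per position over
A/C/G/T/N (per-base quality floor optional) divided by total depth;
zero-depth positions report zero fractions. A position is flagged as an
SNV candidate iff depth ≥ `min_depth` (default 10) and the most frequent
non-reference base reaches `min_alt_freq` (default 0.2) of the depth.
This is a display rule for drawing attention, not a genotyper — no error
model, no strand-bias or quality modeling — and the defaults are exposed
in the layer options. Raising `min_alt_freq` can only remove candidates
(tested). Three highlight styles are provided: `twill` (hatched rectangle
over the locus), `strip` (translucent colored background), `letter`
(reference letter recolored only).

**Reading frames.** Forward-strand frames at offsets 0/1/2, standard
genetic code, codons containing N translate to `X`, trailing 1–2 nt
dropped; each residue carries its 3-bp genomic span for drawing. Reverse
frames are intentionally not drawn by default: six rows of residues
overwhelm the panel, and the forward three match the common browser
presentation.

**Row packing.** Gene/transcript glyphs (and peptide boxes in the protein
panel) are packed by greedy first-fit: extents ordered by start (ties:
longer first) go to the lowest row where they keep ≥ `min_gap` distance
from everything already placed. On interval graphs this order is optimal —
rows used equal the maximum overlap depth — which the tests verify by
brute force. `min_gap` defaults to 1% of the displayed width, because
label collisions happen in display space, not genome space.

**Gene models.** GTF exon/CDS/UTR features are pooled per gene and per
transcript (coordinates converted from 1-based inclusive on read). UTR
parts come from explicit UTR features when present, otherwise exon minus
CDS; remaining exon sequence is drawn at full height, introns are the
gaps between merged exons. A gene overlapping the displayed region at all
is included whole and clipped only at draw time, so partial structures
are never misrepresented as complete ones. Draw heights exon 1.0, UTR
0.6, intron 0.15 of the lane; strand arrows point right for `+` (dark
green) and left for `−` (dark blue); a user group attribute (e.g.
biotype) overrides strand coloring.

**Protein coverage.** Peptides map to the protein by exact substring
occurrence; every occurrence of every peptide adds 1 to the depth of its
residues. Leucine and isoleucine are deliberately not equated (they are
indistinguishable by mass, but conflating them silently would overstate
coverage; callers who want I/L-equivalence can substitute one for the
other before matching). Peptides with characters outside the 20-letter
alphabet are skipped with a warning and reported on the result object.

**CNV track.** Assembly only: normalized bin values as dots, externally
estimated copy-number segments as a step line, ploidy as a reference
line. No segmentation or estimation is performed here — copy-number
inference is a modeling problem of its own and estimates are inputs.

**Contact maps.** Dense symmetric matrices over the displayed region's
bin grid. Cell (i, j ≥ i) is drawn as a diamond at
`x = start + (i+j+1)/2·binsize`, `y = j − i`, i.e. the classic 45°
rotation placing each diagonal cell above its bin midpoint; color is
log1p-scaled by default. Input asymmetric beyond 1e−6 relative tolerance
draws a warning and is symmetrized as `(M + Mᵀ)/2`.

## The layer grammar and rendering

A `FigureSpec` is immutable: `figure + layer` returns a new spec with the
layer appended, so composition is non-mutating, left-associative and
order-preserving, and panel order is addition order (coverage panel
first, by construction). Exactly one coverage-type panel (genomic
coverage or protein) is allowed, and genomic/protein layers cannot mix;
`feature` works in either coordinate space.

Coverage display styles: `facet` (one sub-panel per sample, colored by
group, shared x) and `joint` (overlaid in one panel). Facet y-axes are
free by default; `y_scale="shared"` pins them to a common range — the
third style one sometimes wants for fair cross-sample comparison.
Highlight regions draw as translucent rectangles in every coverage
sub-panel. Default panel height weights (coverage 4; base 1.5 + 0.5 per
frame row; gc 1; cnv 1.5; gene/transcript 0.4 per packed row, min 1;
peak 0.5; ideogram 0.6; tad 3; link 1; feature 0.5; protein 4) give the
coverage panel visual dominance and scale annotation panels with their
content; all are overridable per layer.

The renderer exposes its realized layout — panel kinds, bounding boxes,
x-domains, sub-panel counts — so structural properties (order, shared
axes, facet counts, height ratios) are asserted on the actual figure
rather than on intent. All panels in region space share the region's
x-domain; the ideogram panel is the deliberate exception (it shows the
whole chromosome with the displayed region marked in red and `acen`
centromere bands in green). SVG output is byte-deterministic: the
matplotlib hash salt is pinned and the creation timestamp stripped, which
the CLI-vs-library equivalence test exploits (the declarative YAML path
and programmatic `+` composition produce identical bytes).

Group colors cycle the Okabe–Ito colorblind-safe palette; base colors
follow the IGV convention (A green, C blue, G orange, T red). Post-hoc
hooks (`apply_theme`, `recolor_group`, `set_axis_label`,
`add_reference_line`) return modified copies, never mutate.

## Synthetic data: what it emulates, what it does not

The generators produce a reference with per-window GC control and
optional N runs; perfect-match single-end reads placed uniformly, with
regional enrichment (ChIP/copy-gain), or in transcript space with
spliced `N`-CIGAR alignments; a planted SNV carried by each overlapping
read with probability equal to the target VAF; replicate narrowPeak sets
with shared true peaks (p ∈ [1e−10, 1e−6], jittered positions) and
per-replicate noise peaks (p ∈ [0.01, 0.5]) confined to disjoint zones so
they can never accumulate cross-replicate support; peptide tables that
are exact protein substrings plus a planned 20% of decoys verified absent
from the protein. Default study conditions: a 50 kb chromosome, 1,000 ×
100 bp uniform reads (so 1× scaling against a 50 kb effective genome has
scale exactly 2.0); the demo WGS library uses 15,000 reads (30×
genome-wide), a realistic whole-genome depth that makes the per-locus
variant display meaningful.

Every generator draws from its own stream derived from (seed, generator
tag), so outputs are byte-reproducible and changing one plan leaves the
others untouched. Ground truth is written to a JSON manifest and tests
read truth from the manifest rather than re-deriving it.

What the simulations do *not* model: sequencing errors, indels,
base-quality decay, paired-end fragments, mapping ambiguity, GC-coverage
bias coupling, peak-shape realism, peptide misidentification. Passing
tests therefore demonstrate the correctness of the computations
(pileups, normalization arithmetic, evidence combination, layout,
rendering) under clean inputs — they do not demonstrate robustness to
the noise structure of real libraries, which the display-oriented rules
here (e.g. the SNV frequency rule) make no claim to handle.

## Numerical and degenerate-input choices

- Depth division by zero: zero-depth positions report zero fractions.
- All-N GC bins: NaN, excluded from means and from the drawn line.
- Combined p-values clamp at 1e−300 before −log10 scoring.
- BPM is computed as `r·10⁶ / Σr` (not `r / (Σr/10⁶)`) so the closed-form
  examples hold to the last bit.
- BedGraph writing uses shortest round-trip float repr, so
  read(write(x)) is exact for decimal-representable values.
- Empty interval, negative coordinate, inverted region, overlapping
  BedGraph intervals, non-square contact matrices, overlapping CNV
  segments, unknown themes/genes/chromosomes: all rejected with typed
  errors rather than coerced.

## Known limitations

CRAM, tabix-indexed BedGraph, remote URLs and binary Hi-C containers are
not read; contact maps come from dense TSV. Whole-genome multi-chromosome
layouts and assembly liftover are out of scope. The consensus procedure
is the simplified single-threshold form described above. The CLI's
declarative config covers the layer grammar but not every programmatic
option (post-hoc mutation hooks are library-only). Rendering targets
static PDF/SVG/PNG; there is no interactivity.

## Problem sizes used in the checks

The automated checks run at desk scale by choice: 1,000-read pileups
against the brute-force oracle, 50 random sub-regions per reader for the
subset contract, 20 replicate-set constructions for consensus recovery,
500 random interval sets for layout, 1,000 sequences for translation, 200
protein/peptide sets, and the full demo bundle (26,000 reads across four
libraries) end-to-end. These sizes exercise every code path and keep the
whole suite in seconds; the algorithms themselves are linear in reads or
bins and have no size-dependent branches.
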