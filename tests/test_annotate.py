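import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covplot import annotate
from covplot.annotate import (assign_rows, base_frequencies,
                              build_cnv_track, build_gene_glyphs,
                              build_transcript_glyphs, call_snvs,
                              gc_content_bins, protein_coverage,
                              reverse_complement, translate_frames)
from covplot.errors import (NotFoundError, ParameterError, SequenceError)
from covplot.io import (GeneModel, GeneModelSet, GenePart, LocusBaseCounts,
                        PeptideRecord, PeptideTable, TranscriptModel)
from covplot.regions import BinnedSignal, GenomicRegion, make_region

# independent codon-table oracle (standard genetic code, written out)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(seq, offset):
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


class TestGcContent:
    def test_single_bin(self):
        fr, mean = gc_content_bins("ACGTGC", 6)
        assert fr[0] == pytest.approx(4 / 6)
        assert mean == pytest.approx(4 / 6)

    def test_extremes(self):
        assert gc_content_bins("AAAA", 4)[0][0] == 0.0
        assert gc_content_bins("GGCC", 4)[0][0] == 1.0

    def test_all_n_bin_is_nan_and_excluded_from_mean(self):
        fr, mean = gc_content_bins("NNNNGGCC", 4)
        assert np.isnan(fr[0])
        assert fr[1] == 1.0
        assert mean == 1.0

    def test_non_iupac_rejected(self):
        with pytest.raises(SequenceError):
            gc_content_bins("ACGZ", 2)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=60))
    @settings(max_examples=60)
    def test_strand_invariance(self, seq):
        # GC content of the reverse complement equals GC of the sequence
        _, mean_fwd = gc_content_bins(seq, 10)
        _, mean_rev = gc_content_bins(reverse_complement(seq), 10)
        assert mean_fwd == pytest.approx(mean_rev)


def _counts(rows, refs, start=0):
    region = make_region("chr1", start, start + len(rows))
    return LocusBaseCounts(region=region, counts=np.array(rows),
                           ref_bases=refs)


class TestBaseFrequencies:
    def test_fractions(self):
        counts = _counts([[7, 0, 0, 3, 0]], "T")
        freq = base_frequencies(counts)
        assert freq[0, 0] == pytest.approx(0.7)
        assert freq[0, 3] == pytest.approx(0.3)

    def test_zero_depth_no_division_error(self):
        freq = base_frequencies(_counts([[0, 0, 0, 0, 0]], "A"))
        assert not freq.any()


class TestCallSnvs:
    def test_full_vaf_transversion(self):
        # the 100%-VAF T>A scenario: every read carries the alternate base
        counts = _counts([[20, 0, 0, 0, 0]], "T", start=500)
        calls = call_snvs(counts, min_alt_freq=0.2, min_depth=10)
        assert len(calls) == 1
        snv = calls[0]
        assert (snv.position, snv.ref, snv.alt) == (500, "T", "A")
        assert snv.alt_freq == 1.0

    def test_reference_only_no_call(self):
        assert call_snvs(_counts([[0, 0, 0, 20, 0]], "T")) == []

    def test_below_frequency_threshold(self):
        counts = _counts([[3, 0, 0, 17, 0]], "T")
        assert call_snvs(counts, min_alt_freq=0.2, min_depth=10) == []

    def test_below_depth_threshold(self):
        counts = _counts([[9, 0, 0, 0, 0]], "T")
        assert call_snvs(counts, min_alt_freq=0.2, min_depth=10) == []

    def test_monotone_in_min_alt_freq(self):
        rng = np.random.default_rng(6)
        rows = rng.integers(0, 30, size=(50, 5))
        counts = _counts(rows, "".join(rng.choice(list("ACGT"), size=50)))
        previous = None
        for threshold in (0.05, 0.2, 0.5, 0.9):
            positions = {c.position for c in
                         call_snvs(counts, min_alt_freq=threshold,
                                   min_depth=5)}
            if previous is not None:
                assert positions <= previous  # raising never adds calls
            previous = positions


class TestTranslateFrames:
    def test_offset_zero(self):
        frames = translate_frames("ATGGCCTAA", offsets=(0,))
        assert frames[0].residues == "MA*"
        assert frames[0].spans == [(0, 3), (3, 6), (6, 9)]

    def test_shifted_offsets(self):
        frames = {f.offset: f.residues
                  for f in translate_frames("ATGGCCTAA")}
        assert frames[1] == "WP"
        assert frames[2] == "GL"

    def test_n_codon_is_x(self):
        frames = translate_frames("ATGNNATAA", offsets=(0,))
        assert frames[0].residues == "MX*"

    def test_matches_codon_oracle_random(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(3, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=n,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            for frame in translate_frames(seq, region_start=100):
                assert frame.residues == translate_oracle(seq, frame.offset)
                for aa, (s, e) in zip(frame.residues, frame.spans):
                    assert e - s == 3
                    assert s >= 100


def max_overlap_depth(extents):
    """Brute-force maximum interval overlap (clique number)."""
    events = sorted([(s, 1) for s, _ in extents]
                    + [(e, -1) for _, e in extents])
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best


class TestAssignRows:
    def test_traced_example(self):
        assert assign_rows([(0, 10), (5, 15), (12, 20)]) == [0, 1, 0]

    def test_disjoint_all_row_zero(self):
        assert assign_rows([(0, 5), (10, 15), (20, 30)]) == [0, 0, 0]

    def test_mutually_overlapping_clique(self):
        k = 5
        extents = [(i, 100 + i) for i in range(k)]
        assert sorted(assign_rows(extents)) == list(range(k))

    def test_random_sets_disjoint_and_optimal(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(1, 25))
            starts = rng.integers(0, 500, size=n)
            lengths = rng.integers(1, 120, size=n)
            extents = [(int(s), int(s + l))
                       for s, l in zip(starts, lengths)]
            rows = assign_rows(extents)
            by_row = {}
            for (s, e), r in zip(extents, rows):
                for s2, e2 in by_row.get(r, []):
                    assert s >= e2 or e <= s2  # same-row disjointness
                by_row.setdefault(r, []).append((s, e))
            # first-fit by start on interval graphs is optimal
            assert max(rows) + 1 == max_overlap_depth(extents)

    def test_min_gap_forces_new_row(self):
        assert assign_rows([(0, 10), (12, 20)], min_gap=5) == [0, 1]


def _gene_set():
    def part(s, e, kind):
        return GenePart(GenomicRegion("chr1", s, e), kind)

    tx1 = TranscriptModel("t1", "t1", "+",
                          [part(100, 200, "exon"), part(200, 300, "intron"),
                           part(300, 400, "exon")])
    tx2 = TranscriptModel("t2", "t2", "+", [part(100, 200, "exon")])
    plus = GeneModel("g1", "GENE1", "+", None,
                     [part(100, 200, "exon"), part(200, 300, "intron"),
                      part(300, 400, "exon")], [tx1, tx2])
    minus = GeneModel("g2", "GENE2", "-", None,
                      [part(150, 250, "UTR"), part(250, 500, "exon")], [])
    return GeneModelSet([plus, minus])


class TestGlyphs:
    def test_strand_color_keys(self):
        glyphs = build_gene_glyphs(_gene_set(), make_region("chr1", 0, 600))
        keys = {g.feature_id: (g.color_key, g.strand) for g in glyphs}
        assert keys["g1"] == ("plus", "+")
        assert keys["g2"] == ("minus", "-")

    def test_part_heights_ordered(self):
        glyphs = build_gene_glyphs(_gene_set(), make_region("chr1", 0, 600))
        heights = {p.kind: p.height for g in glyphs for p in g.parts}
        assert heights["exon"] == 1.0
        assert heights["UTR"] == 0.6
        assert heights["intron"] == 0.15
        assert heights["exon"] > heights["UTR"] > heights["intron"]

    def test_overlapping_genes_on_distinct_rows(self):
        glyphs = build_gene_glyphs(_gene_set(), make_region("chr1", 0, 600))
        rows = {g.feature_id: g.row for g in glyphs}
        assert rows["g1"] != rows["g2"]

    def test_parts_clipped_to_region(self):
        glyphs = build_gene_glyphs(_gene_set(), make_region("chr1", 0, 350))
        g1 = next(g for g in glyphs if g.feature_id == "g1")
        assert g1.end == 350

    def test_transcript_glyphs(self):
        glyphs = build_transcript_glyphs(_gene_set(), "g1",
                                         make_region("chr1", 0, 600))
        assert {g.feature_id for g in glyphs} == {"t1", "t2"}

    def test_transcript_lookup_by_gene_name(self):
        glyphs = build_transcript_glyphs(_gene_set(), "GENE1",
                                         make_region("chr1", 0, 600))
        assert len(glyphs) == 2

    def test_unknown_gene(self):
        with pytest.raises(NotFoundError):
            build_transcript_glyphs(_gene_set(), "nope",
                                    make_region("chr1", 0, 600))


def brute_force_protein_depth(protein, peptides):
    depth = np.zeros(len(protein), dtype=int)
    for pep in peptides:
        for i in range(len(protein) - len(pep) + 1):
            if protein[i:i + len(pep)] == pep:
                depth[i:i + len(pep)] += 1
    return depth


class TestProteinCoverage:
    def _table(self, peptides):
        return PeptideTable([PeptideRecord(p) for p in peptides])

    def test_worked_example(self):
        cov = protein_coverage("MKTAYIAKQRQISFVK",
                               self._table(["KTAY", "AYIAK", "QISFVK"]))
        assert cov.depth[3] == 2 and cov.depth[4] == 2  # residues 4-5
        assert cov.covered_fraction == pytest.approx(13 / 16)

    def test_absent_peptide(self):
        cov = protein_coverage("MKTAY", self._table(["WWWW"]))
        assert not cov.depth.any() and cov.matches == []

    def test_peptide_equals_protein(self):
        cov = protein_coverage("MKTAY", self._table(["MKTAY"]))
        assert list(cov.depth) == [1] * 5

    def test_repeated_occurrences_counted_each(self):
        cov = protein_coverage("ABAABA".replace("B", "K"),
                               self._table(["AK"]))  # AKAAKA
        assert cov.depth.sum() == 4

    def test_leucine_isoleucine_not_equated(self):
        cov = protein_coverage("MLLLM", self._table(["III"]))
        assert not cov.depth.any()

    def test_illegal_peptide_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="illegal"):
            cov = protein_coverage("MKTAY", self._table(["K-TAY", "MKT"]))
        assert cov.skipped == ["K-TAY"]
        assert cov.depth[:3].sum() == 3

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(23)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            protein = "".join(rng.choice(aas,
                                         size=int(rng.integers(10, 80))))
            peptides = []
            for _ in range(int(rng.integers(1, 8))):
                if rng.random() < 0.7 and len(protein) > 6:
                    start = int(rng.integers(0, len(protein) - 4))
                    length = int(rng.integers(3, min(12, len(protein)
                                                     - start) + 1))
                    peptides.append(protein[start:start + length])
                else:
                    peptides.append("".join(
                        rng.choice(aas, size=int(rng.integers(3, 10)))))
            cov = protein_coverage(protein, self._table(peptides))
            assert np.array_equal(
                cov.depth, brute_force_protein_depth(protein, peptides))


class TestCnvTrack:
    def _bins(self):
        return BinnedSignal(make_region("chr1", 0, 1000), 100,
                            np.full(10, 2.0))

    def test_assembly(self):
        seg = (make_region("chr1", 500, 1000), 4.0)
        track = build_cnv_track(self._bins(), [seg], ploidy=2)
        assert track.segments[0].copy_number == 4.0
        assert track.ploidy == 2

    def test_empty_segments_ok(self):
        assert build_cnv_track(self._bins(), []).segments == []

    def test_overlapping_segments_rejected(self):
        segs = [(make_region("chr1", 0, 600), 3.0),
                (make_region("chr1", 500, 1000), 4.0)]
        with pytest.raises(ParameterError):
            build_cnv_track(self._bins(), segs)
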