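"""The layer grammar: figure composition with '+', panel stacking, themes.

A figure is an ordered stack of panels: one coverage (or protein) panel
first, then annotation panels in addition order. Layers are value objects;
``compose`` (also available as the ``+`` operator on :class:`FigureSpec`)
never mutates its inputs. Rendering realizes the stack as matplotlib axes
whose layout (panel count, bounding boxes, x-domains) is exposed for
structural assertions, and SVG output is byte-deterministic for identical
inputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection
from matplotlib.ticker import FuncFormatter

from .annotate import (CnvTrack, GlyphRow, ProteinCoverage, SnvCall,
                       TranslatedFrame, base_frequencies)
from .errors import (CompositionError, CoordinateSpaceError, FormatError,
                     NotFoundError, ParameterError)
from .io import (BASES, ContactMatrix, CytobandSet, LocusBaseCounts, PeakSet)
from .regions import BinnedSignal, GenomicRegion, SignalTrack

__all__ = [
    "LAYER_KINDS",
    "LayerSpec",
    "FigureSpec",
    "LinkSpec",
    "FeatureSpec",
    "RealizedPanel",
    "RealizedLayout",
    "coverage_plot",
    "protein_plot",
    "base_layer",
    "cnv_layer",
    "gc_layer",
    "gene_layer",
    "transcript_layer",
    "peak_layer",
    "ideogram_layer",
    "tad_layer",
    "link_layer",
    "feature_layer",
    "compose",
    "render",
    "save",
    "apply_theme",
    "recolor_group",
    "set_axis_label",
    "add_reference_line",
    "THEMES",
]

LAYER_KINDS = ("coverage", "base", "cnv", "gc", "gene", "transcript", "peak",
               "ideogram", "tad", "link", "protein", "feature")
_COVERAGE_KINDS = {"coverage", "protein"}
_GENOME_ONLY = {"coverage", "base", "cnv", "gc", "gene", "transcript",
                "peak", "ideogram", "tad", "link"}
_PROTEIN_ONLY = {"protein"}

# Fig-1-style default aesthetics: strand colors, IGV base colors, the red
# region marker and green centromere on ideograms
STRAND_COLORS = {"plus": "#006400", "minus": "#00008B"}
BASE_COLORS = {"A": "#33A02C", "C": "#1F78B4", "G": "#FF7F00", "T": "#E31A1C",
               "N": "#999999"}
REGION_MARKER_COLOR = "#E31A1C"
CENTROMERE_COLOR = "#2E8B57"
# Okabe-Ito qualitative palette (colorblind-safe) for sample groups
GROUP_PALETTE = ("#E69F00", "#56B4E9", "#009E73", "#F0E442", "#0072B2",
                 "#D55E00", "#CC79A7", "#000000")
_STAIN_SHADES = {"gneg": "#FFFFFF", "gpos25": "#C8C8C8", "gpos50": "#969696",
                 "gpos75": "#646464", "gpos100": "#323232", "gvar": "#DCDCDC",
                 "stalk": "#6488B4", "acen": CENTROMERE_COLOR}

DEFAULT_HEIGHTS = {"coverage": 4.0, "base": 1.5, "gc": 1.0, "cnv": 1.5,
                   "peak": 0.5, "ideogram": 0.6, "tad": 3.0, "link": 1.0,
                   "feature": 0.5, "protein": 4.0}

THEMES: dict[str, dict[str, Any]] = {
    "default": {"facecolor": "white", "grid": False, "spine_top": False,
                "spine_right": False},
    "classic": {"facecolor": "white", "grid": False, "spine_top": True,
                "spine_right": True},
    "minimal": {"facecolor": "white", "grid": True, "spine_top": False,
                "spine_right": False},
}


@dataclass(frozen=True)
class LayerSpec:
    """One panel of a figure: its kind, data/options, and layout weight."""

    kind: str
    params: dict = field(default_factory=dict)
    relative_height: float | None = None  # None: per-kind default at render
    zorder: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise CompositionError(
                f"unknown layer kind {self.kind!r}; expected one of "
                f"{LAYER_KINDS}"
            )
        if self.relative_height is not None and self.relative_height <= 0:
            raise CompositionError("relative_height must be positive")


@dataclass(frozen=True)
class LinkSpec:
    """Arc links between pairs of genomic anchors (peak-gene, DNA-DNA)."""

    anchors: tuple  # of (GenomicRegion, GenomicRegion, score or None)
    style: str = "arc"


@dataclass(frozen=True)
class FeatureSpec:
    """Boxed/marked characteristics in the active coordinate space."""

    features: tuple  # of (start, end, label, shape)

    def __post_init__(self) -> None:
        for start, end, label, shape in self.features:
            if start >= end:
                raise ParameterError(
                    f"feature {label!r}: start must be < end"
                )
            if shape not in ("box", "domain", "marker"):
                raise ParameterError(f"unknown feature shape {shape!r}")


@dataclass(frozen=True)
class FigureSpec:
    """An ordered, immutable stack of panels; supports ``+`` composition."""

    space: str  # "genome" | "protein"
    layers: tuple[LayerSpec, ...]
    region: GenomicRegion | None = None
    protein_length: int | None = None
    style: str = "facet"  # coverage display: facet | joint
    y_scale: str = "free"  # facet y-axis sharing: free | shared
    highlights: tuple[GenomicRegion, ...] = ()
    theme: str = "default"
    color_overrides: tuple[tuple[str, str], ...] = ()
    axis_labels: tuple[tuple[int, str], ...] = ()
    reference_lines: tuple[tuple[int, float], ...] = ()

    def __add__(self, layer: LayerSpec) -> "FigureSpec":
        return compose(self, layer)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(layer.kind for layer in self.layers)


def coverage_plot(tracks: Sequence[SignalTrack | BinnedSignal],
                  region: GenomicRegion | None = None,
                  style: str = "facet", y_scale: str = "free",
                  highlights: Sequence[GenomicRegion] = (),
                  theme: str = "default") -> FigureSpec:
    """Start a genomic figure from one coverage panel over `tracks`."""
    if not tracks:
        raise ParameterError("coverage plot needs at least one track")
    if style not in ("facet", "joint"):
        raise ParameterError("style must be 'facet' or 'joint'")
    if y_scale not in ("free", "shared"):
        raise ParameterError("y_scale must be 'free' or 'shared'")
    regions = {t.region for t in tracks}
    if len(regions) != 1:
        raise ParameterError(
            f"all coverage tracks must share one region, got {regions}"
        )
    track_region = next(iter(regions))
    if region is not None and region != track_region:
        raise ParameterError(
            f"figure region {region} does not match track region "
            f"{track_region}"
        )
    layer = LayerSpec(kind="coverage", params={"tracks": tuple(tracks)})
    return FigureSpec(space="genome", layers=(layer,), region=track_region,
                      style=style, y_scale=y_scale,
                      highlights=tuple(highlights), theme=theme)


def protein_plot(coverage: ProteinCoverage,
                 theme: str = "default") -> FigureSpec:
    """Start a protein figure from a per-residue coverage panel."""
    layer = LayerSpec(kind="protein", params={"coverage": coverage})
    return FigureSpec(space="protein", layers=(layer,),
                      protein_length=coverage.length, theme=theme)


def base_layer(counts: LocusBaseCounts, snvs: Sequence[SnvCall] = (),
               frames: Sequence[TranslatedFrame] = (),
               snv_style: str = "twill",
               relative_height: float | None = None) -> LayerSpec:
    if snv_style not in ("twill", "strip", "letter"):
        raise ParameterError(
            f"snv_style must be twill, strip or letter, got {snv_style!r}"
        )
    return LayerSpec(kind="base", relative_height=relative_height,
                     params={"counts": counts, "snvs": tuple(snvs),
                             "frames": tuple(frames),
                             "snv_style": snv_style})


def cnv_layer(cnv: CnvTrack,
              relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="cnv", params={"cnv": cnv},
                     relative_height=relative_height)


def gc_layer(gc_fractions: np.ndarray, binsize: int, mean_gc: float,
             reference: float | None = None,
             relative_height: float | None = None) -> LayerSpec:
    """GC-content panel; the reference line is the region mean unless a
    user constant (e.g. a genome-wide average) is supplied."""
    return LayerSpec(kind="gc", relative_height=relative_height,
                     params={"fractions": np.asarray(gc_fractions),
                             "binsize": binsize, "mean_gc": mean_gc,
                             "reference": reference})


def gene_layer(glyphs: Sequence[GlyphRow],
               relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="gene", params={"glyphs": tuple(glyphs)},
                     relative_height=relative_height)


def transcript_layer(glyphs: Sequence[GlyphRow],
                     relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="transcript", params={"glyphs": tuple(glyphs)},
                     relative_height=relative_height)


def peak_layer(peak_sets: Sequence[PeakSet],
               relative_height: float | None = None) -> LayerSpec:
    if isinstance(peak_sets, PeakSet):
        peak_sets = [peak_sets]
    return LayerSpec(kind="peak", params={"peak_sets": tuple(peak_sets)},
                     relative_height=relative_height)


def ideogram_layer(bands: CytobandSet, chrom: str,
                   relative_height: float | None = None) -> LayerSpec:
    if chrom not in bands.chromosomes():
        raise NotFoundError(f"chromosome {chrom!r} has no cytobands")
    return LayerSpec(kind="ideogram", params={"bands": bands, "chrom": chrom},
                     relative_height=relative_height)


def tad_layer(matrix: ContactMatrix, log_scale: bool = True,
              relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="tad",
                     params={"matrix": matrix, "log_scale": log_scale},
                     relative_height=relative_height)


def link_layer(links: LinkSpec,
               relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="link", params={"links": links},
                     relative_height=relative_height)


def feature_layer(features: FeatureSpec,
                  relative_height: float | None = None) -> LayerSpec:
    return LayerSpec(kind="feature", params={"features": features},
                     relative_height=relative_height)


def compose(base: FigureSpec, layer: LayerSpec) -> FigureSpec:
    """Append a layer, returning a new figure (inputs are untouched).

    Panel order equals addition order. A second coverage-type layer, or a
    layer from the wrong coordinate space, is rejected.
    """
    if layer.kind in _COVERAGE_KINDS and any(
            l.kind in _COVERAGE_KINDS for l in base.layers):
        raise CompositionError(
            f"figure already has a {base.layers[0].kind} panel; only one "
            "coverage-type layer is allowed"
        )
    if base.space == "genome" and layer.kind in _PROTEIN_ONLY:
        raise CoordinateSpaceError(
            f"cannot add protein layer {layer.kind!r} to a genomic figure"
        )
    if base.space == "protein" and layer.kind in _GENOME_ONLY:
        raise CoordinateSpaceError(
            f"cannot add genomic layer {layer.kind!r} to a protein figure"
        )
    return replace(base, layers=base.layers + (layer,))


def apply_theme(figure: FigureSpec, theme_name: str) -> FigureSpec:
    """Return a copy of the figure using the named theme."""
    if theme_name not in THEMES:
        raise NotFoundError(
            f"unknown theme {theme_name!r}; available: {sorted(THEMES)}"
        )
    return replace(figure, theme=theme_name)


def recolor_group(figure: FigureSpec, group: str, color: str) -> FigureSpec:
    """Post-hoc hook: override the color assigned to one sample group."""
    overrides = tuple(kv for kv in figure.color_overrides if kv[0] != group)
    return replace(figure, color_overrides=overrides + ((group, color),))


def set_axis_label(figure: FigureSpec, panel_index: int,
                   label: str) -> FigureSpec:
    """Post-hoc hook: set the y-axis label of one panel (by layer index)."""
    labels = tuple(kv for kv in figure.axis_labels if kv[0] != panel_index)
    return replace(figure, axis_labels=labels + ((panel_index, label),))


def add_reference_line(figure: FigureSpec, panel_index: int,
                       y: float) -> FigureSpec:
    """Post-hoc hook: add a horizontal reference line to one panel."""
    return replace(figure,
                   reference_lines=figure.reference_lines
                   + ((panel_index, y),))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class RealizedPanel:
    """Realized layout of one layer: for structural tests."""

    kind: str
    index: int
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1 figure fraction
    x_domain: tuple[float, float]
    x_space: str  # "region" | "chromosome" | "protein"
    n_subpanels: int = 1
    sub_bboxes: list[tuple[float, float, float, float]] = field(
        default_factory=list)


@dataclass
class RealizedLayout:
    panels: list[RealizedPanel]
    height_ratios: list[float]

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.panels]


def _layer_height(layer: LayerSpec, figure: FigureSpec) -> float:
    if layer.relative_height is not None:
        return layer.relative_height
    if layer.kind == "base":
        return 1.5 + 0.5 * len(layer.params.get("frames", ()))
    if layer.kind in ("gene", "transcript"):
        glyphs = layer.params.get("glyphs", ())
        rows = 1 + max((g.row for g in glyphs), default=0)
        return max(1.0, 0.4 * rows)
    return DEFAULT_HEIGHTS[layer.kind]


def _group_colors(figure: FigureSpec,
                  groups: Sequence[str]) -> dict[str, str]:
    colors = {g: GROUP_PALETTE[i % len(GROUP_PALETTE)]
              for i, g in enumerate(dict.fromkeys(groups))}
    colors.update(dict(figure.color_overrides))
    return colors


def _style_axis(ax, theme: dict) -> None:
    ax.set_facecolor(theme["facecolor"])
    ax.spines["top"].set_visible(theme["spine_top"])
    ax.spines["right"].set_visible(theme["spine_right"])
    if theme["grid"]:
        ax.grid(True, linewidth=0.3, alpha=0.5)


def _format_bp_axis(ax) -> None:
    # display convention: 1-based inclusive positions with separators
    ax.xaxis.set_major_formatter(
        FuncFormatter(lambda x, _pos: f"{int(x) + 1:,}"))


def _draw_highlights(ax, highlights: Sequence[GenomicRegion]) -> None:
    for h in highlights:
        ax.axvspan(h.start, h.end, color="#D3D3D3", alpha=0.5, zorder=0)


def _track_xy(track: SignalTrack | BinnedSignal
              ) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, BinnedSignal):
        # step outline over bins
        x = np.repeat(np.append(track.bin_starts, track.region.end), 2)[1:-1]
        y = np.repeat(track.values, 2)
        return x, y
    x = np.arange(track.region.start, track.region.end + 1)
    x = np.repeat(x, 2)[1:-1]
    y = np.repeat(track.values, 2)
    return x, y


def _render_coverage(fig, slot, figure: FigureSpec, layer: LayerSpec,
                     theme: dict) -> tuple[list, list]:
    tracks = layer.params["tracks"]
    colors = _group_colors(figure, [t.group for t in tracks])
    axes = []
    if figure.style == "joint":
        ax = fig.add_subplot(slot)
        for track in tracks:
            x, y = _track_xy(track)
            ax.fill_between(x, 0, y, color=colors[track.group], alpha=0.6,
                            linewidth=0.5, label=track.sample)
        ax.legend(loc="upper right", fontsize=6, frameon=False)
        ax.set_ylabel("coverage", fontsize=7)
        _draw_highlights(ax, figure.highlights)
        _style_axis(ax, theme)
        axes.append(ax)
    else:  # facet: one sub-panel per sample
        sub = slot.subgridspec(len(tracks), 1, hspace=0.15)
        ymax = max((float(np.max(t.values)) if len(t.values) else 0.0)
                   for t in tracks) or 1.0
        for i, track in enumerate(tracks):
            ax = fig.add_subplot(sub[i, 0])
            x, y = _track_xy(track)
            ax.fill_between(x, 0, y, color=colors[track.group],
                            linewidth=0.5)
            ax.set_ylabel(track.sample, fontsize=7, rotation=0,
                          ha="right", va="center")
            if figure.y_scale == "shared":
                ax.set_ylim(0, 1.05 * ymax)
            _draw_highlights(ax, figure.highlights)
            _style_axis(ax, theme)
            if i < len(tracks) - 1:
                ax.tick_params(labelbottom=False)
            axes.append(ax)
    return axes, axes


def _render_base(ax, figure: FigureSpec, layer: LayerSpec) -> None:
    counts: LocusBaseCounts = layer.params["counts"]
    snvs = layer.params["snvs"]
    frames = layer.params["frames"]
    snv_style = layer.params["snv_style"]
    freqs = base_frequencies(counts)
    start = counts.region.start
    # stacked per-position frequency bars colored by base
    bottom = np.zeros(len(counts.region))
    for j, base in enumerate(BASES):
        col = freqs[:, j]
        if not col.any():
            continue
        ax.bar(np.arange(start, counts.region.end) + 0.5, col,
               bottom=bottom, width=1.0, color=BASE_COLORS[base],
               edgecolor="none")
        bottom = bottom + col
    ax.axhline(0.5, color=REGION_MARKER_COLOR, linewidth=0.8)  # 0.5 guide
    snv_positions = {s.position for s in snvs}
    for pos in snv_positions:
        if snv_style == "twill":
            ax.bar([pos + 0.5], [1.0], width=1.0, fill=False,
                   hatch="////", edgecolor="black", linewidth=0.3)
        elif snv_style == "strip":
            ax.axvspan(pos, pos + 1, color="#FFD700", alpha=0.35)
    # reference base letters beneath the bars
    n_frame_rows = len(frames)
    row_h = 0.35
    for i, ref in enumerate(counts.ref_bases):
        pos = start + i
        color = (REGION_MARKER_COLOR
                 if snv_style == "letter" and pos in snv_positions
                 else BASE_COLORS.get(ref, "#333333"))
        ax.text(pos + 0.5, -row_h / 2, ref, ha="center", va="center",
                fontsize=5, color=color, clip_on=True)
    # amino-acid frames in IGV style, one row per offset
    for f_idx, frame in enumerate(frames):
        y0 = -row_h * (f_idx + 1.5)
        for aa, (s, e) in zip(frame.residues, frame.spans):
            ax.add_patch(plt.Rectangle(
                (s, y0 - row_h * 0.45), e - s, row_h * 0.9,
                facecolor="#B0C4DE" if aa != "*" else "#E31A1C",
                edgecolor="white", linewidth=0.3, clip_on=True))
            ax.text((s + e) / 2, y0, aa, ha="center", va="center",
                    fontsize=5, clip_on=True)
        ax.text(start, y0, f"  +{frame.offset}", ha="right", va="center",
                fontsize=5, color="#555555", clip_on=False)
    ax.set_ylim(-row_h * (n_frame_rows + 2), 1.05)
    ax.set_yticks([0, 0.5, 1.0])
    ax.set_ylabel("base freq", fontsize=7)


def _render_cnv(ax, layer: LayerSpec) -> None:
    cnv: CnvTrack = layer.params["cnv"]
    mids = (cnv.bins.bin_starts + cnv.bins.bin_ends) / 2
    ax.plot(mids, cnv.bins.values, ".", color="#808080", markersize=2)
    for seg in cnv.segments:
        ax.hlines(seg.copy_number, seg.region.start, seg.region.end,
                  color=REGION_MARKER_COLOR, linewidth=1.5)
    ax.axhline(cnv.ploidy, color="black", linewidth=0.8)
    ax.set_ylabel("copy number", fontsize=7)


def _render_gc(ax, layer: LayerSpec, region: GenomicRegion) -> None:
    fr = layer.params["fractions"]
    binsize = layer.params["binsize"]
    mids = region.start + binsize * np.arange(len(fr)) + binsize / 2
    ok = ~np.isnan(fr)
    ax.plot(mids[ok], fr[ok], color="#4575B4", linewidth=0.8)
    ref = layer.params["reference"]
    ref_value = ref if ref is not None else layer.params["mean_gc"]
    ax.axhline(ref_value, color=REGION_MARKER_COLOR, linewidth=0.8,
               linestyle="--")
    ax.set_ylim(0, 1)
    ax.set_ylabel("GC", fontsize=7)


def _render_glyphs(ax, layer: LayerSpec, region: GenomicRegion) -> None:
    glyphs: Sequence[GlyphRow] = layer.params["glyphs"]
    lane_h = 0.8
    for glyph in glyphs:
        y = -glyph.row  # row 0 on top
        color = (STRAND_COLORS.get(glyph.color_key)
                 or GROUP_PALETTE[zlib.crc32(glyph.color_key.encode()) % 4])
        ax.hlines(y, glyph.start, glyph.end, color=color, linewidth=0.8)
        for part in glyph.parts:
            h = lane_h * part.height
            ax.add_patch(plt.Rectangle((part.start, y - h / 2),
                                       part.end - part.start, h,
                                       facecolor=color, edgecolor="none"))
        # strand arrows along the span: right for '+', left for '-'
        marker = ">" if glyph.strand == "+" else "<"
        n_arrows = 3
        xs = np.linspace(glyph.start, glyph.end, n_arrows + 2)[1:-1]
        ax.plot(xs, [y] * n_arrows, marker=marker, linestyle="none",
                markersize=3, color=color)
        ax.text(min(glyph.end, region.end), y + lane_h * 0.55, glyph.label,
                fontsize=6, ha="right", va="bottom", color=color,
                clip_on=True)
    n_rows = 1 + max((g.row for g in glyphs), default=0)
    ax.set_ylim(-n_rows + 0.0 - 0.8, 1.0)
    ax.set_yticks([])


def _render_peaks(ax, layer: LayerSpec) -> None:
    peak_sets: Sequence[PeakSet] = layer.params["peak_sets"]
    for row, pset in enumerate(peak_sets):
        for peak in pset:
            ax.add_patch(plt.Rectangle((peak.region.start, -row - 0.35),
                                       len(peak.region), 0.7,
                                       facecolor="#333333",
                                       edgecolor="none"))
        label = Path(pset.source).stem if pset.source else f"peaks {row + 1}"
        ax.text(ax.get_xlim()[0], -row, f" {label}", fontsize=5,
                va="center", color="#555555", clip_on=True)
    ax.set_ylim(-len(peak_sets) + 0.0 - 0.6, 0.6)
    ax.set_yticks([])


def _render_ideogram(ax, layer: LayerSpec, region: GenomicRegion) -> None:
    bands: CytobandSet = layer.params["bands"]
    chrom = layer.params["chrom"]
    sub = bands.bands_for(chrom)
    length = bands.chrom_length(chrom)
    for _, band in sub.iterrows():
        color = _STAIN_SHADES.get(str(band["stain"]), "#FFFFFF")
        ax.add_patch(plt.Rectangle((band["start"], -0.25),
                                   band["end"] - band["start"], 0.5,
                                   facecolor=color, edgecolor="none"))
    ax.add_patch(plt.Rectangle((0, -0.25), length, 0.5, fill=False,
                               edgecolor="black", linewidth=0.6))
    # displayed region marked in red, scaled to chromosome length
    ax.add_patch(plt.Rectangle((region.start, -0.4),
                               max(len(region), length / 500), 0.8,
                               fill=False, edgecolor=REGION_MARKER_COLOR,
                               linewidth=1.2))
    ax.set_xlim(0, length)
    ax.set_ylim(-0.6, 0.6)
    ax.set_yticks([])
    ax.set_ylabel(chrom, fontsize=7, rotation=0, ha="right", va="center")


def _render_tad(ax, layer: LayerSpec) -> None:
    cm: ContactMatrix = layer.params["matrix"]
    n = cm.matrix.shape[0]
    start, binsize = cm.region.start, cm.binsize
    values = np.log1p(cm.matrix) if layer.params["log_scale"] else cm.matrix
    verts, colors = [], []
    # rotate 45 degrees: matrix cell (i, j>=i) becomes a diamond whose apex
    # sits at x = start + (i+j+1)/2 * binsize, y = j - i
    for i in range(n):
        for j in range(i, n):
            cx = start + (i + j + 1) / 2 * binsize
            cy = j - i
            half = binsize / 2
            verts.append([(cx - half, cy), (cx, cy + 1), (cx + half, cy),
                          (cx, cy - 1)])
            colors.append(values[i, j])
    coll = PolyCollection(verts, array=np.array(colors), cmap="Reds",
                          edgecolors="none")
    ax.add_collection(coll)
    ax.set_ylim(0, n + 1)
    ax.set_yticks([])
    ax.set_ylabel("contacts", fontsize=7)


def _render_links(ax, layer: LayerSpec, region: GenomicRegion) -> None:
    links: LinkSpec = layer.params["links"]
    for a, b, _score in links.anchors:
        if a.chrom != region.chrom or b.chrom != region.chrom:
            raise ParameterError(
                f"link anchor off the displayed chromosome: {a} / {b}"
            )
        x1 = (a.start + a.end) / 2
        x2 = (b.start + b.end) / 2
        theta = np.linspace(0, math.pi, 64)
        xc, r = (x1 + x2) / 2, abs(x2 - x1) / 2
        ax.plot(xc + r * np.cos(theta), np.sin(theta), color="#4575B4",
                linewidth=0.8)
    ax.set_ylim(0, 1.1)
    ax.set_yticks([])
    ax.set_ylabel("links", fontsize=7)


def _render_features(ax, layer: LayerSpec) -> None:
    features: FeatureSpec = layer.params["features"]
    for i, (start, end, label, shape) in enumerate(features.features):
        color = GROUP_PALETTE[i % len(GROUP_PALETTE)]
        if shape == "marker":
            ax.plot([(start + end) / 2], [0], marker="v", color=color,
                    markersize=5)
        else:
            h = 0.6 if shape == "domain" else 0.4
            ax.add_patch(plt.Rectangle((start, -h / 2), end - start, h,
                                       facecolor=color, alpha=0.8,
                                       edgecolor="none"))
        ax.text((start + end) / 2, 0.55, label, fontsize=5, ha="center",
                clip_on=True)
    ax.set_ylim(-0.6, 1.0)
    ax.set_yticks([])


def _render_protein(ax, layer: LayerSpec) -> None:
    cov: ProteinCoverage = layer.params["coverage"]
    x = np.repeat(np.arange(cov.length + 1), 2)[1:-1]
    y = np.repeat(cov.depth, 2)
    ax.fill_between(x, 0, y, step=None, color="#4575B4", alpha=0.8)
    # matched peptides as stacked boxes beneath the depth area
    from .annotate import assign_rows
    extents = [(s, e) for _pep, s, e in cov.matches]
    rows = assign_rows(extents, min_gap=0.5) if extents else []
    depth_max = max(float(cov.depth.max()), 1.0)
    box_h = 0.08 * depth_max
    for (pep, s, e), row in zip(cov.matches, rows):
        ax.add_patch(plt.Rectangle(
            (s, -box_h * (row + 1.4)), e - s, box_h * 0.8,
            facecolor="#E69F00", edgecolor="white", linewidth=0.3))
    n_rows = 1 + max(rows, default=0) if rows else 0
    ax.set_ylim(-box_h * (n_rows + 1.6), depth_max * 1.1)
    ax.set_xlim(0, cov.length)
    ax.set_ylabel(f"{cov.protein_id}\npeptide depth", fontsize=7)


def render(figure: FigureSpec, width: float = 8.0,
           height: float | None = None, dpi: int = 150
           ) -> tuple["matplotlib.figure.Figure", RealizedLayout]:
    """Realize a figure spec as a matplotlib figure.

    Returns the figure plus a :class:`RealizedLayout` describing panel
    count, per-panel bounding boxes and x-domains, so layout properties
    can be asserted without image comparison.
    """
    theme = THEMES.get(figure.theme)
    if theme is None:
        raise NotFoundError(f"unknown theme {figure.theme!r}")
    heights = [_layer_height(layer, figure) for layer in figure.layers]
    if height is None:
        height = max(2.0, 0.6 * sum(heights))
    fig = plt.figure(figsize=(width, height), dpi=dpi)
    gs = fig.add_gridspec(len(figure.layers), 1, height_ratios=heights,
                          hspace=0.45)
    panels: list[RealizedPanel] = []
    region = figure.region
    panel_axes: list[list] = []
    for idx, layer in enumerate(figure.layers):
        slot = gs[idx, 0]
        x_space = "region"
        if layer.kind == "coverage":
            axes, _ = _render_coverage(fig, slot, figure, layer, theme)
        else:
            ax = fig.add_subplot(slot)
            _style_axis(ax, theme)
            axes = [ax]
            if layer.kind == "base":
                _render_base(ax, figure, layer)
            elif layer.kind == "cnv":
                _render_cnv(ax, layer)
            elif layer.kind == "gc":
                _render_gc(ax, layer, region)
            elif layer.kind in ("gene", "transcript"):
                _render_glyphs(ax, layer, region)
            elif layer.kind == "peak":
                _render_peaks(ax, layer)
            elif layer.kind == "ideogram":
                _render_ideogram(ax, layer, region)
                x_space = "chromosome"
            elif layer.kind == "tad":
                _render_tad(ax, layer)
            elif layer.kind == "link":
                _render_links(ax, layer, region)
            elif layer.kind == "feature":
                _render_features(ax, layer)
                if figure.space == "protein":
                    x_space = "protein"
            elif layer.kind == "protein":
                _render_protein(ax, layer)
                x_space = "protein"
        # harmonize x-domains: all region-space panels share the region
        for ax in axes:
            if x_space == "region":
                ax.set_xlim(region.start, region.end)
                _format_bp_axis(ax)
            elif x_space == "protein" and figure.protein_length:
                ax.set_xlim(0, figure.protein_length)
            ax.tick_params(labelsize=6)
        panel_axes.append(axes)
    # hide x tick labels everywhere except each panel's last axes row
    for axes in panel_axes[:-1]:
        for ax in axes:
            ax.tick_params(labelbottom=False)
    if figure.space == "genome":
        panel_axes[-1][-1].set_xlabel(str(region), fontsize=8)
    else:
        panel_axes[-1][-1].set_xlabel("residue", fontsize=8)
    # post-hoc hooks
    for panel_index, label in figure.axis_labels:
        panel_axes[panel_index][0].set_ylabel(label, fontsize=7)
    for panel_index, yline in figure.reference_lines:
        for ax in panel_axes[panel_index]:
            ax.axhline(yline, color="#555555", linewidth=0.8,
                       linestyle=":")
    for idx, (layer, axes) in enumerate(zip(figure.layers, panel_axes)):
        sub_bboxes = [tuple(ax.get_position().extents) for ax in axes]
        x0 = min(b[0] for b in sub_bboxes)
        y0 = min(b[1] for b in sub_bboxes)
        x1 = max(b[2] for b in sub_bboxes)
        y1 = max(b[3] for b in sub_bboxes)
        x_space = ("chromosome" if layer.kind == "ideogram" else
                   "protein" if figure.space == "protein" else "region")
        panels.append(RealizedPanel(
            kind=layer.kind, index=idx, bbox=(x0, y0, x1, y1),
            x_domain=tuple(axes[0].get_xlim()), x_space=x_space,
            n_subpanels=len(axes), sub_bboxes=sub_bboxes))
    return fig, RealizedLayout(panels=panels, height_ratios=heights)


_SAVE_EXTENSIONS = {".pdf", ".svg", ".png"}


def save(figure: FigureSpec, path: str | Path, width: float = 8.0,
         height: float | None = None, dpi: int = 150) -> RealizedLayout:
    """Render and write a figure to PDF, SVG or PNG.

    SVG output is byte-deterministic: the hash salt is pinned and the
    creation date is stripped, so re-rendering identical inputs gives
    identical files.
    """
    path = Path(path)
    if path.suffix.lower() not in _SAVE_EXTENSIONS:
        raise FormatError(
            f"unsupported figure format {path.suffix!r}; "
            f"use one of {sorted(_SAVE_EXTENSIONS)}"
        )
    with matplotlib.rc_context({"svg.hashsalt": "covplot",
                                "svg.fonttype": "path"}):
        fig, layout = render(figure, width=width, height=height, dpi=dpi)
        try:
            if path.suffix.lower() == ".svg":
                fig.savefig(path, metadata={"Date": None})
            else:
                fig.savefig(path)
        finally:
            plt.close(fig)
    return layout
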