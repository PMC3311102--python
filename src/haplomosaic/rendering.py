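"""Scale-adaptive static track rendering.

Reproduces the viewer's visual conventions as static images: vertically
stacked tracks over a common coordinate ruler, colored mosaic bars for
haplotype/subspecies/heterozygosity state, compatible intervals on two
alternating parity rows, and a density histogram whenever per-feature
detail would exceed one item per pixel.  In detail mode, allele letters
can be overlaid on mosaic tracks.

The renderer builds a flat list of drawing primitives (rect/line/text) and
serializes them to SVG with fixed formatting, so identical inputs produce
byte-identical SVG.  PNG output rasterizes the same primitives through
matplotlib's Agg backend (not byte-stable across library versions).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Any, Sequence

from .coloring import PALETTE, SUBSPECIES_COLORS, ColorMosaic
from .compatible_intervals import (
    CompatibleInterval,
    interval_density_histogram,
)
from .genotype_model import GenomicInterval, GenotypeMatrix
from .haplotypes import IBDInterval
from .mosaic_hmm import MosaicInterval

HET_COLORS = {"inbred": "#c8c8c8", "heterozygous": "#ff8c00"}
IBD_COLOR = "#d02020"
TRACK_KINDS = ("snp", "features", "mosaic", "origin", "het", "ibd", "intervals")

ROW_H = 12
ROW_GAP = 2
TRACK_GAP = 8
RULER_H = 22
LABEL_W = 90
HIST_H = 40


@dataclass(frozen=True)
class TrackSpec:
    """One track request: a kind, a data key, optional strain order."""

    kind: str
    data: str
    strain_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")


@dataclass(frozen=True)
class RenderConfig:
    view: GenomicInterval
    pixel_width: int
    tracks: tuple[TrackSpec, ...] = ()
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.pixel_width < 16:
            raise ValueError("pixel_width must be >= 16")
        if self.output_format not in ("svg", "png"):
            raise ValueError("output format must be svg or png")


def mode_for_view(item_count: int, pixel_width: int) -> str:
    """'detail' when items fit one per pixel, else 'histogram'."""
    if pixel_width < 1:
        raise ValueError("pixel_width must be >= 1")
    return "detail" if item_count <= pixel_width else "histogram"


def pixel_x(pos: int, view: GenomicInterval, pixel_width: int) -> int:
    """Affine genomic-to-pixel map, clamped to [0, pixel_width]."""
    span = view.end_pos - view.start_pos + 1
    x = round((pos - view.start_pos) / span * pixel_width)
    return min(max(x, 0), pixel_width)


# --- drawing primitives -----------------------------------------------------

@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    s: str
    size: int = 9
    fill: str = "#000000"


class _Canvas:
    def __init__(self, config: RenderConfig) -> None:
        self.config = config
        self.items: list[Rect | Line | Text] = []
        self.y = 0.0

    def add(self, item: Rect | Line | Text) -> None:
        self.items.append(item)

    def px(self, pos: int) -> int:
        return LABEL_W + pixel_x(pos, self.config.view, self.config.pixel_width)


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def to_svg(items: Sequence[Rect | Line | Text], width: float,
           height: float) -> str:
    out = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
           f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">']
    out.append(f'<rect x="0" y="0" width="{_fmt(width)}" '
               f'height="{_fmt(height)}" fill="#ffffff"/>')
    for it in items:
        if isinstance(it, Rect):
            out.append(f'<rect x="{_fmt(it.x)}" y="{_fmt(it.y)}" '
                       f'width="{_fmt(it.w)}" height="{_fmt(it.h)}" '
                       f'fill="{it.fill}"/>')
        elif isinstance(it, Line):
            out.append(f'<line x1="{_fmt(it.x1)}" y1="{_fmt(it.y1)}" '
                       f'x2="{_fmt(it.x2)}" y2="{_fmt(it.y2)}" '
                       f'stroke="{it.stroke}" stroke-width="1"/>')
        else:
            s = (it.s.replace("&", "&amp;").replace("<", "&lt;")
                 .replace(">", "&gt;"))
            out.append(f'<text x="{_fmt(it.x)}" y="{_fmt(it.y)}" '
                       f'font-family="monospace" font-size="{it.size}" '
                       f'fill="{it.fill}">{s}</text>')
    out.append("</svg>")
    return "\n".join(out) + "\n"


# --- track drawing ----------------------------------------------------------

def _draw_ruler(cv: _Canvas) -> None:
    view = cv.config.view
    y = cv.y + RULER_H - 6
    cv.add(Line(LABEL_W, y, LABEL_W + cv.config.pixel_width, y, "#000000"))
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        pos = view.start_pos + round(frac * (view.end_pos - view.start_pos))
        x = cv.px(pos)
        cv.add(Line(x, y - 3, x, y + 3, "#000000"))
        cv.add(Text(x - 18, y - 6, f"{pos}", size=8))
    cv.add(Text(2, y, view.chrom, size=9))
    cv.y += RULER_H


def _draw_histogram(cv: _Canvas, items: Sequence[Any], color: str) -> None:
    view, width = cv.config.view, cv.config.pixel_width
    counts = interval_density_histogram(items, view, width)
    top = int(counts.max()) if counts.size else 0
    base = cv.y + HIST_H
    for b, c in enumerate(counts):
        if c == 0 or top == 0:
            continue
        h = HIST_H * (int(c) / top)  # normalized to the max bin in view
        cv.add(Rect(LABEL_W + b, base - h, 1, h, color))
    cv.add(Line(LABEL_W, base, LABEL_W + width, base, "#808080"))
    cv.y = base + ROW_GAP


def _draw_snp_track(cv: _Canvas, markers: Sequence[Any]) -> None:
    view = cv.config.view
    in_view = [m for m in markers if view.contains_pos(m.pos)]
    cv.add(Text(2, cv.y + 10, "SNPs", size=9))
    if mode_for_view(len(in_view), cv.config.pixel_width) == "histogram":
        _draw_histogram(cv, in_view, "#404040")
        return
    base = cv.y + ROW_H
    for m in in_view:
        x = cv.px(m.pos)
        cv.add(Line(x, cv.y + 2, x, base, "#404040"))
    cv.y = base + ROW_GAP


def _draw_features_track(cv: _Canvas,
                         feats: Sequence[tuple[GenomicInterval, str]]) -> None:
    view = cv.config.view
    in_view = [(iv, lab) for iv, lab in feats
               if iv.end_pos >= view.start_pos and iv.start_pos <= view.end_pos]
    cv.add(Text(2, cv.y + 10, "features", size=9))
    if mode_for_view(len(in_view), cv.config.pixel_width) == "histogram":
        _draw_histogram(cv, [iv for iv, _ in in_view], "#2b6cd4")
        return
    for iv, _lab in in_view:
        x0, x1 = cv.px(iv.start_pos), cv.px(iv.end_pos)
        cv.add(Rect(x0, cv.y + 2, max(x1 - x0, 1), ROW_H - 4, "#2b6cd4"))
    cv.y += ROW_H + ROW_GAP


def _draw_intervals_track(cv: _Canvas,
                          intervals: Sequence[CompatibleInterval]) -> None:
    """Compatible intervals on two alternating parity rows."""
    view = cv.config.view
    in_view = [iv for iv in intervals
               if iv.bounds.end_pos >= view.start_pos
               and iv.bounds.start_pos <= view.end_pos]
    cv.add(Text(2, cv.y + 10, "intervals", size=9))
    if mode_for_view(len(in_view), cv.config.pixel_width) == "histogram":
        _draw_histogram(cv, [iv.bounds for iv in in_view], "#2b6cd4")
        return
    for iv in in_view:
        row = 0 if iv.parity == "even" else 1
        x0, x1 = cv.px(iv.bounds.start_pos), cv.px(iv.bounds.end_pos)
        cv.add(Rect(x0, cv.y + 2 + row * (ROW_H - 2),
                    max(x1 - x0, 1), ROW_H - 4, "#2b6cd4"))
    cv.y += 2 * ROW_H + ROW_GAP


def _draw_ibd_track(cv: _Canvas, blocks: Sequence[IBDInterval]) -> None:
    view = cv.config.view
    cv.add(Text(2, cv.y + 10, "IBD", size=9))
    for b in blocks:
        if b.bounds.end_pos < view.start_pos or b.bounds.start_pos > view.end_pos:
            continue
        x0, x1 = cv.px(b.bounds.start_pos), cv.px(b.bounds.end_pos)
        cv.add(Rect(x0, cv.y + 2, max(x1 - x0, 1), ROW_H - 4, IBD_COLOR))
    cv.y += ROW_H + ROW_GAP


def _draw_segment_rows(cv: _Canvas,
                       segments: dict[str, Sequence[MosaicInterval]],
                       colors: dict[str, str],
                       order: Sequence[str] | None,
                       title: str) -> None:
    view = cv.config.view
    cv.add(Text(2, cv.y + 10, title, size=9))
    cv.y += ROW_H
    names = list(order) if order else sorted(segments)
    for name in names:
        for seg in segments[name]:
            if (seg.bounds.end_pos < view.start_pos
                    or seg.bounds.start_pos > view.end_pos):
                continue
            x0, x1 = cv.px(seg.bounds.start_pos), cv.px(seg.bounds.end_pos)
            cv.add(Rect(x0, cv.y + 1, max(x1 - x0, 1), ROW_H - 2,
                        colors.get(seg.label, "#808080")))
        cv.add(Text(2, cv.y + ROW_H - 3, name, size=8))
        cv.y += ROW_H + ROW_GAP
    cv.y += TRACK_GAP - ROW_GAP


def _draw_mosaic_track(cv: _Canvas, mosaic: ColorMosaic,
                       bounds: Sequence[GenomicInterval],
                       order: Sequence[str] | None,
                       alleles: GenotypeMatrix | None) -> None:
    """Haplotype color mosaic; allele letters overlaid in detail mode."""
    view = cv.config.view
    cv.add(Text(2, cv.y + 10, "haplotypes", size=9))
    cv.y += ROW_H
    names = list(order) if order else list(mosaic.strains)
    visible = [t for t, b in enumerate(bounds)
               if b.end_pos >= view.start_pos and b.start_pos <= view.end_pos]
    overlay = None
    if alleles is not None:
        in_view = [j for j, m in enumerate(alleles.markers)
                   if view.contains_pos(m.pos)]
        if mode_for_view(len(in_view), cv.config.pixel_width) == "detail":
            overlay = in_view  # alleles shown only at fine scales
    for name in names:
        i = mosaic.strains.index(name)
        for t in visible:
            b = bounds[t]
            x0, x1 = cv.px(b.start_pos), cv.px(b.end_pos)
            color = PALETTE[int(mosaic.colors[i, t]) % len(PALETTE)]
            cv.add(Rect(x0, cv.y + 1, max(x1 - x0, 1), ROW_H - 2, color))
        if overlay is not None and name in alleles.strains:
            ai = alleles.strain_index(name)
            for j in overlay:
                major, minor = alleles.allele_labels[j]
                code = int(alleles.calls[ai, j])
                letter = {0: major, 1: minor, 2: "H"}.get(code, "N")
                cv.add(Text(cv.px(alleles.markers[j].pos) - 2,
                            cv.y + ROW_H - 3, letter, size=7))
        cv.add(Text(2, cv.y + ROW_H - 3, name, size=8))
        cv.y += ROW_H + ROW_GAP
    cv.y += TRACK_GAP - ROW_GAP


def render_tracks(config: RenderConfig, data: dict[str, Any],
                  path: str | os.PathLike) -> None:
    """Render the configured tracks to ``path``.

    ``data`` maps each track's ``data`` key to its payload:

    - ``snp``: sequence of :class:`Marker`
    - ``features``: sequence of ``(GenomicInterval, label)``
    - ``intervals``: sequence of :class:`CompatibleInterval`
    - ``ibd``: sequence of :class:`IBDInterval`
    - ``mosaic``: ``{"colors": ColorMosaic, "bounds": [GenomicInterval, ...],
      "alleles": GenotypeMatrix (optional)}``
    - ``origin`` / ``het``: ``{strain: [MosaicInterval, ...]}``
    """
    cv = _Canvas(config)
    _draw_ruler(cv)
    for spec in config.tracks:
        if spec.data not in data:
            raise KeyError(f"track data key {spec.data!r} missing")
        payload = data[spec.data]
        if spec.kind == "snp":
            _draw_snp_track(cv, payload)
        elif spec.kind == "features":
            _draw_features_track(cv, payload)
        elif spec.kind == "intervals":
            _draw_intervals_track(cv, payload)
        elif spec.kind == "ibd":
            _draw_ibd_track(cv, payload)
        elif spec.kind == "mosaic":
            _draw_mosaic_track(cv, payload["colors"], payload["bounds"],
                               spec.strain_order, payload.get("alleles"))
        elif spec.kind == "origin":
            _draw_segment_rows(cv, payload, SUBSPECIES_COLORS,
                               spec.strain_order, "origin")
        elif spec.kind == "het":
            _draw_segment_rows(cv, payload, HET_COLORS,
                               spec.strain_order, "heterozygosity")
        cv.y += TRACK_GAP
    width = LABEL_W + config.pixel_width + 10
    height = max(cv.y + 10, RULER_H + 10)
    if config.output_format == "svg":
        with open(path, "w") as fh:
            fh.write(to_svg(cv.items, width, height))
    else:
        _rasterize_png(cv.items, width, height, path)


def _rasterize_png(items: Sequence[Rect | Line | Text], width: float,
                   height: float, path: str | os.PathLike) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(width / 100, height / 100), dpi=100)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # SVG-style y-down
    ax.axis("off")
    for it in items:
        if isinstance(it, Rect):
            ax.add_patch(Rectangle((it.x, it.y), it.w, it.h,
                                   facecolor=it.fill, edgecolor="none"))
        elif isinstance(it, Line):
            ax.plot([it.x1, it.x2], [it.y1, it.y2], color=it.stroke, lw=1)
        else:
            ax.text(it.x, it.y, it.s, fontsize=it.size * 0.75,
                    family="monospace", color=it.fill)
    fig.savefig(path, format="png")
    plt.close(fig)
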