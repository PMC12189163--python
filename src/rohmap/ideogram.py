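"""Multi-sample autozygosity ideograms.

Chromosomes are drawn to scale with one track per sample; autozygous
regions appear as pale blue (affected) or pink (unaffected) bands, with
regions common to all affected samples overlaid in dark blue and
gene-position markers as red lines.  Layouts: linear (chromosome rows,
tracks top-to-bottom in sample order) or circular (concentric rings,
outermost first).

SVG output is authored directly so identical input yields a
byte-identical file (no timestamps, fixed element order and number
formatting); PNG/PDF are rendered from the same geometry with
matplotlib.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import RegionSet
from .synthetic import AUTOSOME_LENGTHS_BP

DEFAULT_COLORS = {
    "affected": "#aecde1",
    "unaffected": "#f2b8c6",
    "shared": "#1f4e9c",
    "marker": "#cc0000",
    "outline": "#555555",
    "text": "#222222",
}


@dataclass
class PlotSpec:
    """Everything one render needs: samples in track order, optional
    shared overlay, markers, layout and chromosome lengths."""

    samples: list[tuple[str, RegionSet, str]]  # (id, regions, affected|unaffected)
    shared: RegionSet | None = None
    markers: list[tuple[str, int, str]] = field(default_factory=list)
    layout: str = "linear"  # "linear" | "circular"
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(AUTOSOME_LENGTHS_BP)
    )
    colors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self) -> None:
        for s, _, status in self.samples:
            if status not in ("affected", "unaffected"):
                raise ValueError(f"sample {s}: unknown status {status!r}")
        for chrom, pos, label in self.markers:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"marker {label!r}: unknown chromosome {chrom!r}")
        if self.layout not in ("linear", "circular"):
            raise ValueError(f"unknown layout {self.layout!r}")


# ---------------------------------------------------------------------------
# geometry -> drawing primitives
# ---------------------------------------------------------------------------

_TRACK_H = 9.0
_ROW_GAP = 14.0
_WIDTH = 1000.0
_MARGIN_L, _MARGIN_R, _MARGIN_T = 60.0, 30.0, 30.0


def _linear_primitives(spec: PlotSpec) -> list[tuple]:
    chroms = sorted(spec.chrom_lengths, key=lambda c: int(c) if c.isdigit() else 99)
    max_len = max(spec.chrom_lengths.values())
    x_scale = (_WIDTH - _MARGIN_L - _MARGIN_R) / max_len
    n_tracks = max(1, len(spec.samples))
    row_h = n_tracks * _TRACK_H
    prims: list[tuple] = []
    y = _MARGIN_T
    y_of = {}
    for chrom in chroms:
        y_of[chrom] = y
        w = spec.chrom_lengths[chrom] * x_scale
        prims.append(
            ("rect", _MARGIN_L, y, w, row_h, "none", spec.colors["outline"], f"chrom-{chrom}")
        )
        prims.append(
            ("text", _MARGIN_L - 8, y + row_h / 2 + 3, chrom, "end", spec.colors["text"])
        )
        y += row_h + _ROW_GAP
    height = y
    # per-sample bands
    for t, (sid, regions, status) in enumerate(spec.samples):
        fill = spec.colors[status]
        for r in regions.regions:
            if r.chrom not in y_of:
                continue
            x = _MARGIN_L + (r.start - 1) * x_scale
            w = max(0.5, r.length * x_scale)
            prims.append(
                ("rect", x, y_of[r.chrom] + t * _TRACK_H, w, _TRACK_H, fill, "none",
                 f"band-{sid}")
            )
    # shared overlay on top of sample bands
    if spec.shared is not None:
        for r in spec.shared.regions:
            if r.chrom not in y_of:
                continue
            x = _MARGIN_L + (r.start - 1) * x_scale
            w = max(0.5, r.length * x_scale)
            prims.append(
                ("rect", x, y_of[r.chrom], w, row_h, spec.colors["shared"], "none",
                 "band-shared")
            )
    for chrom, pos, label in spec.markers:
        x = _MARGIN_L + (pos - 1) * x_scale
        y0 = y_of[chrom]
        prims.append(("line", x, y0 - 4, x, y0 + row_h + 4, spec.colors["marker"], f"marker-{label}"))
        prims.append(("text", x + 3, y0 - 6, label, "start", spec.colors["marker"]))
    return [("size", _WIDTH, height)] + prims


def _circular_primitives(spec: PlotSpec) -> list[tuple]:
    chroms = sorted(spec.chrom_lengths, key=lambda c: int(c) if c.isdigit() else 99)
    total = sum(spec.chrom_lengths.values())
    gap_deg = 2.0
    span_deg = 360.0 - gap_deg * len(chroms)
    n_tracks = max(1, len(spec.samples))
    ring_h = 14.0
    r_outer = 320.0
    cx = cy = 360.0
    # chromosome -> (start_angle, deg_per_bp); angles clockwise from 12 o'clock
    a = -90.0
    angle_of: dict[str, tuple[float, float]] = {}
    for chrom in chroms:
        deg = span_deg * spec.chrom_lengths[chrom] / total
        angle_of[chrom] = (a, deg / spec.chrom_lengths[chrom])
        a += deg + gap_deg
    prims: list[tuple] = [("size", 2 * cx, 2 * cy)]
    for t in range(n_tracks):
        r1 = r_outer - t * (ring_h + 4.0)
        r0 = r1 - ring_h
        for chrom in chroms:
            a0, per_bp = angle_of[chrom]
            a1 = a0 + per_bp * spec.chrom_lengths[chrom]
            prims.append(
                ("arcband", cx, cy, r0, r1, a0, a1, "none", spec.colors["outline"],
                 f"chrom-{chrom}-t{t}")
            )
    for chrom in chroms:  # labels outside the outer ring
        a0, per_bp = angle_of[chrom]
        mid = np.radians(a0 + per_bp * spec.chrom_lengths[chrom] / 2)
        prims.append(
            ("text", cx + (r_outer + 14) * np.cos(mid), cy + (r_outer + 14) * np.sin(mid) + 3,
             chrom, "middle", spec.colors["text"])
        )
    for t, (sid, regions, status) in enumerate(spec.samples):
        r1 = r_outer - t * (ring_h + 4.0)
        r0 = r1 - ring_h
        fill = spec.colors[status]
        for r in regions.regions:
            if r.chrom not in angle_of:
                continue
            a0, per_bp = angle_of[r.chrom]
            prims.append(
                ("arcband", cx, cy, r0, r1, a0 + (r.start - 1) * per_bp,
                 a0 + r.end * per_bp, fill, "none", f"band-{sid}")
            )
    r_in_all = r_outer - n_tracks * (ring_h + 4.0) + 4.0
    if spec.shared is not None:
        for r in spec.shared.regions:
            if r.chrom not in angle_of:
                continue
            a0, per_bp = angle_of[r.chrom]
            prims.append(
                ("arcband", cx, cy, r_in_all, r_outer, a0 + (r.start - 1) * per_bp,
                 a0 + r.end * per_bp, spec.colors["shared"], "none", "band-shared")
            )
    for chrom, pos, label in spec.markers:
        a0, per_bp = angle_of[chrom]
        ang = np.radians(a0 + (pos - 1) * per_bp)
        x0, y0 = cx + (r_in_all - 6) * np.cos(ang), cy + (r_in_all - 6) * np.sin(ang)
        x1, y1 = cx + (r_outer + 6) * np.cos(ang), cy + (r_outer + 6) * np.sin(ang)
        prims.append(("line", x0, y0, x1, y1, spec.colors["marker"], f"marker-{label}"))
        prims.append(("text", x1, y1 - 4, label, "middle", spec.colors["marker"]))
    return prims


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _arc_path(cx, cy, r0, r1, a0, a1) -> str:
    """Annular sector path (angles in degrees, SVG y-down space)."""
    a0r, a1r = np.radians(a0), np.radians(a1)
    large = "1" if (a1 - a0) % 360 > 180 else "0"
    p = [
        f"M {_fmt(cx + r1 * np.cos(a0r))} {_fmt(cy + r1 * np.sin(a0r))}",
        f"A {_fmt(r1)} {_fmt(r1)} 0 {large} 1 "
        f"{_fmt(cx + r1 * np.cos(a1r))} {_fmt(cy + r1 * np.sin(a1r))}",
        f"L {_fmt(cx + r0 * np.cos(a1r))} {_fmt(cy + r0 * np.sin(a1r))}",
        f"A {_fmt(r0)} {_fmt(r0)} 0 {large} 0 "
        f"{_fmt(cx + r0 * np.cos(a0r))} {_fmt(cy + r0 * np.sin(a0r))}",
        "Z",
    ]
    return " ".join(p)


def _render_svg(prims: list[tuple], path: Path) -> None:
    size = prims[0]
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(size[1])}" '
        f'height="{_fmt(size[2])}" viewBox="0 0 {_fmt(size[1])} {_fmt(size[2])}">',
    ]
    for p in prims[1:]:
        kind = p[0]
        if kind == "rect":
            _, x, y, w, h, fill, stroke, klass = p
            lines.append(
                f'<rect class="{klass}" x="{_fmt(x)}" y="{_fmt(y)}" '
                f'width="{_fmt(w)}" height="{_fmt(h)}" fill="{fill}" '
                f'stroke="{stroke}" stroke-width="0.75"/>'
            )
        elif kind == "arcband":
            _, cx, cy, r0, r1, a0, a1, fill, stroke, klass = p
            lines.append(
                f'<path class="{klass}" d="{_arc_path(cx, cy, r0, r1, a0, a1)}" '
                f'fill="{fill}" stroke="{stroke}" stroke-width="0.75"/>'
            )
        elif kind == "line":
            _, x0, y0, x1, y1, stroke, klass = p
            lines.append(
                f'<line class="{klass}" x1="{_fmt(x0)}" y1="{_fmt(y0)}" '
                f'x2="{_fmt(x1)}" y2="{_fmt(y1)}" stroke="{stroke}" '
                f'stroke-width="1.25"/>'
            )
        elif kind == "text":
            _, x, y, s, anchor, fill = p
            lines.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="Helvetica" '
                f'font-size="10" text-anchor="{anchor}" fill="{fill}">{s}</text>'
            )
    lines.append("</svg>")
    path.write_text("\n".join(lines) + "\n")


def _render_matplotlib(prims: list[tuple], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle, Wedge

    size = prims[0]
    fig, ax = plt.subplots(figsize=(size[1] / 96, size[2] / 96), dpi=96)
    ax.set_xlim(0, size[1])
    ax.set_ylim(size[2], 0)  # y-down like SVG
    ax.axis("off")
    for p in prims[1:]:
        kind = p[0]
        if kind == "rect":
            _, x, y, w, h, fill, stroke, _k = p
            ax.add_patch(
                Rectangle(
                    (x, y), w, h,
                    facecolor=fill if fill != "none" else "none",
                    edgecolor=stroke if stroke != "none" else "none",
                    linewidth=0.75,
                )
            )
        elif kind == "arcband":
            _, cx, cy, r0, r1, a0, a1, fill, stroke, _k = p
            ax.add_patch(
                Wedge(
                    (cx, cy), r1, a0, a1, width=r1 - r0,
                    facecolor=fill if fill != "none" else "none",
                    edgecolor=stroke if stroke != "none" else "none",
                    linewidth=0.75,
                )
            )
        elif kind == "line":
            _, x0, y0, x1, y1, stroke, _k = p
            ax.plot([x0, x1], [y0, y1], color=stroke, linewidth=1.25)
        elif kind == "text":
            _, x, y, s, anchor, fill = p
            ha = {"end": "right", "start": "left", "middle": "center"}[anchor]
            ax.text(x, y, s, ha=ha, va="bottom", fontsize=8, color=fill)
    fig.savefig(path, metadata={"CreationDate": None} if path.suffix == ".pdf" else None)
    plt.close(fig)


def render(spec: PlotSpec, out: str | Path) -> Path:
    """Render the ideogram to ``out`` (.svg, .png or .pdf)."""
    out = Path(out)
    prims = (
        _linear_primitives(spec)
        if spec.layout == "linear"
        else _circular_primitives(spec)
    )
    if out.suffix.lower() == ".svg":
        _render_svg(prims, out)
    elif out.suffix.lower() in (".png", ".pdf"):
        _render_matplotlib(prims, out)
    else:
        raise ValueError(f"unsupported output format {out.suffix!r}")
    return out
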