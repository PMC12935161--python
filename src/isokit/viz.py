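"""Figure rendering: DE, DIU and functional-feature panels.

Every panel is built as a structured drawing model — a flat list of shapes
(rectangles, lines, text) carrying a semantic ``role`` and a ``meta`` dict —
shared by all outputs.  Tests make geometric assertions on that model
directly (exon widths, bar lengths, guide positions) instead of on pixels;
the SVG writer serializes it deterministically (fixed float formatting, no
timestamps), and PNG/PDF go through matplotlib.

All panels share the locus track: one lane per isoform on a common display
axis with introns compressed to a fixed width (default 100 display units),
exons as boxes (CDS thick, UTR thin) and a vertical auxiliary guide line at
every distinct transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IsokitError
from .genemodels import DisplayMap, GeneModel, Transcript, build_display_map, tss
from .diffexpr import DEResult, SampleDesign
from .diffusage import DIUResult
from .features import (NonPositionalFeature, PositionalFeature,
                       project_positional_feature)

__all__ = [
    "Rect", "Line", "Text", "Drawing", "FigureSpec",
    "render_locus_track", "render_de_panel", "render_diu_panel",
    "render_ff_panel", "drawing_to_svg", "save_drawing",
]

# layout constants (display units)
LANE_H = 14.0
LANE_GAP = 10.0
THIN_FRAC = 0.4          # UTR box height relative to lane height
PANEL_GAP = 60.0
PANEL_W = 220.0
MARGIN = 30.0
LABEL_W = 150.0

COLORS = {
    "exon": "#9ecae1",
    "cds": "#3182bd",
    "intron": "#636363",
    "tss_guide": "#d62728",
    "control": "#74c476",
    "case": "#fd8d3c",
    "domain": "#756bb1",
    "signal_peptide": "#e6550d",
    "nls": "#31a354",
    "custom": "#969696",
    "text": "#000000",
    "delta_pos": "#d62728",
    "delta_neg": "#3182bd",
}


@dataclass
class Rect:
    x: float
    y: float
    w: float
    h: float
    role: str
    color: str
    meta: dict = field(default_factory=dict)


@dataclass
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    role: str
    color: str
    meta: dict = field(default_factory=dict)


@dataclass
class Text:
    x: float
    y: float
    text: str
    role: str
    size: float = 9.0
    anchor: str = "start"
    meta: dict = field(default_factory=dict)


@dataclass
class Drawing:
    width: float
    height: float
    shapes: list = field(default_factory=list)

    def by_role(self, role: str) -> list:
        return [s for s in self.shapes if s.role == role]


@dataclass
class FigureSpec:
    """Configuration of one rendered figure."""

    gene_id: str
    panel: str  # de | diu | ff
    intron_display_length: int = 100
    control_label: str = "control"
    case_label: str = "case"
    fmt: str = "svg"  # svg | png | pdf
    sort_order: list[str] | None = None

    def __post_init__(self) -> None:
        if self.panel not in ("de", "diu", "ff"):
            raise IsokitError(f"unknown panel {self.panel!r}")
        if self.fmt not in ("svg", "png", "pdf"):
            raise IsokitError(f"unsupported output format {self.fmt!r}")


def _lane_order(model: GeneModel, sort_order: list[str] | None) -> list[Transcript]:
    if sort_order:
        return [model.transcript(t) for t in sort_order]
    # annotated isoforms first, then by id
    return sorted(model.transcripts,
                  key=lambda t: (t.attributes.get("orf_source") == "predicted",
                                 t.transcript_id))


def render_locus_track(model: GeneModel, dmap: DisplayMap,
                       highlight_cds: bool = True,
                       sort_order: list[str] | None = None,
                       x0: float = 0.0, y0: float = 0.0):
    """Locus track shapes: one lane per isoform plus TSS guide lines.

    Returns (shapes, lane_y) where lane_y maps transcript_id to the lane's
    vertical center.
    """
    lanes = _lane_order(model, sort_order)
    shapes: list = []
    lane_y: dict[str, float] = {}
    for i, tx in enumerate(lanes):
        yc = y0 + i * (LANE_H + LANE_GAP) + LANE_H / 2
        lane_y[tx.transcript_id] = yc
        span = tx.span()
        shapes.append(Line(
            x0 + dmap.to_display(span.start), yc, x0 + dmap.to_display(span.end), yc,
            role="intron", color=COLORS["intron"],
            meta={"transcript_id": tx.transcript_id},
        ))
        cds = tx.cds if (highlight_cds and tx.cds) else []
        for e in tx.exons:
            xs = x0 + dmap.to_display(e.start)
            xe = x0 + dmap.to_display(e.end)
            shapes.append(Rect(
                xs, yc - LANE_H * THIN_FRAC / 2, xe - xs, LANE_H * THIN_FRAC,
                role="exon", color=COLORS["exon"],
                meta={"transcript_id": tx.transcript_id,
                      "genomic_length": len(e)},
            ))
        for c in cds:
            xs = x0 + dmap.to_display(c.start)
            xe = x0 + dmap.to_display(c.end)
            shapes.append(Rect(
                xs, yc - LANE_H / 2, xe - xs, LANE_H,
                role="cds", color=COLORS["cds"],
                meta={"transcript_id": tx.transcript_id,
                      "genomic_length": len(c)},
            ))
        shapes.append(Text(
            x0 - 8.0, yc + 3.0, tx.transcript_id, role="lane_label",
            anchor="end", meta={"transcript_id": tx.transcript_id},
        ))
    track_h = len(lanes) * (LANE_H + LANE_GAP)
    tss_displays = sorted({round(dmap.to_display(tss(tx)), 6) for tx in lanes})
    for xd in tss_displays:
        shapes.append(Line(
            x0 + xd, y0 - 4.0, x0 + xd, y0 + track_h - LANE_GAP + 4.0,
            role="tss_guide", color=COLORS["tss_guide"], meta={"display_x": xd},
        ))
    return shapes, lane_y


def _track_figure_base(model: GeneModel, intron_display_length: int,
                       sort_order: list[str] | None):
    dmap = build_display_map(model, intron_display_length)
    x0 = MARGIN + LABEL_W
    y0 = MARGIN + 14.0
    shapes, lane_y = render_locus_track(model, dmap, True, sort_order, x0, y0)
    title = model.gene_name or model.gene_id
    shapes.insert(0, Text(x0, MARGIN, title, role="title", size=12.0))
    return dmap, x0, y0, shapes, lane_y


def _boxplot(x: float, yc: float, h: float, values: np.ndarray, width: float,
             lo: float, hi: float, group: str, transcript_id: str) -> list:
    """Horizontal box plot of ``values`` scaled into [lo, hi] -> [x, x+width]."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    vmin, vmax = float(values.min()), float(values.max())
    scale = width / (hi - lo) if hi > lo else 0.0
    sx = lambda v: x + (v - lo) * scale
    color = COLORS[group]
    meta = {"transcript_id": transcript_id, "group": group,
            "median": float(med), "q1": float(q1), "q3": float(q3)}
    return [
        Line(sx(vmin), yc, sx(q1), yc, role="box_whisker", color=color, meta=meta),
        Line(sx(q3), yc, sx(vmax), yc, role="box_whisker", color=color, meta=meta),
        Rect(sx(q1), yc - h / 2, max(sx(q3) - sx(q1), 0.01), h, role="box",
             color=color, meta=meta),
        Line(sx(med), yc - h / 2, sx(med), yc + h / 2, role="box_median",
             color="#000000", meta=meta),
    ]


def render_de_panel(model: GeneModel, de_results: list[DEResult],
                    log_cpm: dict[str, dict[str, float]] | "object",
                    design: SampleDesign, alpha: float = 0.05,
                    intron_display_length: int = 100,
                    sort_order: list[str] | None = None) -> Drawing:
    """DE panel: locus track, per-isoform log2 CPM box plots, q/log2FC text.

    ``log_cpm`` is a pandas DataFrame (transcripts x samples) of log2 CPM.
    Isoforms without an expression row render as "n/a"; significance is
    marked when q < alpha.
    """
    dmap, x0, y0, shapes, lane_y = _track_figure_base(
        model, intron_display_length, sort_order)
    res = {r.transcript_id: r for r in de_results}
    bx = x0 + dmap.span + PANEL_GAP
    tids = list(lane_y)
    have = [t for t in tids if t in getattr(log_cpm, "index", [])]
    if have:
        allvals = np.concatenate([np.asarray(log_cpm.loc[t], dtype=float) for t in have])
        lo, hi = float(allvals.min()), float(allvals.max())
    else:
        lo, hi = 0.0, 1.0
    samples = list(getattr(log_cpm, "columns", []))
    for tid, yc in lane_y.items():
        if tid in have:
            row = np.asarray(log_cpm.loc[tid], dtype=float)
            for k, group in enumerate((design.control, design.case)):
                mask = np.array([design.groups[s] == group for s in samples])
                yg = yc - LANE_H / 4 + k * LANE_H / 2
                shapes.extend(_boxplot(bx, yg, LANE_H / 2 - 1, row[mask],
                                       PANEL_W, lo, hi, "control" if k == 0 else "case",
                                       tid))
        else:
            shapes.append(Text(bx, yc + 3, "n/a", role="expr_missing",
                               meta={"transcript_id": tid}))
        r = res.get(tid)
        tx_r = bx + PANEL_W + PANEL_GAP / 2
        if r is None:
            shapes.append(Text(tx_r, yc + 3, "n/a", role="de_stats",
                               meta={"transcript_id": tid}))
        else:
            star = " *" if r.q < alpha else ""
            shapes.append(Text(
                tx_r, yc + 3, f"q={r.q:.2e} log2FC={r.log2fc:+.2f}{star}",
                role="de_stats",
                meta={"transcript_id": tid, "q": r.q, "log2fc": r.log2fc,
                      "significant": bool(r.q < alpha)},
            ))
    shapes.append(Text(bx, y0 + len(lane_y) * (LANE_H + LANE_GAP) + 12,
                       "log2 CPM", role="axis_label"))
    width = tx_r + PANEL_W + MARGIN
    height = y0 + len(lane_y) * (LANE_H + LANE_GAP) + MARGIN + 14
    return Drawing(width, height, shapes)


def render_diu_panel(model: GeneModel, diu_results: list[DIUResult],
                     design: SampleDesign, alpha: float = 0.05,
                     intron_display_length: int = 100,
                     sort_order: list[str] | None = None) -> Drawing:
    """DIU panel: locus track, per-group mean usage bars, signed delta-usage
    bars annotated with transcript p-values; confirmed isoforms are marked."""
    rows = {r.transcript_id: r for r in diu_results if r.gene_id == model.gene_id}
    if not rows:
        raise IsokitError(
            f"{model.gene_id}: no DIU results (gene skipped: <2 isoforms or low count)"
        )
    dmap, x0, y0, shapes, lane_y = _track_figure_base(
        model, intron_display_length, sort_order)
    bx = x0 + dmap.span + PANEL_GAP
    dx = bx + PANEL_W + PANEL_GAP
    half = PANEL_W / 2
    for tid, yc in lane_y.items():
        r = rows.get(tid)
        if r is None:
            shapes.append(Text(bx, yc + 3, "n/a", role="usage_missing",
                               meta={"transcript_id": tid}))
            continue
        for k, (group, usage) in enumerate(
                (("control", r.usage_control), ("case", r.usage_case))):
            yg = yc - LANE_H / 4 + k * LANE_H / 2
            shapes.append(Rect(
                bx, yg - (LANE_H / 2 - 2) / 2, usage * PANEL_W, LANE_H / 2 - 2,
                role="usage_bar", color=COLORS[group],
                meta={"transcript_id": tid, "group": group, "usage": usage},
            ))
        w = r.delta_usage * half
        shapes.append(Rect(
            dx + half + min(w, 0.0), yc - LANE_H / 2 + 2, abs(w), LANE_H - 4,
            role="delta_bar",
            color=COLORS["delta_pos" if r.delta_usage >= 0 else "delta_neg"],
            meta={"transcript_id": tid, "delta_usage": r.delta_usage},
        ))
        mark = " *" if r.confirmed else ""
        shapes.append(Text(
            dx + PANEL_W + 8, yc + 3,
            f"P={r.tx_p:.2e} dU={100 * r.delta_usage:+.1f}pp{mark}",
            role="diu_stats",
            meta={"transcript_id": tid, "tx_p": r.tx_p,
                  "delta_usage": r.delta_usage, "confirmed": bool(r.confirmed)},
        ))
    shapes.append(Line(dx + half, y0 - 4, dx + half,
                       y0 + len(lane_y) * (LANE_H + LANE_GAP) - LANE_GAP + 4,
                       role="delta_axis", color="#999999"))
    shapes.append(Text(bx, y0 + len(lane_y) * (LANE_H + LANE_GAP) + 12,
                       "mean usage", role="axis_label"))
    width = dx + PANEL_W + 160 + MARGIN
    height = y0 + len(lane_y) * (LANE_H + LANE_GAP) + MARGIN + 14
    return Drawing(width, height, shapes)


def render_ff_panel(model: GeneModel, positional: list[PositionalFeature],
                    non_positional: list[NonPositionalFeature],
                    intron_display_length: int = 100,
                    sort_order: list[str] | None = None) -> Drawing:
    """Feature panel: positional features on the track, attribute columns on
    the right (binary glyph / categorical tag / max-normalized bar)."""
    dmap, x0, y0, shapes, lane_y = _track_figure_base(
        model, intron_display_length, sort_order)
    txs = {t.transcript_id: t for t in model.transcripts}
    skipped: list[str] = []
    for f in positional:
        tx = txs.get(f.transcript_id)
        if tx is None or f.transcript_id not in lane_y:
            skipped.append(f.label)
            continue
        try:
            segments, projected = project_positional_feature(f, tx)
        except IsokitError:
            skipped.append(f.label)
            continue
        yc = lane_y[f.transcript_id]
        for iv in segments:
            xs = x0 + dmap.to_display(iv.start)
            xe = x0 + dmap.to_display(iv.end)
            shapes.append(Rect(
                xs, yc + LANE_H / 2 + 2, xe - xs, 4.0,
                role=f"feature_{f.kind}", color=COLORS.get(f.kind, COLORS["custom"]),
                meta={"transcript_id": f.transcript_id, "label": f.label,
                      "kind": f.kind, "genomic_length": len(iv),
                      "clipped": projected.clipped},
            ))

    names = sorted({f.name for f in non_positional})
    by_key = {(f.transcript_id, f.name): f for f in non_positional}
    col_w = 70.0
    bx = x0 + dmap.span + PANEL_GAP
    for ci, name in enumerate(names):
        cx = bx + ci * col_w
        shapes.append(Text(cx, y0 - 8, name, role="column_header",
                           meta={"name": name}))
        cont_vals = [abs(float(f.value)) for f in non_positional
                     if f.name == name and f.dtype == "continuous"]
        vmax = max(cont_vals) if cont_vals else 1.0
        for tid, yc in lane_y.items():
            f = by_key.get((tid, name))
            if f is None:
                continue
            meta = {"transcript_id": tid, "name": name, "value": f.value}
            if f.dtype == "binary":
                if f.value:
                    shapes.append(Rect(cx, yc - 4, 8, 8, role="np_binary",
                                       color="#000000", meta=meta))
            elif f.dtype == "categorical":
                shapes.append(Text(cx, yc + 3, str(f.value), role="np_categorical",
                                   meta=meta))
            else:
                frac = abs(float(f.value)) / vmax if vmax > 0 else 0.0
                shapes.append(Rect(cx, yc - 4, frac * (col_w - 10), 8,
                                   role="np_continuous", color="#636363",
                                   meta={**meta, "fraction": frac}))
    if skipped:
        shapes.append(Text(x0, y0 + len(lane_y) * (LANE_H + LANE_GAP) + 12,
                           f"skipped features: {', '.join(sorted(set(skipped)))}",
                           role="warning", meta={"skipped": sorted(set(skipped))}))
    width = bx + max(len(names), 1) * col_w + MARGIN
    height = y0 + len(lane_y) * (LANE_H + LANE_GAP) + MARGIN + 14
    return Drawing(width, height, shapes)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _f(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def drawing_to_svg(d: Drawing) -> str:
    """Deterministic SVG serialization of a drawing (no timestamps/ids)."""
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(d.width)}" '
        f'height="{_f(d.height)}" viewBox="0 0 {_f(d.width)} {_f(d.height)}">',
        '<rect width="100%" height="100%" fill="#ffffff"/>',
    ]
    for s in d.shapes:
        if isinstance(s, Rect):
            out.append(
                f'<rect x="{_f(s.x)}" y="{_f(s.y)}" width="{_f(s.w)}" '
                f'height="{_f(s.h)}" fill="{s.color}" data-role="{s.role}"/>'
            )
        elif isinstance(s, Line):
            out.append(
                f'<line x1="{_f(s.x1)}" y1="{_f(s.y1)}" x2="{_f(s.x2)}" '
                f'y2="{_f(s.y2)}" stroke="{s.color}" stroke-width="1" '
                f'data-role="{s.role}"/>'
            )
        elif isinstance(s, Text):
            esc = (s.text.replace("&", "&amp;").replace("<", "&lt;")
                   .replace(">", "&gt;"))
            out.append(
                f'<text x="{_f(s.x)}" y="{_f(s.y)}" font-size="{_f(s.size)}" '
                f'font-family="sans-serif" text-anchor="{s.anchor}" '
                f'data-role="{s.role}">{esc}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _render_matplotlib(d: Drawing, path, fmt: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(d.width / 72.0, d.height / 72.0))
    for s in d.shapes:
        if isinstance(s, Rect):
            ax.add_patch(Rectangle((s.x, s.y), s.w, s.h, facecolor=s.color,
                                   edgecolor="none"))
        elif isinstance(s, Line):
            ax.plot([s.x1, s.x2], [s.y1, s.y2], color=s.color, linewidth=1.0)
        elif isinstance(s, Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[s.anchor]
            ax.text(s.x, s.y, s.text, fontsize=s.size, ha=ha, va="baseline")
    ax.set_xlim(0, d.width)
    ax.set_ylim(d.height, 0)  # SVG-style y axis (down)
    ax.axis("off")
    fig.savefig(path, format=fmt, dpi=150)
    plt.close(fig)


def save_drawing(d: Drawing, path, fmt: str = "svg") -> None:
    """Write the drawing as svg (native, byte-stable), png or pdf."""
    if fmt == "svg":
        with open(path, "w") as fh:
            fh.write(drawing_to_svg(d))
    elif fmt in ("png", "pdf"):
        _render_matplotlib(d, path, fmt)
    else:
        raise IsokitError(f"unsupported output format {fmt!r}")
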