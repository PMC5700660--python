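"""Comparative neighborhood figure and per-gene annotation records.

Each neighborhood is drawn as one row: genes are arrows whose length is
proportional to gene length, intergenic regions are lines proportional
to the gap, and the target gene always points right (flank genes point
right iff they lie on the target's strand). Arrows are filled from the
occurrence-threshold color map, neutral gray otherwise, and a legend of
colored models with their descriptions sits below the rows.

The primary output is SVG, produced by a small deterministic writer so
identical inputs give byte-identical documents; PDF export redraws the
same layout primitives through matplotlib. The clickable per-gene
annotations of an interactive browser are replaced by a JSON sidecar
holding, for every rendered gene and intergenic region, the full
annotation record (coordinates, taxonomy, accepted COG/Pfam hits with
scores and E-values, sequences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import DomainHit, ProteinAnnotation
from .genome_io import GeneRecord, GenomeError, gene_sequence
from .neighborhood import ColorMap, Neighborhood, OccurrenceTable

__all__ = [
    "RenderStyle",
    "FigureSpec",
    "render_svg",
    "render_figure",
    "emit_annotations",
    "write_legend_tsv",
]


@dataclass(frozen=True)
class RenderStyle:
    """Geometry constants of the figure (pixels)."""

    px_per_kb: float = 50.0  # horizontal scale
    row_height: float = 34.0
    arrow_height: float = 16.0
    head_len: float = 9.0  # arrow-head length, capped at the arrow width
    margin: float = 24.0
    label_width: float = 260.0
    gap_max_px: float = 80.0  # longer gaps are clipped with a break glyph
    font_size: float = 11.0
    legend_swatch: float = 12.0
    legend_row: float = 18.0


@dataclass
class FigureSpec:
    """Everything needed to draw the figure deterministically."""

    neighborhoods: list[Neighborhood]  # already in display order
    colormap: ColorMap
    occurrence: OccurrenceTable
    annotations: Mapping[str, ProteinAnnotation]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    style: RenderStyle = field(default_factory=RenderStyle)

    def legend_entries(self) -> list[tuple[str, str, str]]:
        """(accession, color, description), occurrence order, each once."""
        return [
            (acc, self.colormap.assigned[acc], self.descriptions.get(acc, ""))
            for acc, _pct in self.occurrence.items()
            if acc in self.colormap.assigned
        ]


def _gene_color(
    gene: GeneRecord, spec: FigureSpec
) -> str:
    """Fill color of a gene: its best colored model, else neutral.

    Among the gene's accepted models that carry a color, the one with
    the highest occurrence percentage wins (accession breaks ties).
    """
    if gene.protein_id is None:
        return spec.colormap.neutral
    ann = spec.annotations.get(gene.protein_id)
    if ann is None:
        return spec.colormap.neutral
    colored = [a for a in sorted(ann.accessions()) if a in spec.colormap]
    if not colored:
        return spec.colormap.neutral
    best = min(colored, key=lambda a: (-spec.occurrence.percent(a), a))
    return spec.colormap.color(best)


# ---------------------------------------------------------------- layout

def _arrow_points(
    x: float, y_mid: float, width: float, height: float, head: float,
    rightward: bool,
) -> list[tuple[float, float]]:
    h2 = height / 2.0
    hl = min(head, width)
    if rightward:
        return [
            (x, y_mid - h2), (x + width - hl, y_mid - h2), (x + width, y_mid),
            (x + width - hl, y_mid + h2), (x, y_mid + h2),
        ]
    return [
        (x + width, y_mid - h2), (x + hl, y_mid - h2), (x, y_mid),
        (x + hl, y_mid + h2), (x + width, y_mid + h2),
    ]


def _layout(spec: FigureSpec) -> tuple[list[tuple], float, float]:
    """Compute drawing primitives; returns (ops, width, height).

    Ops: ("polygon", points, fill), ("line", x1, y1, x2, y2),
    ("rect", x, y, w, h, fill), ("text", x, y, string, size).
    """
    st = spec.style
    ops: list[tuple] = []
    x_right = st.margin + st.label_width
    y = st.margin
    for nb in spec.neighborhoods:
        y_mid = y + st.row_height / 2.0
        rep = nb.replicon
        label = " | ".join(
            p for p in ("; ".join(rep.high_level_taxa), rep.organism) if p
        )
        ops.append(("text", st.margin, y_mid + st.font_size / 3.0, label, st.font_size))
        x = st.margin + st.label_width
        for i, gene in enumerate(nb.genes):
            w = gene.length(rep.length) * st.px_per_kb / 1000.0
            ops.append((
                "polygon",
                _arrow_points(x, y_mid, w, st.arrow_height, st.head_len,
                              nb.points_right(gene)),
                _gene_color(gene, spec),
            ))
            x += w
            if i < len(nb.intergaps):
                gap = nb.intergaps[i].gap_length
                gw = gap * st.px_per_kb / 1000.0
                if gw > st.gap_max_px:  # clip very long gaps, mark the break
                    gw = st.gap_max_px
                    mid = x + gw / 2.0
                    ops.append(("line", x, y_mid, x + gw, y_mid))
                    ops.append(("line", mid - 3.0, y_mid + 4.0, mid + 1.0, y_mid - 4.0))
                    ops.append(("line", mid - 1.0, y_mid + 4.0, mid + 3.0, y_mid - 4.0))
                elif gw > 0:
                    ops.append(("line", x, y_mid, x + gw, y_mid))
                x += gw
        x_right = max(x_right, x)
        y += st.row_height
    # legend below the rows
    y += st.row_height / 2.0
    for acc, color, desc in spec.legend_entries():
        ops.append(("rect", st.margin, y, st.legend_swatch, st.legend_swatch, color))
        text = f"{acc}  {desc}".rstrip()
        ops.append((
            "text", st.margin + st.legend_swatch + 6.0,
            y + st.legend_swatch - 2.0, text, st.font_size,
        ))
        y += st.legend_row
    return ops, x_right + st.margin, y + st.margin


# ---------------------------------------------------------------- writers

def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(spec: FigureSpec) -> str:
    """Serialize the figure as an SVG document (deterministic bytes)."""
    if not spec.neighborhoods:
        raise ValueError("nothing to render: zero neighborhoods")
    ops, width, height = _layout(spec)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n',
    ]
    for op in ops:
        if op[0] == "polygon":
            pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in op[1])
            parts.append(
                f'<polygon points="{pts}" fill="{op[2]}" '
                'stroke="#333333" stroke-width="0.75"/>\n'
            )
        elif op[0] == "line":
            _, x1, y1, x2, y2 = op
            parts.append(
                f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
                f'y2="{_fmt(y2)}" stroke="#333333" stroke-width="1.00"/>\n'
            )
        elif op[0] == "rect":
            _, x, y, w, h, fill = op
            parts.append(
                f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
                f'height="{_fmt(h)}" fill="{fill}" stroke="#333333" '
                'stroke-width="0.75"/>\n'
            )
        elif op[0] == "text":
            _, x, y, s, size = op
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" '
                f'font-family="Helvetica, Arial, sans-serif" '
                f'font-size="{_fmt(size)}">{_xml_escape(s)}</text>\n'
            )
    parts.append("</svg>\n")
    return "".join(parts)


def _render_pdf(spec: FigureSpec, path: str | Path) -> None:
    """Redraw the layout primitives into a PDF page via matplotlib."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon, Rectangle

    ops, width, height = _layout(spec)
    fig, ax = plt.subplots(figsize=(width / 72.0, height / 72.0))
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # match SVG's downward y axis
    ax.axis("off")
    for op in ops:
        if op[0] == "polygon":
            ax.add_patch(MplPolygon(op[1], closed=True, facecolor=op[2],
                                    edgecolor="#333333", linewidth=0.75))
        elif op[0] == "line":
            _, x1, y1, x2, y2 = op
            ax.plot([x1, x2], [y1, y2], color="#333333", linewidth=1.0)
        elif op[0] == "rect":
            _, x, y, w, h, fill = op
            ax.add_patch(Rectangle((x, y), w, h, facecolor=fill,
                                   edgecolor="#333333", linewidth=0.75))
        elif op[0] == "text":
            _, x, y, s, size = op
            ax.text(x, y, s, fontsize=size, va="baseline", ha="left")
    fig.savefig(path, format="pdf")
    plt.close(fig)


def render_figure(
    spec: FigureSpec,
    svg_path: str | Path | None = None,
    pdf_path: str | Path | None = None,
) -> str:
    """Render the figure; returns the SVG text, optionally writing files."""
    svg = render_svg(spec)
    if svg_path is not None:
        Path(svg_path).write_text(svg)
    if pdf_path is not None:
        _render_pdf(spec, pdf_path)
    return svg


def write_legend_tsv(spec: FigureSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("model_acc\tcolor\tdescription\n")
        for acc, color, desc in spec.legend_entries():
            fh.write(f"{acc}\t{color}\t{desc}\n")


# ------------------------------------------------------------- sidecar

def _hit_record(h: DomainHit) -> dict:
    return {
        "model_acc": h.model_acc,
        "ali_from": h.ali_from,
        "ali_to": h.ali_to,
        "score": h.score,
        "evalue": h.evalue,
    }


def emit_annotations(
    neighborhoods: Sequence[Neighborhood],
    annotations: Mapping[str, ProteinAnnotation],
    path: str | Path | None = None,
) -> dict:
    """Annotation records for every rendered gene and intergenic region.

    Keys are ``"<row>:gene:<slot>"`` and ``"<row>:gap:<slot>"`` with the
    row index into the display order and the slot the left-to-right
    rendered position. Gene records carry the accepted COG and Pfam
    hits verbatim (coordinates, scores, E-values), the protein and gene
    sequences when available, the genomic coordinates and the taxonomy;
    intergenic records carry coordinates, taxonomy, the sequence and
    its reverse complement.
    """
    out: dict[str, dict] = {}
    for row, nb in enumerate(neighborhoods):
        rep = nb.replicon
        for slot, gene in enumerate(nb.genes):
            ann = annotations.get(gene.protein_id) if gene.protein_id else None
            try:
                gseq = gene_sequence(rep, gene) if rep.sequence else None
            except GenomeError:
                gseq = None
            out[f"{row}:gene:{slot}"] = {
                "gene_id": gene.gene_id,
                "description": gene.product,
                "xrefs": list(gene.xrefs),
                "coordinates": {
                    "replicon": rep.replicon_id,
                    "start": gene.start,
                    "end": gene.end,
                    "strand": gene.strand.value,
                },
                "taxonomy": list(rep.taxonomy),
                "organism": rep.organism,
                "cog_hits": [_hit_record(h) for h in ann.cogs] if ann else [],
                "pfam_hits": [
                    _hit_record(h) for h in ann.pfam_architecture
                ] if ann else [],
                "protein_sequence": gene.protein_seq,
                "gene_sequence": gseq,
            }
        for slot, gap in enumerate(nb.intergaps):
            out[f"{row}:gap:{slot}"] = {
                "coordinates": {
                    "replicon": gap.replicon_id,
                    "start": gap.start,
                    "end": gap.end,
                    "empty": gap.empty,
                },
                "taxonomy": list(rep.taxonomy),
                "organism": rep.organism,
                "sequence": gap.sequence,
                "reverse_complement": gap.reverse_complement,
            }
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))
    return out
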