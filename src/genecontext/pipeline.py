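"""End-to-end neighborhood analysis: hits + genomes + query -> outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    ClanTable,
    DomainHit,
    ProteinAnnotation,
    annotate_proteins,
)
from .genome_io import GenomeSet
from .neighborhood import (
    ColorMap,
    Neighborhood,
    OccurrenceTable,
    Query,
    colorize,
    extract_neighborhood,
    find_targets,
    occurrence,
)
from .ordering import (
    Aligner,
    DisplayOrder,
    SortMode,
    identity_order,
    order_by_msa,
    order_by_taxonomy,
)
from .render import FigureSpec, RenderStyle, emit_annotations, render_figure, write_legend_tsv

__all__ = ["AnalysisResult", "run_analysis", "write_outputs"]


@dataclass
class AnalysisResult:
    """Everything the analysis computed, neighborhoods in display order."""

    query: Query
    annotations: dict[str, ProteinAnnotation]
    neighborhoods: list[Neighborhood]
    order: DisplayOrder
    occurrence: OccurrenceTable
    colormap: ColorMap
    figure: FigureSpec


def _descriptions(hits: Iterable[DomainHit]) -> dict[str, str]:
    out: dict[str, str] = {}
    for h in hits:
        if h.description and h.model_acc not in out:
            out[h.model_acc] = h.description
    return out


def run_analysis(
    genomes: GenomeSet,
    cog_hits: Sequence[DomainHit],
    pfam_hits: Sequence[DomainHit],
    query: Query | str,
    k: int = 9,
    threshold: float = 1.0,
    clans: ClanTable | None = None,
    sort: SortMode = SortMode.TAXONOMY,
    aligner: Aligner | None = None,
    sequences: Mapping[str, str] | None = None,
    palette_seed: int = 0,
    min_score: float = 25.0,
    min_len_frac: float = 0.25,
    max_overlap_frac: float = 0.5,
    style: RenderStyle | None = None,
) -> AnalysisResult:
    """Run the full analysis for one COG/Pfam query.

    Annotates every protein with raw hits, finds all target genes for
    the query, extracts orientation-normalized windows of ``k`` genes,
    sorts them (taxonomy by default; MSA when an aligner and the target
    sequences are supplied), computes the occurrence table and the
    color map at the given threshold, and assembles the figure spec.
    """
    if isinstance(query, str):
        query = Query.from_accession(query)
    annotations = annotate_proteins(
        cog_hits, pfam_hits, min_score, min_len_frac, max_overlap_frac
    )
    targets = find_targets(annotations, genomes, query)
    neighborhoods = [
        extract_neighborhood(genomes.by_protein(t.protein_id)[0], t, k)
        for t in targets
    ]
    if not neighborhoods:
        order = identity_order(0)
    elif sort is SortMode.TAXONOMY:
        order = order_by_taxonomy(neighborhoods)
    elif sort is SortMode.MSA:
        if aligner is None or sequences is None:
            raise ValueError("MSA ordering needs an aligner and target sequences")
        order = order_by_msa(neighborhoods, sequences, aligner)
    else:
        order = identity_order(len(neighborhoods))
    ordered = order.apply(neighborhoods)
    occ = occurrence(ordered, annotations) if ordered else OccurrenceTable(0, {})
    cmap = (
        colorize(occ, threshold, clans, palette_seed)
        if ordered
        else ColorMap(assigned={}, threshold=threshold)
    )
    figure = FigureSpec(
        neighborhoods=ordered,
        colormap=cmap,
        occurrence=occ,
        annotations=annotations,
        descriptions=_descriptions([*cog_hits, *pfam_hits]),
        style=style or RenderStyle(),
    )
    return AnalysisResult(
        query=query,
        annotations=annotations,
        neighborhoods=ordered,
        order=order,
        occurrence=occ,
        colormap=cmap,
        figure=figure,
    )


def write_neighborhood_tsv(result: AnalysisResult, path: str | Path) -> None:
    """One row per rendered gene: row, slot, gene, models, colored flag."""
    with open(path, "w") as fh:
        fh.write("neighborhood\tslot\tgene_id\tmodels\tcolored\n")
        for row, nb in enumerate(result.neighborhoods):
            for slot, gene in enumerate(nb.genes):
                ann = (
                    result.annotations.get(gene.protein_id)
                    if gene.protein_id
                    else None
                )
                accs = sorted(ann.accessions()) if ann else []
                colored = any(a in result.colormap for a in accs)
                fh.write(
                    f"{row}\t{slot}\t{gene.gene_id}\t{','.join(accs)}\t"
                    f"{int(colored)}\n"
                )


def write_outputs(result: AnalysisResult, out_dir: str | Path, pdf: bool = True) -> None:
    """Write figure (SVG + PDF), tables and the JSON annotation sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.neighborhoods:
        render_figure(
            result.figure,
            svg_path=out / "figure.svg",
            pdf_path=(out / "figure.pdf") if pdf else None,
        )
        write_legend_tsv(result.figure, out / "legend.tsv")
        emit_annotations(
            result.neighborhoods, result.annotations, out / "annotations.json"
        )
        result.occurrence.write_tsv(out / "occurrence.tsv")
    write_neighborhood_tsv(result, out / "neighborhoods.tsv")
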