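"""Gene-neighborhood extraction and the occurrence-percentage statistic.

Given per-protein COG/Pfam annotations and a query (one COG identifier
or one Pfam accession), this module finds every target gene whose
product carries the queried model, cuts an orientation-normalized
window of 3–15 genes around each target (the target always renders
pointing right), and computes, for every model seen in the windows, the
percentage of windows that contain at least one gene annotated with it.
Models at or above a 1–100% occurrence threshold receive distinct
colors; Pfam domains sharing a clan share one color.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import ClanTable, ModelKind, ProteinAnnotation
from .genome_io import (
    GeneRecord,
    GenomeSet,
    IntergenicRegion,
    Replicon,
    Strand,
    Topology,
    intergenic,
)

__all__ = [
    "Query",
    "Neighborhood",
    "OccurrenceTable",
    "ColorMap",
    "find_targets",
    "extract_neighborhood",
    "occurrence",
    "colorize",
    "NEUTRAL_COLOR",
]

MIN_K, MAX_K = 3, 15
MIN_THRESHOLD, MAX_THRESHOLD = 1.0, 100.0

NEUTRAL_COLOR = "#c8c8c8"

_ACCESSION_RE = re.compile(r"^(COG\d{4}|PF\d{5})$")


@dataclass(frozen=True)
class Query:
    """A COG identifier (COG0001) or Pfam accession (PF00001)."""

    kind: ModelKind
    accession: str

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.match(self.accession):
            raise ValueError(
                f"accession {self.accession!r} does not match COGnnnn/PFnnnnn"
            )
        expect = ModelKind.COG if self.accession.startswith("COG") else ModelKind.PFAM
        if self.kind is not expect:
            raise ValueError(
                f"accession {self.accession} is not a {self.kind.value} accession"
            )

    @classmethod
    def from_accession(cls, accession: str) -> "Query":
        kind = ModelKind.COG if accession.startswith("COG") else ModelKind.PFAM
        return cls(kind=kind, accession=accession)


@dataclass
class Neighborhood:
    """An orientation-normalized window of genes around one target.

    ``genes`` are in left-to-right rendered order and include the
    target exactly once; ``intergaps`` interleave them (entry *i* sits
    between genes *i* and *i+1*). When the target lies on the reverse
    strand the whole window is mirrored so the target points right and
    ``flipped`` is true.
    """

    replicon: Replicon
    target: GeneRecord
    genes: list[GeneRecord]
    intergaps: list[IntergenicRegion]
    flipped: bool

    @property
    def target_slot(self) -> int:
        for i, g in enumerate(self.genes):
            if g is self.target:
                return i
        raise ValueError("target not in its own neighborhood")

    def points_right(self, gene: GeneRecord) -> bool:
        """Rendered direction: rightward iff on the target's strand."""
        return gene.strand is self.target.strand


def find_targets(
    annotations: Mapping[str, ProteinAnnotation],
    genomes: GenomeSet,
    query: Query,
) -> list[GeneRecord]:
    """All genes whose product carries the queried COG or Pfam model.

    Every paralog qualifies; there is no clustering and no cap on the
    number of targets. A gene whose protein carries the queried domain
    several times (a repeat) is returned once. An accession absent from
    all annotations yields an empty list with a warning.
    """
    targets: list[GeneRecord] = []
    for rep in genomes:
        for gene in rep.genes:
            if gene.protein_id is None:
                continue
            ann = annotations.get(gene.protein_id)
            if ann is None:
                continue
            members = (
                ann.cog_accessions
                if query.kind is ModelKind.COG
                else ann.pfam_accessions
            )
            if query.accession in members:
                targets.append(gene)
    if not targets:
        warnings.warn(
            f"no gene product is annotated with {query.accession}",
            stacklevel=2,
        )
    return targets


def extract_neighborhood(
    replicon: Replicon, target: GeneRecord, k: int
) -> Neighborhood:
    """Cut a window of up to ``k`` genes centered on the target.

    ``k`` counts total genes including the target and must lie in
    [3, 15]. The window is centered in gene-order index space; for even
    ``k`` the extra gene falls on the *rendered* right of the target.
    Windows truncate at the ends of a linear replicon and wrap on a
    circular one. A reverse-strand target mirrors the window.
    """
    if not (MIN_K <= k <= MAX_K):
        raise ValueError(f"neighborhood size k={k} outside [{MIN_K}, {MAX_K}]")
    idx = replicon.gene_index(target)
    n = len(replicon.genes)
    flipped = target.strand is Strand.REVERSE
    left = (k - 1) // 2
    right = k - 1 - left
    if flipped:  # extra gene on the rendered right = genomic left
        left, right = right, left
    if replicon.topology is Topology.CIRCULAR:
        take = min(k, n)
        if take < k:
            left = (take - 1) // 2
            right = take - 1 - left
            if flipped:
                left, right = right, left
        indices = [(idx + d) % n for d in range(-left, right + 1)]
    else:
        lo = max(0, idx - left)
        hi = min(n - 1, idx + right)
        indices = list(range(lo, hi + 1))
    genes = [replicon.genes[i] for i in indices]
    gaps = [
        intergenic(replicon, replicon.genes[a], replicon.genes[b])
        for a, b in zip(indices, indices[1:])
    ]
    if flipped:
        genes = genes[::-1]
        gaps = gaps[::-1]
    return Neighborhood(
        replicon=replicon, target=target, genes=genes, intergaps=gaps,
        flipped=flipped,
    )


def _models_of(gene: GeneRecord, annotations: Mapping[str, ProteinAnnotation]) -> frozenset[str]:
    if gene.protein_id is None:
        return frozenset()
    ann = annotations.get(gene.protein_id)
    return ann.accessions() if ann is not None else frozenset()


@dataclass
class OccurrenceTable:
    """Per-model neighborhood-presence percentages.

    A model is counted at most once per neighborhood (presence, not raw
    gene count); the target gene participates, so the queried model
    shows 100% when every target is annotated with it.
    """

    n_total: int
    n_present: dict[str, int]

    def percent(self, accession: str) -> float:
        return 100.0 * self.n_present.get(accession, 0) / self.n_total

    def accessions(self) -> list[str]:
        return sorted(self.n_present)

    def items(self) -> list[tuple[str, float]]:
        """(accession, percent) pairs, percent descending then accession."""
        return sorted(
            ((acc, self.percent(acc)) for acc in self.n_present),
            key=lambda kv: (-kv[1], kv[0]),
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("model_acc\tn_present\tn_total\tpercent\n")
            for acc, pct in self.items():
                fh.write(f"{acc}\t{self.n_present[acc]}\t{self.n_total}\t{pct:g}\n")


def occurrence(
    neighborhoods: Sequence[Neighborhood],
    annotations: Mapping[str, ProteinAnnotation],
) -> OccurrenceTable:
    """Count, per model, the neighborhoods containing it at least once."""
    if not neighborhoods:
        raise ValueError("occurrence requires at least one neighborhood")
    counts: dict[str, int] = {}
    for nb in neighborhoods:
        present: set[str] = set()
        for gene in nb.genes:
            present |= _models_of(gene, annotations)
        for acc in present:
            counts[acc] = counts.get(acc, 0) + 1
    return OccurrenceTable(n_total=len(neighborhoods), n_present=counts)


# Qualitative base palette (colorblind-aware hues).
_PALETTE = (
    "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231",
    "#911eb4", "#46f0f0", "#f032e6", "#bcf60c", "#fabebe",
    "#008080", "#e6beff", "#9a6324", "#800000", "#aaffc3",
    "#808000", "#ffd8b1", "#000075", "#808080",
)


def _shade(hex_color: str, cycle: int) -> str:
    """Lighten a color toward white for palette reuse beyond one cycle."""
    if cycle == 0:
        return hex_color
    frac = min(0.75, 0.3 * cycle)
    r, g, b = (int(hex_color[i : i + 2], 16) for i in (1, 3, 5))
    mix = lambda c: int(round(c + (255 - c) * frac))
    return f"#{mix(r):02x}{mix(g):02x}{mix(b):02x}"


@dataclass
class ColorMap:
    """Model accession -> color, clan-aware; below threshold is neutral."""

    assigned: dict[str, str]
    threshold: float
    neutral: str = NEUTRAL_COLOR

    def color(self, accession: str) -> str:
        return self.assigned.get(accession, self.neutral)

    def __contains__(self, accession: str) -> bool:
        return accession in self.assigned


def colorize(
    occ: OccurrenceTable,
    threshold: float,
    clans: ClanTable | None = None,
    palette_seed: int = 0,
) -> ColorMap:
    """Assign palette colors to models at/above the occurrence threshold.

    Models are visited by (percent descending, accession ascending);
    all Pfam accessions sharing a clan are colored identically, the
    clan's color fixed at its first-seen member. Models below the
    threshold keep the neutral color. Assignment is deterministic for a
    given seed; when more colors are needed than the palette holds, it
    cycles with a lightened shade.
    """
    if not (MIN_THRESHOLD <= threshold <= MAX_THRESHOLD):
        raise ValueError(
            f"threshold {threshold} outside [{MIN_THRESHOLD:g}, {MAX_THRESHOLD:g}]"
        )
    clans = clans or ClanTable()
    rng = np.random.default_rng(palette_seed)
    palette = [_PALETTE[i] for i in rng.permutation(len(_PALETTE))]
    assigned: dict[str, str] = {}
    group_color: dict[str, str] = {}  # clan (or accession) -> color
    next_slot = 0
    for acc, pct in occ.items():
        if pct < threshold:
            continue
        group = clans.clan_of(acc) or acc
        if group not in group_color:
            cycle, pos = divmod(next_slot, len(palette))
            group_color[group] = _shade(palette[pos], cycle)
            next_slot += 1
        assigned[acc] = group_color[group]
    return ColorMap(assigned=assigned, threshold=threshold)
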