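"""Display ordering of neighborhoods: MSA-based or taxonomy-based.

The default ordering groups neighborhoods of closely related target
proteins by running a multiple sequence aligner over the target amino
acid sequences and taking the aligner's *output* sequence order (the
aligner's guide tree places similar sequences next to each other).
The aligner sits behind a pluggable contract — any callable mapping
``[(id, sequence), ...]`` to the list of ids in output order — so a
deterministic fake engine can stand in during tests. The alternative
ordering sorts by the organism taxonomy; paralogs of one organism stay
adjacent, ordered by coordinate.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .neighborhood import Neighborhood

__all__ = [
    "SortMode",
    "DisplayOrder",
    "Aligner",
    "order_by_msa",
    "order_by_taxonomy",
    "identity_order",
    "external_aligner",
]

logger = logging.getLogger(__name__)

#: sequences in -> ids in aligner output order
Aligner = Callable[[Sequence[tuple[str, str]]], Sequence[str]]


class SortMode(str, Enum):
    MSA = "msa"
    TAXONOMY = "taxonomy"
    NONE = "none"


@dataclass(frozen=True)
class DisplayOrder:
    """A permutation of neighborhood indices (rendered top to bottom)."""

    order: tuple[int, ...]
    mode: SortMode

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("display order is not a permutation")

    def apply(self, items: Sequence) -> list:
        return [items[i] for i in self.order]


def identity_order(n: int) -> DisplayOrder:
    return DisplayOrder(order=tuple(range(n)), mode=SortMode.NONE)


def order_by_msa(
    neighborhoods: Sequence[Neighborhood],
    sequences: Mapping[str, str],
    aligner: Aligner,
) -> DisplayOrder:
    """Order neighborhoods by the aligner's output order of their targets.

    ``sequences`` maps target protein ids to amino acid sequences. Two
    neighborhoods sharing one target protein (the same id) stay in
    input order relative to each other. Aligner failure falls back to
    input order with a logged warning; a single neighborhood is the
    identity.
    """
    n = len(neighborhoods)
    if n <= 1:
        return DisplayOrder(order=tuple(range(n)), mode=SortMode.MSA)
    ids: list[str] = []
    records: list[tuple[str, str]] = []
    for nb in neighborhoods:
        pid = nb.target.protein_id
        if pid is None or pid not in sequences:
            raise ValueError(f"no sequence for target {nb.target.gene_id}")
        ids.append(pid)
        if pid not in (r[0] for r in records):
            records.append((pid, sequences[pid]))
    try:
        out_ids = list(aligner(records))
    except Exception as exc:  # engine failure: keep input order
        logger.warning("aligner failed (%s); keeping input order", exc)
        return DisplayOrder(order=tuple(range(n)), mode=SortMode.MSA)
    if sorted(out_ids) != sorted(r[0] for r in records):
        logger.warning("aligner returned unexpected ids; keeping input order")
        return DisplayOrder(order=tuple(range(n)), mode=SortMode.MSA)
    rank = {pid: i for i, pid in enumerate(out_ids)}
    order = sorted(range(n), key=lambda i: (rank[ids[i]], i))
    return DisplayOrder(order=tuple(order), mode=SortMode.MSA)


def order_by_taxonomy(neighborhoods: Sequence[Neighborhood]) -> DisplayOrder:
    """Order neighborhoods by taxonomy lineage, then organism, then locus.

    Paralogous targets of one organism come out consecutive, ordered by
    their start coordinate. Neighborhoods without taxonomy sort last.
    """

    def key(i: int):
        nb = neighborhoods[i]
        rep = nb.replicon
        return (
            (1,) if not rep.taxonomy else (0,) + rep.taxonomy,
            rep.organism,
            rep.replicon_id,
            nb.target.start,
            i,
        )

    order = sorted(range(len(neighborhoods)), key=key)
    return DisplayOrder(order=tuple(order), mode=SortMode.TAXONOMY)


def external_aligner(
    command: Sequence[str] = ("muscle", "-maxiters", "2"),
) -> Aligner:
    """Aligner contract backed by an external executable (FASTA in/out).

    The default command matches the classic MUSCLE invocation with the
    iteration count set to two. The executable must read FASTA on stdin
    and write aligned FASTA on stdout; output record order is taken as
    the similarity grouping. Convenience plumbing; tests exercise the
    contract with an in-process fake engine instead.
    """

    def run(records: Sequence[tuple[str, str]]) -> list[str]:
        fasta = "".join(f">{pid}\n{seq}\n" for pid, seq in records)
        proc = subprocess.run(
            list(command), input=fasta, capture_output=True, text=True,
            check=True,
        )
        return [
            line[1:].split()[0]
            for line in proc.stdout.splitlines()
            if line.startswith(">")
        ]

    return run
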