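"""Profile-HMM hit filtering and domain-architecture resolution.

A profile-HMM search (e.g. ``hmmscan``) reports, for every protein, a set
of *hits*: regions whose similarity to a COG or Pfam profile HMM is
non-random, each with alignment coordinates, a bit score and an E-value.
This module turns those raw hits into per-protein annotations:

1. significance filtering — a hit is ignored if its score is below 25.0
   bits or if it covers less than 25% of the profile HMM length (both
   thresholds configurable, equality passes);
2. overlap resolution — overlapping hits are reduced by a rule cascade:
   a lower-scored hit overlapped by a higher-scored one over more than
   half of its own length is dropped; between equal-scored hits the one
   with the greater length normalized by its profile HMM length wins;
   between equal-scored, equal-normalized-length hits the longer raw hit
   wins.

COG hits and Pfam hits are resolved independently: a protein may belong
to several COGs (when the hits do not conflict) and simultaneously carry
an ordered Pfam domain architecture.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModelKind",
    "DomainHit",
    "ProteinAnnotation",
    "ClanTable",
    "HitTableColumns",
    "HitTableError",
    "parse_hit_table",
    "filter_significant",
    "resolve_overlaps",
    "annotate_protein",
    "annotate_proteins",
    "audit_hits",
    "HitVerdict",
    "write_annotation_table",
]

DEFAULT_MIN_SCORE = 25.0
DEFAULT_MIN_LEN_FRAC = 0.25
DEFAULT_MAX_OVERLAP_FRAC = 0.5

#: tolerance for the "equal normalized length" branch of the cascade
NORM_LEN_TOL = 1e-9


class ModelKind(str, Enum):
    """Kind of profile HMM a hit was scored against."""

    COG = "COG"
    PFAM = "PFAM"


class HitTableError(ValueError):
    """Raised for malformed hit-table input."""


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on one protein.

    Coordinates are 1-based inclusive residue positions on the protein
    (``ali_from <= ali_to``); ``model_len`` is the number of match
    columns of the profile HMM; ``score`` is in bits.
    """

    protein_id: str
    model_acc: str
    model_kind: ModelKind
    model_len: int
    ali_from: int
    ali_to: int
    score: float
    evalue: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.ali_from < 1 or self.ali_to < self.ali_from:
            raise ValueError(
                f"invalid alignment coordinates {self.ali_from}..{self.ali_to} "
                f"for {self.protein_id}/{self.model_acc}"
            )
        if self.model_len < 1:
            raise ValueError(f"model_len must be >= 1, got {self.model_len}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")

    @property
    def hit_length(self) -> int:
        return self.ali_to - self.ali_from + 1

    @property
    def normalized_length(self) -> float:
        """Hit length divided by the profile HMM length."""
        return self.hit_length / self.model_len


def overlap_residues(a: DomainHit, b: DomainHit) -> int:
    """Number of residues shared by the alignment spans of two hits."""
    return max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1)


@dataclass(frozen=True)
class ProteinAnnotation:
    """Accepted COG memberships and Pfam domain architecture of a protein.

    ``cogs`` and ``pfam_architecture`` hold the post-filter,
    post-resolution hits, each ordered by ``ali_from`` (ties broken by
    ``ali_to``, then ``model_acc``). A protein retained in several COGs
    (non-conflicting hits) keeps all of them.
    """

    protein_id: str
    cogs: tuple[DomainHit, ...] = ()
    pfam_architecture: tuple[DomainHit, ...] = ()

    @property
    def unannotated(self) -> bool:
        return not self.cogs and not self.pfam_architecture

    @property
    def cog_accessions(self) -> frozenset[str]:
        return frozenset(h.model_acc for h in self.cogs)

    @property
    def pfam_accessions(self) -> frozenset[str]:
        return frozenset(h.model_acc for h in self.pfam_architecture)

    def accessions(self) -> frozenset[str]:
        """All accepted model accessions (COG and Pfam together)."""
        return self.cog_accessions | self.pfam_accessions


class ClanTable:
    """Pfam accession -> clan accession mapping (absent = no clan)."""

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = dict(mapping or {})

    def clan_of(self, accession: str) -> str | None:
        return self._map.get(accession)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClanTable":
        """Read a two-column TSV: Pfam accession, clan accession."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise HitTableError(f"{path}:{lineno}: expected 2 columns")
                acc, clan = parts[0], parts[1]
                if acc in mapping and mapping[acc] != clan:
                    raise HitTableError(
                        f"{path}:{lineno}: {acc} mapped to two clans"
                    )
                mapping[acc] = clan
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for acc in sorted(self._map):
                fh.write(f"{acc}\t{self._map[acc]}\n")


@dataclass(frozen=True)
class HitTableColumns:
    """0-based column indices into a whitespace-delimited per-domain table.

    Defaults match the common 22-column per-domain tabular output of an
    HMM search with the profile database as target (``hmmscan
    --domtblout``): model name/accession/length first, then the query
    protein, with the domain (independent) E-value, the domain bit
    score, and the alignment coordinates further right.
    """

    model_name: int = 0
    model_acc: int = 1
    model_len: int = 2
    protein_id: int = 3
    evalue: int = 12  # per-domain independent E-value
    score: int = 13  # per-domain bit score
    ali_from: int = 17
    ali_to: int = 18
    min_fields: int = 22


DOMTBL_COLUMNS = HitTableColumns()


def parse_hit_table(
    path: str | Path,
    model_kind: ModelKind | str,
    columns: HitTableColumns = DOMTBL_COLUMNS,
) -> list[DomainHit]:
    """Parse a per-domain tabular HMM-search output file.

    Lines beginning with ``#`` are comments. One :class:`DomainHit` is
    produced per data line, in file order. When the model accession
    column holds ``-`` (profiles without a registered accession), the
    model name column is used instead.

    Raises :class:`HitTableError` naming the offending line on malformed
    input.
    """
    try:
        kind = ModelKind(model_kind)
    except ValueError:
        raise HitTableError(f"unknown model kind: {model_kind!r}") from None
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < columns.min_fields:
                raise HitTableError(
                    f"{path}:{lineno}: expected >= {columns.min_fields} "
                    f"fields, got {len(fields)}"
                )
            try:
                acc = fields[columns.model_acc]
                if acc == "-":
                    acc = fields[columns.model_name]
                # Pfam accessions may carry a version suffix (PF00001.21)
                acc = acc.split(".")[0]
                hit = DomainHit(
                    protein_id=fields[columns.protein_id],
                    model_acc=acc,
                    model_kind=kind,
                    model_len=int(fields[columns.model_len]),
                    ali_from=int(fields[columns.ali_from]),
                    ali_to=int(fields[columns.ali_to]),
                    score=float(fields[columns.score]),
                    evalue=float(fields[columns.evalue]),
                    description=" ".join(fields[columns.min_fields :]),
                )
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def filter_significant(
    hits: Sequence[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
) -> list[DomainHit]:
    """Drop hits below the bit-score or length-fraction threshold.

    A hit survives iff ``score >= min_score`` and
    ``hit_length >= min_len_frac * model_len`` (equality passes on both
    boundaries). Input order is preserved; the filter is idempotent.
    """
    return [
        h
        for h in hits
        if h.score >= min_score and h.hit_length >= min_len_frac * h.model_len
    ]


def _cascade_cmp(a: tuple[DomainHit, int], b: tuple[DomainHit, int]) -> int:
    """Total priority order for the resolution cascade (best first).

    Score desc, then normalized length desc (1e-9 equality tolerance),
    then raw hit length desc, then model accession asc, then input
    position asc. The last two keys make the order total.
    """
    ha, ia = a
    hb, ib = b
    if ha.score != hb.score:
        return -1 if ha.score > hb.score else 1
    na, nb = ha.normalized_length, hb.normalized_length
    if not math.isclose(na, nb, rel_tol=0.0, abs_tol=NORM_LEN_TOL):
        return -1 if na > nb else 1
    if ha.hit_length != hb.hit_length:
        return -1 if ha.hit_length > hb.hit_length else 1
    if ha.model_acc != hb.model_acc:
        return -1 if ha.model_acc < hb.model_acc else 1
    return -1 if ia < ib else (1 if ia > ib else 0)


def resolve_overlaps(
    hits: Sequence[DomainHit],
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> list[DomainHit]:
    """Reduce overlapping hits on one protein by the rule cascade.

    Candidates are taken best-first (score, normalized length, raw
    length; accession and input position break residual ties). A
    candidate is rejected iff an already-accepted hit overlaps it over
    more than ``max_overlap_frac`` of the *candidate's* length, counted
    in shared residues. A rejected hit plays no further role: it cannot
    veto later candidates. The result is returned in ``ali_from`` order.

    All hits must belong to a single protein.
    """
    if not hits:
        return []
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(
            f"hits span several proteins: {sorted(proteins)}"
        )
    ordered = sorted(
        ((h, i) for i, h in enumerate(hits)),
        key=functools.cmp_to_key(_cascade_cmp),
    )
    accepted: list[DomainHit] = []
    for cand, _ in ordered:
        vetoed = any(
            overlap_residues(cand, acc) > max_overlap_frac * cand.hit_length
            for acc in accepted
        )
        if not vetoed:
            accepted.append(cand)
    accepted.sort(key=lambda h: (h.ali_from, h.ali_to, h.model_acc))
    return accepted


def annotate_protein(
    cog_hits: Sequence[DomainHit],
    pfam_hits: Sequence[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> ProteinAnnotation:
    """Annotate one protein from its raw COG and Pfam hits.

    COG and Pfam hits are filtered and resolved independently: a COG
    hit never suppresses a Pfam hit or vice versa. Non-overlapping
    multi-COG membership is retained.
    """
    protein_ids = {h.protein_id for h in (*cog_hits, *pfam_hits)}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span several proteins: {sorted(protein_ids)}")
    protein_id = next(iter(protein_ids)) if protein_ids else ""
    cogs = resolve_overlaps(
        filter_significant(cog_hits, min_score, min_len_frac),
        max_overlap_frac,
    )
    arch = resolve_overlaps(
        filter_significant(pfam_hits, min_score, min_len_frac),
        max_overlap_frac,
    )
    return ProteinAnnotation(
        protein_id=protein_id,
        cogs=tuple(cogs),
        pfam_architecture=tuple(arch),
    )


def annotate_proteins(
    cog_hits: Iterable[DomainHit],
    pfam_hits: Iterable[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> dict[str, ProteinAnnotation]:
    """Group hits by protein and annotate each one.

    Returns a mapping protein_id -> :class:`ProteinAnnotation` covering
    every protein that has at least one raw hit (even if all of its hits
    are filtered away, in which case ``unannotated`` is true).
    """
    by_protein: dict[str, tuple[list[DomainHit], list[DomainHit]]] = {}
    for h in cog_hits:
        by_protein.setdefault(h.protein_id, ([], []))[0].append(h)
    for h in pfam_hits:
        by_protein.setdefault(h.protein_id, ([], []))[1].append(h)
    return {
        pid: annotate_protein(cogs, pfams, min_score, min_len_frac, max_overlap_frac)
        for pid, (cogs, pfams) in sorted(by_protein.items())
    }


@dataclass(frozen=True)
class HitVerdict:
    """Outcome of the filter/resolution pipeline for one raw hit."""

    hit: DomainHit
    accepted: bool
    reason: str  # "" | "low_score" | "short_hit" | "overlap"


def audit_hits(
    hits: Sequence[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> list[HitVerdict]:
    """Classify every raw hit of one protein/kind with a rejection reason."""
    significant = []
    verdict_of: dict[int, str] = {}
    for i, h in enumerate(hits):
        if h.score < min_score:
            verdict_of[i] = "low_score"
        elif h.hit_length < min_len_frac * h.model_len:
            verdict_of[i] = "short_hit"
        else:
            significant.append((i, h))
    accepted = resolve_overlaps([h for _, h in significant], max_overlap_frac)
    accepted_ids = {id(h) for h in accepted}
    for i, h in significant:
        verdict_of[i] = "" if id(h) in accepted_ids else "overlap"
    return [
        HitVerdict(hit=h, accepted=verdict_of[i] == "", reason=verdict_of[i])
        for i, h in enumerate(hits)
    ]


_TABLE_HEADER = (
    "protein_id\tmodel_kind\tmodel_acc\tali_from\tali_to\t"
    "score\tevalue\taccepted\treason\n"
)


def write_annotation_table(
    path: str | Path,
    cog_hits: Iterable[DomainHit],
    pfam_hits: Iterable[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    min_len_frac: float = DEFAULT_MIN_LEN_FRAC,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> None:
    """Write the per-protein annotation audit as TSV."""
    groups: dict[tuple[str, ModelKind], list[DomainHit]] = {}
    for h in (*cog_hits, *pfam_hits):
        groups.setdefault((h.protein_id, h.model_kind), []).append(h)
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER)
        for (pid, kind), hs in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
            for v in audit_hits(hs, min_score, min_len_frac, max_overlap_frac):
                h = v.hit
                fh.write(
                    f"{h.protein_id}\t{h.model_kind.value}\t{h.model_acc}\t"
                    f"{h.ali_from}\t{h.ali_to}\t{h.score:g}\t{h.evalue:g}\t"
                    f"{int(v.accepted)}\t{v.reason}\n"
                )
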