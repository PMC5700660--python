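"""Synthetic genomes with planted conserved neighborhoods.

Generates a fully self-contained dataset — annotated genomes (GenBank
with sequence), per-domain hit tables for COG and Pfam profiles, a Pfam
clan table, and a truth record — in which a template operon (a target
gene family plus companion families with a fixed relative strand
pattern) is planted contiguously in a chosen number of genomes, at a
random locus and on a random strand. Every genome carries exactly one
copy of the target family (plus optional extra paralogs), so the
pipeline's occurrence percentage for each companion model is forced to
``100 * k_planted / n_genomes`` by construction.

Hit tables also contain configurable decoy hits (sub-threshold scores,
short alignments, overlapped lower-scored hits) that exercise the
significance and overlap filters end to end; the truth record states
every planted fact. All randomness flows from one seed: the same
configuration always produces byte-identical files.

Sequence content (nucleotides, amino acids) is random — the dataset
emulates genome *organization*, not molecular evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .annotation import ClanTable, DomainHit, ModelKind
from .genome_io import GeneRecord, Replicon, Strand, Topology

__all__ = ["FixtureConfig", "Dataset", "make_dataset", "write_dataset"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of one synthetic dataset.

    ``operon`` lists the planted gene families in genomic template
    order as (model accession, strand relative to the target); the
    first entry must be the target family on ``+``. Pfam models from
    ``pfam_models`` ride on the same genes as their COG, and ``clans``
    defines the clan table.
    """

    n_genomes: int = 10
    genes_per_genome: int = 30
    k_planted: int = 4
    operon: tuple[tuple[str, str], ...] = (
        ("COG9900", "+"), ("COG9901", "+"), ("COG9902", "-"),
    )
    pfam_models: tuple[tuple[str, str], ...] = (
        ("COG9900", "PF99000"), ("COG9901", "PF99001"), ("COG9902", "PF99002"),
    )
    clans: tuple[tuple[str, str], ...] = (
        ("PF99001", "CL9001"), ("PF99002", "CL9001"),
    )
    paralogs_per_genome: int = 1  # total target-family copies per genome
    topologies: tuple[str, ...] = ("linear", "circular")  # cycled over genomes
    gene_len_range: tuple[int, int] = (300, 1500)  # nt, rounded to codons
    gap_range: tuple[int, int] = (0, 200)  # nt between consecutive genes
    n_background_models: int = 20  # decoy COG families on flank genes
    background_prob: float = 0.6
    n_decoy_low_score: int = 1  # per genome: hits at 24.9 bits
    n_decoy_short: int = 1  # per genome: hits covering 20% of the model
    n_decoy_overlap: int = 1  # per genome: overlapped lower-scored hits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_planted > self.n_genomes:
            raise ValueError("k_planted cannot exceed n_genomes")
        if not self.operon or self.operon[0][1] != "+":
            raise ValueError("operon template must start with the target on '+'")
        if len(self.operon) + 2 * self.paralogs_per_genome > self.genes_per_genome:
            raise ValueError("operon does not fit in the genome")

    @property
    def target_model(self) -> str:
        return self.operon[0][0]

    @property
    def companion_models(self) -> tuple[str, ...]:
        return tuple(acc for acc, _ in self.operon[1:])


@dataclass
class Dataset:
    """In-memory synthetic dataset plus the planted truth."""

    config: FixtureConfig
    replicons: list[Replicon]
    cog_hits: list[DomainHit]
    pfam_hits: list[DomainHit]
    clans: ClanTable
    protein_seqs: dict[str, str]
    truth: dict


def _rand_seq(rng: np.random.Generator, alphabet: np.ndarray, n: int) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), n)])


def _main_hit(
    rng: np.random.Generator,
    protein_id: str,
    acc: str,
    kind: ModelKind,
    protein_len: int,
    description: str,
) -> DomainHit:
    """A clearly significant hit spanning most of the protein."""
    lead = int(rng.integers(0, 6))
    tail = int(rng.integers(0, 6))
    ali_to = max(protein_len - tail, lead + 1 + 1)
    return DomainHit(
        protein_id=protein_id,
        model_acc=acc,
        model_kind=kind,
        model_len=protein_len,
        ali_from=lead + 1,
        ali_to=ali_to,
        score=float(np.round(rng.uniform(60.0, 300.0), 1)),
        evalue=float(f"{rng.uniform(1e-40, 1e-20):.2e}"),
        description=description,
    )


_DESCRIPTIONS = {
    "COG9900": "membrane ion-translocating subunit, target family",
    "COG9901": "companion subunit A of the planted operon",
    "COG9902": "companion subunit B of the planted operon",
    "PF99000": "target-family domain",
    "PF99001": "companion domain A",
    "PF99002": "companion domain B",
}


def make_dataset(cfg: FixtureConfig) -> Dataset:
    """Generate the dataset for one configuration (seed-deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    m = len(cfg.operon)
    planted = sorted(
        int(i) for i in rng.choice(cfg.n_genomes, cfg.k_planted, replace=False)
    )
    pfam_of = dict(cfg.pfam_models)
    replicons: list[Replicon] = []
    cog_hits: list[DomainHit] = []
    pfam_hits: list[DomainHit] = []
    protein_seqs: dict[str, str] = {}
    truth: dict = {
        "target_model": cfg.target_model,
        "companion_models": list(cfg.companion_models),
        "planted_genomes": planted,
        "expected_occurrence_percent": {
            cfg.target_model: 100.0,
            **{
                acc: 100.0 * cfg.k_planted / cfg.n_genomes
                for acc in cfg.companion_models
            },
        },
        "genomes": [],
        "decoys": [],
    }
    background_pool = [f"COG8{i:03d}" for i in range(cfg.n_background_models)]

    for g in range(cfg.n_genomes):
        n_genes = cfg.genes_per_genome
        is_planted = g in planted
        block = m if is_planted else 1
        # loci of the operon block (or lone target) and extra paralogs,
        # kept one gene away from the replicon ends and from each other
        pos = int(rng.integers(1, n_genes - block - 1))
        paralog_slots: list[int] = []
        guard = set(range(pos - 1, pos + block + 1))
        attempts = 0
        while len(paralog_slots) < cfg.paralogs_per_genome - 1:
            cand = int(rng.integers(1, n_genes - 2))
            attempts += 1
            if attempts > 500:
                raise ValueError("cannot place paralogs: genome too crowded")
            if cand in guard:
                continue
            paralog_slots.append(cand)
            guard.update({cand - 1, cand, cand + 1})
        orientation = 1 if rng.random() < 0.5 else -1

        lengths = (
            np.asarray(
                rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1, n_genes)
            )
            // 3 * 3
        )
        gaps = np.asarray(
            rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1, n_genes + 1)
        )
        strands = [
            Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
            for _ in range(n_genes)
        ]
        # model per slot: None = background candidate
        slot_model: list[str | None] = [None] * n_genes
        target_strand = Strand.FORWARD if orientation == 1 else Strand.REVERSE
        template = list(cfg.operon) if is_planted else [cfg.operon[0]]
        laid = template if orientation == 1 else template[::-1]
        for off, (acc, rel) in enumerate(laid):
            slot = pos + off
            slot_model[slot] = acc
            same = rel == "+"
            strands[slot] = (
                target_strand if same else target_strand.flipped
            )
        target_slot = pos if orientation == 1 else pos + block - 1
        for slot in paralog_slots:
            slot_model[slot] = cfg.target_model
        for i in range(n_genes):
            if slot_model[i] is None and rng.random() < cfg.background_prob:
                slot_model[i] = background_pool[
                    int(rng.integers(0, len(background_pool)))
                ]

        genes: list[GeneRecord] = []
        coord = 1 + int(gaps[0])
        rep_id = f"REP{g:02d}"
        for i in range(n_genes):
            L = int(lengths[i])
            pid = f"G{g:02d}P{i:03d}"
            prot = _rand_seq(rng, _AA, L // 3 - 1)
            protein_seqs[pid] = prot
            acc = slot_model[i]
            genes.append(
                GeneRecord(
                    gene_id=f"G{g:02d}L{i:03d}",
                    replicon_id=rep_id,
                    start=coord,
                    end=coord + L - 1,
                    strand=strands[i],
                    protein_id=pid,
                    product=(
                        _DESCRIPTIONS.get(acc, f"{acc} family protein")
                        if acc
                        else "hypothetical protein"
                    ),
                    protein_seq=prot,
                )
            )
            if acc is not None:
                cog_hits.append(
                    _main_hit(
                        rng, pid, acc, ModelKind.COG, len(prot),
                        _DESCRIPTIONS.get(acc, f"{acc} family protein"),
                    )
                )
                if acc in pfam_of:
                    pfam_hits.append(
                        _main_hit(
                            rng, pid, pfam_of[acc], ModelKind.PFAM, len(prot),
                            _DESCRIPTIONS.get(pfam_of[acc], ""),
                        )
                    )
            coord += L + int(gaps[i + 1])

        genome_len = coord - int(gaps[n_genes]) + int(rng.integers(50, 300))
        topology = Topology(cfg.topologies[g % len(cfg.topologies)])
        replicons.append(
            Replicon(
                replicon_id=rep_id,
                organism=f"Synthetica specimen {g:02d}",
                taxonomy=("Bacteria", f"Synthphylum{g % 4}", f"Synthogenus{g:02d}"),
                topology=topology,
                length=genome_len,
                genes=genes,
                sequence=_rand_seq(rng, _NT, genome_len),
            )
        )

        # decoy hits exercising the filters
        def _decoy_protein() -> tuple[str, int]:
            i = int(rng.integers(0, n_genes))
            return f"G{g:02d}P{i:03d}", len(protein_seqs[f"G{g:02d}P{i:03d}"])

        for _ in range(cfg.n_decoy_low_score):
            pid, L = _decoy_protein()
            cog_hits.append(
                DomainHit(pid, "COG9998", ModelKind.COG, L, 1, L, 24.9, 1e-3,
                          "decoy: sub-threshold score")
            )
            truth["decoys"].append(
                {"protein_id": pid, "model_acc": "COG9998", "reason": "low_score"}
            )
        for _ in range(cfg.n_decoy_short):
            pid, L = _decoy_protein()
            span = max(1, L // 5 - 1)  # < 25% of the model length
            cog_hits.append(
                DomainHit(pid, "COG9997", ModelKind.COG, L, 1, span, 80.0, 1e-10,
                          "decoy: short alignment")
            )
            truth["decoys"].append(
                {"protein_id": pid, "model_acc": "COG9997", "reason": "short_hit"}
            )
        for _ in range(cfg.n_decoy_overlap):
            # fully overlapped, lower-scored than any main hit (< 60 bits)
            pid = f"G{g:02d}P{target_slot:03d}"
            L = len(protein_seqs[pid])
            cog_hits.append(
                DomainHit(pid, "COG9996", ModelKind.COG, L, 1, L, 40.0, 1e-6,
                          "decoy: overlapped by the target-family hit")
            )
            truth["decoys"].append(
                {"protein_id": pid, "model_acc": "COG9996", "reason": "overlap"}
            )

        truth["genomes"].append(
            {
                "replicon_id": rep_id,
                "planted": bool(is_planted),
                "orientation": orientation,
                "operon_slots": list(range(pos, pos + block)),
                "target_slot": target_slot,
                "target_protein": f"G{g:02d}P{target_slot:03d}",
                "paralog_slots": sorted(paralog_slots),
                "topology": topology.value,
            }
        )

    return Dataset(
        config=cfg,
        replicons=replicons,
        cog_hits=cog_hits,
        pfam_hits=pfam_hits,
        clans=ClanTable(dict(cfg.clans)),
        protein_seqs=protein_seqs,
        truth=truth,
    )


# --------------------------------------------------------------- writers

def _domtbl_line(h: DomainHit, qlen: int) -> str:
    desc = h.description or "-"
    return (
        f"{h.model_acc:<20} {h.model_acc:<10} {h.model_len:5d} "
        f"{h.protein_id:<20} - {qlen:5d} "
        f"{h.evalue:9.2e} {h.score + 1.0:6.1f} 0.1 1 1 "
        f"{h.evalue:9.2e} {h.evalue:9.2e} {h.score:6.1f} 0.1 "
        f"1 {h.model_len:5d} {h.ali_from:5d} {h.ali_to:5d} "
        f"{h.ali_from:5d} {h.ali_to:5d} 0.95 {desc}\n"
    )


def _to_seqrecord(rep: Replicon) -> SeqRecord:
    rec = SeqRecord(
        Seq(rep.sequence),
        id=rep.replicon_id,
        name=rep.replicon_id,
        description=f"{rep.organism} synthetic replicon",
    )
    rec.annotations.update(
        molecule_type="DNA",
        topology=rep.topology.value,
        organism=rep.organism,
        taxonomy=list(rep.taxonomy),
        date="01-JAN-2000",  # pinned so repeated runs are byte-identical
    )
    for g in rep.genes:
        feat = SeqFeature(
            FeatureLocation(g.start - 1, g.end, strand=1 if g.strand is Strand.FORWARD else -1),
            type="CDS",
            qualifiers={
                "locus_tag": [g.gene_id],
                "protein_id": [g.protein_id],
                "product": [g.product],
                "translation": [g.protein_seq],
            },
        )
        rec.features.append(feat)
    return rec


def write_dataset(ds: Dataset, out_dir: str | Path) -> None:
    """Write the dataset: GenBank genomes, hit tables, clans, truth YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in ds.replicons:
        SeqIO.write([_to_seqrecord(rep)], str(out / f"{rep.replicon_id}.gbk"), "genbank")
    with open(out / "proteins.faa", "w") as fh:
        for pid in sorted(ds.protein_seqs):
            fh.write(f">{pid}\n{ds.protein_seqs[pid]}\n")
    header = (
        "# synthetic per-domain hit table\n"
        "# target name        accession   tlen query name           "
        "accession qlen E-value score bias # of c-Evalue i-Evalue "
        "score bias hmm-from hmm-to ali-from ali-to env-from env-to acc "
        "description\n"
    )
    with open(out / "cog_hits.domtbl", "w") as fh:
        fh.write(header)
        for h in ds.cog_hits:
            fh.write(_domtbl_line(h, len(ds.protein_seqs[h.protein_id])))
    with open(out / "pfam_hits.domtbl", "w") as fh:
        fh.write(header)
        for h in ds.pfam_hits:
            fh.write(_domtbl_line(h, len(ds.protein_seqs[h.protein_id])))
    ds.clans.to_tsv(out / "clans.tsv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(ds.truth, fh, sort_keys=True)
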