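"""Target selection, window extraction, occurrence statistic, coloring."""

import pytest

from genecontext import FixtureConfig, GenomeSet, make_dataset, run_analysis
from genecontext.annotation import ClanTable, ModelKind, ProteinAnnotation
from genecontext.genome_io import (
    GeneRecord,
    Replicon,
    Strand,
    Topology,
    reverse_complement_replicon,
)
from genecontext.neighborhood import (
    NEUTRAL_COLOR,
    OccurrenceTable,
    Query,
    colorize,
    extract_neighborhood,
    find_targets,
    occurrence,
)
from conftest import make_hit


def linear_replicon(n_genes=7, topology=Topology.LINEAR, strands=None):
    genes = []
    for i in range(n_genes):
        start = 1 + i * 150
        genes.append(
            GeneRecord(
                gene_id=f"g{i}",
                replicon_id="R1",
                start=start,
                end=start + 99,
                strand=(strands[i] if strands else Strand.FORWARD),
                protein_id=f"P{i}",
                product=f"protein {i}",
            )
        )
    return Replicon(
        replicon_id="R1",
        organism="Testus",
        taxonomy=("Bacteria", "Testphylum"),
        topology=topology,
        length=n_genes * 150 + 100,
        genes=genes,
    )


def annotation_for(pid, cog=None, pfam=None):
    return ProteinAnnotation(
        protein_id=pid,
        cogs=tuple(
            make_hit(protein_id=pid, model_acc=a) for a in (cog or [])
        ),
        pfam_architecture=tuple(
            make_hit(protein_id=pid, model_acc=a, kind=ModelKind.PFAM)
            for a in (pfam or [])
        ),
    )


class TestQuery:
    @pytest.mark.parametrize("acc", ["COG0001", "PF00001"])
    def test_valid_accessions(self, acc):
        q = Query.from_accession(acc)
        assert q.accession == acc

    @pytest.mark.parametrize("acc", ["COG1", "PF001", "XYZ0001", "cog0001"])
    def test_malformed_accessions_rejected(self, acc):
        with pytest.raises(ValueError):
            Query.from_accession(acc)

    def test_kind_must_match_accession(self):
        with pytest.raises(ValueError):
            Query(kind=ModelKind.PFAM, accession="COG0001")


class TestFindTargets:
    def test_unknown_accession_warns_and_returns_empty(self):
        rep = linear_replicon()
        anns = {"P0": annotation_for("P0", cog=["COG0001"])}
        with pytest.warns(UserWarning, match="COG0999"):
            out = find_targets(anns, GenomeSet([rep]), Query.from_accession("COG0999"))
        assert out == []

    def test_all_paralogs_returned_without_cap(self):
        rep = linear_replicon()
        anns = {
            f"P{i}": annotation_for(f"P{i}", cog=["COG0042"]) for i in (0, 3, 5)
        }
        out = find_targets(anns, GenomeSet([rep]), Query.from_accession("COG0042"))
        assert [g.protein_id for g in out] == ["P0", "P3", "P5"]

    def test_repeated_domain_returns_gene_once(self):
        rep = linear_replicon(3)
        ann = ProteinAnnotation(
            protein_id="P1",
            pfam_architecture=(
                make_hit(1, 40, protein_id="P1", model_acc="PF00010",
                         kind=ModelKind.PFAM),
                make_hit(60, 99, protein_id="P1", model_acc="PF00010",
                         kind=ModelKind.PFAM),
            ),
        )
        out = find_targets({"P1": ann}, GenomeSet([rep]),
                           Query.from_accession("PF00010"))
        assert [g.protein_id for g in out] == ["P1"]

    def test_pfam_mode_ignores_cog_memberships(self):
        rep = linear_replicon(3)
        anns = {"P1": annotation_for("P1", cog=["COG0042"])}
        with pytest.warns(UserWarning):
            out = find_targets(anns, GenomeSet([rep]),
                               Query.from_accession("PF00042"))
        assert out == []


class TestExtractNeighborhood:
    @pytest.mark.parametrize("k", [0, 1, 2, 16, 100])
    def test_k_outside_range_rejected(self, k):
        rep = linear_replicon()
        with pytest.raises(ValueError, match="outside"):
            extract_neighborhood(rep, rep.genes[3], k)

    def test_k3_mid_replicon_one_gene_each_side(self):
        rep = linear_replicon(7)
        nb = extract_neighborhood(rep, rep.genes[3], 3)
        assert [g.gene_id for g in nb.genes] == ["g2", "g3", "g4"]
        assert nb.target_slot == 1
        assert not nb.flipped

    def test_k15_on_5_gene_replicon_truncates_silently(self):
        rep = linear_replicon(5)
        nb = extract_neighborhood(rep, rep.genes[1], 15)
        assert [g.gene_id for g in nb.genes] == [f"g{i}" for i in range(5)]

    def test_even_k_extra_gene_on_rendered_right(self):
        rep = linear_replicon(9)
        nb = extract_neighborhood(rep, rep.genes[4], 4)
        # 1 left, 2 right of the forward-strand target
        assert [g.gene_id for g in nb.genes] == ["g3", "g4", "g5", "g6"]
        rev = linear_replicon(9, strands=[Strand.REVERSE] * 9)
        nb2 = extract_neighborhood(rev, rev.genes[4], 4)
        # mirrored: the extra (second) rendered-right gene comes from the
        # genomic left, so the target again sits at rendered slot 1
        assert [g.gene_id for g in nb2.genes] == ["g5", "g4", "g3", "g2"]
        assert nb2.flipped and nb2.target_slot == 1

    def test_circular_replicon_wraps_around_the_origin(self):
        rep = linear_replicon(5, topology=Topology.CIRCULAR)
        nb = extract_neighborhood(rep, rep.genes[0], 3)
        assert [g.gene_id for g in nb.genes] == ["g4", "g0", "g1"]

    def test_reverse_strand_target_mirrors_window(self):
        strands = [Strand.FORWARD] * 7
        strands[3] = Strand.REVERSE
        rep = linear_replicon(7, strands=strands)
        nb = extract_neighborhood(rep, rep.genes[3], 5)
        assert nb.flipped
        assert [g.gene_id for g in nb.genes] == ["g5", "g4", "g3", "g2", "g1"]
        assert nb.points_right(rep.genes[3])  # target renders rightward
        assert not nb.points_right(rep.genes[2])  # opposite strand: leftward

    def test_extraction_commutes_with_reverse_complement(self):
        strands = [Strand.FORWARD, Strand.REVERSE] * 4 + [Strand.FORWARD]
        rep = linear_replicon(9, strands=strands)
        mirrored = reverse_complement_replicon(rep)
        by_id = {g.gene_id: g for g in mirrored.genes}
        for k in (3, 4, 9):
            for target in rep.genes[2:7]:
                nb = extract_neighborhood(rep, target, k)
                nb2 = extract_neighborhood(mirrored, by_id[target.gene_id], k)
                assert [g.gene_id for g in nb.genes] == [
                    g.gene_id for g in nb2.genes
                ]
                assert [nb.points_right(g) for g in nb.genes] == [
                    nb2.points_right(g) for g in nb2.genes
                ]
                assert [r.gap_length for r in nb.intergaps] == [
                    r.gap_length for r in nb2.intergaps
                ]


class TestOccurrence:
    def make_neighborhoods(self, present_in):
        """10 single-gene windows; model COG0042 present in `present_in`."""
        nbs = []
        anns = {}
        for i in range(10):
            rep = linear_replicon(3)
            pid = f"P1"
            nb = extract_neighborhood(rep, rep.genes[1], 3)
            nbs.append(nb)
        return nbs

    def test_presence_fraction(self, dataset, analysis):
        cfg = dataset.config
        expected = dataset.truth["expected_occurrence_percent"]
        for acc, pct in expected.items():
            assert analysis.occurrence.percent(acc) == pct

    def test_model_counted_once_per_neighborhood(self):
        rep = linear_replicon(3)
        anns = {f"P{i}": annotation_for(f"P{i}", cog=["COG0042"]) for i in range(3)}
        nb = extract_neighborhood(rep, rep.genes[1], 3)
        occ = occurrence([nb], anns)
        assert occ.n_present["COG0042"] == 1
        assert occ.percent("COG0042") == 100.0

    def test_empty_neighborhood_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            occurrence([], {})


class TestColorize:
    def occ(self, percents):
        return OccurrenceTable(
            n_total=100,
            n_present={acc: int(p) for acc, p in percents.items()},
        )

    @pytest.mark.parametrize("threshold", [0, 0.5, 100.1, -3])
    def test_threshold_outside_range_rejected(self, threshold):
        with pytest.raises(ValueError, match="threshold"):
            colorize(self.occ({"COG0001": 100}), threshold)

    def test_threshold_100_colors_only_full_presence(self):
        cmap = colorize(self.occ({"COG0001": 100, "COG0002": 99}), 100)
        assert set(cmap.assigned) == {"COG0001"}
        assert cmap.color("COG0002") == NEUTRAL_COLOR

    def test_threshold_1_colors_every_visible_model(self):
        cmap = colorize(self.occ({"COG0001": 100, "COG0002": 1, "COG0003": 2}), 1)
        assert set(cmap.assigned) == {"COG0001", "COG0002", "COG0003"}

    def test_clan_members_share_one_color(self):
        clans = ClanTable({"PF00001": "CL0001", "PF00002": "CL0001"})
        cmap = colorize(
            self.occ({"PF00001": 80, "PF00002": 60, "PF00003": 40}), 10, clans
        )
        assert cmap.color("PF00001") == cmap.color("PF00002")
        assert cmap.color("PF00003") != cmap.color("PF00001")

    def test_raising_threshold_never_adds_a_colored_model(self):
        occ = self.occ({f"COG{i:04d}": 10 * i for i in range(1, 11)})
        previous = None
        for t in (1, 20, 40, 60, 80, 100):
            colored = set(colorize(occ, t).assigned)
            if previous is not None:
                assert colored <= previous
            previous = colored

    def test_deterministic_for_fixed_seed_distinct_across_groups(self):
        occ = self.occ({f"COG{i:04d}": 50 for i in range(1, 8)})
        a = colorize(occ, 10, palette_seed=3)
        b = colorize(occ, 10, palette_seed=3)
        assert a.assigned == b.assigned
        assert len(set(a.assigned.values())) == 7


class TestPlantedOperonRecovery:
    def test_occurrence_matches_planted_fraction_and_threshold_boundary(self):
        cfg = FixtureConfig(n_genomes=8, genes_per_genome=12, k_planted=3, seed=41)
        ds = make_dataset(cfg)
        res = run_analysis(
            GenomeSet(ds.replicons), ds.cog_hits, ds.pfam_hits,
            cfg.target_model, k=9, threshold=1.0, clans=ds.clans,
        )
        expected = 100.0 * 3 / 8
        for acc in cfg.companion_models:
            assert res.occurrence.percent(acc) == expected
        at = colorize(res.occurrence, expected, ds.clans)
        above = colorize(res.occurrence, expected + 0.5, ds.clans)
        for acc in cfg.companion_models:
            assert acc in at.assigned
            assert acc not in above.assigned
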