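# genecontext

Comparative analysis of prokaryotic gene neighborhoods.

In bacterial and archaeal genomes, functionally coupled genes are often
organized in conserved gene clusters; orthologs tend to sit in similar
genomic contexts while paralogs with diverged functions do not. Given
per-protein COG/Pfam profile-HMM hit tables and annotated genomes,
`genecontext` finds **all** genes whose products belong to a queried family
(one COG identifier such as `COG0001`, or one Pfam accession such as
`PF00001` — every paralog, no clustering, no cap), extracts an
orientation-normalized window of 3–15 genes around each, and summarizes
which other families co-occur in those windows. It is aimed at comparative
genomicists predicting co-regulated genes, operon structure and new protein
complexes from genomic context.

## Method

**Annotation.** A hit (a region of a protein matching a profile HMM, with
alignment coordinates, bit score *S* and E-value) is kept iff

```
S ≥ 25.0 bits   and   (ali_to − ali_from + 1) ≥ 0.25 · L_HMM
```

Overlapping hits are then reduced best-first by score, then normalized
length (hit length / L_HMM), then raw length: a candidate is discarded iff
an already-accepted hit covers more than 50% of the candidate's own length.
COG memberships and the Pfam domain architecture are resolved independently;
a protein may legitimately belong to several non-conflicting COGs.

**Occurrence statistic.** For *n* target-gene neighborhoods, a model's
occurrence percentage is `100 · m / n` where *m* counts neighborhoods
containing at least one gene annotated with it. Models at or above a
1–100% threshold are colored in the figure (Pfam domains of one clan share
a color); start at 1% and raise it so rare neighbors are not missed.

**Figure.** One row per neighborhood, sorted by taxonomy or by the output
order of a multiple sequence alignment of the target proteins. Genes are
arrows (length-proportional, target always pointing right, flanks pointing
right iff on the target's strand), intergenic regions are lines, a legend
lists colored models, and a JSON sidecar carries full per-gene and
per-intergenic annotations (coordinates, taxonomy, accepted hits with
scores and E-values, sequences, reverse complements).

## Worked example

The built-in generator plants a three-gene operon (target `COG9900` with
companions `COG9901`/`COG9902`, carrying Pfam domains `PF99001`/`PF99002`
from one clan) in 4 of 10 synthetic genomes:

```python
import genecontext as gc

ds = gc.make_dataset(gc.FixtureConfig(seed=7))
gs = gc.GenomeSet(ds.replicons)
res = gc.run_analysis(gs, ds.cog_hits, ds.pfam_hits, "COG9900",
                      k=9, threshold=20, clans=ds.clans)
print(f"{len(res.neighborhoods)} neighborhoods")
for acc, pct in res.occurrence.items():
    if pct >= 20:
        print(f"{acc}  {pct:5.1f}%  {res.colormap.color(acc)}")
```

prints

```
10 neighborhoods
COG9900  100.0%  #ffe119
PF99000  100.0%  #008080
COG8005   50.0%  #4363d8
COG9901   40.0%  #aaffc3
COG9902   40.0%  #e6194b
PF99001   40.0%  #9a6324
PF99002   40.0%  #9a6324
...
```

Ten target genes were found (one per genome), the queried family is present
in 100% of its own neighborhoods, and each planted companion appears in
exactly 40% = 4/10 of them — the planted fraction. The clan-mates `PF99001`
and `PF99002` share one color (`#9a6324`); the `COG8xxx` families are random
background annotation. `gc.render_figure(res.figure, svg_path=..., pdf_path=...)`
writes the comparative figure, and `gc.emit_annotations(...)` the JSON
sidecar.

The same run from the shell:

```bash
genecontext fixtures-make --seed 7 --out data/
genecontext neighborhoods --query COG9900 --k 9 --threshold 20 \
    --sort taxonomy --cog-hits data/cog_hits.domtbl \
    --pfam-hits data/pfam_hits.domtbl --clans data/clans.tsv \
    $(for g in data/*.gbk; do echo --genome $g; done) --out out/
```

writes `out/figure.svg`, `figure.pdf`, `occurrence.tsv`,
`neighborhoods.tsv`, `legend.tsv` and `annotations.json`.

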