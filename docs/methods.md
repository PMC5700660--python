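# Methods

## Problem and model

Functionally coupled genes in bacteria and archaea are often organized in
conserved gene clusters (one or several operons), so orthologs tend to share
genomic context while paralogs with diverged functions tend not to.
`genecontext` compares the genomic neighborhoods of all genes whose products
belong to one protein family — a Cluster of Orthologous Groups (COG) or a
Pfam domain family — across a set of annotated genomes, and summarizes which
other families co-occur in those neighborhoods.

The pipeline has four stages:

1. **Annotation.** Per-domain hit tables from a profile-HMM search (one for
   COG profiles, one for Pfam profiles) are filtered and reduced to
   per-protein annotations.
2. **Neighborhood extraction.** Every gene annotated with the queried family
   becomes a target; a window of `k` genes centered on it is cut out and
   orientation-normalized so the target renders pointing right.
3. **Occurrence statistic.** For each model `m` seen in any window, the
   occurrence percentage is `100 · n_present(m) / n_windows`, where
   `n_present(m)` counts windows containing **at least one** gene annotated
   with `m` (presence semantics — a model repeated inside one window counts
   once; the target gene participates, so the queried family reads 100%
   whenever every target carries it).
4. **Rendering.** One row per window: arrows for genes (lengths proportional
   to gene lengths), lines for intergenic gaps, colors from the occurrence
   threshold, a legend of colored models below, and a JSON sidecar with the
   full annotation of every rendered gene and gap.

## Hit filtering and overlap resolution

A hit is characterized by alignment coordinates on the protein (1-based,
inclusive), a bit score, an E-value, and the length of the profile HMM it
matched. Two significance filters apply first, both boundary-inclusive:

* score ≥ 25.0 bits;
* hit length ≥ 25% of the profile HMM length.

Overlapping surviving hits (COG and Pfam resolved independently — one never
suppresses the other) are reduced by a greedy cascade. Candidates are taken
best-first by

1. higher bit score,
2. greater *normalized length* (hit length / profile HMM length, compared
   with a 1e-9 absolute tolerance),
3. greater raw hit length,
4. model accession (lexicographic), then input position.

Keys 1–3 are the scientific preferences; keys 4–5 only make the order total
so results are independent of input permutation. A candidate is rejected iff
an already-**accepted** hit overlaps it over more than 50% of the
*candidate's own* length (shared residues; exactly 50% is tolerated). A
rejected hit plays no further role and cannot veto later candidates.

Two readings of the 50% rule were possible (denominator = lower-scored hit,
shorter hit, or union); we use the lower-scored/candidate hit's length, which
matches the grammatical subject of the rule as usually stated and makes the
rule well-defined within the greedy order. The test suite checks the greedy
resolver against an independent brute-force oracle that enumerates all 2^n
hit subsets and keeps the unique fixpoint (a hit is in the solution iff no
better-ranked member of the solution vetoes it) — 1,000 seeded random
instances of up to 8 hits.

Consequence worth noting: a *short, higher-scored* hit may survive together
with a longer, lower-scored hit that covers more than half of the short
hit's span, because the veto is always measured against the lower-ranked
candidate. The output invariant is therefore: no surviving lower-scored hit
is covered over more than half of its own length by a surviving
higher-scored hit.

## Window geometry

`k` ∈ [3, 15] counts total genes including the target. The window is
contiguous in gene-rank space: ⌊(k−1)/2⌋ genes on one side, the rest on the
other, truncated at the ends of linear replicons and wrapped on circular
ones. For even `k` the extra gene is placed on the **rendered** right of the
target — i.e. on the genomic right for a forward-strand target and the
genomic left for a reverse-strand target. Defining the split in rendered
space makes neighborhood extraction an exact involution under
reverse-complementing the genome: flipping all coordinates and strands
changes no rendered row, byte for byte. Reverse-strand targets mirror the
window (`flipped = true`); a gene renders pointing right iff it lies on the
target's strand.

## Coloring

Models at or above the occurrence threshold (1–100%) receive distinct colors
from a fixed qualitative palette, visited by (percent descending, accession
ascending); models below threshold are neutral gray. All Pfam accessions
sharing a clan receive one color, fixed at the clan's first-seen member.
The palette order is a seeded permutation (default seed 0) and cycling past
the palette lightens the shade, so assignment is fully deterministic.
Raising the threshold can only remove colored models, never add them. We
suggest starting from the minimal 1% threshold and raising it as needed, so
rare but potentially important neighbors are not missed; the occurrence
percentage is a descriptive statistic, not a significance measure (a
Monte-Carlo null is a possible extension, deliberately not implemented).

## Display order

Default order is taxonomic: lexicographic on (taxonomy lineage, organism,
replicon, target start coordinate), so paralogs of one organism are listed
under each other; missing taxonomy sorts last. The alternative groups rows
by target-protein similarity: the target sequences are passed to a multiple
sequence aligner and rows follow the aligner's *output* record order, which
tracks its guide tree. The aligner is a pluggable contract (sequences in →
ids in output order); the bundled external-command adapter defaults to the
classic MUSCLE invocation with the iteration count set to two, and any
engine failure falls back to input order with a warning. Tests exercise the
contract with deterministic in-process fakes; mapping "alignment order" to a
row order via the output record order (rather than an explicitly built
tree's leaf order) is a documented design choice.

## Rendering

Geometry constants (50 px/kb scale, 34 px rows, 16 px arrow height, 9 px
arrow heads, 80 px gap clip with a break glyph) live in `RenderStyle` and
are configurable. Arrow width equals gene length × scale with no minimum
width, so width ratios equal length ratios exactly (coordinates are written
at 0.01 px precision). SVG is the primary output and is generated by a
purpose-built serializer precisely so identical inputs yield byte-identical
documents; PDF export redraws the same primitive list through matplotlib.
UniProt cross-references are pass-through fields populated only from input
metadata; there is no remote lookup.

## Synthetic data

The fixture generator emulates genome *organization*, not sequence
evolution: random gene lengths (uniform 300–1500 nt, rounded to codons),
random gaps (0–200 nt), random strands, random nucleotide and amino-acid
content, a mix of linear and circular replicons. A template operon — the
target family plus companion families with a fixed relative strand
pattern — is planted contiguously in `k_planted` of `n_genomes` genomes at a
random interior locus and random orientation; every genome carries exactly
one target copy (more when paralogs are requested), so each companion's
occurrence percentage is forced to `100·k_planted/n_genomes` exactly.
Background genes draw annotations from a disjoint accession pool, and decoy
hits (24.9 bits; 20% of the model length; fully-overlapped lower-scored
hits) exercise each rejection path. Defaults: 10 genomes × 30 genes, operon
of 3 families planted in 4 genomes, one Pfam model per planted COG with two
companions sharing a clan.

Because sequence content is random, passing tests demonstrate the
correctness of the bookkeeping (filters, window geometry, statistic,
rendering) — they say nothing about HMM search sensitivity, real operon
detection power, or alignment-based ordering quality on biological
sequences.

## Numerical and degenerate-input choices

* Both significance boundaries are inclusive (25.0 bits and exactly 25%
  pass); whether the original filtering kept equality is unknowable from the
  rule's wording, so the literal strict-inequality reading was chosen.
* Normalized-length equality uses a 1e-9 absolute tolerance; scores and raw
  lengths compare exactly.
* Windows larger than the replicon truncate (linear) or cap at the gene
  count (circular) without error.
* Genes spanning the origin of a circular replicon are stored wrapped
  (start > end) with length `(L − start + 1) + end`.
* Abutting or overlapping genes yield an empty intergenic region, flagged,
  with no sequence.
* An unknown query accession returns an empty target list with a warning,
  not an error; an empty neighborhood list is an error for the occurrence
  statistic and the renderer.
* Features lacking both a protein id and a product are dropped at load time;
  anything else (RNA genes, pseudogenes with products) renders as an
  uncolored arrow.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
10–20 genomes of 10–30 genes, 1,000 random resolver instances of ≤ 8 hits,
and ~90–110 rendered genes per figure. These sizes make every check exact
and reproducible; the pipeline itself streams per-replicon and has no
designed size cap (the target list is deliberately uncapped, unlike
hit-limited context browsers).

## Known limitations

* Running the HMM search itself is out of scope; the package consumes its
  tabular output.
* Occurrence percentage carries no significance estimate.
* Eukaryotic multi-exon features and gene calling are unsupported.
* MSA ordering depends on the chosen external engine's output order and is
  only deterministic for a fixed engine version.
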