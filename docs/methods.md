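# Methods

## The model

A target-primed non-LTR retrotransposon with a restriction-like
endonuclease integrates into a short multicopy target gene.  Two
parameters on the target-gene model describe an integration event:

* `insertion_site` — 1-based position of the last target base 5' of the
  bottom-strand cut (default 38, the U2 convention: downstream target
  fragments begin at nt 39);
* `top_offset` — the top-strand cut position minus the bottom-strand
  cut position.  `+Δ` produces a Δ-bp target site duplication, `0` a
  blunt junction, `−Δ` a Δ-bp deletion of target bases 5' of the bottom
  cut.

The functional proxy for a target-gene copy is presence of its 5'
region (`functional_5prime_len`, default 50 nt): for U2 every nucleotide
required for splicing lies in the first 50 bases.  This is an inherited
presumption, not something the package verifies.

Coordinates are 0-based half-open internally and 1-based closed in TSV
reports; BED outputs are 0-based per the format.

## Synthetic data: what it emulates

`build_target_arrays` emits tandem arrays of exact target-gene copies
separated by spacers.  Each array derives its spacers from one ancestral
random sequence mutated at `spacer_divergence` (default 0.25) per
instance — recognisably related but strongly diverged, as real
intergenic sequence between target-gene copies is.  Genes themselves are
exact; real inter-copy target variation is small and is not modelled.

`insert_elements` applies the cleavage geometry literally: the mutated
locus reads `target[1..s+Δ] ⊕ element ⊕ target[s+1..L]` for `Δ ≥ 0`, and
`target[1..s+Δ] ⊕ element ⊕ target[s+1..L]` with the intervening bases
deleted for `Δ < 0`.  Copies may be 5'-truncated (uniform over
[0, 0.8·length] by default — the non-LTR hallmark of incomplete reverse
transcription), diverged (independent per-site substitutions plus
single-base indels), inserted off-target at uniform random genome
positions, or nested into previously placed copies.  Every edit is
recorded in a truth object, including deleted bases, so edits reverse
exactly (`reverse_edits`), which is the generator's own correctness
oracle.

Orientation: on-target insertions are placed in the fixed orientation
that target-primed reverse transcription enforces (element 3' end joined
at the bottom-strand cut, so the downstream target fragment is the
element-sense 3' flank).  Off-target insertions land on either strand
with probability 0.5.  Nested insertions land at least 70 nt inside the
host so both junctions of the nested copy read element sequence.

The generator does not model recombination or gene conversion after
integration.  Consequently a 5'-target-deletion locus always reflects
the cleavage geometry directly; in real genomes the same signature can
arise or be erased by later recombination, which sequence evidence
cannot distinguish.  Passing recovery tests therefore demonstrates that
the inference reads back the integration-time geometry, not that real
loci are free of post-integration rearrangement.

## Alignment

`smith_waterman` is a full-matrix affine-gap local aligner (match +1,
mismatch −1, gap open −2, gap extend −1; a gap of length L costs
`open + (L−1)·extend`).  It is the package's exact oracle — tests verify
its optimal scores against an independent implementation — and is
limited to ~20 kb per sequence.  N matches nothing, ever, and never
seeds.

`seed_extend_scan` indexes exact k-mers (default k=11), clusters seeds
by diagonal (band 32) and genome position, and extends each cluster with
a banded Smith–Waterman confined to the seeded diagonals ± band.  Hits
below `min_score` (default 30) are discarded; same-strand hits
overlapping over half of the shorter one collapse to the best score.
Defaults were chosen so 70-bp anchors at ≤15% divergence are reliably
seeded (a 70-mer at 15% divergence still contains ~19 clean 11-mers in
expectation); all three are exposed as parameters.

## Copy detection and boundary hygiene

Full-consensus detection chains collinear fragments of one copy when
both query and subject gaps are ≤ 50 nt (tight on purpose: junction
precision matters more than chaining distant fragments; a nested
insertion splits its host into two reported fragments rather than one
blurred copy).  Loci hit by several families resolve to the best
identity.  5'-truncation is the consensus 5' extent absent from the
alignment; the 3' terminus is intact only when the alignment covers the
final consensus base.

Two boundary artefacts of local alignment required explicit handling,
both discovered by the generator's truth channel:

1. a truncated copy's alignment happily extends a few columns past the
   true element boundary whenever flanking target bases chance-match the
   consensus (a one-base extension is a free +1 a quarter of the time).
   Non-terminal alignment ends are therefore trimmed back to an anchored
   run of 6 consecutive matches, and when a small 5' remainder of the
   consensus (≤ 10 nt) is left unaligned, that many genome bases at the
   boundary are treated as element, not flank;
2. in the census, alignment of the target model across a locus can creep
   one or two bases into an adjacent element 3' UTR.  Aligned columns
   falling inside detected element intervals (extended over short
   unaligned consensus 3' tails) are trimmed before the locus boundary
   and the missing-5' extent are measured.

A one-to-two-base ambiguity is irreducible at the junction of a
truncated copy: when the element base at the truncation point equals the
next target base, the junction placement is genuinely unidentifiable
from that copy alone.  The modal statistics over many copies are immune;
per-copy geometry calls at truncated 5' junctions are not, and the
recovery experiments therefore use full-length copies, leaving
truncation to the detection and sensitivity tests.

## Junction classification and geometry inference

Flanks (60 nt, element-sense, reverse-complemented for minus-strand
copies) are classified against the target model and every family
consensus with the exact aligner on both strands.  A classification
needs ≥ 15 matching bases at ≥ 0.85 identity (strict profile; a relaxed
0.75/12 profile exists for weakly specific families whose junctions
carry only short degenerate target fragments).  Target gene beats
element on score ties; flanks with N-runs ≥ 5 are "unsequenced" and
never classified further — they propagate as exclusions, not as
"other".

Geometry per copy:

* sequence TSD = the longest block (≤ `tsd_max` 30) that both ends the
  5' flank and starts the 3' flank, exact by default.  Blocks shorter
  than 4 bp are ignored unless corroborated by target mapping — a
  1-base terminal identity arises by chance at 25% of junctions;
* when both flanks map to the target model (plus strand), the gap
  between the 5'-flank match end and the 3'-flank match start gives the
  deletion length directly; a negative gap is re-reported as a TSD.
  Mapping evidence overrides the sequence block because it sees through
  residual unaligned element bases at the boundary;
* when only the 3' flank maps, starting at model position s > 1, with a
  non-target 5' flank and no sequence TSD, the target's first s−1 bases
  are absent and are reported as a deletion — the inference used for
  5'-target-deleting families, whose upstream target fragment is simply
  missing from the locus;
* a 3' flank mapping upstream of the 5' flank end by more than
  `tsd_max` leaves the geometry unset with a warning.

## Census

The genome is scanned with the model's 5' ~100 nt and with its
post-insertion-site remainder; merged candidate loci are re-aligned
against the full model.  A locus is **intact** when model positions
1..50 are all present from position 1; **disrupted** when it begins at
or after the insertion site *and* an element 3' terminus lies within
`adjacency_gap` (5 nt) of its 5' boundary; otherwise **fragment**.
Adjacency to an element 5' end is recorded but deliberately not counted
as disrupted — the diagnostic signature of this integration mode is
3'-UTR adjacency, and the 5'-side gene stubs left by blunt or
duplication geometries would otherwise inflate the disrupted count.
Note a duplication-type insertion leaves the functional 5' region
upstream of the element, so such loci contribute one intact *and* one
disrupted record; exact intact+disrupted conservation against the
generator's locus count holds for the deletion geometry.

`bootstrap_target_model` optionally re-derives the model from the
majority consensus of the genome's own intact loci, avoiding
cross-species reference bias.

## Family tools

Clustering is single-linkage on pairwise identity (edlib semi-global
alignment, shorter sequence as infix; linkage requires ≥ 100 aligned
columns), order-independent by construction.  The consensus is the
per-column majority non-gap base over a star alignment onto a reference
copy; columns with under half non-gap rows are dropped and ties break
alphabetically.  Trees are neighbor joining (scikit-bio) on p-distances
over shared non-gap columns, with negative branch lengths clamped to
zero, and bootstrap support from 100 column resamples by default.
p-distances rather than model-corrected distances are a deliberate
simplification: the tree is a family-grouping aid, not a publishable
phylogeny.

## Problem sizes and numerical choices

The recovery experiments use 11 arrays × 20 genes (220 loci), a 700-kb
random background contig, a 1.5-kb element consensus and 200 on-target
insertions at 5% substitution / 0.1% indel divergence — enough copies
for stable modal statistics in a ~1.1-Mb genome while a full
three-geometry run stays within a few minutes on one CPU.  Real elements
of this class are several kb; nothing in the analysis depends on element
length beyond detection runtime.

Known limitations: no post-integration rearrangement model; no
orientation bias data for real off-target insertions; the weak-
specificity profile thresholds (0.75/12) are a design choice, not a
fitted quantity; family identity cutoffs are a proxy for curated family
boundaries and make no claim of matching them.
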