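# Methods

## The mapping model

An integrative genetic element (IGE) is a mobile DNA unit for which a
putative *attL*, *attR* and at least one contained integrase gene can be
identified.  Integration by a tyrosine- or serine-family integrase leaves
the element flanked by two recombinant att sites sharing a direct-repeat
(DR) block; the uninterrupted host site (*attB*) carries a single DR copy.
Two empirical principles drive the mapper:

1. **Integration-module cohesion.**  The integrase gene lies close to one
   element terminus, because DNA-active enzymes sit near the site (*attP*)
   they act on.  An integrase midpoint therefore approximately marks a
   chromosome/element boundary.
2. **Sporadic occurrence.**  Among related genomes some carry the element
   and some do not.  A reference genome with the uninterrupted site pins
   both termini exactly.

The two-phase ("ping-pong") search takes 15-kb flank queries left and
right of the seed midpoint (q1L, q1R) against a reference collection.  A
phase-I match longer than 500 bp that does **not** reach the
coordinate-proximal query end (a match that does indicates a reference
carrying the same element; 10-bp slop, configurable) truncates at the
chromosome/element junction, fixing the seed-proximal terminus and the
attB location.  A 3-kb return query is taken from the reference adjacent
to that junction, reaching back 250 bp into the matched region so it
spans the DR block; aligned back to the source replicon, its match distal
to the seed fixes the far terminus.  The DR length falls out of the
geometry: if the distal match begins `o` bases into the reachback region,
`dr = reachback − o + 1`, and then `left = junction − dr + 1`,
`right = distal_start + dr − 1`.  The element span convention is
`[attL_start, attR_end]`, i.e. both DR copies included.  Size limits are
2–200 kb.  Support is the number of distinct uninterrupted reference
genomes yielding the call; calls whose two termini each differ by at most
20 bp (configurable) merge, summing support, onto the best-supported
member's coordinates, and identical calls seen from both flanks collapse
without double-counting.

IS mode runs the identical machinery from a DDE transposase seed with a
30-bp reachback and 5–15 kb size limits.  It backs the transposed-IS
artifact control: when a phase-I or phase-II match region lies entirely
within an IS (as delimited by IS-mode mapping from a DDE gene inside the
region, or covered end-to-end by an IS database record), that piece of
supporting evidence is discarded; a call whose evidence is all
IS-confined is rejected.  The filter runs per supporting reference before
variant merging, so one IS-confounded reference cannot sink an otherwise
well-supported call.

## Alignment engines

Two engines share one match-record contract.  The internal engine is a
deterministic exact k-mer (k=16) seeded, ungapped X-drop extended local
matcher.  It models substitutions but not indels — the regime of the
synthetic fixtures and of the closely related references the method
depends on — and exists so that every stage is testable without network
or databases.  The BLASTN adapter shells out to `blastn` (megablast
defaults) and parses tabular output; on mutation-free fixtures both
engines produce identical calls (tested).

## False-positive score

Seven per-candidate metrics: G+C bias against the host replicon; Karlin
dinucleotide signature distance δ* (relative abundances computed on the
sequence concatenated with its reverse complement); housekeeping and
foreignness gene-content scores (mean per-Pfam enrichment-factor
difference between element genes and all replicon genes, with enrichment
tables built as count-in-positive-set over count-in-all-genes);
hypothetical-protein fraction difference; length; and delta-int, the
distance from a contained integrase to the nearest terminus, floored at 1
(also when the gene overhangs a terminus) so log-scaled modelling is
safe.  Candidates are standardized and projected on principal components;
a convex hull drawn around independently confirmed candidates in the
(PC1, PC3) plane — that plane spreads the data best, and is configurable —
relabels points as within/outside hull; an unregularized logistic-link
linear model on the raw metrics, fit on a random 75% split, yields the
score (higher = more false-positive-like) with a Youden-optimal cutoff
and held-out AUROC stored on the model.  A separate seed-level screen
rejects integrases whose raw-call signal suggests recombination by
another agent: with ≥ 5 mutually overlapping raw calls and a top:second
support ratio < 4 (both configurable; chosen once as round defaults in
the spirit of the original data-driven cutoff), the seed and its
dependent calls are dropped.

## Tandem resolution

Sequential integrations into recombinant sites produce tandem arrays.
Under the both-DRs-inclusive span convention, adjacent units overlap by
exactly one DR copy, so terminus identity uses DR-block start keys
(`right − dr + 1`; `right + 1` when dr = 0): unit B follows unit A when
`B.left == A.block_right`.  Calls are grouped into tandems by transitive
key sharing (fuzz was absorbed earlier by variant merging), and each
tandem is partitioned at internal keys, requiring every unit to contain
an integrase and obey size limits.  Among valid partitions the one
maximizing summed support of directly called units wins, ties broken by
minimal summed false-positive score; units implied by the partition but
never directly called are emitted as inferred.  Overlapping calls that do
not share a terminus are resolved to a fixpoint by rejecting lower
support, then higher false-positive score.  Strictly nested
configurations (an element wholly inside another with neither terminus
shared) drop the inner call.  Combined mode seeds tandems from
tRNA/tmRNA-site (Islander-style) call termini first — such calls carry
pseudo-support 1 — admits comparative calls sharing one of those keys,
then builds tandems from the remaining calls.

Targets are typed from the genes overlapping the DR block (reference
annotation preferred, then the query attL and attR copies): two or more
genes → multi-gene, one gene → its class, none → intergenic.  Names
follow `GenomeID.Size.Target` with size in kb rounded and tRNA isotypes
abbreviated to one letter.

## Deduplication

Vertical inheritance duplicates elements across closely related genomes.
Pairwise fragment ANI cuts the query into non-overlapping 500-bp
fragments (at least 2), places each by best infix alignment in the
partner (edlib; admission at ≥ 80% identity), and reports mean identity
(ANI) and mapped fraction (AF).  Both directions are computed; the pair
keeps an edge if either passes ANI > 0.95 and AF > 0.9.  All-pairs
shortest paths (Floyd–Warshall, unit weights) feed DBSCAN with eps = 1
and min_samples = 2 — provably connected components on such a graph, and
asserted against a union-find oracle on random graphs.  Each cluster is
replaced by one representative: highest support, then best
false-positive score, then lexicographic id.

## Subtyping and the domain-disruption assay

Phage calling uses curated virion / non-virion HMM category counts:
Phage1 needs one of each; Phage2 one hit of a single category.  ICE1
needs ≥ 7 ICE-protein hits covering ≥ 15% of element proteins; ICE2 ≥ 2
hits covering ≥ 12% (< 10 kb) or ≥ 7% (≥ 10 kb).  Strong-phage + ICE
double calls resolve to the composite ICE+Phage; weak-phage + ICE to
ICE.  Raw type fractions are corrected by the heuristics' recall on
positive controls (0.982 phage, 0.752 ICE), the remainder reported as
unknown.

The disruption assay asks whether integration inactivated the target
gene *without* restoration.  A 998-bp window centred at each terminus
(outer 499 bp chromosomal, inner 499 bp element) is translated in six
frames → 12 attLR peptides.  attB candidates join the chromosomal halves
at the DNA level in all nine frame-offset combinations per strand → 18
attB peptides; whatever DR length shifted the downstream frame, one
combination restores the reading frame on both sides of the crossover
(joining at the DNA level rather than concatenating peptide halves
preserves the junction codon, so with dr = 0 one combination reproduces
the uninterrupted protein exactly).  Stop codons stay as `*` and break
match envelopes naturally.  Hits must span the centre crossover residue
at ≥ 20 bits; for the best-scoring domain across all 30 peptides, attB
"wins" — disruption without restoration — when its top attB score is
≥ 1.1 × the top attLR score.  The same best domain is used on both sides.
The scorer contract admits pyhmmer profile searches or a deterministic
stub keyed by exact subsequences of a reference domain peptide, chained
collinearly so small internal deletions cost only the missing residues.

## Tree analytics

Clade depth is the mean pairwise patristic distance among clade leaves
(reroot-invariant); site purity is the percentage of members using the
clade's most frequent attB site; bootstrap support is read from node
labels with percent/fraction auto-detection.  The promiscuity screen
flags high-support (≥ 50%) clades with purity < 25% and depth not
exceeding the IS607 anchor clade's depth; clades of ≤ 4 members are
excluded since their minimum purity is already 25%.  The default
boundary is the rectangle rather than a sloped hypotenuse; the original
triangle's geometry is not numerically specified, and the rectangle is
the conservative superset that still honours both anchors.  IS607-family
membership uses a profile score cutoff of 64 bits.  RGI (regulated gene
integrity) candidates are tight (depth ≤ 0.5 substitutions/site mean
pairwise, configurable), high-support clades of ≥ 2 deduplicated members
all disrupting the same domain at crossover positions within 10 residues
(configurable); nested candidates collapse to the largest qualifying
clade.  The 2×2 chi-square is Pearson's without continuity correction,
df = 1.

## Synthetic data: what it does and does not show

The fixture generator plants elements with the DR duplicated at both
termini, an integrase near one end, references with the site
uninterrupted (single DR copy), references still carrying the element,
tandem arrays with per-flank-combination references, a transposed-IS
artifact pair, and mock elements (random same-length segments of the
same replicon, avoiding real spans — the cleaner negative control).  DR
content is native site sequence, so a DR extending to the end of an
interrupted gene naturally restores it across attL, reproducing the
attP-fragment strategy of real elements.  At every planted junction the
four interior bases nearest the junction are set to differ position-wise
from the corresponding flanking bases, making the true junction the
unique maximal alignment boundary; exact-coordinate recovery is then a
meaningful bit-exact assertion rather than a coin-flip on chance
extensions.  Reference divergence is modelled as i.i.d. substitutions
(no indels by default).

What passing these tests shows: the junction geometry, support
accounting, tandem algebra, artifact control and assay logic are correct
under the stated model.  What they do not show: robustness to indels,
rearrangements, assembly errors, diverged DRs, or reference collections
with complex phylogenetic structure — real-data behaviour beyond the
substitution model is out of scope here.

## Problem sizes and defaults

Synthetic replicons are 40–80 kb with elements of 3–20 kb, DRs of 0–60
bp and 1–3 clean references — small enough that a full planted-recovery
sweep (50 seeded scenarios) completes in about a minute on one CPU with
the internal engine, while exercising every code path the genome-scale
survey would.  Mock cohorts use 500 segments (5 per element is the
production default, `k` configurable).  All generator outputs are pure
functions of (spec, seed).
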