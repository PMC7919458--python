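# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package.  Coordinates are 0-based half-open
everywhere internally; GFF3 is emitted 1-based closed, BED stays half-open.

## Species tree and branch model

The fixed topology has three ingroup taxa (`sim`, `mau`, `sec`) joined by a
`stem` branch, a reference taxon (`mel`) as their sister, and an outgroup
(`yak`) that only polarizes states.  Named branches carry events: the three
ingroup terminals, the stem, the reference terminal, and the `root` edge
subtending reference + trio.  Default durations (Myr): ingroup terminals
0.25, stem 2.5, reference terminal 2.75, root edge 3.25, outgroup terminal
6.0 (substitutions only).  These follow the divergence-time framing of the
clade the design mimics: the trio radiated recently (~0.25 Myr of
independent evolution), the stem lineage persisted ~2.5 Myr after the split
from the reference lineage.

Dollo polarization assigns a two-state character to the unique branch whose
descendant set separates the derived from the ancestral taxa; with missing
data several branches may qualify and the event is reported ambiguous
rather than guessed.  Because the outgroup terminal is not a modeled event
branch, a state private to the outgroup is attributed to the root edge —
the two are indistinguishable with a single outgroup.

## Synthetic genome evolver

The ancestor is a uniform-random sequence per chromosome with a terminal
pericentromeric heterochromatin segment (default 50% of each chromosome),
protein-coding genes (5 exons of 120–400 bp, introns 80–1200 bp, CDS inside
the transcript span) and tRNA clusters in euchromatin, and satellite arrays
(exact tandem copies of 150-bp monomers from a small family library) in
heterochromatin.  Ancestral TE copies are exact suffix copies of per-family
consensus sequences, so multi-copy families have no unique k-mers — the
property that makes repeats "fail to align uniquely" downstream.

Events per branch are drawn from Poisson(rate × branch Myr × genome Mb),
applied in a shuffled order with coordinates interpreted against the
current sequence, so liftover is well defined.  Every (branch, event-type)
pair uses its own named random substream derived from the seed: changing
one rate never perturbs unrelated draws, and a fixed (config, seed) is
byte-reproducible.  Jukes–Cantor substitutions are applied last on each
branch at p = ¾(1 − e^(−4/3 μt)), never within ±5 bp of a planted-event
breakpoint, keeping breakpoints exactly recoverable.  Events that cannot be
placed after bounded retries are skipped with a warning and excluded from
the truth ledger.

Default rates (events/Mb/Myr) are desk-scale choices, not published values
(none are published):

| event | rate | notes |
|---|---|---|
| TE insertion (terminals) | DNA 2.2 / LTR 0.65 / non-LTR 1.15 | LTR-dominated bp shares (~52/34/14), the species-specific pattern |
| TE insertion (stem) | DNA 5.1 / LTR 0.10 / non-LTR 0.20 | ~70% DNA bp — the young DNA-transposon burst |
| TE insertion (root edge) | DNA 2.1 / LTR 0.10 / non-LTR 0.78 | ~52% non-LTR bp — old shared content |
| inversion | 0.5 | breakpoint placement weighted 20:1 het:eu |
| tandem / dispersed duplication | 1.6 / 0.3 | tandem lengths log-normal, median 1.5 kb |
| satellite expansion/contraction | 0.4 | ±2–15 monomers |
| tRNA duplication / deletion / anticodon shift | 0.05 / 0.05 / 0.08 | low turnover, a handful of events tree-wide |
| intron indel | 2.0 | log-normal lengths, median 40 bp; 15% of insertions are TE fragments |

TE lengths are log-normal per class (medians DNA 320 bp, non-LTR 1.5 kb,
LTR 4 kb; copies are 5′-truncated consensus suffixes).  The per-branch
class *rates* were derived from the intended bp shares divided by the class
length medians, which is why DNA events dominate counts while remaining
short.  Inversions default to 5–40 kb: at a 4 × 5 Mb scale, larger
inversions at the same per-Mb rate overlap one another so heavily that few
events remain individually scorable; length is a free desk-scale parameter.
The 20× heterochromatin placement weight with a 50% het fraction puts
≈95% of rearrangements in heterochromatin.

The truth ledger records each event's type, branch, payload and
application-time coordinates, and tracks every event footprint through all
subsequent events, so each leaf taxon has exact derived coordinates for
every event on its root-to-tip path.

What the generator does **not** emulate: nucleotide-level TE decay and
nested insertion structure, polymorphism within species, assembly error,
segmental aneuploidy, and realistic satellite higher-order repeat
structure.  Passing recovery tests therefore demonstrate correctness of
the inference logic under clean divergence, not robustness to assembly
artifacts.

## Synteny

Anchors: packed integer codes for every k-window (k = 21, odd to exclude
palindromes), canonicalized against the reverse complement; windows whose
canonical code occurs exactly once in each genome are matched and merged
into maximal runs.  Chaining is greedy in reference order (same
orientation, gaps ≤ `max_gap` = 20 kb, monotone coordinates with ≤100 bp
overlap tolerance for runs abutting non-unique patches), followed by a
re-merge pass after discarding chains shorter than `min_block` = 1 kb; on
unique-anchor input this attains the maximum-anchored-bp chain.  Blocks are
then made disjoint on both genomes: lighter blocks lose anchors that fall
inside a heavier block's span and are re-chained (repeat-relic chains whose
anchors were displaced into a paralogous copy), and residual ≤200 bp
boundary-window overlaps are trimmed.

Interval projection interpolates between anchors (exact within an anchor,
linear across gaps).  Block identity is an edit-distance alignment
(end-to-end for blocks ≤20 kb, sampled anchor-centred 10-kb windows for
larger blocks, length-weighted) — a deliberate estimate, since end-to-end
alignment of multi-Mb blocks is quadratic cost for no inferential gain.

## Rearrangements and DCJ

The breakpoint count is the number of non-conserved adjacencies of the
signed block permutation, chromosome ends included; it is the package's
"rearrangement count" statistic, chosen because it is the standard,
reproducible scalar when the upstream tool's internal event count is not
specified.  The DCJ distance uses the extremity adjacency graph; path
parity follows the extremity count of the component (each extremity
contributes one adjacency-graph edge), which the brute-force BFS oracle
confirms exactly for all signed genomes with ≤6 markers, both topologies.

Inversion calls from different taxa are clustered by ≥50% reciprocal
overlap in reference coordinates; each cluster's per-taxon orientation
states (projected interval, 'missing' below 50% projection) feed Dollo
assignment, and its compartment is the reference-taxon midpoint rule with
boundary-spanning calls conservatively labeled heterochromatic.

## Duplications

Within a block, a query-side duplication shifts the alignment diagonal by
the copy length, and anchors inside the duplicated region are an
unreliable mosaic (reference k-mers match either copy once one copy has
diverged).  Candidates are therefore diagonal *steps* between anchor runs
(fine steps between all consecutive runs resolve compound regions; coarse
steps between ≥200-anchored-bp runs catch mosaic interiors; duplicate
candidates collapse by ≥50% source-interval overlap).  The surplus length
equals the step, so the copy sequence is extracted directly and matched
against the reference within `copy length + tandem gap (10 kb)` of the gap;
≥2 images of the source within the local window make a tandem call,
a matching insertion elsewhere a dispersed call (bounded genome-wide
search).  Annotated repeat intervals are excluded (≥50% masked), so TE
insertions are not re-reported as duplications.  Gene-model overlap
classes are nested — full_gene (transcript span contained) ⊃ full_CDS ⊃
exonic ⊃ intergenic — and the maximal attained class is reported.
Cross-taxon sharing and outgroup polarization use ≥50% reciprocal overlap
of reference-frame source intervals; stem count = trio-shared −
outgroup-overlapping by construction.

## TE branch assignment

Scope defaults to euchromatin and TE classes only (satellites excluded
from the sharing algebra; a toggle exists).  Containment (fraction 1.0 in
a single block) is evaluated per species pair with that pair's own map —
an element outside the reference-pair's blocks can still be stem-shared,
which is precisely what makes stem elements assignable.  Categories are
mutually exclusive and exhaustive over the focal taxon's analyzed
elements, so category bp totals sum exactly to the element total.
Categories describe *detected* sharing only; an element labeled
taxon-specific may simply have escaped detection elsewhere.

## tRNA orthology

Genes become one isotype letter each (lower-case pseudogenes; case ignored
in scoring), per chromosome in positional order; cluster boundaries fall at
inter-gene distances >5 kb.  Pairwise global alignment to the reference
taxon uses match +2 / mismatch −1 / gap −2 with a deterministic tie order
(diagonal, then gap-in-reference, then gap-in-query), verified against an
exhaustive alignment enumeration for strings ≤8.  Multi-taxon columns are
merged on reference positions; insertions relative to the reference merge
across taxa at equal offsets — exact for single-gene gains, and the reason
multi-event clusters are reported as ambiguous rather than resolved.
Anticodon shifts at orthologous columns are isoacceptor (same isotype) or
alloacceptor (isotype change); the ancestral state is the outgroup's, and
the branch is the Dollo assignment.  Optional flank confirmation projects
±1 kb of the reference member through the synteny map and flags columns
whose member lies >10 kb from the projection.

## Introns

Conserved introns require equal exon counts in all taxa and both flanking
exons within 10% length difference of the reference taxon's, evaluated
symmetrically as |a−b|/max(a,b) ≤ 0.10 (the denominator convention is a
package choice; an all-pairs mode exists).  An intron is complex in a
taxon when ≥1 bp overlaps a TE or satellite annotation there, else simple;
the two classes partition the conserved set exactly.  Length contrasts are
two-sided paired t-tests on per-intron differences; zero-variance inputs
are flagged degenerate (all-zero differences report p = 1, a constant
non-zero shift reports no p-value) rather than producing an infinite
statistic.

## Statistics

The proportion test is the normal-approximation z-test with optional Yates
continuity correction; with the correction and a two-sided alternative it
matches R's `prop.test`.  Both variants are exposed because published
"proportion test" values are variant-inconsistent across results; the
defaults used in the duplication analyses are the variants that reproduce
the pinned values (two-sided with correction; one-sided greater with
correction for the directional contrast).  The exact binomial test
(minimum-likelihood two-sided rule) serves as the oracle; the approximation
is within 10% relative error on well-populated grids (n ≥ 1000, |z| ≤ 2)
and degrades in far tails, as expected.  Tail probabilities come from
scipy's distribution machinery.

## Problem sizes used in tests and the acceptance script

Module tests run on a shared 2 × 500 kb five-genome simulation; the
acceptance suite and script use the package default of 2 × 2.5 Mb
(4 analyzed taxa + outgroup), the scale at which per-branch recovery
statistics have enough planted events to be meaningful while a full run
stays within a few minutes on one CPU.  The anticodon-shift accuracy is
aggregated over the main run plus two small tRNA-focused replicates
(dense clusters, shifts as the only cluster mutations), because at
realistic low turnover a single run may contain only one or two
unambiguous shifts.  The intron-effect scenario plants insertion-only
indels (median 500 bp) on the reference branch across 150 genes / 600
introns; with exons untouched the planted mean shift is recovered exactly
by construction, so the test genuinely measures the matching and pairing
logic.

## Known limitations

* Anchor uniqueness is an analog of — not a re-implementation of — the
  seeding of production whole-genome aligners; absolute aligned-fraction
  numbers are not comparable to theirs.
* Nested or overlapping inversions are reported as maximal reversed runs;
  events that can only be decomposed with multi-taxon information are
  flagged, not resolved.
* Dispersed-duplication discovery uses a bounded genome-wide search and is
  not exhaustive; tandem duplications are the quantitative target.
* The simulator's clean-event assumptions (no breakpoint erosion beyond
  substitutions, no polymorphism) make recovery metrics upper bounds for
  real-data performance.
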