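# Methods

## Diagnostic barcodes and mismatch allowances

A diagnosis targets one species in a labelled, pre-aligned ITS/LSU
matrix. The canonical sequence is the lectotype (by default the first
accession of the target species): printed diagnoses are single concrete
strings, so the barcode is the canonical's window, not a consensus with
ambiguity codes. For each contiguous window of length 20–30 columns
lying inside one region, two quantities are computed by exhaustive
comparison against every sequence:

- `d_in` — the largest window Hamming distance from the canonical to a
  conspecific sequence;
- `d_out` — the smallest window Hamming distance from the canonical to
  any non-target sequence (the nearest heterospecific is reported).

Window Hamming distances treat a gap opposite a base as one difference,
a shared gap as agreement, and two residues as matching when their IUPAC
sets intersect (an `R` in the template matches an observed `A`). A
sequence is attributed to the target iff its distance to the barcode is
at most the allowance `k`; that classification is correct for all
sequences in the alignment exactly when `d_in ≤ k ≤ d_out − 1`, which is
therefore the valid allowance interval. The value printed in a
diagnosis is capped at 1 by convention — allowances beyond one mismatch
are rarely communicated — with the cap floored at `d_in`; both interval
and printed value are emitted.

Candidate windows are filtered (no ambiguity code in any target member
within the window; `d_out ≥ 2`, so the barcode has at least two
differences from the closest relative; non-empty allowance interval) and
ranked by separation margin `d_out − d_in` descending, then fewer gap
columns in the canonical window, then leftmost start, then shortest
length. The tie-breaks are this package's own convention; "most
characteristic" admits several orderings, and the chosen one is
deterministic and favours compact, gap-free, early windows. Windows
containing canonical gap columns are allowed but deprioritised; the
barcode string is the degapped canonical substring and printed positions
are 1-based inclusive on the degapped lectotype, region-relative
(`ITS2 positions 127–146` style). Internally all computation is
column-wise; `CoordinateIndex` performs the conversion explicitly.

The search is vectorised (per-column difference indicators + sliding
window sums), and the test suite holds it equal to an independent
brute-force enumerator over random alignments, including ranking.

### Comparison scope

"Closely related species" means every non-target sequence in the
supplied alignment. The published per-figure comparison sets follow no
stated rule, so scoping the alignment is deliberately the caller's job;
a diagnosis is only as exclusive as the alignment it was computed on.

## Within-species variability and species counts

Within-species variability is the maximum pairwise uncorrected
p-distance among the species' sequences over a region. Comparable
columns exclude shared gaps and every column inside a gap run longer
than `max_indel = 20` columns in either sequence — a long deletion is
one evolutionary event, and counting it per-column would swamp the
estimate (the threshold is configurable; runs are reported alongside
the estimate). A gap opposite a base counts as one difference, so the
statistic represents indels alongside substitutions. Whether
ambiguity-code columns enter the comparison is exposed as a flag
(`drop_ambiguous`, default off) rather than fixed, since either reading
of published percentages is defensible.

Approximate species counts per genus use single-linkage clustering of
members at p-distance ≤ 3% over ITS (scipy's linkage on the pairwise
matrix). The 3% default is this package's operationalisation of a
visual assessment and is always reported next to the count.

## Clade delimitation

Taxa are delimited on rooted, support-annotated trees (ultrafast
bootstrap labels on internal nodes; a `label/value` dialect is parsed on
request; supports on a 0–1 scale are rescaled to 0–100). The
least-inclusive clade of a set of accessions is the MRCA subtree; leaves
under the MRCA not named in the query are reported as swept-in members
rather than silently absorbed.

`propose_taxa` partitions the unlabelled leaves into candidate taxa
satisfying: (i) monophyly; (ii) support > 95 (missing support fails the
filter by default — conservative — with a flag to pass; single leaves
are trivially monophyletic and carry no support); (iii) phylogenetic
breadth, operationalised as the maximum within-clade patristic distance
because no standard metric exists for "breadth", within 0.5×–2.0× the
range of the reference taxa's breadths (band configurable, always
reported); and (iv) minimality of the number of taxa. Acceptance is
greedy from the root down: the qualifying clade closest to the root is
taken and its subtree skipped. Because clades of a tree are laminar
(any two are nested or disjoint), every qualifying clade lies inside a
maximal one, so the greedy partition is exactly the minimum-cardinality
cover of the coverable leaves — the exhaustive-search oracle on small
trees confirms this rather than correcting it. Trees are used as given;
no re-rooting is attempted.

Candidate codes are `<prefix><zero-padded index>` with per-rank prefixes
(GEN/FAM/ORD by default; a bare "GS"-style prefix is a one-line
configuration), ordered by smallest leaf accession so identical input
yields identical codes. The published coding scheme lives in
supplementary materials not reproduced here, so the default prefixes are
placeholders by design.

## Primer screening

Primer/template compatibility is set inclusion: the template base's
IUPAC set must be contained in the primer code's set, so a degenerate
primer position covers its variants but a degenerate template base is
not forgiven (an `N` in the template only matches a primer `N`; a flag
treats template `N` as compatible for permissive screening). Reverse
primers are matched against the reverse complement. Each primer is
placed at every offset of the degapped sequence and the
minimum-mismatch placement kept (ties to the smallest offset);
mismatch positions are indexed from the 3' end, where extension is
compromised: position 1 is terminal, positions 2–3 near-terminal
(window configurable; the published usage never defines
"near-terminal"), the rest central. Group summaries report, per
lineage, the fraction of clean hits — at most one mismatch and none
(near-)terminal — and call a primer "matches well" at ≥ 90% clean; this
threshold approximates a by-eye consensus reading with a per-sequence
statistic and is recorded in the output. No thermodynamic modelling is
attempted. Only the three primer sequences actually printed in the
source are shipped; the other cited primers appear as named
placeholders whose sequences the user must supply, because inventing
published sequences from memory would be worse than omitting them.

## Synthetic data

The generator emulates the data regime the pipeline assumes:
multi-species ITS1/5.8S/ITS2/LSU alignments (default region lengths
150/155/200/700 columns) with tight conspecific clusters and larger
interspecific divergence. A unit-rate Yule tree over species is rescaled
so the mean pairwise species path length equals the JC69 branch length
`t(p) = −(3/4) ln(1 − 4p/3)` matching the between-species divergence
target; conspecific sequences hang off each species tip as a star with
branch `t_within/2`, so the expected pairwise conspecific divergence
hits the within-species target. With `n_genera` set, a genus-level Yule
tree is built first and species trees grafted on, giving a three-tier
topology with known boundaries.

Sequences evolve under JC69: uniform root, per-branch substitution
probability `p(t) = (3/4)(1 − e^(−4t/3))`, new base uniform among the
three alternatives. JC69 is the simplest model adequate for testing
distance-based procedures; the model is a config enum with one
implemented member. Indels are injected post hoc as aligned gap runs
(start probability 5×10⁻⁴ per site, geometric lengths, mean 5) —
emitting an alignment directly sidesteps re-alignment, which is out of
scope — and ambiguity codes replace bases at 10⁻³ per site with a code
containing the true base. Defaults (within 1%, between 8%) follow the
published regime of intraspecific ITS variability up to a few percent
with clearly larger interspecific divergence.

Every run emits a ground-truth record: species/genus assignment,
realized maximum within-species divergence (computed by an independent
plain-loop scan, so truth and pipeline cross-check each other), the
tree, and the planted window if any. Emitted FASTA/TSV/JSON/Newick
bundles co-validate on reload. All randomness flows from one mandatory
integer seed through independent `SeedSequence` streams; reruns are
byte-identical.

### Planted-motif scenario

`plant_barcode` writes one random 25-base motif into all members of a
target species in a gap-free window and minimally edits every other
sequence until it differs from the motif at ≥ 3 window positions, then
records the realized minimum separation. The recovery scenario
(`planted_recovery_config`: 10 species × 5 sequences, within 0.5%,
between 2%) keeps the background quiet — away from the plant, windows
rarely accumulate more than one lineage-private difference — so that a
correct search must rank the planted window first essentially always.
Because the motif is random, heterospecific sequences typically differ
from it at far more than the guaranteed 3 positions.

### Planted-genus scenario

Genus boundaries are recoverable under the breadth criterion only when
the band cannot reach across genera: `band_hi × (within-genus breadth) <
between-genus patristic distance`. `planted_genus_config` (3 genera ×
3 species × 3 sequences; 0.5% within species, 5% between congeners, 30%
between genera) satisfies this with the default 2.0× band. Under the
general defaults the tiers are close enough that an ancestor of two
genera can legitimately qualify, which is a property of the criteria,
not a bug; the scenario documents the identifiability condition
instead of hiding it.

### What passing these tests does and does not show

The simulator has no rate heterogeneity across sites, no rRNA secondary
structure, no alignment error, and no chimeras; conspecific sequences
are a star, not a coalescent genealogy. Passing the planted-truth tests
shows the search, allowance and delimitation logic are correct under the
stated model — not that real ITS alignments satisfy that model. On real
data the limiting factors are alignment quality and comparison-set
scope, which the pipeline deliberately leaves to the user.

## Numerical and edge-case choices

- Distances are exact rational counts evaluated in double precision;
  truth-vs-recomputation checks require exact equality because both
  divide the same integers.
- Zero comparable columns raises an undefined-distance error rather
  than returning 0 or 1.
- A species with a single sequence reports variability 0 with an
  explicit flag.
- Regions shorter than the minimum window length yield an empty window
  set with a machine-readable reason; "no separation" failures report
  the best margin achieved.
- Printed-diagnosis inconsistencies (span ≠ barcode length; one barcode
  string printed for two genera) are flagged by the validator and never
  corrected: which of positions or string is authoritative is unknown.
- Diagnosis fragments use the exact printed punctuation; the one
  published fragment pair that separates barcode and allowance with a
  comma rather than a semicolon is stored as a parameter of the
  transcription, not normalised away.

## Problem sizes used in the shipped experiments

The analysis scripts and acceptance checks run at desk scale, chosen so
a full pass is comfortable on a laptop: 100 random alignments (≤ 15
sequences × ≤ 220 columns) for the brute-force agreement check, 100
seeded planted-motif replicates (50 × 1205 alignments), 10,000 sites
for the JC69 closed-form check, 40 random trees of ≤ 12 leaves for the
minimality check. These sizes are statements about the experiments, not
limits of the implementation; the vectorised search handles
full-length rRNA alignments with hundreds of sequences.
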