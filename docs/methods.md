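# Methods

This note documents the models, parameter choices and numerical conventions
behind `idrscape`, and what the synthetic test conditions do and do not
demonstrate about real data.

## Region model and coordinates

Each protein carries region annotations: one AP2 span (~57–59 aa; the
default generator uses 58), optional β-strand and α-helix sub-spans nested
inside it, and N/C flanks.  Internally all coordinates are 0-based
half-open; on-disk tables are 1-based inclusive, converted only at the I/O
boundary.  Proteins with multiple AP2 spans are structurally supported but
dropped by the pipeline with a warning, because every downstream statistic
assumes an unambiguous three-way partition (full / AP2-only / AP2-deleted).
Non-canonical residues are mapped to `X` on input and excluded from
composition denominators, hydropathy averages and substitution scoring
numerators wherever a canonical residue is required.

## Compositional profiling

The query composition `C_i` is pooled over proteins (not averaged per
protein), and compared to a fully-structured-protein baseline via
`(C_i - C_i^FSP) / C_i^FSP`.  The packaged baseline is a synthetic
stand-in table of typical globular-protein fractions
(`data/synthetic_fsp_baseline.tsv`); any user baseline TSV (residue,
fraction) is accepted, and real analyses should supply one derived from an
actual structured-protein set.  Confidence intervals use the percentile
bootstrap over whole proteins — resampling proteins rather than residues
preserves within-protein compositional correlation — with 10,000 replicates
by default (the pipeline config uses 200 to keep the one-shot run fast; the
estimate itself is not resampled).  BCa corrections are deliberately
omitted: the percentile method matches the plain resampling description the
procedure is based on, and the quantities are smooth functions of counts.

The reporting axis runs from the strongest order-promoting residue (W) to
the strongest disorder-promoting residue (E).  Only the endpoints are
canonical; the interior order is a configurable convention (default
`W F Y I M L V N C T A G R D H Q K S P E`).

## CH and CDF classifiers

The CH plot uses the mean Kyte–Doolittle hydropathy rescaled to [0,1] via
`(h + 4.5)/9`, smoothed with a centred window (default 5, truncated at the
ends), against the absolute mean net charge `|#(K,R) − #(D,E)| / length`
(histidine neutral by default, configurable).  The boundary is the
published line `<R> = 2.785 <H> − 1.151`; the module reports both the raw
vertical offset (used for quadrant calls) and its perpendicular projection.

The CDF curve evaluates the fraction of residues with disorder score ≤ b at
bins 0.1…0.9.  Boundary points are predictor-specific and therefore come
from config; the packaged default is calibrated once as the per-bin
midpoint between reference curves emitted from Beta(2,8) (ordered) and
Beta(8,2) (disordered) score distributions — the same emission model the
generator uses — under a fixed internal seed, making it a reproducible
constant.  The CDF distance is the mean signed offset over the boundary
points, positive on the ordered side.

Quadrants follow the fixed sign convention x = CDF distance (positive =
ordered), y = CH distance (positive = disordered): (+,+) Q1, (+,−) Q2,
(−,−) Q3, (−,+) Q4.  A zero on either axis resolves toward the ordered
call; this tie rule is arbitrary but documented and exercised by tests.

Per-residue disorder tracks are expected from external predictors.  The
built-in stand-in scores `clip(0.5 − k(a·H_w − b − R_w))` with window 21
and gain k = 0.25, chosen so typical windowed offsets spread over roughly
[0.1, 0.9] without saturating.  It encodes only the charge/hydropathy
signal and makes no claim of reproducing any trained predictor; every
score-consuming stage accepts external tracks in its place.

## Low complexity

The detector follows the CAST scheme: score the sequence against an
infinite homopolymer of each residue type using BLOSUM62, find the
maximal-scoring contiguous segment per type (Kadane's linear scan; an
O(n²) enumeration oracle backs it in the tests), and while the best
segment reaches the threshold (default 40), mask occurrences of the
dominant residue inside it and repeat.  Ties resolve by higher score, then
leftmost start, then alphabetical residue, making the output deterministic.
Only the dominant residue is replaced, so interleaved residues survive;
LCAA% counts masked residues within each region class, and a region class
absent from a protein reports missing rather than zero.  The threshold and
matrix come from the cited tool's defaults since no values are stated for
the analysis being reproduced.

## MoRF conservation

Dip candidates are maximal runs of scores below 0.5, between 5 and 25
residues, whose flanking context windows (10 residues; one-sided at
sequence ends) average ≥ 0.5, and which do not overlap the AP2 span —
in-domain MoRFs are accepted from external predictions only, since the dip
signature is undefined inside a uniformly ordered domain.  External tables
take precedence and may be span-shaped or per-residue scores thresholded
at 0.725.

Conservation is called per subgroup: member segments are mapped through
the subgroup alignment into column coordinates, clustered by single
linkage on column overlap ≥ 5, and clusters with occupancy ≥ 0.75 become
conserved MoRFs.  Both cutoffs are package conventions (exposed in config)
because no explicit criterion is published for "conserved within a
subgroup".  Names are `<subgroup> <side><index>` with N/C/AP2 sides and
indices increasing N→C; consensus is the majority residue per column (ties
→ X, columns covered by fewer than half the hits trimmed at the edges).
A conserved MoRF is exclusive when no other subgroup's consensus matches
it at ≥ 60% identity under the best ungapped offset — again a convention,
since exclusivity is only ever marked, not defined, in the source
analyses.

## Phospho fractions

For each region class (full / AP2 / non-AP2) and residue type S, T, Y:
100 × predicted sites / residues of that type in the region, plus the
pooled S+T+Y fraction.  Denominators are residue counts (not
candidate-site counts after predictor filtering, which is the other
possible reading); types with zero residues in a region report missing.
Counts over the AP2/non-AP2 partition add exactly to the full-length
counts, which the tests assert.

## Neighbour joining

Distances are p-distances over shared non-gap columns — no substitution
model, keeping the stage dependency-free and closed-form testable; a pair
with no shared columns is an error rather than a guess.  The agglomeration
is standard Saitou–Nei with deterministic tie-breaking (lexicographically
lowest leaf-label pair), negative branch lengths clamped to zero with the
deficit moved to the sibling, and a trifurcating root representing the
unrooted tree.  On additive matrices the path-length matrix reproduces the
input to 1e-9, verified against exhaustive topology enumeration with
least-squares branch fitting and against an independent NJ implementation.
Bootstrap support resamples alignment columns, rebuilds the tree per
replicate, and reports per-split percentages on the full-data tree;
replicates whose resampled columns leave some pair with no shared data are
skipped as uninformative.  Splits above 70% support are flagged in the
report.  Subgroup classification labels are input data, not an output: the
original assignments involved manual motif inspection that is out of scope.

## Synthetic families

The generator emulates the family architecture the analysis assumes:
per-subgroup AP2 consensuses evolved along a random binary subgroup tree
(per-edge mutation rate 0.25), members mutated from their consensus at
rate 0.08, and disordered flanks (N: 40–90 aa, C: 60–120 aa, fixed within
a subgroup) sampled from a disorder-promoting composition.  Compositions
are deliberate caricatures with effect sizes roughly twice real profiling
trends so that classification properties are deterministic at test sample
sizes: the domain composition is W/A/R-enriched and charge-poor
(K+R+D+E = 0.14 — because the CH statistic takes |mean net charge|, a
charge-rich 58-residue domain would drift across the boundary by sampling
noise alone), the flank composition is E-enriched (0.12) and K-depleted
(0.02).

Each subgroup plants one exclusive N-side motif (EAR-like, acidic, basic
or MCGGAI-like caricature) and one C-side motif shared between subgroup
pairs (LWSY-like, EDLL-like), at homologous offsets within the subgroup
and at least one context window (10 aa) inside the flank — a MoRF is by
definition a segment embedded in disordered context, and plants butted
against the domain would be undetectable by any context-requiring
detector.  A 12-residue poly-S run is planted in each C flank as
low-complexity ground truth.

Disorder scores are *emitted*, not computed from sequence: Beta(2,8) in
the domain, Beta(8,2) in the flanks, Beta(2,8) inside planted motifs
(dips), so score-consuming stages are testable independently of the
internal stand-in predictor (a flag switches to sequence-derived tracks
for integration tests).  A toy phospho predictor flags S/T followed by P
at rate 0.8 (else 0.05) and Y at 0.3 inside the domain (else 0.05),
emulating the designed S/T-outside / Y-inside contrast; it makes no
biological claim.

What passing on these families shows: the machinery (coordinate handling,
clustering, classification logic, bootstrap plumbing) is correct under
conditions where truth is known.  What it does not show: performance on
real predictor outputs, real compositional effect sizes (roughly half the
caricature), alignment uncertainty (within-subgroup alignments here are
substitution-only and gap-free; gap handling is exercised by hand-built
alignments in unit tests), or predictor disagreement.  One known
consequence of the caricature: the S/E-rich flanks score positively
against poly-S/poly-E homopolymers along most of their length, so CAST
segments are much wider than the planted 12-residue run and the
reciprocal-overlap recovery metric for low complexity is conservative;
the LCAA% contrast between flanks and domain is the meaningful readout.

## Problem sizes and determinism

Default study conditions: 4 subgroups × 6 members per family; 10 fresh
families (plus one 100-replicate tree bootstrap) in the acceptance script;
50 families in the conserved-MoRF recovery test; bootstrap sizes 1000
(composition CIs) and 100 (tree support) where exercised.  Every stochastic
stage takes an explicit seed and is bitwise reproducible; the pipeline
writes per-stage manifests with parameter values and SHA-256 digests of
inputs and outputs, so a re-run with identical config is verifiable by
digest comparison.
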