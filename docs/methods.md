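# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Curation model

The curation stage models the screening of a BLASTP hit list mined with a
query enzyme of known substrate specificity. Four rules run in a fixed
order — identity window, same-identity cap, species dedup, triad scan —
and the audit trail records the *first* rule that removed each record.

- **Identity window** (default 30–90%, inclusive): hits above the window
  duplicate the query's characteristics, hits below it are too diverged to
  inform specificity. Records with an experimentally defined function are
  exempt (`keep_defined_regardless`), which is how a 100%-identity query
  survives its own >90% rule.
- **Same-identity cap** (default 2): identity ties are compared at
  integer-percent resolution, the granularity at which mined identities are
  reported. Earliest rows win; references neither count nor fall. Note that
  the packaged 39-entry table is *not* a fixed point of this rule: four
  uncharacterized entries are printed at identity 36%, so re-screening the
  printed table removes two of them (the identities behind the original
  screen were evidently finer than the printed integers). The unit tests
  assert this honestly (37 survivors with two audited casualties) rather
  than pretending the printed table re-screens to itself.
- **Species dedup**: "one sequence per species" is operationalized as
  per-organism *residue-level* dedup, because curated candidate sets
  demonstrably keep two distinct loci from a single strain. Only true
  (organism, sequence) duplicates collapse; first occurrence wins.
- **Catalytic-triad scan**: nitrilase-superfamily members carry a
  Glu-Lys-Cys triad. The scan is an ordered-occurrence heuristic — first
  E, then K, then C, each spacing within a configurable window — not a
  profile match. The low-level operation defaults to unconstrained
  spacing; curation applies a 10–400 residue window (`CurationConfig`),
  loose enough for any plausible fold, tight enough to reject E/K/C
  adjacency by chance in short motifs. It is applied only to records
  annotated "unnamed protein product"; anything with a more specific
  annotation has presumably been triad-checked upstream.

Curation is idempotent, survivors are monotone in the cap and antitone in
window tightening, and references are never removed (all property-tested).

**Pipeline default vs synthetic runs.** `run_pessp` applies the full
curation defaults, which is right for a user-supplied mined table. The
synthetic generator, however, emulates the *post-mining* candidate set, and
its recomputed identities collide freely at integer resolution — re-running
the cap would arbitrarily delete planted subgroup members. Synthetic runs
therefore use `CurationConfig.passthrough()` (validation only, nothing
removed); this is a statement about where mining ends and the pipeline
begins, not a tuning knob.

## Alignment and distances

Pairwise alignment is global affine-gap (Gotoh) dynamic programming with
BLOSUM62 and gap open 10 / extend 0.5 (a gap of length L costs
`open + (L−1)·extend`). Traceback tie-breaking is fixed — diagonal, then
up, then left — so alignments are bit-reproducible; the DP score is
verified against an exhaustive alignment-enumeration oracle on short
sequences. The multiple aligner is guide-tree progressive: UPGMA (average
linkage) on `1 − identity/100` from all pairwise alignments, then
profile-profile merges (frequency-vector column scores `f₁ᵀ B f₂`, gaps
scoring zero) leaf-to-root with the same penalties. No iterative
refinement; this is deliberately the simple, deterministic member of the
progressive-alignment family.

Percent identity divides identical pairs by columns with at least one
residue (a `shorter_sequence` denominator is available). Distances are
p-distances with pairwise gap deletion; the Poisson correction
`d = −ln(1−p)` is offered and errors on saturated pairs (p ≥ 1).

## Tree estimation

Neighbor joining follows the standard Q-criterion agglomeration. Ties in Q
(within 1e-12) join the pair with the lexicographically smallest taxon-name
pair, which makes topologies invariant to input row order. Negative
branch-length estimates are clamped to zero with the deficit moved to the
sister edge, preserving the pair's path length; on exactly additive
matrices NJ provably recovers the generating topology and path lengths
(property-tested on 100 random trees, and cross-checked against an
independent NJ implementation from scikit-bio).

Bootstrap replicates resample alignment columns with replacement to the
original length (default n = 1000, seedable). The consensus is extended
majority rule: splits above 50% first, then compatible minority splits in
decreasing frequency (strict mode available); node support is the split's
replicate frequency in percent. Consensus trees carry supports but no
branch lengths.

Newick serialization stores support as an integer internal-node label
(`(A:1,B:2,(C:3,D:4)95:1);`), lengths to 6 decimal places; the parser
reports character offsets on malformed input.

## Subgroup designation and prediction

The predicted subgroup is the **smallest bipartition side** of the
consensus tree that contains every reference with the target defined
function. Two boundary rules matter:

- A single-leaf *complement* ("everything except X") is not a designatable
  cluster. Without this exclusion, positives scattered across the tree
  would silently collapse into an (n−1)-leaf pseudo-clade; with it they are
  flagged `non_discriminating` and no predictions are emitted.
- Any leaf sharing the target function but falling outside the designated
  clade marks the designation invalid — reported, never dropped.

Candidates are ranked by identity to the mining query (the only
per-candidate scalar available at prediction time), ties alphabetical.
Predictions are suppressed with a warning when the clade's bootstrap
support is below `min_support` (default 50%, matching the convention of
displaying only >50% supports).

## Synthetic data

`simulate_family` plants the geometry the pipeline is designed around:
default 39 taxa with a 12-member subgroup, 5 of them labeled, leaving 7
members to rediscover. The subgroup's stem length is
`separation_factor × mean within-subgroup depth` (default factor 3), so
within-group divergence is well separated from between-group divergence.
Branch lengths are uniform on `[0.5, 1.5] × mean_branch_length` (default
mean 0.05 substitutions/site): the mean is the interesting dial, while the
support bounded away from zero guarantees every edge carries a resolvable
expected number of substitutions at the default sequence length — an edge
of length ≪ 1/root_length is invisible to any estimation method, and a
curated enzyme family would not contain effectively identical sequences at
distinct loci anyway. Labeled positives are chosen to span both children
of the subgroup ancestor (as characterized references in a real clade do),
so the minimal clade spanning them is the whole subgroup.

Sequences evolve from a uniform-random root under a Poisson-style model:
along a branch of length b each site substitutes with probability
`1 − e^{−b}` to a uniformly chosen different residue; no indels by default
(gapless truth keeps distance expectations closed-form). The expected
p-distance along a path is
`(19/20)·(1 − ∏ᵢ (1 − (20/19)(1 − e^{−bᵢ})))`, the uniform-replacement
back-substitution correction, and the simulator is tested against it.
Kinetic data are Michaelis–Menten rates with truncated multiplicative
Gaussian noise on the 0.1–15 mM assay grid.

What passing synthetic tests show: the pipeline's inference machinery is
correct and deterministic, and under clean separation it recovers a planted
specificity clade exactly (20/20 seeds at the default geometry). What they
do not show: performance on real families with domain shuffling, indels,
rate heterogeneity across sites, or specificity boundaries that do not
coincide with clean clades — the generator has none of these.

## Kinetics and characterization

The Lineweaver–Burk estimator is ordinary least squares of 1/v on 1/S
(`Vmax = 1/intercept`, `Km = slope/intercept`). It is kept as the default
because it is the estimator under which the reference constants were
obtained; it is exact on noiseless data but known to weight low-S points
heavily under noise, so a nonlinear Michaelis–Menten refit is available as
a cross-check (`nonlinear_refit=True`) and both are reported when asked.
A zero rate or non-positive intercept is a hard error, not a warning.

The turnover number kcat is an **input**, never derived from Vmax and a
molecular weight: the published constants for the motivating enzyme are
mutually inconsistent under any single MW basis (45.4 µmol·min⁻¹·mg⁻¹ ×
37 kDa gives ≈28 s⁻¹, not the measured 15.4 s⁻¹), so deriving it would
launder an unreproducible assumption. `kcat/Km` uses Km converted from mM
to M and is formatted to 2 significant figures in reports.

Relative-activity profiles report values below 0.5% of the reference
activity as "N.D." (the floor sits below the smallest printed nonzero
relative activity, 1%). Optimum profiles normalize to percent of maximum
with ties resolved to the smallest condition value. Enantiomeric excess is
`100·|R−S|/(R+S)` with the excess enantiomer's label. Oligomer state is
the nearest integer of native/subunit mass, with the raw ratio returned
alongside.

## Problem sizes in the test suite

Deterministic examples run at desk scale. The stochastic end-to-end
property runs the full pipeline at the study geometry (39/12/5, separation
3, 300 residues) across 20 seeds with 50 bootstrap replicates per seed —
replicate depth beyond that does not move a support that is already
saturated, and the package's own analysis drivers use 200 replicates for
reporting. The CLI default remains n = 1000.
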