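# Methods

## The distance model

The package treats the all-vs-all matrix of local-alignment bit scores
as a noisy similarity measurement and converts it into a tree-ready
distance.  Bit scores are asymmetric in principle (the normalisation
depends on the query), so both directions are retained until the final
symmetrising average.  The transform has four steps:

1. **Missing-score repair.**  A pair without a hit gets the value
   *s*<sub>min</sub>(A)/2 in row A — strictly below every observed
   score for that query, so ranking is preserved and the logarithm
   stays finite.  Repaired entries are not added to the hit profile:
   only genuinely observed hits drive the overlap weights.
2. **Row normalisation** by *s*<sub>max</sub>(A), which includes the
   self-hit, bounding *ŝ* in (0, 1].
3. **Overlap weighting** with the Dice form
   2*n<sub>A,B</sub>*/(*n<sub>A</sub>*+*n<sub>B</sub>*).  It is 1
   exactly when the two hit sets coincide and decays with profile
   disagreement.  The alternative form
   *n<sub>A,B</sub>*/max(*n<sub>A</sub>*, *n<sub>B</sub>*) is
   available via `overlap_form="max"`; both satisfy the same boundary
   conditions.  Disjoint hit profiles abort the run: with no shared
   evidence the method has nothing to anchor a distance on.
4. **Log transform** *d = −log S* with the natural log.  The base only
   rescales all distances by a constant, which cannot change the
   topology selected by neighbour joining or minimum evolution; it does
   rescale branch lengths, which should be read as relative, not as
   substitutions per site.

Bit-score distances are not guaranteed metric.  Single-domain families
(and the simulator's output) essentially always satisfy the triangle
inequality; multi-domain proteins can violate it, which is why
`triangle_violations` reports rather than asserts.

## Scoring engine

`compute_scores_internal` is an exhaustive Smith-Waterman pass
(biopython's `PairwiseAligner`, BLOSUM62, gap open 11 / extend 1) with
raw scores converted to bits via (λ·raw − ln K)/ln 2, λ = 0.267,
K = 0.041 — the gapped parameters of the scoring regime the defaults
come from.  Because an exhaustive aligner produces *some* score for
every pair, the hit/no-hit structure of a database search is
reproduced with a threshold: entries under 15 bits (configurable)
count as "no hit".  External `blastp -outfmt 6` files are accepted as
an equivalent input; heuristic, composition-adjusted blastp scores
will differ slightly from the internal engine's, and mixed use within
one analysis is not recommended.  Only the best score per ordered pair
is kept when a file carries multiple HSPs.  Selenocysteine (U) is
scored through the X column since BLOSUM62 carries no U row; B/Z/X use
their own matrix columns.

## Tree inference

Neighbour joining (lowest-index tie-break, deterministic) provides the
starting topology; `bme_nni` then applies nearest-neighbour
interchanges in steepest-descent order under the balanced
minimum-evolution criterion — the Pauplin length, in which each
pairwise distance is weighted 2^(−p) with p the number of internal
nodes on the connecting path.  The NNI gain for an internal edge with
adjacent subtrees A, B | C, D is
((Δ(A,B)+Δ(C,D)) − (Δ(A,C)+Δ(B,D)))/4 over balanced average subtree
distances, so the criterion decreases monotonically and the loop
terminates.  Final branch lengths are balanced averages (external:
(Δ(x,A)+Δ(x,B)−Δ(A,B))/2; internal: the four-subtree formula), with
negative estimates clamped to zero.  SPR moves are not implemented;
the NNI-only variant is the package's refinement path.

## Perturbation model

BLOSUM62 rows are remapped to non-negative distances from the
row-best substitution, B′(i,j) = B_max(i) − B(i,j); for BLOSUM62 every
diagonal is the row maximum, so "no change" sits at distance 0.  The
weight of replacing i by j is the Gamma(1, θ) density at B′(i,j) —
an exponential decay exp(−B′/θ)/θ — divided equally among the amino
acids tying at that distance, then normalised into a proper per-row
distribution (the construction defines relative weights only;
normalisation is the minimal completion that yields exactly one
outcome per site).  Sites are perturbed independently; ambiguity codes
pass through unchanged.  θ = 0 is an explicit no-perturbation mode
rather than a density limit.  The default θ = 1.9644 is the calibrated
optimum (below); at that scale no-change is the modal outcome in every
row (minimum row probability ≈ 0.40), so a replicate is the original
sequence sprinkled with conservative substitutions.

Replicate k draws from the k-th spawned stream of the master seed, so
replicate sets are bit-identical across runs and platforms.

## Calibration

`calibrate_theta` runs the full replicate-consensus pipeline over a θ
grid on families with known reference trees, records the mean
Robinson-Foulds distance per θ, fits a polynomial (default degree 4 —
enough to capture a single-dip curve without chasing noise), and
returns the fitted curve's minimiser over the grid interval.  A θ = 0
grid point means "no perturbation" and serves as the
single-tree-clustering baseline.  Flat fitted curves return the
interval lower bound with a warning.  The parabola-recovery test pins
the fit machinery; the full-pipeline calibration is exercised at
reduced scale (few families, few replicates) because its output on
synthetic families is itself stochastic.

## Consensus and metrics

Bipartitions are stored canonically as the block not containing the
lexicographically smallest leaf; trivial splits are excluded
everywhere.  Majority rule is strict (> 50%): exact-half splits are
dropped, which both matches the standard definition and guarantees
pairwise compatibility, so the consensus constructor (insert blocks
largest-first into a nested clade map) cannot fail.  Tree comparison
reports TP/FP/FN over non-trivial splits, RF = FP + FN,
precision = TP/(TP+FP) and recall = TP/(TP+FN); a star inferred tree
makes precision 0/0, reported as 1.0 with `precision_defined=False`
so batch summaries stay total.  Input rootings are discarded — all
comparisons are between unrooted trees.

## Synthetic families

The simulator draws a uniform random unrooted binary topology
(sequential addition through a uniformly chosen edge), exponential
branch lengths (default mean 0.15 substitutions/site — moderate
divergence: families are clearly related but not saturated), and
evolves sequences under a reversible rate matrix with BLOSUM62-derived
exchangeabilities (2^(B(i,j)/2)) and BLOSUM62 background frequencies,
mean rate 1.  Optional Gamma rate multipliers across sites; no indels
by default, since the pipeline strips gaps anyway and equal-length
families keep the scoring stage's behaviour easy to reason about.
Default test conditions are 12 taxa × 300 residues with 100
replicates, and the benchmark property (replicate-consensus mean RF ≤
single-NJ-tree mean RF over 20 families) is directional: the simulator
is far simpler than realistic protein-evolution protocols — no indels,
one composition, no domain architecture — so passing it shows the
machinery ranks as designed, not that real-data accuracy numbers are
reproduced.

## Numerical and degenerate-input choices

* NNI accepts a move only above a 1e-12 gain; equal-length moves are
  therefore ignored, keeping termination certain.
* Identical sequences give d = 0 and appear as zero-length cherries;
  NJ handles zero distances without special casing.
* Fewer than 4 sequences is a validation error at pipeline entry.
* Self-similarity is fixed at 1 (diagonal distance 0) by construction.
* All stochastic stages take explicit seeds; the CLI exposes one
  master seed per run and exit codes distinguish validation errors (2)
  from the disjoint-hit-profile condition (3).

## Known limitations

Internal bit scores approximate blastp's (no composition-based
statistics), so hit sets near the threshold can differ from a real
database search.  Branch lengths are in −log-similarity units, not
substitutions per site.  The consensus trades recall for precision by
design; fully resolved output is the guide tree's job.  Calibration
quality depends on the supplied families resembling the data the
chosen θ will be used on.
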