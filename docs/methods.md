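# Methods

## The inference problem

After a whole-genome duplication (WGD), triplication (WGT) or
quadruplication (WGQ), each ancestral locus -- a *pillar* -- carries up to N
homoeologous copies spread over N syntenic *tracks* per descendant genome.
Copies are progressively lost, and which copies are orthologous between
genomes depends on how each genome's tracks map onto the N parental
subgenomes (the *phasing*).  `polyphase` infers that phasing, the loss-model
parameters, and the downstream quantities built on them (loss rates per unit
synonymous divergence, reciprocal gene losses, selective-constraint
contrasts) from presence/absence data alone.

## Loss models

All models are irreversible continuous-time Markov chains over small state
spaces, with the base loss rate fixed at 1 so that a branch length is the
expected number of base-rate loss events ("alpha\*t" units); only rate x
time products are identifiable, so this normalization costs nothing.

* **WGD** (6 states U, C1, C2, F, S1, S2): U exits to S1 at rate 1, to S2 at
  rate epsilon (fractionation bias, 0 < epsilon <= 1; subgenome 1 is by
  convention the less fractionated), to the converging states C1/C2 at rate
  delta each (convergent-loss commitment) and to F at rate gamma (duplicate
  fixation).  C states commit to their single-copy state at the base rate;
  a variant biases the C2 exit by epsilon, but the unbiased version is the
  default since bias among converging states is not separately supported by
  loss data.  C states cannot transition to F: commitment is modeled as
  irreversible.  The null model is epsilon = 1, gamma = delta = 0.
* **WGT** (7 states): T loses copy 3 at rate 1 and copies 2 and 1 at
  relative rates f13 and f23; duplicated states lose copy x at sigma_x.
  The fitted models enforce f23 <= f13 <= 1 by optimizing (f13, f23/f13),
  both in (0, 1]: genome 1 is the favored subgenome by construction, and
  which observed genome that is emerges from the phasing.
* **WGQ** (15 states: subsets of 4 subgenomes): Q -> T at rate 1 per copy,
  T -> D at delta per copy, D -> S at sigma per copy.  The two-step
  formation model replaces the root distribution with
  P(Q) = exp(-2 lambda), P(D12) = P(D34) = (1 - exp(-2 lambda))/2: the
  intermediate tetraploid loses either copy at rate lambda over the
  (unobserved, unit-length) inter-event interval.  The waiting-time law is
  an exponential-survival choice; the data only constrain the resulting
  three root probabilities.

Transition matrices are dense scaling-and-squaring matrix exponentials
(`scipy.linalg.expm`); at <= 15 states nothing faster is needed.  Rows are
clipped to [0, 1] and renormalized to remove roundoff at the 1e-16 level.

## The phasing HMM

Hidden states are the per-genome track-to-subgenome assignments (2^n states
for n tetraploid genomes; (N!)^n in general).  Emissions are Felsenstein
pruning over the loss-model state space: a tip's partial likelihood is the
indicator of loss states whose subgenome pattern, viewed through the
genome's assignment, matches the observed track pattern; the root branch
(polyploidy to first speciation) is applied above the first-speciation node
with the model's root distribution, optionally with root-specific
parameters (a separate epsilon for the WGD family; a full separate
parameter set for WGT).

Between adjacent pillars each genome independently keeps its assignment
with probability 1 - theta (switching uniformly among the alternatives),
and a genome whose adjacency is broken uses the uniform kernel -- for a WGD
this is the switch probability 0.5 that makes neighbors uninformative.
Break flags are per genome: the more general reading, which reduces to a
global break when all genomes break together.  The forward recurrence is
the elementwise product of the kernel-propagated previous vector with the
emission vector, base case = the first pillar's emissions, total likelihood
= the sum of the final vector (no initial-distribution weighting; constant
factors affect neither MLEs nor posteriors).  Vectors are rescaled per
pillar with an accumulated log to avoid underflow; forward and backward
loops are numba-compiled.  Posterior decoding is standard
forward-backward; argmax ties break toward the lowest canonical state
index (deterministic).

### Fitting

Bounded L-BFGS-B over theta in [1e-4, 0.5], branch lengths in [1e-4, 20]
and the family's free parameters (epsilon in (0, 1], gamma, delta, lambda
>= 0), with multi-start (default 5 seeded starts; calibration simulations
in the tests use a single start from neutral initial values, which the
smooth likelihood surface makes sufficient).  Convergence at a relative
function tolerance of 1e-11 -- tight, because likelihood-ratio statistics
near 0 must be resolved to much better than 1e-6.  A fit can be
warm-started from a nested fit; the warm start adds the null's optimum as
an extra start point, so the alternative never scores below the null.

### Uncertainty

`param_variance` offers two estimators at the MLE:

* `method="single"`: 1 / (single-dimension central-difference curvature of
  the negative log-likelihood), step max(1e-4, 1e-4 |estimate|), ignoring
  covariances.  This conditional variance feeds the loss-rate/Ks ratio CIs.
* `method="marginal"`: the corresponding diagonal entry of the inverse of
  the full observed information (dense central-difference Hessian).  The
  loss parameters correlate strongly with branch lengths, so the
  single-dimension curvature understates their sampling variance
  (measured coverage ~50-75% at nominal 95% in the recovery simulations);
  the marginal version restores ~95% coverage and is what the
  parameter-recovery test uses.  Boundary estimates are flagged (None)
  rather than given a variance.

Likelihood-ratio tests use the plain chi-square by default; an optional
flag applies the 50:50 boundary mixture for parameters pinned at a box
edge under the null (e.g. epsilon = 1), which otherwise makes the plain
test conservative (~2.5% rejection at nominal 5%).  The type-I
calibration test therefore uses the boundary-corrected p-value: it is the
correctly calibrated reference distribution for the epsilon-on-boundary
null, and the measured rejection rate under it is ~4.5%.

### Topology search and WGQ phasing

Topology search enumerates all rooted binary topologies ((2n-3)!! for n
taxa, capped at 6 taxa), optionally constrained to a fixed sister pair, and
fits each.  WGQ phasing splits octoploid pillars into tetraploid pillar
pairs: because the formation model is exactly symmetric under swapping the
two first-event subgenome pairs, the absolute pair labels are not
identifiable, and the implemented quantity is the posterior co-assignment
of each gene with a per-pillar reference track (the first present track of
the first genome).  Pillars where every gene reaches the confidence
threshold (default 0.99) are emitted; pillars whose genes all descend from
one first-event region -- the common case under the formation model -- are
emitted as single tetraploid pillars rather than pairs.

## Pillar construction

The annealer maximizes the count of synteny relations (gene pairs in
adjacent pillars that are chromosomal neighbors after masking genes without
homologs) over homolog-to-pillar assignments and pillar orders.  Cooling is
geometric (x0.95), with the initial temperature tuned to ~50% acceptance on
200 probe moves and termination after 50 temperature levels without
improvement; moves are homolog reassignment, pillar swaps and short block
relocations (plus block reversals for the global-order search, which
minimizes synteny breaks instead).  The best-visited state is returned, so
the result is never worse than the greedy initial assignment.  Ambiguous
homolog ties break by similarity score then lexicographic gene id; equal-
score orders resolve to the first encountered under the seed.  These
choices are desk-scale-standard; none is statistically load-bearing.

## Divergence analyses

Root-branch Ks values are halved before averaging (the shared internal
branch of a mirrored gene tree spans the progenitor divergence twice).
The homoeologous-exchange check fits 1- vs 2-component normal mixtures to
log Ks inside the (5e-3, 2.0) window via `sklearn` GaussianMixture EM (20
restarts: one quantile-initialized plus random starts), selected by
BIC = -2 lnL + p ln n with p = 2 (k=1) or 5 (k=2).  Ratio CIs draw 1,000
independent normal pairs for (alpha\*t, mean Ks), redrawing nonpositive
denominators (count logged) so exactly 1,000 ratios enter the empirical
2.5/97.5% quantiles.  The five constraint classes partition pillars by
duplicate count (all / all-but-one / exactly-one / none), with fully
single-copy pillars split by the posterior probability that the loss
predates the first speciation (threshold 0.95, configurable; no printed
value exists for this cutoff).  Pillars with intermediate duplicate counts
are reported separately as unassignable.

## RGL detection

The paralogy probability of two single-copy genes is the posterior mass on
phasing states assigning their tracks to different subgenomes.  Calls
require probability >= 0.95 (default) and synteny-hole OR sole-homolog
support; the hole filter demands maintained adjacency to both flanking
pillars in both genomes (the strictest reading -- boundary pillars cannot
pass), and the sole-homolog filter uses per-genome outgroup-homolog counts
carried on the pillar.  An optional veto list (for an external
noncoding-sequence search) marks calls vetoed rather than deleting them,
so every veto is auditable.  Essentiality enrichment is a two-sided
Fisher's exact test (scipy), cross-checked in the tests against a
hand-rolled hypergeometric enumeration.

## The synthetic-data generator

The generator emulates exactly the statistical structure the inference
assumes: a Markov phasing path with per-genome switch probability theta and
per-genome breaks; loss-model evolution down the tree from the model's root
distribution; lognormal per-branch Ks with an inflated root mode (progenitor
divergence) and an optional smaller homoeologous-exchange mode; independent
essentiality labels; and a directly simulated conversion-likelihood table
(sequence evolution is out of scope).  Node states are drawn by exact
matrix-exponential endpoint sampling per branch -- distributionally
identical to simulating the jump process, but vectorized over pillars.
Pillars violating the at-least-one-gene-per-genome rule are resimulated to
keep the requested pillar count (the count is logged; none of the shipped
models can actually produce an all-absent genome).

Default conditions: 4 taxa, 5,000 pillars, theta = 0.05, break probability
0.02, epsilon = 0.6, gamma = 0.05, delta = 0.1, tip/root branches 0.3 and
internals 0.2 (alpha\*t), root Ks log-mean -0.9 vs -1.6 elsewhere (log-sd
0.45), essentiality rate 0.2.  These are plausible mid-resolution
paleopolyploidy values: enough losses for signal, far from saturation.

What passing tests on these data do **not** show: robustness to
misannotation, tandem duplicates, fractionated assemblies, non-lognormal
rate variation, or homology errors upstream of the pillar table -- the
generator produces data exactly under the model, so the tests verify
inference correctness, not model adequacy for real genomes.

## Problem sizes in the test suite

The oracle-equivalence checks run exhaustive enumeration at n = 2 genomes
and <= 6 pillars.  Parameter recovery uses 20 replicates of 5,000 pillars
and 4 taxa; LRT calibration uses 200 replicates of 1,000 pillars and 2
taxa (two taxa suffice for the epsilon test and keep each replicate's two
fits under a second); mixture selection uses 500 draws per replicate;
ratio-CI coverage uses 500 synthetic branches; the RGL pipeline check uses
3 taxa and 2,000 pillars; annealing toys stay at <= 7 pillars so
exhaustive search remains the oracle.  The acceptance script scales some
replicate counts down (5 recovery replicates of 3,000 pillars, 60
calibration replicates of 800 pillars) while measuring the same
quantities.

## Known limitations

* No Viterbi decoding, Bayesian sampling, or rate heterogeneity across
  pillars; at most 4 subgenomes and 6 taxa per event in topology search.
* The WGQ joint computation scales as (4!)^n phasing states and is
  practical only for 2 genomes, mirroring the motivation for the two-step
  phasing route.
* The single-dimension Fisher variance is kept for the ratio CIs for
  comparability, despite its undercoverage for correlated parameters (see
  above).
* The gene-conversion filter consumes externally computed likelihood
  tables; sequence-level likelihoods are out of scope.
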