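# Methods

## The prediction problem

A B cell clonal family (CF) is the set of sequences descending from one
naive ancestor through germinal-center affinity maturation.  Its
*substitution profile* — the per-position distribution over the 20 amino
acids, on the fixed 149-position AHo antibody numbering — summarizes which
positions tolerate which replacements while preserving binding.  In most
experiments only a single sequence per CF is recovered, so the profile
cannot be tabulated directly.  `clonalprof` predicts the full CF profile
from that single sequence by borrowing strength from external information
sources.

## Model

Let `X[i, j, :]` be the one-hot profile of the input sequence of CF `i` at
AHo position `j`, and let `Xstar[i, j, :, l]` (l = 1..p) be the external
source profiles assembled for that CF.  The predictor is an
independent-across-sites convex combination,

```
Yhat[i, j, :] = sum_l alpha[j, l] * Xstar[i, j, :, l]
                + (1 - sum_l alpha[j, l]) * X[i, j, :],
```

with site-specific weights constrained to `0 <= alpha[j, l] <= 1` and
`sum_l alpha[j, l] <= 1`, so every predicted row is itself a probability
vector.  `alpha` is shared across the 20 amino acids at a site.  Setting
all weights to zero recovers the *baseline* model (the input sequence
itself).

Six source kinds are supported: public-repertoire profiles averaged by
V-gene or V-subgroup label; the naive-sequence one-hot; K-means centroids
of the public set clustered on naive one-hot encodings or on frequency
profiles (euclidean distance in the flattened 149x20 = 2980-dimensional
space, K in 2..120, queries assigned to the nearest centroid); and a
simulated neutral-hypermutation profile.

## Objectives and penalties

Two objectives are implemented.

*L2 error*: `(1 / (149 * N_CF)) * sum_{i,j} ||Y[i,j,:] - Yhat[i,j,:]||^2`
over defined cells.  The normalizer deliberately counts all 149 positions
even though undefined (gap) positions contribute zero, matching the
estimator's printed form; CFs with shorter mapped regions are therefore
down-weighted.

*Jaccard similarity* at cutoff `t` (default 0.2): per defined cell, the
observed and predicted high-frequency amino-acid sets are `{k: freq >= t}`
and the similarity is `|A & B| / |A | B|`, averaged over defined cells,
with `J(empty, empty) := 1` (agreement that nothing exceeds the cutoff).
Because the exact metric is piecewise constant, fitting uses a
differentiable surrogate: predicted memberships are smoothed logistically,
`f_eps(a, t) = 1 / (1 + exp(-eps * (a - t)))`, observed memberships stay
hard, and intersection/union become sums of elementwise min/max.  As `eps`
grows the surrogate converges to the exact metric whenever no frequency
sits exactly at `t` (verified to |diff| < 1e-6 in the tests).  A guard of
1e-9 added to numerator and denominator reproduces the empty-set
convention in the sharp limit while perturbing ordinary cells by < 1e-9.
Default sharpness is `eps = 50`.

Estimation minimizes the objective plus a standard lasso penalty
`lambda1 * ||alpha||_1` (shrinks weights of uninformative sources to zero)
and a fused-lasso / trend-filtering penalty
`lambda2 * sum_l ||diff^d(alpha[:, l])||_1` on d-th order successive
differences along positions (d in {1, 2, 3}), encouraging piecewise
polynomial weight trends of order d-1 — adjacent antibody positions are
under similar structural constraints, so their weights should vary
smoothly.  The penalized L2 problem is convex, so any local minimum is
global; the tests verify midpoint convexity numerically and check that the
fitted L1 norm (resp. fused roughness) is non-increasing along a
`lambda1` (resp. `lambda2`) ladder.

## Optimization

Fitting uses L-BFGS-B (via `scipy.optimize.minimize`) with analytic
gradients, within the `[0, 1]` box.  Three numerical choices matter:

* the per-position sum constraint is enforced by an exact linear penalty
  `C * max(0, sum_l alpha[j, l] - 1)` with `C = 1e4`, followed by a final
  euclidean projection of each row onto `{a >= 0, a <= 1, sum a <= 1}`;
* the nondifferentiable `|x|` terms are smoothed as `sqrt(x^2 + 1e-12)`,
  and fitted weights below 1e-6 are snapped to exact zero for sparsity
  reporting;
* the default budget is 2000 iterations at gradient tolerance 1e-8, both
  configurable (`FitOptions`); cross-validation helpers accept lighter
  budgets since held-out scoring is unpenalized and forgiving.

The unpenalized fit is validated against an exhaustive per-position grid
search (step 0.001) on a tiny instance, and against exact recovery of the
generating weights on noise-free synthetic data.

## Neutral simulator

The neutral source asks what a CF would look like under somatic
hypermutation alone, with no selection.  Given the naive DNA sequence and
the observed SHM count `m` (nucleotide Hamming distance between the input
read and the naive), each of `n_samples` (default 10,000) replicates
receives `m` sequential mutations: a site is drawn proportionally to the
*current* sequence's 5-mer mutabilities, the target base from that site's
substitution distribution, and the affected contexts are recomputed before
the next draw.  Replicates are then translated and tallied into a profile
on the naive numbering.

Choices the 5-mer-model literature leaves open, resolved here:

* sites may mutate repeatedly across the `m` draws (back-mutation is
  possible) — the simplest reading of sequential mutation; a
  without-replacement variant is not provided, but resampling behavior is
  configurable for stops (below);
* sequence-edge contexts are padded with N and resolved by averaging over
  all compatible fully-determined 5-mers (tables are precompiled over the
  base-5 ACGTN code space);
* replicates whose translation contains a stop codon keep their non-stop
  codons (the stop position is simply not tallied; mask-safe); setting
  `allow_resampling_stops=True` redraws such replicates instead.  If every
  replicate stops at a position, the naive residue is reported there;
* randomness is counter-based (one Philox stream per replicate, keyed by
  seed and replicate index), so replicate `i` is bit-reproducible and
  independent of `n_samples` and of the other replicates.

The simulator is checked against an independent exact oracle (exhaustive
enumeration of all single-nucleotide mutants, weighted by mutability and
substitution probabilities) and for the Monte-Carlo `n^(-1/2)` SE scaling.
The model table format (5-mer, mutability, four target-base probabilities
with zero self-transition) is user-supplied; a synthetic uniform model is
bundled for testing, and no published parameter values are shipped.

## Selection and inference pipeline

The unit of observation is always the CF: the 80/20 train/test split and
the k-fold CV partitions are over CFs, stratified by donor (round-robin
after a seeded shuffle) when donor labels exist, because repertoire donors
are a natural overfitting axis.  Forward stepwise selection greedily grows
the source set: each remaining candidate is scored by 5-fold CV of the
*unpenalized* fit alongside the already chosen sources; ties break on
declared candidate order; the path runs to the prespecified limit (default
5) so the whole trade-off curve is reported.  The shortlisted groupings
(by default the best grouping at each path length) are then crossed with
the penalty grid — `lambda1, lambda2 in {1e-7, 5.05e-6, 1e-5}`, `d in
{1, 2, 3}` — under penalized 5-fold CV (scores are reported unpenalized),
the winner is refitted on all training CFs, and unpenalized L2/Jaccard
metrics are computed on the held-out CFs next to the baseline.  All seeds,
scores, and choices are logged in the report.

## Evaluation

Per-region metrics restrict the position sums to each framework (FWK1-4)
or complementarity-determining region (CDR1-3); for L2 the normalizer is
(region length x N_CF), so the whole-sequence error is exactly the
region-length-weighted mean of the region values.  The shipped AHo region
table is FWK1 1-26, CDR1 27-42, FWK2 43-56, CDR2 57-69, FWK3 70-106, CDR3
107-138, FWK4 139-149; the conserved tryptophan at position 43 (first FWK2
position, immediately after CDR1) anchors it, and the table is overridable
by config.  Bootstrap standard errors resample CFs with replacement.  The
mode table tallies, per jointly-defined CF-position, whether the input
amino acid is the true mode (argmax of the observed row), whether the
predicted mode is correct, and whether the predicted mode equals the naive
(germline) residue; argmax ties break by alphabet order for determinism.
A weight-aggregation helper merges the germline-segment sources (vgene,
vsubgrp) and the naive-derived sources (naiveAA, neut) into a stacked-area
table of per-position weights plus the residual input-sequence weight.

## Synthetic data generator

`gen_dataset` emulates exactly the statistical structure the model
assumes.  Per CF: each of `p_true` sources contributes Dirichlet
(concentration 0.5, i.e. realistically peaked) site distributions; the
true profile is the convex combination of the sources (weights
`alpha_true`, default a feasible piecewise-constant two-level pattern so
fused-lasso fits have a blocky truth) with a CF-specific Dirichlet
"input-only" component; `seqs_per_cf` sequences are drawn
positionwise-multinomially from the true profile, and `Y` is their
empirical profile.  A contiguous inactive block centered at position 122
emulates the CDR3 coverage gaps of real numbering data (default 120 of
149 positions active).

The input profile `X` has two regimes.  The default
(`input_kind="component"`) supplies the exact input-only component, under
which the population L2 minimizer is `alpha_true` — this is the regime in
which parameter-recovery claims are meaningful, and the fused-lasso fit
recovers piecewise-constant weights with MAE well under 0.05 at 500 CFs x
100 sequences.  `input_kind="subsample"` instead supplies the one-hot
profile of one randomly chosen sequence, matching the
single-sequence-subsampling regime of real repertoire analysis; in that
regime the optimal weights trade the input's sampling variance against
source bias and deliberately exceed the generating weights, so recovery
is not expected and the regime is used for pipeline and evaluation
realism, not for recovery tests.  Both regimes are always generated; the
one-hot stack is available as `dataset.x_subsample`.

The generator makes no attempt at germinal-center phylogenies, selection,
indels, or sequencing error; passing tests demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them (phylogenetic correlation between sequences
of a CF being the largest).

## Degenerate inputs and conventions

AHo positions are 1-based on disk and in all interfaces; internal arrays
are 0-based and never leak.  Undefined positions are explicit masks with
all-zero rows and are excluded from every sum; profile rows are validated
to sum to 1 within 1e-9.  At query-defined positions where an external
source is undefined, tensor assembly substitutes the input profile row for
that source (locally equivalent to zero weight and keeps predictions on
the simplex).  Averaged and centroid profiles are renormalized per
position, which only matters under partial masks.  Label averaging is
unweighted by CF size.  Ambiguous bases are tolerated only within the
first/last 30 nt of a read (the PCR-primer window) and are resolved by
substituting whole naive codons; amino-acid sequences containing
non-standard residues are rejected per sequence.  CFs need at least 5
unique amino-acid sequences after in-CF deduplication.

## Known limitations

* Sites are modeled independently; epistasis enters only through the
  fusion penalty's smoothness assumption.
* `alpha` is shared across the 20 amino acids at a site by design.
* Jaccard fitting optimizes a surrogate; the exact metric is only
  evaluated, and the surrogate's stationary points can differ when many
  frequencies sit near the cutoff.
* V-gene/V-subgroup sources cannot serve query sequences whose label was
  never observed in the public set (an explicit error, by design).
* No VDJ annotation, clonal clustering, numbering computation, or indel
  handling: annotation and numbering are consumed as inputs.
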