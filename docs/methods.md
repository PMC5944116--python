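# Methods

`microdynet` models the temporal dynamics of a gut microbial community —
motivated by the hindgut microbiota of the lower termite *Reticulitermes
flavipes* under dietary change — as a one-step map learned by a feedforward
neural network, and extracts taxon–taxon and taxon–substrate interaction
networks from the trained map by input perturbation. Community-ecology
statistics (rarefaction, Shannon diversity, Bray–Curtis dissimilarity, PCoA,
PERMANOVA) support the descriptive side of the analysis, and a synthetic
generator with a known interaction matrix makes every stage testable.

## Data model

Sequence counts arrive as a classic tab-separated OTU table (leading
`#OTU ID` header, trailing `taxonomy` / `Consensus Lineage` column) with a
`sample_id / diet / day` metadata table. Samples are rarefied **without
replacement** to a fixed depth (default 18,000 sequences; samples below the
depth are dropped, not padded) using `numpy`'s multivariate hypergeometric
sampler, which is exact. OTU counts are then collapsed to taxonomic order:
counts of OTUs sharing an order are summed and divided by the sample total,
so each sample becomes a composition on the simplex over orders. The
arrangement of orders is alphabetical and fixed; every vector downstream
(network nodes, change-matrix rows) uses the same arrangement. OTUs whose
lineage lacks an order rank are binned as
`unclassified_<highest-resolved-rank>`.

Alpha diversity (H′ in bits, E_H = H′/log2(S_obs)) and Bray–Curtis
dissimilarity are computed on the rarefied OTU table — the scale the
original QIIME-based workflow used — while the order-collapsed profiles
drive the core/non-core partition, the PERMANOVA group comparisons and the
network. E_H follows the standard convention (1 = perfectly even,
0 at richness one); descriptions that invert this reading exist in the
literature, but the implementation keeps the standard orientation.

Per-diet series are assembled by averaging replicate profiles per
(diet, day) and renormalising; all day-0 profiles are pooled and their mean
is prepended as every series' first row, since every colony derives from the
same starting stock. A `per_replicate` mode keeps replicate ranks as
separate series for sensitivity checks. Substrate presence is a 0/1 flag
vector with exactly one flag set per diet and none for the starved colony.

An order is **core** when it is present (nonzero) in at least a prevalence
fraction of all profiles; the default threshold is 1.0 ("consistently
present"), configurable.

## The dynamics network

The network maps the state at time *t* — order abundances plus substrate
flags, `T + S` inputs — to the order abundances at *t + 1* (`T` outputs).
Hidden layers hold `round(0.95 · n_input)` and `round(0.85 · n_input)` nodes
(ties rounded away from zero): with 56 orders and 6 substrates this is a
62–59–53–56 architecture. Activations are hyperbolic tangent (first hidden
layer) and the logistic sigmoid `S(x) = 1/(1 + e^{-x})` (second hidden layer
and output). Sigmoid outputs keep every prediction inside (0, 1), the range
of a relative abundance; predicted vectors are *not* renormalised to the
simplex, since raw node outputs are what the evaluation compares.

Consecutive profiles of each series form training pairs — a series of *n*
time points yields *n − 1* pairs; the last time point is never used as an
input. Unequal day spacing is deliberately ignored: steps are consecutive
indices.

Training is classical backpropagation with heavy-ball momentum
(`v ← μ·v − η·∇E`, `w ← w + v`) on the per-pair half-sum-of-squares error
`E_p = ½ Σ_j (y_j − t_j)²`. Defaults: learning rate η = 0.15, momentum
μ = 0.65, at most 20,000 epochs, halting when the MSE (mean over pairs and
output nodes) drops below 10⁻⁵. Weights initialise uniformly on
[−0.1, 0.1] from a seeded generator.

The default update schedule is **incremental** — one weight update per
training pair, pairs in series order. A batch mode (one update per epoch
from the mean per-pair gradient) exists behind a flag, but at the fixed
learning rate of 0.15 it plateaus around MSE ≈ 10⁻⁴ on the full-scale
problem and cannot reach the halt threshold within the epoch budget, while
the incremental schedule reaches 10⁻⁵ in roughly 6,000 epochs; incremental
updating is also the schedule for which a per-pattern learning rate and
momentum of this magnitude are conventional. The incremental inner loop is
JIT-compiled with numba; results are bit-deterministic given (seed, pairs,
config), and momentum velocities are persisted in the saved model so that
resuming training after a save/load reproduces an uninterrupted run exactly.

## Evaluation

**Tenfold cross-validation** partitions the pairs into ten near-equal seeded
folds, trains on nine and scores the tenth with the mean absolute percentage
error, `MAPE = mean |pred − actual| / actual × 100` over (pair, taxon)
terms. Taxa measured at or below `ε = 10⁻⁴` are excluded from the
denominator (a zero denominator makes the term unbounded). Averaging
per fold and then across folds is the headline number; the pooled
average over all terms is reported alongside, since the two conventions can
differ.

**Leave-one-timepoint-out**: one randomly chosen day per diet (never a
series' first day) is held out, the pair targeting it is removed, the
network retrained, and the held-out profile predicted from its predecessor.
Accuracy is summarised as per-taxon absolute differences in percentage
points and as Bray–Curtis similarity (1 − dissimilarity). The headline
similarity is computed on the concatenated predicted/measured vectors across
all diets; per-diet similarities and the similarity of the mean-aggregated
vectors are also reported.

## Perturbation sensitivity analysis

Each input node of the trained network is varied independently while all
others are held at a reference state (the day-0 composition with no
substrate). Taxon inputs are varied 100 times, drawn uniformly within ±5% of
the reference value (an evenly spaced symmetric grid mode exists for
derivative-style checks). For each perturbation and each output,

    relative change = ((new_out − out) / out) ÷ ((new_in − in) / in) × 100%,

and the average over perturbations fills one row of the **change matrix**
(rows = input taxa then substrates, columns = output taxa). The quantity is
an elasticity in percent: 100 means the output moves proportionally with the
input. Zero reference inputs or outputs are floored at ε₀ = 10⁻⁶ and the
affected rows flagged rather than silently reported. Substrate inputs are
binary, so they are toggled (0 ↔ 1) and the input's relative change is
defined as ±100% — the only finite convention for a presence/absence node —
leaving the output's sign-adjusted relative change.

Entries whose absolute value exceeds `mean(|M|) + 3·sd(|M|)` (strict
inequality; "absolute average" read as the mean of absolute values, with
|mean| available behind a flag) become edges of the signed interaction
network: positive entries are direct relationships, negative inverse. Edges
are counted outbound at their source row and inbound at their target column;
substrate rows can only be sources. The network is exported as an edge list,
GraphML, and a diverging heatmap (blue direct, red inverse).

## Synthetic data generator

The generator emulates the feeding experiment: colonies from one stock
(shared day-0 state), six substrates (mulch, spruce, oak, maple, birch,
cardboard) plus a starved colony, sampling days
{0, 1, 2, 3, 7, 14, 21, 28, 35, 42, 49} with the starved series truncated at
day 21 and oak at day 28, and three replicate individuals per time point.
Dynamics are a multiplicative log-linear update on the simplex,

    x(t+1) = normalise( x(t) ⊙ exp(A_taxaᵀ x(t) + A_subᵀ s + ε) ),

with a signed interaction matrix `A` ((taxa+substrates) × taxa), substrate
flags `s`, and i.i.d. Gaussian noise ε on the log-abundance scale. The form
keeps states on the simplex and has an analytic Jacobian, which serves as
the sign oracle for recovery tests. Two noise scales are separated:
*process* noise (default 0.02) perturbs the shared latent trajectory, while
*replicate* noise (default 0.15) models variation between individual guts
sampled at the same time point — without this separation the replicates of a
time point would be implausibly tight around a drifting latent state and
every between-group comparison would be wildly significant.

The default community has two dominant orders (>10%), one mid-abundance
order, and a long tail below 1%; five tail taxa are designated drivers and
carry the strong interactions (sparse rows of `A`). The first substrate
(mulch) is the colonies' original food: its effect row is zero and the
baseline is made a fixed point of the taxon–taxon block (columns are
centred at the baseline state), so only a dietary change — or noise — moves
the community off its day-0 composition. This reproduces the experimental
contrast in which changed diets shift the community while the control
does not.

Counts are drawn multinomially at fixed depth, with each order's mass split
across a configurable number of OTUs; taxonomy strings encode the order so
collapse inverts the split. The generator does **not** model sequencing
error, chimeras, or phylogenetically realistic taxonomy strings, and its
dynamics are a convenient stand-in, not a fitted model of real gut
communities — tests passing on it demonstrate the correctness and internal
consistency of the pipeline, not biological accuracy.

## Community statistics

Bray–Curtis uses `scipy`'s pairwise implementation; PCoA is classical
scaling (double-centred Gower matrix, symmetric eigendecomposition, axes
ordered by descending eigenvalue, negative-eigenvalue axes reported but
dropped). PERMANOVA partitions squared distances among/within groups into a
pseudo-F with seeded label permutations and the add-one p-value
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)` (resolution
1/(n+1), never exactly zero; 999 permutations by default). The group
comparison mirrors the study design: day-0 samples versus the union of a
diet's last two sampled days. The implementation is cross-checked in the
test suite against an exhaustive-enumeration oracle on six samples and
against scikit-bio's PERMANOVA statistic, and its type-I error is calibrated
against the nominal 5% level over 500 null simulations.

## Benchmarks and frozen test conditions

Three learnability/recovery conditions are fixed as named configurations:

- **XOR**: inputs padded to a 4-node input layer (4–4–3–1 network), default
  training config; at least 9 of 10 seeds reach MSE < 10⁻³.
- **Mild learnable dynamics** (5 taxa, 2 substrates, 20 time points,
  noise-free, interaction scale 0.15, near-even baseline): abundances stay
  well away from zero, so a converged network's cross-validated MAPE is
  limited by the halt threshold, not vanishing denominators; mean MAPE
  stays below 10% for a majority of seeds.
- **Sign recovery** (8 taxa, 6 substrates, 30 time points, noise-free,
  3 strong taxon–taxon edges of magnitude 3, substrate→driver edges of
  magnitude 1): the perturbation analysis recovers at least 2/3 of
  strong-edge signs in a majority of 10 seeds. Two conditions are necessary
  and deliberate. First, because compositions close to 1, the elasticity of
  output *j* to input *i* is approximately `x_i (A_ij − 1)`, so an edge's
  sign is only visible above the closure term when |A_ij| > 1. Second, the
  substrates must act on the driver taxa so that the diets trace diverging
  trajectories: if a driver's abundance is a pure function of time, the
  regression surface the network learns confounds the driver's causal
  effect with the time trend and the recovered slope can invert.

## Numerical choices and degenerate inputs

- Rounding of hidden-layer fractions: nearest integer, ties away from zero.
- A constant change matrix (sd = 0) yields no edges (strict threshold) and a
  logged warning.
- An unchanged input in the relative-change formula is an error (undefined
  ratio) rather than a silent zero.
- Series files record diet, days and substrate names in comment lines so a
  directory of per-diet CSVs round-trips losslessly.
- All randomness flows through explicit integer seeds (`numpy` Generators);
  training itself draws no random numbers after initialisation.

## Problem sizes

The default test and acceptance runs use the full 56-order, 6-substrate
architecture (62–59–53–56) with 63 training pairs, tenfold cross-validation,
and 10-seed benchmarks for XOR and sign recovery; these sizes run the whole
pipeline end-to-end in about a minute on a single CPU and were chosen as the
package's standard demonstration scale.

## Known limitations

- MAPE is dominated by low-abundance taxa whenever the measured abundance is
  within a few network-RMS-errors of zero; on the full 56-order synthetic
  community the cross-validated MAPE is large even though Bray–Curtis
  similarity of held-out predictions exceeds 0.9. The mild-dynamics
  configuration isolates the regime where MAPE is informative.
- The sensitivity analysis reports the elasticities of the *learned* map at
  one reference state; where the training series leave input directions
  unexplored, the learned off-manifold slopes — and hence edge signs — are
  not identified (see the sign-recovery discussion above).
- PCoA drops negative-eigenvalue axes rather than applying a correction;
  Bray–Curtis matrices are generally non-Euclidean, so reported coordinates
  reconstruct distances only approximately.
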