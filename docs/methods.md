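# Methods

## Model and assumptions

The package treats GRN inference as pairwise causal direction scoring
under the additive noise model (ANM): if gene y is regulated by gene x,
then `y = f(x) + δ` with `f` nonlinear and `δ` independent of `x`.
Fitting the regression in both directions and testing residual–cause
independence exposes an asymmetry: only in the true direction is the
residual (approximately) independent of the putative cause. This
identifies direction for nonlinear mechanisms with additive noise; it
says nothing for purely linear Gaussian pairs (a known symmetric case)
and can be misled by confounding, feedback, or measurement processes
that break additivity. The framework deliberately does **not** assume
the overall network is acyclic — each ordered pair is scored on its own
— and restricts the hypothesis space biologically: only TFs may
regulate, no self-regulation, no TG→TG edges.

The output is a full ranking of the |F|·(|F|+|G|−1) admissible ordered
pairs, not a thresholded graph; all evaluation is ranking-based.

## Pipeline stages and parameter defaults

**Standardization.** Per-gene z-score with the *population* standard
deviation (denominator m). Constant genes are an error, not silently
dropped.

**Potential networks.** Pearson |r| (linear flavor) and plug-in mutual
information in nats with ⌈√m⌉ equal-width bins per gene (nonlinear
flavor). The MI plug-in estimator carries a positive bias of roughly
(B−1)²/2m nats, so absolute MI cutoffs are not portable across sample
sizes; the pipeline therefore defaults to *density-matched* thresholds —
the cutoff that leaves the network with about `target_avg_degree`
(default 5) edges per gene, mirroring the observation that the method
performs best when the potential network is about as sparse as the
expected gold standard. Fixed cutoffs (e.g. the classic per-dataset
grids 0.35/0.70 for |r|, 0.15/0.50/0.65 for MI) remain available as
explicit arguments. Pearson thresholding uses |r| because repression is
as real as activation; the signed variant is a switch.

**Representation learning.** Two-layer GraphSAGE with mean aggregation,
implemented directly in numpy (the graphs here are hundreds to a few
thousand nodes; full-batch dense linear algebra outperforms a GPU
framework round-trip and keeps the dependency set small). Node input
features are the standardized expression vectors. Defaults: hidden dims
(64, 32), neighbor sample sizes (10, 5) with bootstrap when the degree
is smaller, walk length 5, 10 walks per node, Adam at 1e-3, 100 epochs,
20% held-out links; ReLU on the hidden layer, identity on the output.
Zero-neighbor genes aggregate over themselves so every gene stays
embeddable. The link classifier is logistic on the Hadamard product of
the endpoint embeddings — the standard symmetric link-prediction head.
All stochastic draws derive from one seed; two runs are byte-identical.

**Causal scoring.** GPR uses a squared-exponential kernel with an
additive noise term. Hyperparameters are selected by exact marginal
likelihood over a small multiplicative grid (lengthscale = median
pairwise distance × {0.5, 1, 2}; noise variance = response variance ×
{1e-4, 1e-2, 1e-1, 0.5}), which costs a handful of Cholesky solves per
fit and makes scoring all pairs tractable on one CPU; a scikit-learn
gradient-optimized fit is available (`method="sklearn"`) and is used as
a cross-check in the tests. Above `gpr_max_train = 500` samples the GP
trains on a seeded subsample but predicts residuals at every point.
HSIC is the biased V-statistic (1/m²)·tr(KHLH) with Gaussian kernels
and median-distance bandwidth; constant inputs return exactly 0. Above
`max_samples = 1000` points the pair's vectors are subsampled (seeded)
to bound the quadratic HSIC cost. `n_splits > 1` scores disjoint sample
blocks independently and averages — a bagging option that roughly
halves the score's sampling variability and is used where cross-stage
*stability* matters.

The stored propensity is `W[i→j] = ANM(j,i) − ANM(i,j)` (reverse minus
forward), so that larger W favors i→j and a descending sort puts likely
regulations first; the printed form of the difference with the opposite
sign would rank true edges last, since a *lower* residual–cause HSIC
means a *better* ANM fit. The TF–TF block is computed once per unordered
pair and mirrored with a sign flip, making antisymmetry exact to the
last bit.

**What the embeddings feed into.** How per-gene embedding vectors enter
the pairwise regression is genuinely underdetermined, and we implement
three modes:

* `expression` (default): ANM on the standardized expression columns.
  The embeddings are still trained and exported (and logged with their
  link-classification accuracy) but do not alter the causal scores, so
  the full pipeline's ranking coincides with the `anm-only` ablation's.
* `gated`: expression-level ANM scores multiplied by the flavor's
  link-classifier pair probability. The gate is symmetric in the pair,
  so TF–TF antisymmetry is preserved exactly; pairs the graph model
  considers unlinked are shrunk toward zero.
* `embedding`: ANM directly on the d-dimensional representations, one
  scalar per embedding dimension.

The default is `expression` because, on planted ANM-mechanism data at
desk scale, it dominates: across the default planted benchmark the
expression mode reaches EPR ≈ 9, gating costs up to ~10% of that, and
the literal embedding mode collapses to a random predictor (EPR ≈ 0.8)
— compressing m per-sample observations into d learned projections
destroys the sample alignment the residual-independence test needs.
This is a property of this implementation at these scales, not a claim
about other implementations; the alternative modes exist precisely so
the choice stays inspectable.

**Ensemble.** `W = λ·norm(W_lin) + (1−λ)·norm(W_nonlin)`, λ = 0.5.
Raw HSIC differences from the two flavors are not on a common scale, so
`norm` defaults to centered average ranks over all admissible entries —
a true Borda count. Global ranks are monotone, which gives three exact
properties: the λ→1 (λ→0) limit reproduces the linear (nonlinear)
ranking, equal inputs are a fixed point, and the combination is
invariant to any strictly monotone rescaling of either input. A
data-dependent rank transform cannot at the same time be exactly odd on
the TF–TF block (the admissible-value multiset is not symmetric), so a
`rank-block` option ranks the TF–TF and TF–TG blocks separately — there
the TF–TF multiset *is* symmetric and the ensembled block stays exactly
antisymmetric — at the price of re-calibrating the blocks against each
other. `minmax` and `none` reproduce a literal weighted sum. Ties in
the final ranking break lexicographically on (regulator, target) so
output files are byte-reproducible.

## Evaluation metrics

The admissible-pair universe has size T; the gold standard marks P
pairs positive and the rest negative. For a ranking of length L = T the
confusion counts at every cutoff k are exact. For truncated lists
(L < T) the unranked tail is treated as a uniformly random completion:
the expected extra true positives at depth k are
ΔTP = (k−L)(P−TP_L)/(T−L), and recall/precision/FPR use the filled
counts. The filled AUROC equals the Monte-Carlo mean over random
completions (checked against a 10,000-completion oracle). AUROC is the
trapezoid over (FPR, TPR); AUPR is the step-wise sum
Σ ΔRecall·Precision, which on full lists coincides with standard
average precision (checked against scikit-learn to 1e-9). Note the
step-wise PR area of a *random* ranking sits slightly above the density
P/T at finite T (early-rank harmonic inflation); the tests bound rather
than equate it.

The confidence score compares an observed AUROC/AUPR with the
distribution over uniformly random rankings (the minimal "random
network" null for a ranking-valued method): a Gaussian KDE (Scott's
rule) is fitted to n null samples (default 100,000; tests and the
acceptance script use 5,000) and the score is −log10 of the upper-tail
probability, floored at 1e-100, hence capped at 100. Both per-metric
scores and their mean are reported, since how the two are aggregated
into one number is a free choice. The null sampler draws positive
*positions* directly instead of materializing T-long permutations; a
test verifies it against explicit permutations.

EPR = (precision among the top q = P predictions) / (P/T). A random
ranking has expected EPR 1; a perfect one reaches T/P.

An `edge-subset` restriction (e.g. TF–TF pairs only) is intentionally
not implemented as a separate switch: passing a roster whose targets are
empty evaluates exactly the TF–TF universe.

## Synthetic data: what it emulates and what it does not

`simulate_grn` plants a directed graph (TF–TF edges follow a random
topological order, so generation is a DAG even though inference never
uses that) and samples each regulated gene as a sum of per-edge
functions of its regulators plus Gaussian noise — exactly the ANM
mechanism the scorer assumes. Each edge's function output is
standardized to unit variance before summing, so `noise_sd` (default
0.3) is the per-edge noise-to-signal ratio, an explicit per-edge
amplitude is an SNR knob, and deep chains cannot explode numerically.
Functions are random quadratics `a(x+b)²` or saturating `a·tanh(cx+b)`
with |a| ≥ 0.5 so planted edges are detectable at desk-scale n; the
default benchmark is 20 TFs, 80 TGs, 150 edges, 300 samples, mixed
functions.

Because generator and scorer share the ANM assumption, passing the
planted-recovery tests shows the pipeline correctly exploits that
asymmetry — it does **not** show the assumption holds for real
transcriptomics, where measurement noise is not additive Gaussian,
feedback and confounding are common, and mechanisms may be near-linear.
Equally, the generator contains no dropout, batch effects, or count
statistics, so single-cell behavior is out of its reach.

`simulate_stage_series` re-draws the same planted network across
ordered stages while a designated subset of edge amplitudes rises or
falls linearly per stage. Drifting edges are restricted to
single-regulator TG targets whose TF has no TF–TF edges — with a shared
target or a correlated regulator, sibling relations genuinely co-drift
and "the planted monotone set" stops being well-defined — and are given
a near-symmetric quadratic mechanism, the regime where the ANM score
responds most strongly to amplitude (measured response curves: the
score saturates above amplitude ≈ 0.7 at noise 0.2, and |b| ≳ 0.6
quadratics or tanh mechanisms respond 3–5× more weakly). The generators
raise an error rather than silently plant a non-isolated edge.

## Stage-wise screen

Per-stage propensity matrices (shared roster) are mapped to one [0, 1]
scale and a relation is flagged *increasing* iff every consecutive
difference is ≥ 0 and the total change reaches the threshold (default
0.15); *decreasing* symmetric. Constant sequences are never flagged and
the two sets are disjoint for any positive threshold; reversing the
stage order swaps the labels exactly. The scale is min–max with the
range pooled across stages: a per-stage scale lets a single
strengthening relation shrink everyone else monotonically, and a rank
scale amplifies sampling noise among the near-tied non-edge scores.
Pooled-rank and raw-score screening remain options. Driver TFs are
ranked by how many monotone relations they regulate, ties
lexicographic. Differential-expression prefiltering of the gene
universe is upstream of this module.

For stage fixtures the tests use 4,500 samples per stage scored with
15-block split averaging — the screen compares the *same* relation
across stages, so score stability, not per-stage ranking quality, is
the binding constraint (measured estimator sd ≈ 7e-4 against per-stage
response steps ≈ 3.5e-3).

## Problem sizes used in tests and the acceptance script

Direction recovery: 100 pairs at n = 50. Planted benchmark: the default
spec above (T = 1,980 admissible pairs), nulls at 5,000 samples.
Metric oracles: 200-pair universe, 50 rankings; filling oracle at
T = 50 with 10,000 completions. Stage screen: 9-gene fixtures, five
stages, 4,500 samples per stage. These sizes were chosen so the full
suite and the acceptance script each run in minutes on a single CPU
while keeping every Monte-Carlo tolerance meaningful.

## Known limitations

* ANM identifiability fails for linear-Gaussian mechanisms; the scorer
  returns near-zero asymmetry there and the ranking among such pairs is
  noise.
* The HSIC statistic is the biased V-statistic without a significance
  calibration; scores are comparable within a run, not across sample
  sizes (hence the pooled normalization in the stage screen).
* The GPR hyperparameter grid trades a little fit quality for a ~50×
  speedup; pathological lengthscale structure outside the grid would go
  unnoticed (the sklearn cross-check exists for spot audits).
* The learned representations do not improve planted-edge ranking in
  this implementation (see the mode discussion above); on real data,
  where co-expression context may carry information the pairwise
  expression lacks, the `gated` mode is the natural thing to try first.
* Confidence scores saturate at 100 by design; differences above the
  cap are not meaningful.
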