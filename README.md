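# grincd

Gene regulatory network (GRN) inference from expression data, combining
graph-neural-network gene representations with pairwise causal
discovery, plus the evaluation metrics and downstream analyses that go
with it.

## The problem

A GRN is a directed graph of transcription factor (TF) → gene
regulations. Most inference methods score TF–gene *association*
(correlation, mutual information, regression weight), which cannot
orient an edge — in particular TF–TF regulation is invisible to them.
Regulation is intrinsically causal, so this package scores every
admissible ordered pair (TF → TF and TF → target gene; never target →
anything, never self-regulation) with a *causal direction* statistic and
returns a single ranked edge list.

## The method

For a standardized expression matrix `M'` (z-scored per gene, population
sd) the pipeline is:

1. **Potential networks.** Two undirected co-expression graphs over all
   genes: a *linear* one thresholding |Pearson r| and a *nonlinear* one
   thresholding a binned mutual-information estimate. By default the
   threshold is chosen so the graph's sparsity matches a GRN-typical
   average degree (explicit cutoffs are supported).
2. **Gene representations.** Per graph, a two-layer mean-aggregator
   GraphSAGE encoder (numpy implementation) is trained on link
   prediction: positive pairs are edges visited by uniform random walks,
   negatives are degree-sampled non-edges, classes balanced; the
   classifier is logistic on the Hadamard product of the endpoint
   embeddings. Training is judged by held-out link accuracy.
3. **Causal scoring (the core).** For each admissible pair (x, y) an
   additive noise model (ANM) is fit in both directions: Gaussian
   process regression (squared-exponential kernel, marginal-likelihood
   model selection) gives residuals, and the Hilbert–Schmidt
   independence criterion (HSIC, Gaussian kernels, median bandwidth)
   measures residual–cause dependence. The propensity score

       W[x → y] = HSIC(r_backward, y) − HSIC(r_forward, x)

   is large when the forward mechanism `y = f(x) + noise` fits better;
   the TF–TF block of W is antisymmetric by construction and the
   diagonal is zero (no self-regulation).
4. **Ensemble.** The linear and nonlinear pipelines' W matrices are
   combined by a λ-weighted Borda vote (centered ranks; λ = 0.5 by
   default) and flattened into the ranked edge list.

Evaluation utilities implement ROC/PR areas with a *sampling-and-filling*
correction for truncated lists, a random-ranking confidence score
(−log10 of the KDE-estimated tail probability, capped at 100), and the
early precision ratio (EPR: precision among the top-q predictions,
q = number of gold edges, relative to a random predictor).

A synthetic module plants a known GRN and samples expression from the
same additive-noise mechanism the scorer assumes, so every stage is
testable offline. A stage-wise screen ranks "driver" TFs by how many of
their regulations strengthen or weaken monotonically across ordered
disease stages.

## Worked example

```sh
grincd simulate --out-dir fixture --n-tfs 4 --n-tgs 8 --n-edges 12 \
    --n-samples 200 --seed 1
grincd infer --expression fixture/expression.tsv --tfs fixture/tfs.txt \
    --out predictions.tsv --seed 2
grincd evaluate --predictions predictions.tsv \
    --gold fixture/gold_standard.tsv \
    --expression fixture/expression.tsv --tfs fixture/tfs.txt \
    --null-samples 5000
```

prints (numbers from this exact invocation):

```
wrote 12 planted edges to fixture
wrote 44 ranked edges to predictions.tsv
{
  "auroc": 0.984375,
  "aupr": 0.9722222222222221,
  "confidence_auroc": 18.331340479793102,
  "confidence_aupr": 100.0,
  "confidence_mean": 59.16567023989655,
  "epr": 3.361111111111111
}
```

44 edges is every admissible pair (4 TFs × 11 possible targets). An
AUROC of 0.984 means a planted edge outranks a non-edge 98% of the
time. EPR 3.36 means the top-12 predictions contain 3.36× more true
edges than a random ranking would — on this tiny universe (12 of 44
pairs positive) a perfect ranking tops out at 44/12 ≈ 3.67. The AUPR
confidence hits the 100 cap (no random ranking comes close), while the
AUROC confidence stays at 18 because on a 44-pair universe the AUROC
null is coarse and wide, so even an excellent value is "only" ~1e-18
improbable.

The same workflow is available as library calls (`simulate_grn`,
`run_grincd`, `evaluate`), and `grincd stages` screens an ordered list
of per-stage expression files for monotonically changing regulations.

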