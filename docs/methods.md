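# Methods

## Problem and model

Colorectal tumours fall into four transcriptome-defined consensus molecular
subtypes (CMS1–CMS4). The package classifies samples into these subtypes in
two stages: a univariate filter that keeps genes differentially expressed
between at least one pair of subtypes, followed by a small fully-connected
network trained on exactly those genes.

### Differential-expression filter

For each ordered pair among the six (CMS1vCMS2 … CMS3vCMS4) and each gene:

- **log2 fold-change.** Expression is assumed log2-scale (the microarray
  convention); the fold-change is then the difference of group means, which
  equals log2 of the ratio of geometric means. A linear-scale mode computes
  log2 of the ratio of arithmetic means instead, and the loader can apply
  log2(x+1) on read. On already-logged intensities the arithmetic-mean
  ratio would conflate scale and location, so the difference-of-means form
  is the default.
- **Welch t test.** t = (Ā−B̄)/√(s²_A/n_A + s²_B/n_B) with sample variances
  and Welch–Satterthwaite degrees of freedom. The unpooled form is used
  because real CMS cohorts are strongly unbalanced; the tail probability
  comes from `scipy.stats.t`. Two-sided p values match the two-sided
  |log2FC| rule. Zero-variance degenerate genes: equal means give (t=0,
  p=1); unequal means give p=0 with a warning rather than a silent drop.
- **Benjamini–Hochberg.** Step-up adjustment (sorted p·m/rank, running
  minimum from the right, capped at 1) applied *within* each pair across
  all genes; a flag enables pooled adjustment over all six pairs.

A gene is selected when |log2FC| > 1 and Q < 0.05 in at least one pair
(both thresholds configurable). The union over pairs is ordered
deterministically — pairs in the fixed order above, genes lexicographic
within a pair, duplicates kept at first occurrence — so the network input
ordering is reproducible.

### Network

Layers compute f^l = α_l(W_l·a − θ_l) with ReLU on the two hidden layers
(widths 768 and 128 by default, configurable) and softmax on the 4-unit
output. Inverted dropout (keep probability p = 0.5) masks the *outputs* of
hidden layers 1 and 2 only — never the raw input — multiplying kept units
by 1/p so evaluation needs no rescaling; eval mode is fully deterministic.

The objective is the per-sample average of

    Σ_i CE_i + λ₁·(‖W1‖₁+‖W2‖₁) + (λ₂/2)·(‖W1‖²_F+‖W2‖²_F)

i.e. mean cross-entropy plus penalties carrying a 1/n factor. Keeping the
penalties on the per-sample scale is what makes a coefficient of 0.3 a mild
regularizer whose accuracy-vs-coefficient curve declines gently toward 0.9
(as the scan shows); applied as raw norm sums against a *mean* data loss,
the same coefficient overwhelms the data term entirely and the network
cannot leave chance level. The output layer is never penalized. The
true-class probability is clipped at 1e-12 inside the log.

Gradients are analytic: the output error is (probs − one-hot)/n — the
true-class output row is strengthened along its input, all others punished —
propagated through the ReLU derivative and the identical dropout masks used
forward, with L1 subgradient sign(w) (0 at exactly 0) and L2 gradient λ₂w/n
added for W1 and W2. Thresholds enter as −θ, so their gradients are negated
error sums. The whole backward pass is checked against central finite
differences (masks frozen) at relative error < 1e-5.

Adam is standard: m and v are exponential moving averages of g and g²
(β₁ = 0.9, β₂ = 0.999), bias-corrected by 1−βᵗ, step
−α·m̂/(√v̂ + ε) with ε = 1e-8.

## Tunable parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| fc_threshold | 1.0 | log2 units | the conventional two-fold cut |
| q_threshold | 0.05 | FDR | conventional |
| hidden widths | 768, 128 | neurons | the minimalist two-layer design |
| dropout keep p | 0.5 | probability | strongest standard setting, chosen for generalization |
| l1_coef, l2_coef | 0.3 each | per-sample penalty scale | best point of the coefficient scan; exposed separately though they default equal |
| learning_rate | 1e-3 | Adam α | Adam default; reduced ×0.5 after 10 stagnant epochs, floored at 1e-5 |
| batch size / epochs | 32 / ≤200 | — | early stopping on a 20-epoch training-loss plateau |
| init | He-uniform hidden, Glorot output | — | standard for ReLU / softmax layers |

Training is a pure function of the config seed (initialisation, shuffling,
dropout all draw from one generator), so same-seed runs are bit-identical.

Per-gene standardization (z-score) is fit on the training data and stored
in the model bundle together with weights and gene order; prediction aligns
rows to the stored gene order (missing genes error, zero-fill or mean-fill
by policy) and reuses the stored statistics. Cross-platform application is
implausible without such a contract.

## Synthetic cohorts

The generator emulates log-intensity microarray cohorts: background genes
are Normal(baseline 6.0, sd 0.5) in every class; each planted gene belongs
to exactly one CMS pair (so selector precision/recall are unambiguous) and
is shifted by ±effect_size in the first class of its pair; per-class sample
counts are a vector because real CMS cohorts are unbalanced. The standard
benchmark is 60 samples per class, 2000 genes, 50 planted genes per pair,
effect size 2 log2 units, noise sd 0.5. Replicate cohorts can be drawn from
an existing truth record, and an affine platform shift x → 1.2x + 0.5
(moderate for cross-platform log-intensity data) emulates a test cohort
measured elsewhere.

What the generator does **not** emulate: probe effects, batch surrogate
structure, heavy-tailed noise, count (RNA-seq) distributions, correlated
gene modules, or label noise in the CMS assignments. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
clean Gaussian conditions, not that it reaches any particular accuracy on
real cohorts.

## Problem sizes and numerical choices

- The benchmark cross-validation is 10-fold; the regularizer scan uses the
  reduced grid {0.1, 0.3, 0.9} with 5-fold CV and shared fold composition
  across grid points — enough to exhibit the declining trend while keeping
  the scan a few minutes of CPU.
- Gradient checking runs on a (5, 3, 4)-width toy with 10 genes and 6
  samples; central differences with step 1e-6 and frozen dropout masks.
- BH ties are handled by stable argsort; permutation equivariance is
  property-tested.
- Constant genes get sd 1 at standardization, so they contribute zero
  signal instead of dividing by zero.
- Distance correlation (Székely–Rizzo) uses doubly-centered Euclidean
  distance matrices; a constant input is defined as dCor 0. Cohorts with
  different sample counts are compared over shared genes after reducing
  each cohort to its per-gene mean profile (observations = genes) — the
  construction is a package convention and is stated wherever reported.
- Hold-out and CV splits are stratified (plain random splits would let the
  small CMS1/CMS3 classes vanish from folds); gene selection runs inside
  each training fold by default (`per_fold`), with the leaky `global`
  policy available for comparison.
- Undefined per-class ratios (zero denominator) are excluded from macro
  averages and flagged, never scored 0.

## Known limitations

- The t test is unmoderated; limma-style shrinkage would behave better at
  very small n but is deliberately out of scope.
- The per-pair BH default controls FDR within each comparison, not over
  the union of six comparisons.
- Stored-statistics standardization absorbs moderate affine platform
  shifts only because trained decision margins are wide; it is not a batch
  correction method.
- No GPU path; all linear algebra is NumPy on one CPU, which is ample at
  the few-hundred-gene input sizes the filter produces.
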