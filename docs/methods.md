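# Methods

`cdrank` turns fitted dose–response curves from a secondary viability screen
into per-cell-line drug rankings. This note records the model, the defaults,
the numerical choices, and what the synthetic study data does and does not
emulate.

## Effective score and labels

Each screened drug–cell line pair carries three fitted curve parameters: the
area under the viability curve (AUC), the curve's lower viability limit (LL),
and the half-maximal inhibitory concentration (IC50). All three shrink as a
drug becomes more effective. They are condensed into one continuous effective
score

    CES = log( (AUC + LL + IC50) / (2 · AUC · LL · IC50) )

which is symmetric in its three arguments and strictly decreasing in each
(∂CES/∂a = 1/(a+b+c) − 1/a < 0 for positive arguments), hence strictly
increasing in effectiveness. The log base is configurable and defaults to the
natural log; the score's absolute scale (and therefore any printed threshold)
is dataset- and base-dependent, so no threshold constant is hard-coded.

Labels mark the top decile: the default rule thresholds at the empirical 90th
percentile (linear-interpolation quantile) of the observed scores, since "top
10%" is the operative definition; a normal approximation μ + 1.28σ (1.28
being the standard-normal deviate of the upper decile) is available as
`method="normal_approx"`. The threshold is closed on the effective side
(CES ≥ t → 1). Arguments must exceed a positivity floor ε = 1e−12; a lower
limit in (0, ε] breaks the score's domain and such records are excluded with
a logged reason.

## Filter cascade

Records pass, in order: missing-parameter removal (unparseable numerics are
flagged missing at parse time, never silently zeroed); lower limit < 0;
parameters at or below ε; curve fit R² < 0.7. Duplicate (drug, cell) screens
resolve to the designated high-quality screen id (default `MTS010`) when
present, otherwise to the highest-R² duplicate, ties keeping the first
occurrence. After scoring, pairs of withdrawn drugs are removed, then cell
lines that are unannotated, lack expression, or have fewer than 1% effective
pairs. The one-pass semantics is deliberate: the 1%-effective exclusion uses
labels from the threshold computed on pairs surviving the earlier filters,
and the threshold is not recomputed afterwards — recomputation would make the
definition circular; both orders remain available by re-running
`binarize_scores` on the surviving pairs.

## Contrastive pretraining

A single encoder (multi-layer perceptron) embeds both members of a training
pair — a true twin network, the two applications sharing one weight set — and
the pair head maps the Euclidean distance d between the two embeddings to a
probability of the pair being from *different* groups via σ(w·d + b). Binary
cross-entropy against same/different-group labels pulls same-group entities
together and pushes different groups apart. Drugs are grouped by gene targets
(default relation: sharing at least one target; `exact` and `jaccard`
variants exist, and group keys are the transitive closure of the pairwise
relation), and only drugs with at least one reported target enter
pretraining. Cell lines are grouped by cancer type.

Numerical choices that matter:

- **Affine distance head.** A raw σ(d) on a nonnegative distance can never
  emit a probability below 0.5, so same-group pairs could never be called
  "same" with confidence. The head therefore learns a positive scale
  w = exp(ω) and offset b, initialized at (1, 0) — the literal
  sigmoid-of-distance at initialization — and freezable via
  `distance_scale_learnable=False`.
- **Bounded embedding layer.** The embedding layer applies a sigmoid, keeping
  codes in the unit hypercube. Two failure modes motivated this: a linear
  output layer receives exactly cancelling twin-branch bias gradients (the
  pair loss is translation invariant), so inputs with dead hidden units land
  exactly at the origin where cosine similarity is undefined; and clusters
  spread around the origin drive the inter-group cosine negative, making the
  separability ratio sign-unstable. Bounded positive codes keep the
  cosine-based expressiveness metrics well-defined while leaving the
  contrastive geometry free. ReLU/tanh/linear remain configurable.
- **Small output-projection init.** The embedding layer's weights are scaled
  by 0.1 at initialization so initial pair distances sit in the sigmoid's
  responsive range; with large initial distances the head saturates and the
  loss collapses every embedding toward one point.
- **Input standardization.** Features are z-scored per dimension (fitted on
  the training entities, stored on the encoder) so bit vectors and
  log-expression values enter the network on one scale.
- **Training.** Adam with per-epoch exponential learning-rate decay
  (default 1e−3, ×0.99/epoch), dropout 0.2, early stopping on a
  held-out pair set (patience 10). Validation pairs are drawn once and
  frozen; training pairs are resampled with replacement each epoch, balanced
  50/50 same/different. The best-validation state is restored. One seed
  drives weight init, pair sampling and dropout; `max_epochs` defaults to
  100 with 2048 pairs per epoch. Default architecture: hidden layers
  (128, 64), embedding 64 (drugs) / 32 (cells), ReLU hidden activations.
  None of these is treated as externally mandated; all are config-exposed.

## Autoencoder baseline

The non-contrastive comparator is a symmetric reconstruction autoencoder:
the same hidden stack, a continuous tanh bottleneck (the convention for
reconstruction autoencoders — a saturating positive bottleneck binarizes the
code and changes the baseline's character), a linear reconstruction output,
mean-squared error, and the identical Adam/early-stopping/seeding contract.
Its bottleneck embeddings preserve overall feature variance rather than group
structure, standing in for autoencoder-pretrained cell encoders used by
prior dose–response predictors.

## End classifiers and ranking

Drug and cell representations (fingerprint or embedding; expression or
embedding) are concatenated drug-block-first (a Hadamard option exists for
equal block widths) and scored by one of: L2-penalized logistic regression,
a random forest (default 500 trees, seeded, single-thread), or a dense
network trained like the encoders (Adam, dropout, early stopping, LR decay).
No class reweighting is applied by default — labels are ≈10% positive by
construction — with a balanced-weighting flag available. Prioritization sorts
a drug pool by descending predicted score; exact ties break by ascending drug
id, making rankings a deterministic permutation of the pool.

## Splits

Cancers with fewer than 15 cell lines are withheld entirely (novel-cancer
holdout). Of each remaining cancer, 15% of cells — rounded half away from
zero, minimum one — form the trained-on test set; the rest are dealt
round-robin into k = 5 folds after a seeded per-cancer shuffle, so every fold
retains the cancer distribution even when counts are not divisible by k.
Splits operate on cell lines and all of a cell's pairs follow it, so no
pair-level leakage crosses compartments. In the full pipeline the cell
encoder is pretrained on training-compartment cells only.

## Evaluation

P_cell@k(i) = |D_i(k) ∩ E_i| / k, with D_i(k) the top-k prioritized drugs for
cell i and E_i its effective set; P_cancer@k mean-pools P_cell@k over each
cancer's cells, unweighted. Embedding expressiveness: intra-group similarity
is the mean pairwise cosine over unordered distinct within-group pairs
(singleton groups are skipped with a warning), inter-group similarity the
mean cosine of each member to all non-members, and separability their ratio,
computed per group and averaged with equal group weight (mean of ratios, not
ratio of means — the per-group framing is the defining one; size-weighting is
the flagged alternative). |inter| ≤ 1e−9 caps the ratio at a configured
maximum (default 100) with a warning. Identical embeddings give intra = inter
= separability = 1: groups are indistinguishable.

Feature importance: random forests report native impurity importances;
logistic models |coefficients|, gated behind a cross-fold coefficient
stability check (stable iff the mean per-feature variance across folds is at
most 0.1× the mean coefficient magnitude); dense networks use seeded
permutation importance (log-loss increase per shuffled column) over at most
5000 sampled training rows. All importances are min-max scaled and tagged
drug/cell by assembly block.

Model comparison: two-tailed independent t-tests, pooled-variance by default
(Welch optional), Bonferroni-corrected (p × number of comparisons, capped at
1), starred at α ≤ 0.1 / 0.05 / 0.01 / 0.001. Two zero-variance samples with
equal means give p = 1 by convention.

## Synthetic study data

The generator plants exactly the structure the method is meant to recover:

- **Drugs.** Mechanism-of-action (MOA) classes share one random 256-bit base
  fingerprint; each class flips its own disjoint 6 signal bits (any two
  prototypes differ in exactly 12 positions) and each drug adds 6 random
  noise flips. Class signal and noise are thus commensurate, so raw
  fingerprints barely separate classes (raw separability ≈ 1.04) and the
  encoder has something real to amplify. Each class owns a disjoint
  gene-target set; 5% of drugs are flagged withdrawn.
- **Cells.** Each gene carries a positive baseline ~ U(1, 8) (log-expression
  scale, shared across cells — real transcriptomes are dominated by such a
  baseline, which also anchors cosine similarities); each cancer type shifts
  its own 40-gene block by N(0, 1) and each cell adds N(0, 0.25) noise.
  A configurable number of cells is labeled `Unknown`.
- **Response.** A latent sensitivity s = −2 + match(MOA, cancer) +
  N(0, 0.5) maps monotonically to the curve parameters: AUC = 1/(1+eˢ),
  LL = 0.01 + 0.99/(1+eˢ), IC50 = e⁻ˢ. All three strictly decrease in s, so
  by the CES monotonicity property the effective score strictly increases in
  s and oracle expectations stay closed form. The default match matrix
  boosts four of eight MOA classes by +3 against the four cancers
  (diagonal); with eight classes the matched drugs (12.5% of each cell's
  pool) nearly coincide with the top-decile labels, so a correct ranker can
  approach P_cell@1 ≈ 0.8 while a signal-free dataset (match = 0) pins it at
  the ≈ 0.10 base rate. Quality defects are planted at fixed rates: 10%
  low-R² fits, 5% duplicate lower-quality screen rows, 2% negative lower
  limits.

Not emulated: replicate-level screen noise models, expression covariance
between genes, chemistry-valid SMILES (fingerprints are generated directly as
bit vectors; the SMILES path is exercised on real molecules in unit tests),
and dose-unit semantics. Passing tests therefore demonstrate that the
machinery recovers planted class structure and effectiveness signal under
realistic noise — not performance on real screens.

## Problem sizes and determinism

The acceptance computations use: 100,000 draws for the binarization rate;
10,000 random positive triples for the score oracle; 200 random 30-drug
instances for the ranking oracle; 4 classes × 25 drugs and 4 cancers ×
30 cells over 3 seeds for the embedding-expressiveness comparison; and
80 drugs × 400 cells (≈33,000 records) over 3 seeds per condition for the
end-to-end signal-recovery runs — sizes at which the quantities of interest
are stable against sampling noise while the whole suite runs on one CPU in
minutes. All randomness flows from explicit seeds through `numpy`
Generators (the pipeline derives named substreams for encoders, classifier
and splits), and seeded reruns are byte-identical.

## Known limitations

- The sigmoid-of-distance head is trained on pairs sampled with replacement;
  very small groups are over-represented relative to frequency-proportional
  sampling.
- Separability is undefined for zero-norm vectors by construction; encoders
  avoid them by design, but externally supplied embeddings may not.
- The dense-network attribution is permutation importance, which shares
  correlated-feature caveats with all remove-and-rescore schemes.
- `normal_approx` binarization assumes approximate normality of the score
  distribution; on heavy-tailed score sets the empirical quantile rule is
  the safer default.
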