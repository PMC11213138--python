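# Methods

`promodesign` implements an offline model-based optimization (MBO)
workflow for designing cell-type-specific promoter sequences. This note
documents the model, the numerical choices, and the synthetic oracle the
package tests itself against — including what those tests do and do not
demonstrate about real data.

## Problem setting

Given a static dataset 𝒟 = {(xᵢ, yᵢ)} of fixed-length promoter sequences
with measured promoter-driven expression (PE) in each cell type of a panel
C, the goal is to design sequences that maximize differential expression
(DE) in a chosen target cell type tc:

    DE_tc(x) = (1 / (|C|−1)) · Σ_{oc ≠ tc} [ PE_tc(x) − PE_oc(x) ]

No new measurements are available during optimization, so everything runs
against a learned surrogate f_θ — with all the extrapolation hazards that
implies.

## Expression model

A single multi-task network predicts PE in every panel cell type at once
(one output per cell type), so the same design model serves every target.
The default architecture is deliberately small for CPU-scale training:

- one same-padded convolution (32 filters, width 12) with an
  **exponential** activation and bias initialised at −3, followed by
  max-pooling (window 6). Motif occupancy is exponential in a site's
  log-odds score, so an exponential first layer matches the physics of
  TF binding; empirically it roughly doubles held-out correlation over a
  rectifier on sparse planted-motif data;
- one self-attention block (4 heads) with **gated residuals**: each
  residual branch is scaled by a scalar initialised at zero, so the block
  starts as the identity and blends in only as far as it helps. Plain
  pre-norm blocks scrambled the convolutional features early in training
  and reliably stalled optimization in this small-data regime;
- global max-pooling over positions and a per-cell-type linear head.
  Max-pooling matches the oracle's "best site dominates" structure far
  better than mean-pooling at these sequence lengths.

The backbone contains no positional encodings, so it is length-agnostic:
a backbone pretrained on 120-bp corpora transfers directly to 250-bp
panels (`transfer(..., length=...)`).

All inputs are (L, 4) matrices whose rows sum to one; hard one-hot
encodings and relaxed simplex points share one code path.

Training is Adam (lr 1e-3 fine-tuning, 3e-3 pretraining, decoupled weight
decay 1e-4) on the summed per-cell-type MSE of log-scale expression, with
early stopping on validation loss and best-checkpoint selection.
Pretraining stacks corpora with one head per corpus cell type (missing
labels masked); heads are discarded and re-initialised at fine-tuning.

The network runs on the package's own numpy reverse-mode autodiff engine
(`promodesign.nn`); every operator's backward pass is validated against
central finite differences in the test suite.

## Conservative fine-tuning

Naively ascending predicted DE produces adversarial sequences: inputs the
surrogate scores highly only because it extrapolates badly. The design
models are therefore fine-tuned with a conservative regularizer:

    L(θ) = Σ_c E_𝒟[(PE_θc − y_c)²] + α Σ_c ( E_{μ_c}[DE_θc] − E_𝒟[DE_θc] )

where μ_c is rebuilt at every training step by T steps of Adam ascent on
DE_θc in the per-position probability simplex (softmax over per-position
logits), starting from the training batch. Numerical choices:

- inner ascent defaults: lr 0.5, β₁ 0.9, β₂ 0.999, T = 100 (T = 20 at
  smoke scale); logits initialised at γ·onehot with γ = 5, a near-vertex
  start representing the starting sequence;
- μ samples enter the loss as constants — no gradient flows through the
  inner trajectory — keeping the cost linear in T;
- the per-cell-type μ batches are built in one stacked ascent with
  per-row contrast vectors (identical results, one inner loop);
- at desk scale μ starts from a 32-sequence subset of each batch
  (`InnerAscentConfig.mu_batch`), a minibatch estimate of E_μ[DE];
- validation loss for checkpoint selection is the supervised term only,
  so checkpoints are comparable across the α sweep;
- the default sweep is α ∈ {0, 0.0003, 0.001, 0.003, 0.01, 0.03}.

Because μ starts from the data batch and ascent cannot end below its
starting point, the regularizer converges to a small non-negative value
under strong conservatism rather than crossing zero; what large α does is
crush the adversarial overshoot (measured: Σ_c regularizer falls from ≈6
to ≈1 at α = 1 on the smoke panel).

## Design, scoring, selection, calibration

**Design.** Every fine-tuning sequence is a starting sequence; each design
model ascends it with the same inner-ascent settings, then hard-clips
(per-position argmax, ties to the alphabetically first base) back to
discrete DNA. The pool holds |models| × n candidates; duplicates are
retained (the diversity term handles them).

**Pessimistic scoring.** An independently trained heterogeneous ensemble
(shared pretrained backbone; members differ in head type — linear,
one-hidden-layer, attention-pooling — dropout, learning rate, and seed;
data split seed different from the design models') re-scores all
candidates. The pessimistic DE estimate is mean − SD over members
(population SD, divisor n). Candidates must have positive ensemble-mean
DE and ensemble-predicted target expression at or above a configurable
quantile (default: the fine-tuning panel's median) to survive. The
ensemble default size is 8 (3 at smoke scale), configurable upward.

**Selection.** The final batch of K sequences greedily maximizes
Σ lcb(x) + β·D(S), with D(S) the sum over unordered sequence pairs of the
normalized Hamming distance plus the normalized Euclidean distance
between 6-mer frequency vectors (forward strand, overlapping windows;
normalizer √2, the distance between disjoint one-hot frequency vectors).
Ties break toward the higher pessimistic score, then the smaller
candidate id. Pairwise distances against the chosen set are accumulated
incrementally (O(K·|pool|) distance evaluations). β defaults to 0;
diagnostics (per-position base entropy, mean pairwise Hamming) warn when
raising it would help. Hamming diversity of the selected set is
monotone in β up to greedy slack (measured adjacent-β wobble ≤ 0.4%).

**Difficulty diagnostic.** If fewer than 25% of training sequences have
positive measured DE for a target, the design problem is flagged as
likely too hard for the available data before any compute is spent.

**Cross-batch calibration.** Designed sequences are measured in a later
batch than their starting sequences; raw DE values are not comparable
across batches. A common set of sequences measured in both batches is
used as a percentile anchor (midrank convention, ties split); a design
improves on its start when its percentile in batch B strictly exceeds the
start's percentile in batch A. Calibration is trusted only when the
common set's DE ranks are concordant between batches (Spearman ρ ≥ 0.8 by
default; below that a warning is raised and percentiles should be read
skeptically). The pipeline's common set spans evenly spaced ranks of
measured DE so the anchors cover the scale designs are compared on.

## The synthetic oracle

Wet-lab measurement is replaced by a motif-grammar simulator. Expression
of sequence x in cell type c is

    E_c(x) = basal_c + Σ_m effect_{m,c} · sat(occ_m(x)),
    occ_m(x) = Σ_windows exp(score_PWM − score_consensus),
    sat(s) = s / (1 + s)

so one perfect site contributes sat ≈ 0.5 and stacking copies saturates —
gradient ascent cannot win by unbounded motif stacking. Labels add i.i.d.
Gaussian noise (sd 0.2).

The default grammar has three cell types and six motifs: two shared
activators (+1.0 everywhere), one private activator per cell type (+4.0
own cell only), and one shared repressor (−0.8). Planted instances are
drawn from the PWM sharpened to the fourth power (functional,
near-consensus sites). Effect sizes are calibrated so the panel matches
the observable regime of a real cell-type-specificity screen: best
measured DE near 3 on the log scale and cross-batch DE rank concordance
around 0.8 — a regime where signal clearly exceeds measurement noise.
The third cell type carries a basal deficit of 0.5, which leaves only
~12–20% of training sequences with positive measured DE for it across
panel draws: the deliberately hard target that exercises the difficulty
warning.

What the oracle does **not** emulate: read-count statistics and coverage
filters, reverse-strand and positional (promoter-proximal) effects, motif
interactions/cooperativity, batch effects beyond fresh i.i.d. noise, and
the sheer feature diversity of real MPRA data. Passing end-to-end tests
therefore demonstrates that the machinery — conservative training,
simplex ascent, pessimistic selection, percentile calibration — behaves
as designed on a landscape with realistic signal-to-noise; it does not
certify wet-lab effect sizes.

## Study scales

- **Default panel**: 3,000 sequences × 250 bp — used for the
  trainability gate (held-out Pearson r ≥ 0.6 per cell type against the
  noise-free truth; measured ≈ 0.99 with a pretrained backbone).
- **Smoke scale** (end-to-end studies and `smoke_config()`): 400
  fine-tuning sequences × 120 bp, a 3,000-sequence pretraining corpus,
  T = 20 inner steps, two design models (α = 0 and α = 0.01), a 3-member
  ensemble, K = 50, β = 0. These sizes keep a full workflow run around
  two minutes on one CPU while preserving every mechanism.
- **Micro scale** (pipeline contract tests): 150 × 80 bp, T = 5 — enough
  to exercise orchestration, not design quality.

## Known limitations

- The numpy engine is single-threaded and eager; it is sized for the
  desk-scale studies above, not for 17K-sequence pools with 36-member
  ensembles (the library supports those sizes; they just take hours).
- Greedy selection carries no submodular-optimality certificate (the
  objective need not be submodular); measured quality on enumerable pools
  is ≥ 98% of the exhaustive optimum.
- The batch-B "re-measurement" in oracle mode shares the grammar with
  training data generation; real batch effects are richer than fresh
  noise, so the improvement fractions here are an upper bound on what an
  equally-well-trained model would achieve in the lab.
- `percent_gain_best` is reported relative to the best *measured*
  starting DE and is noisy at smoke scale (it can be negative even when
  most designs improve); the improvement fraction is the robust summary.
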