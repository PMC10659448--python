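# Methods

This note records the modelling conventions, numerical choices and the
reasoning behind the defaults, in the order data flows through the
package.

## Graph construction

Functional network connectivity is the Pearson correlation between ROI
time courses (raw r; no Fisher z-transform, since downstream layers
consume bounded signed weights). Conventions:

* **Thresholding ranks by |r| but keeps signed weights.** "Strongest"
  correlations are strongest in magnitude, yet the convolution
  multiplies messages by e_ij, where an anticorrelated neighbour should
  push in the opposite direction. Ranking ties are broken by row-major
  pair order; with continuous data ties have probability zero.
* **Node features stay the full correlation row** even when edges are
  thresholded — features describe a node's global connectivity profile,
  the edge set controls message routing. The diagonal (self-correlation
  1) is kept in the features; the adjacency diagonal is always 0.
* `keep_percent` is interpreted as keep ⌈p/100 · N(N−1)/2⌉ pairs, so
  the edge set is never empty; at 100 % every pair survives.
* Indexing is 0-based internally; ROI labels carry external naming.

## RGIN convolution

`W_i = Σ_u relu(θ1 r_i)_u β_u + b` with a one-hot ROI encoding r_i.
Choices that were genuinely open:

* **(1 + ε) scales only the self term.** The printed forward
  propagation is ambiguous about the placement; the unambiguous
  GIN-style statement of the update puts (1 + ε) on the node's own
  message, and that is what is implemented.
* **Assignment scores are rectified but not normalised.** Only
  non-negativity is required of the cluster scores; projecting onto a
  simplex would change the parametrisation without a stated reason.
* **Position encodings never change.** A pooled node keeps its original
  ROI index through all layers, so θ1 is K × N₀ everywhere and the
  interpretation stage always speaks in original ROI identities. This
  assumes all graphs order their ROIs identically, which graph
  construction guarantees.
* The update MLP is two affine maps with a ReLU between, hidden width =
  output width, biases included ("2-layered" is all that is fixed).
  ε initialises to 0 and is trainable. Mean aggregation divides by the
  neighbour count (isolated nodes keep only the self term).
* The adjacency is treated as a constant of the differentiation tape:
  gradients flow through node features and weights, not through edge
  weights, matching how such models are trained in practice.

## TopK pooling

* k = ⌈ratio · N⌉, never 0. Ties break toward the lower node index —
  measure-zero in training, but it makes tests and reruns exact.
* The score standardisation uses the population standard deviation with
  a 1e-8 guard added to the denominator; a constant score vector
  standardises to all zeros (gate 0.5 everywhere) rather than erroring.
* Selection indices are kept in descending-score order; the surviving
  adjacency is the submatrix on those indices with weights untouched.

## Readouts

Feature matrices are stored nodes × channels; the attention formulas
are written in the transposed D × N orientation and the implementations
contract the node axis accordingly — this orientation decision is made
once, here, to avoid silent transposes.

* GARO and mean+max are permutation-invariant over nodes. SERO is not,
  by construction: its second weight matrix has one row per node. That
  is a documented property of the method, not a defect; it requires a
  fixed node count per block, which ratio-based pooling on a fixed
  53-ROI graph provides (53 → 21 → 8 → 4 at ratio 0.38).
* Attention coefficients are sigmoids, hence strictly inside (0, 1);
  saturating them recovers the plain row-sum readout (tested).
* The √D scaling of the key-query logits uses the block's feature
  width. The attention readouts return a length-D vector per block
  (the weighted node sum), mean+max returns 2D.

## Losses

* SmoothL1, batch-mean; both branches meet at 0.5 with matching slope
  at |x−y| = 1.
* **Unit loss is (‖ω‖₂ − 1)², not ‖ω‖₂ − 1.** The raw form is unbounded
  below (minimised by ω → 0), contradicting its purpose of pinning the
  projection length to 1; the squared form is the default and the raw
  form remains available as `unit_norm_mode="raw"`.
* TPK loss: sigmoid scores sorted descending per instance (sortedness
  is validated), clamped to [1e-7, 1 − 1e-7] before logs; the batch
  reduction is the mean over instances. λ1 defaults to 0.1.

## Training pipeline

* Targets are residualised before training: OLS of score on covariates
  (categoricals one-hot encoded, intercept included), **fitted on the
  training subjects only** and applied to all. A rank-deficient design
  warns and falls back to minimum-norm least squares.
* Optimiser: Adam at 0.001, halved every 30 epochs (the halving factor
  and the optimiser itself were open choices; an adaptive method at the
  stated initial rate is the natural default). Batch size 64. 100
  epochs covers three schedule steps; the checkpoint returned is the
  best-validation-MSE one. Early stopping exists as a knob
  (`patience`) but defaults off: the selection-consistency losses keep
  improving long after validation MSE plateaus, and the full schedule
  costs under two minutes at the default cohort size.
* Degenerate evaluation (zero-variance predictions) reports Pearson
  r = 0 with a warning flag instead of raising.
* Metrics are averaged over four training seeds; the per-seed best
  validation MSE is recorded so a single model can be selected across
  seeds without touching the test split.
* All computation is float64 NumPy driven by `numpy.random.default_rng`
  seeds, so cohorts, training trajectories and reports are
  bit-reproducible from `(config, seed)`.

## Interpretation

Selection frequency of each original ROI after the first pooling layer,
over a holdout set; the retained set uses an inclusive ≥ threshold.
When several seed models exist, interpretation runs on the one with the
best validation MSE — frequencies pooled across seeds dilute toward the
threshold whenever seeds disagree on the non-core ROIs, whereas the
procedure is defined for a single fully trained model. Domain grouping
is a user-supplied ROI → domain lookup join; the package ships the
seven-domain schema (subcortical, auditory, visual, sensorimotor,
cognitive control, default mode, cerebellar) but no proprietary atlas
table.

## Synthetic cohorts

The generator emulates the *shape* of an ICA-derived resting-state
cohort, not its physiology:

* 53 ROIs in 7 near-equal contiguous communities; ROI i in community c
  emits λ·f_c(t) plus independent noise (λ = 0.6), giving
  within-community correlations of λ² ≈ 0.36 and a positive-semidefinite
  correlation model by construction (explicit factor loadings rather
  than perturb-and-project, for validity and determinism).
* Five planted ROIs in five different communities share an extra
  factor with loading √u_m, so each planted-planted pair has model
  correlation u_m ~ Uniform(0.05, 0.55) — the latent trait. True score
  = 10 · u_m; the observed score adds a 1.0/year age slope, site
  offsets up to ±0.8 across four sites, and Gaussian noise
  (σ = 1.35). The signal lives in *edge weights*, the channel the
  edge-weighted convolution can actually exploit.
* 200 time points per subject keep the empirical-correlation
  measurement error small enough that regressing the true score on the
  mean planted connectivity recovers the effect size within 10 % at
  n = 1000 (tested), while leaving realistic sampling noise in every
  matrix.
* σ = 1.35 was calibrated once so that the planted-connectivity oracle
  (linear fit on the training split) reaches a test correlation of
  about 0.7 at the default size — a deliberately imperfect ceiling the
  network is judged against — and then frozen (measured 0.66–0.74
  across cohort seeds).
* Default 600 subjects split 400/100/100 as contiguous blocks
  (subjects are exchangeable by construction).

What passing the planted-signal benchmark shows: the full pipeline can
find a distributed connectivity signal and attribute it to the right
regions under block-structured correlation noise, covariate
contamination and realistic sampling error. What it does not show:
robustness to hemodynamic confounds, scanner/site artefacts in the
*images*, head motion, atlas misregistration, or any claim about real
cohorts — real FNC data differ in all of those ways.

## Known limitations

* Seed-to-seed variability is real: at the default cohort size the
  seed-averaged test correlation typically lands at 0.45–0.65 against
  the ~0.7 oracle ceiling, and the best-validation model recovers 2–4
  of the 5 planted ROIs at the 0.9 frequency threshold. Averaging over
  the four seeds (as the defaults do) is essential; single runs can be
  noticeably better or worse.
* SERO fixes the node count per block, so cohorts with differing ROI
  counts need per-cohort configurations (or GARO/mean+max).
* The training loop is single-process CPU NumPy — comfortable at
  hundreds of 53-node graphs, not intended for thousands of
  high-resolution parcellations.
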