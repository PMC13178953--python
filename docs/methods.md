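# Methods

## Feature derivation

All features live on a shared parcellation of Q regions; every
normalization is computed within a single subject, so train/test
splits cannot leak statistics.

**Functional connectivity (FC).** Pearson correlation between the
regional time series, min–max scaled to [0, 1] over the off-diagonal
entries; the diagonal is excluded from the scaling (self-correlation
is constant and would distort the range) and re-set to 1. A
zero-variance series is a hard error naming the offending column.

**Structural connectivity (SC).** Raw streamline counts are divided by
√(V_GM(i)·V_GM(j)) — the square root of the product of the connected
regions' gray-matter volumes — correcting the tendency of larger
regions to accrue more streamlines, then min–max scaled over the
off-diagonal entries (the conventionally zero diagonal is left at
zero).

**Intrinsic neural timescale (INT).** For a signal of length T the
lag-k autocorrelation uses the full-series centered sum of squares as
denominator at every lag (the biased estimator, computed via FFT and
verified against the defining sums in the tests). N is the lag
immediately preceding the first negative autocorrelation and
INT = TR·Σ_{k=1..N} acf(k), the area under the initial positive phase,
in seconds. If acf(1) < 0 the INT is 0. For an AR(1) process with
coefficient ρ the population value is TR·ρ/(1−ρ), which the estimator
recovers within 15% at T = 20 000. The estimator accepts region-level
series directly; when unit-to-region assignments are supplied,
unit-level values are averaged within regions.

**Structure–function coupling.** Per region, the Spearman rank
correlation (average ranks on ties) between its SC and FC connection
profiles, each profile being the Q−1 off-diagonal entries of that
region's row. Self-entries are excluded: the FC diagonal is constant
and the SC diagonal conventionally zero. A constant profile either
raises or, configurably, emits 0 with a warning.

**Anatomical statistics (AS).** Nine morphological columns (vertex
count, surface area, gray-matter volume, mean/SD cortical thickness,
mean/Gaussian curvature, intrinsic curvature index, folding index) are
variance-stabilized per column with the signed log transform
sign(x)·log1p(|x|) — chosen because curvatures can be negative, where
a plain logarithm is undefined; the transform is monotone and defined
on all of ℝ — then min–max scaled. INT and coupling are appended as
columns 10 and 11 (each min–max scaled across regions), giving
d_c = 11. Min–max scaling is per subject; cohort-wide scaling would be
a leakage channel and is deliberately not offered.

## Graph construction

The subject's graph derives from FC for any run that includes FC and
from SC for SC-only runs. An edge threshold of 0.001 removes
near-zero connectivities, then each node keeps its k = 30
algebraically largest incident values (fewer when fewer exist); ties
at the k-th value break toward the lower region index for
determinism. Selections are OR-symmetrized so every node retains its
own top connections. The adjacency is binary — edge weighting is
delegated entirely to the learned mask — with zero diagonal. The
propagation operator is D̃^{-1/2}(A+I)D̃^{-1/2}; the combinatorial
Laplacian D−A of the self-loop-free adjacency drives the manifold
penalty. At Q = 20 with k = 30 the graph is complete; sparsity
becomes meaningful at larger parcellations.

## Model

Two masked graph-convolution layers share one edge mask
M = sigmoid(V + Vᵀ) (symmetric by construction, entries strictly in
(0,1); V initialized at zero so every edge starts at the neutral
value 0.5). Layer 1 (rectifier) maps the nodal connectivity profiles
to width 32; its output is concatenated node-wise with the AS table;
layer 2 (identity activation before pooling) maps to width 32; node
embeddings are mean-pooled and a dense layer produces the outputs —
one or more regression targets, or class logits. Dropout on the
pooled vector is available but defaults to 0 (see calibration).
Biases are on. The activation/width/dropout choices are configuration,
not architecture constants.

Design choices where the published description is open: mean pooling
(simplest permutation-invariant readout; configurable), AS fusion
after the layer-1 activation, rectifier/identity activations for
layers 1/2. Hidden widths default to 32.

## Objective and optimization

L = L_e + α·L_manifold + λ₁‖M‖₁ + λ₂‖M‖²_F + λ₃‖MMᵀ−I‖_F, with
L_manifold = ½ΣqΣ_{j∈N(q)}‖h_q−h_j‖² = trace(HᵀLH) over the
last-layer embeddings (both forms computed; their equality is a
standing test). The λ₃ term uses the plain Frobenius norm, which is
non-smooth exactly at MMᵀ = I; the zero subgradient is taken there.
The manifold term is monitored each epoch against a configurable
threshold (warning, optional early stop); no threshold is enforced by
default.

Optimization is Adam (β = 0.9/0.999, ε = 1e-8) with L2 weight decay
1e-6 added to the gradients, initial learning rate 0.005, batch size
32, 50 epochs, and halving of the learning rate when the total
validation loss fails to improve for 10 epochs. Gradients are
hand-derived reverse-mode through both masked layers, the fusion
boundary, pooling, readout and all three penalty terms; the test
suite checks them against central finite differences at 1e-5
relative. All randomness (init, batch order, dropout) flows from one
seed; single-threaded runs are bitwise reproducible.

λ₁–λ₃, α and the architecture defaults were fixed once by a seeded
random search scored on validation prediction loss on a synthetic
calibration cohort (cohort seed 500, train seeds 1–2): hidden width
32 and dropout 0 were selected decisively; λ₁–λ₃ = 1e-4 and α = 1e-3
were indistinguishable from zero within noise and kept small and
nonzero so both regularizers remain active.

Repeated evaluation follows the repeated-random-split convention: 10
iterations by default, each re-splitting 70/10/20 with a fresh seed
derived from a master seed, retraining, and evaluating RMSE/MAE
(regression) or accuracy/F1/AUC (classification). Variants share each
iteration's split, so comparisons use paired t-tests; a
resampling-with-replacement mode is available behind a flag. Subjects
lacking a required modality are excluded from runs that need it.

## Interpretation

**Edge level.** The learned mask is passed through a second logistic
and cut at a display threshold; mask entries lie in (0,1), so their
logistic lies in (0.5, 0.731) and the conventional thresholds
0.52/0.53 fall inside that band. Thresholding is monotone (raising
the threshold never adds edges). Surviving edges are exported as an
edge list and aggregated into inter-network weights (sums by default,
counts behind a flag) over named functional networks; within-network
weight is reported separately.

**Feature level.** Grad-RAM (regression targets) and Grad-CAM (class
logits) compute the gradient of one scalar model output with respect
to the fused AS block — the gradient must flow from the model, so the
model's prediction stands in for the target in the gradient — multiply
it elementwise with the feature values, rectify, average over nodes
and then subjects, and softmax-normalize. For joint multi-target
regression the saliency is computed per target.

**Validation utility.** On synthetic cohorts the mask is scored as a
ranker of planted versus background edges by ROC AUC over the
off-diagonal upper triangle.

## Synthetic cohort design

The generator draws, per subject: regional AR(1) time series
(coefficient 0.5, T = 200 frames at TR 0.8 s — desk-scale stand-ins
for resting-state runs) whose innovation covariance is a two-factor
correlation structure; planted functional edges get a subject-level
correlation perturbation (sd 0.35, clipped, re-projected to the
nearest positive-definite correlation) so that their empirical FC
varies across subjects. Structural counts live on a cohort-level
random support (density 0.3) with log-normal magnitudes and subject
jitter; planted structural edges carry a subject latent in their
counts. Morphology tables are log-normal/normal per column with 5%
subject noise.

Labels are y = Σ w_e·FC(e) + Σ w_s·SC_norm(s) + Σ β_j·u_j + ε, where
FC(e) is the subject's empirical planted-edge correlation, SC_norm(s)
the normalized planted structural entry, u_j ~ N(0,1) the subject's
loading on anatomical column j, and ε ~ N(0, 0.1). Classification
cohorts threshold the same score at the cohort median (balanced by
construction). The anatomical loading multiplies a nonnegative
pattern localized on mid-range regions with amplitude 0.5× the
column's interquartile range: the extreme regions then anchor the
per-subject min–max normalization, so the loading survives it — a
zero-mean or mean-level-scaled pattern would be partially or wholly
erased, which is a normalization fact, not a model property.

Effect sizes are derived from feature-space footprints rather than
tuned: a normalized feature with cross-subject footprint σ_f can
drive the label at effect β only if the network expresses gain
β/σ_f, and Adam at the default budget reaches gains of roughly 2–3.
Hence the defaults: anatomical effects ~0.2 (footprint ≈ 0.06),
structural effects ~2.5 (footprint ≈ 0.08–0.12), functional effects
1.0 (footprint ≈ 0.34). The ablation cohort splits label variance
comparably across the three modality families (≈ 0.23 / 0.12 / 0.04)
so each contribution is individually detectable.

What the generator does **not** emulate: hemodynamics, motion and
scanner artifacts, spatial autocorrelation of parcels, realistic
connectome topology (small-worldness, modules), inter-site
heterogeneity. Passing tests therefore demonstrate the pipeline's
internal correctness and the attribution mechanisms' behavior under
known ground truth — not performance on real neuroimaging data.

## Problem sizes

The shipped tests and the acceptance script use Q = 20 regions,
n = 200 subjects, T = 200 frames for trained checks and
T = 20 000 for estimator-consistency checks; these sizes were chosen
so the full pipeline, including repeated training, remains a
minutes-scale single-CPU computation while keeping every planted
effect well above its sampling noise.

## Known limitations

* **Edge-mask attribution fails — systematically — when node features
  are connectivity rows.** Each planted functional edge's value is
  already present in both endpoints' own feature vectors, so the
  pooled prediction can read it through the dense weights without
  propagating across that edge; message passing along the edge only
  duplicates it. An oracle experiment (mask frozen at the ground
  truth) achieves no better fit than the learned mask, i.e. the
  prediction loss carries no incentive aligned with planted edges,
  and the trained mask in fact *de-weights* them (recovery AUC at or
  below chance, 0.0–0.4 across seeds — the redundancy-suppression
  effect). The mask remains meaningful where propagation is
  informative (sparser graphs, features that are not self-sufficient);
  on this testbed the feature-level saliency, not the edge mask, is
  the reliable attribution channel. The acceptance script reports the
  measured recovery AUC as-is.
* The λ₃ orthonormality penalty cannot reach zero for a logistic-range
  mask (row norms exceed 1 for Q ≥ 5 at the neutral initialization);
  it acts as shrinkage, not as an attainable constraint.
* Mean pooling limits the readout to near-uniform node weighting;
  node-specific selection is expressible only through the mask's
  column sums and the rectifier gates.
* The scheduler can collapse the learning rate early when the first
  epochs plateau; with the 50-epoch budget some seeds fit markedly
  worse than others (visible as the occasional saliency miss).
* Signed connectivity values are used for top-k selection (the
  largest algebraic values win); strongly negative correlations are
  therefore never selected as edges.
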