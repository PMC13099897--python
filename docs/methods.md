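# Methods

This note documents the models, the synthetic data they are validated on,
the numerical conventions, and the design choices made where the design was
genuinely open.

## Label model

The training label is a three-tier recurrence risk derived from the 21-gene
recurrence score. The guideline table this follows is a *treatment* table:
it gives a full three-way split (≤15 / 16–25 / ≥26) only for premenopausal
node-negative patients, and a single <26 / ≥26 decision boundary for the
postmenopausal and premenopausal node-positive groups. Because the
classifier needs a three-tier label for every case, the default thresholds
apply the same (15, 25) interior cut to all three groups; thresholds are a
per-group configuration knob, so any institution-specific convention can be
substituted. When a manifest supplies both a recurrence score and a tier,
the tier wins and a consistency check warns (or raises in strict mode).

## Preprocessing

Segmentation works on a low-magnification pyramid level (default target
downsample 32×, chosen as the highest level at or below the target). The
pipeline is: Gaussian blur (σ = 2 px at the working level) → HSV → saturation
channel, scaled to 8-bit → optional morphological-gradient boost → Otsu
threshold → morphological closing (disk radius 2) → remove connected
components below 1,000 px² → fill holes below 500 px². The gradient boost
adds the grey-level morphological gradient (dilation − erosion, disk
radius 2) of the saturation image before thresholding, sharpening stain
boundaries; with the flag off the threshold is exactly plain Otsu, which the
tests verify against an exhaustive 256-threshold between-class-variance
search.

Patches are non-overlapping 256×256 level-0 squares, 0-based (x, y)
top-left coordinates, half-open footprints; a patch is kept when ≥ 50% of
its footprint (mapped to the working level, index bounds rounded) is
tissue. Truncated edge patches are dropped rather than padded. The working
parameters (coverage 0.5, area thresholds, kernel radii) are package
defaults — reasonable for H&E material but not sacred; all sit in
`SegmentationParams`.

## Models

All three classifiers operate on bags (N×D instance-feature matrices) and
are permutation invariant by construction. They are implemented on a small
reverse-mode autodiff engine (`autodiff.py`) whose gradients are verified
against central finite differences to ~1e-10 in the unit tests.

**Modified CLAM-SB.** Instance encoder D→512 (GELU, dropout 0.4), gated
attention `A = σ(W_b h + b_b) ⊙ tanh(W_a h + b_a)` in a 384-dim space
projected to one score per instance, softmax across the bag, weighted sum
to a 512-dim slide vector, then a two-layer classifier 512→256 (GELU,
dropout) →3. Dropout is applied independently in the encoder, attention and
classifier modules. The auxiliary clustering constraint pseudo-labels the
k = 8 highest-attention instances positive and the k lowest negative and
scores them with a binary instance classifier under plain BCE (the smooth
top-k variants of the original formulation are out of scope); the total
loss is `bag_weight·L_bag + (1−bag_weight)·L_inst` with bag_weight 0.5.
The "-B 8" training knob is read as the instance-clustering sample size
(the clustering-constrained reading); a multi-head attention variant was
considered and not built, as the single-branch model already meets every
capacity target.

**Custom ABMIL.** Eight parallel gated heads; each projects instances to
its own head space (head_dim 512), forms tanh(·) ⊙ σ(·) in a 256-dim
attention space, and maps it linearly to one score per risk class. Head
scores merge by elementwise mean (a concat-then-linear merge was the
alternative; mean keeps the head count a free knob with no parameter-count
coupling), then a per-class softmax **across instances** yields an N×K
attention matrix — each class has its own spatial distribution, normalized
over the bag only, not across classes. Aggregation is three-branch
(`branch_c = Σᵢ attn[i,c]·xᵢ`), followed by a shared bottleneck D→512 with
GELU and a *diagonal* readout: class c's logit reads only branch c. The
diagonal choice follows from the branches being explicitly class-specific;
a concatenation readout would let every class read every branch and blur
that semantics. Input dimension defaults to 768 (a common vision-language
encoder width) and is fully configurable — published widths for candidate
encoders disagree, so nothing is hard-coded. Mean gate activation is
recorded per epoch as telemetry (gates tend to start open and grow
selective), but no assertion is attached to it.

**Attention-pool + boosted trees.** Stage 2 is deliberately simpler than
the gated mechanisms: a tanh attention network scores instances, softmax,
`S = Σ aᵢxᵢ`, and a linear head on S trained with focal loss. Stage 3
summarizes each slide as exactly 23 features in a fixed, named order:
MIL logits (3), MIL probabilities (3), log(1+N) (1), attention statistics
(mean, SD, min, max, median, Shannon entropy, normalized entropy — defined
0 at N = 1 — Gini coefficient, top-1 weight, top-5 mass; 10), and
distribution descriptors (skewness, excess kurtosis, 25th/75th percentiles,
IQR, fraction of weights above the mean; 6). **This enumeration is this
package's normative reconstruction**: the categories are standard
attention-distribution summaries, and the order is frozen in
`ENHANCED_FEATURE_NAMES`. Degenerate bags are handled by convention
(skewness/kurtosis 0 when undefined). The boosted head is a multiclass
softmax XGBoost model (200 trees, learning rate 0.1, depth 6, γ = 0,
λ = 1); by default it sees the 23-vector alone — concatenating the full
slide embedding is possible but squanders the interpretability of the
named features on small cohorts.

## Losses

Focal loss with per-class weights, `−α_t (1−p_t)^γ log p_t`, with
α = (1, 3, 1) (medium tier up-weighted 3×) and γ = 2 — the canonical
focusing value, used because no value is printed anywhere authoritative.
Label smoothing ε = 0.1 over K = 3 classes. The two compose as soft-target
focal loss, `Σ_c y′_c ·(−α_c (1−p_c)^γ log p_c)`, chosen because it reduces
to the hard focal loss at ε = 0 and to smoothed cross-entropy at γ = 0.
Probabilities are clamped to [1e-7, 1−1e-7] before logs. GELU is exact
`x·Φ(x)` in the models; the tanh approximation is provided and agrees to
1e-3 on [−5, 5].

## Training and evaluation

Adam with L2 weight decay 1e-4, linear warmup over 5 epochs (lr·(e+1)/5),
one optimizer step per bag. Per-model defaults: CLAM lr 3e-5 / 100 epochs /
patience 20 with focal + smoothing; ABMIL lr 4e-4 / 20 epochs / patience 5
with weighted CE; attention pool lr 1e-3 / 30 epochs with focal. Early
stopping tracks validation loss (the selection criterion is a choice; loss
is smoother than accuracy on 20-case validation folds) and the best-epoch
parameters are restored. Splitting is stratified by tier at the case level;
no case appears on both sides of a fold. Multiclass AUC is the unweighted
mean of per-class one-vs-rest AUCs on predicted probabilities; absent
classes are excluded with a warning. Fold aggregation reports mean and
sample SD (ddof = 1). Ties in argmax resolve to the lowest class index.

The non-MIL baseline trains a logistic-regression patch classifier with
slide labels propagated to instances and takes the modal patch class per
slide (ties → lowest index); slide probabilities for AUC are mean patch
probabilities, with the argmax forced to the vote.

## Synthetic data: what it shows and what it does not

The generator plants class signal in a fraction of instances: background
instances are N(0, I), signal instances N(effect·u_c, I) with orthonormal
class directions from a seeded QR decomposition (equal pairwise
separations). Priors (0.45, 0.10, 0.45) under largest-remainder stratified
allocation reproduce a 210-case cohort with exactly 21 medium cases. An
optional "grey zone" mode places the medium mean on the segment between the
low and high means, mimicking intermediate biology; it is off by default.

This captures the statistical skeleton MIL assumes — bag labels driven by a
minority of informative instances under class imbalance — but none of the
hard parts of real histology: stain variation, scanner domain shift,
spatial correlation between patches, ambiguous intermediate morphology, or
label noise in the RS cut-offs. Passing the synthetic recovery suite
therefore validates the machinery (optimization, attention, loss behavior,
leakage-free evaluation), not clinical performance.

Desk-scale study sizes were fixed once for the recovery experiments:
150 cases, 64-dim features, bags of 16–64 instances, signal fraction 0.3,
effect size 2.0, and a shorter optimization (lr 5e-4, ≤30 epochs, patience
8) suited to these dimensions — the full-scale defaults assume
foundation-model features at D ≈ 1024. Under these conditions the 5-fold
CLAM-SB reaches macro AUC ≈ 0.999 and beats the majority-vote baseline by
~14 accuracy points, and focal loss with α_medium = 3 lifts medium-tier
recall well above plain cross-entropy (1.00 vs ≈ 0.47 pooled over folds at
seed 1).

## Numerical conventions and degenerate cases

- Softmax uses max subtraction; attention weights sum to 1 within 1e-6.
- A constant saturation image yields an empty mask with a warning, not an
  error; an empty mask yields an empty patch grid.
- Heatmap min-max normalization: a singleton score paints 1.0 against a 0
  background; several all-equal scores map to the neutral 0.5. Gaussian
  smoothing uses reflective padding (mass-conserving for interior blobs);
  the bilinear path upsamples from patch-grid resolution.
- Checkpoints are single-file `.npz` archives with the model config
  embedded as JSON; attention exports are HDF5 scores aligned to bag
  coordinates.
- `k_sample` in the clustering loss is clamped to the bag size; an N = 1
  bag degenerates to the same instance pseudo-labeled both ways and stays
  finite.

## Known limitations

- No real pretrained pathology encoder ships here; the encoder interface
  accepts adapters, and all tests run on deterministic stubs.
- Vendor slide formats and true pyramidal TIFF reading are out of scope;
  the slide abstraction wraps in-memory/plain rasters as pyramids.
- The printed SDs of the reference per-fold tables are not reproducible
  from their printed fold values under either the sample or population
  convention, so only means are checked.
- Single-optimizer-step-per-bag training is sequential and CPU-bound;
  at foundation-model scale (N in the thousands, D ≈ 1024) a GPU tensor
  backend would be the natural replacement for the autodiff core.
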