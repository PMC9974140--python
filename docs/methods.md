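# Methods

## Problem setting

Top-down images of *Arabidopsis thaliana* rosettes carry several correlated
phenotypes at once: the genotype (here five classes — col-0, ein2, pgm, ctr,
adh1), the number of leaves, and the leaf area.  A hard-parameter-sharing
multi-task network exploits that correlation: one convolutional trunk feeds
a 5-way softmax head and two single-unit regression heads, and the trunk's
structure is chosen by neural architecture search rather than by hand.

## The multi-task model

An architecture is a DAG of typed layers (input, cast, conv, flatten,
dropout, dense, softmax head, regression head, add, concat).  Output shapes
are derived layer by layer; trainable parameters are counted in closed form
(conv `k²·c_in·c_out + c_out`, dense and regression heads
`d_in·d_out + d_out`, everything else 0).  The reference model is, layer for
layer: 28×28×3 input → cast → four 3×3/32 valid convolutions → a
flatten→dense(5)→softmax genotype branch, a dropout→flatten→1-unit
leaf-count branch, and a flatten→1-unit leaf-area branch, both regression
branches taken from the fourth convolution.  Its per-layer counts are 896,
9248, 9248, 9248, 64005, 12801, 12801 and the total is 118,247.  Summary
tables of the framework that generated this model attach the regression
heads' weights to the head rows themselves, so here `regression_head` is a
single-unit dense layer while the softmax head is parameter-free.

Training minimizes

    w_cls·CE(genotype) + w_count·MSE(count) + w_area·MSE(area) + λ‖θ‖²

with Adam.  Defaults: weights (1, 1, 1), λ = 0, learning rate 1e-3, batch 32,
300 epochs, dropout rate 0.25, ReLU after every convolution, identity on
regression heads.  None of the task weighting, optimizer, batch size or
dropout rate is dictated by the model summary; these are the conventional
choices for this model family and are all configurable.  Counts are
regressed as floats (predictions are also exposed rounded); area is
regressed in normalized units (fraction of the canvas).

Inside `train` both regression targets are standardized with
training-split statistics, and the inverse transform is folded back into
the head weights on exit, so predictions and checkpoints stay in raw
units.  Without this, nominally equal task weights are scale-inconsistent:
the raw-count MSE (counts run 4–16) is some three orders of magnitude
larger than the normalized-area MSE, and the area head barely trains.
Frameworks of the kind this package emulates apply the same normalization
in their regression heads.  A warm-started model is unfolded with the
current statistics before training, which exactly restores its trained
standardized heads when the data split is unchanged.

The engine is a compact NumPy implementation: im2col convolutions, reverse
topological-order backpropagation with gradient accumulation at branch
points, inverted-dropout scaling, float32 throughout.  Builds and training
runs are deterministic given their seeds on a fixed device, which is what
makes the search's bit-identical-log contract testable.

## Architecture search

The loop mirrors morphism-based Bayesian-optimization NAS:

1. **Seeds.**  One small template per enabled family: a plain two-conv CNN
   (valid padding), a residual template with two additive skips, and a
   densely connected template with two concatenative links (same padding so
   merges are shape-compatible).  Seeds cycle through families.
2. **Trial training.**  Each architecture trains for a per-trial epoch
   budget with early stopping (patience 5 on the validation total loss).
   The trial's objective is its best validation total loss — lower is
   better; the maximized "performance" of the usual NAS formulation is the
   negative of this.  Early-stopped objectives are what the surrogate sees,
   and the trial record flags them.
3. **Surrogate.**  A Gaussian process over architectures with kernel
   `κ(a,b) = exp(−ρ·d(a,b)²) + σ²·1[a=b]`, ρ = 0.5, σ² = 1e-4, prior mean
   equal to the mean observed objective and unit amplitude.  `d` is a
   Levenshtein distance over the layer sequence: insertions and deletions
   cost 1, matched same-kind layers cost the normalized width difference
   `|w_a−w_b|/max(w_a,w_b)`.  The posterior is the standard closed form via
   Cholesky factorization, with escalating jitter on numerical failure.
4. **Proposal.**  Parents are drawn from the trial history through a
   Metropolis/annealing gate — always accepted if at least as good as the
   incumbent, otherwise with probability `exp(−Δ/T)`; a random legal
   morphism produces a candidate; candidates structurally identical to any
   previous trial are discarded; the survivor with the lowest
   lower-confidence-bound score `μ − β·√σ²` is trained next.  T starts at
   1.0 and β at 2.5, both decaying by 0.9 per trial, shifting from
   exploration to exploitation as the budget runs out.  A bounded retry
   budget (64 draws) guards against exhausted spaces.
5. **Morphisms** are function-preserving, so children start from their
   parent's trained weights and verifiably compute the same function before
   retraining: *deepen* inserts a same-padding convolution initialized to
   the identity kernel (exact after a ReLU layer, whose outputs are
   nonnegative); *widen* copies existing filters cyclically into the new
   channels and zero-initializes every downstream consumer's cross-terms
   (dense consumers are re-indexed through the flatten layout); *add_skip*
   sums a zero-initialized 1×1 linear projection of an earlier layer into a
   later one.  Widening a convolution whose channel change would reach an
   add/concat merge is rejected rather than propagated.
6. **Final retrain.**  After `max_trials` trials the best architecture is
   rebuilt from scratch and trained for the full epoch budget without early
   stopping — the "extra" training run beyond the trial budget — and the
   retrain is appended to the trial log.

## Synthetic data

The generator emulates the layout of CVPPP-style rosette datasets: per plant
an RGB PNG, an indexed-color label PNG with one color per leaf, and a CSV
manifest (`image_id,genotype,declared_leaf_count`); genotypes are assigned
round-robin.  Leaf *i* sits at azimuth *i*·137.5° (the phyllotactic
divergence angle) with strictly increasing radial distance, rendered as a
filled ellipse; later leaves occlude earlier ones.  A leaf's area is its
*visible* pixel count after z-order painting, a leaf occluded below 5
visible pixels is removed from both label image and ground truth (sub-pixel
slivers otherwise make the count-consistency filter flaky), and the
leaf-area regression target is total visible foreground normalized by
canvas area — the one quantity derivable from the label image alone, which
is why it was chosen over per-leaf or bounding-box area.

The five genotype presets differ jointly in leaf-count range (4–6 up to
12–16), leaf length scale (16–38 px on a 128 px canvas), aspect ratio and
hue, so genotype is recoverable above chance from (count, area) alone — the
test suite checks this with a nearest-centroid probe.  Canvas 128 px,
additive Gaussian RGB noise (σ = 4 intensity levels) seeded from the scene
geometry so rendering stays a pure function; label images are noise-free.

What the generator does **not** emulate: real leaf shapes and texture,
illumination variation, soil/moss background clutter, overlapping plants,
camera distortion, or growth dynamics.  Passing the recovery tests therefore
shows the pipeline and optimizer work end to end on images whose information
content matches the task structure — not that the model reaches any
particular accuracy on real rosette photographs.

## Evaluation metrics

Classification metrics come from the confusion matrix (rows true, columns
predicted): accuracy is trace/total — exactly `(TP+TN)/(TP+TN+FP+FN)` in the
two-class case — and precision/recall/F1 are exposed macro- (default) and
micro-averaged, since micro averaging makes precision, recall and accuracy
coincide for single-label multiclass data.  R² defaults to the conventional
`1 − SSres/SStot`; the explained-variance ratio `Σ(ŷᵢ−ȳ)²/Σ(yᵢ−ȳ)²` is
available as `variant="as_printed"` because some reports print that form —
the two coincide only for least-squares fits with intercept, and the ratio
can exceed 1 for other predictors (worked example in the tests: y=[1,2,3],
ŷ=[1,2,4] gives 0.5 vs 2.5).

## Numerical and design choices

- Coordinates: masks and internal boxes are 0-based half-open; COCO bboxes
  are `[x, y, w, h]`; VOC XML is 1-based inclusive.  Each conversion is
  tested explicitly.  The VOC dialect adds one `area_px` element per object
  so per-leaf areas survive the XML round trip (standard VOC has no area
  field); genotype is an image-level attribute in both formats and "leaf"
  is the single object category.
- Cleaning compares the derived count against the CSV manifest's declared
  count (a COCO-derived declared count can be passed instead); it is
  idempotent.
- Weight initialization: He-normal for convolutions, Glorot-uniform for
  dense layers, zero biases; all from one seeded generator so equal seeds
  give bit-identical networks.
- GP numerics: kernel matrix solved by Cholesky with jitter escalating from
  1e-10; posterior variance clipped at 0; an architecture re-observed
  replaces its previous objective rather than duplicating a row.
- Degenerate inputs rejected with messages: truecolor label images with
  antialiased edges (too many distinct colors, offenders named), constant
  `y` in R², non-finite losses (aborts with per-task diagnostics),
  spatially incompatible skip endpoints.
- Problem sizes in the test suite are chosen to keep a full run on one CPU
  comfortable: the search contract and recovery tests use 200 plants
  (160 fit / 40 held out), 10 trials at 20 epochs with patience 5, and a
  120-epoch final retrain — the same shape as a full-scale run, scaled to
  the synthetic task's difficulty.  On these conditions the retrained best
  model reaches ≥ 0.90 genotype accuracy and ≥ 0.80 R² on both regressions
  on the held-out split.

## Known limitations

- The NumPy engine targets 28×28-scale inputs and small batches; it has no
  GPU path and trials run sequentially.
- COCO output carries bounding boxes and areas, not polygon/RLE masks.
- The surrogate's edit distance ignores wiring topology beyond the layer
  sequence, so two differently connected architectures with the same layer
  list look identical to the GP (the novelty check, by contrast, uses full
  structural identity).
- Seed templates are fixed; the search cannot change kernel sizes or head
  structure, only depth, width and skip connections, which is the intended
  morphism menu.
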