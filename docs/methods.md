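# Methods

## Problem

Single-particle cryo-EM analysis needs the pixel coordinates of many
thousands of particle projections in low-SNR micrographs.  Supervised
neural pickers want large labeled sets; template matchers want good
templates.  `maepick` implements a few-shot alternative: label ~15
particles on ONE reference micrograph, train a small masked-autoencoder
(MAE) encoder on that single image, and transfer it to the remaining
("query") micrographs by nearest-exemplar cosine scoring.

## Stage 1 — training on one reference micrograph

Crops are square regions of side equal to the particle diameter:
`m` exemplar crops centered on the labeled coordinates and `n` random
("unlabeled") crops drawn blindly from the same micrograph, which are
mostly background because particles are sparse.  Normalization happens
in two steps chosen to keep the discriminative cue alive: the whole
micrograph is scaled once to unit global standard deviation (so crop
amplitudes are comparable across micrographs), and each crop then has
only its mean removed.  Per-crop *variance* scaling — the other obvious
choice — turned out to erase exactly the signal that separates a
structured particle crop from flat background noise (both become
unit-variance textures), so it is not the default, though a `zscore`
mode remains selectable in `MaeConfig`.  The normalized crop is cut
into square patches and a fraction `mask_ratio` (default 0.75) of the
patches is masked uniformly at random.  The ViT-style encoder sees only visible patches; a light
decoder reconstructs the full patch grid; the reconstruction loss
`l_mse` is the mean squared error over masked patches only, the
standard MAE objective.

Training runs in two phases:

1. **Pre-training** — reconstruction only, on a broad pool of unlabeled
   crops (default 4x the fine-tuning pool).  This exposes the encoder to
   the background variability (ice blobs, gradients, noise texture)
   before any discriminative pressure is applied.
2. **Fine-tuning** — every step batches all `m` exemplars together with
   a minibatch of unlabeled crops and minimizes
   `l_total = l_mse + beta * l_scs`, where `l_scs` is the self-cross
   similarity loss computed from the pooled latent features *of the
   masked inputs* (they share the forward pass with reconstruction).

The self-cross similarity loss is the floored hinge

    l_scs = max(tau, 1 + alpha * S_cross - (1 - alpha) * S_self)

with `S_self` the mean pairwise cosine among exemplar features
(including the diagonal, as defined) and `S_cross` the mean cosine
between exemplar and unlabeled features.  Because a fraction `pi_hat`
of blind crops actually contains particles (positive-unlabeled
contamination), the default uses the adjusted similarities computed from
the raw pairwise cosine sums `S_ll, S_lu, S_uu`:

    S^_self  = (S_ll + 2 pi S_lu + pi^2 S_uu) / (m + n)^2
    S^_cross = ((1 - pi) S_lu + pi (1 - pi) S_uu) / ((m + n) n)

These are implemented exactly as written.  Note a formal wrinkle we
preserve deliberately: the `pi_hat -> 0` limits do not reduce to the
unadjusted definitions (the normalizations differ, `1/(m+n)^2` vs
`1/m^2`).  Both variants are selectable (`LossConfig.adjusted`), so the
discrepancy is observable rather than hidden.

The `1/(m+n)^2` normalization has a practical consequence for `tau`:
with m = 15 exemplars and a batch of 32 unlabeled crops, `S^_self` is
bounded near 0.2, so the adjusted hinge ranges over roughly
`[0.7, 1.1]` and a conventional small floor such as 0.05 can never
engage.  Without an engaging floor the loss keeps rewarding separation
indefinitely and the latent space collapses onto two antipodal
prototypes — cosine scores degenerate to ±1 and window scoring loses
all its gradation (we observed exactly this).  The floor must
therefore live on the scale of the similarities it floors: the default
is `tau = 0.8` for the adjusted variant (halting the contrastive
pressure once exemplars and background are well separated, before
collapse) and `tau = 0.05` for the unadjusted one, whose hinge can
genuinely approach zero.

## Stage 2 — picking on query micrographs

The trained encoder slides over each query micrograph with a stride
(default 28 px) and a window of one particle diameter; windows are
encoded WITHOUT masking and scored by cosine similarity to the exemplar
features — by default the **max** over exemplars, because with varied
in-plane orientations the best-matching exemplar is the meaningful
reference and averaging dilutes it (a `mean` mode exists for
comparison).

The per-micrograph cutoff is automatic: for each score compute the mean
absolute difference to its `k = 5` nearest neighbors in score space;
order these average distances by descending score; place the cutoff at
the score where the sequence *drops* the most, i.e. where the sparse
high-similarity tail ends and the dense background bulk begins (ties go
to the higher score, the more conservative cut).  Everything strictly
above the cutoff is picked; the recorded coordinate is the window
center.  Above-threshold windows are then reduced to one coordinate per
particle by greedy non-maximum suppression with radius
`dedupe_radius = window_size / 2` (the "auto" default): with a stride
much smaller than the window, several overlapping windows fire on every
particle, and emitting all of them would report window multiplicity,
not detections — on the synthetic benchmark essentially *all* false
positives before suppression were such overlapping windows, not
background.  Set `dedupe_radius=None` to emit the raw above-threshold
set (the evaluation still charges duplicate detections as false
positives either way).

With fewer than `k + 2` scores the rule is undefined and the midpoint
of the score range is used, with a warning.

## Evaluation

A pick is a true positive when its diameter-sized square box reaches
IoU >= 0.5 with an *unmatched* ground-truth box; each truth can be
matched once; duplicates and misses are false positives; unmatched
truths are false negatives.  Matching is greedy in descending pick-score
order (ties by pick index); the test suite verifies agreement with the
exhaustive optimal assignment on small fixtures.  Conventions:
precision is 0 with no picks, F1 is 0 when precision + recall is 0.
Squares (not circles) were chosen as the box geometry since boxes are
what coordinate-exchange formats describe; the choice only matters near
the IoU threshold.

## Synthetic data generator

The generator emulates the operating conditions of a few-shot picker,
not cryo-EM physics: a grayscale field containing many copies of one
particle motif at random in-plane orientations plus nuisances.

* **Motifs** (`ring`, `bar`, `trefoil`) are analytic intensity profiles
  evaluated on rotated coordinates (no interpolation); `ring` is
  rotation-invariant, `bar` 180deg-periodic, `trefoil` 120deg-periodic.
  The default is `trefoil`, the simplest motif that genuinely exercises
  orientation diversity.
* **Placement** is rejection sampling with a minimum pairwise center
  distance and a diameter/2 inset from the edges; the attempt budget is
  1000 per particle, after which generation fails loudly.
* **Nuisances** are elliptical Gaussian blobs (random eccentricity,
  sign, and scale) and linear intensity ramps — stand-ins for ice
  contamination and illumination gradients.
* **Noise** is additive white Gaussian; the clean particle signal is
  normalized to unit variance inside particle footprints, and the noise
  sigma is `sqrt(1/snr)`, so the requested SNR (footprint signal
  variance over noise variance) holds by construction.

What this does *not* model: CTF oscillations, structured/correlated
noise, ice thickness variation, particle aggregation, carbon edges.
Passing the end-to-end checks therefore shows the pipeline is correct
and the loss does what it claims under controlled conditions; it does
not predict absolute performance on real micrographs.

Coordinates everywhere are `(x, y)` = (column, row), 0-based, particle
centers; images are `[y, x]` float32 arrays.

## Model sizes and study conditions

The architecture is deliberately small ("the method, not capacity, is
the contribution"): embed dim 64, depth 4, 4 heads, decoder 32/depth 2.
Two input geometries are provided:

* `MaeConfig()` — the conventional 224-px / 16-px-patch ViT geometry
  (196 patches, 147 masked at the 0.75 ratio).
* `MaeConfig.desk_scale()` — 64-px input with 8-px patches.  The
  end-to-end study conditions use 64-px particle crops; encoding them at
  native resolution avoids a 3.5x upsampling that adds no information
  and makes a 1-CPU run of the whole pipeline take minutes instead of
  hours.

Desk-scale study conditions (used by the end-to-end tests and
`scripts/acceptance.py`): 1024x1024 micrographs, diameter 64 px, ~40
particles per field, SNR 2.0 (an easy regime chosen so detection quality
is attainable at this scale), 1 reference + 3 queries, m = 15
exemplars, n = 64 unlabeled crops (pre-training pool 256), 150
pre-training and 300 fine-tuning steps with 32 unlabeled crops per
step, AdamW at 3e-4 with no schedule, stride 28, k = 5.  The optimizer
settings were fixed once on a small calibration set of generator
seeds: the larger unlabeled minibatch stabilizes the pairwise
similarity sums, and the lower learning rate compensates for the
absence of a warmup schedule.

## Numerical choices

* All tensors are float32; gradients are reverse-mode on a minimal
  in-package autodiff engine (verified against finite differences in
  the test suite).
* Positional embeddings are fixed 2D sine-cosine; latent pooling is the
  mean over token embeddings (visible tokens in stage 1, all tokens in
  stage 2), which keeps the two stages' features in the same space; a
  cls-token mode exists.
* Cosine similarity raises on zero-norm vectors rather than silently
  returning 0.
* The SCS hinge passes gradient only where the pre-floor value exceeds
  `tau` (standard subgradient convention).
* Determinism: every stochastic step (placement, crop sampling, mask
  shuffling, init, batching) derives from explicit integer seeds, so a
  run is bit-reproducible from its config snapshot + seed.

## Default loss weights

`alpha = 0.5` (equal weight on cohesion and separation), `tau = 0.05`,
`beta = 1.0`, `pi_hat = 0.1` (sparse-particle prior: a blind
diameter-sized crop rarely hits a particle).  All are exposed in
`LossConfig` and the YAML config.

## Known limitations

* The density cutoff assumes the score distribution has a sparse
  high-similarity tail separated from a dense background bulk; when
  stage-1 separation is weak the largest drop can occur in the noisy
  low tail and the threshold becomes permissive.  The score histogram
  (`viz.plot_score_histogram`) makes this easy to inspect.
* With duplicate suppression disabled, precision at small strides is
  bounded by the windows-per-particle ratio.
* Picking never scans the right/bottom margin smaller than one window.
* The generator's nuisances are mild; real ice contamination is harder.
* The mean-removal normalization assumes micrographs of one dataset
  share an intensity scale after per-micrograph contrast scaling; data
  with strong within-micrograph gain variation would favor the
  `zscore` mode.
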