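# Methods

`stormdistill` studies whether the dense-emitter localization capacity of a
large encoder–decoder network (a DRL-STORM-style teacher) can be transferred
to a small three-layer network (an SRCNN student) operating at magnification
1, i.e. producing its reconstruction on the same pixel grid as the input
frame. This note records the models, the synthetic-data protocol, the
numerical conventions, and the design choices made where the design was
genuinely open.

## Problem setting

In single-molecule localization microscopy (STORM/SMLM), raising the emitter
density shortens acquisitions but makes point-spread functions overlap, so
frames must be deconvolved by a multi-emitter localizer. CNN localizers do
this well but are large; distilling one into a compact student would enable
deployment on edge devices. The package frames this as paired image
regression: input `X` is a diffraction-limited camera frame, target `Y` is a
same-grid sparse "spike" image with each emitter's signal at its true pixel.

## Synthetic data

The generator emulates a ThunderSTORM-style simulation protocol:

* **Emitter fields** — emitter count ~ Poisson(ρ·A) for density ρ
  (defaults: 13 emitters/μm² for the dense set, 5 for the sparse set) over
  field area A; positions uniform; photons fixed at 1000 per emitter by
  default (a lognormal mode with shape 0.5 exists, but the default keeps the
  density/background statistics independent of brightness fluctuations).
* **Pixel size** — 0.1 μm/px, typical of SMLM cameras; every density
  computation flows through this value. **PSF** — isotropic Gaussian,
  σ = 1.6 px, representative of visible-light SMLM at this pixel size.
* **Frames** — `X = Poisson(PSF(spikes) + b)` with uniform background
  b = 200 counts; Poisson shot noise applies to signal plus background. A
  noise-free mode exists for oracle tests. `Y` is the spike image itself:
  nearest-pixel deposition, zero elsewhere. The spike reading of the
  "super-resolved counterpart" is an interpretation — magnification 1 plus
  an L1 sparsity penalty presuppose a sparse target, and the 3×3 Gaussian
  inside the loss supplies the sub-pixel tolerance.
* **Patches** — random square crops (200×200 by default; overlapping
  allowed, offsets uniform with replacement), each labeled train/val/test by
  an independent categorical draw at probabilities (0.8, 0.1, 0.1). X
  patches are z-scored by the mean/std pooled over the entire dataset; the
  stats are stored for inference-time reuse. The protocol's stated patch
  count (200 per frame from five frames) and its stated total (20,000 pairs)
  are irreconcilable as written; `patches_per_image` is configurable and
  4000/frame reproduces the 20,000-pair total.
* **Target amplitude** — `render_pair` deposits raw photon counts (so the
  spike sum equals the emitter's photons), but the dataset builder rescales
  Y by the nominal photon count to unit-amplitude spikes
  (`y_scale="unit"`, recorded in the sidecar). Unit spikes put the losses at
  the O(1)–O(10³) magnitudes the training protocol was tuned for; raw
  photon-count targets (`y_scale="photons"`) would scale every loss and
  gradient by 10³ without changing the comparison.

What the generator does **not** emulate: EM gain/readout noise and the rest
of a real camera model, blinking kinetics across frames, drift, and 3-D or
astigmatic PSFs. Passing tests therefore show correctness of the method
under idealized Poisson imaging, not performance on real microscope data.

## Architectures

Both networks are factorized at the penultimate **32-channel hint layer**
into a *body* (input → hint) and a *head* (hint → 1-channel reconstruction);
`head(body(x))` is exactly the full forward pass, and all convolutions are
zero-padded to preserve H×W.

* **SRCNN student** — body: 9×9 conv (1→64) + ReLU, 1×1 conv (64→32) +
  ReLU; head: 5×5 conv (32→1). 8129 parameters. Kernel sizes follow the
  original SRCNN family.
* **DRL-STORM-style teacher** — encoder: three stages of 3×3 conv + ReLU +
  2×2 max-pool with widths (32, 64, 128); decoder: three stages of 2×
  nearest-neighbour up-sample + 3×3 conv + ReLU with widths (64, 32, 32),
  ending at the hint layer; head: 3×3 conv (32→1). ~195k parameters, ~24×
  the student. Inputs must be divisible by 8. The exact published widths
  are not enumerated anywhere; these follow a Deep-STORM-like progression
  and are config-exposed, since the study's claims rest on the structural
  features (pooling, up-sampling, skip, 32-channel penultimate layer), not
  exact widths.
* **Skip connection** — the input, block-averaged to the bottleneck
  resolution and projected by a 1×1 conv, is *added* to the encoder output
  ("output of the first half"); concatenation is available as a config
  alternative. Block-averaging is our resolution of the spatial mismatch
  between a full-resolution input and an 8×-downsampled encoder output.
* **Initialization** — Kaiming fan-in normal (suited to ReLU), fully
  seeded; two builds from one seed are bit-identical.

The layers themselves (`stormdistill.nn`) are a small numpy implementation:
im2col convolutions with exact analytic backward passes, 2×2 max-pool
(ties route to the first element), nearest/bilinear up-sampling, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). First-layer convolutions skip the input
gradient, which nothing consumes. Arithmetic is float32 for
activations/weights and float64 inside loss computations.

## Losses

* **L1L2** (sparsity weight λ, default 100):
  `L = (1/N) Σᵢ [(λ/2)‖(x̂ᵢ−xᵢ)⊗g‖² + ‖x̂ᵢ‖₁]`, where g is a normalized
  3×3 Gaussian, σ = 1 (zero-padded, same-size convolution — the simplest
  reproducible boundary convention). The λ/2 convention is deliberate.
* **Attentive imitation loss** (attention α ∈ [0,1]): blends the student's
  own L1L2 term against ground truth with a teacher-informed term scaled by
  `Φ = mean(e_T)/η`, `η = max(e_T) − min(e_T)`, where `e_T` holds the frozen
  teacher's per-sample L1L2 losses over the training set, computed in one
  post-training pass (mid-training losses depend on epoch ordering and are
  not reproducible). Two teacher-term forms are implemented:
  `as_printed` (default) penalizes the **teacher-vs-truth** squared error
  together with the student's L1; `imitation` penalizes the
  **student-vs-teacher** squared error, the form standard in regression
  distillation. Both are exposed because the printed form gives the teacher
  term no student gradient beyond the L1 — users can test either without
  guessing. A literal reading that would embed the student's L1 inside
  `e_T` itself is unreachable (e_T exists before any student) and is
  documented here rather than implemented. α = 1 reduces to plain L1L2 and
  the implementation takes that branch literally, so baseline equivalence
  is bit-exact.
* **Hint MSE** — mean squared error over all elements of the two 32-channel
  hint tensors. The mean convention makes the value resolution-independent
  and puts it at the O(0.1–1) magnitudes reported for hint learning; a
  `sum` switch exists.

## Training

Adam (lr 1e-4), 50 epochs, batch size 5 by default; validation loss each
epoch; reduce-on-plateau scheduler ×0.1 after 5 epochs without improvement.
"No observable change" is operationalized as improvement < 1e-4 absolute
(the protocol names the patience, not the threshold), monitored on the
validation loss by default with a `train` switch. Three regimes:

1. **baseline** — either network on L1L2;
2. **AIL distillation** — student on AIL with frozen-teacher predictions
   computed per batch (exactness preferred over caching at desk scale);
3. **hint learning** — student body on hint MSE against the frozen teacher,
   then the body frozen and the head alone trained with AIL.

λ sweeps default to {10, 50, 100, 200, 400, 800}; a preset adds the 5 and
25 discussed alongside the sweep results. α sweeps default to 0.1–0.8 in
0.1 steps (0.9 can be passed explicitly).

## Metrics

* **NMSE** = ‖x̂−x‖²/‖x‖ — the unsquared denominator is the convention this
  study's evaluation prints, kept as the default, with the standard
  ‖x‖² form as an option. Values are fractions; ×100 renders percent.
* **SSIM** — standard windowed SSIM, C1 = (0.01R)², C2 = (0.03R)², uniform
  7×7 window and unbiased covariances by default (Gaussian window optional),
  data range R = max−min of the truth per pair unless overridden; validated
  against scikit-image to 1e-6. The original evaluation's window/range
  conventions are unstated, hence config-exposed.
* **Cross-profiles** — bilinear interpolation along a segment.

## Representation analysis

Hint tensors are pooled per channel (global average, d = 32; a strided
flatten is available) — the original analysis does not state its pooling,
and global average pooling is deterministic and preserves channel identity.
Models are compared by (a) a joint seeded UMAP embedding
(n_neighbors = 15, min_dist = 0.1) and (b) per-patch Euclidean distances
between matched feature vectors, which is the only pairing that yields the
stated teacher-vs-student comparisons on common inputs. The
hint-vs-plain distance shift (negative = hint-learned student closer to the
teacher) is reported as a soft, logged check: the underlying finding is a
small leftward shift ("minimal hint learning"), so the corresponding test
asserts non-increase with 5% slack rather than a hard margin.

## Problem sizes

Full-scale training (five 1000×1000 frames, 1000 patches of 200×200, 50
epochs) is the protocol's headline configuration and is what the
configuration presets describe. The checked-in analyses, the tests and the
acceptance script run a scaled-down version of the same study — typically
400 patches of 64×64 at 13 emitters/μm² trained for 10–20 epochs (tests use
smaller still) — chosen as the size at which the qualitative orderings
(trained beats untrained; the teacher's reconstruction advantage; hint-loss
descent) are measurable on a single CPU. Absolute metric values at desk
scale are *not* comparable to full-scale results (e.g. full-scale mean test
SSIM ≈ 0.80 teacher / 0.56 student); only orderings and reductions are.

## Known limitations

* The desk-scale teacher is far from convergence at 10–20 epochs; SSIM/NMSE
  orderings between teacher and student can be noisy at the smallest sizes.
* The simulator omits camera electronics and photophysics (above), so λ and
  α defaults tuned here may not transfer to real data unchanged.
* UMAP embeddings are seeded but algorithm-version dependent; distances, not
  coordinates, are the stable quantity.
* The `as_printed` AIL mode gives the teacher term no squared-error
  gradient; distillation pressure in that mode flows only through the L1
  scaling. This mirrors the printed equation and is the documented default,
  not a bug.
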