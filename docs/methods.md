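# Methods

`roarid` identifies individual animals from image renderings of their
calls.  This note documents the models and procedures the package
implements, the choices made where the design was genuinely open, and
what the synthetic-data results do and do not show.

## Pipeline

1. **Audio** — mono PCM WAV, normalised to [-1, 1] at load (integer
   samples are rescaled by the bit-depth maximum; 8-bit data is
   offset-binary decoded).  The reference recording format is
   8-bit/16 kHz single-microphone field audio.
2. **Representations** — each clip becomes one of eight 2-D matrices
   (below), optionally rescaled, then affinely mapped to [0, 255],
   bilinearly resized, and replicated to 3 channels for an image
   backbone.
3. **Classification** — an image backbone with its final layer replaced
   by a freshly initialised n-way softmax head, trained per fold.
4. **Fusion** — softmax score matrices of 2 or 3 members are summed
   elementwise and renormalised (sum rule); all C(m, k) member subsets
   are ranked exhaustively.
5. **Evaluation** — grouped leave-one-out designs and a one-vs-many
   Equal Error Rate protocol.

## Representations

With window w, hop h, FFT length N (defaults 512/256/512, Hamming;
frames are taken without padding or centering, so a clip of n samples
yields `1 + floor((n - w)/h)` columns):

* **Spectrogram** — one-sided power |STFT|².
* **Mel spectrogram** — triangular filterbank (peak 1, filters spaced
  uniformly on m = 2595·log₁₀(1 + f/700)) applied to the power
  spectrogram; 32 bands by default over [0, f_s/2].
* **LM / L2M / L3M** — the iterated-log chain
  LM = 100·log₁₀(S),
  L2M = 100·log₁₀(LM − min(LM)),
  L3M = 100·log₁₀(L2M − min(L2M)),
  where S is the Mel spectrogram.  Subtracting the global minimum
  ("minref") shifts values to start at 0, which makes L2M/L3M invariant
  to any global additive offset of their input — but it also puts the
  minimum exactly at 0, where log₁₀ diverges.  Every log argument is
  therefore floored at `log_floor` (default 1e-16, the same constant
  the dB scaling uses), so the chain's minimum is exactly
  100·log₁₀(log_floor) and all images are finite by construction.
* **MFCC** — per frame, |F⁻¹(log(mel(|F(x)|²) + floor))|², truncated to
  the first 13 coefficients.  This is the inverse-DFT reading of the
  cepstrum (natural log, inverse Fourier transform), not the DCT-II
  convention of most toolboxes; the two differ numerically, and the
  inverse-transform form is what this pipeline defines and tests.
* **Stockwell** — the input is decimated by 10 (zero-phase order-8
  Butterworth at 0.8x the new Nyquist, then subsampling — the transform
  is quadratic in signal length, so decimation keeps it tractable),
  then the fast frequency-domain S-transform is evaluated: for voice
  n, the inverse DFT over m of X[m+n]·exp(−2π²m²/n²) with m the signed
  frequency index.  The image is the one-sided magnitude with the
  zero-frequency voice dropped.  Tests verify equality (to 1e-6
  relative) with the O(N³) time-domain definition using periodised
  Gaussian windows of width N/n.
* **Embedding** — consecutive non-overlapping windows are mapped to
  128-vectors and stacked as columns.  The embedder is a plug-in
  contract (`window_samples` + `embed()`); the packaged `StubEmbedder`
  is a fixed seeded random projection of the window's mean log-Mel
  spectrum — deterministic and dependency-free, standing in for a
  pretrained audio-embedding network in tests and offline runs.

**Scaling modes** (composable post-transforms): `min_max` maps
[min, max] affinely onto [0, 255]; `db` is 10·log₁₀(x + 1e-16);
`box_n` maps onto [0, C] (C = 1000 reproduces the [0–1000] Mel
normalisation).  A constant matrix cannot be min-max scaled (division
by zero); it maps to all-zeros with a logged warning rather than
aborting batch extraction, and `to_network_image` maps a constant
image to mid-gray 127.5.

## Synthetic roars

The field dataset the pipeline was designed around (164 full-throated
roars from 5 male lions, recorded by animal-borne loggers over 4–10
days per animal, arriving in bouts of 1–3) is private, so the package
ships a generator that emulates its statistical structure:

* **Voice model** — additive harmonic synthesis: ≥ 10 harmonics of a
  time-varying F0 (rise to a peak multiplier, power-law fall), −6
  dB/octave rolloff, shaped by 2–3 Gaussian formant resonances
  (σ = 90 Hz) plus an attack/decay envelope, slow jitter, and white
  noise at a configurable SNR.  The simplest source–filter model that
  gives individuals controllable low-frequency signatures.
* **Identity** — each individual's F0 is drawn from its own slice of
  [150, 250] Hz and its formant centers are drawn independently; a
  nearest-centroid check in the test suite confirms the voices are
  separable in principle (≥ 90 % LOOCV on mean log-spectra at ≥ 20 dB
  SNR) — without that, downstream recovery results would be vacuous.
* **Grouping** — the "paper-shaped" preset draws 5 individuals x 4
  day-groups x 4 bouts/day with bout sizes uniform on {1, 2, 3}
  (≈ 160 samples); roars in one bout share a ±2 % F0 offset, giving
  the intra-bout correlation that grouped cross-validation exists to
  control.
* All generation is a pure function of its seed.

**What this does not emulate:** acoustic propagation, wind/rain and
anthropogenic noise, overlapping roars, moan and grunt phases,
microphone response, or realistic per-individual sample imbalance.
Passing recovery tests on this data shows the pipeline is correct and
that it can exploit stable spectral signatures; it does not predict
field accuracy.

## Classifier

The built-in backbone `tiny-scratch` is two fixed random convolutional
blocks (8 5x5 and 16 3x3 filters, ReLU, 2x2 max pooling, seeded) whose
features feed a trainable softmax head (minibatch SGD, momentum 0.9,
learning rate 0.05, 30 epochs, batch 16, L2 1e-4, per-feature
standardisation).  Fixed random convolutional features with a trained
linear head is a standard small-data construction and keeps the
package runnable offline on one CPU; it also makes head replacement
exact — backbone weights are never touched by training, which tests
assert bit-for-bit.  Named pretrained backbones (`alexnet-class`,
`vgg16-class`, `resnet50-class`) are plug-ins resolved through a torch
runtime and raise an explicit, resolvable error when that runtime is
absent.  Built-ins therefore train `head_only`; `all_layers` is the
plug-ins' affair and is rejected for built-ins rather than silently
reinterpreted.

Per fold the head is re-initialised from scratch with a seed derived
deterministically from the master seed and fold index (CRC-32 hash),
so nothing leaks between folds and a run is reproducible from one
integer.

## Evaluation designs

* **Day LOOCV** — one fold per (individual, day) group.  A "day" is a
  per-individual recording day, not a calendar date shared across
  animals: each animal's logger ran on its own window, and only this
  reading yields 20 groups for 5 animals over 4 day-groups each.
* **Bout LOOCV** — one fold per bout (test size 1–3).
* **Naive per-sample LOOCV** — provided only to demonstrate leakage:
  with intra-bout correlation, training on a held-out roar's
  bout-mates inflates accuracy, which the suite asserts
  (naive ≥ day-grouped accuracy).
* **One-vs-many EER** — a target individual's roars are class 1, all
  others class 2.  One fold per base-scheme group: the held-out group
  supplies the test sample for its own binary class, the other class's
  sample rotates round-robin over that class's groups, and that
  sample's entire group is excluded from training so no group ever
  spans train and test (the base design's group-integrity invariant).
  Genuine/impostor posteriors are pooled across folds per target, one
  EER computed per target, and the mean over targets reported.
  Fold-averaged EER per target is the plausible alternative; pooling
  was chosen because per-fold score pairs are far too small (one of
  each) to define a per-fold rate.
* **EER** — FAR(t) = fraction of impostor scores ≥ t, FRR(t) =
  fraction of genuine scores < t; thresholds sweep midpoints of
  adjacent distinct scores plus sentinels; if no threshold gives exact
  equality the crossing is linearly interpolated between the
  bracketing thresholds.  Accuracy ties break toward the lowest class
  index — any fixed rule works, but it must be deterministic.
* Degenerate folds (a class absent from training) raise a named error
  in day/bout schemes; in the EER schemes sparse folds are expected by
  design and are skipped with a log entry.

Ensemble search reports rankings on whatever scores it is given;
because selecting the best ensemble on the same data it is scored on
is optimistic, the search accepts any split of stored score matrices,
so a caller can rank on one scheme (e.g. Day) and re-score the chosen
ensemble on another (e.g. Bout) — the two-dataset hygiene the
evaluation module's design encourages.

## Problem sizes

The shipped tests and the acceptance script run the study-shaped
preset at 0.5 s clip duration (structure unchanged: 5 classes, 20 day
groups, 80 bouts, ≈ 160 samples), chosen so a full run of every check
completes in CPU minutes.  Transform-oracle checks use signals of
length ≤ 256 where O(N²)/O(N³) direct evaluations are exact and fast.

## Known limitations

* The high-SNR synthetic voices are easy by field standards;
  recovery accuracies near 100 % are a correctness check, not a
  performance claim.
* The MFCC convention is the inverse-DFT form described above; do not
  compare coefficients numerically against DCT-based toolboxes.
* `decimate` requires the sample rate to be divisible by the factor.
* No data augmentation, denoising, or open-set identification beyond
  the one-vs-many protocol.
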