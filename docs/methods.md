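# Methods

This note documents the modelling choices, default parameters, synthetic
data design, and the problem sizes used by the test suite and the
acceptance script, together with what those runs do and do not demonstrate.

## Preprocessing

A trial consists of a pre-stimulus **baseline** segment and a stimulus
segment with a 1–9 rating per emotion dimension.  Baseline removal cuts the
baseline into non-overlapping windows of the analysis window length, takes
the per-channel elementwise mean as a template, and subtracts it from every
stimulus window (a trailing partial window receives the leading part of the
template, so length is preserved).  Segmentation discards the trailing
remainder.  For variable-length recordings the centred span is kept, with
the extra sample of an odd trim taken from the head.  Ratings binarise at
the conventional threshold: rating > 5 → high, 5 itself → low.

Defaults by profile: 128 Hz / 2-s windows with a 3-s baseline (DEAP-like),
256 Hz / 0.5-s windows on the middle 30 s (MAHNOB-like).  These shapes give
1,200 windows per subject (26,400 over 22 subjects) and 30,000 windows over
25 subjects respectively — the counts the acceptance script recomputes.
Artifact rejection (EOG/ICA) is out of scope.

## 3D feature construction

Band decomposition uses an order-4 Butterworth filter applied
forward-backward (`sosfiltfilt`), so band signals stay time-aligned; band
edges are θ 4–7, α 8–13, β 14–30, γ 31–50 Hz.  Differential entropy uses
the Gaussian closed form ½ ln(2πeσ²) in **nats**, with σ² the unbiased
sample variance of the band-limited sub-slice and a variance floor of
1e-12 so constant slices stay finite.  Each window is split into T equal
sub-slices (T = 4 for 2-s windows, so each DE value summarises 0.5 s);
values are scattered onto a 9×9 grid via the packaged 32-channel 10–20
montage (JSON, editable); unoccupied cells are exactly zero.  The grid
coordinates follow the usual sparse topographic convention for 32-channel
caps; any injective montage can be substituted.

## Networks and initialisation

The networks are implemented on a small tape-based reverse-mode autodiff
engine over numpy (`eegemotion.nn`); every primitive's gradient is checked
against central finite differences in the test suite.  There is no GPU
path; this bounds the practical problem sizes (below).

* **EEG CNN**: four same-padded stride-1 convs (5×5→64, 4×4→128, 3×3→256,
  1×1→128, ReLU), one 2×2/stride-2 max pool (prose wins over the printed
  "Conv" label for this operator), flatten (4·4·128 = 2048) and a linear
  layer to 512.
* **LSTM**: two stacked layers, hidden 128, with peephole terms kept as
  full matrices because the printed gate equations include cell-state
  weights in all three gates.  Forget-gate bias starts at 1; input maps use
  Glorot-uniform, recurrent maps orthogonal initialisation, all seeded.
* **Band attention**: global average pool per band → 1-D conv (no bias) of
  kernel k = nearest-odd(log₂B/γ + b/γ) with γ=2, b=1 (k = 1 for B = 4;
  ties round down, minimum 1) → sigmoid.  With a scalar kernel the gate's
  initial sign decides whether high-energy bands are amplified or
  suppressed; the weight is initialised with positive magnitude so the gate
  opens toward high-energy bands, breaking that symmetry deterministically.
  Gates are computed per time slice with shared parameters.
* **Self-attention**: additive form S_t = W_t·relu(W₁h_t + W₂d_t + b₁) + b₂
  with a bias-free linear alignment d_t = W_d h_t of the same dimension;
  N_t = S_tᵀh_t, P = softmax(N), A_t = P_t h_t.  The classifier sums A over
  time and applies a linear + softmax head.
* **Student features V_s** are the LSTM hidden-state sequence H (T×128),
  *upstream* of the attention weighting.  Tapping downstream (A) makes the
  L1 pull fight the attention probabilities — teacher rows are
  homoscedastic across time while A_t scales with P_t — which measurably
  destabilised distilled runs; H also matches the dimension the loss pairs
  with the teacher.
* **Visual branch**: per-frame CNN (3×3 convs to 32 and 64 channels, 2×2
  max pools, linear 9216→512 — internals are not fixed by the printed
  architecture beyond layer counts and the 512 width); a 1×1 entry conv
  maps 512→128 so that the two temporal-conv modules can share *all*
  parameters (a 512-in module cannot share weights with a 128-in one);
  each module is conv k3/d1 + two convs k3/d2 (ReLU, per-channel batch
  normalisation, dropout 0.5 after each) with a 1×1-conv residual; same
  padding (non-causal — clips are processed offline) preserves T; receptive
  field 11 steps per module.  A k2/stride-1 same-padded average pool
  follows, then a per-step linear to 2 classes; training penalises every
  step against the clip label.

## Losses and training

L1 feature loss: w\*·(1/TF)·Σ|U − V| — the absolute value is implied by the
loss's name.  Multi-task objective: ρ·CE + (1−ρ)·L1 with ρ = 0.8;
probabilities are clamped at 1e-12 inside the log.  With ρ = 1 (or no
teacher) the teacher term is never built, so a distilled call degenerates
bit-identically to a plain cross-entropy run under the same seed.
Optimiser: Adam (the source architecture names only learning rates; Adam is
the field default), seeded minibatch shuffling.  The visual trainer keeps
the best-validation-accuracy parameters seen across epochs and reloads them
at the end.  Grid search for w\* scores candidates on a held-out
*validation* split (never the test data) and breaks ties toward the smaller
w.  Cross-validation is per-subject stratified 10-fold repeated 5 times,
aggregated as mean ± std over subject means, positive class = high; the
classifier is injectable because 50 full network fits per subject are not
practical on one CPU at full width.

## Synthetic data

Each channel is a sum of four sinusoidal oscillators — one per band, with
seeded random frequency inside the band and random phase — plus 1/f^α pink
noise (α = 1, noise std 0.3, oscillator amplitude 1).  The class signal
multiplies the informative band's oscillator power by `effect_size` on the
informative channels only, so an independent Welch estimate recovers the
injected ratio (measured 2.97 for effect 3).  The baseline segment uses the
same background process without the class effect.  Ratings are integers
1–4 / 6–9 consistent with the class (never 5); classes are balanced within
subject to ±1.  With `intensity_coupling` on, the class-1 boost scales with
the rating's distance from threshold (rating 6 → ¼ of the effect, 9 → full),
emulating graded emotional arousal; off by default so `effect_size` is the
exact class-wise power ratio.

Visual teachers come as (a) T×F feature sequences with class-conditional
means ±snr·noise_std/2 along a fixed random direction and Gaussian noise of
scale `noise_std` — optionally graded by per-trial signed intensity — and
(b) 48×48×3 frame clips of a drifting Gaussian blob whose drift speed
depends on the class (1 vs 6 px/frame), the minimal dynamic a temporal
network can learn motion from.  None of this emulates real facial
appearance, electrode artifacts, inter-subject variability, or non-
stationarity: green tests show the pipeline recovers *known injected*
structure, not that the method attains any particular accuracy on real
recordings.

A note on baseline subtraction in the benches: the synthetic baseline
carries no artifact, and when the baseline spans only one window the
subtracted template is a full-amplitude independent oscillation that leaks
into every stimulus window (measured class-separation drop d′ 3.2 → 0.96).
The training benches therefore run with baseline subtraction off; the
operation itself is verified by oracle unit tests and runs in the pipeline
smoke test.

## Bench problem sizes and findings

All training experiments use a reduced-width network (convs 8/8/16/8,
FC 64, LSTM hidden 32) on 2 subjects × 30 trials × 8-s trials (240 windows,
T = 4); shape-contract tests use the full printed widths.  Two training
protocols are used deliberately:

* **Stable protocol** (lr 1e-3, 25 epochs, batch 32) for the band-recovery
  and attention-ablation experiments, where optimisation noise is a
  confound — at a higher rate one data draw produced a seed-dependent
  training collapse of the full model.
* **Short protocol** (lr 3e-3, 12 epochs) for the distillation study.

Findings the tests assert: the trained mean γ attention weight is the
maximum band in ≥4/5 seeds when only γ carries class signal; the full model
is ≥ the attention-free variant as 5-seed means; and under the short
protocol with a graded low-noise teacher (snr 6, noise scale 0.02 — the
magnitude of the student's own hidden states) the distilled model is ≥ the
ρ=1 baseline on an independently generated evaluation set.  Honest
characterisation of the last point: the measured distillation gain at this
scale is small (0–4 pp across data seeds), depends on the optimisation
regime, and vanishes (to ~0, occasionally slightly negative) under fully
converged training — consistent with the L1 anchor acting as an auxiliary
regulariser rather than a source of new information.

## Known limitations

* CPU-only numpy training: full-width training at realistic dataset sizes
  is out of reach; reported experiments are reduced-scale analogues.
* The EDF reader loads a recording as a single trial with a fixed
  pre-stimulus span; event-based trial extraction is not implemented.
* Montage coordinates are a convention, not calibrated positions;
  alternative layouts load from JSON.
* The synthetic generator's oscillator model makes band power the only
  class cue; real EEG carries cross-frequency and spatial-pattern cues the
  benches do not probe.
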