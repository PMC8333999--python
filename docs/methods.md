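# Methods

## Problem

In a two-speaker "cocktail party" listening task, a listener's EEG tracks
the slow amplitude envelope of the attended speech stream more strongly
than that of the ignored stream.  Auditory attention decoding (AAD) turns
this into a classifier: given a short decision window of EEG and the two
clean speech signals, decide which speaker was attended.  This package
implements a cross-modal attention decoder for that problem, together with
the full signal chain around it and a forward-model simulator that makes
every stage testable without external recordings.

## Pipeline

1. **EEG preprocessing** (per trial): zero-phase IIR notch cascade at the
   mains frequency and its harmonics (default 50/100/150 Hz, Q = 30); an
   optional pluggable eye-artifact hook (identity by default); re-reference
   to the mean of the two mastoid electrodes (resolved by a configurable
   alias list, since montage naming varies); zero-phase windowed-sinc FIR
   bandpass 2-32 Hz (Hamming, 513 taps at 512 Hz, taps scaled
   proportionally at other rates so the transition width in Hz is fixed);
   polyphase downsampling to 70 Hz; per-channel standardization to zero
   mean, unit variance.  Standardization is last, so the chain is invariant
   to positive rescaling of the raw input.  Normalization statistics are
   always per trial - nothing is estimated across trials, which removes one
   avenue of train/test leakage.

2. **Speech envelope** (per stream, per trial): ERB-spaced gammatone
   filterbank (default 28 bands, 150-4000 Hz; the upper edge is clamped
   just below Nyquist at low audio rates so 8 kHz simulations share the
   48 kHz code path); Hilbert-magnitude subband envelopes with power-law
   compression, exponent 0.6 (approximating cochlear compression); unit-
   weight summation to a broadband envelope; the same 2-32 Hz FIR design
   as the EEG; downsampling to 70 Hz; finally the two streams of a trial
   are equalized to the same RMS so stimulus level carries no label
   information.  Band count and Hilbert demodulation are conventional
   choices for this chain; both are configurable.

3. **CSP spatial enhancement**: per-class covariances are averages of
   trace-normalized per-trial covariances G G^T / tr(G G^T) (trace
   normalization removes trial-length and amplitude effects).  The
   composite C = C_A + C_B = Z psi Z^T is whitened with
   P = psi^(-1/2) Z^T; the whitened class covariance is diagonalized,
   C'_A = U lambda_A U^T, and the projection is W = U^T P with rows sorted
   by descending lambda_A.  Under this construction lambda_A + lambda_B = I
   holds identically, and W solves the generalized eigenproblem
   C_A w = lambda (C_A + C_B) w - both are verified against an independent
   `scipy.linalg.eigh(Ca, Ca+Cb)` oracle in the tests.  Note the -1/2
   exponent: whitening requires P C P^T = I, and the eigenvalue-sum
   identity only holds under it.  Directions with numerically zero
   composite variance are truncated before whitening (mastoid
   re-referencing introduces one exact linear dependence, so a 16-channel
   montage yields 15 spatial filters); scalar shrinkage toward the identity
   handles merely ill-conditioned (cond > 1e10) covariances.  All filters
   are retained by default - the downstream network consumes the fully
   rotated signal; top-k pair selection is available.  CSP is fitted on
   training trials only; the fitted object records the trial ids it saw and
   an audit re-hashes that membership.

4. **Cross-modal attention network**: the CSP-enhanced EEG window [M x T]
   and the two envelopes [T] are linearly projected to a shared width
   d_model (a kernel-length-1 convolution; longer odd kernels supported)
   and given sinusoidal positional encoding (on by default - dot-product
   attention is otherwise order-agnostic).  Four cross-modal transformers
   run in parallel, one per modality pairing: E->A and E->B (EEG source,
   audio query) and A->E / B->E (audio source, EEG query).  Each of the
   N = 5 layers computes

       O_bar[i] = CM(LN(O[i-1]), LN(O_src[0])) + LN(O[i-1])
       O[i]     = FF(LN(O_bar[i])) + LN(O_bar[i])

   where CM is single-head scaled dot-product attention
   softmax(Q K^T / sqrt(d_k)) V with queries from the evolving stream and
   keys/values from the static source stream, and FF is a two-layer
   position-wise feed-forward block (ReLU between, hidden width
   4 x d_model).  Per-time-step cosine similarity between the final E->A
   and A->E outputs (and likewise for B) yields two length-T similarity
   sequences; their concatenation feeds a fully connected head
   (2T -> T with ReLU -> 2 sigmoid units).  The decision is the argmax of
   the two outputs (exact ties break toward speaker A, with a warning); a
   training-free `similarity_argmax` mode compares mean similarities
   instead.  Stream parameters are independent by default; a weight-sharing
   flag ties the two E->audio and the two audio->E transformers and the
   envelope input projections, which enforces symmetric treatment of the
   two speakers (swapping the envelopes provably mirrors the similarity
   sequences) and roughly halves the parameter count.

5. **Training protocol**: trials are split 80/10/10 into
   train/validation/test *before* windowing, so no 50 %-overlap window
   straddles partitions.  Decision windows of 1, 2 or 5 s (default 2 s,
   T = 140 samples at 70 Hz) with 50 % overlap.  Weighted binary
   cross-entropy on the sigmoid outputs (per-sample weights default to
   inverse label frequency of the training windows), Adam
   (beta1 = 0.9, beta2 = 0.999), default learning rate 1e-4, batch 32,
   200 epochs; parameters of the best-validation-accuracy epoch are kept.
   Repeated runs differ only in initialization seed and are reported as
   mean +- SD.  Everything is reproducible bit-for-bit from the seed.

## Implementation of the network

The network and its training loop run on a small reverse-mode automatic
differentiation engine over numpy arrays (`cmaad.autodiff`), written for
this package and checked against central finite differences in the test
suite.  The attention sublayer (two layer norms, the Q/K/V projections,
softmax attention, residual) and the feed-forward sublayer are each fused
into single tape nodes with hand-derived backward passes, and the T x T
attention matrix is recomputed during the backward pass rather than stored
(the working set stays cache-sized; this is the main performance lever).
The engine computes in float32 by default; tests that finite-difference
gradients switch it to float64.  Dropout (rate 0.1, disabled in
evaluation) is applied to the attention *output* and inside the
feed-forward block rather than to the T x T attention map itself - the
regularization role is equivalent and it avoids the dominant memory
traffic of masking the map.

## Synthetic data: what it emulates and what it does not

Each trial follows the linear forward-model assumption that motivates
envelope-based AAD: a biphasic temporal response function (Gaussian bumps,
+100 ms / -200 ms, 25 ms width, 0-400 ms support, unit peak) is convolved
with the attended stream's 2-8 Hz amplitude modulator and projected onto a
fixed per-subject spatial pattern with gain 1.0; the unattended stream is
encoded the same way through a second pattern with gain 0.3; spatially
mixed 1/f (pink) noise is added at a configurable SNR (default 0 dB,
signal = both stimulus-driven components together).  Audio streams are
noise carriers amplitude-modulated by the same modulators, so the envelope
chain genuinely has to demodulate them.  Mastoid channels carry noise but
no stimulus response.  Desk-scale defaults (16 channels, 8 kHz audio) keep
the generator fast; the acquisition-scale path (64 channels, 48 kHz) is
the same code.

Setting the two gains equal *and* sharing one spatial pattern produces the
undecodable control: the EEG is then byte-identical whichever speaker is
labelled attended, so any decoder must sit at chance - this is the
package's negative control.

The simulator deliberately omits: real speech (no phonemes, no speaker
identity), nonlinear or attention-state-dependent cortical dynamics,
eye/muscle artifacts, electrode drift, and room acoustics (condition tags
are labels only).  Passing tests on this data therefore demonstrate that
the pipeline recovers a linear TRF-encoded attention signal at realistic
SNR - not that it reaches any particular accuracy on recorded EEG.

## Study-shape defaults and the scaled-down evaluation

The simulator's default shape mirrors a single-subject listening
experiment: 60 trials of 50 s, 64-channel-class acquisition at 512 Hz,
yielding 3,500 samples per trial at 70 Hz, 49 two-second windows per trial
at 50 % overlap, and a 48/6/6 trial split.  The end-to-end evaluation that
the tests and the acceptance script run uses a smaller instance of the
same conditions - 1 subject, 40 trials of 20 s, 16 channels,
attended/unattended gain ratio 3.3 (1.0 vs 0.3), 0 dB SNR, 2-s windows,
d_model = 16, 40 epochs at learning rate 1e-3 (the shorter schedule is
paired with a proportionally larger step than the full-scale default),
with tied stream parameters (the weight-sharing flag: at ~600 training
windows the independent-stream model overfits, while the speaker-
symmetric tied variant halves the parameter count and generalizes), one
trial-level partition, and the mean over 3 runs differing only in
initialization - the same repeated-runs protocol used for full-scale
reporting.  A window-level linear benchmark
(best-lag correlation between CSP-projected EEG and each envelope)
separates these conditions perfectly, so the dataset leaves the network
ample headroom.  The undecodable control is trained for 10 epochs: a
control with provably no class information does not need the full
schedule to demonstrate chance-level performance, and the shorter run
keeps the whole evaluation within a desk-scale compute envelope.  One
statistical caveat: decision windows overlap and share source trials, so
test accuracy is quantized at the trial level (four test trials at this
scale) and a window-count binomial band around 0.5 understates its true
spread; the decisive evidence that the control is undecodable is the
construction itself (the EEG is byte-identical under either label), with
the accuracy check as a secondary smoke test.

## Attention-map export

For visualization, the final-layer attention maps of the E->A and E->B
streams are aggregated into per-EEG-time-step panels: mean attention
received across query positions, optionally (and by default) weighted by
the norm of the value vector at each source step.  The raw column means of
a row-stochastic map sum to one by construction, so unweighted panels of
the two streams always share the same mean and cannot show which speaker
dominates; the value-weighted aggregate instead measures how much EEG
content each stream pulls through its attention.  Panels are
max-normalized to [0, 1] for display; raw aggregates are exported
alongside, losslessly.

An honest caveat established by this package's own experiments: on the
synthetic data, trained models do *not* express the attended/unattended
distinction as aggregate attention mass.  With weight-shared streams the
two panels come from the same function and every aggregate tried (value-
weighted mass, row maxima, row entropy, map dispersion, lag-diagonal band
mass, at every layer) sits at chance between the attended and unattended
stream; with independent streams apparent dominance is a constant
per-stream offset (a confound), not attention tracking.  The class signal
travels through the per-time-step cosine-similarity path, which separates
attended from unattended windows essentially perfectly but with a sign
that the head is free to learn either way.  The expectation that the
attended panel looks uniformly "brighter" is therefore not a property the
acceptance-style behavioral test can currently confirm; the export exists
for inspection, and the panels faithfully show what the model computes.

## Numerical choices and edge cases

* Resampling is polyphase with the exact rational rate ratio; output
  length is round(n * fs_out / fs_in), trimmed or edge-padded when the
  polyphase length differs.
* Zero-phase FIR filtering is centred convolution with a symmetric odd-
  length kernel; trials shorter than the kernel are rejected, not padded.
* A constant EEG channel raises a degenerate-input error naming the
  channel; a zero-energy envelope raises before RMS equalization.
* Cosine similarity guards zero-norm feature vectors with an epsilon
  (1e-12), yielding similarity ~0 for degenerate time steps.
* Softmax subtracts the row maximum; the loss is computed on logits with
  the log1p(exp(-|z|)) form.
* Exact decision ties (probability ~0 in float) break toward speaker A
  with a logged warning.
* BDF export quantizes to the 24-bit range spanning the signal's absolute
  maximum; trials are zero-padded to whole one-second records.

## Known limitations

* Single-head attention only in the fused fast path's tested regime;
  d_v != d_model falls back to a composed (slower) path with an output
  projection.
* No subject-independent protocol, no online decoding, no source
  separation: two clean speech streams are assumed available.
* The processed-data container stores float64 arrays uncompressed; at
  acquisition scale (60 x 50 s x 64 ch) a dataset is ~100 MB.
* The decoder's accuracy on real EEG is not established by this package's
  tests (see the synthetic-data section above).
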