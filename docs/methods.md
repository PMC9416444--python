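# Methods

`emats` implements a complete, desk-scale articulation-to-speech (ATS)
pipeline with speaker adaptation on both the articulatory input and the
acoustic output, plus a synthetic-corpus generator that plants exactly the
inter-speaker structure the adaptation stages are designed to remove.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not show.

## Pipeline model

An utterance pairs an EMA trajectory (6 sensors — TT, TB, TR, UL, LL, JAW —
× 3 spatial axes, 100 Hz, mm) with mono audio at 22,050 Hz.  The regression
chain per experiment design is:

1. **Procrustes matching** (optional): the pooled (vertical,
   anterior–posterior) point cloud of each sentence is translated so its
   centroid is at the origin and rotated so the lower-lip→upper-lip centroid
   segment points along the vertical axis.  Scaling to unit size is
   implemented but off by default; in shape-analysis practice it removes
   size information that is useful here, and it empirically degrades
   silent-speech normalisation.  Sentence-level matching is
   self-normalising: it needs no cross-speaker pairing, so it applies
   unchanged to unseen test speakers.  Speaker-level matching (one parameter
   set per speaker, estimated from the training sentences) is available.
2. **Features**: 80-band log-mel spectrograms (FFT 1024, hop 256, Hann
   window, Slaney-style area-normalised filterbank over 0–8000 Hz, natural
   log floored at 1e-5).  MFCCs are the orthonormal DCT-II of each log-mel
   frame with coefficient 0 (overall energy) dropped and coefficients 1–13
   retained, so evaluation is gain-invariant.  Articulatory features are the
   18 position channels linearly interpolated onto the utterance's acoustic
   frame grid and stacked with Δ/ΔΔ (central differences computed after
   interpolation, so derivatives live on the grid the regressor sees) — 54
   channels.  Articulatory features are z-scored with statistics fitted on
   the design's own training frames (std floored at 1e-8); this subsumes the
   translation component of Procrustes matching, fixing the order
   Procrustes → z-score.
3. **Voice conversion** (optional): for each source→target speaker pair, a
   bidirectional LSTM is trained on DTW-aligned parallel sentences (source
   mel warped onto the target's time base by averaging source frames aligned
   to each target frame; Euclidean frame distance, steps {(1,0),(0,1),(1,1)},
   no band constraint).  Converted source acoustics replace the source
   speakers' training *and* validation targets, so the ATS model is fitted
   end-to-end against target-voice acoustics.
4. **ATS regression**: a unidirectional LSTM stack maps the 54-dim input to
   80-dim log-mel frames, frame-synchronously and causally (prefix outputs
   depend only on prefix inputs — the streaming property a real-time silent
   speech interface needs; the VC model, which has no latency constraint, is
   bidirectional and demonstrably non-causal).
5. **Evaluation**: frame-averaged mel-cepstral distortion
   MCD = (1/T) Σ_m (10/ln 10) √(2 Σ_{d=1..13} (C_{m,d} − Ĉ_{m,d})²) dB.
   The frame average makes the value length-independent.  Group differences
   use the exact Mann–Whitney U test (mid-ranks, full enumeration of the
   C(16,8) group assignments at n = 8 per condition; reported U is the larger
   of the two samples' statistics, p the two-tailed extreme count).

### Regressor training protocol

Published topologies: ATS 3 × 256-unit LSTM layers (speaker-dependent
lr 3e-4 / 50 epochs; multi-speaker lr 1e-5 / 30 epochs), VC 3 × 128-unit
BLSTM (lr 5e-5 / 30 epochs); Adam; one whole sentence per batch.  Choices
the published protocol leaves open are pinned here: MSE loss on output
frames, Glorot-style uniform initialisation with forget-gate bias 1,
gradient clipping at global norm 5, per-epoch seeded reshuffling, and model
selection by best validation loss (checkpointed every epoch).  Outputs are
internally z-scored during optimisation (statistics from the training
targets) and un-scaled at prediction; this is an optimisation-scaling device
only and does not change the evaluated quantity.  All randomness flows from
explicit integer seeds (per-model seeds are derived with CRC-based
SeedSequence keys, so runs are reproducible across processes).

### Experiment designs

Seven designs are orchestrated under leave-one-subject-out cross-validation:
SD (target-only training), SI (sources only), SI-P (+Procrustes), SI-VC
(+voice conversion), SI-VC-P (both), SA-P (sources + target, Procrustes),
SA-VC-P (SA-P with converted source acoustics).  Speaker-independent designs
validate on the source speakers' validation sets; SD and SA designs validate
on the target's.  For SI-VC the target's *audio* necessarily enters VC
training (the design is, strictly, not speaker-independent — a caveat the
audit test makes explicit: no target articulatory frame ever enters ATS
training in SI* designs).  One ATS model is trained per target speaker; VC
models are reused across the designs of one target.

## Synthetic corpus generator

The generator emulates a parallel multi-speaker EMA+audio corpus:

* **Canonical trajectories** per prompt: sums of ≤ 8 Hz sinusoids around
  plausible midsagittal rest positions (real EMA is low-pass filtered at
  20 Hz; keeping well under that bound keeps Δ/ΔΔ well-behaved), normalised
  to the canonical Procrustes pose so planted transforms are recovered on
  the generator's own scale.
* **Planted articulatory structure**: each speaker renders prompts through
  the inverse Procrustes transform of a planted rotation/translation
  (defaults ±0.3 rad, ±8 mm — the scale of visible between-speaker pose
  differences in real EMA), optional scale, plus 0.3 mm i.i.d. sensor noise.
* **Deterministic articulation→acoustics map**: each articulatory channel
  excites a Gaussian band profile in mel space; the summed excitation is
  squashed through tanh onto a base level of −6 ± 2.5 nats.  Smooth in time
  and frequency, moderately nonlinear, learnable by a small LSTM in minutes.
* **Planted acoustic coloration**: per-speaker affine per-band transform in
  log-mel space (smooth gain/shift vectors; defaults 0.08 nats shift,
  1 ± 0.02 gain).  Coloration is deliberately second-order relative to the
  phonetic (within-utterance) variation: in this generator articulation
  carries *no* speaker cue after Procrustes matching, so speaker identity is
  unrecoverable from the input and any coloration becomes an irreducible
  error floor for designs trained on unconverted mixed-speaker acoustics.
  Real speech sits in the same regime — speaker-adaptive training can reach
  speaker-dependent performance — and the defaults were chosen to place the
  generator there.
* **Audio**: waveforms are synthesised from the speaker's coloured mel
  matrix by the Griffin–Lim inversion hook (pseudo-inverse filterbank,
  zero-phase initialisation, 32 iterations), so stored audio re-extracts to
  the generating mel within ≈ 0.1–0.3 nats mean absolute error.  The hook is
  a vocoder-free reconstruction device; audio quality is outside the
  evaluation surface (evaluation is cepstral, not perceptual).

What the generator does **not** emulate: phonetic segment structure,
prosody, text/phone alignment, articulatory idiosyncrasy beyond rigid
transforms, non-stationary noise, or sensor dropouts longer than the
5-sample gap-interpolation limit.  Passing synthetic tests therefore shows
that the pipeline removes exactly the planted nuisance structure — not that
it reaches any particular fidelity on real recordings.

## Simulation-study sizes

The desk-scale adaptation study runs 4 speakers × 60 sentences (1–2 s each),
splits of 10 test / 10 validation / 40 training sentences per speaker, VC
development splits of 5/5/rest (the full-scale protocol uses 50/50/rest and
14/14/rest), and reduced regressors (1 layer, 64 units, 10 epochs, lr 2e-3
— the published learning rates are tuned for thousands of sentence-steps
and would barely move a small net in 10 epochs).  Under these conditions
the qualitative ordering reproduces the full-scale findings: SI worst;
Procrustes matching and voice conversion each reduce mean MCD; both
together are best; including target data (SA-P) lands within ~15% of SD,
and SA-VC-P edges out SD.  Exact MCD levels are not comparable to
full-scale values — the synthetic task is easier and the vocoder-free
round-trip adds its own floor (SD ≈ 3.5–5.7 dB across seeds).

## Numerical choices and degenerate inputs

* Rotation convention: positive θ rotates the point cloud clockwise in the
  (vertical, anterior–posterior) plane; (1, 0) ↦ (0, −1) under θ = 90°.
  Estimation and application share the matrix, so the convention is
  internally consistent.
* Coincident lip centroids make the rotation undefined → error.  Scale
  factors are reciprocals of the centred root-sum-of-squares (unit-size
  shapes are fixed points).
* DTW backtracking breaks cost ties toward the diagonal predecessor;
  alignment cost is symmetric because the step set is.
* Mel extraction floors magnitudes at 1e-5 before the log; silence maps to
  the constant floor vector.  Frame count is 1 + ⌊n/256⌋ (centred frames,
  reflect padding); the inversion hook emits (T−1)·256 samples so the
  round-trip preserves T.
* Zero-variance feature dimensions are floored at std 1e-8 with a warning.
* EMA NaN gaps ≤ 5 samples are linearly interpolated at load; longer gaps,
  leading/trailing gaps, or all-NaN channels abort with the utterance named.
* Audio at other rates is resampled polyphase (`scipy.signal.resample_poly`,
  Kaiser-windowed sinc) to 22,050 Hz on ingestion.

## Known limitations

* The neural vocoder used at full scale is out of scope; Griffin–Lim audio
  is intelligible-class at best and is never evaluated.
* Exact Mann–Whitney enumeration is used up to ~500k assignments; larger
  groups fall back to the normal approximation.
* The LSTM kernels are CPU/numba implementations tuned for whole-sentence
  batches at desk scale, not for GPU-scale corpora.
* Speaker-level Procrustes matching and the scale option are implemented
  and tested for contract correctness but not exercised by the simulation
  study (sentence-level, no-scale matching is the reported configuration).
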