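# Methods

`msfusion` implements a multimodal analysis of error-related brain states
recorded with simultaneous EEG and fNIRS during a complex motor task:
EEG microstate segmentation on one side, and reconstruction of cortical
oxyhemoglobin (HbO) from EEG band power on the other. Because raw
recordings of this kind are rarely shareable, the package ships a
ground-truthed synthetic cohort generator, and every stage is validated
by parameter recovery against it.

## The microstate model

The working assumption is that the scalp potential field moves through a
sequence of quasi-stable topographies ("microstates") of roughly
60–120 ms, and that at any instant a single map describes the global
state, with residuals treated as noise. The quantities involved:

- **GFP** (global field power): the spatial standard deviation of the
  scalp map at one sample,
  `GFP(t) = sqrt((1/N) Σ_i (EEG_i(t) − mean_i EEG(t))²)`.
  GFP peaks are high-SNR snapshots of the momentary topography and are
  the samples used for clustering.
- **Modified K-means**: polarity-invariant clustering. A map `s` is
  assigned to the prototype `a_k` maximizing `(a_kᵀ s)²`, and each
  prototype is re-estimated as the dominant eigenvector of its cluster's
  scatter matrix. Polarity invariance matters because the same generator
  configuration produces maps of either sign. Defaults: 100 random
  initializations, 1000 iterations, relative tolerance 1e-6.
  Initialization uses a polarity-invariant k-means++ seeding.
- **GEV** (global explained variance):
  `GEV = Σ_t (Corr(EEG(t), A_{l(t)}) · GFP(t))² / Σ_t GFP(t)²`,
  where `Corr` is the Pearson spatial correlation of average-referenced
  maps. GEV grows monotonically with K.
- **CV criterion**: `CV = σ² ((C−1)/(C−K−1))²` with `σ²` the mean squared
  residual orthogonal to the assigned prototypes and `C` the channel
  count. The modified-K-means convention for `σ²`
  (`σ² = (Σ_s ‖s‖² − (a_{l(s)}ᵀ s)²) / (n (C−1))`) is used; the criterion
  is minimized over K = 2..8.
- **Backfitting**: each epoch sample is labeled with the prototype
  minimizing the polarity-invariant global map dissimilarity
  `GMD = ‖EEG(t)/GFP(t) − A_k/GFP(A_k)‖ / sqrt(C)`; for
  average-referenced maps `GMD² = 2(1 − Corr)` exactly, and assignment by
  maximal `Corr²` is equivalent. Ties break to the lowest state index.
- **Temporal smoothing**: segments shorter than 30 ms (default) are
  dissolved into their neighbours at the split point maximizing summed
  `Corr²`; the segment count strictly decreases, so the procedure
  terminates.
- **Per-state statistics**: occurrence (segments/s), duration (mean
  segment length, ms), coverage (fraction of samples), mean GFP, mean
  |spatial correlation|, per-state GEV, and a first-order transition
  matrix over consecutive distinct segments (zero diagonal, rows
  normalized).

## The fusion model

Neurovascular coupling links EEG band power (1–40 Hz) to HbO through a
hemodynamic response peaking near 6 s, so the coupling lives below
0.1 Hz. The chain:

1. Surface-Laplacian-filtered EEG → per-channel 1–40 Hz band power in
   1-s windows, resampled to the fNIRS rate (5 Hz), then band-limited to
   the neurovascular coupling band (0.01–0.1 Hz). The band-limiting step
   is deliberate: the HbO side of the canonical correlation is already
   confined to that band by preprocessing, and leaving the auxiliary side
   broadband parks most of its variance where no coupling can exist,
   making the 0.99 selection threshold unreachable.
2. Temporal embedding: lagged copies at 0, 0.4, …, 8 s. The 8-s range
   covers the HRF main lobe (peak 6 s); a 3-s range would not, which is
   why the default is longer than the shortest plausible choice.
3. Ridge-regularized CCA between the embedded band power and all
   long-separation HbO channels (`C + reg·mean(diag C)·I`, reg = 1e-4).
   With additive ridge the canonical correlations shrink monotonically to
   zero as reg grows — a testable invariant. Canonical variates with
   correlation > 0.99 (at most 15) become the EEG-derived regressors.
4. GLM per long-separation channel: EEG regressors, all short-separation
   HbO channels (systemic nuisance — scalp physiology common to SS and
   LS), and a Legendre drift basis of order 3. Ordinary least squares;
   the EEG-column part of the fit is the reconstructed neural HbO.

## fNIRS preprocessing

Intensity → optical density (`−log10(I/mean I)`), motion-artifact
detection (amplitude excursions > 0.5 OD in 0.5-s windows, or
first-difference jumps > 50 robust SDs), patching by a Savitzky–Golay
trace (order 3, 10-s window) computed after bridging the flagged spans
(so the artifact cannot leak into its own replacement), zero-phase
band-pass 0.01–0.1 Hz, and the modified Beer–Lambert inversion with unit
partial pathlength (`[HbO;HbR] = E⁻¹ OD / d`, d the source–detector
distance in mm; extinction coefficients at 760/850 nm from the standard
compiled tables). Concentrations are in µM·mm-normalized units; the
simulator applies the same forward model, so the round trip is exact by
construction and verified to r > 0.99.

## EEG preprocessing

Resample to 250 Hz, zero-phase 1 Hz high-pass (4th-order Butterworth,
forward–backward), line noise by sliding-window sinusoid regression
(adapts to amplitude/phase drift without notch ringing). Bad channels:
flat (SD < 1e-8 µV over 5 s) or poorly predicted by the spherical-spline
interpolation from the remaining channels (r < 0.8 in more than half of
5-s windows); more than 5 bad channels flags the subject for exclusion.
Bad channels are replaced by Perrin-style spherical-spline estimates
(order m = 4, regularization 1e-5, Legendre series to degree 60), then
average re-reference, ASR, and average re-reference again.

ASR is the simplified Euclidean form: calibration = quietest 60 s by
windowed RMS; sliding 500-ms windows with 50% overlap; principal
components whose amplitude exceeds 20× the calibration SD along the same
direction are reconstructed from the calibration covariance and windows
are blended with a Hann taper. Two numerical details are load-bearing:
directions with (near-)zero calibration variance — the constant vector
removed by average referencing — carry no artifact evidence and are
exempted, and the calibration covariance and the reconstruction
pseudo-inverse carry a small ridge; without either, the procedure either
"corrects" every window or fails stochastically on partial bursts.

The surface Laplacian shares the spherical-spline basis (output µV/m²,
head radius 0.085 m) and is validated against the analytic eigenvalue
−l(l+1)/r² of spherical harmonics on a dense montage. Microstate
clustering runs on average-referenced (non-Laplacian) data by default;
the Laplacian feeds only the band-power branch. This is configurable.

## The synthetic cohort

The generator produces what the analysis assumes, with known ground
truth:

- **States**: a semi-Markov chain with gamma-distributed durations
  (mean 80 ms, shape 2 — "quasi-stable" at the scale the literature
  describes), a configurable zero-diagonal transition matrix, and
  i.i.d. ±1 polarity per segment.
- **Topographies**: random degree ≤ 3 solid-harmonic fields on the
  10-5 montage, zero-mean, unit-norm, pairwise |corr| < 0.7 by rejection
  sampling. Harmonic fields have the spatial smoothness of
  volume-conducted sources; one prototype set is shared by the whole
  cohort, since microstate maps are population-level objects.
- **EEG**: `polarity · envelope(t) · prototype + noise`, envelope =
  rectified 5–15 Hz noise plus a floor (GFP maxima every few tens of
  ms), scaled to GFP of a few µV. Noise is 1/f in time and split 80/20
  into a spatially smooth component (random harmonic fields — background
  brain activity is volume-conducted too) and channel-independent sensor
  noise. The default SNR of 10 dB was calibrated so that the group-level
  GEV of the recovered six-state model lands near 0.78, the regime
  reported for comparable real-data analyses; it was fixed before the
  acceptance runs and not revisited.
- **fNIRS**: LS HbO = mixing of the HRF-convolved EEG band power
  (double-gamma kernel, peak 6 s, undershoot 16 s) + shared systemic
  physiology (0.1 / 0.25 / 1.0 Hz sinusoids plus low-frequency drift,
  amplitude comparable to the neural signal — superficial physiology
  dominates real scalp hemodynamics) + white noise (SD 0.1 µM); SS
  channels carry only systemic + noise. HbR = −0.3·HbO. The forward
  modified Beer–Lambert model emits two-wavelength intensities.
- **Events and groups**: per trial, task start/stop plus error markers;
  each error transiently boosts the EEG envelope (gamma-shaped, ~2 s),
  with a larger boost in novices (0.8) than experts (0.3) — this is what
  makes the channel-wise group contrast non-trivial. Groups also differ
  in mean duration (70 vs 95 ms) and transition structure (uniform vs
  neighbour-biased).
- **Cohort**: 13 novices + 9 experts by default. Default session length
  is three 90-s trials with 30-s rests — a desk-scale stand-in for the
  10-minute trials of a real session; tests and the acceptance script
  use two 60-s trials. All randomness derives from one master seed;
  reruns are byte-identical (SNIRF written with HDF5 time-tracking off).

What the generator does **not** emulate: eye/muscle artifacts beyond
amplitude bursts, inter-subject topography variability, optode-scalp
coupling drift, wavelength-dependent scattering, or any anatomy. Passing
recovery tests therefore demonstrate the correctness of the algorithms
under the model's own assumptions, not robustness to everything real
recordings contain.

## Validation strategy and known limitations

- Formula-level operations (GFP, GEV, CV, GMD) are tested against
  literal term-by-term transcriptions at 1e-9; clustering against
  exhaustive polarity-invariant assignment search on tiny instances;
  K selection against the known K = 6; the fusion chain against the
  ground-truth neural HbO (r > 0.9 with noiseless coupling, > 0.6 at
  nominal SNR, and strictly better with SS regression than without);
  BH-FDR and the two-way ANOVA against their nominal error rates.
- Duration/transition recovery has two layers. The bookkeeping layer
  (statistics computed from label sequences) recovers the generator's
  parameters to Monte-Carlo accuracy (10% / 0.03). The full noisy chain
  (render EEG → preprocess → backfit → smooth) is biased: backfitting
  misassigns ~18% of samples at the calibrated SNR, and the 30-ms
  smoothing floor censors short genuine segments (gamma(2, mean 80 ms)
  puts ~17% of segments below 30 ms). The two biases partially cancel;
  end-to-end recovery is tested at 20% (duration) and 0.06 (transition
  entries). Real analyses face the same bias and rarely acknowledge it.
- With coverage proportions summing to 1 within each subject, the skill
  main effect of the two-way ANOVA is structurally null; group structure
  expresses itself in the skill-by-state interaction, which the power
  property tests (≥ 80% detection at the generator's default group
  differences).
- The CCA threshold 0.99 interacts with the regularization level: more
  ridge deflates sample canonical correlations below the threshold, less
  ridge admits overfit components. reg = 1e-4 with the 15-regressor cap
  keeps both failure modes away at the session lengths used here; very
  short sessions (under ~2 minutes) leave the CCA badly overdetermined
  and the cap is what keeps the GLM solvable.
- Problem sizes in tests and the acceptance script (two 60-s trials,
  2-subject replicates for model selection, 30–60 K-means restarts) are
  the package's chosen desk scale; results at these sizes are stable
  across seeds, and all sizes are configurable upward.
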