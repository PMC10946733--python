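# Methods

`touchersp` re-implements, as a verifiable pipeline, the analysis chain of an
active-touch EEG experiment: participants stroke one of two textures (rough
hessian, smooth silk) with the right index finger under three estimation
conditions (sensory, hedonic, no estimation) while 128-channel EEG and a
six-axis force/torque plate record at 1000 Hz.  The scientific question the
chain answers is how band-limited cortical power (alpha 8–12 Hz, beta
16–24 Hz) changes during exploration, after movement-onset locking and after
absorbing trial-level variation in touch behaviour.

## Touch kinetics

The plate measures the force **F** = (Fx, Fy, Fz) and torque **M** =
(Mx, My, Mz) the finger applies.  Channels are block-averaged to 20 Hz
(non-overlapping arithmetic means) before any kinetic quantity is formed.
Under static equilibrium the centre of pressure is

    x = (−My − Fx·h) / Fz,    y = (Mx − Fy·h) / Fz,

with `h` the panel thickness (default 3 mm; the convention places the contact
plane at z = −h relative to the sensor reference, and the synthetic generator
uses the exact inverse so the pair is self-consistent).  Friction is the
tangential magnitude √(Fx²+Fy²) in newtons; load is |Fz| expressed in
grams-force (g₀ = 9.80665 m/s²); speed is the first-difference path speed in
mm/s.  Compression gives Fz < 0.

Movement onset is the earliest of the first half-height peaks of the signed
per-axis velocities (prominence 1 trace unit, minimum separation 1 sample —
the permissive peak-finder defaults; a scalar-speed mode exists behind a
flag).  Velocities are stamped with the forward-difference convention (the
difference of samples k, k+1 is attributed to sample k): an onset detector
must never date movement later than the data supports, and with this
convention the detected onset is within ±50 ms of the true onset on ≥95 % of
synthetic trials.  The generator therefore draws *valid* onset latencies in
[0, 340] ms — one detector tolerance below the 400-ms rejection boundary —
so that quantisation cannot turn a valid trial into a rejected one; planted
late-onset violations are drawn in [500, 1500] ms.

Trial rejection: `no_trigger` (missing cue event), `baseline_movement`
(speed > 5 mm/s sustained for ≥ 250 ms, i.e. 5 consecutive 20-Hz samples,
anywhere in the baseline/cue window — the sustained-run requirement keeps
isolated sensor-noise exceedances from rejecting clean trials),
`late_onset` (onset undefined or strictly > 400 ms after the cue), and
`zscore_outlier` (|z| strictly > 2 on median speed, friction or load within
each subject × block × texture group; sample SD, single pass, degenerate
groups pass through).  Median covariates are computed from onset to the end
of the 4-s exploration window.

## EEG processing

Zero-phase 4th-order Butterworth band-pass 1–100 Hz plus 48–52 Hz band-stop
(`sosfiltfilt`; an FIR mode exists — the original filter realisation is
unknown, so the choice is recorded in provenance metadata rather than
presented as "the" original).  Epochs span −5.5…+5 s around (cue +
detected onset); polyphase resampling to 256 Hz; common-average reference;
a peak-to-peak amplitude threshold (default 500 µV) stands in for manual
artifact screening (the synthetic data contain no ocular sources, so this
hook is exercised only by planted spikes).

## Time–frequency analysis

Complex Morlet wavelets (σ_t = n_cycles/(2πf), 5 cycles, unit L2 energy —
the log-ratio makes the ERSP invariant to wavelet normalisation), FFT
convolution with reflective padding; samples within one wavelet half-support
(5 σ_t) of the epoch edges are flagged and may not enter the baseline or
analysis windows — with the −4…−2 s baseline and 0…4 s crop inside a
−5.5…+5 s epoch this holds by construction.  Power is rescaled per
trial/channel/frequency as dB(t) = 10·log₁₀(P(t)/mean_baseline P) (natural-log
and median-baseline modes behind flags), then averaged over the band's
integer bins — dB first, then average; a discriminating test pins this
order — and cropped to 0…4 s.

Arithmetic is float64 by default; the pipeline uses a float32 FFT path
(`tf_precision='single'`), which changes band dB maps by ~1e-5 dB and halves
runtime and memory.

## Scalp-time images and smoothing

Electrodes are flattened by an azimuthal-equidistant projection (2D radius ∝
polar angle from the vertex, azimuth preserved; stereographic behind a flag)
and scaled to land inside the standardised grid: 32 × 32 pixels of
4.25 × 5.38 mm, x ∈ [−68, +68] mm, y from −98 mm posterior (taking the pixel
size as exact puts the anterior edge at +74.16 mm rather than a nominal
+72 mm; the 2-mm discrepancy in the source geometry is resolved in favour of
the stated pixel size).  Channel values are interpolated piecewise-linearly
via Delaunay barycentric weights, precomputed once per montage; pixels
outside the convex hull are masked, never extrapolated.  Smoothing is a
separable Gaussian of 9 × 9 mm × 20 ms FWHM (σ = FWHM/√(8 ln 2)) applied as
mask-weighted (renormalised) convolution, which preserves in-mask constants
exactly and avoids edge attenuation.  Band maps are decimated in time
(default every 4th sample) before stacking; the wavelet bandwidth makes the
maps heavily oversampled at 256 Hz.

## GLM and cluster inference

First level, per subject: single-trial scalp-time images are modelled with
six cell dummies (HH, SH, NH, HS, SS, NS — hedonic/sensory/no-estimation ×
hessian/silk) plus six parametric regressors holding the summation of median
friction (N) and load (g) within the trial's cell, mean-centred over the
whole column (per-cell centring behind a flag; note that only per-cell
centring makes contrast images exactly invariant to a constant shift of the
covariate — under column centring the model span, not the contrast, is
invariant).  The raw N + g summation follows the source convention; a
standardised-sum mode (z-score each behaviour over trials, then sum) is
available and recommended for new analyses.  The trade-off is quantitative
and worth spelling out: under whole-column centring each modulator column
retains its cell-mean component, whose size relative to the within-cell
variation (mean/SD ≈ 5 for the N + g sum at realistic loads) makes the
column nearly collinear with its cell dummy and roughly doubles the
standard error of condition contrasts; standardisation removes the offset
while preserving the per-cell covariate direction, so condition-correlated
touch behaviour is still absorbed.  Only whole-column centring (either
covariate scale) can absorb *between*-cell confounds at all — per-cell
centring spans within-cell variation only — which is why the
confound-recovery verification runs the raw column-centred design and the
detection-power verification runs the standardised one.  A
covariate column with no within-cell variance would be collinear with its
dummy and is dropped.  OLS betas give five contrast images: texture
(±1/3 per cell, so the contrast estimates a mean dB difference), sensory vs
hedonic, hedonic vs none (±1/2), and two interaction pairs (±1/2).

Second level: the texture effect uses a one-sample F-test (F = t², df 1,
n−1); estimation and interaction enter their two contrast images per subject
into a two-column group design with F-contrast [1 0; 0 1] (df 2, N−2,
N = 2n; the unpaired two-column form as described by the source — a paired
variant is a noted alternative).  Voxels above the upper-tail F quantile at
p < .001 form clusters under 18-connectivity (faces + edges; 6 and 26
available); components smaller than 35 voxels are discarded.  No
random-field or permutation correction is applied — the decision rule is
exactly "p < .001 uncorrected + k ≥ 35", and an empirical null
characterisation (below) is part of the test suite.  Cluster peak latency is
reported at the maximal-F voxel (ties: earliest latency, then lowest y, then
lowest x).  Power in each cluster is extracted per subject × condition and
tested post hoc (paired t for texture, one-way repeated-measures ANOVA for
estimation, two-way for the interaction).

## Behavioural statistics

Two-way within-subject ANOVAs from cell means (ratings: texture × block;
touch behaviour: texture × condition), each effect tested against its
interaction with subjects.  Greenhouse–Geisser ε = tr(S)²/(r·tr(S²)) from the
covariance of orthonormal within-subject contrasts, bounded by 1/r and 1 and
equal to 1 exactly for two-level factors; ε is always reported and the
corrected dfs are applied when Mauchly's test rejects at .05 (an
always-correct mode exists).  Effect size is partial η².  Post-hoc paired t
tests are Bonferroni-adjusted (p·m capped at 1).  Behavioural outliers
(|z| > 2 within group, strict) are trimmed in a single pass before ANOVA.
The covariate screen computes Pearson correlations between behaviour pairs
per texture: pairs significant (p < .05) in both textures are combined by
summation; behaviours without a significant texture or estimation effect are
excluded.  On the default synthetic world the plan reproduces the source's:
combine friction + load, exclude speed.

## The synthetic world

The generator is a stated world, not a fixture: its defaults are the
conditions the analysis assumes, and every downstream test measures recovery
of quantities the generator knows exactly.

* **Trial structure** — 4 s baseline, 1 s condition cue, 4 s exploration;
  four blocks with the texture switching at each block's halfway point;
  the full-scale configuration is 60 trials per cell (360 per subject,
  31 subjects); the desk-scale default for continuous verification is
  8 subjects × 12 per cell.
* **Touch** — loads ~N(100, 20) g floored at 40 g (resting finger loads below
  that are unrealistic and would make centre-of-pressure jitter comparable to
  the stillness criterion); friction coefficients 0.55 (hessian) vs 0.35
  (silk); load gains 1.08 (hedonic), 1.04 (sensory), 1.00 (no estimation),
  reproducing the reported hedonic > no-estimation load effect; trajectory
  speed is maximal at onset (a brisk start — what a first-velocity-peak
  detector marks); sensor noise 5 mN on forces, 5 mN × 1 cm on moments.
* **EEG** — pink (1/f) background noise plus 10-Hz and 20-Hz oscillators
  with random phase per channel and trial (10 µV base amplitude); on the
  contralateral (left) sensorimotor channel group the post-onset alpha
  amplitude is scaled by 10^(dB/20) with dB = −3.36 (hessian) or −1.91
  (silk) — the reported cluster-power means — plus a per-subject offset
  (SD 0.3 dB at desk scale) and per-trial jitter (SD 1 dB).  In-band noise
  sits 20 dB below the oscillator so the measured ERSP recovers the injected
  dB within the stated tolerances.  Between-subject ERD spread is not
  characterised by the source; the desk default (0.3 dB) is chosen so the
  8-subject verification world has group-level sensitivity comparable to the
  full-scale study (whose reported spread, 1.64 dB, is the paper-scale
  config's default: t ≈ 4.9 at n = 31 there, a similar standardised effect
  at n = 8 here).
* **What a green test does not establish** — the generator has no ocular,
  muscle or line-noise artifacts, no volume-conducted source mixing (channels
  are independent oscillators), no non-stationary behaviour drift, and its
  onset dynamics are idealised.  Detection of the injected effect therefore
  verifies the pipeline's arithmetic and inference chain, not its robustness
  to real recording pathologies.

## Numerical choices and degenerate inputs

Positions and speeds are NaN where |Fz| < 0.05 N (no contact) rather than an
exception; z-scoring skips groups with < 2 accepted trials or zero SD;
`block_average` truncates a final partial block; rank-deficient first-level
designs raise with the offending columns named; all-NaN (out-of-mask) voxels
never enter cluster formation; the empirical null rate of the cluster rule
(~0.1–0.2 per analysis at desk scale) is asserted to stay below 0.20, and is
reported, because "p < .001 + k ≥ 35" is a heuristic, not an FWE-controlled
procedure.

Reproducibility: every random draw descends from one config seed through
`numpy` `SeedSequence` spawning (per-subject streams), so equal configs give
bit-identical recordings and byte-identical artifact files.

## Known limitations

EDF+ reading is not implemented (EEG I/O uses the TSV fixture format with a
JSON sidecar); ocular/cardiac component removal is replaced by a documented
amplitude threshold; random-field-theory corrected p-values and permutation
cluster inference are out of scope; the second-level two-contrast design is
unpaired; intermediate results are not cached between runs (desk-scale runs
are fast enough that content-hash caching would add state without benefit).
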