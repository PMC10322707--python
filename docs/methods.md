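# Methods

This note documents the models and procedures implemented in `cephalosleep`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Signal conventions

Brightness is in 8-bit camera units; the resting octopus skin pattern is
uniformly white, so both active-sleep (AS) bouts and quiet-sleep (QS)
colour flashes are modelled and detected as brightness *decreases*.
Detectors negate the z-scored signal so darkening events become positive
peaks.  All event times are seconds from trace start; frames are 0-based
and converted with the exact frame rate.  All Butterworth filters are
applied zero-phase (forward–backward), preserving event times at the cost
of squaring the magnitude response; filter orders quote the one-pass
design (three poles unless a two-pole order is specified for a step).

## Behavioural trace model and detectors

The brightness generator (`BehaviorSimConfig`) draws AS bouts as a renewal
process: inter-bout intervals are normal with mean
`base_interval_min + interval_slope_min_per_C * (T − 22 °C)` (defaults
60 min and −5 min/°C) and SD `interval_sd_min` (16.4 min, matching the
reported spread of QS bout durations); bout durations are normal
(75 ± 28 s, truncated at 10 s).  Circadian modulation is an optional
two-level day/night rate multiplier with a 30-min raised-cosine taper,
mirroring the lighting protocol; its default is 1 (off) so that the
generator's realized mean interval equals the configured one.  Flashes are
an inhomogeneous Poisson process within each inter-bout interval whose
rate falls linearly from `flash_rate_start` to `flash_rate_end`
(defaults 1.0 → 0.2 events/min — the study reports only that the rate
decreases; the scale was chosen to be consistent with its total flash
counts).  Flash pulses are raised cosines of duration 7.1 ± 0.3 s; bouts
are plateaus with 5-s cosine edges.  Events are kept disjoint by rejection
and flashes at least 12 s apart.

Event amplitudes are in units of the frame-noise SD.  `flash_depth_z`
defaults to 5: the 0.005–2 Hz detection bandpass leaves a noise floor of
~0.42 noise-SD while the trace's z-scale (inflated by the events
themselves) sits near 0.8–1.0, so the 2-z peak threshold corresponds to
~4 filtered-noise SDs.  A 5-SD flash clears this comfortably
(recall and precision > 0.99 end to end); a 3-SD flash would sit at the
threshold and drown in false alarms.  This regime dependence is inherent
to a fixed z threshold: on a trace with few events the z-scale is not
event-inflated and the same threshold admits noise peaks, which is why
detection precision is only meaningful at realistic event loads.

Flash detection follows the printed recipe exactly (0.005–2 Hz three-pole
Butterworth, negated z-score, peak height 2 z, prominence 0.5 z,
separation 10 s; conflicts resolved by keeping the higher peak).  Flash
duration uses the −500/+1000-frame window (21/42 s at 24 fps), z-scores
it and takes the 2-z crossings flanking the peak; a side without a
crossing clamps to the window edge and flags the result.  Note a
structural property: a 7-s dip occupies ~11% of that window, capping its
windowed z-score at √((1−f)/f) ≈ 2.8, so the 2-z crossing sits at ~70% of
the pulse depth — duration estimates of smooth pulses are therefore
narrower than the full event, and accuracy claims are made on clean
rectangular pulses.  Bout duration z-scores a −10/+100 s window, lowpasses
at 0.1 Hz (two poles) and returns the longest contiguous run below
−0.2 z; bouts longer than ~90 s are truncated by the window, a property
inherited from the fixed window length.  The automatic bout-start
detector (0.05 Hz lowpass, 3-z threshold, 20-s minimum run) is a package
convenience — bout starts were identified manually in the study — and
recovers simulated bout counts within ~4%.

Circadian rates use 2-h histograms, a 0.1-h binned count smoothed with a
Gaussian of SD 40 bins (4 h, reflective edges, mass-conserving), and a
kernel density estimate on 5-min binned times with Silverman's bandwidth
(the estimator is named in the source description; the bandwidth is not,
so the standard rule is used).  The Rayleigh p-value uses the standard
finite-n corrected approximation; Monte-Carlo calibration over 2000
replicates puts the type-I error at 0.045–0.055 for n ∈ {10, 50, 100} and
power ≈ 1 at von-Mises concentration κ = 1 with n = 50.  The
temperature model is OLS with intercept (statsmodels), reporting slope,
R², F versus the constant model and its p from F(1, n−2); acceptance
recovers a −5 min/°C slope at noise calibrated to R² ≈ 0.55 with n = 243.

Breathing metrics smooth with a 10-frame moving average (reflect-padded to
avoid edge artifacts; peaks within two smoothing windows of the ends are
discarded), z-score, detect peaks at prominence 0.05, and interpolate
60/interval to the frame rate; CV is the population SD/mean of the
inter-peak intervals.  Reaction magnitude is the 1-s post-stimulus mean
minus the 1-s pre-stimulus mean of the movement-magnitude trace.

## LFP model and analysis

The LFP generator builds each channel from two unit-variance Gaussian
components scaled per sample by the state's band SDs: a slow component
with a 1/f amplitude spectrum band-limited to 0.1–10 Hz and a fast flat
component at 20–150 Hz (defaults, in µV: QS 30/4, wake 60/25, AS 90/45 —
ordering QS < wake < AS as observed).  The 1/f slow spectrum matters: it
concentrates QS background power below the 4–40 Hz event-detection band,
which is what makes the fixed 2-z peak threshold selective.  A broadband
common-mode artifact (20 µV) is added identically to every channel.
Spindle-like events are Hann-windowed sinusoids at uniform-random
12–18 Hz, 0.3–1.0 s, 300–700 µV ("large, up to ~700 µV"), shared across
the designated spindle channels, with log-normal inter-event intervals
(median 6 s, log-SD 0.8 — the simplest heavy-tailed family; at these
defaults every injected event clears the detection threshold, so the
recovered inter-event distribution reproduces the generator's tail).

Preprocessing resamples to 1 kHz (polyphase), bandpasses 0.1–150 Hz
(three poles, zero-phase) and subtracts the per-sample median of the
out-of-brain channels: any signal common to all channels cancels to
machine precision.  Because the zero-phase three-pole response is the
squared magnitude, in-band gain sags ~6% at 100 Hz and a 200 Hz tone is
attenuated 19.5 dB; tests assert measured gains against the designed
response rather than round numbers.

Band intensity is the mean analytic envelope of the band-filtered
segment, median-filtered over a five-channel sliding window along the
probe (edge channels use shrunken windows) and averaged over segments.
The envelope uses the FFT analytic signal by default: a ~150-tap FIR
Hilbert transformer at 1 kHz (available as `envelope="fir"`) distorts
envelopes below ~10 Hz by 12–30%, which would break the low-band
intensity of slow components; the FFT path is exact for in-band tones
(measured error ~1% at 5 Hz).  Spectrograms are complex-Morlet CWTs
(bandwidth 1.5, centre frequency 1.0; 100 log-spaced frequencies in
1–100 Hz) normalised by their maximum.  Spectra are DPSS multitaper
estimates (NW = 5, nine tapers) on non-overlapping 1-s chunks, averaged;
the one-sided density integrates to the signal variance (Parseval,
verified to 10%).

QS oscillatory events are peaks of the per-segment z-scored 4–40 Hz
signal (height 2 z, prominence 2 z, separation 1 s), detected in up to
1200-s QS chunks preceding each AS bout with wake intervals excised.
z-scoring is per segment (matching chunked loading) and chunk rates are
averaged with equal weight; both choices were open and are config-free.
On channels without events the threshold sits at ~2 noise SDs and
reports a noise-floor peak rate (~0.5 Hz); interpreting rate maps
therefore requires contrast against event-carrying channels, where the
inflated z-scale suppresses the floor entirely (measured false-alarm
rate 0 at default spindle loads).  Region aggregation averages channel
values per atlas region, requires two probes per region, and optionally
splits each region at the (min+max)/2 midpoint of its
anterior–posterior coordinate; which table column is the A–P axis is a
parameter, not hard-coded.

## Pattern-trajectory model and metrics

The pattern generator places a library of `library_size` (80) patterns in
a `latent_rank` (60) dimensional subspace of the 512-dimensional feature
space, embedded by a random orthonormal basis.  Library latent
coordinates are whitened so the subspace is sampled isotropically, making
the latent rank a well-defined recovery target.  Each bout visits a
random subset of patterns in random order — starting and ending at the
designated white resting pattern — with Poisson dwell times (mean 45
frames at 30 fps), short linear transitions, Gaussian smoothing, per-frame
latent jitter (SD 0.1) and a small full-dimensional observation noise.
Animal identity adds a constant latent offset (SD 0.15).  At these
defaults the zero-lag inter-trajectory distance is ~7–8× the
intra-trajectory step distance — the several-fold separation regime
described for recorded bouts, and controllable through `step_sd` — and
the nearest-point distribution overlaps the intra distribution, because
different bouts revisit the same library patterns at different times.

Start alignment standardises the per-trajectory PC1 score to unit SD and
thresholds its absolute first difference at 0.1 (per-trajectory PC1, the
natural reading of a per-clip feature-by-frame matrix; standardisation
makes the 0.1 threshold scale-free).  DTW uses the symmetric step pattern
(diagonal/horizontal/vertical, unit weights) with no band constraint and
is exact against exhaustive path enumeration; the reported ratio divides
the mean path cost by the zero-lag inter distance (the ambiguous
"trajectory distance" divisor; cumulative path length is available as an
option).  Parallel analysis compares sample-correlation eigenvalues
rank-wise to the 95th percentile of column-permuted surrogates (20 by
default; Horn's mean criterion is an option) on up to 10,000 frames
subsampled without replacement with an explicit seed; it recovers the
60-dimensional latent space exactly at generator defaults and reports ≤ 1
on iid noise.  Silhouette uses the standard Euclidean coefficient with
animal labels (scikit-learn), skipping singleton labels; overlapping
animals at default offsets score ~0.01, well inside the "largely
overlapping" regime.  The wake-placement test calls a wake vector within
AS space when its nearest distance to any AS frame is at most the 95th
percentile of pooled intra-trajectory step distances.

The default featurizer is a deterministic Gabor bank (4 frequencies × 8
orientations, response magnitudes mean-pooled over a 4×4 grid → 512
dims) on zero-centred images.  It is a stand-in interface for learned
convolutional features: it separates macroscopic blob layouts from
re-noised copies of the same layout by more than an order of magnitude,
but does not reproduce any particular learned feature space.

## Image alignment and warping

Mantle alignment fits second-moment ellipses to the two masks and maps
centre and major axis by a similarity transform; the 180° major-axis
ambiguity is resolved by an explicit anterior/posterior flag (determined
manually in practice).  Output is cropped to the reference mask's
bounding box, downsampled to 20% (or a given target size), background
painted uniform grey.  The similarity-variant MLS warp (weights
|v−p|^(−2α), α = 2) is computed in closed form as a weighted complex
linear regression per pixel; the similarity variant avoids the shear
artifacts of affine MLS on elongated mantles.  It interpolates control
points exactly (< 1e−13 px), reproduces any global similarity transform
exactly, and warps images by backward mapping with bilinear sampling.
The image-pair generator checks the forward map's Jacobian determinant on
a coarse grid and rejects fold-over.  Threshold matching inverts the
greyscale, binarises (default: Otsu's threshold on the pooled inverted
pixels, clipped to the 180–230 range used for image-specific thresholds)
and scores intersection-over-union; display-only brightening is excluded
from scoring.

## What the generators do not emulate

The brightness generator has stationary Gaussian frame noise and
stereotyped event shapes — no posture changes, lighting drift, partial
occlusion or segmentation failures, so detector performance on real video
will be bounded above by these results.  The LFP generator is Gaussian
within states with instantaneous state switches and contains no spikes,
probe drift, or inter-regional structure beyond the configured band
powers; its spindles are pure windowed sinusoids.  Pattern trajectories
live exactly in a linear latent subspace, whereas learned feature spaces
are only locally linear; the mantle textures are elliptical blobs, not
chromatophore patterns.  Passing tests therefore demonstrate correctness
of the procedures and recoverability of parameters under the stated
statistical structure, not performance on raw recordings.

## Problem sizes

The test suite and acceptance script run the behavioural recovery on
twenty and ten 24-h traces respectively; spindle injection-recovery on
twenty 300-s, 4-channel segments plus one 30-minute 64-channel recording
at 2.5 kHz; trajectory metrics on the full generator defaults
(3 animals × 8 bouts × ~1500 frames × 512 dims) with distance ordering
evaluated on four bouts per seed; silhouette on 3000 subsampled frames;
and image metrics on twenty (tests) or ten (script) 256×256 pairs.  These
sizes were chosen so the full cycle completes in a few minutes on one CPU
while keeping every Monte-Carlo band at least two standard errors wide.
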