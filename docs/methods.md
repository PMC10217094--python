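# Methods

This note documents the models implemented in `thermospec`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Plant masking (NDblue)

The index is implemented exactly as `NDblue = V / (max V − min V)` with
`V = R550 − R450`, *not* the min-shifted form `(V − min V)/(max V − min V)`.
The two differ by a constant offset, so the threshold semantics attach to the
chosen form; the 0.1–0.5 working range for `thr` assumes the un-shifted one.
The 450/550 nm bands are located by nearest wavelength on the cube's header
grid (ties break to the lower channel index).  The max/min of `V` are scene
statistics; by default they are taken over the whole image, with an optional
region argument for per-pot analysis.  A constant-`V` image makes the index
undefined and raises rather than returning zeros.  Masks get no morphological
cleanup: soil admixture is controlled only through `thr`.

## Registration

TIR-to-HSI alignment is a projective homography fitted to user-supplied
control points by the normalised direct linear transform (at least four
non-collinear correspondences).  Warping inverse-maps each target pixel into
the source frame; out-of-frame targets become NaN, the pipeline-wide missing
flag (never a sentinel temperature — every downstream statistic drops NaN
records explicitly and counts them).  Default interpolation is nearest
neighbour, which preserves the sensor's 0.1 °C quantised values; bilinear is
available for display-style smoothing.  Note that a nearest-mode warp
composed with its inverse is the exact identity only for integer
translations; general projective transforms re-round pixel centres, so a few
per cent of cells near cell boundaries may change.

## Correlation spectra

The Pearson coefficient uses population (divide-by-n) moments throughout —
the convention cancels in the ratio, but fixing one makes results bit-stable.
Channels with zero variance under a mask yield NaN (flagged, not zeroed).
Day averaging takes the per-channel mean of |r|, never |mean r|: late-stress
days flip the sign of the correlation (canopy temperature rises while NIR
reflectance falls), and signed averaging would cancel genuine signal.

Extrema of the |r| curve are found after an optional centred moving average
(default window 5, reflect-padded; window 1 disables smoothing).  Comparison
against both neighbours is strict; a plateau strictly above (below) its
flanks reports its lowest channel index; curve endpoints are never reported.
Real correlation curves carry many micro-extrema, so the window is the main
stabiliser of candidate lists and is exposed in the configuration.

Channel subsets for the reduction study are *evaluated, not searched*: they
come from the full range, a contiguous sub-range, the ranked extrema of the
day-averaged |r| curve, explicit lists, or the shipped named presets
(`paper-32`, `paper-8`, `paper-7` — printed channel lists from the published
204-band study, kept as data because they are not derivable from synthetic
scenes).

## Single-channel moment line and truncation

The predictor is `y(x) = Ey + s·(σy/σx)·(x − Ex)` with `s = sign r(x, y)` —
the reduced-major-axis line through the centroid.  The sign factor is a
deliberate choice: the literal unsigned `σy/σx` slope predicts
anti-correlated clouds with the wrong orientation, and several key days are
anti-correlated.  A `signed_slope=False` switch restores the literal form.

Truncation thresholds are *fractions of the one-sided extreme residuals* of
the initial fit: `threshold_up = a · max(positive residuals)`,
`threshold_down = b · |min(negative residuals)|`; a record is kept iff its
residual lies in `[−threshold_down, threshold_up]`.  This makes `a = b = 1` a
guaranteed no-op (the anchor that pins the semantics; an absolute-°C reading
would not guarantee it).  Truncation is single-pass — one refit on the kept
records afterwards for reporting, no iteration to a fixed point.  The day
report evaluates RMSE-in on the kept records and RMSE-out on the removed
records, both with the kept-records refit.

A caveat worth knowing: with these per-side thresholds, "fixed-line RMSE over
kept ≤ full-cloud RMSE" is a theorem-like regularity only for the symmetric
`a = b` variant (the one the study design uses; 10⁴ random-cloud trials show
no violation).  Strongly asymmetric pairs can violate it, because a kept
record on the loose side may have a larger squared residual than removed
records on the tight side.

## SLP regressor

The "single-layer perceptron" is one linear layer with identity activation
over standardised features — the minimal faithful reading; a sigmoid output
rescaled to the training target range exists as an experimentation hook.
Features are the selected channel values plus, optionally, the key-day
ordinal min-max scaled to [0, 1]; per-column mean/std come from the training
rows and are stored with the model.  The loss is the pooled multi-day RMSE
(flat RMSE over all mask pixels of all days — not an unweighted mean of
per-day RMSEs).

Optimisation is gradient descent with early stopping (default max 500
epochs, patience 20, monitoring the validation split — the held-out test
clouds when given, else a seeded 10 % row split; the best-epoch weights are
restored).  The default step size is `"auto"`: the exact line-search length
`g·g / gᵀHg` for the quadratic objective, recomputed each epoch.  This is the
key numerical choice: hyperspectral channels are strongly collinear, so the
Hessian's largest eigenvalue grows roughly with the channel count and any
fixed step that is safe at k = 1 either diverges or crawls at k = 204 (a
fixed stable step leaves the full-spectrum fit ~3× above the least-squares
floor within the epoch budget; the line-search step reaches the floor).  A
numeric learning rate, if given, is applied verbatim, and mini-batch descent
with a seeded shuffle is available.  Training is deterministic given the
seed; a non-finite loss raises a divergence error naming the epoch.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes, not
plant optics:

- **Geometry.** A Gaussian-smoothed random field thresholded at the coverage
  quantile gives blob-shaped plant regions; smoothing the binary layout with
  a configurable boundary width (default 1.5 px) yields a per-pixel mixing
  fraction `mix ∈ [0, 1]`, emulating thermal pixels that straddle leaf and
  soil.
- **Spectra.** `R(c) = mix·plant(c) + (1 − mix)·soil(c) + N(0, 0.005)`.  The
  endmembers are fixed piecewise-linear tables: green peak, red edge and NIR
  plateau for leaf; nearly flat with a mild slope for soil.  Only the 450/550
  contrast (NDblue separability) and the NIR level matter downstream.
- **Temperature.** `T = mix·(T0 + stress) + (1 − mix)·(T0 + soil_offset) +
  N(0, 0.1 °C)`, with `T0 = 20 °C` and soil 3 °C warmer than unstressed
  plants.  The TIR raster is quantised to 0.1 °C (the thermal camera's
  resolution).  The default 7-key-day stress schedule
  (0, 0.05, 0.2, 0.3, 0.6, 1.2, 2.0 °C) emulates a developing drought with
  the early ~0.2 °C warming that defines "early" detection, then a monotone
  rise.
- **Coupling.** The marked channel's reflectance is additionally shifted by
  `(T − T0)/β` with `β = −15 °C` per reflectance unit — negative because
  water-stressed (warmer) tissue reflects *less* in the NIR, so the coupling
  reinforces the mixture gradient rather than cancelling it.  With all noise
  off, the coupled channel is an exact affine image of temperature and its
  correlation with TIR is exactly ±1 by construction.
- **Determinism.** Each scene is fully determined by its seed; a time series
  shares geometry across days and derives per-day noise seeds from the base
  seed, so adding days never perturbs earlier ones.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: radiative-transfer realism (no canopy model), sensor
artefacts beyond quantisation, spatially correlated noise, and — importantly —
the redundancy structure of real spectra.  Because every non-coupled channel
here is an independent-noise copy of the mixing fraction, a full-spectrum
linear model can estimate `mix` almost noiselessly and becomes *stronger*
relative to small channel subsets than on real imagery whenever the
channel-temperature relation varies across days (a day-varying stress
schedule changes the mixture-to-temperature slope).  Channel-subset
equivalence — a reduced set matching the full spectrum within ~1.3× test
RMSE — therefore holds in the stationary regime (e.g. an unstressed control
series, or single-day training), and the tests assert it there; under the
drought schedule the full spectrum retains a genuine edge on synthetic data.

## Pipeline

One YAML configuration drives the sweep over thresholds, (a, b) pairs and
channel sets.  A single run seed fans out to per-stage seeds through a fixed
stage-name hash (CRC32, reduced mod 2³¹), so adding a stage never perturbs
earlier randomness.  Every CSV row carries the configuration hash, seed and
stage; wall-clock timings go to the run log only, keeping reports
byte-identical across reruns of the same (config, seed).  The SLP train/test
split on synthetic scenes is a seeded half/half row split per day cloud
(pot-level splits apply only when real multi-pot imagery is supplied).

## Problem sizes

Default study rasters are 128×128 with K = 204 channels over 7 key days
(about 42 000 mask pixels pooled at thr = 0.3); property tests use 32–64 px
rasters and the full suite runs in well under a minute on one CPU.  These
sizes were chosen so the statistical assertions (correlation argmax, RMSE
recovery within 1.5× the noise floor, mask-area monotonicity) have
comfortable margins while the whole study stays interactive.

## Known limitations

- Control points for registration are user-supplied; there is no automatic
  keypoint matching, lens-distortion model, or sub-pixel boundary unmixing.
- The truncation step is one-shot by design; it is a cloud-cleaning device,
  not a robust-regression estimator.
- Channel subsets are evaluated, not globally optimised; no automated search
  over channel combinations is attempted.
- The SLP is strictly linear in its features; any nonlinearity in the real
  channel-temperature relation is absorbed into the residual.
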