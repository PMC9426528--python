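# Methods

## The generative model

The synthetic movie generator encodes the entrenchment picture of ring
formation in cycling colony biofilms. A colony is a disk whose edge
advances at constant radial speed *v* (px/h) from a fixed center, so a
pixel at distance *r* from the center is born at *t*₀ = *r*/*v*. The
light/dark (and temperature) schedule is piecewise constant; the
condition in force at *t*₀ selects the pixel's saturating amplitude,
which never changes afterwards:

    I(t) = agar_mean + A_label(t0) * (1 − exp(−(t − t0)/tau)) + noise,  t >= t0

with `A_dark > A_light`. Frames are taken every 0.5 h (one image every
30 min) from *t* = 0 up to, but excluding, the experiment end. Noise is
i.i.d. Gaussian per pixel per frame: SD `agar_sd` outside the colony,
`noise_sd` inside. Reduced-TTC signal is encoded as intensity *above*
the agar mean; darkening of raw color images is handled by the channel
transforms (`luminance` for movies, `redness` = R − (G+B)/2 for endpoint
ring images), not by the generator.

### Default parameters and why

| parameter | default | rationale |
| --- | --- | --- |
| `frame_interval_h` | 0.5 h | imaging protocol: one frame every 30 min |
| `radial_speed` | 3 px/h | a ~2.6-mm-radius colony after 6 days imaged at ~10 µm/px; the edge advances 1.5 px per frame, so birth times are resolvable on the frame grid |
| `tau_h` | 5 h | puts the rapid accumulation phase in the first ~10–15 h after a ring forms |
| `amp_light`, `amp_dark` | 50, 100 | dark-born biomass reduces about twice as strongly; mid-range 8-bit-like intensities over a dim background |
| `agar_mean`, `agar_sd` | 20, 1 | dim, slightly noisy background (5% CV) |
| `noise_sd` | 5 | 5% of `amp_dark`, the standard validation noise level |
| `image_size` | 881×881 | final colony (431 px radius) plus ~10 px margin |

The prolonged-cycle scenario (24 h light / 24 h dark over 312 h) is
rendered at 1 px/h — the lower magnification a larger, longer-running
colony would be imaged at — because at 3 px/h its final radius (~930 px)
would need an impractically large frame. Period recovery does not depend
on magnification. One integer seed drives all randomness.

### Standard scenarios

* **standard / combined** — 12 h light (25 °C) / 12 h dark (23 °C),
  144 h; amplitude contrast `A_dark − A_light` = 50.
* **light_only** — same light cycle at constant 25 °C; contrast halved
  (A_dark = 75), reflecting that the temperature swing roughly doubles
  the ring amplitude.
* **short_cycle** — 6 h / 6 h over 144 h. **long_cycle** — 24 h / 24 h
  over 312 h.

## The analysis pipeline

**Background and boundary.** The final frame approximates the colony
footprint: border pixels (guaranteed agar, since the colony must fit in
the frame) give initial background statistics; pixels deviating > 3 SD
from them are marked colony, and the colony mask is dilated adaptively
until the agar SD stops shrinking, which excludes the dim rising ramp at
the colony edge from the background estimate. Agar mean and SD use the
population convention (divide by *n*). Rays from the image border toward
the center (64 angles by default) mark the boundary at the first pixel
whose *absolute* deviation from the agar mean exceeds *k*·SD with
*k* = 3. Whether the original rule was one- or two-sided is not
documented; two-sided is the default and `two_sided=False` is available.

**Threshold and birth times.** The threshold is the median final-frame
intensity of the boundary pixels (median for robustness to single-pixel
noise). A pixel's birth time is the timestamp of the first frame at or
above the threshold — first crossing is final, no hysteresis. Pixels
that never cross carry NaN. Coordinates are 0-based (row, col); the
center is user-supplied or the centroid of the final colony mask.

**Known bias.** Because the threshold sits ≥ 3·`agar_sd` above the
background (plus up to one radial sampling step of the dark edge ramp),
detection lags true birth by `tau·ln(1/(1 − excess/A))` — about 0.3–0.9 h
for light-born pixels at the default scale — plus first-crossing noise
jitter of roughly `tau · noise_sd/A` ≈ 0.5 h at 5% noise. All
within-movie quantities are unaffected (every pixel is late by a similar
amount), but pixels born within that delay before a schedule switch are
assigned to the following interval when labels are recovered from
measured births: pixelwise label recovery on the standard noisy scenario
is ~92% overall (~96% away from interval boundaries) and is limited by
this delay, not by the rhythm statistics. On noise-free movies, measured
births agree with frame-quantized truth within one frame for all pixels
— the frame grid is also where the generator quantizes birth, so that is
the resolution at which birth times are meaningful.

**Ring dynamics.** Cohorts are pixels born within one half-open window
(default: one frame interval; aggregable to schedule intervals). A
cohort trace is the mean working-channel value over the cohort's pixels
at each frame from the window start, re-indexed to time-since-birth.
Rates are centered finite differences after smoothing over 1.5 h (3
frames) with a degree-1 Savitzky–Golay filter — a sliding mean in the
interior whose end fits preserve linear traces exactly. The lagged edge
trace reports, for each distinct birth time, the cohort mean at the
frame nearest birth + 12 h (nearest-frame lookup, no interpolation —
exact and testable at 0.5-h frames); birth times whose readout would
fall beyond the movie are omitted. Kymographs and radial profiles use
nearest-pixel sampling along rays (no subpixel interpolation, keeping
oracle equivalence exact); radial profiles average 1–*n* equally spaced
rays per integer radius.

**Rhythm statistics.** Peaks are local maxima with prominence ≥ 25% of
the series' linearly detrended SD (no rule is documented for the
original trimming; this one is robust at the working noise scale and
configurable). Everything up to and including the first peak and from
the last peak onward is removed; with fewer than two peaks the series
passes through untrimmed with a warning. Detrending is ordinary least
squares on (x, value); amplitude is half the peak-to-trough range of the
residuals. The dominant period is the lag of the first positive
autocorrelation peak exceeding the large-sample white-noise band 2/√N;
series failing that rule report no period. Amplitude groups are compared
with a two-sided unpaired Welch *t*-test (no evidence of equal
variances; may diverge slightly from pooled-variance defaults in other
software). Both time series and radial-distance series can be analyzed;
the axis is whatever `x` is supplied.

## What the synthetic data does and does not emulate

Emulated: constant-speed radial expansion, condition-locked saturating
accumulation, dim noisy background, frame-interval birth quantization,
the direction and rough magnitude of the dark/light and
temperature-contrast effects. Not emulated: photobleaching or
illumination drift, colony translation/registration error, non-circular
colonies, nutrient depletion, 3-D structure, and the late-light-interval
"rebound" of reduction activity (a candidate kinetics extension, left
out of v1). Passing tests therefore validate the pipeline's correctness
and its recovery of entrenchment-model signals, not robustness to every
artifact of real microscopy.

## Numerical choices and degenerate inputs

* Half-open conventions everywhere: schedule intervals, cohort windows;
  a birth exactly on a boundary belongs to the later interval.
* Sentinel for "never crossed": NaN (empty field in CSV).
* Zero agar SD (noise-free data) makes the 3-SD band zero-width: the
  boundary is the first pixel differing from the mean at all.
* Single-frame stacks are allowed; birth times collapse to {t₀, NaN}.
* Nearest-frame ties resolve to the earlier frame.
* Welch test of two identical constant groups reports t = 0, p = 1.
* Problem sizes: validation runs use the full standard scenario
  (881² × 288 frames); multi-seed sweeps and the amplitude comparison
  run at 1 px/h magnification (311² × 288), which leaves every compared
  quantity unchanged.

## Known limitations

The detection-delay bias above is intrinsic to thresholding at
background + 3 SD and affects any label assignment keyed to absolute
birth times near schedule switches. The boundary scan assumes one
roughly centered colony per frame; multi-colony plates, drift
correction, and illumination-field correction are out of scope.
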