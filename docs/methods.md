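# Methods

## Signal model

A color flow acquisition is modeled per pixel as a complex baseband channel
ensemble `u_i[k]`, `i = 1..M` receive elements, `k = 1..K` slow-time samples
at the PRF. Each pixel is the sum of independent zero-mean circular complex
Gaussian components — blood, stationary speckle, moving clutter, thermal
noise — each defined by a linear amplitude, a slow-time Doppler fraction
`f` (phase ramp `exp(j 2π f k)`), and a receive-aperture coherence profile
`ρ[m]`. A component's aperture field is drawn as `A z` with
`A Aᴴ = T`, `T[i,j] = ρ[|i−j|]` (eigendecomposition, negative eigenvalues
clipped to zero), so the channel covariance equals the prescribed Toeplitz
matrix exactly. Blood, speckle, and clutter hold one aperture draw across
the ensemble (optionally decorrelated by an AR(1) redraw fraction); noise
redraws at every slow-time sample.

Default profiles: blood and speckle use the van Cittert–Zernike triangle
`ρ[m] = 1 − m/M` appropriate for a rectangular receive aperture; clutter
uses `(1 − m/M)·exp(−m/m0)` ("weakly coherent") or the full triangle (the
correlated-clutter regime); noise is spatially white. Bulk clutter motion
("flash") is modeled by scaling the clutter Doppler fraction with
`sin(2π·2 Hz·t)` sampled at the frame times; stationary speckle shares one
aperture draw across frames while blood, clutter, and noise are redrawn
per frame (flow displacement and bulk motion decorrelate the aperture field
between 12 Hz frames).

The sign convention follows the velocity estimator: positive axial velocity
(toward the transducer) corresponds to slow-time fraction
`f = −2 f0 v / (c·PRF)`, so the simulated pipeline recovers the prescribed
velocity with its sign.

## Estimators

**Coherence.** `R[m]` averages the per-sample normalized channel products
over slow time and element pairs; SLSC sums `Re R[m]` for `m ≤ Q`
(default Q = 10). Summing real parts is standard practice — for aligned
data the imaginary parts average to zero. Zero-magnitude samples (possible
after aggressive filtering) are dropped pairwise with the divisor reduced;
an all-dropped lag reads 0. Because of the per-sample normalization the
estimator is biased low: for Gaussian channels with correlation ρ,
`E[R] = (π/4)·ρ·₂F₁(½,½;2;ρ²)` (verified against Monte Carlo). All
calibration of synthetic scenes goes through this map and its numerical
inverse. SLSC is computed pixel-wise (no spatial kernel) for selection.

**Velocity.** The Kasai estimate uses the four-quadrant angle of the
lag-one slow-time autocorrelation accumulated over `k = 1..K−1` and an
optional spatial kernel (default: single pixel; kernels are specified in mm
and truncated at borders). A zero accumulator is flagged `no_signal` and
reads 0. `v = −c·PRF·φ/(4π f0)` in cm/s.

**Clutter filters.** Butterworth high-pass of order 2 (order is a knob;
order 2 keeps the transient short relative to K = 14) designed on the
normalized slow-time axis. "Projection initialization" removes the
component of the input lying in a degree-p polynomial slow-time subspace
(default p = 0: the DC projection) before running the recursion from rest —
any constant complex ensemble maps to output below 1e−10 of the input, and
the degree is exposed for higher-order polynomial clutter. The evaluation
bank is the identity ("no filter") member plus 8 members with cutoffs
evenly spaced over 0.03–0.24 of the PRF. All K output samples are retained.

**Selection.** Per pixel and frame, `argmax_f w_f·SLSC_f` with uniform
default weights; ties break toward the lowest cutoff (identity first), the
conservative choice that preserves slow flow. Optional coherence
thresholding rejects pixels whose maximum SLSC falls below a fraction of
the theoretical speckle maximum `q − q(q+1)/(2M)`; the alternative reading
(assign the identity member instead of rejecting) is switchable via
`below_threshold="no_filter"`.

**Priority encoding.** Variance and power thresholds per the conventional
formulation: population (1/N) kernel variance compared against σ² (σ given
in mm/s), and kernel-mean ensemble power normalized by the per-frame image
maximum compared against P in dB, both over 2×2 mm kernels by default.
Masks are computed from pre-encoding inputs, so the two encodings commute;
rejected pixels are zeroed *and* flagged so statistics can distinguish
"measured 0" from "rejected". Normalization is per frame (the per-
acquisition alternative is noted here as an open choice).

## Scene presets and calibration

Three presets emulate imaging through water and through two tissue layers
of increasing clutter severity; each contains a 4.8 mm plug-flow vessel at
a 70° Doppler angle (beam-projected mean velocity 5 cm/s for water, 10 cm/s
for the tissue conditions — the calibrated flow-rate range), background
speckle, and thermal noise, on a 46×46 grid at 0.4 mm spacing (≥1000
speckle pixels for ROI statistics).

The binding calibration target is the measured speckle-ROI lag-one
coherence (LOC): 0.75 (water), 0.45 (tissue #1), 0.36 (tissue #2). The
mixture lag-one correlation `(ρ_s P_s + ρ_c P_c)/(P_s + P_c + P_n)` is set
equal to the inverse-bias-mapped target:

* water: no clutter; noise power solved from the LOC target (≈0.16);
* tissue #1: clutter +15 dB over speckle with noise power 0.2; the clutter
  coherence decay constant `m0` is solved from the LOC target (≈1.7
  elements) — partially coherent at lag one, negligible beyond short lags;
* tissue #2: clutter +20 dB over speckle with *full triangle* coherence
  (correlated clutter); noise power solved from the LOC target (≈122,
  i.e. a low-SNR regime).

Clutter bulk motion is 1.3 cm/s peak axial velocity at 2 Hz. These choices
were fixed from an analytic budget of the post-filter coherence and bias
(clutter at ~0.02·PRF leaks through the 0.03 cutoff but not 0.09; blood at
10 cm/s, ~0.15·PRF, passes both), and they reproduce the qualitative
regimes: the low cutoff is accurate in water, biased under tissue #1, and
under tissue #2 raw correlated clutter out-coheres filtered blood so the
adaptive method preferentially selects "no filter" and in-vessel velocity
collapses — the known failure mode.

The B-mode contrast metric is implemented (amplitude convention,
`20·log10` of mean envelope ratio) but is not a calibration target: the
single-Gaussian-mixture pixel model cannot match LOC and contrast
simultaneously, and LOC is the binding statistic.

## What the simulator does and does not capture

It reproduces, by construction, the statistical quantities the method
consumes: channel coherence vs lag, slow-time spectra, component power
ratios, frame-time flash modulation. It does *not* model wave propagation
(no attenuation, aberration, reverberation paths), lateral speckle
correlation between pixels (pixels are independent; acceptable because all
estimators operate per pixel or on kernels of statistically identical
pixels), blood slow-time decorrelation by default (pure phase ramp; an
AR(1) redraw fraction is available), scan conversion, or the elevation
dimension. Passing tests therefore demonstrate correctness of the
processing chain and reproduction of the mechanism-level trends, not
performance on physical acquisitions.

## Numerical choices and problem sizes

* Tolerances: constant-input filter residual < 1e−10 relative; single-tone
  phase recovery < 1e−9 rad; pipeline-vs-brute-force oracle 1e−10.
* LOC calibration verified to ±0.05 over ≥1000 speckle pixels, one frame.
* Behavioral trend checks run on 32×32-pixel scenes, M=64, K=14, with 3
  frames (water, stationary) or 6 frames (tissue conditions; 6 frames at
  12 Hz cover a full 2 Hz flash cycle) — sizes chosen to make the
  mechanism-level contrasts decisive at interactive runtimes.
* Simulated data are complex64 by default (dtype is a parameter);
  oracle-grade tests construct complex128 inputs directly.
* Degenerate inputs: all-zero pixels yield zero coherence (flagged), zero
  Kasai accumulators yield 0 cm/s (flagged); an all-zero image under power
  encoding rejects every pixel.
* The per-pixel independence of scene generation permits vectorized draws;
  the Toeplitz factor is cached per coherence profile.

## Known limitations

* The projection subspace degree actually used in practice varies; only
  the polynomial family is implemented (default DC).
* Velocity-estimation kernel size for the Kasai sum is a free parameter
  (default single pixel); only the priority-encoding kernel (2×2 mm) has a
  conventional default.
* Priority-encoding power normalization is per frame; pooling across an
  acquisition would shift absolute dB thresholds.
* ROI standard errors are spatial (per frame); temporal and spatial
  variability are reported separately rather than pooled.
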