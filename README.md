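# cacflow

Coherence-adaptive clutter filtering (CACF) for color flow ultrasound.

Color flow imaging estimates blood velocity from the slow-time phase shift
of repeated firings, after a high-pass *clutter filter* removes echoes from
stationary and slowly moving tissue. The filter cutoff is a painful
trade-off: too low and residual clutter biases velocities toward zero (and
bulk tissue motion paints *flash* artifacts), too high and slow flow is
erased, leaving thermal-noise *jitter*. Conventional systems paper over
this with operator-tuned priority encoding (variance and power thresholds).

CACF replaces the fixed cutoff with a per-pixel, per-frame decision driven
by receive-aperture spatial coherence. The time-delayed channel ensemble
`u_i[r, k]` (element `i`, slow-time `k`) is passed in parallel through a
bank of projection-initialized IIR high-pass filters (plus a "no filter"
member). At each pixel the normalized channel correlation

    R[m] = 1/(K(M-m)) Σ_k Σ_i  u_i[k] u*_{i+m}[k] / (|u_i[k]||u_{i+m}[k]|)

is summed over the first Q lags to the short-lag spatial coherence,
`SLSC = Σ_{m=1..Q} Re R[m]`, and the filter `f_opt = argmax_f SLSC_f` is
selected. On-axis blood and tissue are spatially coherent (triangle
coherence `1 - m/M` for a rectangular aperture) while diffuse clutter and
thermal noise are not, so maximizing post-filter coherence picks the
gentlest filter that actually removes the clutter. The winning filter's
Kasai (2-D autocorrelation) velocity estimate

    φ[r] = angle( Σ_k U[r, k+1] U*[r, k] ),    v[r] = -c·PRF·φ[r] / (4π f0)

is mapped to the output image. The package implements the full adaptive
pipeline, the conventional baseline (fixed filter + priority encoding), a
synthetic channel-data simulator with prescribed Toeplitz coherence
structure that emulates flow-phantom imaging through water and through two
clutter-generating tissue layers, evaluation metrics (ROI statistics, B-mode
contrast, lag-one coherence, FLOP model), an HDF5 container, and a CLI.

Intended users: ultrasound signal-processing researchers who want a
reproducible desk-scale testbed for adaptive clutter filtering without a
research scanner.

## Worked example

Moderate moving clutter (the `tissue1` condition: clutter +15 dB over
speckle, 2 Hz bulk motion, lag-one coherence calibrated to 0.45) with plug
flow at 10 cm/s beam-projected velocity:

```python
import numpy as np
import cacflow as cf

acq = cf.default_acquisition()                 # 3.5 MHz, 3 kHz PRF, M=64, K=14
scene = cf.scene_presets("tissue1", shape=(32, 32), seed=7)
ens = cf.simulate_scene(scene, acq, n_frames=6)

adaptive = cf.cacf_image(ens, cf.default_bank(), q=10)
conventional = cf.conventional_image(ens, cf.design_highpass(0.03))

vessel = cf.vessel_roi(scene, shrink_mm=0.4)
print(np.mean([s.mean for s in cf.roi_stats(adaptive, vessel)]))      # 9.94
print(np.mean([s.mean for s in cf.roi_stats(conventional, vessel)]))  # 8.44
```

Output of the full comparison script:

```
in-vessel mean velocity  adaptive:  9.94 cm/s   conventional fc=0.03:  8.44 cm/s
outside mean |velocity|  adaptive:  1.80 cm/s   conventional fc=0.03:  8.00 cm/s
median selected cutoff in vessel: 0.12 x PRF
speckle-ROI lag-one coherence: 0.45
```

The adaptive image recovers the prescribed 10 cm/s flow (the 0.03·PRF
conventional filter under-reads it by ~1.6 cm/s because residual moving
clutter leaks through its passband) and keeps the stationary background
quiet, while the fixed low-cutoff image shows flash/jitter there. The
selection map shows CACF choosing mid-bank cutoffs (~0.12·PRF) inside the
vessel — wide enough to reject the clutter, narrow enough to keep the flow.

The same pipeline is scriptable from a shell:

```sh
cacflow simulate --preset tissue1 --seed 7 --out data.h5
cacflow cacf --in data.h5 --q 10 --out img.h5
cacflow evaluate --in img.h5 --roi roi.yaml --out stats.csv
```

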