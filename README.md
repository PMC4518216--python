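# bubbletrace

Quantitative dark-field x-ray imaging of flowing microbubble contrast
agents, simulated end to end.

Microbubbles — micron-scale gas cores in a thin polymer shell — refract
hard x-rays: each bubble is a weak x-ray lens, and a suspension of them
scatters the beam into a microradian-wide angular fan (ultra-small-angle
scattering). An analyser-based imaging (ABI) system places a perfect
crystal between sample and detector so that this angular broadening
modulates detected intensity through the crystal's rocking curve. Parked
on the curve's tail at 5 % reflectivity ("single-shot dark-field" mode),
the analyser mostly rejects the unscattered beam, so a bubble-filled
vessel lumen appears *bright* and its brightness tracks the bubble
volume concentration. `bubbletrace` is for researchers exploring this
contrast mechanism: it simulates the whole measurement and implements
the quantification chain that turns image sequences back into
concentrations.

The package contains:

* **optics** — x-ray optical constants (δ, μ) for the phantom materials
  from a bundled table, and a parametric analyser rocking curve with its
  tail working point.
* **phantom** — reproducible 3-D vessel phantoms: a Nylon-12 tube
  (4 mm internal diameter) whose water lumen holds a random,
  non-overlapping pack of polydisperse gas microspheres (truncated
  lognormal radii, median 4 μm) at a target volume concentration.
* **simulate** — a ray-optics Monte Carlo forward model: parallel
  17 keV rays accumulate attenuation `exp(-Σ μᵢ ℓᵢ)` and interface
  refractions (a sphere crossed at impact parameter *b* deflects by
  `2Δδ·b/√(r²-b²)`), the diffraction-plane deflection component is
  pushed through the rocking curve at the working point, and intensity
  is binned into 36 μm effective detector pixels with optional Poisson
  noise. Sequences model a dilution run, `C(t) = C₁·e^(-Dt)`, with a
  fresh bubble population every frame.
* **flow** — the well-mixed loop dilution kinetics and the acquisition
  timing model (0.5 s exposure + 0.27 s readout → 0.77 s frame period).
* **quantify** — ROI intensity extraction, background subtraction,
  simulation-benchmarked intensity↔concentration calibration with
  linear fit and residuals, decay-constant recovery by log-linear
  fitting with a bootstrap confidence interval, and the Rose-criterion
  (SNR ≥ 5) detection limit `c_min = 5σ/slope`.
* **cli / config** — a YAML-configured command line
  (`bubbletrace simulate | calibrate | quantify | run-all`) whose
  defaults reproduce the reference acquisition geometry.

## Worked example

```python
import bubbletrace as bt
from bubbletrace import benchmarks as bm

setup = bm.bench_setup()                       # reference imaging conditions

# calibrate: simulated intensity vs known bubble concentration
cal = bm.calibration_benchmark(setup, seed=42)

# simulate one dilution run and recover its decay constant
dil = bt.DilutionModel(c1=0.01, decay_rate=0.056)
seq = bt.render_sequence(setup.geometry, setup.dist, dil, setup.timing, 40,
                         setup.grid, setup.curve, setup.wp,
                         photon_budget=1e5, seed=42)
series = bt.roi_mean_series(seq, setup.roi)
bg_mean, bg_sigma, _ = bm.background_roi_stats(setup, seed=42)
est = bt.estimate_decay_constant(series, bg_mean, background_sigma=bg_sigma,
                                 seed=42)
```

This prints (seed 42):

```
calibration slope     : 2.321
calibration R^2       : 0.9996
Rose detection limit  : 5.14e-05
true D                : 0.056 1/s
recovered D           : 0.055 1/s  (95% CI 0.0536-0.0564)
frame-0 concentration : 0.00953 (true 0.00986)
```

Read: the background-subtracted ROI intensity rises by ≈2.3 intensity
units per unit volume concentration and is linear to R² ≈ 0.9996 over
[0, 0.01] (the residuals are small but structured — the response is
only approximately linear). Fitting the log of the subtracted intensity
series against time recovers the true dilution decay constant
0.056 s⁻¹ within 2 %, and inverting the calibration recovers the
per-frame bubble concentration within a few percent. At this photon
budget the Rose criterion puts the smallest distinguishable
concentration near 5×10⁻⁵.

The same chain runs from the shell:

```bash
bubbletrace run-all --config myrun.yaml --seed 1 --out runs/demo
```

which writes the frame stack (`sequence.tif` + timing sidecar), the
calibration table and plot, the estimated concentration series, and a
JSON decay report, each alongside an echo of the exact configuration.

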