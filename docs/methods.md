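# Methods

This note documents the physical model, the numerical choices and the
limits of what the simulations can show.

## Imaging model

**Geometry.** The beam propagates along +z; the vessel axis lies along
x, perpendicular to the beam; the analyser's diffraction plane is y–z.
A crystal analyser is a one-dimensional angular filter, so only the y
component of a ray's angular deviation is retained. Lengths are mm
internally; bubble radii are μm at the API surface; angles are
microradian; energies keV.

**Optical constants.** The refractive index is `n = 1 − δ + iβ` with
μ = 4πβ/λ. A bundled table (`data/materials.csv`, 15–20 keV) carries δ
computed exactly from the electron-density formula
δ = rₑλ²nₑ/(2π) and μ from standard mass-attenuation tabulations with
power-law energy interpolation (water and Nylon-12 good to ~2 %; the
optional shell copolymer is coarser, ~10 %, and off by default). The
gas core uses vacuum constants; air outside the tube is also treated
as vacuum (μ_air ≈ 1.4×10⁻⁴ mm⁻¹ is negligible over the few-mm
geometry). Note that Nylon-12's attenuation is genuinely about half of
water's at 17 keV — "water-like" in the sense of same order of
magnitude, which is what matters next to the ~2 mm water path.

**Rocking curve.** The analyser reflectivity profile is parametric:
Gaussian by default, pseudo-Voigt optionally, with configurable FWHM
(default 20 μrad — order-of-magnitude typical for Si(111) optics near
17 keV). The qualitative dark-field contrast depends on the working
level and tail shape, not the exact width, so the width is a config
knob rather than a calibrated quantity. The dark-field working point
is root-found on the tail where reflectivity equals 5 % of peak
(offset σ√(2 ln 20) ≈ 2.448σ for the Gaussian); the positive tail is
the default, the side being a config option.

**Ray optics.** Rays accumulate attenuation `exp(-Σ μᵢℓᵢ)` over
analytic chords (hollow cylinder decomposed as outer Nylon cylinder
plus an inner water cylinder replacing it; bubbles replace water along
their chords) and a refractive deviation at every interface pair. A
sphere of index contrast Δδ = δ_in − δ_out crossed at impact parameter
b deflects by `2Δδ·b/√(r²−b²)`, directed radially (gas bubbles in
water have Δδ < 0 and act as converging lenses); a cylinder crossed
perpendicular to its axis obeys the same form in the transverse plane.
Deviations are microradian-scale, so straight-line chords are used for
all intersection finding (re-steering would move a ray < 1 μm over the
geometry, far below the 36 μm pixel). Attenuation multiplies ray
weights continuously rather than absorbing rays stochastically — same
expectation, lower variance — so the rays-per-pixel budget (default
64, rounded to a square for the stratified jittered subgrid) controls
only refraction sampling noise. Free-space propagation is not
modelled: ABI maps deflection directly to rocking-curve angle.

The detected intensity per ray is `weight × R(θ_wp − α_y)`. On the
convex 5 % tail, the symmetric angular broadening produced by many
bubble crossings *raises* the mean reflectivity, which is the bright
dark-field signal: to leading order the ROI gain is
`≈ ½ Var(α)·R''/R`, and Var(α) grows linearly with the number of
crossings, hence with volume concentration — the mechanistic origin of
the approximately linear intensity–concentration response and of its
mild saturation (structured residuals) at the top of the range.

Grazing rays (b → r, or tube-edge crossings) receive divergent
deflections; they land far down (or across) the rocking curve and
simply contribute ≈ 0 reflectivity, which is the physically right
behaviour (dark tube edges) and needs no regularisation beyond an
epsilon in the denominator.

## Phantom generation

Bubble radii follow a truncated lognormal, median 4 μm. The geometric
SD (1.7) and truncation bounds (1–12 μm) are declared assumptions
typical of polymer-shelled agents, since only the median is an
established quantity; both are config knobs. The thin polymer shell is
not resolved — the phase signal is dominated by the gas–water δ
contrast — though a shell material exists in the table for users who
want it.

Packing is sequential rejection sampling: candidate centers uniform in
the lumen cylinder, rejected on wall protrusion or overlap with any
earlier sphere, accepted until the gas volume fraction first reaches
the target (overshoot ≤ one bubble volume, i.e. ≪ the 2 % tolerance at
the concentrations of interest). The implementation screens candidates
in vectorised KD-tree batches but reproduces the one-at-a-time
accept/reject decisions exactly, so the result is a deterministic
function of (seed, parameters). Rejection packing is appropriate
because the supported volume fractions (≤ 5 %) are far below any
jamming regime; non-overlap is enforced because it is physically
required at these dilutions.

## Dilution and timing

The loop concentration follows `C(t) = C₁e^(−Dt)`. D is the primary
parameter: runs are specified by it directly, matching how experiments
report them (e.g. D = 0.056 s⁻¹). The helper
`decay_constant(Q, V_p, V_l, R) = R·Q/(V_p+V_l)` is a well-mixed
single-compartment *assumption* offered for convenience (defaults
V_p = 2.3 ml, V_l = 2.8 ml); the split into two loop volumes hints at
a two-compartment refinement that is deliberately not invented here.

Frames are timestamped at mid-exposure (t₀ + k·0.77 s + 0.25 s by
default) so each intensity pairs with the concentration halfway
through its integration window, minimising pairing bias while C(t)
decays. "Frame period" is exposure + readout = 0.77 s. Each frame of a
sequence draws a completely fresh bubble pack — flow replaces the
population between frames — and intra-exposure motion blur is not
modelled.

## Quantification

The ROI is the central 50 % of the lumen width (config knob), all
axial columns, never touching wall pixels. The background is the ROI
mean of bubble-free renders at identical settings; subtracting it
makes zero intensity correspond to zero concentration. Calibration
renders ≥ 3 replicates per concentration level (zero level required);
the noise level σ is the standard deviation of the replicate
zero-concentration ROI means, and this σ is what enters the Rose
detection limit `c_min = 5σ/slope`. The detection limit therefore
scales with the photon budget chosen (default 10⁵ incident photons per
effective pixel, a synchrotron-like exposure); it is reported with the
simulation's own σ and is not comparable across noise settings.

The linear fit is ordinary least squares of subtracted intensity on
concentration. The "passes through the origin" check is the standard
statistical one — |intercept| within 2 standard errors of zero from
the OLS fit — because the calibration points carry phantom-realisation
Monte Carlo scatter that the zero-level photon-noise σ does not
represent, and because the response is deliberately only approximately
linear (the residual structure is part of the physics, see above).

D is recovered by OLS on log(subtracted intensity) vs time, after
dropping frames below a noise floor of 3× the background σ (the log of
near-background values is noise-dominated; this mirrors how the
visible asymptote is handled). The confidence interval is a seeded
bootstrap over frames (1000 resamples by default, percentile 2.5–97.5)
rather than an asymptotic formula. Sequences from slowly-diluting runs
may span less than one e-folding above background; the estimator warns
but proceeds. For display, `align_at_intensity` shifts runs so t = 0
falls at a common intensity level, reproducing the convention used
when runs start from slightly different initial concentrations;
analysis paths use absolute simulated time, since ground truth is
known.

## Benchmark problem sizes

The reproduction benchmarks (`bubbletrace.benchmarks`, used by the
test suite and `scripts/acceptance.py`) run at a 0.5 mm axial field of
view over the full 4.6 mm transverse span (128 × 14 effective pixels),
32 rays per pixel, C₁ = 0.01, 40-frame sequences, 10 independent runs
per decay constant for recovery statistics, and 200 random cases for
the refraction oracle. These sizes were chosen so the full chain runs
in minutes on one core while every statistical check retains a
comfortable margin; the physics is identical at the full defaults
(larger fields of view, 64 rays per pixel).

## Degenerate inputs and tie-breaks

Zero concentration yields an empty pack; `geometric_sd = 1` collapses
the size distribution to the median; rays missing the vessel return
unchanged; a constant-reflectivity analyser with zero absorption
returns exactly the incident flux in every pixel (energy bookkeeping:
refraction redistributes angle, not weight). Root-finding for the
working point brackets outward from one FWHM and is exact to 10⁻¹²
relative. Concentration estimates are clipped below at zero;
extrapolation beyond the calibrated intensity range warns.

## What the synthetic data does and does not show

The simulator reproduces the statistical structure of a dilution
experiment: a bright lumen band whose ROI intensity decays
exponentially to a non-zero background with Poisson noise, a
near-linear concentration response with structured residuals, and a
finite Rose-criterion sensitivity. It does not model wave-optics
propagation or coherence, dynamical diffraction of the real crystal,
detector PSF beyond binning, bubble buoyancy/destruction, motion blur,
or the "structural noise" of real tissue. Passing tests therefore
validate the computational chain and its internal consistency — not
the absolute sensitivity of any particular beamline, which depends on
the measured rocking curve, the true size distribution and the real
photon flux.
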