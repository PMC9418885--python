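# Methods

This note documents the models behind each stage, the defaults that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Synthetic force curves

**Model.** An approach trace is sampled on a uniform tip–sample separation
grid (default step 0.02 nm, the resolution of a ~50 kHz acquisition at the
standard 0.5 µm/s approach velocity), in acquisition order (separation
decreasing). Above the contact point the force is baseline noise. On contact
with the top of the layer stack the force loads piecewise-linearly in
indentation with the preset's contact stiffness; a layer may declare an
initial *elastic-compression prelude* (a depth over which the stiffness is a
fraction of the full value). When the load reaches the layer's sampled
rupture force, the layer yields instantaneously at sample resolution: the
force drops and the tip advances through the layer's sampled thickness at
zero force before re-contacting the next layer (or the substrate). The curve
terminates at the first sample at or above the 10 nN setpoint.

**Scenarios.** Five presets encode the sample classes studied:

| preset | layers | rupture force (nN) | thickness (nm) | notes |
|---|---|---|---|---|
| DMPC-20C | 1 | N(1.3, 0.3) | N(5.0, 0.4) | gel-phase bilayer, single step |
| DMPC-30C | 1 | N(0.34, 0.08) | N(4.0, 0.4) | fluid phase, softer contact (0.5 nN/nm) |
| LPS-DMPC | 2 | α N(0.5, 0.2); β N(1.4, 0.5) | α N(3.0, 0.5); β N(5.0, 0.4) | α present with p = 0.95 |
| OM-DMPC | 1 | N(2.03, 0.41) | N(6.0, 0.5) | 2 nm prelude at 0.25× stiffness |
| LPS-VESICLE | 1 | N(6.0, 0.5) | N(8.0, 1.0) | contact at 30 nm; soft regime (0.1× stiffness) down to 12 nm, then stiff |

The α-layer force scale is a free default (the experimental constraint is
only that it sits below the β cluster), as are the contact stiffnesses, the
thickness spreads, the prelude parameters and the vesicle soft/stiff
stiffness ratio of 1:10; the remaining numbers are the anchored means and
spreads of the corresponding measured populations. Sampled forces are floored
at 0.05 nN and thicknesses at 0.2 nm for physicality. Default force noise is
0.05 nN (0.02 nN for the soft DMPC-30C scenario, whose rupture force would
otherwise drown).

**Truth records.** Each curve carries both the drawn (analytic) event
parameters and their *grid-realised* counterparts measured on the emitted
noiseless samples: the yield sample (last sample on the loading ramp), the
noiseless force at that sample, and the separation span to the first sample
where the force rises above 10⁻⁹ nN. Detector output is compared against the
grid-realised truth, which makes exact (zero-tolerance) oracle equality a
meaningful test on noise-free curves.

**Retraction.** Retract traces carry a smooth adhesion well (zero at
contact, single minimum of 0.3 nN at 2 nm, exponential decay) plus, when
requested, unfolding sawteeth: a gradual attractive build-up over 3 nm
released abruptly in one sample, at positions recorded in the truth.

## Rupture-step detection

Curves are median-filtered (default window 5) and baseline-subtracted (mean
over the far-separation 20% of samples); the baseline-subtracted unfiltered
force is kept alongside. The contact point is the largest separation where
the filtered force exceeds 5× the far-field noise for 5 consecutive samples.

Detection walks the filtered force from contact with a running-maximum
hysteresis: a drop must exceed max(5× filtered noise, 0.05 nN) before a
candidate opens, which prevents noise re-triggering. The yield sample is then
localised on the *unfiltered* force as the most negative first difference
near the candidate edge — the median filter preserves step edges but rounds
the peak at the yield point, so the reported rupture force is the raw
(baseline-subtracted) force at the last sample before the drop: unbiased
under noise, and exactly equal to the grid truth on noise-free curves.
Recovery (the subsequent force increase) is the first sample after the
zero-force gap that exceeds max(4× filtered noise, 10⁻⁹ nN) with the force
still above that floor two and four samples ahead, so a lone noise excursion
inside the gap cannot truncate the thickness. Rupture thickness is the
separation span from the yield sample to the recovery sample. Events pass
the gates if the force at yield exceeds `min_force` (default 0.1 nN; gating
on the drop magnitude is available as an option) and the thickness exceeds
`min_thickness` (0.1 nm). Tied maxima resolve to the larger separation.

**Populations.** Within a multi-step curve, every event but the last is
labelled α (initial, low-force steps) and the last β (the bilayer rupture);
single-step curves are β below the γ force gate and γ above it (single
high-force combined ruptures, characteristic of protein/LPS-reinforced
bilayers). The gate is fitted per batch as the midpoint between the two
modes of the single-step force distribution (1D Gaussian mixture), but only
when a two-component model is supported by BIC and at least 20 single-step
events exist; otherwise a fixed 1.7 nN gate applies. The BIC check matters
because a unimodal single-step batch (pure DMPC, or pure OM-DMPC) has no two
modes to split.

## Synthetic topographies

A scene is a 2×2 µm raster (default 512×512, pixel 3.9 nm). Phase domains
come from a Gaussian random field smoothed over 24 px and thresholded at
exact pixel quantiles, which gives blobby, nested domains (substrate outside,
fluid rim, solid interior, rough LPS domains innermost — the arrangement the
real patches show) with pixel-exact coverages. Heights are class plateaus
(fluid 4 nm, solid 5 nm, OM-DMPC 6 nm) plus independent Gaussian texture per
class; the rough-domain texture default is 0.5 nm versus 0.08 nm for smooth
phases, and the single-plateau roughness scene uses 0.77 nm, the measured
R_q of a DMPC SLB image. Optional features: sinusoidal stripes (15 nm
period, 0.4 nm amplitude, arbitrary orientation and phase) on the lipid
area, and spherical-cap vesicles on the substrate. Artifacts are a global
background plane (1 nm amplitude, random orientation) and per-scanline
offsets (σ 0.15 nm) and linear tilts (σ 0.3 nm across the width) — the
signature of per-line AFM acquisition. The truth stores the label map,
realized coverages, the artifact-free heights and all feature parameters.

**Vesicle sizing convention.** The generator and detector share one
definition: a vesicle's diameter is the equal-area disc diameter of its
contour at half-maximal height. Caps are drawn with height = 0.4 × diameter
and a footprint radius chosen in closed form so the drawn diameter *is* the
half-max diameter. Diameters are drawn from a lognormal with mean 29 nm and
sd 22 nm floored at 8 nm — a right-skewed law natural for vesicle sizes
whose truncated mean (~30.5 nm) stays at the measured population mean,
whereas a normal with that mean and spread truncated at 8 nm would average
~36 nm and no longer represent the measured population.

## Topography analysis

**Leveling.** Supported-bilayer images contain several height plateaus, so a
naive per-row polynomial fit latches onto whichever phase dominates each row
and shears the image. `flatten_map` instead iterates to a fixed point:
detect the plateau levels (smoothed height-histogram peaks, refined as
medians of the assigned pixels), subtract the per-pixel level model, fit the
per-row polynomial (order 0–2, default 1) and a global plane on the
*residuals* with 3σ clipping (so rough domains and vesicles do not bias the
fits), and repeat until the correction increment is below 10⁻⁹ nm RMS.
Running to a fixed point makes flattening idempotent. The substrate
reference is the median of the pixels under the lowest histogram peak
(selected by the inter-peak midpoint), shifted to 0 nm; in a full-coverage
image this zeroes the plateau itself, which is the usual AFM ambiguity when
no substrate is exposed. Rows whose exclusion mask leaves too few pixels are
fitted on all pixels, with a warning.

**Segmentation.** Level classes come from multi-Otsu thresholds
(deterministic default; `n_classes='auto'` uses the histogram peak count,
capped at 4). Classes are named by height: a lowest class below 1.5 nm is
substrate; the lipid levels are fluid then solid in ascending order (a
single lipid level is fluid below 4.5 nm, else solid). Rough domains are
pixels whose 5×5 local height variance exceeds 3× the smooth-phase variance
(estimated as the lower quartile of the local variance over the lipid
interior, which stays on the smooth phase even when rough domains cover much
of the patch); a morphological opening removes the thin high-variance
ribbons that plateau steps leave, while true rough domains survive.
Components protruding > 1.5 nm above the top plateau become bumps. Coverage
fractions are pixel counts over the lipid area (substrate excluded) by
default, or over the whole frame.

**Roughness, profiles, texture.** R_q is the RMS height deviation about the
mean over a mask of ≥ 100 pixels. Profiles are bilinear interpolations along
a segment with endpoints in nm. Stripe periodicity comes from a
Hann-windowed, plane-detrended 2D power spectrum: the dominant wavelength is
the highest-power bin outside the low-frequency disc (wavelengths above ¼ of
the image side are treated as background), reported only when the peak
exceeds 30× the median spectral power — white noise peaks near 20× by order
statistics, so an isotropic texture reports "no periodicity" rather than a
number. The amplitude is the full-frame-equivalent sinusoid amplitude
obtained by Parseval bookkeeping over the 3×3 peak neighbourhood. Vesicles
are connected components above 1 nm (border-touching components excluded),
sized by the shared half-max convention; sub-half-max-pixel caps (diameter
below ~2 pixels) are not detectable, one reason the generator floors drawn
diameters at 8 nm.

## DLS forward model and MEM inversion

One forward implementation serves both the generator and the inversion:
intensity weights wᵢ on a diameter grid give g₁(τ) = Σᵢ wᵢ e^(−q²Dᵢτ) with
Stokes–Einstein Dᵢ = k_BT/(3πηdᵢ), and g₂ = 1 + β g₁² (Siegert, coherence
factor β = 0.9 by default). The instrument default is the stated geometry —
λ = 457 nm, θ = 90°, T = 298.15 K — with water viscosity interpolated from a
tabulated 10–40 °C range and refractive index 1.340.

The inversion maximises the entropy S = −Σ pᵢ ln(pᵢ/mᵢ) against a uniform
prior m subject to χ² ≤ `chi2_target` × n_lags (default target 1.0 per lag,
σ from the correlogram's noise estimate, floored at 10⁻⁴ — a realistic
correlator baseline — so noiseless data does not demand unattainable
precision). The solver follows the regularisation path of χ²/2 − αS: the
damped multiplicative update log p ← (1−η) log p + η(log m − ∇(χ²/2)/α) is
an exponentiated-gradient step, kept monotone by backtracking on the
objective; α starts at the gradient scale (where the first update is order
one) and descends geometrically with warm starts until the misfit target is
met, after which a bisection in log α finds the largest — maximum-entropy —
α still meeting it. Iterations stop at a relative entropy change below 10⁻⁸
or 10 000 iterations; if even the nearly-unregularised end of the path
misses the target the best iterate is returned flagged non-converged. The
default grid is 60 log-spaced diameters from 1 to 1000 nm. Weights are
intensity weights (what DLS measures); a d⁻⁶ conversion to number weights is
provided but off by default. Peak statistics report local maxima with their
watershed-basin masses above a mass floor (default 0.05); a mode at a grid
edge is flagged.

**Resolution limit.** A monodisperse 40 nm sample with 1% g₂ noise inverts
to a single mode within one grid cell. A 30/120 nm equal-intensity bimodal
resolves into two modes within one cell each at 0.1% noise; at 1% noise the
maximum-entropy solution at the attainable misfit merges the components into
one broad band — with χ² at the *true* distribution already at or above the
per-lag target for typical noise realisations, the data no longer support
two separate modes, and any two-mode answer would be over-interpretation.
The test suite pins both behaviours.

## What the generators do and do not emulate

The synthetic data reproduce the *measurable signatures* each analysis stage
consumes: step-like breakthroughs on elastic loading ramps, multi-level
patchy topographies with texture, stripes, caps and line artifacts, and
Siegert-form correlograms. They deliberately omit tip–sample convolution,
thermal drift and feedback dynamics, cantilever calibration errors,
non-instantaneous ruptures, tip-shape broadening of vesicle caps, and
multiple scattering or number fluctuations in DLS. Passing recovery tests
therefore demonstrates that the analysis correctly inverts the stated data
model at realistic noise levels — not that it is robust to every artifact of
real instruments; the gates, windows and thresholds are exposed as
parameters for exactly that reason.

## Problem sizes

The recovery checks use the batch sizes of the emulated study: 400 curves
per force scenario (100 for the vesicle-compression scenario), single
512×512 scenes per image quantity with four scenes (~240 caps) for vesicle
statistics, and 200-lag correlograms on the 60-point diameter grid. The full
acceptance recomputation runs in well under a minute on one CPU.
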