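# Methods

This note documents the measurement models, the synthetic-data generators
that stand in for raw microscope images and amplifier recordings, the
numerical choices, and the known limitations.

## Imaging model and TIRF quantification

In total internal reflection fluorescence (TIRF) microscopy only
fluorophores within ~100–200 nm of the coverslip are excited, so the
signal reports the adherent membrane. Two confounds make raw TIRF
intensity an unreliable expression readout: local membrane-to-substrate
distance (adhesion) and excitation of non-adherent membrane folds. Both
affect a homogeneously partitioning membrane dye in the reference channel
the same way they affect the protein channel. The synthetic generator
encodes exactly this structure:

    F_M(x)   = A(x) · c              + ε_M(x)
    F_β(x)   = A(x) · c · E(x)       + ε_β(x)

with a shared adhesion field `A` (1 on the cell body, 1.5 in
filopodia/lamellipodia-like processes by default), a base level `c`
(100 AU in both channels), and an expression field `E` equal to 1 inside
the footprint and to the enrichment factor ρ within a border ring
(default width 1 µm) and inside processes. Noise is additive Gaussian
with SD given relative to the mean in-cell signal (default 10%); pixels
are clipped at zero afterwards so images remain physical, which slightly
raises the background mean but touches none of the measurements (all
windows are placed inside the cell). The footprint is an ellipse (default
semi-axes 16 × 13 µm) with optional lamellipodial lobes and filopodia;
the default pixel size is 0.1 µm at 512×512 pixels. The generator refuses
geometry that leaves the frame.

**Intensity difference.** `D = F_β − F_M·⟨F_β⟩/⟨F_M⟩` with both means
taken over a 5×5 µm² central ROI of approximately homogeneous signal.
The ROI mean of `D` is zero by construction and negative values are
preserved. The quantity is invariant under global rescaling of either
channel; pseudo-color display is cosmetic only.

**Edge detection.** Gaussian smoothing (σ = 0.3 µm) followed by Otsu
thresholding, then one refinement pass that re-thresholds at the midpoint
of the inside/outside medians — this centres the contour on the true
edge independently of how bright the enriched border is. The largest
connected component is kept and holes are filled. Exact pixel equality
with ground truth is not attainable for threshold methods (pixels whose
smoothed value sits at the threshold are undecidable, and locally
brighter processes dilate the contour by about a pixel); noiseless masks
agree with truth to Jaccard > 0.99 with all disagreement in a one-pixel
boundary band.

**Radial profiles and border-to-center ratios.** Ten 10 µm segments per
cell are placed on the detected edge, perpendicular to the boundary,
centred on it, avoiding (dilated) process masks — lamellipodia-like
structures are excluded from this analysis by design. Boundary normals
come from local osculating-circle (Kåsa) fits over ±40 contour points;
straight-line tangent estimators carry a lattice-locked staircase bias
of up to ~3° near diagonal orientations, while the circle fit recovers
radial directions on a disk to better than half a pixel. Intensities are
sampled at pixel pitch by bilinear interpolation. The edge sample is the
last profile sample inside the footprint; the border window is the five
samples strictly inside the cell ending at the edge crossing (the
crossing sample itself is excluded because its bilinear value mixes in
background), and the centre window is the first five samples at the
interior end. The ratio is the border mean over the centre mean. With
the default ring (1 µm) the window sits fully inside the enriched band,
and the estimator recovers ρ ∈ {1.0, 1.34, 2.0} to ±0.01 at 10% noise
over 8 cells × 10 segments.

**Expression index.** `R = (S − N)/N`, with `S` the mean over ten
non-overlapping seeded 3×3 µm² ROIs inside the cell and `N` the same over
background (non-transfected) regions. `R` is exactly affine in the cell
level, so a cell at 35.69× background returns R = 34.69.

## Morphometry

**Segmentation.** Smoothing (σ = 0.15 µm — narrower than for edge
detection so 0.4 µm-wide processes survive) and the same two-pass
threshold. The cell body is the morphological opening of the mask with a
disk of radius half the process-width ceiling (0.5 µm).

**Process detection.** The skeleton of the full mask is split into a
thick backbone (local width ≥ 1 µm: soma, dendrites, lamellipodia-like
structures) and thin branches. Geodesic distances are propagated from
all backbone anchors through the thin subgraph; every thin endpoint
whose branch extends at least 0.5 µm beyond the parent's edge is one
process. Counting per endpoint keeps protrusions distinct even when
their bases fuse into a locally thick blob or their shafts cross;
protrusions whose tip touches another branch (no free endpoint) are
recovered at the ridge where two anchors' geodesic fronts meet. Length
is the chord-resampled skeleton arc from the parent's (opened-body) edge
to the tip plus the local cap radius — resampling every 4 pixels removes
the ~8% staircase overestimate of raw 8-connected chains; accuracy on
isolated synthetic processes is ±0.2 µm. The attachment is reported both
at the parent's edge and on the parent centreline (nearest body-skeleton
pixel); the centreline point is what selection counting uses.

**Length groups.** Half-open bins [0, 4), [4, 8), [8, ∞) µm, lower-edge
inclusive (exactly 4.0 µm falls in the middle group); the edges are
configurable. Empty inputs yield an all-zero histogram with a warning.

**Counts per 20 µm dendrite selection.** A process counts when its
centreline attachment lies within 0.5 µm of the selection path and its
closest approach does not clamp to the path's end points (otherwise a
20 µm window would count a ±0.5 µm overhang). The same rule scores
ground truth and detections. Against truth, the detector is within ~5%
at 7.6 protrusions per 20 µm and ~1% at 1.89.

**Branching-area index.** High-pass (image minus a Gaussian blur of
σ = 2 µm — a re-specification of a proprietary "HighGauss" sharpening
filter), 3×3 median filter, Otsu threshold, soma pixels removed from
numerator and denominator, result in percent of the remaining field.
The index is invariant to linear intensity rescaling and monotone under
realistic branch additions (Otsu re-thresholding makes strict
monotonicity unprovable in adversarial cases). The denominator is the
full imaged frame minus the soma; on noiseless synthetic arbors the
index matches the ground-truth branch-area fraction to ±0.5 points.

## Synthetic neurons

A soma (radius 6 µm) sprouts 5 dendrites grown as random walks
(22–38 µm, 5° step jitter, branching probability 0.02/µm) and one longer,
straighter, sparsely branched axon. Filopodia-like protrusions (width
0.4 µm, dendrite width 1.2 µm) are placed along dendrites only — the
axon never carries any, mirroring the dendrite-specific phenotype — as a
density-preserving hard-core renewal process: gaps are a 1 µm minimum
plus an exponential whose mean keeps the rate exactly at the configured
density (default 7.6 per 20 µm), and the first arrival is drawn from the
equilibrium delay distribution so short branches carry no density
deficit. The hard core reflects that filopodia are discrete, spatially
exclusive structures; a pure Poisson stream would place ~20% of
protrusions within half a micron of a neighbour, where they fuse into
optically unresolvable blobs at the 0.1 µm pixel scale and no detector
could separate them. Generated counts remain inside the Poisson 99%
interval. Protrusion lengths come from a three-component mixture over
the <4, 4–8 and >8 µm ranges (default weights 0.6/0.3/0.1), with
component supports kept clear of the bin edges so truth membership is
unambiguous.

## Voltage-clamp model and analysis

The cell is a series access resistance Ra into a membrane RC (Cm ∥ Rm)
with leak reversal pinned at the −90 mV holding potential (leak is zero
at rest — a stated simplification) plus a sodium conductance
`G(V) = Gmax · m∞(V)` with `m∞(V) = 1/(1+exp((V½ − V)/s))`. The
membrane voltage satisfies `Vm = Vcmd − I(Vm)·Ra`, solved by damped
fixed-point iteration to |ΔVm| < 0.01 mV (an explicit error is raised
for non-contracting Ra·Gmax products). Each sweep carries the analytic
step response `I(t) = I_ss + (ΔV/Ra − I_ss)·e^(−t/τ)`,
`τ = Cm·RaRm/(Ra+Rm)`, a 60 ms pulse with 2 ms pre/post segments at
100 kHz, and four P/4 subpulses per test voltage, negative-going
(hyperpolarizing) by default so the subpulses activate no channels.
Noise is multiplicative Gaussian per sample (default 3%). Quasi-static
gating (the default) makes the peak equal the steady state exactly; the
kinetic mode (`m` relaxing with τ_m = 0.1 ms, `h` decaying with
τ_h = 5 ms at fixed Vm) is provided for realism but its peak
underestimates m∞ by ~9% at those constants, so recovery work uses
quasi-static mode.

**Analysis chain per cell.** (1) P/4 subtraction:
`corrected = test − polarity·4·mean(subpulses)`, the sign chosen so a
purely linear cell nulls — the defining property of the protocol;
mismatched subpulse amplitudes (>1%) raise. (2) Passive parameters from
an exponential fit `I(t) = I₀e^(−t/τ) + I_ss` of the averaged largest
subpulse transient: `Ra = ΔV/I(0)`, `Rm = ΔV/I_ss − Ra`,
`Cm = τ(Ra+Rm)/(RaRm)`; noiseless recovery is exact to <1%. (3) Peak
inward current per corrected sweep, smoothed over 0.3 ms, excluding the
first 6τ after pulse onset in the pipeline: multiplicative noise rides
on the *uncancelled* transient amplitude (ΔV/Ra, tens of nA), and at the
conventional 2τ its residual can exceed a small cell's sodium current.
(4) Access-resistance correction
`Vm = Vcmd − (I_peak + (Vcmd − V_hold)/(Ra+Rm))·Ra`: the P/4-corrected
peak excludes the linear leak the cell actually draws, so the leak is
reconstructed from the passive fit before the Ra drop is applied —
without this term the missing ~100 pA of leak biases fitted V½ by
+1.7 mV at Ra = 10 MΩ. (5) `G = I_peak/(Vm − E_rev)` with points within
5 mV of the reversal potential excluded; normalization to the highest
retained depolarizing voltage (where m∞ > 0.999 for all conditions
studied, so the anchor bias is negligible). E_rev comes from
configuration when known (synthetic truth, +65 mV) and otherwise from
linear interpolation of the peak I–V zero crossing — which requires the
protocol to cross E_rev; the default protocol tops out at +40 mV, so
estimation needs extended steps. (6) Boltzmann least squares on the
normalized curve; `q_g = (k_BT/e)/s` at 295 K (configurable). (7) QC:
cells with Ra > 15 MΩ (strict) are excluded; fitted slopes below
3 mV/e-fold or a normalized rise from <0.1 to >0.9 within one 5 mV step
are flagged as space-clamp suspects. Every exclusion is logged with its
reason.

Over 100 synthetic cells (Ra 5–12 MΩ, Cm 8–15 pF, Gmax 5–25 nS, 3%
noise) the mean recovery bias is <0.1 mV in V½ and <0.1 mV/e-fold in s.

## Statistics and reporting

Groups are summarized as mean ± SEM (sd/√n, ddof = 1). Comparisons use
two-tailed t-tests — pooled-variance Student by default, matching common
practice, Welch by flag — with p < 0.05 as the significance criterion
and no multiple-testing correction. Two zero-variance groups with equal
means take p = 1 by convention. Fold changes are reported raw and
rounded to the nearest integer. Per-cell averages enter group statistics
(segments and selections are averaged within a cell first). The report
builder assembles caption-style tables; empty stages are recorded as
notices, never errors.

## Problem sizes

The validation suites use 8 two-channel cells × 10 segments per
condition for border-to-center recovery, 15 and 13 simulated cells for
the two activation-recovery conditions, 24 neurons × 10 selections per
density condition for protrusion counting (the same arbor seeds serve
both densities, a paired design that removes arbor-geometry variance
from the density contrast), and 100 cells for the population-bias check.

## Limitations

* The generators emulate the *statistical structure* the estimators
  assume — shared adhesion fields, discrete protrusions, passive RC plus
  Boltzmann conductance. They do not model evanescent-field depth decay,
  photobleaching, dye internalization, uneven illumination, or
  space-clamp voltage gradients; passing recovery tests therefore
  validates the estimators under these idealizations, not the optics or
  biology of any particular instrument or preparation.
* Threshold-based segmentation localizes edges to ~1 pixel and dilates
  around locally brighter structures; border windows are placed to be
  insensitive to this at the default ring width.
* Protrusions that fuse below the optical resolution are intrinsically
  uncountable; the generator's hard-core spacing keeps the ground truth
  resolvable by construction.
* Kinetic-mode peaks underestimate steady-state activation (~9% at the
  default time constants); activation-curve recovery should use
  quasi-static simulations or faster inactivation-free kinetics.
* The branching-area index depends on the high-pass σ and the Otsu
  threshold; both are configurable and recorded, but absolute values are
  comparable only within a fixed configuration.
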