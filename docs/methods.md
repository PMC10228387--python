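# Methods

`nvuq` re-implements, as a tested library, the quantification procedures used
to read out neurovascular-unit physiology from two-photon and bright-field
imaging of the mouse cortex: vesicular transcytosis across the blood–brain
barrier (BBB), paracellular tracer leakage, stimulus-evoked vasodilation and
its synaptic drive, amyloid-plaque load, perivascular fibrinogen, and
pericyte coverage.  Every estimator is paired with a seeded synthetic-data
generator that embodies the statistical structure the estimator assumes, so
the whole pipeline is validated by parameter recovery rather than by eye.

## Imaging containers and conventions

A recording is a `HyperStack`: a 5-D array in fixed `(T, Z, C, Y, X)` order
with a `VoxelGeometry` (XY pixel pitch, Z step, frame period).  Defaults
(0.124 µm pixels, 2.5 µm sections) match a high-zoom two-photon acquisition.
Coordinates are 0-based, intervals half-open; depth is in µm, positive
downward from the brain surface, plane 0 shallowest.  On disk a stack is a
uint16 multi-page TIFF with a `*.geometry.json` sidecar that is authoritative
for axes and geometry — TIFF axis tags are too dialect-dependent to trust.
In memory intensities are floats in arbitrary units; additive read noise may
dip below zero and is only clipped when written to disk.  Detector gain and
bit depth are never interpreted: every statistic downstream is either a ratio
or is thresholded relative to a per-recording amplitude.

## Transcytosis (AMT) density

Adsorptive-mediated transcytosis is scored as albumin-tracer punctae per µm²
of vessel surface.  For segment *i* of vessel type *typ* with puncta count
*n*, diameter *d* and length *l*:

    a_i = π d_i l_i,     ρ_typ = Σ_i n_i / Σ_i a_i,     ρ_overall pooled over all types

Pooling (totals first, then one division) weights segments by surface area;
a mean of per-segment ratios would not, and the two differ whenever areas
differ — the test suite pins this distinction.  Vessel types missing from a
field of view are *absent*, never zero.

Manual puncta counting is replaced by `detect_punctae`: local maxima of the
tracer channel restricted to a shell within 1 µm of the vessel-mask boundary
(where transcytotic vesicles sit), greedily non-maximum-suppressed at a
physical separation (default 1 µm) and localised to sub-voxel precision by a
3³-neighbourhood intensity centroid.  The formula layer is unchanged by this
substitution.  Detection is exact (recall = precision = 1, localisation
< 0.5 µm) on noise-free scenes sampled finely enough to resolve the spots
(≈ 0.3 µm voxels); at coarser sampling, diffraction-limited spots alias and
no detector can be guaranteed exact.  Counting is done in 3-D.

The mask-based route (`segeval`) quantifies from binary segmentation masks:
vessel area = foreground pixels × pixel area × π (the projected strip
wrapped into a cylinder, commensurate with π·d·l), puncta count = connected
components (8-connectivity in 2-D by default, configurable — diagonal
touches merge), density pooled across ROIs before division.  Segmentation
quality is evaluated by the Dice coefficient 2Σ(ŷ·y)/(Σŷ+Σy), undefined and
an explicit error when both masks are empty.  Trained segmentation networks
are out of scope; synthetic truth masks (optionally degraded morphologically)
stand in for their outputs.

## Paracellular leakage

After a small-tracer bolus, blood intensity decays and parenchyma slowly
accumulates.  The generator implements the one-compartment uptake model

    C_b(t) = c₀ e^(−t/τ),     dC_p/dt = k C_b  ⟹  C_p(t) = k c₀ τ (1 − e^(−t/τ))

with τ the blood decay constant (default 20 min), k the permeability-like
uptake rate (1/min), over a 45-min recording sampled every 3 min.  The
leakage statistic is AUC(parenchyma)/AUC(blood), which cancels c₀ and any
detector gain; its closed form,

    ratio = k τ [T − τ(1 − e^(−T/τ))] / [τ(1 − e^(−T/τ))]

is checked against numerical quadrature to 1e-6 and recovered by the
pipeline to better than 0.5% on a noise-free time-lapse (the residual is the
trapezoid-rule bias on a 3-min grid, which partially cancels between the
convex blood and concave parenchyma curves).

Pipeline choices: AUC by the trapezoid rule on the actual sample times;
parenchymal ROI curves at one depth are averaged before integration; t = 0
is the first post-injection frame.  Rigid lateral drift is estimated per
frame from phase correlation of maximum-intensity projections, integer-pixel,
and applied to ROI positions; a frame whose normalised correlation at the
estimated shift falls below 0.1 inherits the previous frame's shift with a
warning.  Each parenchyma ROI (default 20 × 20 µm, 4–5 per depth at 20/40/80
µm) is served by the plane whose surface-relative depth is nearest its
requested depth, within one Z-step; ROIs flagged under a vessel or plaque
are rejected and logged.  Axial drift is diagnosed but no automatic cut is
applied — the original exclusion criterion is qualitative.

## Neurovascular coupling

Movies are stimulus-locked (40 s baseline, 15 s stimulation, 75 s post).
The movie is maximum-projected along Z; a rectangular ROI across the vessel
is collapsed along the vessel's longitude into one cross profile per frame;
the profile is binarised at `min + 0.5·(max − min)` of the *time-averaged*
profile (a full-width-at-half-maximum analogue, constant over time), and the
diameter is the largest connected above-threshold run × pixel size — the
largest run, not the raw pixel count, so isolated noise pixels never inflate
the diameter.  The original threshold was adjusted by hand; a fixed relative
threshold makes the pipeline deterministic while preserving "same threshold
across time and ROIs".  The generator renders the tube cross-section as a
PSF-blurred top-hat (difference of Gaussian CDFs), whose FWHM equals the
true diameter, so half-amplitude thresholding is unbiased; the tube centre
carries a random sub-pixel offset per seed so pixel quantisation dithers out
in multi-seed means.

From the trajectory: D₀ = mean of all pre-onset diameters; Dₚ = max of the
5-point centred running average (edge-truncated) within [onset, onset+40 s];
relative dilation = (Dₚ−D₀)/D₀.  Smoothing before the max matters: a
single-frame spike of +10 on a baseline of 10 yields Dₚ = 12, not 20.

Exclusion rules quantify two qualitative criteria.  (i) Unstable baseline:
pre-onset coefficient of variation > 0.10.  (ii) Spontaneous pre-stimulus
dilation: any smoothed late-baseline value exceeding the *early*-baseline
mean by more than 3 × the early-baseline CV (floored at 1%).  The bound is
anchored on the first half of the baseline deliberately: a genuine pre-onset
rise inflates whole-baseline variability and would otherwise raise the very
threshold meant to catch it.  Only the pre-onset segment is smoothed here,
so post-onset frames cannot leak into the centred window.  Both rules are
configurable and excluded trajectories still report their metrics for audit.

Evoked LFP amplitude: per pulse, |minimum within 5–100 ms post-pulse minus
the 50-ms pre-pulse baseline mean|; the reported amplitude is the mean over
all pulses but the first (the first response is systematically larger).
Response and baseline windows are configurable; they are not recorded in the
original protocol.

## Histology estimators

**Plaque density** = plaques / tissue volume, volume integrated column-wise
between the stack bottom and a brain-surface model: piecewise-linear
interpolation over a Delaunay triangulation of 50–200 labelled points,
extended by nearest-point values outside the convex hull.  Plaque centres
inside the field are counted; partially visible edge plaques are counted by
their centres.  The estimator accepts manual centre lists (matching the
original manual counts); a blob detector is provided for synthetic scenes.

**Fibrinogen profiles**: the fibrinogen signal of a DAB/cresyl-violet
bright-field section is the inverted blue channel of the sRGB image.  A band
from 3 µm inside to 11 µm outside a traced vessel boundary is resampled
bilinearly (0.5 µm across, 1 µm along) onto an (L, x) rectangle; pixels
inside a nucleus mask (red channel below threshold, default 140) are dropped;
fully masked columns are interpolated from neighbours; the band is averaged
along L.  Per animal, profiles are averaged weighted by traced length L
(each wall side is its own profile with weight L), then normalised: profile
minimum ↦ 0, mean of the last 10 points ↦ 1, so perivascular enrichment
appears as values above 1.  An exponential `A·exp(−x/λ)` fitted to the
above-background tail recovers the generator's decay length within 20%.

**Pericyte density** = pericyte somata per mm of capillary (vessels < 10 µm
only), pooled per animal as Σn/ΣL — again totals before division.

## Group statistics

All tests run on one value per mouse (averages within animals are the
independent unit).  Each group is Shapiro–Wilk-tested at α = 0.05; if both
pass, the classical equal-variance two-sample t-test is used (Welch behind a
flag), otherwise the two-sided Mann–Whitney U — exact when the combined
sample is ≤ 20 without ties (verified against full label-assignment
enumeration), normal approximation with tie correction otherwise.  The
per-group gate is a choice (a pooled-residual gate is available); summaries
follow the test (mean ± SEM vs median with quartiles).  No multiple-testing
correction and no outlier removal; reports annotate the number of tests run.
Age effects use OLS `value ~ age` (pooled slope) and `value ~ age × group`
(the interaction term tests slope difference).

Calibration, measured by simulation: on null cohorts (equal lognormal group
parameters, 20% CV, n = 8/8) the gated procedure rejects at a rate inside
the binomial 95% CI of 0.05 over 200 cohorts; a 2× difference in true
leakage ratio at 20% between-mouse CV is detected in ≥ 80% of 200 cohorts
when each mouse's ratio is measured through the full imaging pipeline.

## The synthetic generators: what they emulate, and what not

All generators are pure functions of parameters and a single integer seed
(NumPy PCG64; sub-streams derived per mouse/stack), so every dataset is
reproducible bit for bit.  Between-mouse variation is lognormal —
positive-valued physiological quantities — parameterised by mean and CV.

Emulated: punctae as a Poisson process on the lateral tube surface at
per-type densities (arterioles about 3× capillaries/venules by default;
absolute scales are order-of-magnitude choices, the estimators are
scale-free); plaques as a 3-D Poisson process at 2,200/mm³; blood/parenchyma
tracer kinetics as above; stimulus-locked dilation on the 40/15/75-s
paradigm with a ≥ 5-frame plateau so window-5 smoothing preserves the peak;
DAB sections as a step plus exponential perivascular enrichment with
compact-support nuclei; LFP trains as one alpha-function deflection per
pulse (30 pulses at 2 Hz, 20 kHz sampling).

Not emulated — and therefore not demonstrated by passing tests: vascular
branching topology (vessels are straight tubes), scattering and depth
attenuation, detector noise statistics beyond additive Gaussian, motion
beyond rigid lateral drift, and real stain variability.  Recovery on these
scenes shows the estimators are correct and unbiased under their stated
assumptions, not that the assumptions hold in any particular animal.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by construction: scenes of
tens of µm at 0.3–0.5 µm voxels for detection studies, count-level (unrendered)
truth for Poisson studies at the full 250 × 250 × 150 µm geometry, leakage
movies of 128 × 128 × 6 planes × 16 frames (48 × 48 µm for cohort studies),
NVC movies of 96 × 64 px × 3 planes × 88 frames, 200 cohorts for calibration
and power.  Tolerances: exact formula layers at 1e-12 relative; closed-form
recoveries at the quadrature-bias level (0.5%); stochastic recoveries at
3 SE or the stated absolute bands.  Ties in the diameter threshold are
broken upward (`>=`); the running average shrinks at trajectory edges; the
surface integral uses a 1-µm column grid (5 µm where only totals matter).
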