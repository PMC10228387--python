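# nvuq — neurovascular-unit quantification

`nvuq` is a Python library and CLI for quantifying blood–brain-barrier (BBB)
transport and neurovascular function from in-vivo two-photon microscopy and
bright-field histology, aimed at labs studying BBB integrity and
neurovascular coupling in mouse models (e.g. amyloidosis models such as
5xFAD against wild-type controls).  It packages the full analysis chain —
image I/O, drift correction, ROI tracing, thresholding, densities, group
statistics — together with seeded synthetic-data generators with known
ground truth, so every stage can be validated by parameter recovery without
any external data.

## What it computes

**Vesicular transcytosis (AMT).**  Albumin-tracer punctae per unit vessel
surface, per vessel type and overall.  For segment *i* of type *typ*:
*a*<sub>i</sub> = π·d·l, ρ<sub>typ</sub> = Σn / Σa (pooled totals, not a mean
of ratios).  Punctae come from annotated counts, from automated 3-D spot
detection in a 1-µm shell around the vessel wall, or from segmentation masks
(area = pixels × pixel² × π, count = connected components); mask quality is
scored by the Dice coefficient 2Σ(ŷ·y)/(Σŷ+Σy).

**Paracellular leakage.**  Small-tracer leakage as the ratio of the area
under the parenchymal intensity–time curve to the area under the blood
curve, per cortical depth (20/40/80 µm below an interpolated brain surface),
after rigid lateral drift correction.  The normalisation cancels injection
and detector gain differences.

**Neurovascular coupling.**  Vessel diameter over time from FWHM-style
thresholding of a cross profile; baseline D₀ (pre-stimulus mean), peak Dₚ
(max of the 5-point running average within 40 s of onset), relative dilation
(Dₚ−D₀)/D₀, with quantified exclusion rules for unstable baselines and
spontaneous pre-stimulus dilation; evoked LFP negative-peak amplitudes
(mean over all pulses but the first).

**Histology.**  Amyloid-plaque density (count / volume under a triangulated
brain-surface model); perivascular fibrinogen profiles (straightened
[−3, +11] µm band across the vessel wall, nucleus pixels masked,
length-weighted averaging, background-normalised); pericyte density per mm
of capillary.

**Group statistics.**  Per-mouse averaging, Shapiro–Wilk-gated choice
between Student's t and the exact Mann–Whitney U at α = 0.05, and
linear-regression age checks with a slope-difference (interaction) test.

## Worked example

Simulate a 45-min leakage recording with known permeability and a
stimulus-locked vessel movie with known dilation, then run both pipelines:

```python
import numpy as np
from nvuq import synth, leakage, nvc

stack, truth = synth.generate_leakage_timelapse(k_perm=1e-3, tau_blood=20.0, seed=1)
rois = leakage.default_rois(stack, truth, seed=1)
res = leakage.measure_leakage(stack, rois, mouse_id="m01")
print(f"expected AUC ratio (closed form): {truth.expected_ratio:.5f}")
for depth, ratio in sorted(res.ratio_by_depth.items()):
    print(f"depth {depth:3.0f} um: ratio = {ratio:.5f}  (n={res.n_rois_by_depth[depth]} ROIs)")

movie, _ = synth.generate_nvc_timelapse(synth.NvcTruth(d0_true=12.0, dilation_frac=0.2),
                                        noise_sd=10.0, seed=2)
win = nvc.StimulusWindow(onset_index=int(round(40.0 / movie.geometry.time_step)))
traj = nvc.extract_diameter_trajectory(movie, roi=(10, 0, 80, 64), window=win)
r = nvc.qc_exclude(traj)
print(f"D0 = {r.d0:.2f} um, Dp = {r.dp:.2f} um, "
      f"relative dilation = {r.rel_dilation:.3f}, excluded = {r.excluded}")
```

prints

```
expected AUC ratio (closed form): 0.03030
depth  20 um: ratio = 0.03021  (n=4 ROIs)
depth  40 um: ratio = 0.03021  (n=4 ROIs)
depth  80 um: ratio = 0.03021  (n=4 ROIs)
D0 = 12.00 um, Dp = 14.50 um, relative dilation = 0.208, excluded = False
```

The measured AUC ratios sit within 0.3% of the closed form (the residual is
trapezoid-rule bias on the 3-min sampling grid), and the recovered dilation
matches the programmed 0.2 to within pixel quantisation at 10% noise.

The same pipelines are available from the shell:

```bash
nvuq simulate leakage --seed 1 --out runs/leak
nvuq leakage --stack runs/leak/leakage.tif --rois runs/leak/rois.csv --out runs/leak/res
nvuq stats --table cohort.csv --measure leakage_ratio --out runs/stats
```

Every command takes `--seed`/`--out` (and `--config` where applicable),
writes a `run_manifest.json`, and is byte-identical on re-run with the same
inputs.

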