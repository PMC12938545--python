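# plugforge

Annotation-free simulation of airway **mucus plugs** in chest-CT-like
volumes, plus the lesion-level evaluation protocol used to score plug
detectors.

Mucus plugs — inspissated secretions occluding bronchial lumens — are
imaging biomarkers of disease burden in COPD, asthma, and cystic fibrosis,
but voxel-wise manual annotation is prohibitively slow (hours per scan) and
clinical datasets are dominated by tiny distal plugs. `plugforge`
implements a simulation pipeline that sidesteps annotation entirely: it
grows anatomically constrained synthetic plugs inside segmented airway
lumens and textures them by copying Hounsfield values from depth-matched
voxels of an adjacent pulmonary vessel, exploiting the fact that mucus
(~95 % water) and blood are nearly indistinguishable on non-contrast CT
(~30–50 HU). The package targets researchers building or benchmarking
airway-lesion segmentation models who need controllable, perfectly
labelled training data.

Because real segmented CT cohorts are private, the pipeline ships with a
procedural **phantom** generator that emits everything a real segmented
scan would provide: a CT-like HU volume, lung / airway-lumen / vessel
masks, and the airway centerline tree with per-point lumen radius.

## Method

For each plug, three phenotype parameters are sampled uniformly:

* target length `L ∈ [2, 20]` mm along the airway centerline,
* target occlusion ratio `q ∈ [0.35, 1.0]` (plugged ÷ lumen cross-sectional
  area, per one-voxel-thick section),
* eligible airway caliber `d ∈ [1, 20]` mm.

A seed voxel is drawn uniformly from the eligible lumen; constrained region
growing then expands a corridor of `⌊L/h⌋` sections around the seed
(`h` = voxel size), plugging `⌈q·n⌉` of each section's `n` lumen voxels in
order of in-plane distance from the seed's radial position
(mural-adherent; a centered variant is configurable). Growth never leaves
the lumen and never crosses a bifurcation; corridors truncate at branch
ends and at previously placed plugs, so a fixed density of 50 plugs/scan is
always realized on the default phantom.

Texture: with signed distance fields `SDF(x) < 0` inside a compartment,
each plug voxel `P_airway` is matched to a companion-vessel voxel
`P_vessel` with `SDF_vessel(P_vessel) ≈ SDF_airway(P_airway)` (nearest
available depth, random choice among ties, 0.5 mm tolerance), and the
vessel HU is copied in. Depth matching reproduces the radial
partial-volume profile of a real soft-tissue tube.

Evaluation follows the standard lesion-level protocol: a ground-truth
lesion is a **TP** if any predicted voxel overlaps it, a predicted lesion
overlapping nothing is an **FP**, sensitivity = TP/(TP+FN) with a Wilson
95 % CI, FP burden is reported per scan, everything stratified by length
bins (0,3), [3,6), [6,15), [15,∞) mm, plus voxel-level Dice
`D(A,B) = 2|A∩B|/(|A|+|B|)` and paired two-sided t-tests for model
comparison.

## Worked example

```python
import numpy as np
from plugforge import (PhantomSpec, generate_phantom, LumenMap,
                       populate_scan, transfer_scan)

model = generate_phantom(PhantomSpec(seed=0))     # 63 branches, ~727 mm centerline
lm = LumenMap(model)
plugs, labels = populate_scan(model, 50, rng=np.random.default_rng(1), lumen_map=lm)
ct, maps = transfer_scan(model, plugs, rng=np.random.default_rng(2))

lengths = [p.achieved_length_mm for p in plugs]
print(len(plugs), np.mean(lengths), ct.data[labels.data > 0].mean())
```

This prints `50` plugs with mean length `9.59` mm (sd 3.67, range
1.89–16.05 — lengths below the sampled 2 mm minimum are truncated plugs),
mean occlusion `0.73`, and mean plug attenuation `40.5` HU — the phantom's
vessel attenuation, confirming the transfer. `labels` is an instance-label
volume (plug *k* labelled *k*, background 0) that serves as perfect ground
truth.

The same pipeline is scriptable from the shell:

```bash
plugforge phantom  --out ph/ --n-cases 1 --seed 9
plugforge simulate --anatomy ph/ --n-plugs 50 --seed 9 --out sim/
plugforge build-dataset --in sim/ --out ds/ --seed 9     # 0.8 mm isotropic pairs
plugforge evaluate --pred pred.nii.gz --gt gt.nii.gz --out report.json
plugforge sweep    --out sweep.csv                       # 10..100 plugs/scan
```

## Limitations

Phantoms are straight-tube dichotomous trees — no lobar anatomy, cardiac
structures, or scanner-specific noise. The evaluation module scores any
predicted segmentation, but no network training is included; see
`docs/methods.md` for model details, parameter defaults, and what phantom
results do and do not imply about real CT.
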