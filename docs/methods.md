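# Methods

## Scope and model

`plugforge` simulates airway mucus plugs in CT-like volumes and scores
plug detections at the lesion level. The simulation rests on two
anatomical facts: plugs occur only inside airway lumens, and on
non-contrast CT their attenuation is nearly identical to that of pulmonary
vessels (both are mostly water, ~30–50 HU). The pipeline therefore (1)
grows a geometrically constrained plug inside the lumen and (2) borrows
its texture from an adjacent vessel at matched anatomical depth.

All geometry is computed in millimetres; arrays are indexed (z, y, x) with
per-axis spacing, 0-based voxel indices, and `world = origin + index ·
spacing`.

## Phantom anatomies

Real segmented cohorts are private, so study conditions are realized on
procedural phantoms. A phantom is a dichotomous tree of straight airway
segments: generation-g lumen radius `r_g = r_0 · τ_r^g` and segment length
`ℓ_g = ℓ_0 · τ_ℓ^g`. Children leave the parent at ± the half-angle inside
a bifurcation plane that rotates ~90° per generation (with ±12° random
azimuthal jitter) plus a bias along +z, mimicking the descending course of
the bronchial tree. Each branch carries one companion vessel: a parallel
tube of radius `0.7 ×` the airway outer radius at 10 mm center-to-center
offset, its azimuth searched so it stays inside the volume and clear of
every lumen (bronchoarterial pairing). Rasterization paints parenchyma
(−850 HU), wall (−200 HU), vessel (+40 HU), lumen (−1000 HU), then adds
Gaussian HU noise (σ = 15 HU); masks are noise-free by construction.

Defaults (the package's study conditions, chosen once):

| parameter | default | why |
|---|---|---|
| volume | 112³ voxels @ 1.0 mm | thin-slice-CT-like resolution; fits a depth-5 tree |
| tree depth | 5 (63 branches) | total centerline ≈ 730 mm |
| root lumen radius | 4.0 mm, taper 0.8 | calibers 8.0 → 2.6 mm diameter, inside the 1–20 mm eligibility range; deepest radius 1.31 mm stays resolvable at 1 mm voxels |
| segment length | 22 mm, taper 0.85 | see capacity note below |
| wall thickness | 1.0 mm | typical proximal airway wall |
| vessel HU | +40 | mid-range soft-tissue/blood attenuation |

Capacity note: 50 plugs/scan with mean target length ~11 mm demand
~550 mm of corridor; the default tree's ~730 mm guarantees the density is
reached exactly on every scan (verified over the whole 83-scan cohort).

## Plug growth

Phenotypes sample length `L ~ U[2, 20]` mm, occlusion `q ~ U[0.35, 1]`,
with the eligible-caliber interval [1, 20] mm passed through. Seeds are
uniform over eligible, unoccupied lumen voxels.

The lumen is parametrized once per scan (`LumenMap`): every lumen voxel
gets its nearest branch, arc-length coordinate `s`, radial offset vector,
and section bin `⌊s/h⌋` (`h` = smallest voxel dimension; sections are
one-voxel slabs along the centerline). Growth is deterministic given
(anatomy, seed, phenotype): a window of `⌊L/h⌋` sections expands
alternately left/right from the seed; within each section the plugged set
accretes voxels in order of in-plane distance from the seed's radial
position until `⌈q·n⌉` of the section's `n` voxels are plugged. The final
voxel set is the 26-connected component containing the seed; if pruning
ever drops a section below `q`, that section is trimmed and the component
recomputed, so the per-section occlusion floor holds unconditionally.

Design choices where the protocol is open:

* **Mural-adherent growth** (anchor = seed's radial offset) is the
  default because mucus lines airway walls; `mural_adherent=False` centres
  the plug on the axis instead.
* **No bifurcation crossing**: a plug lives on one branch, keeping
  "length along the centerline" single-valued.
* **Truncation**: corridors clip at branch ends *and* at previously
  placed plugs (flagged on the plug). This extends the short-branch
  truncation rule and is what makes an exact fixed density achievable on
  compact anatomies; it also produces a tail of achieved lengths below
  the 2 mm sampling minimum, as seen in realistic synthetic cohorts.
* **Occlusion is enforced per section**, with the mean over covered
  sections reported, rather than as a single averaged ratio.
* Plug disjointness is guaranteed structurally: each (branch, section)
  bin is owned by at most one plug.
* A saturated anatomy yields fewer plugs with a warning instead of an
  error, so small test phantoms stay usable.
* Reported plug length is `(s_max − s_min) + h`, so a single-voxel plug
  has one voxel of extent and every plug falls into a length bin.

## Signed distance fields and intensity transfer

Signed distances are computed with the exact Euclidean distance transform
on the mask and its complement (`sdf = edt(¬M) − edt(M)`), giving exact
sign antisymmetry and a zero level set on the inside/outside interface.
This is an exact O(N) computation of the same field a fast-marching
eikonal solver approximates; tests verify it against an exhaustive
nearest-opposite-voxel search (agreement within one voxel diagonal) and
check `|∇SDF| ≈ 1` away from boundary and medial axis. Whether distances
should be geodesic within the lung rather than Euclidean is not decidable
from the protocol; Euclidean is used and component connectivity is fixed
at 26 throughout.

For each plug, a **companion vessel** is the connected vessel component
closest to the host branch among those within 20 mm whose caliber (twice
the max inscribed-sphere radius) is within ±50 % of the airway's
("comparable caliber" made concrete). Each plug voxel is then matched to
the companion voxel whose signed depth is *nearest* its own, drawing
uniformly among exact ties, and the vessel HU is copied in. Matches whose
best residual exceeds 0.5 mm — an airway deeper than the vessel is thick —
keep the nearest-depth pool but are flagged as fallbacks in the
`CorrespondenceMap` (exportable to CSV for QC). Nearest-depth matching
matters: sampling uniformly across a ±0.5 mm window would over-weight
shallow vessel shells (larger area) and bias plugs darker by ~100 HU.

The transfer's contract is conditional: at a given matched depth, plug HU
is an unbiased draw from the companion's HU pool at that depth.
`depth_transfer_audit` verifies exactly this — per matched-depth class, a
two-sample KS distance bounded by the α = 0.01 critical value
`1.63·√((n+m)/nm)`. Marginal 1 mm depth strata are additionally compared
via binned means with a 75 HU bound (profile slope ~300 HU/mm at the wall
× half the ~0.5 mm depth quantization of a 1 mm grid); marginal KS across
a stratum is *not* expected to vanish because airway and vessel shell
areas weight the depth classes differently.

Acquisition-realism augmentation (Gaussian smoothing σ ∈ [0, 0.8] mm,
noise σ ∈ [0, 10] HU, drawn per call) is applied at patch-extraction time,
not baked into saved volumes, matching the dynamic-augmentation intent.

## Dataset construction

Images and labels are resampled to exactly 0.8 mm isotropic spacing
(trilinear / nearest-neighbor via SimpleITK; output size rounds
`extent/0.8`, preserving world extent within one voxel). Instance labels
collapse to binary for export (instance ids stay in the per-plug CSV).
Balanced batches draw positive patches centered on plug voxels and
negative patches from air-containing, plug-free positions at a configured
ratio (default 1:1; the protocol fixes the *existence* of a ratio but
never prints its value, and patch size — default 96³ at 0.8 mm, enough to
contain a 20 mm plug with context — is likewise unstated, so both are
explicit configuration, not claims).

## Evaluation

`dice` defines the both-empty case as 1.0 (agreement on absence; the
formula is 0/0 there). `match_lesions` instances binary volumes with
26-connectivity; one prediction overlapping k ground-truth lesions credits
all k and counts itself matched once (lesion-recall semantics).
Sensitivity CIs use the Wilson score interval (Clopper–Pearson via
config); exact-coverage computation over the binomial pmf shows ≥ 93 %
coverage at the proportions and sample sizes in play. False positives are
binned by the predicted lesion's own length (FPs have no ground-truth
length) and each FP is assigned to exactly one bin. An evaluation set with
no ground-truth lesions is flagged `sensitivity_defined=False` rather than
scored 0. `paired_compare` is the classical paired two-sided t-test with
explicit degenerate results: identical vectors → t = 0, p = 1;
constant nonzero differences → p = 0, flagged "zero-variance"; n < 2 →
"insufficient-n".

## Density sweep

`run_density_sweep` re-runs population → transfer → detection → scoring at
10–100 plugs/scan (step 10). Since no trained network ships with the
package, detectors are pluggable callbacks; the built-in perfect oracle
and a small-lesion-blind noisy oracle exercise the loop end-to-end on a
CPU. Only the curve *machinery* is reproduced — absolute sensitivity/FP
values at each density require real CT and GPU training.

## What phantom results do and do not show

Phantoms have exact masks, straight branches, homogeneous compartments,
and stationary Gaussian noise. Passing tests therefore demonstrate the
*algorithmic* contracts — constraint honoring, disjointness, depth-matched
texture transfer, metric arithmetic, determinism — not clinical
performance. Real airways curve and taper continuously, segmentations are
imperfect (especially distally, which bounds where plugs can be seeded),
and scanner noise is neither white nor stationary. Clinical claims require
real annotated CT.

## Numerical conventions

Problem sizes used by the test suite and acceptance script: cohort runs
use the default 112³ phantom; unit tests use a 72³ depth-2 variant.
Determinism is byte-level: a fixed seed reproduces identical NIfTI
(gzip mtime pinned to 0), CSV, and JSON outputs. All randomness flows
through `numpy.random.Generator` objects seeded from a single entry seed;
derived seeds stay below 2³¹.
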