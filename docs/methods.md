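# Methods

`sparsecbct` simulates a linac-mounted kilovoltage cone-beam CT (CBCT)
system and asks a concrete image-guidance question: if the reconstruction
uses only every *n*-th projection frame — delivering roughly 1/*n* of the
imaging dose — what happens to image quality and, more importantly, to
automatic rigid registration accuracy? This note records the models, the
defaults and the reasoning behind every genuinely open design choice.

## Scanner model

The geometry is an XVI-class onboard imager: point source at 1000 mm from
the isocenter, flat panel at 1536 mm, 512×512 pixels of 0.8 mm, rotating
360° (full fan) or 200° (half fan). Site acquisition presets (kVp, mA,
pulse length, nominal projection count, arc, collimator) are tabulated for
the seven study subjects (QA phantom, three rigid anthropomorphic sites,
three patient-like sites).

**Desk scale.** Simulations run at reduced *sampling*, never reduced
physics: `scale_factor` s multiplies detector pixel counts by s and the
pitch by 1/s, so distances, field of view, fan angle and object sizes stay
in physical millimetres. The default study scale is s = 0.5 (256² panel,
1.6 mm pitch) with 160³ voxels of 1.25 mm and 240 full-scan views (240 is
divisible by every scheme divisor 2…6). The QA runs keep the full 0.8 mm
pitch (cropped to 288 rows) because the resolution test needs ~0.5 mm
sampling at the isocenter, and use 360 views.

## Phantoms

Phantoms are ordered lists of analytic primitives (ellipsoids, z-axis
cylinders, boxes) with attenuation μ per mm at a nominal ~60 keV: water
0.020, soft tissue 0.019, cortical bone 0.048, lung 0.004, air 0.
Voxelization samples primitive membership at voxel centers in painter's
order (last primitive wins); optional 2× supersampling averages
partial-volume voxels. Because the description stays analytic, exact
chord-length line integrals through the same primitives are available —
used both as an independent oracle for the ray-marching projector and as
the projection route for the QA phantom, whose 0.55–0.71 mm line-pair bars
no practical voxel grid can carry.

* **QA phantom** — 20 cm water cylinder with three axial modules: a
  resolution module with radial bar groups at 1–9 lp/cm (bar width
  1/(2f) cm, bone-like bars), a low-contrast module with polystyrene and
  LDPE analogue inserts, and a uniform module. Insert attenuations follow
  the real sensitometry materials (−35 HU and −100 HU, i.e. μ 0.0193 and
  0.0180): each sits within a few percent of water, and the insert-insert
  contrast (~6.5 %) is large enough that the low-contrast-visibility
  denominator is not itself noise-dominated.
* **Rigid head / pelvis** — soft-tissue body, bone shells and cores,
  internal air. The skull carries deliberately rich structure (teeth row,
  mastoids, occipital bump, nasal septum, 30 seeded surface bumps): a
  perfectly smooth parametric shell makes rotation nearly unobservable
  from edges and lets small edge-localization biases act coherently, which
  no real skeleton does. The pelvis carries seeded soft-tissue texture and
  bowel-gas pockets; gas placement has its own seed so two builds of the
  same patient can differ in bowel contents, as planning CT and
  treatment-day scans do.
* **Thorax** — a *deliberately* near-periodic chain of vertebrae
  (default 9 at 25 mm pitch, matching 2.5 cm slab spacing) with rib pairs
  at every level: the chamfer cost then has secondary minima one vertebra
  superior/inferior, which is the failure mode under large misalignment.
* **Nonrigid pair** — the same pelvis twice: the treatment-day copy is
  smoothly deformed (seeded Gaussian-filtered displacement field, C¹,
  tapered to zero at an ellipsoidal mask boundary, amplitude scale 12 mm
  giving ≤ ~6 mm actual displacement) and has independently placed gas.
  The rigid component of the ground truth is the identity, so
  "registration error" stays well defined.

## Forward projection and noise

The generic projector marches each source→pixel ray in uniform steps of
half the smallest voxel spacing, accumulating trilinear samples. Interior
rays agree with the analytic chord oracle to better than 1 % (95th
percentile). The detector is ideal — no blur, lag or glare — so the
resolution ceiling is set by detector pitch, voxelization and the ramp
filter alone; this is a stated limitation, not an oversight.

Noise is photon counting: counts ~ Poisson(i0·e^(−p)) per pixel, clipped
to ≥ 1, re-logged. The fluence is one calibrated constant,
`I0_PHOTONS_PER_MAS = 1e5` photons per pixel per mAs, scaled by each
preset's mA×ms per frame (head 0.1 mAs → 10⁴; QA phantom 1.2 mAs →
1.2×10⁵). The value was fixed once against the QA acceptance behaviour
(uniformity comfortably inside 2 %, SD clearly noise- rather than
ripple-dominated) and is in the plausible range for flat-panel detectors.
Scatter, beam hardening, bow-tie filtration and detector calibration
artifacts (rings) are all outside the model.

## FDK reconstruction

Standard Feldkamp filtered backprojection on the virtual detector through
the isocenter: cosine preweighting D/√(D²+u²+v²); redundancy weighting
(uniform ½ for 360° arcs, smooth Parker weights for short scans of at
least 180° + fan, with the half-overscan angle taken from the arc span);
row-wise convolution with the band-limited discrete Ram-Lak kernel
(Shepp-Logan optional; Ram-Lak is the default so no apodization confounds
the resolution test), zero-padded to ≥ 2× width; voxel-driven
backprojection with SID²/L² magnification weighting. The per-view angular
weight is the *retained* spacing (arc span / retained views), so sparse
schemes reconstruct to the same scale as the full scan — measured ROI
means agree within 3 ‰ across schemes. The truncated discrete kernel keeps
a small DC residual (∝ 1/n); forcing the DC bin to zero would bias the
reconstruction scale and is not done. Voxels outside the fully-sampled
field-of-view cylinder are zeroed.

## Rigid registration

Both console modes are implemented over a 6-DOF transform (fixed-frame
Euler Z·Y·X about the isocenter, then translation; moving→fixed).

**Bone mode** is chamfer matching: edge points of the moving image against
the exact Euclidean distance transform of the fixed image's edge set.
Three implementation details matter far more than the optimizer:

1. *Sub-voxel edge localization.* Edge voxels (gradient magnitude of the
   1-voxel-Gaussian-smoothed volume ≥ 0.007 μ per voxel) are refined along
   the gradient direction by a parabolic fit of the gradient magnitude.
   Without this, both point set and distance map are locked to the voxel
   lattice and the cost develops spurious minima at integer-voxel offsets
   (~1 mm errors at fractional shifts).
2. *Edge gate at 0.015 μ* (~75 % of soft tissue), not at a bone-level
   threshold: the gate keeps bone-tissue, tissue-air and skin-air
   interfaces. A bone-level gate truncates thin or partially averaged
   bone asymmetrically and was measured to bias recovered rotations by up
   to ~0.5°.
3. *Edges are always extracted at full resolution*; the multiresolution
   pyramid (×4/×2/×1) coarsens only the distance-map grid and the point
   budget. Block-mean image pyramids destroy thin bone shells at coarse
   levels and steered the optimizer toward the identity.

**Grey-value mode** is negative normalized cross-correlation over a clip
box (default the central 85 % of the grid; studies may pass an absolute
target-centered box, as console users draw one).

The optimizer is Powell's method (derivative-free line searches over the
six parameters, scaled 1 mm ≙ 1°), coarse-to-fine, deterministic — no
restarts, so repeat-to-repeat scatter comes only from acquisition noise.
On 32³ fixtures it lands within one grid step of an exhaustive ±3-voxel
translation search in both modes.

## The accuracy protocol

One noiseless acquisition is simulated per study; each repeat applies an
independent Poisson realization (seeds spawned from the master seed via
`numpy.random.SeedSequence` spawn keys); every 1/n scheme is reconstructed
from nested frame subsets of the *same* noisy acquisition, mirroring the
single-scan re-reconstruction design and making scheme comparisons paired.
A gold-standard registration of the untransformed reference against the
full-scheme reconstruction is subtracted componentwise from every result
(for the small offsets involved, componentwise subtraction and transform
composition differ at second order). Conditions — per-axis translations of
2/5/20 mm, per-axis rotations of 3°/10°, and the two combinations — are
applied by resampling the reference volume (cubic interpolation; trilinear
resampling blurs edges enough to bias rotations). Errors are the
translation-vector norm and the maximum per-axis rotation residual against
the exact Euler parameters of the inverse condition. A cell is flagged as
a local minimum when its mean error exceeds the 2 mm / 3° clinical
criteria.

Measured at desk scale (bone mode, head phantom, 3 repeats): worst mean
translation error ≈ 0.04 mm and worst rotation error ≈ 0.13° over all 24
scheme×condition cells, with no trend in n — the sub-millimetre headline
bound holds with a wide margin, and repeat scatter is far below 0.1 mm/0.1°.

## Dose arithmetic

A 1/n scan fires 1/n of the pulses, so surface dose scales exactly as
full/n from the published full-scan values (brain 0.22, lung 4.6, prostate
2.4 cGy); percentages are against a 200 cGy fraction by default.

## Known limitations

* The low-contrast-visibility statistic, 5.5·mean(SD)/|ΔMean|, is a plain
  fraction and is O(1) for any physically plausible noise level; the 2 %
  console specification evidently refers to a different display scale.
  The package reports the fraction and the literal <0.02 pass flag (false
  at every scheme); the scientifically meaningful behaviour — LCV grows
  monotonically as projections are removed, driven by √n noise growth
  over flat means — reproduces robustly.
* The resolution score at desk scale reaches 9 lp/cm at every scheme
  (≥ 7 everywhere): with an ideal detector and analytic projections, only
  pitch and the ramp filter limit resolution, confirming (more strongly
  than a real detector would) that subsampling does not degrade spatial
  resolution.
* The thoracic large-misalignment trap reproduces at *every* scheme, as
  reported for periodic anatomy. The sparse-only trapping of nonrigid
  sites does **not** reproduce in this model, and the nonrigid study says
  so rather than hiding it: additive projection noise rescales the
  NCC cost surface without moving its optimum, the chamfer edge sets
  barely change between full and 1/6 at the calibrated fluence, and the
  streaks produced by realistic bone contrast in a scatter-free
  monochromatic simulation are too weak to corrupt either cost surface.
  Reproducing that failure mode would need the real-scanner nonidealities
  (scatter, beam hardening, detector lag) that are outside this model's
  scope, and/or a narrow-capture optimizer.
* Timing comparisons between modes or schemes are hardware-bound and are
  not modelled.
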