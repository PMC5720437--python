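# sparsecbct

Simulation pipeline for studying **projection-number reduction in
kilovoltage cone-beam CT (CBCT)** for image-guided radiotherapy.

Daily CBCT guidance adds real dose to patients. One way to cut it is to
reconstruct from only every *n*-th projection frame ("1/n schemes"),
which delivers ~1/n of the imaging dose and shortens the scan. The
question that matters clinically is not how pretty the sparse image is,
but whether **automatic rigid registration** — the step that actually
positions the patient — still lands within clinical tolerance
(2 mm / 3°). This package reproduces that whole study chain in
simulation, for medical physicists and image-guidance researchers:

1. **Phantoms** (`phantoms`) — analytic, seeded digital subjects: a
   Catphan-style QA cylinder (line-pair gauge, polystyrene/LDPE inserts,
   uniform module), rigid head and pelvis anatomies, a deliberately
   near-periodic thorax, and a nonrigid "patient" pair related by a
   smooth deformation.
2. **Acquisition** (`geometry`, `projector`) — XVI-class scanner geometry
   (SID 1000 mm, SDD 1536 mm, full-fan 360° / half-fan 200° arcs), site
   technique presets, cone-beam line integrals (ray-marched, or exact
   chords through the analytic primitives), and photon-counting noise
   scaled by each preset's mAs.
3. **Reconstruction** (`fdk`) — Feldkamp filtered backprojection with
   cosine preweighting, Parker short-scan weights, band-limited Ram-Lak /
   Shepp-Logan kernels, and per-view angular weights equal to the
   *retained* spacing, so XVI-1/n reconstructions are not dimmer than
   XVI-full.
4. **Image quality** (`quality`) — resolvable line pairs per cm,
   low-contrast visibility `LCV = 5.5·mean(SD)/|ΔMean|`, and uniformity
   `(max(mean) − min(mean))/max(mean)` over four 1×1 cm probe windows.
5. **Registration** (`registration`) — the two console modes: "bone"
   (Borgefors-style chamfer matching of sub-voxel edge points against a
   Euclidean distance transform) and "grey value" (normalized
   cross-correlation over a clip box), both minimized by deterministic
   coarse-to-fine Powell search over 6 rigid parameters.
6. **Protocol** (`protocol`) — gold-standard baselining against the
   full-scheme reconstruction, a battery of known translations/rotations
   applied to the reference, repeats over independent noise seeds,
   local-minimum flagging against the 2 mm / 3° criteria, and the
   dose-scaling arithmetic (a 1/4 scan gives 1/4 of the 0.22 / 4.6 /
   2.4 cGy full-scan surface dose for brain / lung / prostate).

## Worked example

Run a small registration-accuracy study from Python (a few minutes on one
CPU; the CLI equivalent is `sparsecbct evaluate`):

```python
from sparsecbct.phantoms import build_rigid_anatomy
from sparsecbct.protocol import run_protocol

head = build_rigid_anatomy("head", seed=1)
records = run_protocol(
    head, preset_site="R-H&N", schemes=(1, 2, 3, 4, 5, 6),
    conditions=("T=2mm", "T=5mm", "R=3deg", "T=2mm,R=3deg"),
    modes=("bone",), repeats=3, master_seed=20260901, n_views=240,
)
print(records[["scheme", "condition",
               "mean_translation_error_mm",
               "mean_rotation_error_deg"]].to_string(index=False))
print("worst translation error:",
      round(records.mean_translation_error_mm.max(), 3), "mm")
print("worst rotation error:",
      round(records.mean_rotation_error_deg.max(), 3), "deg")
```

Output (abbreviated):

```
  scheme    condition  mean_translation_error_mm  mean_rotation_error_deg
XVI-full        T=2mm                   0.037332                 0.124765
XVI-full        T=5mm                   0.008218                 0.002430
XVI-full       R=3deg                   0.020193                 0.089062
...
 XVI-1/6        T=5mm                   0.013508                 0.014306
 XVI-1/6       R=3deg                   0.019165                 0.087265
 XVI-1/6 T=2mm,R=3deg                   0.020567                 0.089476
worst translation error: 0.037 mm
worst rotation error: 0.125 deg
```

Each row is one scheme × applied-transform cell: the mean (over noise
repeats) of the translation-vector error and the maximum per-axis
rotation error after gold-standard subtraction. The headline result: even
at one-sixth of the projections, bone-mode registration of a rigid
anatomy stays within 0.7 mm and 0.3° — dose can drop ~6× without losing
automatic-positioning accuracy. The same pipeline shows the failure
modes: a 10° misalignment on the periodic thorax traps the optimizer in a
wrong-vertebra minimum at *every* scheme (see
`protocol.run_thorax_study`).

CLI stages compose the same way:

```bash
sparsecbct phantom --kind head --seed 1 -o head.nii.gz
sparsecbct project --volume head.nii.gz --preset R-H&N --views 240 \
    --noise-seed 7 -o stack.h5
sparsecbct reconstruct --stack stack.h5 --scheme 1/4 -o recon.nii.gz
sparsecbct register --fixed recon.nii.gz --moving head.nii.gz \
    --mode bone -o result.json
sparsecbct qa --seed 7 -o qa_report.csv
```

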