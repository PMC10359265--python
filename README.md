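# bonemorph

Automated clinical bone measurements — torsional, angular and linear — of
the **pelvis, femur and tibia/fibula** from 3D surface meshes, plus the
cohort statistics used to describe paediatric skeletal growth (per-age and
per-height group summaries, growth regression, two-way ANOVA by age/height
and sex).

## Who this is for

Researchers and clinicians working with 3D bone reconstructions (e.g. from
CT segmentations fitted with a corresponded template mesh) who need
reproducible, rater-free measurements of rotational profile and limb
alignment in growing skeletons: femoral anteversion, tibial torsion,
neck-shaft angle, mLDFA/mMPTA, and the standard linear dimensions of the
pelvis and lower-limb long bones.

## The measurements

Each bone is placed in an anatomical frame (x anterior, y superior,
z lateral, in the spirit of the International Society of Biomechanics
conventions) built from landmarks resolved by **nodal correspondence**: a
JSON registry maps anatomical names to template node indices, so
landmarking is automatic on any mesh that shares the template's vertex
ordering. Primitive fits supply the geometric axes:

* a **sphere** is fitted to the femoral head (and to each acetabulum) by
  the analytic linearised least squares — exact on noise-free spheres;
* **cylinders** are fitted to the femoral neck, shaft and condyles and the
  tibial condyles by nonlinear least squares over the axis direction, with
  the axis position and radius recovered analytically per direction.

The seven angles (degrees):

| name | definition |
|---|---|
| AA | transverse-plane angle of the femoral neck axis (head centre − neck cylinder centre) vs the posterior condylar axis; + = anteversion |
| NSA | 3D angle between the neck axis and the femoral shaft axis |
| mLDFA | frontal-plane lateral angle between the femoral mechanical axis and the knee joint line |
| BA | frontal-plane angle between the perpendicular of the knee axis and the shaft axis |
| TT | transverse-plane angle between the posterior tibial condylar axis and the malleolar axis; + = external |
| mMPTA | frontal-plane medial angle between the tibial mechanical axis and the tibial knee axis |
| RP | rotational profile, TT − AA of the same limb |

and eleven lengths (cm): ASIS width, PSIS width, pelvis depth, hip joint
centre distance, hip joint diameter, femoral head diameter, femoral
length, epicondylar width, condylar width, tibial length, malleolar width.
Left bones are mirrored across the sagittal plane before measurement so
signs are comparable across sides.

Because cohort imaging data cannot ship with a library, validation is
**closed-loop on synthetic parametric bones**: stylised primitive
assemblies whose construction parameters *are* the measurement definitions
(see `bonemorph.synthetic`), plus simulated cohorts with planted growth
slopes and sex effects for the statistics layer.

## Worked example

Generate a synthetic right femur with 20° anteversion, a 135° neck-shaft
angle, a 9° bicondylar angle and 0.05 cm surface noise, then measure it:

```python
from bonemorph import FemurSpec, make_femur, measure_bone

mesh, registry, truth = make_femur(
    FemurSpec(anteversion=20.0, neck_shaft=135.0, bicondylar=9.0,
              joint_line_tilt=3.0, femoral_length=30.0, noise_sd=0.05, seed=42))
record = measure_bone(mesh, registry, case_id="demo", side="R")
for name, value in record.values.items():
    print(f"{name:22s} {value:8.2f}   (construction {truth.values[name]:.1f})")
```

prints

```
anteversion_angle         19.87   (construction 20.0)
neck_shaft_angle         134.99   (construction 135.0)
mldfa                     86.87   (construction 87.0)
bicondylar_angle           9.14   (construction 9.0)
femoral_head_diameter      3.00   (construction 3.0)
femoral_length            29.98   (construction 30.0)
epicondylar_width          6.02   (construction 6.0)
```

i.e. every angle is recovered within a fraction of a degree and every
length within a fraction of a percent despite the added surface noise.

The same workflow runs from the shell:

```bash
bonemorph synth spec.yaml -o synth_out        # meshes + registries + cohort
bonemorph measure synth_out/manifest.csv -o out   # measurement CSV
bonemorph stats out/measurements.csv -o reports   # summaries, regression, ANOVA
bonemorph validate measurements out/measurements.csv
```

`stats` writes `summary.csv` (per category × sex: n, mean, SD),
`regression.csv` (slope, intercept, Pearson R, p per measurement ×
covariate) and `anova.csv`/`anova.json` (Type II two-way ANOVA effects
plus per-category Welch sex comparisons and the detected sex-divergence
age).

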