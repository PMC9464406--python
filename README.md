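# femaw

**Femoral anteversion morphometry via the anterior wall of the greater
trochanter.**

The femoral anteversion angle (FA) — the axial-plane angle between the
femoral neck axis and the posterior condylar line — matters in proximal
femoral surgery (rotational osteotomy, fixation of neck fractures and
slipped capital femoral epiphysis), but measuring it properly requires CT
of the whole femur, which is not always available. The anterior wall of
the greater trochanter (GT) is directly visible intraoperatively, and its
obliquity turns out to track anteversion: define the **AW angle** as the
sagittal-view angle between the femoral shaft axis and the line tangential
to the anterior wall of a simulated GT osteotomy cut, and FA can be
predicted linearly from AW and sex.

`femaw` is a reusable implementation of that measurement-and-prediction
pipeline for people who work with 3-D bone surface models:

* **`femaw.phantom`** — parametric proximal-femur phantoms (spherical
  head, waisted neck, cylindrical shaft, GT block with an exactly planar
  anterior wall, posterior condylar bosses) whose FA, neck-shaft angle
  (NSA) and AW angle are known in closed form. They stand in for CT
  reconstructions, which cannot be redistributed.
* **`femaw.morphometry`** — the measurement pipeline: least-squares sphere
  fit of the head, iterative narrowest-neck-section search, medullary
  shaft axis from two transverse canal centres, simulated GT cut (entry
  5 mm distal to the lateral ridge, tilted until the resected cap is
  10 mm thick), anterior-wall tangent line, and the three projected
  angles (FA axial, NSA anteroposterior, AW sagittal/ISB).
* **`femaw.cohort`** — a generative cohort simulator
  (`FA = 4.330 + 0.744·AW − 4.998·male + ε`, AW normal within sex)
  calibrated to the published sex-specific marginals, plus a
  repeated-observer generator with closed-form variance components for
  ICC targets.
* **`femaw.stats`** — ICC (two-way random, absolute agreement), Pearson
  correlation, chi-square, Shapiro–Wilk gate, Welch/Student group
  comparisons, forced-entry multiple regression with standardized betas,
  95 % CIs, F, adjusted R², Durbin–Watson and a ±3 SD outlier screen, and
  the sex-specific rounded prediction equations
  (`FA_male = 0.7·AW − 0.7`, `FA_female = 0.7·AW + 4.3`).

## Worked example

Generate a phantom with known ground truth, measure it, then simulate and
analyse a 100-hip cohort:

```sh
$ femaw simulate-femur --anteversion 14.8 --neck-shaft-angle 127.3 \
        --aw-angle 17.5 --seed 1 --out fem
wrote phantom (FA=14.8 NSA=127.3 AW=17.5) to fem

$ femaw measure --mesh fem/femur.stl --landmarks fem/landmarks.json --out angles.csv
1: FA=14.8 NSA=127.3 AW=17.5 (right)

$ femaw simulate-cohort --n 100 --seed 1 --out cohort.csv
wrote 100 hips to cohort.csv

$ femaw analyze --cohort cohort.csv --out analysis
male: FA = AW × 0.7 − 2.0
female: FA = AW × 0.7 + 4.1
adjusted R² = 0.546, DW = 2.520

$ femaw predict --aw 17.5 --sex male
predicted FA = 12.352 deg
```

The measurement line shows the pipeline recovering the dialled ground
truth (14.8°/127.3°/17.5°) from the mesh alone. The analyze step refits
the forced-entry regression on one simulated cohort: with n = 100 the
fitted equations scatter around the generating ones (slope 0.744, male
intercept −0.668, female intercept 4.330), exactly as repeated cohorts
would scatter around a single study's printed fit. `analysis/` contains
the regression table (B, SE B, β, P, 95 % CI) and a JSON bundle with the
group summaries, correlations, normality checks and diagnostics.

The same operations are available as a library:

```python
from femaw import PhantomSpec, build_phantom, measure_femur

mesh, landmarks = build_phantom(PhantomSpec(true_anteversion=-12.1))
angles = measure_femur(mesh, landmarks)   # AngleSet(fa≈-12.1, nsa≈127.3, aw≈17.5)
```

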