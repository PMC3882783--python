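# cinedense

Analysis of **cine DENSE** (Displacement ENcoding with Stimulated Echoes)
cardiovascular MR of the mouse left ventricle, paired with an analytic
deformation phantom that makes every stage of the pipeline verifiable
without scanner data.

DENSE stores the in-plane displacement of the tissue at each pixel —
relative to its end-diastolic position — in the image phase:

```
u = phi / (2 * pi * ke),        ke = displacement encoding frequency (cycles/mm)
```

From a five-view study (basal/mid/apical short-axis + two/four-chamber
long-axis; magnitude plus wrapped X/Y phase per cine frame) the package
computes the advanced measures of cardiac function used to characterise
diet-induced obese versus control mice:

* **Strains** — material points seeded at end-diastole are tracked by
  inverting the decoded displacement field; the local deformation gradient
  `F` is estimated by weighted least squares over a reference-frame
  neighbourhood, and the Green–Lagrange tensor `E = (FᵀF − I)/2` is
  projected on the radial/circumferential/longitudinal directions and
  reported as engineering percent length change,
  `100·(√(2E_dd + 1) − 1)`, per transmural layer (subendo/mid/subepi) and
  per the standard 16-segment model (6 basal / 6 mid / 4 apical).
* **Torsion** — basal-to-apical twist difference normalised by the
  end-diastolic epicardial long-axis length (°/cm), the length averaged
  over the two- and four-chamber views.
* **Synchrony** — CURE/RURE uniformity ratio estimates: with per-frame DFT
  coefficients `c_k` of the 24-sector strain profile,
  `index = Σ_t |c₀|² / Σ_t (|c₀|² + |c₁|² + |c_{N−1}|²)`; 1 = perfectly
  synchronous.
* **Volumetrics** — EDV, ESV, EF, mass (1.05 mg/µL) and mass/EDV from a
  smooth ray-wise surface reconstruction of the propagated contours.
* **Group statistics** — exact Mann–Whitney U by complete enumeration,
  percent changes, Pearson correlations, and a two-group summary table.

The **phantom** (`cinedense.phantom`) renders displacement-encoded images
of a thick-walled half-ellipsoidal ventricle with prescribed transmural
circumferential stretches, longitudinal shortening, twist, and per-wall
activation delays, and reports the exact ground truth (strains, torsion,
CURE/RURE, volumes, mass) for parameter-recovery testing.

## Worked example

```python
from cinedense import load_builtin_config
from cinedense.phantom import Phantom
from cinedense.pipeline import analyze_study

config = load_builtin_config("lowfat")      # control-mouse phantom
study, truth = Phantom(config).render_study("demo", "lowfat")
result = analyze_study(study)
m = result.metrics
print(f"Ecc endo {m['ecc_endo']:+.1f}%  (truth {truth.peak_strain['ecc']['endo']:+.1f}%)")
print(f"Ecc epi  {m['ecc_epi']:+.1f}%  (truth {truth.peak_strain['ecc']['epi']:+.1f}%)")
print(f"torsion  {m['peak_torsion_deg_per_cm']:.2f} deg/cm  (truth {truth.peak_torsion:.1f})")
print(f"RURE {m['rure']:.3f}   EDV {m['edv_ul']:.1f} uL  (truth {truth.edv:.1f})")
```

prints

```
Ecc endo -16.9%  (truth -17.0%)
Ecc epi  -9.3%  (truth -9.4%)
torsion  8.77 deg/cm  (truth 8.8)
RURE 1.000   EDV 62.6 uL  (truth 60.9)
```

i.e. the pipeline recovers the prescribed subendocardial/subepicardial
circumferential strains to within 0.1–0.5 strain-%, peak torsion to within
0.1 °/cm, a perfectly synchronous RURE for the zero-delay phantom, and the
analytic cavity volume to within 3%.

The `analysis/` scripts run the study end to end: `01_simulate_cohorts.py`
renders five control and five obese phantom subjects (4% parameter jitter),
`02_analyze_studies.py` computes per-subject metrics
(`results/group_metrics.csv`), and `03_group_statistics.py` produces the
group comparison (`results/report.csv`, e.g. obese vs control: Ecc epi
−35%, p = 0.008; torsion −27%, p = 0.008; RURE 0.924 vs 0.997, p = 0.008;
mass +24%, p = 0.032 with unchanged EDV) and the correlations of mass/EDV
with average strains (`results/correlations.csv`).

The same chain is scriptable from the shell:

```bash
dense phantom --config lowfat --out scratch/demo     # study + truth.json
dense analyze scratch/demo --out scratch/demo/metrics.json
dense stats --metrics results/group_metrics.csv --out results/report.csv
dense io validate scratch/demo
```

## Layout

```
src/cinedense/       library: model/io, phantom, phase, kinematics,
                     globalfn, volumetrics, stats, pipeline, cohort, cli
analysis/            numbered study drivers (simulate -> analyze -> stats)
tests/               pytest suite incl. parameter-recovery acceptance tests
docs/methods.md      model, estimator and design notes
```
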