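# spinefea

A desk-scale re-implementation of a QCT/micro-CT-driven vertebral
fracture-risk analysis: synthetic vertebral specimens → cortical-shell
morphometry and cancellous-attenuation measurement → Hounsfield-unit to
elastic-modulus calibration → linear-elastic finite-element solve →
nonparametric case statistics.

It is written for biomechanics researchers who want a fully testable,
dependency-light pipeline of this kind: every stage — image synthesis,
measurement, material mapping, meshing, FE assembly, statistics — is a
plain Python module with closed-form or brute-force oracles in its test
suite, so the whole chain can be verified on a laptop.

## The model

Each vertebral body (C3–L5) is analysed in isolation:

* **Cortical shell** — triangular plane-stress membrane elements on the
  body surface, thickness `t_c` = the level's cortical thickness Cr.Th
  (101–223 µm range, measured at 25 µm on micro-CT sections), fixed
  modulus `E_cor = 8000 MPa`.
* **Cancellous core** — linear tetrahedra sharing the shell's nodes, with
  one spatially uniform modulus per vertebra from the density chain

  `ρ_BMD = a + b·HU` (a = −14 mg/cm³, b = 0.385 mg/cm³/HU, HU clamped at 50)
  → `ρ_ash = 0.0633 + 0.887·ρ_CHA` (g/cm³)
  → `E_spong = 21700·ρ_ash^2.07 MPa`, `S_max,spong = 137·ρ_ash^1.88 MPa`,

  where the mean HU comes from a spherical cancellous ROI read as the
  mean of the three central orthogonal plane means.
* **Intervertebral disc** — a bed of grounded springs under the inferior
  endplate, `k_i = E_iv·A_i/t_iv` in total (`E_iv = 9.8 MPa`,
  `t_iv = 5 mm`, `A_i` tributary areas).
* **Load** — an axial force `F = fraction(level)·m·g` (level-dependent
  supported-mass fraction, donor mass 104.5 kg) spread over the superior
  endplate by an RBE3-style interpolation that adds no stiffness.

Outputs per vertebra: element von Mises stresses by compartment, maximal
axial deflection, and a failure margin (peak cancellous stress over
`S_max,spong`; ≥ 1 predicts fracture).  The case layer aggregates medians
and quartiles per spinal section (CS/TS/LS), Kruskal–Wallis and
Bonferroni-adjusted Mann–Whitney U tests, Spearman correlation and
t-based 95% CIs.

Because no real scans ship with the package, `default_donor_spine()`
provides a parametric 22-vertebra reference specimen that encodes the
study conditions of the analysed case (an 83-year-old donor with
osteoporosis and DISH-type endosclerosis of Th5–Th8; BMI 40.3 kg/m²),
with section-median shell thicknesses (156/188/149 µm) and cancellous
attenuations (222/117/47.8 HU).

## Worked example

```python
from spinefea import (default_donor_spine, build_material_card,
                      level_load, solve_vertebra)

spine = default_donor_spine(noise_seed=1)
spec = spine["Th8"]                       # a DISH-affected thoracic body
card = build_material_card(spec.cancellous_hu_mean, vertebra_label="Th8")
force = level_load(spine, "Th8")          # supported-mass fraction × m·g
res = solve_vertebra(spec, card, force)
print(res.summary())
```

prints

```
Vertebral body FE results — Th8
================================================
nodes 1524   tets 7128   shell tris 1224
E_cor 8000 MPa   E_spong 268.748 MPa   nu 0.3
shell thickness 188 µm   axial load 386.626 N
spring bed: 127 nodes, total 645.888 N/mm
------------------------------------------------
cortical von Mises (p100)   20.22 MPa
cancellous von Mises (p100) 0.6586 MPa
deflection (max axial)          0.6479 mm
failure margin (max/S_max)      0.2594
```

The DISH-elevated attenuation (202 HU) maps to `E_spong ≈ 269 MPa`; the
thin cortical shell concentrates the load (20.2 MPa vs 0.66 MPa in the
core — a ratio of ~30, mirroring how the shell and endplates do the
load-bearing), and the failure margin of 0.26 predicts no fracture.

The full pipeline — 22 clinical-CT ROI measurements, 1800 micro-CT
thickness samples on 15 bodies, 22 FE solves and the statistics tables —
runs in well under a minute:

```python
from spinefea import default_donor_spine, run_pipeline
report = run_pipeline(default_donor_spine(noise_seed=1))
print(report.summary())           # markdown case summary
report.write_csv("out/")          # tidy CSV tables
```

A thin CLI wraps both entry points:

```bash
spinefea report --out out/ --seed 1
spinefea run-fea --vertebra L3 --out l3.vtk
```

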