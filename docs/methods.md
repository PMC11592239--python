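# Methods

## Scope and model

`spinefea` analyses one vertebral body at a time as a linear-elastic
composite: a thin cortical membrane shell bonded to a homogeneous
cancellous core, supported below by an elastic disc bed and loaded above
by a distributed axial force.  The package covers the whole measurement
chain that feeds such a model — synthetic CT/micro-CT image generation,
ROI attenuation and cortical-thickness morphometry, density calibration,
meshing, assembly/solve, and the nonparametric statistics layer that
summarises a multi-level spine as a case report.

Assumptions baked into the mechanical model:

* **Linear elasticity, small strain, static load.**  One load case per
  vertebra; no multi-body coupling, no geometric or material
  nonlinearity, no time dependence.
* **Membrane shell.**  The cortex carries in-plane stress only.  Axial
  load through near-planar endplates is membrane-dominated; bending
  shells are out of scope.  A consequence worth knowing: endplate
  membranes act as in-plane diaphragms that resist the Poisson expansion
  of the end faces, which shifts mid-wall von Mises by a few percent at
  ν = 0.3 relative to the Poisson-free composite closed form.
* **Uniform cancellous material per vertebra.**  The calibration chain is
  evaluated once on the vertebra's mean ROI attenuation.  A per-element
  mapping would be straightforward but is deliberately not the default,
  matching the single-value material card the report layer documents.
* **Isotropy, ν = 0.3 in both compartments.**  The Poisson ratio is a
  free parameter (`VertebralFEModel(nu=...)`); 0.3 is the conventional
  bone default.

## Material calibration

`ρ_BMD = (a + b·HU)/1000` g/cm³ with a = −14 mg/cm³, b = 0.385 mg/cm³/HU
and HU clamped from below at 50: sub-threshold attenuation maps to a
floor material rather than being excluded, so every element keeps a
positive modulus.  The ρ_BMD → ρ_CHA step is implemented in two modes
because its published algebra is ambiguous:

* `pragmatic` (default): ρ_CHA ≡ ρ_BMD — phantom-calibrated BMD is
  already an equivalent-CHA density.  This yields section-dependent
  moduli (e.g. HU 222 → 301 MPa, HU 117 → 151 MPa, HU ≤ 50 → 83 MPa).
* `literal`: ρ_CHA = max(0, D_CHA·(ρ_BMD − D_H2O)/(D_CHA − D_H2O)).
  Every physiologic vertebral HU then falls below water density and
  collapses to the 0.0633 g/cm³ ash floor, erasing all section
  differences — which is why this reading is shipped but not default.

Both modes are logged in the material card's provenance.

## Boundary conditions and coupling

The disc bed applies `k_total = E_iv·A/t_iv` (E_iv = 9.8 MPa, t_iv =
5 mm) over the inferior contact nodes; the axial force is distributed
over the superior contact nodes by an RBE3-style interpolation (force
weights, minimum-norm-corrected for exact force and moment balance, no
stiffness added).

How the totals are *apportioned* across contact nodes matters on a body
shorter than its diameter.  Two modes exist:

* `area` — weights proportional to tributary areas, i.e. uniform
  pressure, the behaviour of a fluid-like disc nucleus.  The traction
  then differs from the shell/core composite's stiffness-weighted
  traction by a self-equilibrated load whose Saint-Venant decay length is
  of the order of the body diameter, so the equal-strain composite state
  never fully develops and the top cancellous layer sees ≈ F/A
  regardless of its modulus.
* `stiffness` (default) — weights proportional to each node's tributary
  axial stiffness `E_spong·A_i + E_cor·t_c·l_i` (with `l_i` the node's
  tributary rim-perimeter length).  The load then enters the two
  compartments compatibly with the composite cross-section — the regime
  a much stiffer adjacent vertebral body enforces — and the cancellous
  stress field matches the equal-strain estimate.  Totals (ΣF, Σk) are
  identical in both modes.

The default was chosen because the uniform-pressure mode predicts
cancellous endplate stresses of ≈ F/A (≈1.2–1.3 MPa in the lumbar
spine), which would imply trabecular failure in every osteoporotic
lumbar body — inconsistent with the intact-spine finding this kind of
analysis reproduces; the compatible mode yields cancellous stresses in
the 0.2–0.7 MPa range with failure margins well below one.

The solver verification fixture (`spinefea.validation`) uses the
`stiffness` coupling with ν = 0, where the equal-strain composite state
is the *exact* solution of the discrete model; the FE results agree with
the closed forms to ~1e-13 (and with the ideal-circle closed forms to
0.2%, the polygonal perimeter error at a 2 mm edge target).

Spring reactions always balance the applied load to the direct solver's
round-off; rigid-body modes are constrained by making the bed isotropic
(the disc also supports shear), which leaves the axial stiffness of each
spring exactly `k_i`.

## Synthetic specimens

Each body is an elliptical cylinder with a cosine waist (scale
`1 − (1−w)·cos²(πz/h)`, default waist factor w = 0.88) — no posterior
elements, since only the body is in the load path.  Geometry defaults
grow linearly craniocaudally (anterior-posterior semi-axis 6.5 → 10.5 mm,
mediolateral 8.0 → 15.0 mm, height 14 → 27 mm); they are free parameters
chosen from adult anthropometry and from consistency with printed
deflections of the reference case, and are not fitted to any test.

Rasterization is voxel-centred (`world = origin + index·spacing`).  The
cortical band is carved with a Euclidean distance transform: an interior
voxel is cortical when its centre lies within `t_c + half a voxel` of
the exterior (the half-voxel converts centre-to-centre distances to
distance-to-surface).  On an axis-aligned wall this reproduces the
specified thickness to within half a voxel; obliquely the quantisation
error stays below one voxel, which is why the recovery criterion is one
25 µm voxel on section medians.  Cancellous voxels draw i.i.d. Gaussian
noise (default sd 25 HU) from a stream keyed by (spine seed, vertebra
position, acquisition), so volumes are bit-reproducible and independent
of list slicing.  Synthetic cortical/background values (1500 / −800 HU)
only drive masks, never the material chain.  Clinical-CT spacing
defaults to 0.625 mm; at that spacing the shell band is thinner than a
quarter voxel and the rasterizer flags it, mirroring why cortical
thickness is measured on micro-CT instead.

Micro-CT volumes are generated as one-voxel-thick mid-sagittal slabs at
25 µm: the thickness protocol reads only that section, and a full 3-D
volume of a lumbar body at 25 µm (~10⁹ voxels) would buy nothing for it.

The DISH levels Th5–Th8 carry a +85 HU endosclerotic elevation over the
thoracic baseline — a single fixed offset placing them between the
thoracic and cervical medians, as endosclerosis presents.

What the generator does **not** emulate: real trabecular texture and
anisotropy, endplate curvature and rim geometry, posterior elements,
beam-hardening or partial-volume artefacts, between-vertebra biological
variation within a section (attenuation and thickness are constant per
section apart from voxel noise, so within-section quartile ranges in the
synthetic report are narrower than in real data).  Passing tests
therefore demonstrate the *pipeline's* correctness (measurement
operators, calibration, solver, statistics), not that real vertebrae
behave like the phantoms.

## Measurement operators

* **ROI attenuation**: unweighted mean of three central orthogonal plane
  means over a sphere placed strictly in cancellous bone (any cortical or
  exterior voxel is a hard error naming the offending index).  The
  default radius is 0.4 × the smallest waist semi-axis.
* **Cortical thickness**: on the mid-sagittal section, Gaussian smooth
  (σ = 1 voxel), threshold at 800 HU (midpoint of the synthetic
  cortical/cancellous contrast), take the longest iso-contour, classify
  contour points into ventral/dorsal/cranial/caudal by 45° sectors of
  the outward normal, resample 30 points per edge equally by arc length
  with 5% corner margins, and march each point inward to the first
  sub-voxel threshold crossing.  Stopping at the *first* exit makes a
  double contour (an inner lamella behind the cortex) report the outer
  lamella only.  The manual protocol this replaces is operator-defined;
  this surrogate is deterministic and is validated against analytic
  phantoms to ±1 voxel.
* **Aggregation**: medians and quartiles use linear interpolation
  between order statistics (type 7), stated in the report footer because
  manual protocols rarely name a quantile rule.

## Case pipeline conventions

* Load table: supported-mass fraction linear from 0.08 at C3 to 0.60 at
  L5 — an explicit stand-in for the in-vivo segmental mass distribution,
  overridable everywhere and flagged as an assumption in every report.
* Micro-CT covers 15 of 22 bodies (C3–C7, Th8–Th12, L1–L5; 15 × 4 × 30 =
  1800 samples).  Levels without micro-CT (Th1–Th7) receive the section
  median of measured vertebrae as their shell thickness; the FE table
  records `measured` vs `section_median` per vertebra.
* Stress summary: the 100th percentile (maximum) of element von Mises
  per compartment by default, percentile config-exposed; deflection is
  the maximal axial displacement component (total-magnitude mode behind
  a flag).
* Statistics: scipy.stats engines with fixed conventions — mid-ranks
  with tie correction, exact Mann–Whitney enumeration when both groups
  have ≤ 8 observations and the normal approximation otherwise,
  Bonferroni multiplier = number of tested pairs, t-based 95% CIs.
  Degenerate inputs are defined, not fatal: identical data give H = 0 /
  p = 1; groups of size < 2 are excluded with a warning; zero rank
  variance reports an undefined correlation.

## Problem sizes and determinism

Default FE meshes use a 2 mm edge target (≈ 3 600–15 000 tetrahedra per
body, 5 000–12 000 DOF), solved by direct sparse factorisation — small
enough that the full 22-vertebra pipeline plus 1800 thickness
measurements runs in tens of seconds on one CPU, yet converged: halving
the edge length changes the fixture displacement solution by well under
2%.  All randomness flows from the single spine seed; reports and CSVs
are byte-identical across reruns.

## Known limitations

* The absolute stress magnitudes of any real donor depend on true
  vertebral geometry (endplate curvature, cortical thickening at the
  rim, local concentrations).  A smooth parametric body under a monotone
  load table reproduces the craniocaudal *ordering* of cortical stress
  and the order-of-magnitude gap to cancellous stress, but compresses
  the lumbar-to-cervical stress ratio: the equal-strain composite bound
  `(F_L/F_C)·(ΣEA_C/ΣEA_L)` stays near 4 for any craniocaudally growing
  geometry, versus >6 reported for donor-specific geometry.
* Membrane shells cannot represent endplate bending or buckling of the
  cortex.
* The generic (non-parametric) tetrahedralization path is exact only for
  convex surfaces; waisted bodies use the structured generator, whose
  boundary is the shell triangulation by construction.
* The failure check is a stress-ratio screen on the cancellous
  compartment, not a damage or fracture-mechanics model.
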