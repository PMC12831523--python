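# Methods

## Problem and scope

Proton treatment planning needs the relative stopping power (RSP) of every
voxel: the ratio of a material's proton stopping power to that of water,
which sets how much range a proton loses crossing it. Dual-energy CT (DECT)
decomposition yields two voxel-matched maps — effective atomic number
(Zeff) and relative electron density (RED) — from which RSP can be computed
directly. `dectrsp` implements that computation and the phantom-based QA
protocol used to quantify its accuracy: tissue-surrogate inserts with known
reference values are imaged (here: simulated), ROI means are compared with
references as percent errors, and accuracy is summarized per tissue
category as the mean absolute percent error (MAPE).

The scanner itself is out of scope. The proprietary projection-domain
decomposition that produces Zeff/RED from raw dual-kVp data is treated as
an opaque upstream source and emulated by the synthetic phantom module;
no spectral, bowtie-filter, or reconstruction modeling is attempted.

## Physics

**RSP (Bethe ratio).** For a proton of speed `beta` relative to c,

    RSP = RED * [ln(2 m_e c^2 beta^2 / (1 - beta^2)) - beta^2 - ln I_m]
              / [ln(2 m_e c^2 beta^2 / (1 - beta^2)) - beta^2 - ln I_w]

with `I_w = 75.3 eV` (the water convention used throughout) and `I_m` the
material's mean excitation energy. When `I_m = I_w` the bracket ratio is
exactly 1 and RSP equals RED; this identity is enforced to machine
precision in the tests.

**Proton energy.** `beta^2` comes from relativistic kinematics,
`beta^2 = 1 - (M_p / (T + M_p))^2`, `M_p = 938.272 MeV`. The default
kinetic energy is `T = 100 MeV` (mid-therapeutic range), exposed as a
parameter everywhere. The choice is immaterial below the percent level:
over 80–200 MeV and `I_m` in 60–120 eV the RSP changes by < 1 % (tested).

**Composition-derived references.** For a material with elemental mass
fractions `w_i`:

* Mayneord effective atomic number
  `Zeff = [sum w_i (Z_i/A_i) Z_i^n / sum w_i (Z_i/A_i)]^(1/n)`, `n = 3.21`;
* relative electron density
  `RED = rho N_A sum w_i Z_i/A_i / rho_e,w`, with `rho_e,w` computed from
  the standard water composition at 1 g/cm^3;
* Bragg-additivity mean excitation energy
  `ln I_m = sum w_j (Z_j/A_j) ln I_j / sum w_j (Z_j/A_j)` over elemental
  ICRU-37 I-values (bundled in `data/elements.csv`).

Direct evaluation of the Mayneord formula for water gives about 7.46; the
bundled reference table carries the conventional tabulated 7.42. Tabulated
manufacturer/reference values always take precedence over
composition-derived ones when defining ground truth (the composition route
remains available for QA via `dectrsp reference`).

**The Zeff -> I correlation.** Clinical pipelines assign a voxel's `I_m`
from its Zeff through an empirical, proprietary curve. The package's open
equivalent is calibrated from the bundled surrogate library by computing
(Zeff, ln I) per material and fitting `ln I` as a *straight line* in Zeff
(least squares), stored as a piecewise-linear node curve clamped outside
its range. Two deliberate choices here:

* *Fit, not interpolation.* Chemically different surrogates can share a
  Zeff while differing in Bragg-additivity I, so a curve threaded through
  every point is jagged and non-monotone. Because voxel Zeff carries
  noise with sigma up to ~0.6, curvature (kinks) rectifies zero-mean noise
  into a systematic I shift — large enough to bias ROI means by several
  standard errors at N ~ 3700 voxels. A straight line has zero curvature,
  so noisy voxel averages stay unbiased. Exact through-node interpolation
  (duplicates merged by averaging) remains available as
  `calibrate_correlation(..., mode="interpolate")`.
* *Water anchoring.* Elemental Bragg additivity ignores molecular binding
  and lands ~8 % low for water (~69 eV). The whole curve is shifted by a
  constant in `ln I` so that water's Zeff maps exactly to 75.3 eV,
  restoring the I-scale the RSP denominator uses; a water voxel
  (Zeff 7.42, RED 1.00) then converts to RSP 1.000.

The fitted node span is the calibration Zeff range widened by 2 units on
each side, so the end clamps sit several noise-sigmas away from every
insert's Zeff (a clamp is itself a kink and would otherwise bias materials
near the boundary, e.g. adipose at Zeff 6.14).

## Synthetic phantoms

The generator emulates the five study phantoms with the documented
geometry: Model 467 (33 cm disk, 16 plugs on two rings — outer edge radius
12 cm with 5 cm gaps, inner edge radius 7 cm with 1.4 cm gaps), George
Body (27 cm, 6 plugs, edge radius 10 cm, 3.5 cm gaps), George Head (18 cm,
8 plugs, edge radius 7 cm, 3.3 cm gaps, with the sinus plug tucked between
enamel and cortical bone at 1.6 cm edge distance), AED Head (20 cm, 10
plugs, solid water at the center), and AED Body (40 x 30 cm ellipse, the
head layout plus 6 plugs on an outer elliptical ring). Within a ring,
inserts are placed sequentially with the exact documented edge gap
(angular layout is not documented for the physical phantoms; any slack is
left as one larger closing gap). "Spaced X apart" is read as edge-to-edge
gap — the only reading consistent with the inner-ring 1.4 cm figure.
Plug diameters are not documented; 2.8 cm is used (the standard
characterization-phantom plug, also the noise-ROI diameter), except the
custom George Head wax plugs (2.0 cm; smaller is the only way the
documented ring closes) and its sinus (1.5 cm). Assigned per-insert
Zeff/RED are the reference values of the bundled per-insert table.

Default grid: 1.0 mm in-plane spacing, 2.5 mm slices (the scan thickness),
10 slices, phantom centered, voxel-center-in-shape labeling. Outside-air
voxels get RED 0.001 (not 0, to avoid downstream division issues) and
Zeff 7.70.

**Noise** is i.i.d. additive Gaussian per voxel, with magnitudes taken
from the measured per-acquisition table (`noise_presets()`, keys like
`model467_14.55` = phantom and CTDIvol). Real CT noise is spatially
correlated and nonstationary; only the central-circle sigma is emulated,
so passing tests demonstrate statistical correctness of the chain, not
robustness to structured artifacts. **Bias** near high-density structures
is modeled, optionally and off by default, as
`amplitude * exp(-d/decay)` around a source point — a deliberately simple
stand-in for scatter/beam-hardening shifts.

What the synthetic data cannot show: beam-hardening and scatter coupling
between inserts (the very effects the study discusses for sinus, LN-300
and brain), bowtie/SFOV differences, partial-volume edge blur, and any
fidelity of the proprietary decomposition. Results on synthetic volumes
validate the *evaluation chain*, not the scanner.

## Evaluation protocol

* ROI: concentric circle of diameter `sqrt(0.6)` x insert diameter (exactly
  60 % of the insert area; the protocol says "at least 60 %"), averaged
  over all slices. Configurable upward via `area_fraction`.
* Percent error `100 (ROI_mean - ref)/ref`; residual is the numerator.
* Tissue categories on reference RED: air/lung 0.28–0.44, fat 0.93–0.97,
  water 0.99–1.00, muscle 1.02–1.08, bone 1.09–1.78. The printed bins do
  not cover the gaps or the extremes, so values outside every bin go to
  the bin with the nearest boundary (0.200 -> air/lung, 1.875 -> bone) —
  the assignment under which the published category arithmetic reproduces.
* MAPE per category and overall; SDs use the n-1 denominator; aggregation
  is always on unrounded values, tables are written with RSP to 3 decimals
  and percent errors to 2.
* Noise sigma: sample SD (n-1) of a central 2.8 cm circle; 1 cm circle
  inside the central insert when the phantom center is occupied (AED Head).
* Body-vs-Head comparison: two-sided paired Student's t-test on per-insert
  ROI means. Identical sequences return p = 1.0 by convention;
  zero-variance nonzero differences raise instead of fabricating a p.

On the bundled measurement table, percent errors and residuals are used
as printed (they were computed upstream from unrounded ROI means;
recomputing them from the rounded table means would shift last digits).
The bone-category MAPE computed from the printed per-insert errors is
1.126, while the published summary prints 1.12 — a rounding inconsistency
of the source tables; comparisons are therefore made within one unit of
the last printed digit.

## Numerical/problem-size choices

* Recovery property tests use the full five presets at measured noise,
  100 noise realizations each, on the default 10-slice grid (~30 s total);
  each insert's RSP ROI mean must sit within 3 standard errors (estimated
  from the ROI sample SD) of its noiseless value in >= 95 % of seeds.
* Volumes are stored float64 in memory and float32 in NIfTI (labels
  int16); the float32 round-trip keeps percent errors below 0.01 %.
* RED <= 0 after noise (common in outside-air voxels) is clamped to 0.001
  with a logged count; NaN inputs propagate as NaN with a logged count.
* Random streams: `numpy` `SeedSequence(seed)` spawns independent child
  streams for the Zeff and RED volumes, so one seed fixes the whole
  simulation bit-exactly.

## Known limitations

* The correlation is a single global line in (Zeff, ln I); real empirical
  curves are often piecewise by tissue class. The line is the right
  trade-off here because unbiasedness under Zeff noise matters more than
  per-material I fidelity (references for accuracy evaluation are carried
  separately), but I-values far from the calibration cloud are rough.
* Surrogate compositions are published-style elemental recipes, not vendor
  certificates; manufacturer-corrected RED agrees with the
  composition-derived value within ±0.02 across the library (tested), and
  reference precedence means any residual mismatch does not touch the
  ground truth used in evaluation.
* No DICOM I/O; NIfTI only.
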