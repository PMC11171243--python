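# Methods

This note documents the models inside `mwasim`, the choices made where the
design was genuinely open, and what the synthetic phantoms do and do not
establish about clinical data.

## Electromagnetic model

The antenna field is time-harmonic at 2.45 GHz.  Interstitial coaxial
applicators are rotationally symmetric, so the vector problem reduces to the
azimuthal magnetic component `u = H_phi(r, z)`; writing `w = r u` turns the
curl–curl equation into an anisotropic Helmholtz form

```
-d/dr[(f/r) dw/dr] - d/dz[(f/r) dw/dz] - (k0^2/r) w = 0,   f = 1/(eps_r - j sigma/(omega eps0)),
```

discretised with a conservative cell-centred finite-volume scheme on a graded
rectilinear grid (0.125 mm cells across the antenna cross-section and slot,
geometrically graded to 1 mm in the far field, domain radius 60 mm).  The
full clinical model solves the 3-D vector problem in a commercial FEM code;
the axisymmetric reduction is the principal fidelity trade-off of this
package, and off-axis heterogeneity (vessels) is seen by the EM solve only
through the nearest-label section along the trajectory half-plane.  The
thermal solver, by contrast, is fully 3-D.

Boundary handling:

* **Axis** — regularity, `w = 0` at `r = 0`.
* **Conductors** — in the H-formulation, zero tangential electric field is
  the *natural* (zero-flux) condition, so conductor cells are simply removed
  from the unknown set.
* **Outer boundaries** — first-order absorbing (Sommerfeld) condition with
  the local complex wavenumber `k = k0 sqrt(eps_complex)`.
* **Port** — the coax TEM mode (`H_phi ∝ 1/r`) is injected through a Robin
  condition at the inlet annulus.  The mode amplitude is normalised with the
  same discrete midpoint quadrature used by the overlap integral, so the
  injected time-averaged power equals the requested input power on any grid
  (verified to 0.5 % on a matched line).  The reflection coefficient S is
  the overlap of the residual field with the mode.

Power bookkeeping: the audit compares absorbed power (volume integral of
`sigma |E|^2 / 2`) plus Poynting outflow through the absorbing boundaries
against `(1 - |S|^2) P_in`; on the default grid it closes within 2 %.

### Antenna template

The clinical device is a proprietary triaxial 2.45 GHz antenna with no
published dimensions.  The package ships a standard published interstitial
slot geometry instead (inner conductor 0.135 mm, dielectric 0.47 mm, outer
conductor 0.595 mm, catheter 0.895 mm; 1 mm ring slot 5 mm from the
short-circuited tip), fully overridable in the material config.  Two
consequences worth knowing:

* its input match is moderate (|S| ≈ 0.3 cold, rising as tissue near the
  slot desiccates), so delivered power is below the generator setting, as in
  practice;
* a slot antenna without a choke carries a backward surface wave along the
  shaft — the very effect triaxial designs suppress — so part of the
  absorbed power heats tissue proximally along the insertion track.  For the
  near-surface reference tumors a fraction of that power lies outside the
  phantom volume entirely; the run report therefore distinguishes *absorbed*
  power (EM domain) from *deposited* power (inside the thermal grid).

### Heat-source revolution

The axisymmetric `Q_ext` is rotated onto the 3-D voxel grid by ring
splatting: each (r, z) cell's power is distributed along its revolution ring
with arc steps of half a voxel and binned into voxels.  This is conservative
by construction (important because the source is strongly peaked within a
millimetre of the antenna, which bilinear sampling on ≥1 mm voxels badly
underestimates) and deterministic; a fixed golden-ratio phase per ring
prevents rings whose point count is not a multiple of four from biasing one
azimuth.

## Thermal model

Pennes bioheat on the voxel grid, backward Euler with the
temperature-dependent coefficients lagged one step (single Picard
iteration): unconditionally stable, first order in `dt` (default 0.5 s),
second order in space.  The linear system is a symmetric positive-definite
7-point stencil with harmonic-mean face conductivities, solved matrix-free
by Jacobi-preconditioned conjugate gradients (relative tolerance 1e-9,
warm-started from the previous step).  Summing the discrete update over the
insulated domain yields an exact energy identity, which the per-step audit
checks (residuals are at solver tolerance, far below the 1 % contract).

Defaults and their reasoning:

* initial and arterial temperature 37 °C (310.15 K);
* metabolic heat 33 800 W/m³ in perfused tissue.  Note the equation pair
  implies a baseline drift: with `omega_b(37 °C) = 1.127e-3 1/s` the
  steady-state excess is ≈ 7.86 K with a ~15 min time constant, so the far
  field warms a few kelvin during a 10 min ablation.  This is faithful to
  the governing equations rather than a bug;
* vessels are a static material compartment (conduction only, no flow); an
  optional constant-temperature (Dirichlet) vessel mode exists for heat-sink
  studies but is off by default;
* antenna voxels conduct with generic metal/PTFE constants; no active
  cooling is modelled (whether the clinical antenna is cooled is unknown);
* EM re-solve policy: every 10 s, or as soon as the maximum pointwise
  relative change in `sigma(T)` exceeds 2 % — but never more often than
  every 2 s, so the threshold cannot degenerate into a re-solve per step.

## Damage model and reports

First-order Arrhenius kinetics per tissue (liver `A = 7.39e39 1/s`,
`dE = 2.58e5 J/mol`), accumulated with the left-rectangle rule at the
thermal step (consistent with coefficient lagging; trapezoid available).
The ablation zone is `theta_d > 0.98`; the alternative 50 °C criterion uses
the running-maximum temperature, treating the crossing as irreversible.

Two kinetics subtleties:

* the tabulated tumor frequency factor (`3.25e4 1/s`) yields no measurable
  necrosis at any reachable temperature — almost certainly a typographic
  exponent.  The default profile keeps the tabulated value; the
  `tumor_kinetics_adjusted` profile (used by the reference scenarios that
  assert tumor destruction) sets `3.25e43 1/s`, which makes tumor and liver
  kinetics comparable (necrosis in ~14 s at 60 °C);
* the liver pair has a small baseline rate at 37 °C (≈ 2.6e-4 1/s,
  `theta_d ≈ 0.14` over 10 min) — a known artifact of this parameter set,
  an order of magnitude below the zone threshold, so zones are unaffected.

**MAM** is the minimum distance from tumor-surface voxels to the
ablation-zone surface, computed with Euclidean distance transforms, signed
negative where tumor is uncovered (an extension; clinical reports quote
only achieved margins).  Antenna-track voxels carry no kinetics and are
counted as ablated for margin purposes — otherwise the track punches a
spurious internal zone surface through the tumor and pins the MAM at zero
on fine grids.  Damage *volumes* remain label-based (healthy-liver-only and
total non-tumor are both reported, since which one a clinical "tissue
damage" figure refers to is ambiguous).

**Stopping time** scans the zone time series for the earliest time with
complete tumor destruction and MAM at or above the target (default 5 mm),
and reports the healthy-damage volume saved by stopping there instead of at
full duration.

## Dielectric property laws

Liver and tumor permittivity and conductivity follow falling sigmoids in
temperature (desiccation above ~90 °C).  The tumor coefficient pairs are
tabulated in the literature in "offset form" `exp(c1 - c2 T)`; the package
stores every sigmoid as (steepness, midpoint, amplitude), i.e.
`steepness = c2`, `midpoint = c1/c2` (tumor permittivity midpoint 100.44 °C,
conductivity 111.58 °C).  Read positionally instead, those same triplets
would put the sigmoid midpoint at 0.05 °C and give a tumor permittivity of
1 at body temperature — physically impossible — while the offset-form
reading also reproduces the liver row exactly
(`0.076 × 82.271 = 6.25`).  All coefficients live in
`src/mwasim/data/materials.yaml` and can be edited freely.

## Synthetic phantoms

Each reference case is an ellipsoidal liver (semi-axes 36/30/40 mm) with a
spherical tumor of the printed volume placed near the superior pole at the
printed distance from the liver surface, a 2 mm-radius horizontal vessel at
the printed clearance beneath it, and a vertical antenna trajectory ending
at the tumor centre.  Realized volumes and distances converge to the
requests at first order in voxel size and are verified by distance
transforms to within one voxel.  The liver exterior is modelled as generic
soft tissue with liver properties (no air gap); there is no CT intensity
simulation, no deformable registration and no segmentation model.

What passing tests show — and what they do not: the phantoms establish that
the coupled solver chain is internally consistent (conservation,
convergence, monotone zone growth) and that under the study conditions
(65 W, 10 min, adjusted tumor kinetics) the reference scenario reaches
complete tumor destruction with a ≥ 5 mm margin before the scheduled stop,
with a meaningful damage saving from stopping at the endpoint.  They cannot
reproduce patient-specific Dice/sensitivity/specificity values, which
depend on real anatomy and clinical ablation zones; only the printed
relative-improvement arithmetic between the published model and vendor
scores is recomputed exactly.

## Problem sizes

The test-suite coupled scenario uses 2.5 mm voxels (≈ 32 000 cells, 1 200
implicit steps, ~120 EM re-solves; about a minute on one core).  The
acceptance script re-runs it at 1.5 mm (≈ 150 000 cells, a few minutes).
Halving the voxel size again is straightforward but was not adopted as the
default because margin and volume metrics were already stable to within one
voxel between 2.5 and 1.5 mm.

## Known limitations

* Axisymmetric EM solve (heterogeneity enters only through the section);
  full 3-D vector FEM is out of scope.
* No vaporisation enthalpy, tissue shrinkage or porosity change: peak
  temperatures above 100 °C are overestimated, as in the parent model
  class.
* The antenna geometry is a stand-in; absolute zone shapes depend on it.
* Vendor burn-chart dimensions are proprietary: `VendorZoneSpec` values
  must be supplied by the user.
* Specificity needs a bounded true-negative universe; the default
  evaluation region (mask union dilated 10 mm) is a convention and is
  recorded in every report.
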