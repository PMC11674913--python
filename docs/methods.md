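# Methods

`depcyte` simulates and analyzes a dielectrophoresis (DEP)–imaging flow
cytometer: a shallow, wide microfluidic channel with a coplanar electrode
pair on its floor, imaged from above at high frame rate. Cells advected by
the laminar flow cross the electrodes, where the non-uniform AC field
deflects them up (negative DEP) or down (positive DEP) depending on the
real part of their Clausius–Mossotti factor (CMF), Re{Kcm}. Because the
flow profile is parabolic, a height change is read out as a velocity
change: the differential velocity v_diff = vi − vo between the fitted
velocities before and after the electrodes is the dielectric observable,
and cell size comes from the same images. This note records the models,
the numerical choices, and the limits of what the synthetic experiments
demonstrate.

## Dielectric models

A particle's complex permittivity is ε̃ = ε0·εr − j·σ/ω. The CMF is
Kcm = (ε̃p − ε̃m)/(ε̃p + 2ε̃m), bounded between −0.5 and 1 in Re for
physical inputs. Cells are modelled as double-shell spheres — nucleoplasm,
nuclear envelope (40 nm), cytoplasm, plasma membrane (5 nm) — reduced to a
single equivalent sphere by three confocal shelled-sphere reductions

    ε̃eq = ε̃shell · (γ³ + 2K)/(γ³ − K),
    γ = r_out/r_in,  K = (ε̃core − ε̃shell)/(ε̃core + 2ε̃shell),

which is exact in the matched-material and zero-thickness limits (both are
unit-tested to machine precision). The bundled `cho_viable` /
`cho_nonviable` presets use the published dielectric parameter set for
Chinese hamster ovary cells (viable: r = 6.25 µm, σcyt = 0.53 S/m,
εmem = 8.5 ε0, σn = 1.5 S/m, εn = 120 ε0; non-viable: r = 5.5 µm,
σcyt = 0.07 S/m, εmem = 5 ε0, σn = 0.56 S/m, εn = 69 ε0; shared: nucleus
radius 0.55·r_cell, σmem = 1e−6 S/m, σne = 1e−3 S/m, εne = 11.5 ε0,
εcyt = 54.5 ε0). In the 0.17 S/m, 78 ε0 assay medium at 6 MHz these give
Re{Kcm} = +0.353 (viable, pDEP) and −0.199 (non-viable, nDEP) — the sign
split that viability discrimination exploits. Polystyrene calibration
microspheres are homogeneous spheres (εr = 2.5) whose conductivity is
surface-dominated, σp = 2·Ksurf/r with Ksurf = 1 nS; in DI water at 1 MHz
a 15.7 µm sphere has Re{Kcm} = −0.475 ≈ −0.5. DI water is taken as
εr = 78, σ = 5.5e−6 S/m (the result is insensitive to σ at 1 MHz since
σ ≪ ωε; both values are configurable). ε0 = 8.854187817e−12 F/m.

Sensitivity bands sweep one parameter by ±20% (cell radius co-scales the
nucleus radius as 0.55·r_cell); the crossover frequencies of a spectrum
are located by sign change on the grid plus log-frequency bisection to
1e−6 relative tolerance.

## Electrostatic field

The potential above the electrode pair (35 µm strips, 25 µm gap, on the
floor of a 50 µm channel) solves the 2-D Laplace equation in the (x, h)
cross-section; the electrodes span the full channel width, so the third
dimension drops out. Drive: electrodes at ±V0/2 with V0 = Vpp/2;
E_rms = |∇φ|/√2.

The solver splits φ = φ_cps + ψ. φ_cps is the exact conformal-map
potential of a coplanar strip pair in the open half-plane, with complex
derivative C/√((ζ²−a²)(ζ²−b²)) (a = gap/2, b = a + width,
C = −V0·b/(2K(m)), m = (a/b)², K the complete elliptic integral; the
floor potential has closed form in incomplete elliptic integrals). It
carries the inverse-square-root edge singularities and satisfies the
insulating-floor condition exactly. ψ is the smooth correction for the
finite channel height and truncated domain, solved with a five-point
finite-difference stencil (mirror ghost nodes for Neumann walls, flux
terms from φ_cps, direct sparse factorization, residual checked against
1e−8·V0). Subtracting the singular part is what makes ∇E²rms converge
cleanly under grid refinement (<0.2% change at the cell heights when the
default 0.5 µm step is halved) and agree with the two-half-plane
closed-form field to <1% in the semi-infinite-electrode limit.

The DEP force is the point-dipole expression
F = 2π·ε0·εrm·r³·Re{Kcm}·∇E²rms, evaluated at the particle center by
bilinear interpolation. No electrode polarization, double-layer screening,
or medium heating is modelled.

## Transport

Particle Reynolds and Stokes numbers at the operating point are ~1e−2 and
~7e−4, so inertia is dropped and the force balance gives instantaneous
velocities. Downstream: v_px = v_m(h) + F_DEP,x/(6πηr·λ∥); vertical:
v_ph = (F_DEP,h + F_lift + F_grav+buoy)/(6πηr·λ⊥), with
v_m(h) = 6·v̄·(h/H)(1−h/H) the parabolic profile and net weight
(4/3)πg·r³(ρp − ρm) (cells 1050 kg/m³, medium 1017.5 kg/m³). The wall
drag enhancements λ⊥ and λ∥ are products of truncated single-wall
method-of-reflections corrections, 1/(1 − (9/8)s + s³/2) perpendicular
and 1/(1 − (9/16)s + s³/8) parallel, s = r/(center-to-wall distance).
The parallel correction matters: during strong pDEP dips cells skim within
a micron of the floor, where the unbounded-drag estimate of the downstream
DEP force would spuriously stall them on the electrode-edge field
singularity.

### Hydrodynamic lift

The lift on a sphere translating in shear flow near a wall is the least
constrained ingredient; the package uses a screened wall repulsion

    F_lift = 6·C·η·v̄·r³/gap² · exp(−gap/ℓ) · tanh(z/δ),

with C = 0.31, gap the particle-surface-to-nearest-wall distance,
ℓ = 1.0 µm, and δ = 0.5 µm a regularization width that makes the
mid-channel null continuous (z = H/2 − h). The screening length is the
one deliberate calibration in the transport stage, chosen once so that
the no-DEP equilibrium (lift balancing net weight) of 10–15 µm cells
sits at heights where the transport velocity is ~900–1100 µm/s — the
band in which the instrument is described as operating, and the only
regime in which its phenomenology is self-consistent: cells entering
near equilibrium show v_diff ≈ 0 without actuation, nDEP cells rise
*and speed up* (they sit below the parabola maximum), and pDEP cells dip
without being captured (the repulsion catches the dive near the floor).
An unscreened inverse-square form and a bounded "plateau" form are
provided as alternates (`lift_model`), because the functional form itself
is an approximation; with the unscreened form the equilibrium moves to
mid-channel and the nDEP speed-up inverts, which contradicts the device's
observed behavior.

Trajectories are integrated with x as the independent variable
(RK45, rtol 1e−6, step ceiling gap/5 so the electrode region is always
resolved), with a terminal event when the downstream velocity reaches
zero (pDEP capture at an electrode edge; the trajectory is flagged).
vi and vo are least-squares slopes of x(t) over windows ending 50 µm
before and starting 50 µm after the electrode pair — the same estimator
the video tracker applies, so simulated and measured observables are
commensurable. A reference integration at 1/100 the step ceiling agrees
with the default settings to <0.5% in v_diff.

### Drive voltages

At the 8 Vpp discrimination drive the vertical DEP velocities near the
electrodes reach the mm/s scale, hundreds of times the net settling
speed. Strongly pDEP cells therefore dive to the lift floor and their
v_diff saturates (nearly independent of Re{Kcm} within the viable band)
— ideal for binary viability discrimination (+50…110 µm/s versus
−250…−500 µm/s for nDEP), useless for quantitative inversion. The
forward mapping for Re{Kcm} estimation is therefore built at a gentler
2 Vpp drive, where v_diff is graded and strictly monotone in Re{Kcm}
over [−0.5, 0.55]. This mirrors instrument practice: discrimination and
quantitative spectroscopy are different operating points.

## Velocity → Re{Kcm} mapping

The forward grid tabulates v_diff over (radius, Re{Kcm}, vi). Entry
height is not observable, so each (r, vi) node root-finds the entry
height whose *fitted* vi matches the node value (Kcm = 0 during the
search; tolerance 1% of vi), restricted to heights between the no-DEP
equilibrium and just below mid-channel — below equilibrium the wall
repulsion restores cells within a few frames, so lower vi values are not
sustained and such nodes are marked invalid (>20% invalid nodes aborts
the build). Inversion interpolates bilinearly in (r, vi) and monotonically
along the Kcm axis; the confidence interval inverts v_diff ± 56 µm/s, the
instrument's no-DEP differential-velocity standard deviation. Default
axes: r = 5.0–7.6 µm (5 nodes), Kcm = −0.5–0.55 (8 nodes),
vi = 1080–1440 µm/s (5 nodes).

Cells observed at velocities above their equilibrium band are still
settling, which adds a +10–35 µm/s baseline to v_diff (below the 56 µm/s
noise unit). The baseline is part of the forward model, so round-trip
inversion is unbiased (median |ΔRe{Kcm}| ≈ 0.004, max ≈ 0.07 over 100
noise-free draws); but a *measured* v_diff of exactly zero at an
above-equilibrium vi correctly inverts to a slightly negative Re{Kcm}
(the nDEP push that cancels settling), not to zero.

## Synthetic imaging

The generator emulates the instrument's optics: 0.62 µm/pixel, 226 fps,
8-bit quasi-darkfield frames (full field of view 670 × 894 µm² =
1080 × 1442 pixels; the demonstration pipeline defaults to a 320-row
lateral crop, which carries the same per-cell information at a fraction
of the cost since the physics is invariant across the width). Background:
a dark base level (12 gray levels) with a smooth illumination ramp, a
static fixed-pattern texture, and two darker stripes at the true
electrode positions. Cells are bright-rimmed disks — the rim, a 1-pixel
Gaussian ring, is centered √(2 ln 2)·σ inside the true radius so the
apparent extent (full width at half maximum) equals the true diameter,
e.g. a 14.7 µm cell spans 23.7 pixels — with a dim interior, plus
Gaussian read noise (σ = 3 levels) and signal-dependent shot noise.
No physical optics: defocus blur versus height, diffraction, and
halo asymmetries are not modelled, so passing tests demonstrate pipeline
correctness on edge-dominated images, not robustness to real optical
aberrations.

The default population emulates a five-day nutrient-depleted CHO culture:
45% viable (diameter 14.67 ± 3.07 µm) and 55% non-viable
(12.00 ± 2.86 µm), truncated to 8–20 µm, Poisson arrivals, lateral
positions uniform over the frame. Each cell's Re{Kcm} is evaluated from
its component's double-shell preset rescaled to its own radius, so the
size spread induces the published ±20% Re{Kcm} spread. Entry height is
the cell's hydrodynamic equilibrium plus an upward half-normal jitter
(scale 3 µm): cells arrive from the top inlet and are still settling,
which is what spreads the incoming velocities over the working band.

## Tracking

Static background = pixel-wise temporal median over ≤200 uniformly
subsampled frames. Detection: Gaussian smooth (σ = 1 px), absolute
residual against the background, threshold at 4× the robust noise scale
(1.4826·MAD), 8-connected components, hole filling. Features are measured
on the *unsmoothed* residual: intensity-weighted sub-pixel centroid;
size by edge thresholding — the equivalent-circle diameter of the
component's support above half its rim intensity (95th-percentile), whose
outer contour is the apparent cell boundary, making the size estimate
independent of the detection threshold; eccentricity
√(1 − λminor/λmajor) from the binary component's central second moments.
Components outside 5–30 µm or with eccentricity > 0.75 are rejected as
anomalies. Under this moment-based definition single cells measure
≈0.1–0.3 and merged overlapping pairs ≥0.8, which is what the cutoff
separates; it is not comparable to eccentricity values quoted under other
shape conventions.

Linking: per frame pair, optimal bipartite assignment
(`linear_sum_assignment`) on squared distances to constant-velocity
predicted positions, gated at 15 px (gate widened while coasting);
unmatched tracks may coast up to 2 frames; tracks shorter than 5
detections are dropped. Velocities use the same windowed OLS slopes as
the simulator; tracks missing a side are flagged `partial` and excluded
from population analysis.

## Population analysis

Two-component full-covariance Gaussian mixture on (vi, v_diff), best of
10 seeded EM restarts, convergence 1e−8, diagonal regularization 1e−6.
The component with larger mean v_diff is labelled pDEP (viable at 6 MHz).
Two stability diagnostics flag unsupported fits: restarts disagreeing on
weights by >0.1, or component means separated by <2 pooled-Mahalanobis
units (a single blob split in half looks stable but is not a mixture).
Probability ellipses are Mahalanobis contours at the χ²(2 dof) quantile
of the requested mass (the levels are configurable; no level is
hard-coded). Size statistics report per-cluster sample mean and ML normal
fit of the optically measured diameters.

## Problem sizes in the test suite

The bundled experiments are sized for a desk-scale run: field solves at
0.5 µm steps on a 1 mm × 50 µm domain; mapping grids of 5 × 8 × 5 nodes;
100-draw round-trip checks; and an end-to-end experiment of 70 cells in a
320 × 1000-pixel strip (~1300 frames), of which typically ~60 survive
tracking (losses are overlapping cells rejected as anomalies, plus a few
track fragmentations). These sizes recover mixture weights to binomial
accuracy at n ≈ 60 and per-cell label agreement well above 90%; they are
statements about the pipeline's consistency with its own generator, not
about any recorded dataset.

## Known limitations

- The lift law (form and screening length) is a modelling choice
  constrained only by the device's described operating point; absolute
  v_diff magnitudes therefore carry model uncertainty even though signs,
  orderings, and round-trip inversions are robust.
- The point-dipole DEP force overestimates gradients once the gap between
  cell and floor is small compared to the cell radius (no Maxwell stress
  integration).
- The rectangular mapping grid cannot cover (r, vi) pairs below the
  largest radius's equilibrium velocity; queries there raise rather than
  extrapolate.
- Eq-of-motion integration treats capture as terminal; partial
  post-electrode data of captured cells are not used.
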