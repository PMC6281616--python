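# Methods

This note documents the models and procedures implemented in `memtube`:
the coarse-grained membrane-tube simulator, its trajectory observables,
the fluorescence morphometry pipeline, and the synthetic-data generators
that stand in for the microscope.  It states the assumptions, defaults
and numerical choices, and what the desk-scale defaults do and do not
establish about full-scale behavior.

## 1. Coarse-grained membrane model

### Lipids

Each lipid is three sites in a row — head (H), body (B), tail (T) —
connected by harmonic bonds of rest length 1.0 nm (k = 100
kcal mol⁻¹ nm⁻²) with a soft 1–3 spring (k = 5, rest 2.0 nm) keeping
the molecule straight.  Site mass is 1 (reduced).  Nonbonded
interactions have two parts:

* a **soft repulsive core**, `V_rep(r) = ε_rep (1 − (r/r₀)²)²` for
  r < r₀ = 2^{1/6} σ, with barrier height ε_rep = 15 kcal mol⁻¹
  (≈ 24 kT at 310 K) for every class pair.  Soft cores are the
  signature of effective potentials obtained by force-matching highly
  coarse-grained membrane models: two sites *can* pass through each
  other at a finite energy cost.  This choice is deliberate and is what
  makes membrane topology changes (lipid flip-flop, stalk formation,
  scission of thin necks) thermally accessible on simulated timescales.
  A hard-core (WCA) variant of the same three-site geometry was
  evaluated during development and produced bilayers whose thin tubes
  never underwent scission within any affordable run (including a
  3×10⁵-step probe of a 2 nm-lumen tube) because single-lipid passage —
  the elementary step of neck remodeling — was excluded;
* a **finite-range attractive well** between hydrophobic (B/T) sites,
  flat at −ε up to r₀ and decaying smoothly to zero at r₀ + w_c
  (C¹ at both ends, polynomial in r²; the same shape as the cos²
  well of Cooke-type models), with ε = 0.65 kcal mol⁻¹ ≈ 1.05 kT and
  w_c = 1.30 nm.  kT/ε ≈ 1.0 with a wide well keeps the bilayer fluid.

Range parameters: σ = 0.80 nm for hydrophobic pairs, σ = 0.68 nm for
head–head and 0.74 nm for head–hydrophobic pairs.  The smaller head
makes the lipid effectively cone-shaped, which favors self-assembly
into bilayers and stabilizes the negative-curvature intermediates of
fission.  Head-involved pairs are repulsive-only by default; the
parameter tables support a head–head attractive term (headgroup
bridging of apposed membranes), off by default because it destabilizes
strongly curved tubes.

DOPS and DOPC are carried as per-lipid labels (default composition
40:60) with identical interactions; a per-species multiplier on the
head repulsion is available as a configuration hook.

### Emergent properties and conventions

At 310 K a planar patch built at 0.70 nm² per lipid is stable and fluid;
leaflet head sheets are well separated (per-leaflet z-spread ≈ 0.3 nm).
The mean head-to-head distance across the bilayer is ≈ 3.8 nm; the
**bilayer thickness** reported by the package is the steric thickness,
head-to-head distance plus one head diameter (≈ 4.5 nm), i.e. the
outer-surface separation an excluded-volume probe would measure.  The
relaxed area per lipid is ≈ 0.70–0.75 nm²; tubes built at the
full-scale geometric value (0.67 nm²) therefore carry a small
compressive strain and relax their radii upward by a few percent.

### Protein scaffolds

Scaffolds are stacked rings of frozen sites: ring diameter 25 nm, 35
sites per ring (adjacent sites 2.24 nm apart), rings 0.25 nm apart
axially; a 4 nm scaffold has 16 rings (560 sites) and a 20 nm scaffold
80 rings (2800 sites).  Scaffold sites interact with lipid **head**
sites only through a 12-6 Lennard-Jones potential with σ = 0.2 nm and
ε = 1 kcal mol⁻¹, energy-shifted to zero at the cutoff (2.5 σ at full
scale).  Scaffold sites are frozen: they exert forces but are never
integrated, and they are excluded from the thermostat's degrees of
freedom and from kinetic-temperature reporting.

### Units and integration

Lengths are nm, energies kcal mol⁻¹, site mass 1.  The CG time unit τ
is defined as the default integrator step; internally 1 τ = 0.01
√(m·nm²·mol/kcal), so thermostat damping of 100 τ equals one natural
oscillation time of the nonbonded landscape.  No mapping of τ to
seconds is attempted.

Dynamics are velocity-Verlet with a Nosé–Hoover chain of length 3
(damping 100 τ, chain length chosen for ergodicity).  Equilibration
draws Maxwell–Boltzmann velocities at 10 K and ramps the thermostat
target linearly to 310 K, capping per-step displacements at 0.04 nm (a
gentle push-off that lets freshly built lattices relax without
divergence).  Neighbor handling is a typed Verlet list over cell-sorted
sites with a 0.3–0.4 nm skin, rebuilt when any site has moved half the
skin.  A divergence guard aborts a run if any site speed exceeds 60
nm per internal time unit.  Single-threaded kernels make trajectories
bit-reproducible for a given seed.

## 2. Desk-scale study conditions

The full-scale reference system (100 nm tube, 14,500 lipids, 10⁶-step
ramp, 10⁷-step production) is available as the `paper_full` preset but
is not exercised by the test suite.  Desk-scale experiments use 30 nm
tubes with proportionally fewer lipids (≈ 1,500–4,000) and runs of
10³–10⁴ τ.

Two desk choices compensate for the ~10²–10³-fold shorter sampling:

* **Build tension.**  Desk tubes are built at 0.80 nm² per lipid,
  above the relaxed value, putting the membrane under modest lateral
  tension.  Scission of sub-critical tubes is a stochastic, thermally
  activated event; at the full-scale run length it is sampled at native
  rates, while desk runs observe it at a tension-accelerated rate.  All
  radii in a scan share the same build rule, so the radius ordering of
  stability — the observable of interest — is preserved.  Under these
  conditions tubes with initial lumen radii ≤ 2 nm undergo scission
  within ~10⁴ τ while tubes with lumen diameters of 5–6 nm remain
  intact for the whole desk run, reproducing the full-scale dichotomy.
* **Scaffold reach.**  The desk scaffold ring sits 1.0 nm above the
  tube's outer radius (full scale: 2.5 nm) and the protein–head cutoff
  is widened to 5 σ = 1.0 nm, keeping the attraction band within reach
  of the thermal undulations of a scaled-down tube so that adhesion
  nucleates within desk runs.

Desk runs use 3 seeded replicas per condition with early termination
once scission is detected.  The desk defaults are a 5×10³-step ramp and
1.2×10⁴ production steps.  The acceptance scan gives the scission-prone
radii (1–2 nm) that full protocol and runs the wide tubes (3–6 nm) —
which have never fissioned in any desk run — over a shorter bounded
stability window (2×10³ + 2×10³ steps) so the whole 6-radius, 3-replica
scan stays desk-sized.  These counts are desk-scale approximations,
far below the full-scale 10⁷-step protocol, and quantities that depend
on rare events at larger radii (e.g. the occasional fission of a
3 nm-lumen tube over 10⁷ τ) are outside what they can sample.

## 3. Trajectory observables

* **Lumen radius.**  The tube axis is the line parallel to x through
  the lipid center of mass (the scaffold pins the tube; tilt is
  negligible).  Leaflets are assigned per frame from the sign of the
  head-minus-body radial component, lipids with |component| < 0.05 nm
  keeping their previous label.  The lumen radius of an axial bin is
  the mean radial distance of inner-leaflet head sites in it; profiles
  report mean and variance over the last 20 dumped snapshots in 1 nm
  bins (scaled with tube length).  Empty bins are flagged, not
  silently dropped.
* **Scission detection.**  The tube is severed at axial position x when
  no contact pair of hydrophobic sites (cutoff 1.1 nm) spans x; gaps
  wider than 0.3 nm are reported with their position.  The
  pre-scission lumen radius is the minimum of the profile within
  ±2 nm of the break in the last intact frame; a lumen already
  stripped of inner-leaflet heads (fully collapsed neck) has radius 0
  by definition.
* **Thinning series.**  Per snapshot, the lumen radius at the tube
  middle and at the thinnest site outside the scaffold boundaries;
  post-scission frames are NaN and flagged.
* **Interleaflet mixing.**  Fraction of lipids whose leaflet assignment
  differs from their t = 0 label, per snapshot.

## 4. Fluorescence morphometry

The intensity→radius calibration implements the standard two-slope
scheme for diffraction-limited tubes.  k₁ (a.u. nm⁻²) is the
through-origin regression of SLB ROI integrated densities on ROI areas;
a tube segment of length l then has radius r = ID/(k₁·2πl), reflecting
the distance from the lumen to the bilayer midplane.  k₂ (a.u. nm⁻¹)
is the through-origin slope of peak tube intensity against radius;
dividing a peak-intensity trace by k₂ gives the per-pixel radius
profile.  Background correction subtracts the median of an empty
region.

Bulges are contiguous runs of the radius profile above the local
rolling-median baseline by 20% (default), merged within 200 nm;
constrictions are the mirrored criterion.  R_b/R_c is the extreme
radius in the run.  Bulge onset is operationally the first frame the
bulge criterion fires at a position; scission in movies is the first
frame a ≥300 nm run of the profile falls below 2 nm.  The fission time
of an event is scission minus onset.  Remodeling/fission probabilities
per starting-radius bin carry Wilson 95% intervals.

FRAP recovery uses the model-independent hyperbolic form
F(t) = F_b + (F∞ − F_b)·t/(t_half + t) with mobile fraction
(F∞ − F_b)/(F_p − F_b); a single-exponential alternative is available
by flag.  Scaffold growth rates are Theil–Sen slopes of the
half-maximum edge position per kymograph line against time; edges that
move less than one pixel report rate 0 with a low-confidence flag.

## 5. Synthetic imaging

The generator renders what the morphometry stage assumes: tube
brightness proportional to local membrane area (line density ∝ 2πr(x)),
uniform SLBs, isotropic Gaussian PSF (σ = 120 nm default, roughly
epifluorescence at ×100), pixel size 80 nm, Poisson–Gaussian camera
noise, all deterministic per seed with exact ground-truth logs.

The remodeling-movie generator grows bulges under scaffolds at a set
rate while holding ∫r dx constant by uniformly thinning uncovered
regions (the finite-reservoir constraint), logs onset when a bulge
crosses the same 20% criterion the detector uses, triggers scission in
the widest inter-scaffold gap when the thinned radius reaches the
fission threshold, and renders retracting capped ends as bright puncta.
With baseline 10 nm and threshold 5 nm the thinned regions pass
through ~7 nm before scission at ~5 nm.

What the generators do **not** emulate: vectorial/asymmetric PSFs,
photobleaching beyond the FRAP bleach step, tube wobble out of focus,
and dense fields requiring segmentation.  Detector tests passing on
synthetic data therefore validate the estimators' numerics and
conventions, not their robustness to those real-data effects.

## 6. Numerical choices and degenerate inputs

* Pair kernels split the Verlet list by type so the dominant
  hydrophobic loop is branch-light; energies are only accumulated on
  logging steps.
* Through-origin calibration fits require ≥3 ROIs (≥2 distinct areas)
  and ≥3 tubes (≥2 distinct radii, warning below a two-fold span);
  non-positive slopes raise.
* Negative corrected intensities clip to zero with a warning;
  zero-variance traces make the Pearson statistic undefined (error).
* FRAP fits require F_b < F_p and ≥10 points; non-convergence raises
  with the residual.
* Scission detection rasterizes pair coverage at 0.05 nm; detection is
  monotone in practice because cut ends retract under tension, but the
  detector itself re-evaluates every frame independently.
* `build_tube` refuses geometrically impossible lumens and warns when a
  requested lipid count implies an area per lipid far from target;
  leaflet counts follow mid-surface areas to within one lipid.

## 7. Known limitations

* The lipid force field is a surrogate parameterization: it reproduces
  the emergent behaviors the study needs (stable fluid bilayer at
  310 K, thickness ≈ 4.5 nm steric, stable 5–6 nm-diameter tubes,
  scission of ≤4 nm-diameter tubes, scaffold-induced bulging), not any
  specific published parameter set.
* Desk-scale scission statistics are tension-accelerated; absolute
  fission times in τ are not comparable with full-scale runs.
* The soft-core model trades excluded-volume realism for accessible
  topology changes; osmotic/solvent effects and electrostatics are
  absent, and DOPS/DOPC differ only by label under the defaults.
* Post-scission analyses treat fragments by the same axis/leaflet
  conventions as intact tubes; per-fragment axes are not fitted.
* Scaffold adhesion in the soft-core model proceeds partly by
  interleaflet transfer at the contact line: lipids feeding the adhered
  outer surface drain the inner leaflet beneath the ring.  A long
  scaffold therefore shows the expected phenotype (bulge under the
  scaffold above the shoulders above the thinned far field, progressive
  off-scaffold thinning, scission within ~3×10⁴ τ), but a *short*
  scaffold's lumen under and near the ring collapses instead of
  inflating — the outer surface bulges while the lumen profile does
  not — and scission of long-scaffold tubes tends to occur beneath the
  scaffold center rather than in the far field.  These two desk-scale
  deviations from the full-scale pathway are inherent to the soft-core
  adhesion mechanism, not tunables of the presets.
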