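# Methods

## Scope and data flow

The package models a single actuation of a nasal spray into one nasal
passage of a 10-day-old infant and the subsequent fate of the liquid:

1. `geometry` builds a labelled triangulated surface and sets the
   gravity vector from the body position;
2. `spray` turns a dose and device parameters into droplet parcels at
   the nozzle exit;
3. `transport` flies the parcels to first wall contact, producing the
   initial deposition map;
4. `film` advances the deposited liquid film under the holding-capacity
   constraint and tallies runoff;
5. `assay` implements the ex vivo mucosa retention analysis that
   anchors the holding capacity, and `synth` generates statistically
   matched synthetic trials;
6. `scenario` orchestrates the chain over dose/h_max/posture matrices
   and formats the dose-distribution tables.

## Geometry surrogates

Patient CT anatomy is not available, so the nasal passage is a
parametric curved duct calibrated to the measured per-region surface
areas of a 10-day-old airway (vestibule, valve, turbinate, nasopharynx,
pharynx, larynx). The duct ascends at 35° through the vestibule and
valve, runs posteriorly through the turbinate, and descends at 70°
(still drifting posteriorly) through the nasopharynx to an open
laryngeal outlet, so the passage drains toward the outlet in both
supine and back-tilt postures. Each region is a circular segment whose
radius comes from its effective diameter (4V/A) and whose length is
iterated (3–4 fixed-point passes against the meshed area) until every
region's lateral area matches its target within 0.5 % — comfortably
inside the 2 % contract. Anterior regions (paired structures) enter at
half their bilateral area for single-passage dosing. What the
surrogate preserves is exactly what the runoff mechanics depend on:
per-region area × h_max capacity and down-gradient connectivity. What
it does not preserve: cross-sectional shape (real turbinates are
convoluted slits, not tubes), left/right asymmetry, and the widening
vestibule chamber — hence regional *deposition* splits are
geometry-dominated here (see Limitations).

Body orientation only rotates the gravity vector (body frame:
+x posterior, +z superior; supine gravity = +x, back tilt rotates about
the lateral axis). Coordinates are mm; g = 9.81 m/s².

## Spray source

Droplet count follows the dose divided by the single-droplet volume,
rounded, with larger doses scaling the rounded 0.25 mL reference count
proportionately (so a doubled dose carries exactly twice the
droplets). The three measured volume percentiles over-determine a
two-parameter lognormal; the fit anchors the median exactly at Dv50
and least-squares the log-slope through the Dv10/Dv90 z-scores, so the
headline volume-median is exact while the tails land within ~3 % of
the measurements. Parcels (default 50,000 per actuation; scenario runs
here use 3,000) carry equal liquid volume; directions are uniform in
solid angle within the 45° plume cone; speeds default to the measured
8.5 m/s with no per-droplet jitter (the bench measurement reports a
spread, but whether jitter was applied per droplet is unstated — the
deterministic default makes runs reproducible and the spread is
available via `speed_jitter_m_s`).

## Droplet transport

Ambient air is quiescent: the coma-state inhalation flow (0.76 L/min)
is an order of magnitude slower than the droplets and air is three
orders less dense than the liquid, so deposition is inertia-dominated;
an analytic background flow can be supplied for sensitivity runs. Drag
is Stokes with the Schiller–Naumann correction f = 1 + 0.15 Re^0.687,
integrated semi-implicitly (exact in the drag-free limit, where the
chord integration reproduces the ballistic parabola to machine
precision). Substeps are capped at 1 mm of travel; wall contact is an
exact segment–triangle intersection over KD-tree candidates with the
nearest hit along the path winning; a touching droplet deposits its
full parcel volume (no rebound or splash). Parcels leaving the domain
box are tallied as escaped; parcels still airborne at `t_max` (0.25 s)
are flagged and counted with the escaped volume (zero in closed-duct
runs).

## Wall film

The film is face-centred finite volumes on the triangle mesh: height
`h` and depth-averaged tangential velocity **V** per face, first-order
upwind edge fluxes for mass and momentum, Green–Gauss face gradients
with a metric correction (the discrete gradient of a constant field is
forced to zero on curved patches), and a two-pass gradient/divergence
operator for the surface Laplacian in the capillary pressure. A
transient momentum term is carried so explicit stepping is well posed;
the steady balance recovers the printed wall-film momentum equation.
The ambient pressure is spatially constant (its gradient vanishes) and
the gas-side interfacial shear is zero in quiescent air.

Numerical choices:

* semi-implicit wall drag, whose fixed point reproduces the terminal
  balance V = g_τ h²/(3ν) exactly for any step size (verified to 1 %
  against the closed form on 60° and 90° plates at two resolutions);
* adaptive Δt = 0.4 × min(advective/gravity-wave bound, capillary-wave
  bound ℓ²/(π √(σh/ρ)));
* a thin-film floor h_min = 10⁻⁶ mm in the drag denominator; dry faces
  carry no momentum; a 1 m/s velocity limiter guards wetting-front
  division noise;
* explicit `step_film` rejects an oversized step with the required Δt
  and aborts on negative heights (a scheme failure, not a data state).

**Holding capacity and adhesion.** The measured maximum film heights
(0.324 mm at 45°, 0.220 mm at 90°) act twice. First, films at or below
the local h_max are immobilised: their tangential weight cannot
overcome the liquid–wall intermolecular resistance, which is the
observed ex vivo behaviour and the reason a sub-capacity dose is
retained at all — a free film on a slope would drain indefinitely. (A
stress-threshold yield formulation was tried and rejected: capillary
stress at a discrete wetting front grows as Δx⁻², defeats any finite
threshold, and produces perpetual band-edge churn.) Second, excess
above h_max is redistributed by `apply_hmax_constraint`: each pass
strips the excess and hands it to neighbours weighted by the
gravitational potential drop plus a small lateral share (10 % of the
mean edge length), so an overloaded deposition patch spreads as a
widening downslope fan, absorbing into free capacity as it goes;
excess crossing an outlet rim leaves to the runoff ledger, and excess
trapped in a saturated closed basin stays put under a pooling flag.
Mass is conserved exactly (checked to 10⁻¹² relative). A pure
steepest-descent chain router was rejected because a one-face-wide
valley has far less area × h_max capacity than the region it crosses
and would spuriously flush sub-capacity doses to the outlet.

`run_film` alternates stepping and constraint, snapshots requested
checkpoint times, and stops early once relative film redistribution
falls below 0.01 %/s; on the surrogate the film settles in ~0.05 s of
simulated time, consistent with the second-scale stabilisation seen in
the source simulations. Constant h_max is the default (matching the
comparison of the 0.324 mm and 0.220 mm bounds); an angle-dependent
h_max(θ) interpolation table is supported as an optional mode.

## Retention assay and synthetic data

The assay analysis is pure mass balance: applied = syringe loss,
runoff = cardboard gain, deposited = applied − runoff, theoretical
thickness = deposited/(4 cm² × 1.0088 g/cm³), compared with the mean
of five optical point thicknesses (2–18 mm from the lower edge) and
reported at bench precision (0.001 g, 1 µm, 0.1 %) with full precision
retained internally. Values recomputed from raw masses take precedence
over published derived cells when they conflict (five such cells exist
in the shipped reference table; `compare_with_printed` reports both).
The optical image analysis itself is out of scope — point thicknesses
are first-class inputs.

The synthetic generator emulates that experiment: a true retained
thickness curve, monotone in tilt angle and anchored at the measured
capacities (625 µm at 0° — the full dose over the coupon — 324 µm at
45°, 293 µm at 60°, 220 µm at 90°, monotone PCHIP between), applied
mass ~ N(0.246 g, 0.8 %), runoff noise 3.9 %, optical noise 4.3 %
(the observed column RSDs; the noise law is modelled as independent
Gaussian since no distributional form was reported), and a linear
five-point gradient of −5 µm/mm toward the upper edge. The noise-free
round trip is exact by construction, which is what makes the generator
a usable oracle for the analysis pipeline; what it does not emulate is
image noise, evaporation drift during the settling minute, or any
angle dependence of the gradient (exposed as a parameter instead).

## Problem sizes

Default scenario runs here use a 1.8 mm target edge (~2,600 faces),
3,000 parcels and a 1 s film horizon with early stopping; these sizes
give region areas within 0.5 % of target, parcel-count-independent
deposition splits at the percent level, and second-scale runtimes per
(dose, h_max) case. The spray-distribution check draws 10⁵ diameters.

## Limitations

* Regional deposition splits on the surrogate are set by ray geometry:
  the neonatal valve (r ≈ 1.2 mm) intercepts nearly all parcels at any
  exit speed, so exit-speed sensitivity of the deposition pattern —
  which real, wider anatomies show — is not reproducible here. The
  underlying inertia-vs-gravity physics is verified on plate
  geometries instead.
* Absolute runoff fractions are anatomy-specific; the surrogate
  reproduces the qualitative structure (full retention at 0.25 mL,
  runoff onset at 0.50 mL, capacity-limited saturation at 1–2 mL, and
  more runoff for smaller h_max) and lands within a few points of the
  published dose-runoff table, but only the structural properties are
  asserted.
* Evaporation and tissue absorption are deliberately omitted (as in
  the source model), making runoff predictions conservative; two-way
  air–film coupling, film stripping, and contact-line physics beyond
  the h_max surrogate are out of scope.
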