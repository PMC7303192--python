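# Methods

`tavisim` is a desk-scale simulator of transcatheter aortic valve
implantation (TAVI): it deploys parameterised stent frames into synthetic,
patient-like aortic roots with an explicit quasi-static finite-element
scheme, and computes the three outcome predictors used to compare such
simulations against clinical imaging — the projected stent diameter at the
valve level, paravalvular-leak (PVL) gap channels, and regional maximum
principal strain of the implantation site.  It also ships the per-patient
outcome tables of a published 28-case retrospective cohort (14
balloon-expandable, 14 self-expandable devices) as plain-text fixtures and
recomputes their summary statistics.

This note documents the models, their assumptions, the defaults, and what
the synthetic set-up can and cannot say about real patients.

## Synthetic anatomy

The implantation site is a surface of revolution: a cylindrical left
ventricular outflow segment below the annulus plane (z = 0), three sinuses
of Valsalva modelled as a three-lobed radial bulge (`sinus_bulge`, default
1.35, peaked mid-sinus and vanishing at the annulus and sinotubular
junction), a smooth-step taper to the ascending aorta, and a structured
triangle grid (default 48 around, ~1.25 mm ring spacing).  Landmarks follow
one fixed convention shared by all modules: axis = +z toward the aorta,
angles counter-clockwise seen from the aorta, non-coronary sinus (NCC)
centered at 0°, right (RCC) at 120°, left (LCC) at 240°, each sector a
half-open 120° interval.  Coronary ostia are landmark points on the wall
(defaults 14 mm / 13 mm above the annulus for left/right), not holes.

Native leaflets are structured membrane patches: the attachment edge is a
U-shaped curve snapped onto wall grid vertices (commissures at 65% of the
sinus height, dipping to the annulus at the sector center), the free edge
runs commissure-to-commissure through a central coaptation ring
(`leaflet_free_edge_radius`, default 35% of the annulus radius, coaptation
center at 5 mm), interior nodes blend the two with a mostly-downward belly
droop.  The droop is sized so the free-margin length is about 1.25 times
the commissure-to-commissure chord — the anatomical redundancy of real
leaflets; perfectly taut synthetic leaflets cage an expanding frame well
short of the wall, which real (redundant, post-valvuloplasty) valves do
not.  Attachment nodes are merged with wall nodes at assembly, so leaflets
follow wall deformation exactly.

Calcific deposits are modelled as stiffened, thickened leaflet patches, not
separate contact bodies: a patch of leaflet elements (one nodule per
selected cusp; placement jittered by the seeded generator, the only random
element in the whole pipeline) is assigned the calcium material and an
equivalent membrane thickness solved so that the closed prism surfaces
built over the patches integrate — by the divergence theorem — to the
requested total volume within a fraction of a percent.  The default total
volume, 726 mm³, is the balloon-expandable cohort's average leaflet calcium
load; the nodular patch radius scales with the per-nodule volume so single
bulky deposits stay anatomically plausible (a few mm thick).  Calcium
morphology beyond total volume is not constrained by any source; pattern
(`nodular`/`arc`), cusp selection and volume are plain configuration.

## Device frames

Both families are diamond-cell lattices of two-node beam elements
(defaults: 8 cells circumferentially, two beam elements per strut; strut
section 0.40 × 0.35 mm for the balloon-expandable family and
0.50 × 0.40 mm for the self-expandable one — the latter calibrated so the
frame's radial force at large opening is strong enough to appose a
stenotic root, the role the many fine struts of the commercial frame
play).  The exact strut dimensions and cell counts of the commercial
frames are not public; these are representative defaults, and every
topology parameter is configurable.

* Balloon-expandable (sizes 23/26/29 mm): cylindrical at the nominal
  diameter, heights 14.5/17.2/19.1 mm, cobalt-chromium alloy (elastoplastic),
  valve level at mid-height.
* Self-expandable (sizes 26/29 mm): hourglass profile — inflow flared to the
  nominal diameter, waist at 78% of it, outflow at 110% — built of
  superelastic Nitinol, with the 12 mm inflow skirt marked as `skirt_rings`
  (heights 48/50 mm and 8 axial cells place a node ring at the 12 mm skirt
  boundary; these heights are a desk-scale choice so the frame fits the
  synthetic root plus ascending segment).  The valve level defaults to the
  waist.

## Constitutive models

All stresses in MPa, unit system mm/N/MPa/s.

* Linear elastic (artery E = 7.78, ν = 0.45, t = 1.9 mm; leaflets E = 6.375,
  ν = 0.45, t = 0.5 mm; balloon fabric E = 600, ν = 0.4, t = 0.06 mm).
* Elastoplastic, 1-D radial return with optional linear hardening (default
  perfect plasticity): calcium E = 250, ν = 0.3, yield 0.25; frame alloy
  E = 232,800, ν = 0.34.  The source table's frame-alloy row is
  typographically corrupted where yield and density should be; the defaults
  (yield 414 MPa — annealed MP35N literature value — and density
  8,000 kg/m³) are documented stand-ins and plain config.
* Superelastic Nitinol, a 1-D flag-shaped hysteresis: austenite elastic
  branch (E_A = 45,000), forward transformation along the loading plateau
  line (440 → 540 MPa as the signed martensite fraction grows to ±1,
  carrying a transformation strain of 4.5%), reverse transformation along
  the unloading plateau (250 → 140 MPa), full strain recovery at zero
  stress.  During transformation the stress is computed with the austenite
  modulus, which makes the dissipated energy of a full cycle exactly the
  area between the plateau lines; the martensite modulus (32,000) governs
  only the fully transformed branch.  The parameter set is a representative
  literature card (the cohort study defers its Nitinol parameters to prior
  work without printing them); tension/compression are symmetric, and
  temperature dependence is out of scope.

Beams integrate these laws at fiber level on a 2 × 2 Gauss grid over the
cross-section, so struts can yield or transform in bending, which is where
stent frames actually deform.  Membranes use plane-stress
St. Venant–Kirchhoff from the surface deformation gradient; calcium patches
add a von Mises stress-scaling return with an elastic-compliance plastic
strain update (an approximation of the exact plane-stress return map,
adequate at the sub-percent yield strain of the calcium card); the balloon
uses a tension-field (wrinkling) variant that drops negative principal
stresses, so the radially shrunk "deflated" balloon is slack rather than
compressed.

## Structural solver

Central-difference explicit dynamics with lumped masses, mass scaling and
mass-proportional damping.  Corotational beam kinematics: an
element-attached frame follows the chord and the averaged nodal normals;
local end rotations (extracted from the nodal rotation matrices relative to
that frame) drive Hermite bending curvatures at two Gauss points plus
linear-elastic torsion; nodal forces are assembled so each element exerts
zero net force and zero net moment (the transverse shear couple equilibrates
the end moments).  Rigid motions therefore produce forces at round-off
only.  Rotational inertias are deliberately boosted (lever-arm scale); only
stability matters for quasi-static runs.  Membrane nodal forces come from
the first Piola stress and reference shape gradients.

Contact is one-pass node-to-surface penalty: followers against rigid
analytic surfaces (cylinder, plane) or against deformable triangulated
targets whose vertices are system nodes (reactions distributed
barycentrically, so action–reaction holds exactly).  A clearance
`gap_offset` absorbs strut radius and shell half-thickness.  Open tissue
sheets make one-pass contact ambiguous from the far side, so apparent
penetrations deeper than a capture band are treated as "not engaged" and
the force tapers smoothly to zero at the band edge; contacts against the
balloon avoid the ambiguity entirely by using the closed balloon surface as
the target with tissue/frame nodes as followers.  Friction (default 0,
frame–tissue) is a viscous-regularised Coulomb cap.  Candidate triangles
come from a periodically rebuilt centroid k-d tree, with an
activity-radius prefilter so distant followers cost nothing.

The stable step is the elementwise length-over-wave-speed minimum (true
shortest triangle altitude for membranes), scaled by √(mass scaling), with
an extra 0.5 margin and the contact-spring limit.  The balloon group
carries a selective ×4 mass boost so its slender shoulder triangles do not
govern the global step.

Quasi-static validity: every protocol stage ramps its loading with a
smooth-step, then settles with loading held until both (i) the kinetic
energy falls below 5% (configurable) of the *current recoverable strain
energy* of all elements and (ii) the largest nodal displacement per settle
chunk drops below 0.05 mm — superelastic recovery creeps slowly through
its hysteresis, and an energy gate alone can pass while the configuration
is still drifting.  Settling stays viscous (no velocity resets): the
momentum built up during recovery is what carries the frame through
hysteresis states in which a purely static relaxation would strand it, as
a real frame's inertia does.  Accumulated internal work is logged too, but
it is not the gate denominator because elastic springback (balloon
deflation, sheath release) legitimately returns stored work toward zero.
A stage that cannot pass the gate within its settle budget marks the whole
run invalid.

## Deployment protocols

Defaults follow the clinical procedure: valvuloplasty balloon inflated to
5 atm inside the native valve and deflated; both frames crimped to a 6 mm
delivery diameter by a rigid coaxial cylinder; the balloon-expandable frame
positioned with 1/3 of its height below the annulus and deployed by balloon
inflation (5 atm) and deflation; the self-expandable frame positioned at a
4 mm implantation depth (a mid-range default under the ≤ 6 mm guideline
limit, which is enforced as a hard validation error) and released by
pulling the confining sheath 80 mm axially.  The exposure front sweeps from
the inflow (annulus) end upward, so inflow rings expand first — the
clinical anchoring sequence; the partial-pullback invariant is a contiguous
expanded prefix from the released end.  Balloon sizing is derived from the
device (inflated-reference diameter = 0.88 × nominal, so the fabric's
pressure stretch brings it near nominal at 5 atm); for self-expandable
cases the balloon serves valvuloplasty only and is sized to the root
(1.2 × sinus height) rather than to the tall frame.  Balloon
deflation-folding is approximated by a prescribed radial shrink map — fold
mechanics are out of scope, only the inflated/deflated envelopes matter
here.  Stage durations and damping are configuration with tuned defaults;
all values are logged per stage together with the energy ratio and maximum
contact penetration.

## Outcome metrics

* **Projected diameter**: the valve-level ring nodes are projected onto the
  plane normal to a configurable x-ray viewing direction (deployed frames
  are not circular); the reported diameter is the maximal projected
  point-pair distance of a single view — whether the clinical measurement
  averages views is unknown, so the view is explicit configuration.
* **Gap map / PVL**: on a cylindrical grid (default 2 stations/mm, 72 bins)
  the leak clearance of a cell is the radial distance from the frame's
  outer envelope (beam samples + strut radius, angularly interpolated) to
  the *first* tissue surface along the bin's ray — wall inner surface,
  leaflet inner face, or calcific deposit.  A paravalvular channel hugs the
  device, so a leaflet pressed onto the frame seals its cell regardless of
  the open sinus pocket behind it; surfaces already inside the envelope
  count as contact.  Cells
  with clearance above a 0.1 mm threshold are open; connected components
  (8-neighbourhood with angular wraparound, so helical paths count) that
  span the device rule range — the full frame for the balloon-expandable
  device, the proximal 12 mm skirt for the self-expandable device — are
  leak channels, labelled by the sinus sectors their bins cross.  The
  discretisation and threshold are explicit stand-ins for an unpublished
  in-house criterion and are reported with every map.
* **Strain report**: per-element maximum principal Green–Lagrange strain of
  the wall membrane (logarithmic strain selectable), in percent;
  summarised as the average over elements below the lower coronary ostium
  and above the proximal frame end, the absolute maximum anywhere, and the
  maximum in the NCC–RCC angular span (0°–120°, the two half-sectors
  flanking the commissure over the left bundle branch, where conduction
  injury arises).

## Cohort tables

The three shipped TSV fixtures hold the printed per-patient rows of the
retrospective cohort (diameters from fluoroscopy, simulation-vs-fluoroscopy
differences, echo PVL descriptors, strain statistics for the
self-expandable cohort).  `summarize` reproduces the printed average rows;
because the source does not state its standard-deviation convention — and
its columns are in fact internally inconsistent (the balloon-expandable
mm-difference std reproduces only under the population convention, the
%-difference std only under the sample convention) — both conventions are
computed and a printed value is considered reproduced when either matches
to printed precision.  One printed cell (the absolute-max strain column's
±5.2) reproduces under neither convention and appears to be a typesetting
duplication of the neighbouring column; it is excluded from the
fixture-reproduction checks.  Echo descriptors are parsed to
presence + sinus sets by a fixed documented rule ("No PVL…" prefixes are
absent; otherwise every cusp token names a sinus).

## What the synthetic set-up shows — and what it does not

The generator emulates the *content* of patient-derived models (root with
coronary ostia, leaflets, ascending aorta, calcific deposits with realistic
total volume) but not patient-specific shape: real roots are non-circular,
calcium is irregular, and wall properties vary.  Passing the end-to-end
recovery suite therefore demonstrates that the machinery is mechanically
consistent (superelastic frames recover their nominal profile after
crimping to within 2%; a 26 mm frame deployed in a 24.5 mm-annulus
calcified root — an undersized deployment — opens a leak channel biased to
the deposit's sinus, while the same frame in a 23.5 mm root — the
oversized counterpart — seals; the 29 mm frame strains the sub-coronary
root of the same root strictly more than the 26 mm one) — it does not
demonstrate
clinical accuracy.  The cohort's headline agreements (83% PVL
identification, per-patient diameter errors, the pacemaker patient's
strain) require the unavailable patient CT anatomies; the package
reproduces the printed per-patient statistics exactly and exposes the same
agreement computation for synthetic batches.

## Numerical choices and problem sizes

Default test/acceptance runs use deliberately coarse discretisations — wall
36 × ~40 grid, 8-cell frames, two elements per strut, mass scaling 10⁶,
stage durations ~0.5–1.5 s with settle budgets of the same order — chosen
as the package's working point for desk-scale studies; every one of them is
configuration.  Determinism: fixed config + seed reproduce results bitwise
(the only randomness is the seeded calcium jitter and seeded test
utilities).  Known limitations: one-pass penalty contact admits small
penetrations (reported per stage) and no beam–beam self-contact; membranes
carry no bending stiffness, so leaflet coaptation is approximate; the
balloon's fold pattern, catheter tracking, post-dilatation and
fluid dynamics are out of scope; PVL severity grading is deliberately not
attempted — presence and sinus location only, as a geometric criterion.
One genuinely unexpected model behaviour is worth recording: the larger
(29 mm) self-expandable frame consistently opens ~0.5 mm *less* at its
inflow than the 26 mm frame in the same root, because its taller inflow
cone is dragged by the leaflet-held waist above; the undersized/oversized
leak contrast is therefore demonstrated with one device in two roots,
while the strain ordering uses the two devices in one root.
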