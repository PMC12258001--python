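# Methods

This note records the models `csgarc` implements, the assumptions behind
them, the parameters that matter, and what the synthetic test bed does and
does not establish about real treatment plans.

## Plan model

A step-and-shoot arc plan is an ordered list of control points, each one
gantry angle carrying exactly one energy layer, its spots, and the trimmer
configurations of the dynamic collimation system (DCS).  Angles are
degrees (IEC gantry convention); a clockwise full arc runs −180° → +180°
with strictly increasing angle, and an arc designed with *n* inclusive
positions has resolution 360/(n−1) degrees (129 positions → 2.8125°,
reported as 2.8°).  Trimmer bar positions are signed distances of each
bar's medial edge from the beam central axis in the beam's-eye view (BEV),
positive away from the axis on the bar's own side; 65 mm is the fully
retracted "off" state and −20 mm a permissive over-travel bound (a
configuration choice — the hardware limit is not published).  Spots below
0.025 MU are not deliverable; validated plans exclude them and any control
point they empty.  Canonical JSON serialization rounds floats to six
decimals so write∘read∘write is byte-stable.

## Beam delivery time

Delivery is strictly sequential (the DCS cannot move during scanning, and
energy switching is assumed to happen after the gantry reaches each
position), so total time decomposes exactly into four components:

* **Gantry**: rest-to-rest moves under a symmetric trapezoidal velocity
  profile with v = 6°/s and a = 0.6°/s²; `t = d/v + v/a` for d ≥ v²/a,
  else the triangular profile `2√(d/a)`.  The profile is concave in
  distance, so merging moves (after cutting a control point) never costs
  time.
* **Energy**: 6 s per low-to-high switch, 0.8 s per high-to-low, nothing
  for equal consecutive energies (a no-op switch takes no time; the
  source material is silent and this is the conservative-zero choice).
* **Spot**: `6.6 ms/MU × MU + 2.2 ms` slew per spot.
* **Trimmer**: a second-order polynomial `c0 + c1·x + c2·x²` of the travel
  `x` between consecutive configurations, with travel measured as the
  maximum single-bar excursion (bars move simultaneously; the slowest bar
  gates the pause — `sum_bars` is available for sensitivity studies).
  Zero travel costs nothing.  The published characterization reports only
  the fit quality of such a polynomial, not its coefficients; the shipped
  default (0.3, 0.008, 2×10⁻⁵) makes a full 65 mm throw take ≈ 0.9 s and
  is documented configuration, not a machine constant.

Trimmer state threads across control points (the last configuration of
one control point is the arrival state of the next; the arc starts from
"off"), and no energy switch is charged before the first control point.
The IMPT comparison model prices manual intervention only: 30 s per
beam-to-beam transition plus 120 s when the couch angle changes.

## SWELS

The sliding-window sort reorders the one-energy-per-control-point
sequence toward descending (fast) transitions while bounding how far any
layer moves from the gantry angle it was optimized at.  Capacity is
`⌊window° / resolution°⌋`; the window grows from a single index to
capacity, sorting its contents descending at each growth step, then
slides one index per step; when, after a slide, the energy at the last
index exceeds the energy at the first, the window jumps so the last index
becomes the new first and regrows.  One left-to-right pass; ties are
stable; the arc simply terminates (no wraparound).

The per-window sort is **displacement-bounded**: a layer whose cumulative
displacement from its original control point has reached capacity − 1 is
pinned at its deadline slot rather than carried further.  An unconstrained
window sort can drag the lightest layer rightward indefinitely across
overlapping windows, which would silently break the guarantee the window
exists to provide; the bounded sort preserves it by construction, at the
price of idempotence — a second pass has a fresh displacement budget and
may legally sort further (it never increases the up-jump count; the test
suite checks this).  Property tests over thousands of random sequences
assert multiset conservation, the displacement bound, and up-jump
monotonicity.

When a layer moves, its spots and configurations move with it to the new
gantry angle.  Because lateral target coverage depends on the angle, the
pipeline regenerates the spot lattice at every angle after sorting and
reoptimizes the weights (see below).

## Grouping

Spots whose every bar edge is at least `mult · σ` from the spot center
(inclusive; default mult = 3, σ = 3.2 mm in-air sigma, so ≈ 99.7% of the
Gaussian is unclipped) are *effectively uncollimated* and share one "off"
configuration per control point.  Collimated spots are merged greedily
(agglomerative, cheapest merge first) under an envelope cost — the total
extra aperture opening the merged envelope imposes on members — until the
number of groups corresponds to the target mean group size.  Each group's
shared configuration is the per-bar maximum (least collimating) of its
members, so no spot is ever clipped tighter than its own plan allowed.
The clustering rule itself is a documented gap-fill: only the group-size
knob is prescribed by the method being implemented.

Configuration delivery order is an open-path travelling-salesman problem
from the arrival trimmer state, solved by an elitist ant system
(visibility = inverse move time, pheromone deposit `q/cost` by the
best-so-far ant, evaporation ρ = 0.1, max–min pheromone bounds, a 5%
uniform-exploration step) with every constructed tour refined by
2-opt/relocation local search.  On instances of ≤ 6 configurations the
sequencer attains the exhaustive-enumeration optimum across all tested
seeds; exhaustive search stays in the test suite as the independent
oracle.  Grouping never alters spot MU or positions — dose changes only
through the relaxed apertures, which the pipeline accounts for by
renormalization.

## Dose engine

A deliberately simple analytic stand-in for a clinical engine, exact
enough to rank collimation trade-offs on a water phantom:

* **Range**: Bragg–Kleeman `R[cm] = 0.0022 · E[MeV]^1.77` (monotone, so
  ordering by energy is ordering by range).
* **Depth dose**: entrance plateau (0.30 of peak, sigmoid falloff at the
  peak) plus a Gaussian Bragg peak of width `max(1.5 mm, 0.035·R)`.
* **Lateral profile**: the in-air Gaussian spot (σ_air = 3.2 mm, the
  median dedicated-nozzle spot size) windowed by ideal trimmer edges and
  convolved with an in-medium scattering Gaussian
  `σ_med = max(0.025·depth, 0.3 mm)`.  The convolution has a closed form:
  a Gaussian of combined sigma times per-axis error-function window
  factors.  Fully retracted trimmers reproduce the untruncated Gaussian;
  closing any bar only removes fluence (monotonicity is asserted in
  tests, and the closed form is checked against numeric quadrature to
  1e-6).
* **Geometry**: the gantry rotates in the axial plane about the
  superior–inferior axis; water-equivalent depth accumulates along
  parallel rays through the voxelized density (trapezoidal density
  weighting at grid resolution, half a step at the surface).  Dose scales
  with local density, so air receives nothing.
* **Grid**: 3 mm isotropic, voxel volume 0.027 cm³.  Dose is linear in MU;
  the influence matrix stores one sparse Gy/MU column per spot, truncated
  laterally at 18 mm (≈ 5 combined sigma) and at 10⁻⁹ Gy/MU.

DVH quantiles use the "smallest dose received by at least q% of the
structure" convention on raw voxel doses.  V50%/V100% for the gradient
index are evaluated over the whole grid (the external-contour alternative
would differ only in air, where this engine deposits nothing); CI is the
Paddick conformity index with TV_PIV the target volume at or above
prescription.  When nothing reaches prescription, GI and CI are reported
as NaN rather than a number.

## Cut, reoptimization, pipeline

Control-point weights are MU sums normalized to the plan average; Cut
removes exactly the set below the threshold (single fixed pass at 30% —
the iterative variant is out of scope) and refuses to empty a plan.

Reoptimization minimizes a convex composite — per-structure uniform-dose
quadratics, one-sided overdose/underdose penalties, mean-dose penalties,
each averaged over its structure — over nonnegative MU, by projected
gradient descent with Barzilai–Borwein spectral steps and a backtracking
Armijo safeguard (the objective is monotone nonincreasing by
construction).  Only the voxels the objective references enter the
iteration.  Convergence is declared when the relative decrease over a
10-iteration window falls below 10⁻⁶; pipeline stages run with a
400-iteration budget — the problem is ill-conditioned and further
iterations change no reported index at its printed precision.  On
pure-target instances the solver matches a nonnegative-least-squares
oracle in objective value to 10⁻⁴ relative.

Pipeline order: Cut → reoptimize → Sort → regenerate lattices +
reoptimize → Group → renormalize D95% to prescription.  Reoptimization
runs only when a stage actually changed plan geometry, and trimmers are
*not* reoptimized after Group (the grouped apertures are the point);
renormalization likewise fires only when some spot's effective aperture
changed.  With neutral parameters (threshold 0, window below resolution,
group size 1, no uncollimated spots) the pipeline is the identity.

## Robustness

Scenario sampling per draw: a global range-scale (Gaussian with two-sided
95th percentile at 3.5%, i.e. σ = 3.5/1.96 %; a systematic ±3.5%
alternating mode is provided because "systematically sampled" is genuinely
ambiguous — sampled mode is the default), i.i.d. Gaussian spot shifts
(σ = 0.5 mm), per-control-point uniform gantry offsets (±1°), one
systematic DCS mount shift per scenario (σ = 0.05 mm X, 0.1 mm Y —
a mount misalignment moves the whole aperture rigidly), and i.i.d.
Gaussian bar noise (σ = 0.3 mm) per bar per configuration.  Patient setup
error is deliberately excluded: the analysis isolates uncertainties of
the delivery system itself.  Each scenario's stream derives from
`SeedSequence(seed, spawn_key=(index,))`, so scenario k is identical
regardless of evaluation order.  The identity scenario reproduces the
nominal dose bit-for-bit.  Outputs: per-structure mean(sample − nominal)
and SD for D2/D50/D98/Dmean over the sampled scenarios, plus DVH band
curves (min/max/5th/95th percentile per dose level).

## Synthetic scenes

The generator emulates the *structure* of a cranial DC-PAT study on a
water sphere: default scene 170 mm phantom radius, 20 mm spherical PTV at
isocenter, 10 mm rind, CTV = PTV eroded 3 mm, one adjacent 12 mm OAR.
Tests and the worked example use a scaled-down scene (33 mm phantom,
7.5 mm PTV, 37 arc positions) chosen so the full pipeline and its
20-seed property suite run in minutes on one CPU; the scaling changes
problem size, not mechanism.  Per-angle energies cycle deterministically
over eight target depth slabs (stride 3, seed-shuffled slab order) — a
round-robin stand-in for the genetic per-angle energy selection used to
build the original plans, chosen because it produces the non-monotone
energy sequences the Sort stage exists to clean up.  Out-of-target spots
are trimmed at 0 mm offset on the side(s) facing away from the target
projection centroid, the rest stay off; in-target spots are uncollimated.

What passing tests show: the implemented operators obey their contracts
(conservation, bounds, monotonicity, optimality against oracles) and the
pipeline's qualitative behavior — large BDT reductions at near-constant
target coverage — reproduces on synthetic plans.  What they do not show:
absolute delivery times or dose indices of patient plans (those depend on
patient anatomy, a clinical dose engine, and fitted trimmer-time
coefficients, none of which are published), heterogeneity effects, nuclear
halo, or collimator transmission/penumbra beyond the ideal-edge model.

## Known limitations

* The dose engine is water-only with ideal collimator edges; it claims
  qualitative, not dosimetric, fidelity.
* The homogeneity index of grouped plans on the desk-scale phantom
  degrades more than on realistic targets: with a 7.5 mm PTV almost every
  spot is near an edge, so relaxed envelopes touch a larger dose fraction.
* The trimmer-time polynomial coefficients are configuration; absolute
  trimmer-time components should not be compared against hardware logs
  without refitting.
* Single-arc, coplanar, step-and-shoot delivery only; no dynamic
  (moving-gantry) mode, no LET or biological modeling, no robust
  optimization.
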