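# Methods

## Model family

All four models share one mechanism: existing primordia repel new ones
through an inhibitory field, and growth carries primordia radially outward
(r = R0·e^t in standardized time, because the radial velocity is
proportional to r).  They differ in the apex geometry, the kernel, and the
insertion rule:

| model | apex    | kernel                                   | insertion rule                      | parameters |
|-------|---------|------------------------------------------|-------------------------------------|------------|
| DC1   | plane   | k·d^(−η), planar distance                | one per plastochron, at the argmin  | η, G       |
| EDC1  | plane   | DC1 kernel × logistic F(age; a, b)       | as DC1 (η fixed at 2)               | G, a, b    |
| DC2   | cone    | E(d/d0), smoothed conical distance       | immediate, wherever I < Es          | α, Γ, N    |
| EDC2  | cone    | DC2 kernel × logistic F(age; A, B)       | as DC2                              | α, Γ, N, A, B |

Normalization: R0 = V0 = Es = 1 throughout, so the only relevant
parameters are those listed.  G = ln(r_m/r_{m+1}) is the growth per
plastochron (Richards' plastochron ratio in log form); Γ = d0/(R0·N)
compares the exclusion range d0 of a primordium with the SAM size; α sets
how abruptly the inhibitory effect collapses around d0; N = sin(ψ/2) ∈
(0, 1] is the apex flatness (1 = plane); a/A and b/B are the rate and
timing of the age-dependent change of the inhibitory power (positive rate
= power grows as the primordium matures).

The threshold kernel is evaluated in the algebraically identical form
E(x) = Es·expm1(2α)/expm1(2αx), which is stable where coth would be
computed from an underflowing tanh; exponents are capped at 700 so the
far tail underflows cleanly to zero.

## Conical distance

The distance between two points (r, θ) on the cone is taken as the
three-dimensional chord,

    d² = (r₁ − r₂)² + 2 N² r₁ r₂ (1 − cos Δθ),

which agrees with the unrolled-cone geodesic to second order in Δθ but
stays smooth and monotone over the whole circle — precisely the
discontinuity fix the threshold model needs, since the naive unrolled
distance is non-smooth for widely separated points.  For N = 1 it reduces
to the planar law of cosines at all radii.  This reading was selected by
behavior: it is the only member of the family c_r(Δr)² + c_a r₁r₂(1−cosΔθ)
that yields the documented DC2 regime sequence (stable 180° divergence at
Γ = 2.6, α = 8, N = 1/3; antipodal exclusion boundary exactly at Γ = 2)
and reproduces the EDC2 orixate plastochron oscillation (0.10/0.33) at the
reference parameter point.  A `variant="scaled"` reading
(d = √N × planar distance) remains switchable on `conical_distance` and
`DC2Params` for comparison.

## Simulation engines

Both engines are deterministic and evaluate the field on a uniform
angular grid (default 0.1°, dividing 360).

* **DC1/EDC1**: iterations n = 2…100; the new primordium takes the first
  global minimum encountered while scanning the grid from 0° upward
  (tie-break `ccw`; `cw` scans downward).  Chirality is physically
  arbitrary, and the two scan directions give exactly mirrored traces.
* **DC2/EDC2**: time advances in steps Δt = 0.001.  After each step the
  field on *M* is evaluated; while its minimum is below Es a primordium is
  inserted at the minimizing grid angle with the current time as birth
  time, and the field is re-evaluated including the newborn before
  looking for further sub-threshold points.  A newborn contributes from
  age 0 (factor F(0) in EDC2) and its own grid angle carries divergent
  self-inhibition, which prevents double insertion at one point while
  allowing genuine simultaneous insertions (whorls, and the initial
  cascade that populates an empty periphery with 2^x evenly spaced
  primordia).  Runs start from a single primordium at 0° or two at
  0°/120°, stop at 100 primordia, and raise an error if a single sweep
  would insert more than the whole primordium budget or if no insertion
  occurs before a configurable time cap (a stalled parameter set).

Two numerical details matter for exactness:

* Angle differences are taken from grid-index differences through a
  cosine table folded at 180°, so mirror-image configurations produce
  bit-identical field values and the two tie-break directions give
  bit-exact mirror trajectories.
* Primordia whose best-possible contribution (kernel at the closest
  approach to *M*, age factor at 1) falls below 10⁻¹²·Es are dropped from
  the active set; the bound shrinks monotonically with age, so the cut is
  permanent.  Switching pruning off changes no trace (verified in tests);
  it only changes runtime.

## Series extraction and classification

Divergence angles are signed differences θ_{m+1} − θ_m wrapped into
(−180°, 180°] (opposite placement reported as +180°); standardized
plastochrons are birth-time differences, equal to ln(r_m/r_{m+1}).
Primordia inserted at the same time step form one node.

Classification looks at the trailing end of a run: the last two nodes for
whorled patterns (2 + 2 members rotated 90° ± 10° → decussate, 3 + 3
rotated 60° ± 10° → tricussate, other stable counts → other whorled) and
the last nine primordia (eight angles) for alternate ones.  The smallest
period c ∈ {1, 2, 4} under which the angle sequence repeats within 2°
decides regular / two-cycle / four-cycle; the four-cycle label
additionally requires the (p, q, −p, −q) sign signature.  x-cycle motifs
(one step near ±180° followed by c − 1 steps near 0°, both bins ±10°) are
searched for c = 2…8 over the last 30 angles, because eight angles cannot
contain two repeats of a long cycle.  A detected cycle must tile the
window at least twice, otherwise the pattern is `other`.  The 2° equality
tolerance is a package choice (stable simulated patterns fluctuate well
below 1°; the 0.1° grid bounds placement error) and is exposed as a
parameter, as are the 10° x-cycle bins, which must be wide enough to
absorb cycle wobble yet narrow enough to exclude the small-angle spirals
that mediate x-cycle transitions.

Colors: alternate patterns map the mean absolute divergence of the cycle
to hue (cyan at 0° to red at 180°), the small/large ratio of successive
absolute angles to saturation (1 = fully saturated) and the small/large
plastochron ratio to lightness (0 = full lightness, i.e. white).  Whorled
categories, x-cycles (black), and `other` use fixed reserved colors; the
exact reserved hues are package choices.

## Orixate stability analyses

`make_normal_orixate` builds the idealized arrangement: angles follow the
exact 180/90/−180/−90 cycle (every fourth primordium collinear), times
follow either unit plastochrons (DC1-like) or an oscillation in which the
short interval spans opposite pairs and the long one adjacent pairs
(default 0.1/0.325, the values the free-running EDC2 orixate pattern
produces).  Two backward geometries exist relative to the incipient
primordium at 0°: the last primordium at ∓90° (situation 1) or at 180°
(situation 2).

For EDC1 the stationarity condition dI/dθ = 0 at the incipient position
is solved for b along a grid of a values.  The derivative is taken by
central differences at 0.01° (an analytic derivative serves as the
cross-check oracle in tests); 100 preceding primordia are kept, after
which the geometric decay of contributions leaves residual changes below
10⁻⁹ (doubling the depth is asserted to change nothing at that level).
The residual is linear in the age factors, so per-primordium sensitivities
are precomputed and every (a, b) evaluation is a dot product.  Roots are
bracketed on a 400-point b-scan in [0, 20] and polished with Brent's
method; the residual is nearly periodic in b (period 4, the length of the
angle cycle), so curves carry several branches and can fold.  Curve
intersections are therefore located in the (a, b) plane directly: both
situations' residual surfaces are sampled over the curves' bounding box
(cells ≈ 0.02 × 0.1, with a margin around the box because crossings can
sit just past a fold), cells where both residuals change sign seed a
two-variable hybrid-Newton solve, and converged solutions are
deduplicated.  At G = 0.5 the lowest crossing (a ≈ 1.51, b ≈ 4.52) has
positive field curvature (a true minimum) and sits inside the window
where EDC1 sweeps generate orixate patterns; at G = 0.1 all crossings are
field maxima, so normal orixate geometry cannot be stabilized there.

For plain DC1 the same residuals are scanned over an (η, G) grid.  In
both situations the residual is a sum over the ±90° ranks only, and the
younger flanking primordium always dominates its older partner, so the
residual never vanishes: no parameter choice makes the normal orixate
position stationary, let alone a minimum.  The 50 × 50 scan in the
acceptance suite is the numerical counterpart of that argument.

## Sweeps

A sweep runs one model over a 1–2 axis linear grid, classifies each
point, and attaches the legend color; rows are independent and the result
records full provenance (axes, fixed parameters, settings, density scale
relative to the reference 101 × 101 panels).  Failed points (stalled or
runaway runs) are flagged and do not abort the sweep.  Desk-scale default
density is one tenth of the reference panels per axis.

## Problem sizes used by the test suite and acceptance script

Target reproductions use the full study conditions (100 primordia, 0.1°
grid, Δt = 0.001).  Supporting checks are scaled to what they need:
engine-vs-brute-force oracles use 10–12 primordia against a 0.01°
reference grid; the DC2/EDC2 step-limit equivalence check screens random
(α, Γ, N) points with 30-primordium runs and verifies classification
agreement on 80-primordium runs, which is enough for the slowly decaying
divergence-angle transients near region boundaries to die out; robustness
checks rerun the four target configurations at 0.05° and Δt = 0.0005 and
assert the classification is unchanged.

## Behavior near the distichous–spiral transition, and known limitations

* In DC2 at α = 8, N = 1/3 the stable divergence angle declines from 180°
  (Γ ≳ 2.5) through golden-angle values (≈ 137°–138° around Γ ≈ 2.05–2.15)
  as Γ shrinks; below Γ ≈ 2.0 the engine converges to period-two
  oscillations of the divergence angle (e.g. 113.5°/155.5° at Γ = 1.9,
  mean 134.5°) rather than a single intermediate angle, and these
  two-cycles are robust to halving the grid and the time step, to longer
  runs, and to both initial conditions.
* The free-running EDC2 orixate attractor at A = 4.8, B = 0.72, Γ = 2.8,
  N = 1/3, α = 1 has divergence cycle 176.2°/89.3° with plastochrons
  0.101/0.325 — orthogonal tetrastichy to within ~4°, not exactly 180/90;
  consistently, an artificially exact 180/90 arrangement with those
  plastochrons has its field minimum at 1.9°–4.4° rather than 0°.
* Simultaneity is grid-time simultaneity: primordia born one Δt apart
  count as separate nodes, so marginally split whorls classify as
  two-cycle alternates.
* No stochasticity, no sub-grid interpolation of the insertion angle, no
  3D meristem surface, no parastichy counting; the Γ(t) ramp is supported
  as a parameter option but frame rendering of animations is out of
  scope.
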