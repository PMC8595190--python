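# Methods

## Physical model and assumptions

The package models steady aqueous-humor outflow after implantation of a
glaucoma drainage device as a three-branch resistor network:

* **Source.** The ciliary body injects Q_cb (default 2 µl/min). A fixed
  fraction (default 0.15) leaves through the pressure-independent
  uveoscleral pathway, so the pressure-driven branches share
  Q_0 = Q_cb·(1 − fraction) = 1.7 µl/min. The pressure dependence of both
  inflow and uveoscleral outflow is neglected.
* **Trabecular branch.** Trabecular meshwork plus Schlemm's canal are a
  single linear resistance discharging to the episcleral venous pressure
  p_ev (default 10.5 mm Hg). Because the pre-surgery steady state carries
  the whole Q_0 across this branch at the pre-surgery IOP p_g (default
  35 mm Hg), its resistance is calibrated as (p_g − p_ev)/Q_0 and assumed
  flow-rate independent (creeping flow; no tissue deformation or canal
  collapse). The branch carries flow only while the IOP exceeds p_ev.
* **Implant branch.** The tube is a straight duct in creeping flow; the
  entrance length is negligible, so the generalized Hagen–Poiseuille law
  Δp = 128·𝒮·L_v·μ·Q/(π·D_h⁴) holds along its whole length, with
  μ = 0.75 mPa·s for aqueous humor. Downstream, the filtration bleb acts as
  an effective resistance R_b to a constant reference pressure p_r
  (default 0); this lumps the subconjunctival transport and absorption
  process into one constant.

Mass balance at the anterior-chamber node closes the system. Both regimes
(trabecular branch open/shut) admit closed-form IOP solutions; the
implementation computes the open-branch solution first and falls back to
the shut-branch one, with the boundary state p_c = p_ev flagged and
labelled trabecular-closed by convention (the model is continuous there, so
the label is a convention, not a physical claim).

## Shape factor

The shape factor is defined through the unit-forced Dirichlet–Poisson
problem ∇²v̂ = −1, v̂ = 0 on the section contour, on the cross-section scaled
so its hydraulic diameter is 1; then 𝒮 = (π/128)(∫ v̂ dS)⁻¹. This
normalization makes 𝒮 = 1 for the circular bore exactly, and reproduces the
closed-form concentric-annulus factor

    𝒮(κ) = (1−κ)⁴ / [ 1 − κ⁴ + (1−κ²)²/ln κ ],   κ = D_s/D_i.

Two numerical notes on this closed form:

* As κ → 1 the bracket cancels catastrophically in double precision (O(ε)
  terms cancel to an O(ε³) residual, ε = 1−κ). For ε < 0.1 the
  implementation switches to the series
  (4/3)ε³ − (2/3)ε⁴ + ε⁵/45 + ε⁶/90 + …, accurate to ~3×10⁻⁹ relative at
  the switch point; continuity across the switch is tested.
* 𝒮 is **not** monotone from 1: a thin coaxial wire barely obstructs the
  flow while D_h = D_i − D_s shrinks linearly, so 𝒮 rises above 1 (peak
  ≈ 1.239 near κ ≈ 0.02) before decreasing. This is a property of the exact
  annulus solution, confirmed independently by the PDE solver. The quantity
  that drives all design calculations, the resistance ratio
  𝒮(κ)·(1−κ)⁻⁴, is globally strictly increasing from 1, so every inversion
  remains well posed.

### Numerical solver

Arbitrary sections (in practice: the wall-touching annulus, and custom
closed polylines) are solved by second-order finite differences on a
cell-centred Cartesian grid with Shortley–Weller boundary treatment: at
points adjacent to the contour the stencil arms are shortened to the exact
ray/boundary intersection, preserving O(h²) accuracy on curved boundaries.
The linear system is solved with sparse LU (scipy). The integral uses
midpoint quadrature; since v̂ → 0 at the wall, the boundary band contributes
O(h²) error, consistent with the scheme.

Resolution control: the base grid puts `cells_per_gap` (default 24) cells
across the annular half-gap (1−κ)/2, bounded to [96, 3072] cells across the
section. Each solve is done on two grids (h, h/2); the reported value is
the Richardson extrapolation and the error estimate is |S_h − S_{h/2}|/(3·S).
Grids double until the estimate meets `rtol` (default 5×10⁻³ relative —
comfortably exceeded in practice: concentric sections agree with the closed
form to ~10⁻⁵–10⁻⁶) or the cap is hit, which raises a numerical-accuracy
error rather than returning a silently degraded value.

The wall-touching geometry has a cusp at the tangency point. No graded mesh
is used: v̂ → 0 inside the cusp, so its contribution to ∫v̂ dS is negligible
and uniform grids with Richardson comparison meet the tolerance; the
two-level agreement is itself the acceptance check. An optional
`tangency_gap` parameter pulls the suture off the wall for sensitivity
studies (moving it toward the axis raises 𝒮 toward the concentric value);
the default is exact tangency with no regularization.

For custom polyline sections the hydraulic diameter is the conventional
4·area/perimeter (the model does not otherwise define one), and point
location/boundary intersection use shapely.

### Wall-touching interpolation table

Design calculations need 𝒮_wall(κ) inside root-finding loops and parameter
sweeps, where a PDE solve per evaluation would be wasteful (and, near
κ → 1, infeasibly large). `shape_factor(κ, "wall_touching")` therefore
evaluates a monotone PCHIP interpolant built lazily (once per process) from
Poisson solves at 31 interior knots on κ ∈ [0.03, 0.93], anchored at the
exact limits 𝒮(0) = 1 and 𝒮(1) = 0. The table solves use a lighter
discretization (12 cells per gap) because interpolation error dominates
there; interpolated values agree with fresh production-resolution solves to
~1% mid-range. Direct solves remain available (`exact=True`, or
`poisson_shape_factor`). Beyond the last interior knot the interpolant is a
smooth monotone decay to the κ = 1 anchor — adequate for the qualitative
near-blockage regime, and the dominant (1−κ)⁻⁴ divergence of the resistance
ratio is always exact.

Inversion of the resistance ratio uses bracketed Brent iteration on
[0, 1−10⁻⁶] (strict monotonicity guarantees uniqueness); a requested ratio
below 1 or above the value at the bracket end raises an infeasibility error
("suture alone insufficient", with the attainable bound).

## Suture correction

The bleb pressure is not measurable in clinic. Assuming the bleb morphology
— hence R_b — is unchanged between the measurement of p_c1 and the suture
insertion, R_b can be eliminated from the paired steady states, leaving the
required resistance ratio 𝒮₂(1−κ)⁻⁴ as an explicit function of (p_c1, p_c2)
and known constants. Three cases arise from the IOPs relative to p_ev
(equality assigned to the closed side):

* both below: ratio = 1 + A·(p_c2 − p_c1), with A = πD_i⁴/(128 L_v μ Q_0);
  independent of p_ev and p_r — the robust clinical case;
* p_c1 below, p_c2 above (mixed); and both above, where the trabecular
  branch shares flow and the formulas involve p_g, p_ev, p_r. The p_ev·p_r
  cross terms in the mixed case are implemented exactly; with the default
  p_r = 0 they vanish, and the p_r > 0 behaviour is verified in tests
  against an explicit resistor-network solve rather than against any
  printed value.

A large-p_g approximation of the both-above case (drop the pressure-ratio
factor; equivalently, assume the implant branch carries nearly all flow)
is available behind an explicit opt-in flag: it needs neither p_ev nor p_r,
which are literature values rather than measurements, but the exact case
formula is the default. Its error decays as 1/p_g (tested).

Forward prediction with p_c1 ≤ p_ev evaluates the both-closed formula
first; if the predicted p_c2 crosses p_ev that assumption is inconsistent
and the mixed formula is used. Monotonicity of the network response makes
exactly one case self-consistent; the implementation verifies this and
flags exact-boundary states. The forward map p_c2(p_c1) is continuous
across all case boundaries, p_c2 is strictly increasing in D_s, and the
forward/inverse composition round-trips to ≤ 10⁻⁴ mm Hg (all tested, the
case formulas additionally against an independent resistor-network oracle
to 10⁻⁹ relative).

Every inverse solution is labelled an **upper bound** on the suture
diameter: the model assumes the minimum-resistance configuration (straight
suture, unchanged bleb). Cicatrization of the subconjunctival tissue
between interventions, or bending of the suture inside the lumen, adds
resistance beyond the model — the latter is a plausible explanation for
clinically observed IOP rises from sutures the straight-suture model deems
negligible, but is deliberately not modelled.

## Units and baseline parameters

All computation is in SI; all interfaces are clinical (mm Hg, µm, mm,
µl/min, mPa·s), with the conversions fixed at 1 mm Hg = 133.322 Pa and
1 µl/min = 10⁻⁹/60 m³/s so results are bit-stable. Raising micrometre
diameters to the fourth power is the motivating failure mode.

| parameter | default | meaning |
|---|---|---|
| p_g | 35 mm Hg | pre-surgery IOP; calibrates the trabecular resistance |
| p_ev | 10.5 mm Hg | episcleral venous pressure; regime threshold |
| p_r | 0 mm Hg | bleb discharge reference pressure |
| Q_cb | 2 µl/min | ciliary inflow |
| uveoscleral fraction | 0.15 | pressure-independent bypass share |
| μ | 0.75 mPa·s | aqueous humor viscosity |
| D_i, L_v | 305 µm, 11 mm | Baerveldt tube (narrow-bore preset: 100 µm) |

These defaults are the values commonly used for the human eye in the
aqueous-humor-dynamics literature and are what the test suite and the
acceptance script exercise. There is no synthetic-data generator and no
stochastic component: the model is deterministic, and what the tests show
is internal consistency (independent oracles, round trips, invariants) plus
agreement with the handful of externally stated reference magnitudes — not
validation against clinical measurements, which the model's central
constant-R_b assumption anyway idealizes.

## Known limitations

* The constant-R_b assumption ignores bleb remodelling between
  interventions; reported suture diameters are upper bounds.
* Straight, rigid, single sutures only; no bending, no multiple strands,
  no non-Newtonian rheology, no entrance/minor losses, no tube compliance.
* The trabecular branch is a fixed linear resistance; Schlemm's-canal
  collapse or washout effects are outside the model.
* Wall-touching values beyond κ ≈ 0.93 rely on the anchored interpolant
  tail rather than direct solves.
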