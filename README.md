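# sutureflow

Hydraulic modelling of glaucoma drainage devices and their correction by
intraluminal suture occlusion.

## The problem

Glaucoma drainage devices (e.g. the non-valved Baerveldt implant: a tube of
inner diameter D_i ≈ 305 µm and length L_v ≈ 11 mm) shunt aqueous humor from
the anterior chamber to a subconjunctival filtration bleb. Over-drainage
leaves the eye hypotonic (IOP of 2–6 mm Hg), a sight-threatening
complication. Surgeons correct hypotony by threading a suture of diameter
D_s into the tube lumen, raising its hydraulic resistance and with it the
intraocular pressure (IOP) — but there has been no quantitative guidance for
choosing D_s. This package implements an analytical lumped-parameter model
of the post-implant outflow network that predicts the IOP after suture
insertion (forward problem) and sizes the suture for a target IOP (inverse
problem), for users who study or plan such interventions.

## The model

Flow in the tube is viscous-dominated and fully developed, so the pressure
drop obeys a generalized Hagen–Poiseuille law

    p_c − p_b = 128 · 𝒮 · L_v · μ · Q_i / (π · D_h⁴),

with hydraulic diameter D_h = D_i − D_s and a dimensionless shape factor 𝒮
of the annular cross-section. 𝒮 comes from the unit-forced Poisson problem
∇²v̂ = −1, v̂ = 0 on the contour, on the section scaled so D_h = 1:
𝒮 = (π/128)(∫ v̂ dS)⁻¹. The open circular bore has 𝒮 = 1; the concentric
annulus has a closed form; the wall-touching annulus (a free suture settles
against the tube wall) is solved numerically and always gives the smaller 𝒮,
i.e. less resistance at equal suture diameter.

The anterior chamber drains through two parallel branches: the trabecular
meshwork (linear resistance calibrated from the pre-surgery IOP p_g, active
only while the IOP exceeds the episcleral venous pressure p_ev) and the
implant in series with the bleb (effective resistance R_b to a reference
pressure p_r). The ciliary inflow Q_cb, minus a fixed uveoscleral fraction,
fixes the flow Q_0 = 1.7 µl/min. Assuming the bleb resistance is unchanged
between interventions eliminates the clinically unmeasurable bleb pressure,
so the IOP change caused by a suture depends only on measured IOPs, the tube
geometry and literature constants. Three regime cases arise from the IOPs
relative to p_ev; the most frequent clinical case (both IOPs below p_ev)
needs no literature pressures at all.

## Worked example

```python
from sutureflow import CorrectionProblem, Placement, predicted_iop_after_suture
from sutureflow.presets import aqueous_humor, baseline_eye, narrow_implant

sol = predicted_iop_after_suture(CorrectionProblem(
    eye=baseline_eye(),            # p_g=35, p_ev=10.5, p_r=0 mm Hg, Q_0=1.7 ul/min
    geometry=narrow_implant(),     # D_i=100 um, L_v=11 mm
    p_c1_mmhg=5.0,                 # measured hypotonic IOP
    placement=Placement.CONCENTRIC,
    d_s_um=35.0,                   # coaxial 35 um suture
    fluid=aqueous_humor(),         # mu = 0.75 mPa s
))
print(sol.case_label.value, round(sol.p_c2_mmhg, 2))
```

prints `both_closed 7.13`: both IOPs sit below the episcleral venous
pressure (10.5 mm Hg), and the 35 µm coaxial suture raises the IOP by about
2.1 mm Hg — from hypotony toward the safe range. The same suture in a
305 µm Baerveldt tube would raise the IOP by only ~0.02 mm Hg, which is why
wide-bore implants cannot be regulated by thin straight sutures.

The `examples/` directory holds one short script per capability (pressure
drops, shape-factor curves, forward prediction, inverse suture sizing,
implant design, parameter sweeps). A thin CLI mirrors them:

```
sutureflow predict --d-i 100 --p-c1 5 --d-s 35 --placement concentric
sutureflow design-suture --d-i 100 --p-c1 5 --target 7 --placement concentric
sutureflow shape-factor --kappa 0.35
sutureflow figures --out-dir figures_out
```

Inverse-design outputs are labelled upper bounds: bleb scarring between
interventions or bending of the suture inside the tube adds resistance
beyond this model, so a thinner suture may suffice in practice.

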