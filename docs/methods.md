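# Model and methods

`shuntsim` is a closed-loop, lumped-parameter (0D) model of the systemic and
pulmonary circulations of a child with idiopathic pulmonary arterial
hypertension (iPAH), built to compare the acute hemodynamic and
oxygen-transport consequences of an atrial septostomy (AS) against a Potts
shunt (PS) across disease severities.  This note documents the model, its
assumptions, the numerical choices, and what the synthetic reference patient
does and does not represent.

## Circulation model

**Network.** Four cardiac chambers (RA, RV, LA, LV), five vascular storage
nodes (proximal aorta AoP, descending aorta AoD, systemic veins SV, pulmonary
artery PA, pulmonary veins PV), four valves (tricuspid, pulmonary, mitral,
aortic), an aortic-arch segment connecting AoP to AoD, resistive upper- and
lower-body beds draining into SV, venous return resistances SV→RA and PV→LA,
and a linear pulmonary bed PA→PV.  An optional constant-diameter bidirectional
orifice connects the atria (AS) or PA to AoD (PS).

**Chambers.** Each wall is a one-fiber shell: fiber stretch
λ = (V_m/V_m,ref)^(1/3) with midwall volume V_m = V_cav + V_w/2; fiber stress
σ_f = σ_act·a(t)·max(0, λ−λ_s)/λ_s + σ_pas·(e^{k(λ−1)}−1)·[λ>1], with a
sin² activation pulse a(t) (atria start at cycle onset, ventricles 0.15·T
later; durations 0.15·T and 0.40·T); transmural pressure
p = (σ_f/3)·ln(1 + V_w/V_cav).  Below a cavity volume of 1.5 mL a steep
suction barrier mimics the wall collapsing around the inflow; it is far
outside the operating range and only guards startup transients.

**Septum.** The ventricles are coupled by a lumped septal compliance
S_c = 0.2 mL/mmHg: a bulge of volume ΔV = S_c(p_RV − p_LV) toward the LV
stretches the LV wall as if its cavity held ΔV more blood and relieves the RV
by the same amount.  The self-consistent ΔV is found per evaluation by a
bracketed regula-falsi iteration (≤50 evaluations, relative tolerance 1e-9),
with |ΔV| capped at half the smaller cavity.  This closure is the simplest
one that is numerically stable (the shift reduces its own driving pressure
difference) and reproduces the leftward LV loop shift under suprasystemic RV
pressure.

**Valves and shunts.** Orifice momentum:
dq/dt = (Δp − ρ/(2A²)·q|q|)·A/(ρ·l_eff), ρ = 1050 kg/m³, l_eff = 16 mm.
Two-way orifices (arch segment, shunts) always use the open area.  A closed
one-way valve (q ≤ 0 and Δp ≤ 0) relaxes quasi-steadily (τ = 2 ms) to its
closed-form Bernoulli leak flow through A_leak = 1e-4·A_open: the literal
leak-area momentum equation has a microsecond time constant and is
intractable at the working step; the quasi-steady limit is the same flow.

**Vessels.** Linear storage p = p_0 + (V − V_0)/C; below V_0 the vessel
collapses softly (pressure saturates ≈5 mmHg below p_0, slope-continuous), a
transient guard only.  The pulmonary bed is the linear law
q_pulm = q_ref·Δp_pulm/Δp_ref with q_ref = 2.1 l/min; mean PA pressure is set
by tuning Δp_ref.

**Integration.** Fixed-step classical RK4 at dt = T/ceil(T/0.5 ms) ≤ 0.5 ms;
15 states (9 volumes, 6 orifice flows).  Fixed stepping makes every run
bit-reproducible.  The kernels are numba-compiled.

## Homeostatic control and steady state

Between beats (never within a cycle) the systemic resistance is scaled by
(CO/CO_target)^γ and total blood volume by 1 + γ_v(MAP_target − MAP)/MAP_target,
with the volume change distributed over the storage nodes in proportion to
compliance.  CO is the cycle-mean aortic valve flow; MAP the cycle-mean AoP
pressure.  The solver uses γ = 0.15, γ_v = 0.05: the classical gains
(exponent 1, 0.3) are fixed points of the same maps but ring against the
venous filling lag on this plant.  Three safeguards never move the fixed
point: a per-beat rate limiter and physiologic resistance bounds, a deadband
(updates stop inside half the set-point tolerance so the autonomous orbit can
become strictly periodic), and gain annealing plus a period-2 breaker (when
the beat-to-beat residual plateaus, the state jumps to the midpoint of
consecutive cycle starts, which lies near the coexisting period-1 orbit).

A run is converged when every compartment's cycle-mean volume changes < 1e-4
(relative) between beats and the set-points are met to 0.1%; the returned
cycle is additionally refined until the state at cycle start and end agrees
pointwise to 1e-4.  Pump-limited runs (used while the adaptation loop is
still sizing the heart) may instead end with stalled controllers.

## Structural adaptation and the study protocol

Walls remodel toward a peak-fiber-stress target (55 kPa) and vessel
cross-sections toward a mean-velocity target (0.17 m/s), both measured in a
converged **exercise** simulation (CO target and heart rate multiplied by the
exercise factors).  During exercise the pulmonary reference flow scales with
the CO factor — exercise recruits the pulmonary bed, so the reference
pressure drop, not the resistance, is preserved.  Updates are under-relaxed
(square root, rate-limited to [0.6, 5/3], annealed on stalls); vessel V_0 and
C scale with area, and node volumes are remapped pressure-preserving after
each geometry change (remodeling is slow in vivo, so pressures carry over).

Protocol stages (all deterministic):

1. **Reference child** (BSA ≈ 0.75 m², HR 100/min): controllers recover
   CO 2.1 l/min and MAP 61 mmHg; Δp_ref tuned (clipped secant, tol
   0.05 mmHg) so resting mPAP = 15 mmHg; adaptation at threefold CO and
   twofold HR; tuning and adaptation alternate until both hold.
2. **Compensated moderate PAH**: re-tuned to mPAP 50 mmHg, re-adapted at
   twofold CO and 1.8-fold HR.
3. **Decompensation sweep**: Δp_ref raised stepwise (controllers active,
   geometry frozen) to mPAP 50…80 in 5 mmHg steps — seven bases.
4. **Acute shunts**: for each base and each kind/diameter (0–16 mm, 1 mm
   steps → 2 × 7 × 17 = 238 cells), the orifice is inserted with controllers
   and geometry frozen and the model re-converged from the base state.

## Oxygen transport

Saturations of the nine compartments are advected with the blood on the
frozen periodic hemodynamic solution (one-way coupling), upwinded on the
instantaneous flow direction, with forward pulmonary-bed flow entering the
pulmonary veins at S_pv = 98% and whole-body consumption (102 mL O₂/min,
sized for a mixed-venous saturation ≈ 70% at CO 2.1 l/min with carrying
capacity 174 mL O₂/L) withdrawn from the systemic venous pool.  Transport
repeats cycles until every compartment's cycle-mean saturation moves < 1e-5.

The aortic-arch segment is treated as a plug-flow tube for oxygen: flow
pushed retrograde accumulates in a last-in-first-out pocket at the junction
and returns downstream first, so only net throughflow advects oxygen.  This
is O₂-conserving and reflects that oscillatory flow in a tube barely mixes
scalar content; with naive perfect-mixing advection the sustained diastolic
retrograde arch flow under a large Potts would desaturate the upper body by
several points, which contradicts the clinical picture of strictly
differential cyanosis.  Valve and shunt jets keep full upwind mixing — this
is what desaturates both body halves under an atrial defect even when its
*net* flow is left-to-right.

## Reference-patient calibration

Only CO, MAP, mPAP, the exercise factors and the Δp_ref range are externally
given; the remaining defaults are the package's own design, chosen once for
physiologic plausibility and then frozen:

- stress scales σ_act = 250 kPa (ventricles) / 100 kPa (atria), slack
  stretch 0.85 — resting EF ≈ 0.6 with systolic reserve for the exercise and
  decompensation stages;
- LV diastole: V_ref 26 mL, σ_pas 5 kPa, k_pas 10 — left filling pressure
  ≈ 5 mmHg at the compensated stage, falling toward ≈ 2 mmHg at mPAP 80 as
  septal compression shrinks the LV; together with the pulmonary venous
  resistance (0.3 mmHg·min/l) this puts the pulmonary venous pressure in the
  range implied by the printed Δp_ref span 44.3–77.5 mmHg;
- RV diastole: V_ref 28 mL, σ_pas 30 kPa, k_pas 1 — a nearly linear
  end-diastolic pressure-volume relation, so right-heart filling pressure
  rises gradually (≈0.3 mmHg at mPAP 50 to ≈4 mmHg at mPAP 80) as the
  frozen-geometry RV dilates, the clinical signature of decompensation;
- node compliances/volumes and the 50:50 upper:lower resistance split are
  ordinary pediatric values; vessel segment lengths are set so that the
  velocity-target adaptation reproduces them at the reference exercise.

## What the synthetic patient shows — and does not

The generator emulates *the average catheterized iPAH child* as a single
deterministic parameter set.  It contains no inter-patient variability, no
measurement noise, no heart-rate control, no baroreflex dynamics within a
beat, no pericardium, no wave propagation, and the septum is a lumped
compliance rather than a wall segment with its own mechanics.  Passing tests
therefore demonstrate internal consistency of the model family and
reproduction of the study's set-points and qualitative shunt physiology; they
do not validate patient-specific prediction.

Two documented deviations from idealized expectations remain, both traceable
to the lumped septum and the instantaneous-pressure coupling: (i) at
infrasystemic mPAP levels the atrial defect carries net left-to-right flow
(left atrial pressure exceeds right), so RV pump work is not monotonically
non-increasing in defect size at every level — it decreases from 0 to 16 mm
only at suprasystemic levels, with a shallow minimum near 8 mm; (ii) the
net-flow direction of a Potts shunt at a level within ~1–2 mmHg of the mean
systemic pressure is set by pulsatile rectification rather than by the sign
of the mean gradient.

## Problem sizes

Default runs integrate 1200 steps per beat (HR 100), typically 30–150 beats
per converged simulation.  The full study (reference and compensated builds
with their adaptation loops, the seven-level sweep, and both 119-cell
matrices with oxygen transport) takes on the order of a minute and a half on
one CPU; the matrices alone are a few seconds because every cell warm-starts
from its base.
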