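# Methods

`thromboflow` couples time-resolved 2D incompressible blood flow to a
reduced, haemodynamics-driven description of thrombus formation, and
adds a Lagrangian platelet-activation (PAS) post-processor. This note
records the model, the numerics, the calibration choices that were
genuinely open, and what the synthetic cases do and do not demonstrate.

## The model

**Flow.** Blood is incompressible and laminar with shear-thinning
Quemada viscosity

μ(γ̇) = μ_p (1 − ½ k(γ̇) H)⁻²,  k(γ̇) = (k₀ + k_∞√(γ̇/γ̇_c)) / (1 + √(γ̇/γ̇_c)),

with plasma viscosity μ_p = 1.2 mPa s, haematocrit H = 0.45, k₀ = 4.33,
k_∞ = 2.07, γ̇_c = 1.88 s⁻¹ (standard literature constants for human
blood) and a
shear-rate floor γ̇_min = 10⁻³ s⁻¹ so stagnant cells sit on the finite
zero-shear plateau. ρ = 1060 kg m⁻³. A Newtonian override exists for
the verification cases.

The momentum equation carries two thrombus feedbacks: the transient
term is scaled by the clot porosity (superficial-velocity/Brinkman
form, ρ/ε ∂u/∂t), and a Darcy-type sink

S_M = −k_M ϕ_BP(BP) u,  k_M = 10⁷ kg m⁻³ s⁻¹,

opposes flow through forming clot. ϕ_BP is a saturation switch (below).
Porosity follows the bound-platelet concentration linearly,
ε = 1 − 0.25·min(BP/BP_t, 1), i.e. 1 in open lumen and 0.75 in a
completely formed clot (BP ≥ BP_t = 20 nmol l⁻¹).

**Species.** Four scalars are transported
(convection–diffusion–reaction); bound platelets BP are a fifth,
immobile field:

- residence time RT: ∂(εRT)/∂t + ∇·(uRT) = ∇·(D_RT∇RT) + ε, RT = 0 at
  the inlet; reported normalized by the cardiac period T.
- resting/activated platelets RP, AP, tracked relative to the inlet
  platelet concentration (RP_rel = 1, AP_rel = 0.05 at the inlet — a 5%
  background activation); both are consumed where platelets bind.
- coagulant C: released at wall faces whose previous-cycle TAWSS is
  below τ_w,t = 0.2 Pa at the fixed rate k̄_c = 20 nmol m⁻¹ l⁻¹ s⁻¹
  (per unit wall length in 2D, applied to the wall-adjacent cell as
  k̄_c·ℓ_face/A_cell), shut off over complete thrombus
  (BP > 200 nmol l⁻¹); bulk kinetics
  k_c ϕ_BP ϕ_γ̇↓ − k_c (C/C_t) ϕ_γ̇↑ with k_c = 200 nmol l⁻¹ s⁻¹
  (production inside forming clot at low averaged shear, consumption at
  high averaged shear); effective diffusivity D_c,eff = f_aug·D_c with
  D_c = 10⁻⁸ m² s⁻¹ and f_aug = 150 (kinetic acceleration). Coagulant
  convection is scaled by ϕ_γ̇↑(γ̇_avg), making transport
  diffusion-limited inside low-shear reaction zones.
- bound platelets BP: dBP/dt = k_BP · AP_rel · ϕ_C↑(C) · ϕ_γ̇↓(γ̇_avg),
  restricted to eligible cells (below); BP is never advected or
  diffused and is monotone non-decreasing.

All switches are Hill-type saturations, ϕ↑(x; x_t) = xⁿ/(xⁿ + x_tⁿ)
with n = 2 and ϕ↓ = 1 − ϕ↑. The shear thresholds are γ̇_t = 50 s⁻¹
(bulk) and 0.2 Pa TAWSS (wall); both hard deposit gates, the TAWSS one
a strict indicator in the wall-flux law.

**Gating and cycle averaging.** Wall shear stress is accumulated per
wall face over each cardiac cycle; the wall-flux law and the
deposition gates always see the *previous* cycle's TAWSS and the
previous cycle's cell-averaged shear rate γ̇_avg. A cell may deposit BP
if it is wall-adjacent with a gating face below 0.2 Pa, or a bulk cell
with γ̇_avg < 50 s⁻¹, or 4-adjacent to existing thrombus (BP > BP_t in
a neighbour) — the adjacency rule lets a clot expand contiguously into
its margin. The run audits every deposition event and records the
largest gate values actually used.

**Run protocol.** Two spin-up cycles with the thrombosis model off
initialize the periodic flow and the cycle averages; growth runs from
the third cycle. The two-tear restart protocol additionally seeds all
wall cells with an initial coagulant concentration (1% of the maximum
reached in the single-tear run), lets coagulant production/consumption
run for two cycles before platelet binding is enabled, and holds the
proximal false-lumen cap at BP above the complete-thrombosis level
(wall flux there is then off automatically).

**PAS.** Particles released at the inlet at four cycle phases
(0, 0.15, 0.30, 0.45 of the period by default — start of systole,
mid-acceleration, peak, mid-deceleration; configurable) are advected
by RK4 through stored
velocity snapshots (bilinear in space, linear in time, periodic
extension). Along each pathline the scalar load τ = μγ̇ feeds

PAS(t) = C · [ (PAS₀/C)^{1/a} + ∫₀ᵗ τ^{b/a} ds ]^a,

a = 1.3198, b = 0.6256, C = 10⁻⁵, PAS₀ = 0, evaluated by trapezoidal
quadrature and clipped at 1. For constant τ this is C τ^b t^a; using
μγ̇ as the scalar stress load is the package's scalarization choice.

## Numerics

Uniform Cartesian MAC (staggered) grid with solids embedded by cell
masking; no body-fitted mesh. Time stepping is an incremental Chorin
projection with a fixed step chosen from the waveform peak (CFL safety
0.3–0.4): implicit (θ-scheme; backward Euler by default,
Crank–Nicolson for the pulsatile verification case) variable-viscosity
diffusion and fully implicit Brinkman sink (stiff at k_M = 10⁷), solved
per velocity component by Jacobi-preconditioned CG to 10⁻¹⁰ relative;
explicit first-order upwind momentum convection (monotone on masked
grids; the scalar fields, where the accuracy targets live, use the
higher-order scheme below). The pressure Poisson operator is weighted
by face porosity and factorized once by sparse LU; it is refactorized
only when ε has drifted by more than 5·10⁻³, and the face porosity in
the velocity correction is always the one inside the matrix, so the
discrete divergence is exact (LU round-off, ≲10⁻¹⁴) at every step.
Boundary conditions: prescribed plug (or profile) inlet velocity, zero
relative pressure at the outlet, rigid no-slip walls enforced by
reflection ghosts.

Scalar advection is MUSCL with the van Leer limiter (first-order at
region boundaries), explicit; diffusion implicit by CG, or explicit
when the diffusion number D·dt/Δ² is below 10⁻² (platelets and RT,
whose D = 10⁻⁹ m² s⁻¹ is negligible at these scales). Scalar storage
uses ε frozen within the step (ε changes by ≲10⁻⁵ per step, so the
φ dε/dt correction is dropped). Negative concentrations are clipped to
zero and counted. Wall WSS is the one-sided difference
μ·|u_t|/(Δ/2) at each wall face; γ̇ = √(2D:D) from the MAC velocity
gradients with no-slip ghosts.

Everything is deterministic: no randomness, fixed iteration
tolerances, and checkpoints store every field and accumulator plus the
porosity baked into the pressure operator, so a restart reproduces the
uninterrupted trajectory bit for bit.

## Parameters that had to be chosen

The model's standard parameter set pins k_c, k̄_c, k_M, D_c, f_aug,
BP_t, γ̇_t, the 0.2 Pa TAWSS threshold, the 200 nmol l⁻¹ shutoff, the
porosity bounds, T = 1.054 s, the 5% activation and the PAS constants.
The remaining constants are package calibrations:

- **k_BP = 80 nmol l⁻¹ s⁻¹.** With the 5% background activation this
  gives dBP/dt ≈ 4 nmol l⁻¹ s⁻¹ in a fully gated pocket, so a clot
  crosses BP_t in ~5 cardiac cycles and approaches completion within
  the 20-cycle protocol — the timescale the accelerated kinetics are
  designed for.
- **C_t = 1 nmol l⁻¹.** C_t sets both the coagulant level that
  saturates platelet binding and the strength of the high-shear
  consumption, k_c·C/C_t. Near emitting walls the flux law produces
  C ~ 10⁴–10⁵ nmol l⁻¹, and coagulant leaking past a tear into the
  open lumen decays over a length ≈ u·C_t·(C/C_t-scaled) that must fit
  inside the desk-scale domain; at C_t = 1 the open lumen clears the
  leak within ~2 mm, at C_t = 10 it would need more lumen length than
  the 6 cm analog has.
- **n = 2** for all switches; **D_RT = D_p = 10⁻⁹ m² s⁻¹**;
  **N_pool = 10⁴ nmol l⁻¹** of BP-equivalent per unit relative platelet
  concentration for the binding sink (platelet counts and BP
  concentrations carry incommensurable units in this model family, so
  the sink strength is a free constant; at 10⁴ the
  consumption is present but never caps growth below the
  complete-thrombosis level).

## Synthetic cases (what they emulate, what they don't)

- **Channel (Poiseuille/Womersley):** pure solver verification; both
  flows are exact solutions of the solved equations, so measured errors
  are discretization error only (≈3·10⁻⁴ L2 steady at ny = 64, ≈8·10⁻⁴
  pulsatile at α = 5).
- **Backward-facing step** (inlet 4 mm, step 2 mm, mean inlet speed
  0.2 m s⁻¹, Δ = 0.5 mm, steady): the kinetics-calibration geometry.
  The default configuration is the 40 s calibration run; the test
  suite runs an 8.5 s segment, long enough for the recirculation-zone
  clot to cross BP_t. The measured laminar reattachment length at
  Re_step = 100 (Newtonian, Δ = 0.25 mm) is ≈4.6 step heights. The
  inflow speed is chosen so the redeveloping wall layer behind
  reattachment recovers above the 0.2 Pa gate within the 8-step-height
  recirculation region; at half this speed the gate stays open far
  downstream and coagulant spreads past the bubble.
- **Idealized dissection** (true lumen 8 mm, flap 2 mm, false lumen
  8 mm, length 6 cm, Δ = 1 mm; TL mean velocity 0.2 m s⁻¹ giving wall
  shear rates ≈150 s⁻¹, aortic order): one proximal 6 mm tear
  (admission-stage analog) or proximal + middle tears with the restart
  protocol (follow-up-stage analog). The false lumen is closed at both
  ends, so its only exchange is tidal flow through the tears. These
  analogs reproduce the model's qualitative behaviour — false-lumen
  residence times of ≥5 cycles, thrombus confined to the false lumen
  and tears with a clean lumen core, reduced false-lumen residence time
  and between-tear deposition once a second tear exists, and monotone
  throttling of tear exchange as the clot grows. They do not reproduce
  any patient geometry: no curvature, no branches, no flap motion, 2D
  planar flow, and tear dimensions are assumptions exposed in the
  configuration.

The test-suite problem sizes (10 growth cycles at Δ = 1 mm for the
dissection analogs, 8.5 s at Δ = 0.5 mm for the step) are the package's
standard desk-scale protocol; the full 20-cycle runs use the same code
paths via the case defaults.

## Known limitations

- First-order momentum convection diffuses separated shear layers on
  coarse grids (the step reattachment length shortens from 4.6 h at
  Δ = 0.25 mm to 3.6 h at Δ = 0.5 mm).
- The wall-flux source has no saturation, so near-wall coagulant grows
  to 10³–10⁴× C_t inside sealed pockets; only the shear-gated
  consumption limits its spread. Consequences of this choice are
  discussed under C_t above.
- The bulk shear gate (γ̇_avg < 50 s⁻¹) always admits a thin
  channel-centreline band; it stays clean only because coagulant
  cannot accumulate there. Very slow lumens (mean speeds ≲0.1 m s⁻¹ at
  these dimensions) violate that protection and thrombose — a regime
  boundary of the model worth knowing about, not a numerical artifact.
- The time-scale map (simulated seconds × 150 ≈ real seconds) is
  calibrated under steady flow and is only an order-of-magnitude guide
  under pulsatile conditions.
- No high-shear (von Willebrand factor) pathway, no coagulation-factor
  biochemistry, no fluid–structure interaction.
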