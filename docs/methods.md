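# Methods

## The model

The paravascular space (PVS) around a cortical penetrating arteriole is
modelled as an axisymmetric annulus of cerebrospinal fluid, R1 ≤ r ≤ R1+wd,
0 ≤ z ≤ La, embedded in a brain-tissue annulus extending to R3. The z = La
end opens toward the subarachnoid space (SAS), z = 0 toward the parenchyma.
Three ingredients are coupled:

**Fluid.** Incompressible Darcy–Brinkman flow through the porous annulus,

    ρ_f [∂v/∂t + ((v − w)·∇)v] + (µ_f ζ/k_s) v = ∇·σ_f,   ∇·v = 0,
    σ_f = −p I + µ_f (∇v + ∇vᵀ),

in arbitrary Lagrangian–Eulerian (ALE) form on a mesh moving with the
boundaries (mesh velocity w). Infinite permeability k_s drops the drag and
recovers Navier–Stokes. At the default parameters the drag term dominates
inertia and viscosity by 3–4 orders of magnitude, so the flow is
quasi-static Darcy lubrication with Brinkman boundary layers of thickness
√(k_s/ζ) ≈ 0.16 µm at the walls.

**Solid.** The brain annulus is a compressible Saint-Venant–Kirchhoff
solid: E = (FᵀF − I)/2, S = λ_s tr(E) I + 2µ_s E, λ_s = 2νµ_s/(1−2ν), with
µ_s = 4 kPa, ν = 0.45, fixed at r = R3, axially rolled at the deep face,
traction-free at the pial face. Inertia is retained but negligible at the
frequencies of interest.

**Coupling and drive.** On the arteriolar wall the radial displacement
u_wall(z, t) is prescribed (travelling 10 Hz heartbeat wave of ±0.5% of R1;
a gamma-shaped functional-hyperemia dilation peaking at 15% of R1; or a 4%
peak-to-peak sweep sinusoid) and the fluid follows it (no slip). On the
brain–PVS interface, mesh displacement, fluid velocity and traction all
match the tissue. The two axial ends carry lumped Robin resistances:
traction −R_out·q(t)·n with q the instantaneous signed outflow,
R_out = 0.01·R_PVS (SAS side) and 10·R_PVS (parenchymal side), where
R_PVS = µ_f ζ La/(k_s A) is the Darcy resistance of the annulus
(A = π((R1+wd)² − R1²); ≈ 3.9×10¹⁶ Pa·s/m³ at the defaults).

## Numerical treatment

Structured triangulations (tanh-clustered radially in the PVS toward both
walls; geometric grading into the brain) carry equal-order P1/P1 fluid
elements with residual-based PSPG pressure stabilization whose coefficient
interpolates between the viscous (h²/12µ) and drag (k_s/µζ) limits; the
drag and inertia parts of the momentum residual are retained in the
stabilization so the scheme stays mass-consistent in the Darcy-dominated
regime. The solid uses P1 displacements with an analytically linearized
SVK tangent (Newton). Time stepping is BDF2 with a BDF1 start; the no-slip
wall data is the BDF derivative of the prescribed displacement, which
keeps boundary kinematics and domain-volume change in exact discrete
agreement. Mesh motion is a component-wise harmonic extension (factorized
once); ends slide axially. The coupled system is solved monolithically:
interface fluid-velocity unknowns are eliminated through the kinematic tie
v_f = BDF(u_s) (trial side weighted c0/dt), while interface residuals are
summed with unit test weights, which enforces the traction balance. The
in-step geometry (interface position) is converged by a short fixed-point
loop starting from a second-order extrapolation.

Verification oracles: the steady axial-flow profile against a 1-D
Brinkman two-point boundary-value solution (≤1% L²); the static annulus
against the plane-strain thick-cylinder (Lamé) closed form (≤2%); the
Navier–Stokes limit against k_s → ∞; per-step mass defect below 0.1% of
the peak boundary flux (after the BDF1→BDF2 start-up, which carries a
localized O(dt) transient for ~5 steps); exchange fractions move < 2%
under mesh/time refinement.

## Transport metrics

* Mean downstream speed: time-average of the annulus through-flux
  (q_deep − q_pial)/2 divided by A — the cross-section-averaged −v_z, with
  downstream = toward the parenchyma. For periodic compliant-brain runs the
  start-up storage transient (the tissue creeps toward its oscillation mean
  for many cycles, τ ~ R_PVS·C_tissue ≈ 1 s with a diffusive tail) is
  removed by regressing per-cycle deep outflow against the measured volume
  growth rate (`periodic_mean_downstream_speed`).
* Volume exchange fraction Q_f: maximum cumulative net outflow through the
  pial end from rest, divided by the *fluid* volume ζ·π((R1+wd)²−R1²)·La.
  The porosity scaling is forced by an invariant: the inviscid-limit
  hyperemic event expels nearly the full wall-swept volume, which is ~67%
  of the fluid volume but only ~53% of the geometric envelope, and only the
  former is consistent with the reported open-channel exchange.
* Re and Pe: Re = 2ρ_f q wd/(µ_f A), Pe = 2 q wd/(D A) with q the *peak*
  instantaneous magnitude of the flow rate at z = La (Pe_0) or z = La−50 µm
  (Pe_50), D = 1.4×10⁻⁶ cm²/s (amyloid-β). Peak is the conservative
  reduction of a transient flow; any single-number reduction of these
  events is a convention and the choice shifts Pe by tens of percent.
* Particle tracking: forward-Euler advection of tracer positions on the
  stored velocity snapshots of the deforming mesh, with a batch of
  SAS-side particles appended every 0.5 s.

### Outlet anchoring in the Navier–Stokes limit

When the PVS interior is idealized as an open channel, the annulus
resistance drops ~30-fold below the Darcy value, and the question arises
which reference the outlet resistances should multiply. The package
anchors them to the physiological Darcy value by default
(`outlet_reference="darcy"`): the SAS and parenchyma are unchanged by an
idealization of the PVS interior. The pure free-channel normalization
(`"poiseuille"`) is available and is the appropriate reading for the
rigid-wall open-channel baseline, whose reported pressures match it.

## Imaging chain and its synthetic validation

The two-photon pipeline follows the in-vivo processing design: red-driven
subpixel DFT registration and a (3,3,5) median filter; scalar crosstalk
unmixing by 1-D minimization of ‖r − αg‖ over (0, 1.5); vessel lumen area
by Radon-space thresholding (1° steps, per-angle min–max rescale, 0.2
threshold, inverse transform, largest region); gamma-function HRF between
binarized locomotion (acceleration above 3 MAD of rest, or any nonzero
acceleration for sparse-event traces) and diameter, gated at R² > 0.6;
piecewise-rigid tissue displacement on 64×64 tiles with 48-px overlap,
top-20th-percentile fluorescence gate, ≤5 registration iterations with the
1%-increment convergence rule and 0.7 error gate, scrubbing/median-fill and
biorthogonal-3.3 soft-threshold wavelet denoising; radial-direction (±30°)
and wall-correlation (Pearson > 0.8) tile gates; regularized
frequency-domain deconvolution for peak-normalized impulse responses.

The synthetic generators emulate (i) a 512×512 field of ~100 random
anti-aliased line segments displaced uniformly radially outward with a
gamma time course after a rest period, and (ii) a two-channel recording
with a dilating lumen (red), a neurite field displaced at a chosen
tissue-to-wall ratio ρ (green, carved out of the lumen so the channels are
spatially disjoint), crosstalk α·green added to red, and Gaussian (option:
Poisson) noise calibrated so that mean signal / background SD hits the
requested SNR using displacement-dilated masks. They do not model
photobleaching, detector nonlinearity, axial (z) motion, or non-rigid
tissue shear within a tile — so passing tests demonstrate correctness of
the estimator chain, not robustness to every in-vivo artefact.

## Problem sizes and known limitations

Default suite/script sizes: 8–14 radial × 24–64 axial PVS cells, 10–20
radial brain cells, dt = 0.25–0.5 ms (heartbeat) and 5–10 ms (hyperemia);
the reported exchange fractions and hyperemia mean speeds are within ~1–2%
of refinement at these sizes.

Limitations worth knowing:

* The compliant-brain *periodic* mean downstream speed is a second-order
  residual ~10⁻⁶ of the oscillatory amplitude, reachable only after the
  slow storage transient; the regression estimator removes most but not
  all of the contamination at desk scale.
* The hyperemia waveform is specified only graphically in its source; the
  gamma (k = 2, t_peak = 1.2 s) parameterization used here fixes the peak
  amplitude and approximate rise time, and hyperemia-driven quantities
  inherit that uncertainty (hence the wider tolerance band).
* Pe/Re values depend on the scalar reduction of a transient flow (peak
  here).
* Single-phase porous PVS with an elastic (not poroelastic) brain;
  concentric circular cross-section; no solute transport PDE.
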