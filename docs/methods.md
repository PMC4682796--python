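# Methods

This note documents the model equations as implemented, the numerical
schemes, the unit system, the parameters that matter (with defaults and the
reasoning behind them), and the limitations a user should keep in mind when
interpreting results.

## Units and scales

- **Length.** Continuum fields are solved in units of `length_scale_mm`
  (default 0.2 mm, the oxygen-diffusion length scale), so the 2 × 2 mm field
  is 10 × 10 model lengths and the oxygen diffusivity is the unit
  diffusivity. Network geometry (radii, lengths, surface areas) is kept in
  SI meters because the adhesion constants (α, β, γ) are printed in SI.
- **Time.** Days for tissue dynamics; the treatment loop uses an inner step
  of 0.5 h; network NP transport uses seconds internally (segment transit
  times are ~0.03 s; the implicit scheme lets the injection hour be covered
  in 60-s steps).
- **Concentrations.** Inlet NP concentration is normalized to 1; bound
  amounts and drug are in the corresponding dimensionless units. The
  conversion `drug_load_scale` from bound-NP units to drug units is an
  arbitrary overall factor: it rescales λ̄_IC50 but cancels in every
  comparison of relative efficacy.

## Grid and field solvers

Fields live on a cell-centered square grid with a 5-point Laplacian and
mirrored ghost cells (zero-flux boundaries), which makes the discrete
operator exactly conservative. Steady reaction–diffusion problems
(oxygen) are solved by one sparse LU solve — the saturating source
S(x)(1 − σ) is linear in σ — with a Picard loop available for genuinely
nonlinear sources. Time-dependent fields (drug, TAF) use backward-Euler
steps; the implicit operator is factorized once per (coefficients, dt) and
reused, so a 72-h treatment run costs one triangular solve per step per
field. Backward Euler is first order and unconditionally stable; one global
step size serves every field.

The oncotic pressure is solved only on the tumor with a homogeneous
Dirichlet condition on the interface. The masked solve uses a half-cell
expanded band: the ghost Dirichlet cells then sit ~one grid cell outside
the zero contour, which cancels most of the staircase bias in the
near-interface pressure gradient (without this, interface speeds are
systematically ~6% low at the test resolution).

## Tumor interface

The lesion boundary is the zero contour of a signed-distance level set,
advected with a first-order upwind scheme under a CFL-limited substep. The
Darcy velocity is extended off the tumor by linear extrapolation along the
inward normal (nearest interior cell plus one cell deeper), which is exact
for linearly varying velocity — e.g. uniform proliferation on a disc, where
|v| = λ_p r/2. The field is re-initialized to a signed distance every
fourth step by marching-squares contour extraction plus a KD-tree distance
query; each re-initialization costs a small area (inscribed-polygon bias),
which is why it is not done every step. The tumor area is measured with a
smeared Heaviside (width 1.5 cells), accurate to ~1% for lesions a few
cells across but biased upward for sub-cell nodules.

Nodules spanning fewer than `analytic_growth_cells` (default 16) grid cells
bypass the discrete Darcy solve entirely: for a small disc with
near-uniform net proliferation the exact dynamics are dR/dt = λ̄ R/2, and
the signed-distance field is shifted by R(e^{λ̄Δt/2} − 1) in closed form.
This is how a 20-µm seed grows on a 31-µm grid.

With uniform rates the area then obeys dA/dt = λ̄A exactly, and in the
resolved regime the property suite checks the exponential law to 5% over a
doubling.

### Region classification

Oxygen thresholds σ_H = 0.5 and σ_N = 0.3 split the tumor into
proliferating/hypoxic/necrotic. Necrosis is **irreversible**: a cell that
has died stays necrotic while inside the tumor. Besides being the
physiological reading, this removes a genuine bistability — necrotic tissue
consumes little oxygen, so σ recovers over the dead core and a memoryless
classifier would flip the region back to viable every other step.

## Oxygen

Quasi-steady (oxygen equilibrates much faster than tissue grows; the field
is re-solved once per growth step):

    0 = ∇²σ + λ̄_ev·1_vessel·max(h/H̄_D − h̄_min, 0)·(1 − k_pi·min(p_i/p_e, 1))·(1 − σ) − λ(σ-region)·σ

Pre-existing capillaries always carry the normal hematocrit H̄_D = 0.45
(constant-hematocrit approximation); perfused neovessels carry half of it,
and unperfused dead-end sprouts carry none — the hematocrit switch
(h̄_min = 0.25) then cuts their oxygen delivery. The positive-part clamp on
the hematocrit term is deliberate: it is the only reading under which
h̄_min acts as a minimum hematocrit for extravasation.

**Interstitial-pressure surrogate.** Extravasation is suppressed by the
factor (1 − k_pi·p_i/p_e) with p_i taken as the *depth inside the tumor*
(the negative part of the level set), saturating at p_e = 0.5 model lengths
(~100 µm). Solid stress and interstitial pressure build with distance from
the lesion boundary, and the depth is a monotone, always-available proxy.
An earlier design coupling p_i to the oncotic pressure P was abandoned:
P collapses whenever hypoxia stalls growth, so the suppression switched off
and the oxygen/region coupling limit-cycled. With k_pi = 0.95 the deep core
keeps only 5% of its exchange capacity, which (together with the uptake
contrast λ_tumor = 2.5 vs λ_tissue = 0.12) produces the proliferating-rim /
hypoxic-band / necrotic-core anatomy. The hypoxic band is a transient
feature: as the peri-tumoral plexus matures it can re-oxygenate, so
whether Ω_H is non-empty at exactly day 18 depends on seed and parameters
(the necrotic core it produced remains).

## Vasculature and flow

Pre-existing capillaries form lines every 250 µm along both axes of the
2-mm field (9 lines per direction), discretized in one-grid-cell segments
(radius 10 µm). Left-edge nodes are pressure inlets and right-edge nodes
outlets (Δp = 500 Pa, viscosity 3 mPa·s), giving capillary-range flows
(~0.3 nL/s) and wall shear ~400 s⁻¹, and a left-to-right perfusion
direction that produces inflow-side NP accumulation. Interior nodes satisfy
Kirchhoff mass balance to <1e−8 relative.

**Solid-stress compression.** Segments inside the tumor have their
*hemodynamic* radius reduced linearly with depth, down to 50% at one model
length; since conductance goes as R⁴, deep intratumoral segments lose ~94%
of their conductance and perfusion reroutes around the core. This is the
package's simplification of full stress-coupled vascular remodeling, and it
is what confines NP delivery to the lesion periphery and its plexus.

**Angiogenesis.** TAF is released by hypoxic tissue (implicit
diffusion–decay steps; decay length ~280 µm) and sprout tips nucleate on
vessels where TAF exceeds a threshold, then walk on the lattice with move
probabilities ∝ (motility D) + (chemotactic weight χ/(1+ηT)·∂T) +
(haptotactic weight χ_E·∂E), normalized with a stay option. Tips fuse with
any vessel node they step onto (after a minimum age that prevents trivial
re-fusion with the parent line); only anastomosed loops carry flow.
Nucleation rates, tip speed (0.45 mm/day) and the tip budget (150 active)
were chosen to give a dense peri-lesional plexus by day 18 (~500 neovessel
segments); they are free parameters constrained only by that qualitative
morphology.

## Nanoparticle adhesion and transport

The wall-adhered density is n = n₀ α d^δ1 exp(−β(1 + γ d^δ2) Srt) with
δ1 = 0.45, δ2 = 1.57, β = 1e−4 m⁻²s, γ = 1e4 m^−δ2. Multiplying by the
segment surface area and dividing by the luminal-exposure normalization n₀
gives a per-transit capture probability, clamped to [0, 1] (the clamp count
is reported). n₀ = 10 places the reference case (100 nm, α = 10¹² m⁻²,
10-µm segments) at ~13% capture per 31-µm segment, i.e. a depletion length
of a few hundred µm: small particles survive far enough into the
tumor-associated network to coat it, while 600–1000-nm particles (capture
2.2–2.8× higher per segment) exhaust within the first segments at the
inflow side. This partial-capture regime is the load-bearing calibration:
with much larger capture everything saturates and size no longer matters;
with much smaller capture the network strips too few particles for the
affinity contrast to matter.

**Receptor activation.** The 100× lower α describes *host-tissue*
endothelium. Segments within the tumor's angiogenic halo (1.5 model
lengths ≈ 300 µm outside the interface, and everything inside) are treated
as activated endothelium carrying the full α_neo whether or not the vessel
is newly formed: receptor expression follows the microenvironment, not the
vessel's birth date. Without this, the only high-affinity path segments are
the sprouts themselves, upstream depletion cannot differentiate particle
sizes, and the payload advantage (∝ d) of large particles would dominate
every efficacy comparison.

Transport through the network is fully implicit: each step solves a sparse
nodal system in which inflows, outflows and capture are all evaluated at
the new time level, so the update is unconditionally stable,
positivity-preserving, and conserves particles exactly (free + bound +
boundary fluxes balance to solver precision; the suite checks 1e−6).
Injection is a square pulse of inlet concentration 1 for 1 h followed by
washout; the tumor is frozen during the injection hour (bolus transit is
seconds; tissue dynamics are days).

## Drug release and transport

Payload per segment = bound amount × (d / 100 nm); zero-order release rate
= payload / full-release time with the full-release time 12·√(d/100 nm) h.
The √d law is fixed by the stated calibration (100 nm in 12 h, 1000 nm in
~38 h = 3.16× longer); a rate linear in d would make the duration
size-independent and could not produce that spread. When less than one
step's release remains, the remainder is released exactly.

Released drug enters the tissue at the segment's grid cell and evolves by
implicit diffusion–decay with λ̄_decay = ln2 / 6 h. D_G is relative to a
reference diffusivity (20 model-lengths²/day) chosen so that the standard
D_G = 0.022 drug spreads ~100 µm around its source — the drug field then
inherits the spatial footprint of the NP distribution, which is what makes
distribution quality matter — while a D_G = 1 drug ("optimally diffusive")
covers the whole lesion within a half-life. Drug mass balance per step
(released − decayed) holds to 1e−6.

## Efficacy analysis

"Reducing the tumor by 50% of its original area" is evaluated as the
*minimum relative area over the 72-h observation window* (the nadir), with
"original" the area at injection time. A fixed-time readout would depend on
an arbitrary sampling instant; the nadir is well defined, and in practice
the post-nadir plateau is flat, so the area near 24 h is within a few
percent of the minimum for the reference formulation. Bisection on
λ̄_effect starts from [0, λ_hi] with λ_hi·max(G) ≈ 10 (deep-kill regime),
expands up to three times if needed, and stops when the nadir is within
0.01 of the target; for the boundary target 1.0 (growth stall) the response
is flat below the stall point, and a bracket-width stop (0.1%) locates the
knee instead. A formulation that cannot reach the target even at the
expanded maximum is reported as a non-converged low-efficacy outcome
(relative efficacy 0), not an error.

The local drug-induced death rate is capped at 48/day (death within ~30
minutes — instantaneous at tissue time scales) so that "kill" stays
resolvable by the interface CFL; the cap does not bind at the tuned
potencies.

## Problem sizes

The test suite and the acceptance script run at 64 × 64 cells (31-µm cells)
with dt = 0.1 day for growth and 0.5 h for treatment: a full 18-day growth
takes a few seconds and one IC50 tuning under a minute, so the whole
formulation grid is minutes of compute. The default configuration for
interactive use is 200 × 200 (10-µm cells); results shift quantitatively
with resolution (the per-segment capture probability scales with segment
length), so calibrated statements refer to the test resolution.

## What the simulations do and do not show

All inputs are synthetic by design (the generator *is* the study system):
a regular capillary bed, a single circular seed, homogeneous tissue
parameters. Passing tests therefore demonstrate internal consistency —
conservation laws, closed-form limits, monotonicities, and the qualitative
orderings of the formulation comparison — not calibration to any real
tumor. Known limitations: 2-D geometry (vessel planes and diffusion
kernels differ in 3-D); no NP extravasation (EPR) or RES clearance; no
pulsatile or non-Newtonian flow; constant hematocrit; drug units are
relative, so λ̄_IC50 values are comparable within this model only; single
injection schedules only; and the angiogenesis rates are qualitative
choices, not measured kinetics.
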