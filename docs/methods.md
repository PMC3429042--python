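# Methods

This note records the model equations, the numerical choices, the defaults
and their rationale, and what the package's tests do and do not demonstrate.

## Coagulation cascade

The chemistry is the 18-species, 16-reaction mass-action model of the
tissue-factor pathway: reversible substrate binding to TF:VIIa, tenase
(VIIIa:IXa) and prothrombinase (Va:Xa) with explicit enzyme–substrate
complexes, first-order catalytic turnover of those complexes, second-order
activation of V/VIII by Xa and by thrombin (the positive feedback), IX
activation by Xa, and meizothrombin conversion to thrombin by
prothrombinase. The turnover constants are published as Michaelis–Menten
Vmax values; because the scheme carries the complexes explicitly, they are
used here as first-order catalytic constants on those complexes — the only
reading consistent with writing dc/dt = S·r over 18 species.

The stoichiometric matrix is *constructed* from the reaction list rather
than transcribed, and is validated structurally: each of the six moiety
indicator vectors (IX-, TF:VIIa-, X-, V-, VIII- and II-backbones) must lie
in the left null space of S. Catalysts cancel in S (e.g. the
meizothrombin→thrombin column touches only mIIa and IIa).

Units are mol/m³ (numerically equal to mM) and s throughout; no unit
conversion layer exists on purpose, since mixing nM-based constants with
m³-based concentrations is the classic failure mode in this literature.

**Batch integration.** BDF with analytic Jacobian, rtol = 1e-8,
atol = 1e-12 mol/m³; the rate constants span ~9 orders of magnitude, which
rules out explicit stiff-free integration on the minutes-long horizon. The
default horizon of 1000 s doubles automatically (up to 64 000 s) until the
plateau detector succeeds. Phase detection: the lag phase ends when [IIa]
first exceeds 1% of its final value; the plateau starts once the relative
rate |d[IIa]/dt|/[IIa]_final stays below 1e-6 s⁻¹; a flat or unsettled
trajectory yields an explicit "no plateau" outcome rather than an error.

**Negative-concentration policy.** Mass-action rates are undefined for
negative inputs: values in [−atol, 0) are clipped to zero before rate
evaluation, anything more negative raises. Trajectory *outputs* are not
clipped — BDF can undershoot zero by O(100·atol) at a depletion kink, and
clipping would break the otherwise exact (round-off-level) conservation of
the linear moiety invariants. Tests therefore assert min c ≥ −1e-10.

## Rheology

Carreau–Yasuda with the standard 37 °C whole-blood fit (μ0 = 0.16 Pa·s,
μ∞ = 0.0035 Pa·s, λ = 8.2 s, n = 0.2128, a = 0.64; ρ = 1050 kg/m³). Scalar
shear rate γ̇ = √(2 D:D). Wall shear stress uses second-order one-sided
differences through the two near-wall cell centroids (first-order wall
gradients visibly bias WSS at coarse resolution); AWSS is the
2πR(z)·ds-weighted mean over a configurable wall strip, defaulting to the
distal-contraction strip [z_c + 0.3 L_b, z_c + 0.5 L_b] where the shed
vortex impinges — the exact extent of that region is not an established
number, hence configuration.

## Geometry, grid, waveform

Idealized axisymmetric fusiform aneurysm: cosine bulge
R(z) = R0 + (Rmax−R0)(1+cos(2π(z−z_c)/L_b))/2, giving compact support and
C¹ continuity at the bulge ends (a Gaussian would leak into the entrance
and exit tubes). Defaults: maximum luminal diameter 4.4 cm (clinically
relevant small AAA); inlet diameter 2.0 cm, bulge length 10 cm,
entrance/exit 6 cm — the latter three are *assumed* physiological values,
exposed in configuration and tagged as assumed in the provenance record.
Rmax = R0 degenerates to a straight tube, used by the verification tests.

The grid is cell-centered and body-fitted: uniform axial nodes, radial
nodes at η_j·R(z_i) with tanh clustering toward the wall (resolving the WSS
and concentration boundary layers). All face areas and cell volumes carry
the axisymmetric 2πr weighting exactly for linear-in-r variation, so
discrete budgets close to round-off. A structured grid (rather than an
unstructured triangulation) keeps the solver compact and makes monotone
upwinding and positivity trivial to guarantee.

**Exposure patches.** Case A (large) covers the proximal half of the bulge
wall; case B (focal) a strip of 10% of the bulge length on the proximal
bulge wall. Published figures of such configurations are only graphical, so
these extents are stated guesses, configurable per run.

**Inlet waveform.** Real measured infrarenal waveforms are not available to
the package, so a synthetic stand-in is generated: a von-Mises-type bump on
a constant base, period T = 1.2 s, systolic peak at t = 0.25 s, mean flow
1 L/min (resting infrarenal value) and peak 6 L/min, chosen a priori so the
peak Reynolds number (≈1.9·10³ on the inlet diameter at μ∞) sits in the
transitional range typical of AAA inflow. The mean is enforced exactly by
construction; the diastolic minimum stays positive (~0.16 L/min). All
flow-magnitude-dependent outputs (WSS values, vortex strength, transport
rates) therefore carry waveform uncertainty and are treated as qualitative.

## Flow solver

Incremental pressure-projection finite-volume scheme:

* collocated cell-centered velocities, first-order upwind convection
  (explicit), implicit-Euler viscous step with the variable Carreau–Yasuda
  viscosity; the viscous operator (and the adaptive CFL time step) is
  refreshed every few steps (default 10) with lagged viscosity — viscosity
  evolves on the cardiac time scale, not the step scale;
* the divergence constraint is imposed on *face volume fluxes* via a
  two-point-flux (TPFA) pressure Poisson solve, LU-factorized once; after
  correction every cell's net flux is zero to solver precision, so
  instantaneous inlet/outlet mass balance is exact by construction and the
  very same fluxes drive conservative scalar transport. This face-flux
  formulation plays the role usually assigned to staggered variable
  placement (no pressure checkerboarding, exact discrete continuity);
* boundary conditions: parabolic inlet profile scaled to Q(t) with exact
  annular face fluxes (a Womersley profile is omitted; the entrance length
  absorbs the difference), no-slip wall, symmetry axis (axis faces have
  zero area, so axis conditions are automatic), zero-gradient outflow with
  reference pressure 0 — with rigid walls and incompressible flow only the
  pressure differential matters;
* the simplified stress divergence ∇·(μ∇u) (plus the axisymmetric hoop term
  −μ u_r/r², taken implicitly) is used; the (∇u)ᵀ·∇μ cross term is dropped,
  a standard generalized-Newtonian simplification consistent with the
  overall first-order spatial accuracy of the upwind convection.

The impulsive start is washed out by discarding the first N−1 of N cycles
(default N = 4); the cycle-to-cycle L2 velocity change is reported as the
periodicity diagnostic and decreases monotonically in all test runs
(0.32 → 4e-3 → 5e-4 over three washout cycles at 200×40).

## Species transport

Strang splitting per step: half-step chemistry, full transport step,
half-step chemistry.

* *Transport*: explicit first-order upwind convection on the
  divergence-free face fluxes plus implicit central diffusion
  (D = 1e-8 m²/s for all species — the deliberately inflated regularization
  value; the physical ~1e-10 m²/s is selectable, and an additional
  artificial-diffusion knob exists for experiments). Both sub-operators are
  monotone, so no oscillation can drive a concentration negative; a
  monotone scheme was preferred over a stabilized higher-order one
  precisely because negative concentrations are not acceptable inputs to
  mass-action chemistry. The diffusion operators (one with the wall-patch
  Dirichlet rows for TF:VIIa, one without) are assembled and LU-factorized
  once per run and shared across species and steps.
* *Chemistry*: fixed-step RK4 vectorized over all cells. At transport step
  sizes (~1 ms, CFL-limited) the fastest kinetic eigenvalues (~1e2 s⁻¹)
  give λ·Δt ≈ 0.1, so the split reaction step is not stiff and a per-cell
  implicit solve would buy nothing; the batch-equivalence test (flow-free,
  flux-free run vs. the BDF batch integration, 1e-4 relative in every cell)
  pins the accuracy of exactly this choice. Stages are clipped at zero;
  undershoot beyond 1e-10 mol/m³ aborts with cell/species diagnostics.
* *Boundaries*: Dirichlet physiological concentrations at the inlet with
  TF:VIIa = 0; TF:VIIa = 1e-6 mol/m³ on exposure-patch wall faces (all
  other species zero-flux there — whether patches also absorb species is
  not established, so the conservative choice is made); zero flux on the
  remaining wall; zero-gradient outflow; TF:VIIa and its complexes are
  transported in the fluid like every other species (microparticle-borne
  tissue factor).

The coupled driver reuses one recorded flow cycle periodically (linear
interpolation between stored divergence-free flux snapshots stays
divergence-free), reports the per-cycle L2 change of the thrombin field
(no hard periodicity threshold is imposed), and computes the
distal-accumulation metric: volume-weighted axial centroid of thrombin
mass and the mass fraction distal to the bulge apex, with the convention
that the cell center decides the side; an all-zero field yields an
explicit "undefined" outcome.

## Vortex eduction

λ₂ is the middle eigenvalue of D² + Ω², computed by the closed-form
trigonometric solution of the symmetric 3×3 eigenproblem (deterministic,
vectorized, no iteration; accuracy near degenerate eigenvalue pairs is
~1e-7 relative, which the tests account for). Hoop terms are included for
axisymmetric input; planar fixtures carry a zero third row/column.
Thresholded regions use 4-connectivity (corner-linked blobs stay separate)
with deterministic scan-order labeling, sorted deepest-first. The default
visualization threshold is 1% of max |λ₂| in the snapshot — no canonical
numeric threshold exists, so it is configuration.

## Problem sizes and budgets

Default production grid 200×40 (8000 cells), ~1000–2000 flow steps per
cardiac cycle (adaptive CFL 0.35), ~1800 transport steps per cycle. Chosen
so that a full verification pass — the pulsatile flow, the λ₂ suite, the
transport–batch equivalence on 50×10, and two coupled 5-cycle runs — fits
comfortably on a single CPU core in minutes. The coupled acceptance run
uses 5 cycles per exposure case; this is a *scaled-down transient*, not the
periodic state (see limitations).

## What the tests show — and what they do not

The synthetic-data layer (analytic fixtures, synthetic waveform, idealized
geometry) emulates: parabolic/rotational/vortical reference flows with
known closed forms, physiological pulsatility with a systolic peak, and
localized subendothelial TF:VIIa exposure. It does not emulate: measured
patient waveforms (so WSS magnitudes and vortex strength are
order-of-magnitude, not reproducible numbers), patient-specific lumen
shapes, 3D instability of the vortex ring, moving walls, platelet dynamics,
inhibitor chemistry, or ILT accretion feedback on the lumen.

Two quantitative behaviors are fully reproduced: the batch plateau
(1.4e-3 mol/m³ = initial prothrombin, within integrator tolerance) and the
conservation/verification suite (moiety drift <1e-6, exact mass balance,
Poiseuille within 3%, Lamb–Oseen core radius within 10%). The coupled
qualitative behaviors reproduced are: no thrombin without exposure; the
larger exposure (case A) produces a larger high-thrombin area than the
focal one (case B); thrombin mass drifts distally cycle by cycle; AWSS in
the distal impingement strip peaks in systole an order of magnitude above
the diastolic baseline.

**Known limitation — distal dominance needs the periodic state.** After 5
cycles the thrombin mass is still dominated by the near-stagnant activation
layer over the proximal patch (shear-thinning blood makes the diastolic
near-wall fluid almost static, so the cascade matures in place before the
vortex can strip it). The distal mass fraction grows monotonically
(~0.003 at 5 cycles, ~0.11 at 20, ~0.27 at 60 on a coarse grid) but
crossing 0.5 requires approaching the periodic state, which at these
problem sizes lies beyond a desk-scale run. The distal *shift* is therefore
demonstrated as a monotone trend plus the case A/B comparison, while the
absolute >0.5 fraction at 5 cycles is reported as computed, not achieved.

Other numerical limitations: first-order upwinding is diffusive (vortices
weaken faster than at second order and fine concentration filaments are
smeared); the collocated projection is first-order in time; the inflated
diffusivity (1e-8 m²/s) over-spreads near-wall gradients — with the
physical value the near-wall segregation of thrombin would be stronger, not
weaker, so the qualitative conclusions are conservative in that respect.
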