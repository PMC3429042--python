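# thromboflow

Coupled fluid–chemical modeling of intra-luminal thrombus (ILT) initiation
in abdominal aortic aneurysms (AAAs).

Most large AAAs harbor an intra-luminal thrombus, and the thrombus is
typically thickest in the *distal* part of the sac. `thromboflow` is a
research code for studying one candidate mechanism: pulsatile blood flow in
the dilated lumen sheds coherent vortices that capture coagulation products
generated at sites of exposed subendothelium and redistribute them toward
the distal aneurysm. It is aimed at cardiovascular-biomechanics and
systems-biology researchers who want a compact, fully scriptable
implementation of the whole chain — cascade kinetics, non-Newtonian
hemodynamics, species transport, vortex analysis — without a commercial FEM
package.

## The model

**Coagulation cascade.** The tissue-factor (extrinsic) pathway to thrombin
is modeled with 18 species and 16 mass-action reactions (zymogens IX, X, V,
VIII, II; their active forms; the transient complexes IX:TF:VIIa,
X:TF:VIIa, X:VIIIa:IXa, II:Va:Xa; the cofactor complexes VIIIa:IXa
("tenase") and Va:Xa ("prothrombinase"); and meizothrombin mIIa). With the
concentration vector **c** (mol/m³) and the 18×16 stoichiometric matrix
**S**,

    dc/dt = S r(c),

where each reversible binding contributes a single column with rate
k_on·[A][B] − k_off·[AB]. Inhibitors (TFPI, antithrombin, protein C) are
deliberately omitted: they are endothelium-bound, and the aneurysmal lumen
has largely lost its endothelium. Six moiety totals (e.g. all
prothrombin-derived species) are exact invariants and are used to verify
every integration.

**Blood rheology.** Carreau–Yasuda shear-thinning viscosity

    μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)^a]^((n−1)/a),   γ̇ = √(2 D:D),

with the standard 37 °C whole-blood constants (μ0 = 0.16 Pa·s,
μ∞ = 0.0035 Pa·s, λ = 8.2 s, n = 0.2128, a = 0.64, ρ = 1050 kg/m³).

**Hemodynamics.** Incompressible axisymmetric Navier–Stokes on an idealized
fusiform aneurysm (cosine bulge, 4.4 cm maximum luminal diameter) under a
synthetic pulsatile inlet waveform (period 1.2 s, mean 1 L/min, systolic
peak at t = 0.25 s), solved by a finite-volume projection method with
divergence-free face fluxes on a body-fitted structured grid.

**Species transport.** Eighteen convection–diffusion–reaction equations

    ∂c_i/∂t + u·∇c_i = ∇·(D ∇c_i) + R_i(c)

ride on the precomputed flow, with Strang splitting (chemistry ↔ monotone
upwind transport), D = 10⁻⁸ m²/s, physiological inlet concentrations with
TF:VIIa = 0, and TF:VIIa clamped at 10⁻⁶ mol/m³ on exposed-subendothelium
wall patches (a large "case A" and a focal "case B").

**Vortex eduction.** The λ₂ criterion: a vortex is a connected region where
the middle eigenvalue of D² + Ω² is negative.

## Worked example

```sh
$ python examples/batch_cascade.py
integrated 2000 output times up to t = 1000 s
lag phase ends        :     15.5 s
plateau phase starts  :     92.0 s
plateau [IIa]         : 1.4000e-03 mol/m^3
prothrombin moiety    : 1.4000e-03 mol/m^3 (conserved)
```

Thrombin ([IIa]) shows the classic sigmoid: a slow time-lag phase (~15 s)
while trace TF:VIIa builds the first Xa, an accelerated phase driven by the
thrombin positive feedback through factors V and VIII, and a plateau at
1.4 × 10⁻³ mol/m³ — exactly the initial prothrombin concentration, because
without inhibitors every prothrombin molecule is eventually converted.

A three-cycle pulsatile run (`python examples/pulsatile_aaa_flow.py`)
prints, among other things,

```
max instantaneous inlet/outlet imbalance: 1.69e-20 m^3/s
AWSS over distal strip: peak 2.12 Pa at t = 0.24 s, diastolic mean 0.07 Pa
t = 0.39 s: 2 interior vortical structures; strongest centroid at z = 0.078 m
```

i.e. exact discrete mass balance, a systolic spike of the space-averaged
wall shear stress where the shed vortex impinges on the distal contraction
(an order of magnitude above the diastolic baseline of the enlarged lumen),
and a ring vortex born on the proximal half of the bulge that then advects
distally. `examples/coupled_thrombin_transport.py` runs the full
fluid–chemical pipeline for both exposure cases and prints the thrombin
distribution metrics (axial mass centroid, distal mass fraction).

There is also a thin CLI:

```sh
thromboflow batch --out out/           # cascade batch run, CSV + phases
thromboflow flow --out out/            # flow + WSS/AWSS series + snapshots
thromboflow coupled --case A --out out/
thromboflow lambda2 --snapshot out/run_snapshot_000_00002.csv --out out/
thromboflow peclet  --snapshot out/run_snapshot_000_00002.csv --out out/
```

All parameters live in one YAML file (`--config`); every run emits a JSON
provenance record with the fully resolved configuration and a tag per
parameter (`paper` / `assumed` / `user`). Units are SI throughout
(mol/m³, m, s, Pa) — note that coagulation literature often quotes nM;
1 mol/m³ = 1 mM.

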