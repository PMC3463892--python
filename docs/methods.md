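# Methods

`ttflux` simulates spatio-temporal Ca²⁺ dynamics in a single t-tubule
microdomain of a rabbit ventricular myocyte under voltage clamp, with the
sarcoplasmic reticulum pharmacologically disabled. The model couples a
3-D reaction–diffusion system for free Ca²⁺ and four Ca²⁺ buffers to
sarcolemmal flux boundary conditions (L-type Ca²⁺ current, Na⁺/Ca²⁺
exchange, ATPase pump, background leak) on a synthetic, morphometrically
calibrated geometry.

## Model compartment

The compartment is one repeating unit of the t-system: a half-sarcomere
box, 2.34 × 2.58 µm in the sarcolemmal plane and 5.76 µm deep, pierced by
a single t-tubule running along the depth axis. The published unit was
segmented from confocal stacks and is not distributable, so the geometry
generator emulates it from printed morphometrics:

* t-tubule ≈ 4.6 µm long, elliptical cross-section with diameters
  0.39–0.62 µm, sinusoidal constrictions every 1.87 µm reducing the
  cross-sectional area to 57.7 % of nominal (the published ±-spreads are
  population statistics across tubules and are not sampled for the single
  synthetic tubule);
* cytosolic volume 0.0282 pL, t-tubule membrane area 7.8 µm²,
  outer-sarcolemma area 8.1 µm².

A flat-capped box is inconsistent with the printed numbers (its outer
face has area 6.04 µm² < 8.1 µm² while its volume 0.0348 pL > 0.0282 pL),
so the outer sarcolemma is carved as a plateau-clipped sinusoidal relief
`r(x,y) = A·min(1, 2(1 − cos kx'·cos ky'))`. The clipped form matters:
an unclipped sinusoid cannot remove ~6 µm³ of volume while adding only
~2 µm² of area within a physically shallow amplitude, whereas the
plateau decouples volume removal (amplitude A) from wall slope
(wavelength). The relief zero is anchored at the line-scan column so
the scan line starts at a true outer-surface point.

Three parameters — tubule mean diameter, relief amplitude, relief
wavelength — are calibrated by deterministic coordinate descent (secant
steps with a bracketed-bisection fallback) against the three printed
morphometrics; each knob dominates one observable (tubule area, volume,
outer area), and the default targets converge in one sweep to < 1 %
residuals at 40 nm voxels, well inside the 3 % acceptance band.

Voxelization uses cubic voxels (50 nm in the test suite, 40 nm for the
acceptance geometry, 80 nm for production dynamics — see *Problem sizes*
below), voxel-center classification, and explicit labeling of every
boundary face (outer sarcolemma, t-tubule membrane, reflective box
faces). Staircase bias in face-counted areas (≈ 4/π for a cylinder) is
corrected per label against quadrature areas of the analytic generating
surfaces; membrane flux distribution is normalized against *raw* face
areas, so the residual area bias can never corrupt whole-cell fluxes.

LCC cluster patches (three, ≈ 200 nm diameter) are placed on the tubule
membrane: one pinned 2 µm below the outer surface, the others either at
seeded-random depths with a non-overlap constraint or at prescribed
spacings (0.57 / 0.8 / 1.07 / 1.8 µm) for the spacing scan. Probe
definitions mirror the line-scan experiment: the scan line runs in the
transverse cell direction (into the cell, parallel to the tubule),
offset 200 nm laterally from the tubule mouth edge, with cytosolic
sample spots at 1.5 and 5.3 µm along it; sub-sarcolemmal probes sit at
the tubule mouth and adjacent to the deepest LCC cluster. The
sub-sarcolemmal mask is the cytosol shell within 40–50 nm of any
membrane face (one voxel layer at the working resolutions).

## Membrane fluxes

All four fluxes are expressed as whole-cell volumetric rates (µM/ms,
positive = Ca²⁺ entry) using the rabbit surface-to-volume ratio
C_m/V_cell = 4.54 pF/pL for current↔flux conversion (10 pA/pF of inward
current ≈ 0.235 µM/ms).

**NCX.** The Weber/Shannon product `J = V_max · Allo · ΔE`, where ΔE is
the electrochemical turnover of the 3 Na⁺ : 1 Ca²⁺ antiporter and
`Allo = 1/(1 + (K_mCaAct/Ca)ⁿ)` is Hill-type activation by Ca²⁺ at the
regulatory (non-transported) sites. V_max = 0.207 µM/ms and
K_mCaAct = 0.29 µM are rabbit-specific fits; the remaining constants
(K_mCai 3.59 µM, K_mCao 1.3 mM, K_mNai 12.29 mM, K_mNao 87.5 mM,
k_sat 0.27, η 0.35, T 310 K, n = 2) are lineage defaults, all exposed in
the configuration. The exchanger flux reverses exactly at
V = 3E_Na − 2E_Ca (≈ −53 mV at basal conditions, which is why a −50 mV
hold sits almost at exchange equilibrium), and `allosteric=False`
reproduces Allo ≡ 1 exactly for the non-allosteric variant. In the
solver the exchanger senses the Ca²⁺ of the membrane-adjacent voxel,
not a compartment average.

**LCC.** Whole-cell gating is not modeled; the voltage step drives an
empirical waveform `J(t) = A(1 − e^(−t/τ_act))·e^(−t/τ_inact)` per step
potential, with τ_act solved so the peak falls at the observed time to
peak (15 ms at 0 mV, 20 ms at +50 mV; τ_inact = 45 and 60 ms). The
amplitudes A are the last calibration stage (below). Only 0 and +50 mV
are parameterized; other step potentials are rejected.

**Pump and leak.** Hill-type sarcolemmal ATPase
(V_max 5 µM/s, K_m 0.5 µM, n = 2 — a deliberately small term, matching
its negligible reported contribution) and a voltage-dependent background
leak `J = −g_leak(V − E_Ca)`. g_leak is not a free choice: it is solved
in closed form so that basal conditions (0.1 µM Ca²⁺, 10 mM Na⁺,
−50 mV) are an exact steady state of the full flux balance
(residual < 10⁻¹⁰ µM/ms).

**Surface distribution.** Region density multipliers follow the
immunolabeling data: LCC 9× and NCX 3× higher in the t-tubule membrane,
pump/leak uniform. Distribution weights are normalized so the surface
integral of any distributed flux equals the whole-cell volumetric flux
times the compartment volume — exactly, on any grid. Clustered LCC mode
supports two readings of the source description: the default `matched`
mode gives each ~200 nm patch the tubule multiplier times the outer
density (the only reading consistent with the reported local
trigger-flux magnitudes of a few µM/s; the bare tubule between patches
then carries no LCC flux), while `tubule_share` concentrates the entire
9×-weighted tubule share into the patches, producing near-singular local
sources (hundreds of µM/s at an adjacent probe). Continuous mode spreads
the 9× density over the whole tubule membrane.

## Buffers

Four single-site mass-action buffers: Fluo-3 (50 µM as loaded in the
underlying experiments, K_d 1.1 µM), ATP (455 µM, K_d 200 µM),
calmodulin (24 µM, K_d 7 µM) mobile; troponin C (70 µM, K_d 0.6 µM)
stationary and excluded from the sarcolemma and the 40–50 nm
sub-sarcolemmal shell — implemented as a per-voxel exclusion *fraction*
(the share of each boundary voxel's volume inside the physical shell),
so the excluded TnC pool is identical at every grid resolution rather
than scaling with the boundary-layer voxel volume. Free buffer is
carried implicitly as
(total − bound); free and bound forms of each mobile buffer share one
diffusion coefficient so totals stay uniform. D_Ca = 0.35 µm²/ms;
D_Fluo-3 = 0.025 µm²/ms (myoplasmic, protein-bound dye) < D_ATP = 0.14.
The dye on-rate is the fast measured value (0.23 µM⁻¹ms⁻¹); with the
slower 0.1 µM⁻¹ms⁻¹ variant the global trigger flux peaks ~2 ms after
the step (a dye-disequilibrium artifact) instead of tracking the L-type
waveform maximum as observed. At basal Ca²⁺ the aggregate buffering
ratio β ≈ 130 (dominated by TnC and the dye), so ~1 % of entering Ca²⁺
stays free at equilibrium; TnC equilibrates slowly (τ ≈ 40 ms), which
makes the *effective* early-transient β closer to ~50.

## Numerics

Lie (first-order) operator splitting at Δt = 0.5 ms:

1. *Sources + reactions*, sub-stepped 20× per Δt, each sub-interval
   itself Strang-split (half source, buffer exchange, half source, so
   NCX/pump/leak re-sense local sub-membrane Ca²⁺ as it moves). Each
   Ca–buffer pair is advanced by the *exact* solution of its isolated
   pair ODE (a constant-coefficient Riccati equation in the bound
   concentration, with the pair total conserved) — unconditionally
   stable for the stiff dye/ATP kinetics, exactly conservative per
   pair, and positivity-preserving; the buffers are swept in symmetric
   (forward-then-reverse half-interval) order so the inter-buffer
   splitting error is second order.
2. *Diffusion*, backward Euler per mobile species on the 7-point
   no-flux Laplacian. Small systems (≤ 25 k unknowns) use a direct
   sparse LU factorization; production grids use unpreconditioned
   conjugate gradients (the operator is SPD) warm-started by linear
   extrapolation from the previous two solutions, rtol 10⁻⁸. Zero row
   sums make diffusion conserve mass to solver precision.

Membrane fluxes enter as volumetric sources in the boundary voxel layer
(face area / voxel volume scaling), the voxelized equivalent of a
Neumann condition at the working resolution. A mass ledger accumulates
every applied source; the balance audit
|Δ(total Ca) − ∫flux| / total Ca closes below 10⁻⁶ in routine runs
(tolerance 10⁻⁴). Concentrations below −10⁻⁹ µM abort the run; smaller
negative excursions are clipped and logged. Runs start from uniform
basal Ca²⁺ (0.1 µM) with buffers in analytic equilibrium; with the
calibrated leak this is already a steady state at the −50 mV hold
(pre-equilibration is a no-op). For Na⁺-free arms no steady state
exists at hold (the exchanger is efflux-only), so those runs start from
the same basal equilibrium, as in the underlying protocol; requesting a
strict steady start raises instead.

Refinement behavior is tested (acceptance suite): halving Δt or the
voxel size changes the global transient by < 2 %, and in the well-mixed
limit (small closed box, Ca diffusivity ×10⁴) the solver matches an
independent 0-D ODE integration (`scipy.solve_ivp`, LSODA) of identical
fluxes and buffer kinetics within 1 %.

## Calibration chain

Calibration runs once, in a fixed order, each stage freezing the last:

1. **geometry** → printed morphometrics (3 % band);
2. **leak** → exact basal rest balance at −50 mV (closed form);
3. **LCC amplitudes** → secant iteration on A at each step potential
   until the simulated global transient at the end of the 200 ms step
   matches the measured plateau (0.19 µM at 0 mV, 0.20 µM at +50 mV)
   within 2 %; convergence takes 2–3 full runs per voltage because the
   plateau excess over basal is nearly proportional to A.

Everything downstream — trigger-flux ratios, L-type share, zero-Na
reductions, local/sub-sarcolemmal observables — is *predicted*, not
fitted.

## Observables

Trigger fluxes are central-difference d[Ca²⁺]/dt maxima on the 0.5 ms
output grid (no smoothing; the first 1 ms after the step is excluded to
skip the clamp discontinuity). NCX aggregates evaluate the full
exchanger equation (including Allo) at mask-averaged Ca²⁺ — the
compartment mean for I_NCXglobal, the sub-sarcolemmal shell mean for
I_NCXsarc; with the lineage constants this Allo-weighted evaluation is
the only reading that reproduces the reported whole-cell magnitudes
(the bare electrochemical term is ~4–5× larger and *decreases* with
Ca²⁺, so it cannot make the sub-sarcolemmal aggregate exceed the global
one). Cross-scenario comparisons use the experimental normalization:
L-type flux and global trigger flux are each normalized by their 0 mV
maxima, making the L-type "share" at +50 mV the ratio of normalized
maxima. Line-scan images are raw kymographs along the scan line with no
optical blurring or photon noise.

## Problem sizes

Default working resolutions are a deliberate accuracy/cost trade-off of
this package: 40 nm voxels for geometry calibration and morphometrics
(seconds), 80 nm voxels / Δt 0.5 ms for the production scenario matrix
(~550 k voxels at 40 nm vs ~53 k at 80 nm; a 200 ms clamp run costs
roughly a minute at 80 nm), and 100 nm for the heavier end-to-end tests.
The refinement suite bounds the resolution sensitivity of the global
transient at the few-percent level, which is small against the ±15 %
bands used for simulation-derived comparisons.

## What the synthetic geometry does and does not capture

The generator reproduces the printed morphometrics (volume, areas,
tubule caliber, constriction statistics) and the qualitative features
that drive local signaling: a high surface-to-volume sub-sarcolemmal
shell, a constricted tubule lumen with restricted clearance, and an
undulating outer surface with excess area. It does not reproduce the
actual confocal surface: the relief is periodic rather than irregular,
the tubule is straight and unbranched, and the line-scan column sits in
an artificial local basin of the relief (the relief zero is anchored
there), which makes the 1.5 µm scan-line spot more surface-proximal
than a mid-myoplasm point in the real cell. Consequently, quantities
tied to fine surface texture (local probe derivatives, sub-sarcolemmal
averages) carry geometry-surrogate uncertainty beyond the solver's
numerical error — this is why simulation-derived comparisons use ±15 %
bands and why probe-level magnitudes should be read as order-of-scale,
while conservation properties, reversal potentials, refinement bounds
and the calibrated global transients are tight.

## Known limitations

* No SR release (RyR), SERCA, Na⁺/K⁺ dynamics, action-potential drive,
  or mitochondrial fluxes — voltage-clamp, SR-disabled conditions only.
* LCC has no gating kinetics or Ca²⁺-dependent inactivation feedback;
  the waveform is prescribed per voltage.
* NCX is continuous (no exchanger clustering); its supplementary-level
  constants in the source model are not recoverable, so the lineage
  defaults above are used and config-exposed.
* One compartment represents the whole t-system: all repeating units
  are implicitly identical, and inter-tubule coupling is absent.
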