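# ttflux

Spatial Ca²⁺ trigger-flux simulation in a cardiac t-tubule microdomain
with the sarcoplasmic reticulum disabled.

`ttflux` is for cardiac electrophysiologists and modelers who want to
rerun, at desk scale, voltage-clamp experiments on the Ca²⁺ *trigger
flux* — the sarcolemmal Ca²⁺ entry that would gate SR release in an
intact rabbit ventricular myocyte — and ask how it is shaped by t-tubule
micro-anatomy, L-type channel (LCC) clustering, and allosteric
activation of the Na⁺/Ca²⁺ exchanger (NCX).

## Model

One repeating unit of the t-system is simulated: a half-sarcomere box
(2.34 × 2.58 × 5.76 µm) with a single constricted t-tubule (~4.6 µm
long, elliptical cross-section) and an undulating outer sarcolemma,
generated synthetically and calibrated so its morphometrics match the
published unit (volume 0.0282 pL, membrane areas 7.8 / 8.1 µm²). On
this domain the package integrates the reaction–diffusion system

    ∂[Ca]/∂t = D_Ca ∇²[Ca] − Σ_b R_b + J_mem,
    ∂[CaB_b]/∂t = D_b ∇²[CaB_b] + R_b,
    R_b = k_on,b [Ca] (B_tot,b − [CaB_b]) − k_off,b [CaB_b],

with four buffers (Fluo-3, ATP, calmodulin mobile; TnC stationary and
excluded from the 40–50 nm sub-sarcolemmal shell), reflective outer
boundaries, and membrane fluxes applied on labeled boundary faces:

* **LCC** — prescribed whole-cell waveform
  `J(t) = A(1−e^(−t/τ_act))·e^(−t/τ_inact)` per step potential, 9×
  denser in the t-tubule membrane, either continuous or concentrated in
  three ~200 nm clusters;
* **NCX** — Weber-type `J = V_max · Allo · ΔE` with Hill allosteric
  activation `Allo = 1/(1+(K_mCaAct/[Ca])²)`, K_mCaAct = 0.29 µM,
  V_max = 0.207 µM/ms, 3× denser in the t-tubule, sensing local
  sub-membrane Ca²⁺;
* **pump/leak** — Hill-type ATPase and a voltage-dependent background
  leak solved so basal conditions are a steady state at the −50 mV hold.

Whole-cell current densities convert to volumetric fluxes via
C_m/V_cell = 4.54 pF/pL. The voltage-clamp protocol steps from −50 mV
to 0 or +50 mV for 200 ms; LCC amplitudes are calibrated so the global
transient converges to the measured plateaus (0.19 / 0.20 µM), and
everything else — trigger-flux ratios, zero-Na effects, local and
sub-sarcolemmal signals — is prediction. See `docs/methods.md` for the
numerics and parameter provenance.

## Worked example

```python
from ttflux import (ExperimentContext, Scenario, calibrate_lcc,
                    run_scenario, measure_morphometrics)

ctx = ExperimentContext(voxel_size=0.08)      # 80 nm production grid
ctx.calibrate_geometry()                      # printed morphometrics
ctx.calibrate_leak()                          # basal rest balance
m = measure_morphometrics(ctx.build().grid)
print(f"volume {m.volume:.4f} pL, areas {m.area_ttubule:.2f}/{m.area_outer:.2f} um2")

calibrate_lcc(ctx)                            # plateau anchors, ~6 runs
r = run_scenario(ctx, Scenario("0mV_Na10_allo", step_V=0.0))
s = r["summary"]
print(f"plateau {s['plateau_uM']:.3f} uM")
print(f"global trigger {s['global_trigger_uM_per_s']:.2f} uM/s "
      f"at {s['global_trigger_t_ms']:.0f} ms")
print(f"NCX global mean {s['ncx_global_mean_uM_per_s']:.1f} uM/s")
```

prints (each 200 ms clamp run takes a couple of minutes at 80 nm):

```
volume 0.0282 pL, areas 7.75/8.07 um2
plateau 0.188 uM
global trigger 3.14 uM/s at 8 ms
NCX global mean 3.6 uM/s
```

The plateau is the calibration anchor (measured: 0.19 µM); the global
trigger flux d[Ca]/dt_max and the exchanger aggregate (~3 µM/s reverse
mode at 0 mV) are model outputs. Local probes sit at the tubule mouth
and beside the deepest LCC cluster; `run_scenario(..., outdir=...)`
writes the full per-probe series, line-scan kymograph, config snapshot
and summary JSON.

The same pipeline is scriptable from the shell:

```
ttflux geometry --resolution 0.04 --outdir out/geom
ttflux run --scenario 0mV_Na10_allo --scenario 50mV_Na10_allo --outdir out/runs
ttflux report --results out/runs/results.json
```

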