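# slowwave

A whole-hemisphere thalamocortical network model of sleep slow oscillations,
with the analysis suite used to characterize them.

During non-REM sleep the cortex alternates at < 1 Hz between silent (Down)
and active (Up) states — the slow oscillation (SO).  How far each Up state
spreads (global "Type I" waves vs local "Type II" waves) depends on the
pattern of cortico-cortical connectivity.  `slowwave` is a simulator for
studying exactly that: map-based spiking cortical columns are placed on an
icosphere hemisphere, wired by a distance-dependent generative connectome,
switched between wake and sleep parameter sets, and systematically
manipulated (connection density, maximum radius, conduction delay, synaptic
strength) while the resulting slow waves are detected, tracked and compared.

It is written for computational neuroscientists who want a self-contained,
data-free reimplementation of this class of model: no imaging or clinical
data is required (built-in generators emulate the cortical geometry,
parcellation, myelination gradient and connectivity statistics), but real
meshes, parcel tables, hierarchy tables, residual connectivity matrices and
recording-sparsity masks can be dropped in.

## The model in brief

* **Columns.** One cortical column per mesh vertex (`10·4^L + 2` vertices at
  icosphere level `L`; level 5 gives the full 10,242-column hemisphere, 870
  of them masked as medial wall).  Each column holds one excitatory (PY) and
  one inhibitory (IN) cell in each of six layers, modeled as discrete-time
  maps stepped every 0.5 ms (`V = 50x − 15` mV).  A four-variable PY map
  carries fast spiking (`x`), slow ion-channel drive (`y`), spike-triggered
  adaptation (`u`, the Up-state terminator) and input sensitivity (`k`).
* **Connectome.** Fiber length is a rational map of geodesic distance,
  `F(x) = (p₁x + p₂)/(x + q₁)`; connection probability decays as
  `β·e^(−F/λ)` with λ = 23.4 mm, β = 0.17.  Connections are classed
  feedforward/feedback by a parcel hierarchy gradient, delayed
  proportionally to fiber length (40 ms at 226.1 mm), and normalized so
  each neuron's synaptic budget is invariant under ablation-with-
  compensation.  Local inhibition, a canonical within-column circuit, and
  optional core/matrix thalamus complete the wiring.
* **States.** Wake→sleep switches a small parameter set (PY leak `p_L`
  0.15→0.5, adaptation `p_D` 1.6→4.0, stronger AMPA/GABA, retuned thalamic
  K⁺ leak).  Asleep, miniature synaptic events nucleate Up states that
  propagate as traveling waves and collapse under adaptation.
* **Analysis.** Up-state detection on the layer-2 LFP, per-cell Up/Down
  thresholding with merge/remove refinement, onset/offset latency maps,
  participation, wave-origin and propagation-speed estimation, per-parcel
  regularity (inverse approximate entropy), intact score, and a coherence
  pipeline (resonator filterbank → Hilbert → magnitude-squared coherence →
  exponential distance fits λ/α → percent-connected and Louvain community
  count).

See `docs/methods.md` for the full model description, the interpretation
decisions behind it, and its limitations.

## Worked example

```python
import numpy as np
from slowwave.fixtures import mini_hemisphere
from slowwave.engine import RunConfig, record_lfp, run
from slowwave import so

# scaled-down study network: ico3 hemisphere, full-size geometry,
# synthetic exponential connectome, thalamus detached
mesh, conn = mini_hemisphere(level=3, n_parcels=60, seed=0)

r = run(conn, mesh, RunConfig(duration_s=60.0, seed=3, state="sleep",
                              thalamus_on=False))

cat = so.detect_global_up_states(record_lfp(r, mesh))
cat = so.onsets_offsets(cat, r.v_l2, r.mean_v_l2, r.record_stride)
cat = so.summarize(cat, mesh, r.active_columns)
print(f"events={cat.n_events}  f={cat.frequency_hz:.3f} Hz  "
      f"amp={cat.mean_amplitude:.0f}  part={cat.mean_participation:.1f}%")
print(f"onset std={cat.onset_std_ms:.0f} ms  offset std={cat.offset_std_ms:.0f} ms  "
      f"speed={cat.mean_speed_mm_s:.0f} mm/s")
```

prints

```
events=8  f=0.247 Hz  amp=421  part=100.0%
onset std=65 ms  offset std=183 ms  speed=853 mm/s
```

i.e. eight global slow waves in a minute (~0.25 Hz), each recruiting every
active column, with Up-state onsets far more synchronous than offsets and a
propagation speed under 1 m/s.  The same network with `state="wake"` fires
tonically and irregularly at ~16 Hz with a voltage mode near −60 mV and a
1/f-shaped spectrum.

A command-line interface wraps the same functionality:

```bash
slowwave build-mesh --level 3 --out mesh/
slowwave simulate --state sleep --duration 60 --seed 7 --out rundir/
slowwave analyze-so rundir/ --out so_report/
slowwave run-scenario --name density_P --p 0.5 --out out/
slowwave generate-fixture --kind synthetic_coherence_field --out fixtures/
```

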