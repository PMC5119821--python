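# fibroslab

Discrete 3D slab model of cardiac tissue with diffuse microfibrosis
near the percolation threshold.

## What this is for

Atrial tissue is thin (0.5–3 mm) and often structurally heterogeneous:
fibrosis disrupts cell-to-cell coupling at the 100 μm scale
("microfibrosis"). When the fraction ϕ of broken connections approaches
the percolation threshold ϕ_c of the remaining conducting network, a
*single* passing wave can fragment inside the fibrotic maze, reenter,
and turn the region into an ectopic pacemaker that fires into the
surrounding tissue — no premature beats or fast pacing required. This
package is a laboratory for that mechanism in thin 3D slabs: it
simulates wave propagation through partially disconnected lattices,
classifies the outcome (no reentry / non-sustained / confined activity /
global reentry), estimates percolation thresholds ϕ_c(N) as a function
of slab thickness N, and synthesizes unipolar electrograms whose
fractionated, low-amplitude waveforms over fibrotic tissue mirror
clinical CFAE recordings.

It is intended for computational electrophysiologists who want a fast,
fully reproducible, deliberately minimal model — not an anatomically
realistic simulator.

## Model in brief

Membrane kinetics are the three-variable Fenton–Karma model (fast
inward, slow outward, slow inward currents; gates v, w; Heaviside
switches at V_c and V_v), with the excitability parameter τ_d acting as
the remodeling dial. Tissue is a cubic lattice (ℓ = 100 μm) evolving

    dV_i/dt = −(I_fi + I_so + I_si) + ξ Σ_j η_ij (V_j − V_i),  ξ = D/ℓ²

with D = 1 cm²/s, Δt = 0.0165 ms, explicit midpoint (RK2) integration,
no-flux boundaries. Microfibrosis removes each link inside a cylinder
of radius R0 with probability ϕ (linear decay across a border of width
W); the region is optionally remodeled (τ_d° > 0.25 ms). See
`docs/methods.md` for every definition and numerical choice.

## Worked example

Calibrate the three remodeling levels on a homogeneous 8 cm cable:

```text
$ fibroslab calibrate
tau_d (ms)   APD (ms)  CV (cm/s)    WL (cm)
      0.25      135.2       46.0       6.22
      0.30      121.5       40.4       4.91
      0.35       78.0       35.7       2.78
```

Action potential duration and conduction velocity both fall as τ_d
grows — shorter, slower waves, i.e. progressive electrical remodeling;
the wavelength WL = CV·APD drops from 6.2 cm to 2.8 cm, which is what
lets reentrant circuits fit inside a centimeter-scale fibrotic region.

Estimate the monolayer percolation threshold (the exact square-lattice
bond value is 1/2):

```text
$ fibroslab percolation --size 400 -n 1 --phi-min 0.46 --phi-max 0.54 \
      --phi-step 0.01 --n-real 100 --seed 41
N=1: phi_c = 0.4999 +- 0.0004
```

Run one microfibrosis realization just below ϕ_c on a 2.4 cm, 5-layer
slab (a reduced-scale version of the published showcase):

```python
from fibroslab import (FibrosisSpec, LatticeGeometry, SimulationConfig,
                       classify_outcome, ectopic_cycle_length, run_simulation)

geom = LatticeGeometry(nx=240, ny=240, n_layers=5)
fib = FibrosisSpec(phi=0.70, R0=0.84, border_width=0.2,
                   tau_d_core=0.30, seed=876514893)
hist = run_simulation(SimulationConfig(geom=geom, fibrosis=fib, t_end=500.0))
print(classify_outcome(hist, fib).value)            # -> reentry
print(f"{hist.last_activity_time:.0f}")             # -> 500  (active until t_end)
print(f"{ectopic_cycle_length(hist):.0f}")          # -> 202  (ms per ectopic beat)
```

The wave crosses the slab in ~60 ms, fragments inside the fibrotic
cylinder, and from ~300 ms onward the region re-excites the whole slab
— a confined microreentry acting as an ectopic pacemaker with a cycle
length of roughly 200 ms. With other
seeds the same ϕ produces confined activity or nothing: outcomes near
ϕ_c are genuinely probabilistic, which is why the `sweep` command
estimates probabilities over many link-field realizations with exact
binomial confidence intervals.

## Layout

| module | contents |
|---|---|
| `fibroslab.model` | membrane model, parameters, pointwise RK2 step |
| `fibroslab.lattice` | slab geometry, link removal, τ_d maps, HDF5 I/O |
| `fibroslab.percolation` | spanning tests, ϕ_c estimation |
| `fibroslab.simulation` | coupled time stepping (numba kernel), activation recording |
| `fibroslab.activation` | detectors, APD/CV calibration, outcome taxonomy |
| `fibroslab.electrogram` | unipolar EG synthesis, amplitudes |
| `fibroslab.experiments` | seeded probability sweeps, binomial CIs |
| `fibroslab.cli` | `fibroslab` command (`calibrate`, `percolation`, `run`, `sweep`, `egm`) |
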