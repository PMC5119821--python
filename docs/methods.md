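# Methods

## Model

### Membrane kinetics

Each lattice node carries the three-variable (Fenton–Karma) membrane
model: a normalized transmembrane potential `V` (rest ≈ 0, plateau ≈ 1)
driven by three phenomenological currents,

    dV/dt = −(I_fi + I_so + I_si) + coupling

    I_fi = −v · θ(V−V_c) · (V−V_c)(1−V) / τ_d
    I_so =  V · (1−θ(V−V_c)) / τ_o + θ(V−V_c) / τ_r
    I_si = −w · (1 + tanh(k(V−V_c_si))) / (2 τ_si)

with gates

    dv/dt = (1−p)(1−v)/τ_v⁻(V) − p·v/τ_v⁺,   τ_v⁻(V) = (1−q)τ_v1⁻ + q·τ_v2⁻
    dw/dt = (1−p)(1−w)/τ_w⁻      − p·w/τ_w⁺

where `p = θ(V−V_c)`, `q = θ(V−V_v)`. The Heaviside convention is
`θ(0) = 1` (a measure-zero choice, fixed for reproducibility). Defaults
(`FKParameters`): τ_v⁺ = 3.33 ms, τ_v1⁻ = 19.6 ms, τ_v2⁻ = 1000 ms,
τ_w⁺ = 667 ms, τ_w⁻ = 11 ms, τ_o = 8.3 ms, τ_r = 50 ms, τ_si = 45 ms,
k = 10, V_c_si = 0.85, V_c = 0.13, V_v = 0.055.

The single dial `τ_d` (activation time of the fast inward current)
emulates electrical remodeling. On a homogeneous cable the package
measures:

| τ_d (ms) | APD (ms) | CV (cm/s) | WL (cm) | remodeling |
|---------:|---------:|----------:|--------:|------------|
| 0.25 | 135.2 | 46.0 | 6.2 | normal |
| 0.30 | 121.5 | 40.4 | 4.9 | intermediate |
| 0.35 | 78.0 | 35.7 | 2.8 | strong |

(Values printed by `fibroslab calibrate`; the widely used reference
values for this parameter set are APD 135/120/76 ms and CV 44/39/34
cm/s — our APDs match closely, our CVs sit ≈ 4% above, within the
calibration tolerance we accept, ±7 ms / ±2 cm/s.)

Note that `τ_d` has almost no effect on the APD of an *uncoupled* cell
stimulated instantaneously — it only scales the upstroke current, which
an instantaneous reset bypasses. The remodeling effect on APD is a
tissue property and is therefore calibrated on a propagating cable.

### Discrete tissue and microfibrosis

Tissue is a cubic lattice (spacing ℓ = 100 μm; `nx × ny` nodes per
layer, `N` layers) with nearest-neighbor coupling

    dV_i/dt = −ΣI + ξ Σ_j η_ij (V_j − V_i),    ξ = D/ℓ²

with D = 1 cm²/s (ξ = 10/ms). Link flags η_ij ∈ {0, 1} encode
microfibrosis: inside a cylinder of radius R0 (axis along the
thickness, centered in-plane) each link is removed independently with
probability ϕ; across an optional border zone of width W the removal
probability decays linearly to zero. Eligibility is decided by the
*link midpoint* radius (unambiguous for links straddling the boundary);
vertical links are removed at the same rate as in-plane links
(isotropic model). Nodes at radius ≤ R0 + W carry the remodeled
excitability `τ_d°` ∈ {0.25, 0.30, 0.35} ms; the rest of the slab keeps
τ_d = 0.25 ms. Absent links across the domain faces realize no-flux
boundaries.

Defaults that the published experiments fix: W = 0.2 cm (the border
exists but its width/profile is not published; linear decay over 2 mm
is this package's choice, exposed in `FibrosisSpec`), domain 4×4 cm for
probability grids, 7×7 cm for showcase runs, R0 = 1.4 cm, monitoring
time 1500 ms.

### Protocol

Each run applies a single stimulus at t = 0 — a quarter-disc of radius
0.2 cm at a corner, through all layers, set to V = 1 with gates
untouched (size/amplitude are not published; this choice robustly
launches exactly one wave) — and integrates to `t_end`.

## Numerics

* Explicit midpoint (RK2) in time, Δt = 0.0165 ms; reaction and
  diffusion advance together in both stages (method of lines, no
  splitting); gates receive no diffusion. Heun's variant agrees with
  the midpoint rule to < 0.5% in APD (tested); midpoint is the default.
* Stability: 6·ξ·Δt ≈ 0.99 at the defaults; configurations at or above
  1 are rejected.
* Convergence: halving Δt changes the cable APD by < 0.5%; halving ℓ
  (with ξ rescaled) changes CV by ≈ 0.3%.
* The production kernel (`_kernel.py`, numba) evaluates the slow-inward
  `tanh` from an 8193-knot lookup table over [−16, 16] with linear
  interpolation (absolute error < 2·10⁻⁶, far below the O(Δt²)
  truncation error); the numpy reference path (`model.py`) uses the
  exact `tanh`, and a test pins the two paths together at 5·10⁻⁶.
* Runs are bit-reproducible for a given configuration and seed within
  one build of the package.
* Early termination: once every node satisfies V < 5·10⁻³ the slab can
  never re-activate (there are no further stimuli), so integration
  stops and the quiescence time is recorded.

## Activation analysis

* Activation = upward crossing of V* = 0.13 (= V_c, the model's
  depolarization switch) with a 50 ms dead time (well below the
  shortest APD of 76 ms); crossing times are interpolated linearly
  inside a step. First/second/last activation maps are accumulated at
  native Δt resolution, so classification is independent of any
  snapshot cadence.
* APD convention: time spent above V = 0.5 (mid-amplitude of the
  normalized AP) at a mid-cable node. A low fixed threshold such as
  V = 0.1 gives durations ≈ 20 ms longer and does not reproduce the
  reference remodeling table; the mid-amplitude convention does, and is
  fixed package-wide.
* CV: activation-time difference between two cable probes ≥ 2 cm apart
  in the cable interior.
* Outcome taxonomy (operational definitions — the published taxonomy is
  qualitative):
  * **reentry** — ≥ 1 second activation outside the fibrotic region
    (in-plane radius > R0 + W) *and* at least one activation event in
    the final 100 ms window before `t_end`;
  * **activity** — sustained (same window) but every re-activation
    stays inside R0 + W;
  * **non_sustained** — re-activations occurred but the slab was fully
    quiescent before `t_end`;
  * **no_reentry** — otherwise (including failure of the stimulus to
    propagate).
* Ectopic cycle length, two estimators: (i) `pacing_cycle_length` —
  median inter-activation interval at edge probes far outside the
  region (≥ 3 events required, else undefined); (ii)
  `ectopic_cycle_length` — median over all nodes with ≥ 3 activations
  of the mean re-activation interval (last − second)/(count − 2),
  computed from the activation maps. The two agree for long runs with
  1:1 conduction; the map-based estimator also works when the monitored
  window ends before the rhythm has reached distant probes three times
  (e.g. 500 ms windows, where the source has completed 2–3 cycles but
  distant tissue has only seen the first ectopic beat).

## Percolation

Spanning = existence of a conducting path between the faces x = 0 and
x = L (face adjacency only), decided by connected-component labeling of
the conducting-link graph; an exhaustive DFS oracle cross-checks it on
small lattices. ϕ_c is the midpoint of a logistic sigmoid fitted to the
spanning probability over a ϕ grid (n realizations per point, binomial
weights); grids that do not straddle the transition are rejected. The
monolayer estimate at 4×4 cm reproduces the exact square-lattice bond
threshold 1/2 to ±0.01; thick slabs approach the simple-cubic bond
value ≈ 0.7512 from below.

## Electrograms

Unipolar EG at electrode position r_e, 0.01 cm above the top surface by
default:

    EG(t) = A Σ_i c_i(t) / |r_i − r_e| · ℓ³,   A = 1 (arbitrary units)

where c_i is the *same* discrete coupling operator used by the
simulation — removed links contribute no current, which is what makes
EG amplitude fall roughly linearly with ϕ and makes traces above the
fibrotic region weak and fractionated (CFAE-like). The whole tissue
volume is summed (all layers). Electrodes closer than ℓ/2 to a node are
rejected rather than regularized.

## Experiment grids

Sweeps over (ϕ, τ_d°, N, R0) tally the four outcomes per cell with
exact Clopper–Pearson binomial confidence intervals. Per-realization
seeds derive from `SeedSequence(base_seed, spawn_key=(cell,
realization))`, making every realization independently reproducible and
sweeps resumable and order-independent; published probabilities with
n = 100 carry ±5–10% sampling error, so comparisons are CI-overlap
tests.

## Test problem sizes

The test suite runs the full physics at reduced sizes chosen once:

* calibration cables at the published 8 cm / Δt / ℓ (exact conditions);
* percolation: the monolayer check at the published 400×400×1 with 100
  realizations per ϕ; the thickness trend at 100×100×N with 40;
* regime checks on 2×2 cm, N = 3, R0 = 0.7 cm;
* probability experiments on reduced domains that preserve the
  published R0:width ratio of 0.35 — 2.4 cm/R0 = 0.84 (N = 5),
  1.6 cm/R0 = 0.56 (N = 10), 1.2 cm/R0 = 0.42 (N = 20) — with 1–2
  realizations per cell and 500–1000 ms of monitoring.

What the reduction preserves: the wavelength-to-region-size physics of
microreentry (region diameters stay above the ≈ 1 cm minimum for
reentry), the relation of ϕ to ϕ_c, and every numerical parameter.
What it does not: the published probabilities themselves are defined at
4×4 cm with n = 100; at 1–2 realizations a binomial CI-overlap check
has very little statistical power (with n = 1 it cannot fail, and with
n = 2 it only fails when no realization reenters), so these tests
demonstrate the mechanism and the pipeline rather than re-estimating
the probabilities. The `fibroslab sweep` CLI runs the full published
grids when given the time (hours to days on one core).

Synthetic data in unit tests (rectangular AP pulses, hand-built
activation maps) exercise detectors and classifiers against known
answers; they do not emulate tissue noise, pacing variability or
anatomical geometry, so passing them says nothing about physiological
realism beyond the model's own assumptions (isotropy, monodomain, three
currents, cubic lattice).

## Known limitations

* No anisotropy, no realistic atrial/ventricular anatomy, no
  myocyte–fibroblast coupling, no S1–S2 or fast-pacing protocols — all
  outside this model's scope.
* The cubic lattice's six-neighbor topology sets ϕ_c; denser packings
  (e.g. twelve-neighbor HCP) would shift all ϕ-dependent results upward.
* CV at the default discretization sits ≈ 4% above the reference table
  values; the discrepancy is insensitive to the RK2 variant, Δt and ℓ
  refinement, and is accepted within the calibration tolerance.
* The EG model is a large-volume-conductor approximation with A = 1;
  amplitudes are comparable only within a fixed geometry.
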