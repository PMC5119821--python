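"""Coupled-lattice simulation: discrete monodomain time stepping.

Each node obeys dV_i/dt = −(I_fi + I_so + I_si) + ξ Σ_j η_ij (V_j − V_i),
where the sum runs over the (up to six) nearest neighbors, η_ij ∈ {0, 1}
are the link flags and ξ = D/ℓ² with ℓ the lattice spacing. Gates are not
coupled. A single run applies one corner stimulus at t = 0, integrates to
``t_end`` with an explicit midpoint (RK2) scheme and records activation
events at native dt resolution plus optional voltage snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ._kernel import TANH_TABLE, _simulate
from .lattice import FibrosisSpec, LatticeGeometry, LinkField, build_link_field, build_tau_d_map
from .model import FKParameters

__all__ = [
    "StimulusSpec",
    "SimulationConfig",
    "StateHistory",
    "coupling_term",
    "step_tissue",
    "run_simulation",
]

#: diffusion coefficient, cm^2/s (converted internally to cm^2/ms)
DEFAULT_D = 1.0
ACTIVATION_THRESHOLD = 0.13  # = V_c, the depolarization switch
DEAD_TIME = 50.0  # ms, refractory gap between counted activations
QUIET_THRESHOLD = 5e-3  # whole-slab V below this => quiescent, stop early


@dataclass(frozen=True)
class StimulusSpec:
    """Single corner stimulus: a quarter-disc (through all layers) set to V = 1.

    ``corner`` picks the in-plane corner as a pair of 0/1 flags for
    (x, y); the default (0, 0) is the origin corner.
    """

    corner: Tuple[int, int] = (0, 0)
    radius: float = 0.2  # cm
    time: float = 0.0  # ms

    def mask(self, geom: LatticeGeometry) -> np.ndarray:
        x0 = (geom.nx - 1) * geom.dx * self.corner[0]
        y0 = (geom.ny - 1) * geom.dx * self.corner[1]
        xs = np.arange(geom.nx) * geom.dx - x0
        ys = np.arange(geom.ny) * geom.dx - y0
        in_disc = np.hypot(xs[np.newaxis, :], ys[:, np.newaxis]) <= self.radius
        mask = np.broadcast_to(in_disc, geom.shape)
        if not mask.any():
            raise ValueError("stimulus region is empty")
        return mask


@dataclass
class SimulationConfig:
    """Everything needed to run one realization."""

    geom: LatticeGeometry
    fibrosis: Optional[FibrosisSpec] = None
    params: FKParameters = field(default_factory=FKParameters)
    D: float = DEFAULT_D  # cm^2/s
    dt: float = 0.0165  # ms
    t_end: float = 1500.0  # ms
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    snapshot_every: Optional[float] = None  # ms; None = no movie
    activation_threshold: float = ACTIVATION_THRESHOLD
    dead_time: float = DEAD_TIME
    probes: Sequence[Tuple[int, int, int]] = ()  # (z, y, x) nodes with full event lists
    early_stop: bool = True

    @property
    def xi(self) -> float:
        """Coupling rate ξ = D/ℓ² in 1/ms."""
        return (self.D * 1e-3) / self.geom.dx**2

    def stability_factor(self) -> float:
        """6·ξ·dt; must stay below 1 for the explicit scheme."""
        return 6.0 * self.xi * self.dt

    def validate(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.stability_factor() >= 1.0:
            raise ValueError(
                f"explicit-stability bound violated: 6*xi*dt = "
                f"{self.stability_factor():.3f} >= 1; reduce dt"
            )


@dataclass
class StateHistory:
    """Result of one run: activation maps, probe events, optional movie."""

    config: SimulationConfig
    first_activation: np.ndarray  # (nz, ny, nx), NaN where never activated
    second_activation: np.ndarray
    last_activation: np.ndarray
    activation_count: np.ndarray  # (nz, ny, nx) int32
    final_state: Tuple[np.ndarray, np.ndarray, np.ndarray]
    snapshots: Optional[np.ndarray] = None  # (n_snap, nz, ny, nx) float32
    snapshot_times: Optional[np.ndarray] = None  # ms
    probe_events: dict = field(default_factory=dict)  # (z,y,x) -> sorted times
    quiescent_at: Optional[float] = None  # ms, or None if active at t_end
    t_end: float = 0.0

    @property
    def propagated(self) -> bool:
        """True if any node outside the stimulus region activated."""
        stim = self.config.stimulus.mask(self.config.geom)
        return bool(np.isfinite(self.first_activation[~stim]).any())

    @property
    def last_activity_time(self) -> float:
        la = self.last_activation
        return float(np.nanmax(la)) if np.isfinite(la).any() else float("nan")


def coupling_term(V: np.ndarray, links: LinkField, xi: float) -> np.ndarray:
    """Discrete diffusion operator ξ Σ_j η_ij (V_j − V_i), vectorized.

    The same operator (with the same removed links) is used by the
    electrogram module, so that tissue currents and recorded potentials
    are consistent. Missing boundary neighbors contribute nothing
    (no-flux). The node-sum of the result is zero by antisymmetry.
    """
    if V.shape != links.geom.shape:
        raise ValueError(f"V has shape {V.shape}, expected {links.geom.shape}")
    c = np.zeros_like(V, dtype=float)
    lx = links.lx.astype(float)
    ly = links.ly.astype(float)
    lz = links.lz.astype(float)
    dVx = lx * (V[:, :, 1:] - V[:, :, :-1])
    c[:, :, :-1] += dVx
    c[:, :, 1:] -= dVx
    dVy = ly * (V[:, 1:, :] - V[:, :-1, :])
    c[:, :-1, :] += dVy
    c[:, 1:, :] -= dVy
    dVz = lz * (V[1:, :, :] - V[:-1, :, :])
    c[:-1, :, :] += dVz
    c[1:, :, :] -= dVz
    return xi * c


def _inv_params(params: FKParameters):
    return (
        1.0 / params.tau_v_plus,
        1.0 / params.tau_v1_minus,
        1.0 / params.tau_v2_minus,
        1.0 / params.tau_w_plus,
        1.0 / params.tau_w_minus,
        1.0 / params.tau_o,
        1.0 / params.tau_r,
        1.0 / (2.0 * params.tau_si),
        params.k,
        params.V_c_si,
        params.V_c,
        params.V_v,
    )


def _flat_links(links: LinkField):
    """Pad the forward-link arrays to full node shape (flat, float64).

    Entry i of the padded x-array is the flag of the link i -> i+1; the
    padding slot at the domain face is 0 (no link), realizing no-flux.
    """
    geom = links.geom
    nz, ny, nx = geom.shape
    lx = np.zeros(geom.shape)
    ly = np.zeros(geom.shape)
    lz = np.zeros(geom.shape)
    if nx > 1:
        lx[:, :, : nx - 1] = links.lx
    if ny > 1:
        ly[:, : ny - 1, :] = links.ly
    if nz > 1:
        lz[: nz - 1, :, :] = links.lz
    return lx.ravel(), ly.ravel(), lz.ravel()


def _run_kernel(V, v, w, links, tau_d_map, params, dt, xi, n_steps, *,
                act_thr=ACTIVATION_THRESHOLD, dead_time=DEAD_TIME,
                probe_mask=None, ev_cap=1, snaps=None, snap_every=0,
                quiet_thr=0.0, t0=0.0):
    geom = links.geom
    n = geom.n_nodes
    Vf = np.ascontiguousarray(V, dtype=float).ravel()
    vf = np.ascontiguousarray(v, dtype=float).ravel()
    wf = np.ascontiguousarray(w, dtype=float).ravel()
    bufs = [np.zeros(n) for _ in range(7)]
    lx, ly, lz = _flat_links(links)
    inv_tau_d = 1.0 / np.ascontiguousarray(tau_d_map, dtype=float).ravel()
    first = np.full(n, np.nan)
    second = np.full(n, np.nan)
    last = np.full(n, np.nan)
    count = np.zeros(n, dtype=np.int32)
    if probe_mask is None:
        probe_mask = np.zeros(n, dtype=np.uint8)
    probe_events = np.zeros(ev_cap)
    probe_node = np.zeros(ev_cap, dtype=np.int64)
    if snaps is None:
        snaps = np.empty((0, n), dtype=np.float32)
    steps, quiescent_at, n_ev = _simulate(
        Vf, vf, wf, bufs[0], bufs[1], bufs[2], bufs[3], bufs[4], bufs[5], bufs[6],
        inv_tau_d, lx, ly, lz,
        xi, dt, n_steps, t0,
        *_inv_params(params),
        act_thr, dead_time,
        first, second, last, count,
        probe_mask, probe_events, probe_node, 0,
        snaps, snap_every,
        quiet_thr, TANH_TABLE,
        geom.shape,
    )
    if steps < 0:
        raise FloatingPointError(
            f"non-finite membrane potential at t = {-steps * dt:.4f} ms"
        )
    if steps % 2 == 1:
        final = (bufs[3], bufs[4], bufs[5])
    else:
        final = (Vf, vf, wf)
    return {
        "steps": steps,
        "quiescent_at": quiescent_at,
        "final": tuple(a.reshape(geom.shape) for a in final),
        "first": first,
        "second": second,
        "last": last,
        "count": count,
        "probe_events": probe_events[:n_ev],
        "probe_node": probe_node[:n_ev],
        "snaps": snaps,
    }


def step_tissue(
    V: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    links: LinkField,
    tau_d_map: np.ndarray,
    params: FKParameters,
    dt: float,
    xi: float,
    n_steps: int = 1,
):
    """Advance coupled tissue fields by ``n_steps`` RK2 steps; returns new (V, v, w)."""
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    out = _run_kernel(V, v, w, links, tau_d_map, params, dt, xi, n_steps)
    return out["final"]


def run_simulation(
    config: SimulationConfig,
    links: Optional[LinkField] = None,
    tau_d_map: Optional[np.ndarray] = None,
) -> StateHistory:
    """Run one single-stimulus realization to ``t_end``.

    If ``links``/``tau_d_map`` are not supplied they are generated from
    ``config.fibrosis`` (a missing fibrosis spec means homogeneous
    tissue). Deterministic: identical config and seed give bit-identical
    activation maps. A stimulus that fails to propagate is a labeled
    outcome downstream, not an exception.
    """
    config.validate()
    geom = config.geom
    if links is None:
        if config.fibrosis is not None:
            links = build_link_field(geom, config.fibrosis)
        else:
            from .lattice import uniform_link_field

            links = uniform_link_field(geom, 0.0)
    if tau_d_map is None:
        if config.fibrosis is not None:
            tau_d_map = build_tau_d_map(geom, config.fibrosis)
        else:
            tau_d_map = np.full(geom.shape, config.params.tau_d)

    V = np.zeros(geom.shape)
    v = np.ones(geom.shape)
    w = np.ones(geom.shape)
    V[config.stimulus.mask(geom)] = 1.0

    n = geom.n_nodes
    n_steps = int(round(config.t_end / config.dt))
    snap_every = 0
    snaps = None
    snap_times = None
    if config.snapshot_every is not None:
        snap_every = max(int(round(config.snapshot_every / config.dt)), 1)
        n_snap = n_steps // snap_every
        snaps = np.zeros((n_snap, n), dtype=np.float32)
        snap_times = (np.arange(n_snap) + 1) * snap_every * config.dt

    probes = [tuple(int(c) for c in p) for p in config.probes]
    probe_mask = np.zeros(n, dtype=np.uint8)
    for (z, y, x) in probes:
        probe_mask[(z * geom.ny + y) * geom.nx + x] = 1
    ev_cap = max(len(probes), 1) * (int(config.t_end / config.dead_time) + 4)

    out = _run_kernel(
        V, v, w, links, tau_d_map, config.params, config.dt, config.xi, n_steps,
        act_thr=config.activation_threshold, dead_time=config.dead_time,
        probe_mask=probe_mask, ev_cap=ev_cap,
        snaps=snaps, snap_every=snap_every,
        quiet_thr=QUIET_THRESHOLD if config.early_stop else 0.0,
    )

    shape = geom.shape
    if snaps is not None:
        k_done = out["steps"] // snap_every
        snaps = snaps[:k_done].reshape(k_done, *shape)
        snap_times = snap_times[:k_done]

    probe_dict = {}
    for p in probes:
        idx = (p[0] * geom.ny + p[1]) * geom.nx + p[2]
        sel = out["probe_node"] == idx
        probe_dict[p] = np.sort(out["probe_events"][sel])

    qa = out["quiescent_at"]
    return StateHistory(
        config=config,
        first_activation=out["first"].reshape(shape),
        second_activation=out["second"].reshape(shape),
        last_activation=out["last"].reshape(shape),
        activation_count=out["count"].reshape(shape),
        final_state=out["final"],
        snapshots=snaps,
        snapshot_times=snap_times,
        probe_events=probe_dict,
        quiescent_at=None if qa < 0 else float(qa),
        t_end=config.t_end,
    )
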