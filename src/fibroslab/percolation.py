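"""Spanning connectivity and percolation thresholds of slab lattices.

Removing a fraction ϕ of links eventually disconnects the two lateral
faces of the slab; wave propagation across the slab is impossible above
that point. The percolation threshold ϕ_c(N) is the removed-link
fraction at which the probability of a spanning conducting path drops
through 50%. For a single layer (N = 1) the lattice is the 2D square
lattice whose bond-percolation threshold is exactly 1/2 (duality);
for thick slabs ϕ_c grows towards the simple-cubic bond value ≈ 0.7512.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.csgraph import connected_components

from .lattice import LatticeGeometry, LinkField, uniform_link_field

__all__ = [
    "SpanningResult",
    "ThresholdEstimate",
    "spans",
    "spanning_probability",
    "estimate_threshold",
]


@dataclass(frozen=True)
class SpanningResult:
    """Outcome of one spanning test along x."""

    spans: bool
    cluster_count: int


@dataclass(frozen=True)
class ThresholdEstimate:
    """Fitted percolation threshold for one slab geometry."""

    phi_c: float
    phi_c_stderr: float
    width: float  # logistic width parameter of the fitted sigmoid
    phi_grid: np.ndarray
    p_hat: np.ndarray  # spanning probability per grid point
    n_spanning: np.ndarray
    n_realizations: int

    def __post_init__(self):
        if not 0.0 < self.phi_c < 1.0:
            raise ValueError("phi_c must lie strictly inside (0, 1)")


def _adjacency(links: LinkField) -> sparse.coo_matrix:
    """Sparse undirected adjacency of conducting links (face adjacency only)."""
    geom = links.geom
    nz, ny, nx = geom.shape
    n = geom.n_nodes
    idx = np.arange(n).reshape(geom.shape)
    rows = []
    cols = []
    if nx > 1:
        m = links.lx.astype(bool)
        rows.append(idx[:, :, :-1][m])
        cols.append(idx[:, :, 1:][m])
    if ny > 1:
        m = links.ly.astype(bool)
        rows.append(idx[:, :-1, :][m])
        cols.append(idx[:, 1:, :][m])
    if nz > 1:
        m = links.lz.astype(bool)
        rows.append(idx[:-1, :, :][m])
        cols.append(idx[1:, :, :][m])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.empty(0, dtype=int)
        c = np.empty(0, dtype=int)
    data = np.ones(len(r), dtype=np.int8)
    return sparse.coo_matrix((data, (r, c)), shape=(n, n))


def spans(links: LinkField) -> SpanningResult:
    """Does a conducting path connect the faces x = 0 and x = Lx?

    Connectivity is through face-adjacent nearest neighbors only, via
    connected-component labeling of the conducting-link graph.
    """
    geom = links.geom
    adj = _adjacency(links)
    n_comp, labels = connected_components(adj, directed=False)
    lab = labels.reshape(geom.shape)
    left = np.unique(lab[:, :, 0])
    right = np.unique(lab[:, :, -1])
    return SpanningResult(
        spans=bool(np.intersect1d(left, right, assume_unique=True).size > 0),
        cluster_count=int(n_comp),
    )


def spanning_probability(
    geom: LatticeGeometry,
    phi: float,
    n_real: int,
    rng: np.random.Generator,
) -> tuple:
    """Fraction of random link fields at removal fraction ϕ that span; returns
    (n_spanning, n_real)."""
    n_span = 0
    for _ in range(n_real):
        if spans(uniform_link_field(geom, phi, rng=rng)).spans:
            n_span += 1
    return n_span, n_real


def _logistic(phi, phi_c, width):
    return 1.0 / (1.0 + np.exp((phi - phi_c) / width))


def estimate_threshold(
    geom: LatticeGeometry,
    phi_grid: Sequence[float],
    n_real: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ThresholdEstimate:
    """Estimate ϕ_c from the spanning-probability curve on a ϕ grid.

    ``n_real`` independent link fields are drawn per ϕ; a logistic
    sigmoid is fitted to the empirical spanning probabilities and ϕ_c is
    its midpoint (probability 50%). The grid must straddle the
    transition, otherwise the fit is rejected.
    """
    phi_grid = np.asarray(sorted(phi_grid), dtype=float)
    if n_real < 10:
        raise ValueError("n_real must be at least 10")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_span = np.empty(len(phi_grid), dtype=int)
    for i, phi in enumerate(phi_grid):
        n_span[i], _ = spanning_probability(geom, float(phi), n_real, rng)
    p_hat = n_span / n_real

    if len(phi_grid) < 3 or p_hat.max() < 0.5 or p_hat.min() >= 0.5:
        raise ValueError(
            "phi grid does not resolve the spanning transition "
            f"(p_hat spans [{p_hat.min():.2f}, {p_hat.max():.2f}] over "
            f"{len(phi_grid)} grid points); refine the grid around the 50% point"
        )

    # binomial weights; clip to avoid zero-variance points pinning the fit
    sigma = np.sqrt(np.clip(p_hat * (1 - p_hat), 0.25 / n_real, None) / n_real)
    phi0 = float(phi_grid[np.argmin(np.abs(p_hat - 0.5))])
    popt, pcov = optimize.curve_fit(
        _logistic,
        phi_grid,
        p_hat,
        p0=(phi0, 0.02),
        sigma=sigma,
        absolute_sigma=True,
        maxfev=10000,
    )
    stderr = float(np.sqrt(np.diag(pcov))[0])
    return ThresholdEstimate(
        phi_c=float(popt[0]),
        phi_c_stderr=stderr,
        width=float(abs(popt[1])),
        phi_grid=phi_grid,
        p_hat=p_hat,
        n_spanning=n_span,
        n_realizations=n_real,
    )
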