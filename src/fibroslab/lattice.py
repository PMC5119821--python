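"""Cubic slab lattice, random link removal (microfibrosis) and τ_d maps.

Tissue is a regular lattice of excitable nodes with spacing ``dx`` (100 μm
by default), ``nx × ny`` nodes per layer and ``N`` stacked layers. Nearest
neighbors exchange current through conducting links; diffuse microfibrosis
is modeled by removing each link independently with probability ϕ inside a
cylindrical region (axis along the thickness), optionally surrounded by a
border zone where the removal probability decays linearly to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LatticeGeometry",
    "FibrosisSpec",
    "LinkField",
    "build_link_field",
    "uniform_link_field",
    "build_tau_d_map",
    "node_radius",
    "save_link_field",
    "load_link_field",
]


@dataclass(frozen=True)
class LatticeGeometry:
    """Node counts and spacing of the slab lattice.

    ``nx``/``ny`` are in-plane node counts, ``n_layers`` the slab thickness
    in layers (100 μm per layer at the default spacing).
    """

    nx: int
    ny: int
    n_layers: int = 1
    dx: float = 0.01  # cm (100 um)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_layers) < 1:
            raise ValueError("nx, ny and n_layers must all be >= 1")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self):
        """Array shape (n_layers, ny, nx); x is the fastest axis."""
        return (self.n_layers, self.ny, self.nx)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny * self.n_layers

    @property
    def size_cm(self):
        return (self.nx * self.dx, self.ny * self.dx, self.n_layers * self.dx)

    @property
    def center_cm(self):
        """In-plane coordinates of the domain center (cylinder axis)."""
        return ((self.nx - 1) / 2.0 * self.dx, (self.ny - 1) / 2.0 * self.dx)


@dataclass(frozen=True)
class FibrosisSpec:
    """Geometry and statistics of the cylindrical microfibrotic region.

    ``phi`` is the link-removal probability inside the cylinder of radius
    ``R0``; over the border zone of width ``W`` the probability decays
    linearly to zero. ``tau_d_core`` is the excitability parameter assigned
    to nodes inside the region (core plus border), emulating electrical
    remodeling of fibrotic tissue; healthy tissue keeps ``tau_d_outside``.
    """

    phi: float
    R0: float  # cm
    border_width: float = 0.2  # cm
    tau_d_core: float = 0.25  # ms
    tau_d_outside: float = 0.25  # ms
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.R0 < 0 or self.border_width < 0:
            raise ValueError("R0 and border_width must be non-negative")

    @property
    def outer_radius(self) -> float:
        return self.R0 + self.border_width


@dataclass
class LinkField:
    """Conducting/removed flags for every nearest-neighbor link.

    One flag per undirected link, stored per forward direction:
    ``lx[z, y, x]`` joins node (x, y, z) to (x+1, y, z), and likewise for
    ``ly`` and ``lz``. 1 = conducting, 0 = removed. Links across the domain
    boundary do not exist, which realizes no-flux boundaries.
    """

    geom: LatticeGeometry
    lx: np.ndarray  # (nz, ny, nx-1) uint8
    ly: np.ndarray  # (nz, ny-1, nx) uint8
    lz: np.ndarray  # (nz-1, ny, nx) uint8

    def __post_init__(self) -> None:
        nz, ny, nx = self.geom.shape
        expect = {
            "lx": (nz, ny, max(nx - 1, 0)),
            "ly": (nz, max(ny - 1, 0), nx),
            "lz": (max(nz - 1, 0), ny, nx),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    @property
    def n_links(self) -> int:
        return self.lx.size + self.ly.size + self.lz.size

    @property
    def n_removed(self) -> int:
        return self.n_links - int(self.lx.sum()) - int(self.ly.sum()) - int(self.lz.sum())

    def copy(self) -> "LinkField":
        return LinkField(self.geom, self.lx.copy(), self.ly.copy(), self.lz.copy())


def _link_midpoints_radius(geom: LatticeGeometry, axis: str) -> np.ndarray:
    """In-plane radius (cm) of every link midpoint from the cylinder axis."""
    cx, cy = geom.center_cm
    nz, ny, nx = geom.shape
    if axis == "x":
        xs = (np.arange(nx - 1) + 0.5) * geom.dx - cx
        ys = np.arange(ny) * geom.dx - cy
    elif axis == "y":
        xs = np.arange(nx) * geom.dx - cx
        ys = (np.arange(ny - 1) + 0.5) * geom.dx - cy
    else:  # vertical links share the in-plane position of their endpoints
        xs = np.arange(nx) * geom.dx - cx
        ys = np.arange(ny) * geom.dx - cy
    return np.hypot(xs[np.newaxis, :], ys[:, np.newaxis])


def removal_probability(r: np.ndarray, spec: FibrosisSpec) -> np.ndarray:
    """Removal probability p(r): ϕ in the core, linear decay across the border."""
    r = np.asarray(r, dtype=float)
    p = np.zeros_like(r)
    p[r <= spec.R0] = spec.phi
    if spec.border_width > 0:
        in_border = (r > spec.R0) & (r <= spec.outer_radius)
        p[in_border] = spec.phi * (1.0 - (r[in_border] - spec.R0) / spec.border_width)
    return p


def build_link_field(
    geom: LatticeGeometry,
    spec: FibrosisSpec,
    rng: Optional[np.random.Generator] = None,
) -> LinkField:
    """Draw the random link field of a cylindrical microfibrotic region.

    Each link whose midpoint lies at in-plane radius r from the domain
    center is removed independently with probability p(r). Vertical links
    are treated exactly like in-plane ones (isotropic removal). The same
    seed reproduces the field bit for bit.
    """
    half_width = min(geom.size_cm[0], geom.size_cm[1]) / 2.0
    if spec.outer_radius > half_width:
        raise ValueError(
            f"fibrotic region (R0+W = {spec.outer_radius:g} cm) exceeds the "
            f"domain half-width ({half_width:g} cm)"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nz, ny, nx = geom.shape
    out = {}
    for axis, shape in (("x", (nz, ny, nx - 1)), ("y", (nz, ny - 1, nx)), ("z", (nz - 1, ny, nx))):
        shape = tuple(max(s, 0) for s in shape)
        r = _link_midpoints_radius(geom, axis)
        p = removal_probability(r, spec)[np.newaxis, :, :]
        u = rng.random(shape)
        out[axis] = (u >= p).astype(np.uint8)
    return LinkField(geom, out["x"], out["y"], out["z"])


def uniform_link_field(
    geom: LatticeGeometry,
    phi: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> LinkField:
    """Remove every link of the slab independently with probability ϕ.

    This is the whole-domain removal used for percolation-threshold
    studies (no cylindrical confinement).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    nz, ny, nx = geom.shape
    lx = (rng.random((nz, ny, nx - 1)) >= phi).astype(np.uint8)
    ly = (rng.random((nz, ny - 1, nx)) >= phi).astype(np.uint8)
    lz = (rng.random((max(nz - 1, 0), ny, nx)) >= phi).astype(np.uint8)
    return LinkField(geom, lx, ly, lz)


def node_radius(geom: LatticeGeometry) -> np.ndarray:
    """In-plane distance (cm) of every node from the cylinder axis, shape (nz, ny, nx)."""
    cx, cy = geom.center_cm
    xs = np.arange(geom.nx) * geom.dx - cx
    ys = np.arange(geom.ny) * geom.dx - cy
    r2d = np.hypot(xs[np.newaxis, :], ys[:, np.newaxis])
    return np.broadcast_to(r2d, geom.shape).copy()


def build_tau_d_map(geom: LatticeGeometry, spec: FibrosisSpec) -> np.ndarray:
    """Per-node τ_d field: ``tau_d_core`` over the fibrotic region (core plus
    border), ``tau_d_outside`` elsewhere."""
    r = node_radius(geom)
    tau = np.full(geom.shape, spec.tau_d_outside, dtype=float)
    if spec.R0 > 0 or spec.border_width > 0:
        tau[r <= spec.outer_radius] = spec.tau_d_core
    return tau


def save_link_field(path, links: LinkField, spec: Optional[FibrosisSpec] = None,
                    tau_d_map: Optional[np.ndarray] = None) -> None:
    """Store a link field (and optionally the τ_d map) in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("links")
        g.create_dataset("lx", data=links.lx, compression="gzip")
        g.create_dataset("ly", data=links.ly, compression="gzip")
        g.create_dataset("lz", data=links.lz, compression="gzip")
        f.attrs["nx"] = links.geom.nx
        f.attrs["ny"] = links.geom.ny
        f.attrs["n_layers"] = links.geom.n_layers
        f.attrs["dx"] = links.geom.dx
        if tau_d_map is not None:
            f.create_dataset("tau_d_map", data=tau_d_map, compression="gzip")
        if spec is not None:
            f.attrs["phi"] = spec.phi
            f.attrs["R0"] = spec.R0
            f.attrs["border_width"] = spec.border_width
            f.attrs["tau_d_core"] = spec.tau_d_core
            f.attrs["tau_d_outside"] = spec.tau_d_outside
            if spec.seed is not None:
                f.attrs["seed"] = spec.seed


def load_link_field(path):
    """Inverse of :func:`save_link_field`; returns (LinkField, tau_d_map or None)."""
    import h5py

    with h5py.File(path, "r") as f:
        geom = LatticeGeometry(
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
            n_layers=int(f.attrs["n_layers"]), dx=float(f.attrs["dx"]),
        )
        links = LinkField(
            geom,
            f["links/lx"][...].astype(np.uint8),
            f["links/ly"][...].astype(np.uint8),
            f["links/lz"][...].astype(np.uint8),
        )
        tau = f["tau_d_map"][...] if "tau_d_map" in f else None
    return links, tau
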