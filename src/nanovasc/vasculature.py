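"""Vessel network: capillary-grid construction, Poiseuille flow, shear rates.

The network is a graph of nodes (points in the 2-mm field) joined by
cylindrical segments one grid cell long, so every segment maps onto exactly
one or two grid cells of the continuum fields. Pre-existing capillaries form
a regular grid (lines every ``vessel_spacing_mm``); angiogenic neovessels are
appended later by the sprout model with ``origin='neovessel'``.

Blood flow is Poiseuille/Kirchhoff: each segment is a resistor with
conductance ``g = pi R^4 / (8 mu L)``; nodal pressures solve the linear
mass-balance system with fixed inlet/outlet pressures. Wall shear rate per
segment is ``4 |Q| / (pi R^3)``, the quantity that suppresses nanoparticle
adhesion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .grid import GridSpec

__all__ = [
    "VesselNetwork",
    "build_preexisting_grid",
    "solve_flow",
    "shear_rate",
    "FlowError",
]

PREEXISTING = "preexisting"
NEOVESSEL = "neovessel"


class FlowError(RuntimeError):
    pass


def shear_rate(Q: float, R: float) -> float:
    """Wall shear rate 4|Q|/(pi R^3) of Poiseuille flow Q through radius R."""
    if R <= 0:
        raise ValueError(f"radius must be positive, got {R}")
    return 4.0 * abs(Q) / (math.pi * R**3)


@dataclass
class VesselNetwork:
    """Mutable vessel graph with per-node pressures and per-segment flow state.

    Node positions are stored in mm. Grid-aligned networks also carry a
    lattice map (cell-index pair -> node id) used for rasterization onto the
    continuum grid and for anastomosis tests during sprouting.
    """

    grid: GridSpec | None = None
    node_xy_mm: list = field(default_factory=list)          # [(x, y)]
    is_inlet: list = field(default_factory=list)
    is_outlet: list = field(default_factory=list)
    pressure: np.ndarray | None = None
    seg_nodes: list = field(default_factory=list)           # [(a, b)]
    seg_radius_m: list = field(default_factory=list)
    seg_length_m: list = field(default_factory=list)
    seg_origin: list = field(default_factory=list)          # PREEXISTING | NEOVESSEL
    seg_flow: np.ndarray | None = None                      # signed, a -> b, m^3/s
    seg_shear: np.ndarray | None = None                     # 1/s
    seg_hematocrit: np.ndarray | None = None
    seg_radius_eff_m: np.ndarray | None = None              # compressed lumen
    lattice: dict = field(default_factory=dict)             # (i, j) -> node id

    # -- construction ---------------------------------------------------------

    def add_node(self, x_mm: float, y_mm: float, *, inlet: bool = False,
                 outlet: bool = False, lattice_key: tuple | None = None) -> int:
        nid = len(self.node_xy_mm)
        self.node_xy_mm.append((float(x_mm), float(y_mm)))
        self.is_inlet.append(bool(inlet))
        self.is_outlet.append(bool(outlet))
        if lattice_key is not None:
            self.lattice[lattice_key] = nid
        return nid

    def add_segment(self, a: int, b: int, radius_m: float, length_m: float,
                    origin: str = PREEXISTING) -> int:
        if radius_m <= 0 or length_m <= 0:
            raise ValueError("segment radius and length must be positive")
        sid = len(self.seg_nodes)
        self.seg_nodes.append((int(a), int(b)))
        self.seg_radius_m.append(float(radius_m))
        self.seg_length_m.append(float(length_m))
        self.seg_origin.append(origin)
        return sid

    @property
    def n_nodes(self) -> int:
        return len(self.node_xy_mm)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    def surface_area_m2(self) -> np.ndarray:
        """Luminal surface area 2 pi R L per segment."""
        R = np.asarray(self.seg_radius_m)
        L = np.asarray(self.seg_length_m)
        return 2.0 * math.pi * R * L

    def volume_m3(self) -> np.ndarray:
        R = np.asarray(self.seg_radius_m)
        L = np.asarray(self.seg_length_m)
        return math.pi * R**2 * L

    # -- rasterization --------------------------------------------------------

    def segment_cells(self) -> list[tuple[int, int]]:
        """One grid cell (j_row, i_col) per segment: the segment midpoint cell."""
        if self.grid is None:
            raise ValueError("network has no grid attached")
        n = self.grid.n_cells
        h = self.grid.spacing_mm
        out = []
        xy = self.node_xy_mm
        for a, b in self.seg_nodes:
            mx = 0.5 * (xy[a][0] + xy[b][0])
            my = 0.5 * (xy[a][1] + xy[b][1])
            i = min(max(int(mx / h), 0), n - 1)
            j = min(max(int(my / h), 0), n - 1)
            out.append((j, i))
        return out

    def vessel_mask(self) -> np.ndarray:
        """Boolean grid mask of cells containing a vessel segment."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for j, i in self.segment_cells():
            mask[j, i] = True
        return mask

    # -- serialization --------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        xy = np.asarray(self.node_xy_mm).reshape(-1, 2)
        return pd.DataFrame({
            "id": np.arange(self.n_nodes),
            "x_mm": xy[:, 0], "y_mm": xy[:, 1],
            "is_inlet": self.is_inlet, "is_outlet": self.is_outlet,
            "pressure": self.pressure if self.pressure is not None
            else np.full(self.n_nodes, np.nan),
        })

    def segment_table(self) -> pd.DataFrame:
        ab = np.asarray(self.seg_nodes).reshape(-1, 2)
        m = self.n_segments
        return pd.DataFrame({
            "id": np.arange(m),
            "node_a": ab[:, 0], "node_b": ab[:, 1],
            "radius_m": self.seg_radius_m, "length_m": self.seg_length_m,
            "origin": self.seg_origin,
            "flow_m3_s": self.seg_flow if self.seg_flow is not None
            else np.full(m, np.nan),
            "shear_1_s": self.seg_shear if self.seg_shear is not None
            else np.full(m, np.nan),
        })

    def to_json(self) -> str:
        return json.dumps({
            "nodes": self.node_table().to_dict(orient="records"),
            "segments": self.segment_table().to_dict(orient="records"),
        })


def build_preexisting_grid(
    grid: GridSpec,
    vessel_spacing_mm: float = 0.25,
    radius_m: float = 10e-6,
    *,
    inlet_side: str = "left",
) -> VesselNetwork:
    """Regular capillary grid: vessel lines every ``vessel_spacing_mm``.

    Lines run at every multiple of the spacing along both axes (so a 2-mm
    domain with 250-um spacing has 9 horizontal and 9 vertical lines).
    Lines are snapped to the nearest cell-center row/column of the continuum
    grid; interior line-to-line spacing is exact. Left-edge ends of the
    horizontal vessels are inlets and right-edge ends outlets by default
    (configurable via ``inlet_side``), giving the directional perfusion that
    produces inflow-side nanoparticle accumulation.
    """
    ratio = grid.domain_size_mm / vessel_spacing_mm
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"vessel_spacing_mm={vessel_spacing_mm} does not divide "
            f"domain_size_mm={grid.domain_size_mm}"
        )
    if inlet_side not in ("left", "right"):
        raise ValueError("inlet_side must be 'left' or 'right'")
    n = grid.n_cells
    h = grid.spacing_mm
    k_lines = int(round(ratio)) + 1
    # snap each requested line position to the cell whose lower edge is at
    # the position (exact when the spacing is a multiple of the cell size)
    line_idx = []
    for k in range(k_lines):
        idx = int(math.floor(k * vessel_spacing_mm / h + 1e-9))
        line_idx.append(min(max(idx, 0), n - 1))
    line_idx = sorted(set(line_idx))

    net = VesselNetwork(grid=grid)

    def node_at(i: int, j: int) -> int:
        key = (i, j)
        if key in net.lattice:
            return net.lattice[key]
        x = (i + 0.5) * h
        y = (j + 0.5) * h
        inlet = (i == 0) if inlet_side == "left" else (i == n - 1)
        outlet = (i == n - 1) if inlet_side == "left" else (i == 0)
        return net.add_node(x, y, inlet=inlet, outlet=outlet, lattice_key=key)

    seg_len_m = h * 1e-3
    seen = set()

    def seg(i0, j0, i1, j1):
        key = ((i0, j0), (i1, j1))
        if key in seen:
            return
        seen.add(key)
        a = node_at(i0, j0)
        b = node_at(i1, j1)
        net.add_segment(a, b, radius_m, seg_len_m, PREEXISTING)

    for j in line_idx:                      # horizontal lines (constant y)
        for i in range(n - 1):
            seg(i, j, i + 1, j)
    for i in line_idx:                      # vertical lines (constant x)
        for j in range(n - 1):
            seg(i, j, i, j + 1)
    net.line_positions_mm = [(idx + 0.5) * h for idx in line_idx]  # type: ignore[attr-defined]
    net.requested_line_positions_mm = [k * vessel_spacing_mm for k in range(k_lines)]  # type: ignore[attr-defined]
    return net


def compress_tumor_vessels(
    net: VesselNetwork,
    depth: np.ndarray,
    depth_scale: float,
    max_compression: float,
) -> VesselNetwork:
    """Squeeze vessel lumina according to local tumor depth (solid stress).

    ``depth`` is the per-cell distance inside the tumor interface (model
    units, zero outside). The effective radius ramps linearly from the
    anatomical radius at the boundary down to ``(1 - max_compression) * R``
    at ``depth_scale`` and beyond. Only hemodynamics (conductance, shear)
    see the squeezed lumen; since conductance scales as R^4, deep intratumor
    segments lose most of their flow and perfusion reroutes around the
    lesion — the reason systemic nanoparticles reach the tumor mainly
    through its peripheral (neo)vasculature.
    """
    if not (0.0 <= max_compression < 1.0):
        raise ValueError("max_compression must lie in [0, 1)")
    R = np.asarray(net.seg_radius_m)
    scale = np.ones(len(R))
    if depth_scale > 0 and max_compression > 0:
        for s, (j, i) in enumerate(net.segment_cells()):
            f = min(max(depth[j, i], 0.0) / depth_scale, 1.0)
            scale[s] = 1.0 - max_compression * f
    net.seg_radius_eff_m = R * scale
    return net


def solve_flow(
    net: VesselNetwork,
    p_in: float = 1.0,
    p_out: float = 0.0,
    viscosity_pa_s: float = 3e-3,
) -> VesselNetwork:
    """Solve nodal pressures and segment flows (Poiseuille + Kirchhoff).

    Inlet/outlet nodes are Dirichlet (``p_in`` / ``p_out``); every other node
    satisfies mass balance. Dead-end branches carry exactly zero flow. Any
    connected component without a pressure-fixed node makes the system
    singular and raises :class:`FlowError` naming the component.
    """
    N = net.n_nodes
    if N == 0 or net.n_segments == 0:
        raise FlowError("empty network")
    fixed = np.asarray(net.is_inlet, bool) | np.asarray(net.is_outlet, bool)
    if not np.any(net.is_inlet) or not np.any(net.is_outlet):
        raise FlowError("network needs at least one inlet and one outlet")

    ab = np.asarray(net.seg_nodes)
    R = np.asarray(net.seg_radius_m)
    if net.seg_radius_eff_m is not None:
        # solid-stress compression: hemodynamics see the squeezed lumen
        R = np.asarray(net.seg_radius_eff_m)
    L = np.asarray(net.seg_length_m)
    g = math.pi * R**4 / (8.0 * viscosity_pa_s * L)

    adj = sp.coo_matrix(
        (np.ones(len(ab)), (ab[:, 0], ab[:, 1])), shape=(N, N)
    )
    ncomp, labels = connected_components(adj + adj.T, directed=False)
    for c in range(ncomp):
        members = np.where(labels == c)[0]
        if not fixed[members].any():
            raise FlowError(
                f"connected component {c} (nodes {members[:8].tolist()}...) has "
                f"no inlet or outlet; flow system is singular"
            )

    # assemble weighted graph Laplacian
    rows = np.concatenate([ab[:, 0], ab[:, 1], ab[:, 0], ab[:, 1]])
    cols = np.concatenate([ab[:, 1], ab[:, 0], ab[:, 0], ab[:, 1]])
    vals = np.concatenate([-g, -g, g, g])
    K = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))

    p = np.zeros(N)
    p[np.asarray(net.is_inlet, bool)] = p_in
    p[np.asarray(net.is_outlet, bool)] = p_out
    free = ~fixed
    if free.any():
        Kff = K[free][:, free].tocsc()
        rhs = -K[free][:, fixed] @ p[fixed]
        p[free] = spsolve(Kff, rhs)

    Q = g * (p[ab[:, 0]] - p[ab[:, 1]])
    net.pressure = p
    net.seg_flow = Q
    net.seg_shear = 4.0 * np.abs(Q) / (math.pi * R**3)
    return net


def flow_imbalance(net: VesselNetwork) -> float:
    """Max relative nodal flow imbalance over interior (non-boundary) nodes."""
    if net.seg_flow is None:
        raise FlowError("flow not solved")
    N = net.n_nodes
    ab = np.asarray(net.seg_nodes)
    netflux = np.zeros(N)
    np.add.at(netflux, ab[:, 0], -net.seg_flow)
    np.add.at(netflux, ab[:, 1], net.seg_flow)
    fixed = np.asarray(net.is_inlet, bool) | np.asarray(net.is_outlet, bool)
    scale = np.abs(net.seg_flow).max()
    if scale == 0:
        return 0.0
    return float(np.max(np.abs(netflux[~fixed])) / scale) if (~fixed).any() else 0.0
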