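"""Deterministic toy fixtures: small vessel networks and seed tumors.

Everything here is tiny, RNG-free and constructed in code; the unit tests of
the flow, transport, and growth machinery run entirely on these objects.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec
from .tumor import TumorState, make_disc_levelset
from .vasculature import PREEXISTING, VesselNetwork, build_preexisting_grid

__all__ = ["make_toy_network", "make_toy_tumor", "TOY_KINDS"]

TOY_KINDS = ("single_segment", "y_branch", "ladder", "grid3x3")

#: toy dimensions: capillary radius 10 um, segment length 100 um
_R = 10e-6
_L = 100e-6
#: ladder rail/rung radii (m): asymmetric so the loop flows are nontrivial
LADDER_RADII = {
    "rail_left_0": 10e-6, "rail_left_1": 8e-6,
    "rail_right_0": 9e-6, "rail_right_1": 7e-6,
    "rung_0": 6e-6, "rung_1": 5e-6, "rung_2": 6e-6,
}


def make_toy_network(kind: str) -> VesselNetwork:
    """Small deterministic networks for flow/transport tests.

    - ``single_segment``: inlet -- outlet, one 100-um capillary.
    - ``y_branch``: inlet trunk splitting into two identical children.
    - ``ladder``: two rails joined by three rungs (two loops) with the
      radii in :data:`LADDER_RADII`; inlet at the left-rail head, outlet at
      the right-rail tail.
    - ``grid3x3``: regular capillary grid, 1-mm domain, 0.5-mm spacing
      (3 lines per direction, 4 interior degree-4 crossings).
    """
    if kind == "single_segment":
        net = VesselNetwork()
        a = net.add_node(0.0, 0.0, inlet=True)
        b = net.add_node(0.1, 0.0, outlet=True)
        net.add_segment(a, b, _R, _L, PREEXISTING)
        return net
    if kind == "y_branch":
        net = VesselNetwork()
        src = net.add_node(0.0, 0.0, inlet=True)
        j = net.add_node(0.1, 0.0)
        top = net.add_node(0.2, 0.05, outlet=True)
        bot = net.add_node(0.2, -0.05, outlet=True)
        net.add_segment(src, j, _R, _L, PREEXISTING)
        net.add_segment(j, top, 7e-6, _L, PREEXISTING)
        net.add_segment(j, bot, 7e-6, _L, PREEXISTING)
        return net
    if kind == "ladder":
        net = VesselNetwork()
        l0 = net.add_node(0.0, 0.0, inlet=True)
        l1 = net.add_node(0.0, 0.1)
        l2 = net.add_node(0.0, 0.2)
        r0 = net.add_node(0.1, 0.0)
        r1 = net.add_node(0.1, 0.1)
        r2 = net.add_node(0.1, 0.2, outlet=True)
        rr = LADDER_RADII
        net.add_segment(l0, l1, rr["rail_left_0"], _L, PREEXISTING)
        net.add_segment(l1, l2, rr["rail_left_1"], _L, PREEXISTING)
        net.add_segment(r0, r1, rr["rail_right_0"], _L, PREEXISTING)
        net.add_segment(r1, r2, rr["rail_right_1"], _L, PREEXISTING)
        net.add_segment(l0, r0, rr["rung_0"], _L, PREEXISTING)
        net.add_segment(l1, r1, rr["rung_1"], _L, PREEXISTING)
        net.add_segment(l2, r2, rr["rung_2"], _L, PREEXISTING)
        return net
    if kind == "grid3x3":
        grid = GridSpec(domain_size_mm=1.0, n_cells=16, length_scale_mm=0.2)
        return build_preexisting_grid(grid, vessel_spacing_mm=0.5, radius_m=_R)
    raise ValueError(f"unknown toy network kind '{kind}' (one of {TOY_KINDS})")


def make_toy_tumor(radius_mm: float, grid: GridSpec,
                   center_mm: tuple[float, float] | None = None) -> TumorState:
    """Disc tumor with signed-distance level set, all-proliferating regions."""
    if not (0.0 < radius_mm < grid.domain_size_mm / 2):
        raise ValueError(
            f"radius {radius_mm} mm out of range (0, {grid.domain_size_mm / 2})")
    phi = make_disc_levelset(grid, radius_mm, center_mm)
    state = TumorState(grid, phi)
    inside = state.tumor_mask
    state.mask_P = inside.copy()
    state.mask_H = np.zeros_like(inside)
    state.mask_N = np.zeros_like(inside)
    return state
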