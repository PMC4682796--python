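"""Quasi-steady oxygen transport from vascular extravasation.

Oxygen sigma (normalized to [0, 1]) extravasates from perfused vessel cells,
diffuses with unit nondimensional diffusivity, and is consumed at a
region-dependent rate:

    0 = lap(sigma) + S(x) * (1 - sigma) - lam(x) * sigma

where the extravasation coefficient per cell is

    S = lam_ev * 1_vessel * max(h / H_D - h_min, 0) * (1 - k_pi * p_i / p_e)

The hematocrit switch means vessels below the minimum hematocrit deliver no
oxygen (unperfused neovessels in particular), and the interstitial-pressure
factor shuts extravasation down where the tumor compresses its vasculature
(the mechanism that starves the tumor core and drives hypoxia). The uptake
rate lam(x) is lam_tissue outside the tumor, lam_tumor in the proliferating
region, q_s in the hypoxic region, and lam_necrosis in the necrotic core.

Because S does not depend on sigma, the saturating source makes the problem
linear; one sparse solve gives the equilibrium, and the maximum principle
keeps sigma in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, ScalarField, solve_steady_reaction_diffusion
from .vasculature import NEOVESSEL, VesselNetwork

__all__ = ["OxygenParams", "vessel_source_coefficient", "extravasation_field",
           "solve_oxygen"]

#: fraction of the max |Q| below which a segment counts as unperfused
PERFUSION_EPS = 1e-8


@dataclass
class OxygenParams:
    """Oxygen transport rates (nondimensional; diffusivity is the unit)."""

    lam_ev: float = 10.0          # vessel transfer rate
    lam_tissue: float = 0.12      # normal-tissue uptake
    lam_tumor: float = 2.5        # proliferating-tumor uptake
    q_s: float = 0.5              # hypoxic-tissue uptake
    lam_necrosis: float = 0.35    # decay in necrotic tissue
    hematocrit_normal: float = 0.45   # H_D
    hematocrit_min: float = 0.25      # h_min (as a fraction of H_D)
    neovessel_hematocrit_fraction: float = 0.5
    k_pi: float = 0.95            # convective-transport weight, in [0, 1]
    p_e: float = 0.5              # pressure scale: tumor depth (model lengths)
                                  # at which extravasation suppression saturates

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_pi <= 1.0):
            raise ValueError("k_pi must lie in [0, 1]")
        if self.p_e <= 0:
            raise ValueError("p_e must be positive")
        for name in ("lam_ev", "lam_tissue", "lam_tumor", "q_s", "lam_necrosis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def segment_hematocrit(net: VesselNetwork, params: OxygenParams) -> np.ndarray:
    """Per-segment hematocrit under the constant-hematocrit approximation.

    Pre-existing capillaries always carry the normal hematocrit H_D.
    Neovessels carry a fixed fraction of H_D once they are part of a
    perfused loop, and zero while they are unperfused dead-end sprouts
    (no flow, no red cells, no oxygen delivery).
    """
    m = net.n_segments
    h = np.full(m, params.hematocrit_normal)
    origin = np.asarray(net.seg_origin)
    neo = origin == NEOVESSEL
    h[neo] = params.neovessel_hematocrit_fraction * params.hematocrit_normal
    if net.seg_flow is not None:
        q = np.abs(net.seg_flow)
        qmax = q.max() if len(q) else 0.0
        perfused = np.zeros(m, dtype=bool)
        # segments added since the last flow solve are unperfused dead ends
        perfused[: len(q)] = q > PERFUSION_EPS * max(qmax, 1e-300)
        h[neo & ~perfused] = 0.0
    return h


def vessel_source_coefficient(
    net: VesselNetwork,
    p_i: np.ndarray | None,
    params: OxygenParams,
) -> np.ndarray:
    """Extravasation coefficient S(x) on the grid (zero off-vessel).

    ``p_i`` is the interstitial-pressure surrogate (tumor depth in model
    lengths; see the scenario runner), scaled by ``p_e`` and clipped to
    [0, 1]; None means zero everywhere.
    """
    grid = net.grid
    S = np.zeros(grid.shape)
    h_seg = segment_hematocrit(net, params)
    switch = np.maximum(h_seg / params.hematocrit_normal - params.hematocrit_min, 0.0)
    for s, (j, i) in enumerate(net.segment_cells()):
        S[j, i] = max(S[j, i], params.lam_ev * switch[s])
    if p_i is not None:
        pi_scaled = np.clip(np.asarray(p_i) / params.p_e, 0.0, 1.0)
        S *= 1.0 - params.k_pi * pi_scaled
    return S


def extravasation_field(
    net: VesselNetwork,
    sigma: ScalarField,
    p_i: np.ndarray | None,
    params: OxygenParams,
) -> ScalarField:
    """Local oxygen extravasation rate S(x) * (1 - sigma)."""
    S = vessel_source_coefficient(net, p_i, params)
    return ScalarField(sigma.grid, S * (1.0 - sigma.values))


def uptake_field(
    grid: GridSpec,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    params: OxygenParams,
) -> np.ndarray:
    """Region-dependent uptake/decay rate lam(x)."""
    lam = np.full(grid.shape, params.lam_tissue)
    if masks is not None:
        mask_P, mask_H, mask_N = masks
        lam[mask_P] = params.lam_tumor
        lam[mask_H] = params.q_s
        lam[mask_N] = params.lam_necrosis
    return lam


def solve_oxygen(
    net: VesselNetwork,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    params: OxygenParams,
    p_i: np.ndarray | None = None,
) -> ScalarField:
    """Steady oxygen field for the current vasculature and tumor regions."""
    grid = net.grid
    S = vessel_source_coefficient(net, p_i, params)
    lam = uptake_field(grid, masks, params)
    if not np.any(S > 0):
        return grid.zeros()
    # saturating source S*(1-sigma) folded into the linear operator
    sigma = solve_steady_reaction_diffusion(grid, 1.0, source=S, sink_rate=S + lam)
    np.clip(sigma.values, 0.0, 1.0, out=sigma.values)
    return sigma
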