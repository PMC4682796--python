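"""Continuum tumor: region classification, net proliferation, Darcy flow,
level-set interface advection, and area accounting.

The tumor occupies the region where a level-set field ``phi`` (a signed
distance, negative inside) is below zero. Oxygen partitions the tumor into a
proliferating rim (sigma >= sigma_H), a hypoxic band (sigma_N <= sigma <
sigma_H) and a necrotic core (sigma < sigma_N). The net volume-gain rate
``lambda_p`` is piecewise:

    lambda_p = lam_M * sigma * (1 - lam_effect * G) - lam_A   (proliferating)
             = 0                                              (hypoxic)
             = -lam_N                                         (necrotic)

with the drug G acting only on proliferating (cycling) tissue. Mass
conservation of incompressible tissue gives div(v) = lambda_p with the Darcy
velocity v = -mobility * grad(P) + chi_E * grad(E); the oncotic pressure P is
solved with P = 0 on the tumor boundary. The interface moves with v
(extended off the tumor along normals), so the tumor area obeys
dA/dt = integral of lambda_p over the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.spatial import cKDTree
from skimage.measure import find_contours

from .grid import GridSpec, ScalarField, gradient, solve_masked_poisson

__all__ = [
    "GrowthParams",
    "TumorState",
    "make_disc_levelset",
    "classify_regions",
    "net_proliferation",
    "solve_pressure_and_velocity",
    "advance_interface",
    "tumor_area_mm2",
    "reinitialize",
]


@dataclass
class GrowthParams:
    """Tumor kinetic and mechanical parameters (rates per day).

    ``lam_effect`` is the drug potency (per unit drug concentration); it is
    the parameter the IC50 procedure tunes. ``kill_cap_per_day`` bounds the
    local death rate so that "instantaneous" drug kill stays resolvable by
    the interface CFL; 48/day means doomed tissue is gone within ~30 min.
    """

    lam_mitosis: float = 0.70        # 1/day, proliferation rate at sigma = 1
    lam_apoptosis: float = 0.10      # 1/day
    lam_necrosis: float = 0.25       # 1/day, necrotic volume-loss rate
    lam_effect: float = 0.0          # drug-induced death coefficient
    mobility: float = 1.0            # Darcy mobility (model units)
    chi_E: float = 0.0               # haptotaxis coefficient (off by default)
    sigma_H: float = 0.50            # hypoxia threshold on oxygen
    sigma_N: float = 0.30            # necrosis threshold on oxygen
    kill_cap_per_day: float = 48.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma_N < self.sigma_H <= 1.0):
            raise ValueError(
                f"need 0 <= sigma_N < sigma_H <= 1, got "
                f"sigma_N={self.sigma_N}, sigma_H={self.sigma_H}"
            )
        for name in ("lam_mitosis", "lam_apoptosis", "lam_necrosis", "mobility"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TumorState:
    """Level-set field plus derived region masks and pressure."""

    grid: GridSpec
    phi: np.ndarray                      # signed distance, model units, <0 inside
    ecm: np.ndarray | None = None        # ECM density E (uniform 1 by default)
    pressure: np.ndarray | None = None
    mask_P: np.ndarray | None = None
    mask_H: np.ndarray | None = None
    mask_N: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ecm is None:
            self.ecm = np.ones(self.grid.shape)

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.phi < 0.0

    def area_mm2(self) -> float:
        return tumor_area_mm2(self.grid, self.phi)

    def copy(self) -> "TumorState":
        return TumorState(
            self.grid, self.phi.copy(),
            None if self.ecm is None else self.ecm.copy(),
            None if self.pressure is None else self.pressure.copy(),
            None if self.mask_P is None else self.mask_P.copy(),
            None if self.mask_H is None else self.mask_H.copy(),
            None if self.mask_N is None else self.mask_N.copy(),
        )


def make_disc_levelset(grid: GridSpec, radius_mm: float,
                       center_mm: tuple[float, float] | None = None) -> np.ndarray:
    """Exact signed-distance field of a disc (model length units)."""
    if center_mm is None:
        c = grid.domain_size_mm / 2.0
        center_mm = (c, c)
    x, y = grid.cell_centers_mm()
    r = np.hypot(x - center_mm[0], y - center_mm[1])
    return (r - radius_mm) / grid.length_scale_mm


def _smeared_heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    h = np.where(
        phi < -eps, 1.0,
        np.where(phi > eps, 0.0,
                 0.5 * (1.0 - phi / eps - np.sin(np.pi * phi / eps) / np.pi)),
    )
    return h


def tumor_area_mm2(grid: GridSpec, phi: np.ndarray) -> float:
    """Sub-cell-accurate tumor area via a smeared Heaviside of the level set."""
    eps = 1.5 * grid.spacing
    H = _smeared_heaviside(phi, eps)
    return float(H.sum()) * grid.cell_area_mm2


def classify_regions(
    sigma: ScalarField,
    tumor_mask: np.ndarray,
    params: GrowthParams,
    prev_necrotic: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition the tumor into proliferating / hypoxic / necrotic by oxygen.

    Necrosis is irreversible: cells once necrotic stay necrotic while they
    remain inside the tumor (re-oxygenating dead tissue does not revive it).
    Hypoxic tissue, by contrast, re-enters the proliferating pool when oxygen
    returns. Without the necrotic memory the oxygen/uptake coupling is
    bistable (dead tissue consumes little oxygen, so sigma recovers and the
    region flips back), which is both unphysical and numerically unstable.
    """
    s = sigma.values
    inside = np.asarray(tumor_mask, bool)
    mask_N = inside & (s < params.sigma_N)
    if prev_necrotic is not None:
        mask_N |= inside & np.asarray(prev_necrotic, bool)
    mask_P = inside & (s >= params.sigma_H) & ~mask_N
    mask_H = inside & ~mask_N & ~mask_P
    return mask_P, mask_H, mask_N


def net_proliferation(
    state: TumorState,
    sigma: ScalarField,
    G: ScalarField | None,
    params: GrowthParams,
    lam_effect: float | None = None,
) -> ScalarField:
    """Piecewise net proliferation rate lambda_p (1/day) on the grid.

    The drug enters only in the proliferating region; the local death rate
    is capped at ``kill_cap_per_day`` (instantaneous death at the tissue
    time scale without breaking the advection CFL).
    """
    lam_eff = params.lam_effect if lam_effect is None else lam_effect
    lam_p = np.zeros(state.grid.shape)
    if state.mask_P is None:
        raise ValueError("region masks not classified; call classify_regions first")
    g = np.zeros(state.grid.shape) if G is None else G.values
    if np.any(g < 0):
        raise ValueError("drug concentration must be non-negative")
    mP, mH, mN = state.mask_P, state.mask_H, state.mask_N
    lam_p[mP] = (
        params.lam_mitosis * sigma.values[mP] * (1.0 - lam_eff * g[mP])
        - params.lam_apoptosis
    )
    lam_p[mN] = -params.lam_necrosis
    np.maximum(lam_p, -params.kill_cap_per_day, out=lam_p)
    return ScalarField(state.grid, lam_p)


def solve_pressure_and_velocity(
    state: TumorState, lam_p: ScalarField, params: GrowthParams
) -> tuple[ScalarField, np.ndarray, np.ndarray]:
    """Oncotic pressure (P=0 on the interface) and Darcy velocity.

    Returns (P, vx, vy); velocity is valid inside the tumor and extended
    outside by copying from the nearest interior cell, so the level set can
    be advected in a band spanning the interface.
    """
    grid = state.grid
    mask = state.tumor_mask
    # solve on a half-cell-expanded band: the ghost Dirichlet cells then sit
    # ~one cell beyond the zero contour, which cancels the staircase bias of
    # the masked solve (the expanded cells carry no source, so the solution
    # inside the tumor is unchanged to leading order)
    solve_mask = state.phi < 0.5 * grid.spacing
    P = solve_masked_poisson(grid, solve_mask, lam_p.values,
                             coeff=params.mobility)
    gx, gy = gradient(grid, P)
    vx = -params.mobility * gx
    vy = -params.mobility * gy
    if params.chi_E != 0.0 and state.ecm is not None:
        ex, ey = gradient(grid, state.ecm)
        vx += params.chi_E * ex
        vy += params.chi_E * ey
    if mask.any() and not mask.all():
        # extension off the tumor: linear extrapolation along the inward
        # normal from the nearest interior cell and one cell deeper. A
        # constant (nearest-cell) extension samples v half a cell inside the
        # interface and systematically under-advects; the linear correction
        # is exact for linearly varying velocity (e.g. uniform growth).
        dist, (jj, ii) = distance_transform_edt(~mask, return_indices=True)
        gx2, gy2 = gradient(grid, state.phi)
        norm = np.hypot(gx2, gy2)
        norm[norm == 0] = 1.0
        nxs, nys = gx2 / norm, gy2 / norm
        v1x, v1y = vx[jj, ii], vy[jj, ii]
        coords = [jj - nys, ii - nxs]  # one cell deeper, index units
        v2x = map_coordinates(vx, coords, order=1, mode="nearest")
        v2y = map_coordinates(vy, coords, order=1, mode="nearest")
        reach = np.minimum(dist, 3.0)  # extrapolate only a short band
        out = ~mask
        vx = np.where(out, v1x + (v1x - v2x) * reach, vx)
        vy = np.where(out, v1y + (v1y - v2y) * reach, vy)
    state.pressure = P
    return ScalarField(grid, P), vx, vy


def uniform_disc_growth(
    state: TumorState,
    sigma: ScalarField,
    G: ScalarField | None,
    params: GrowthParams,
    dt: float,
    lam_effect: float | None = None,
) -> TumorState:
    """Analytic interface motion for tumors too small to resolve on the grid.

    A nodule spanning only a few cells cannot support the discrete pressure
    solve, but for a disc with (near-)uniform net proliferation the continuum
    solution is exact: the boundary moves radially at ``mean(lambda_p) R / 2``.
    The mean rate is taken over the smeared tumor indicator with the whole
    nodule treated as proliferating (sub-50-um nodules are pre-hypoxic).
    Expanding the signed-distance field by a constant preserves it exactly.
    """
    lam_eff = params.lam_effect if lam_effect is None else lam_effect
    grid = state.grid
    w = _smeared_heaviside(state.phi, 1.5 * grid.spacing)
    if w.sum() <= 0:
        return state
    g = np.zeros(grid.shape) if G is None else G.values
    lam_p = params.lam_mitosis * sigma.values * (1.0 - lam_eff * g) - params.lam_apoptosis
    np.maximum(lam_p, -params.kill_cap_per_day, out=lam_p)
    lam_mean = float((w * lam_p).sum() / w.sum())
    area = tumor_area_mm2(grid, state.phi) / grid.length_scale_mm**2
    r_eq = np.sqrt(max(area, 0.0) / np.pi)
    # dR/dt = lam R / 2 integrates exactly to R exp(lam dt / 2)
    state.phi = state.phi - r_eq * np.expm1(0.5 * lam_mean * dt)
    return state


def reinitialize(grid: GridSpec, phi: np.ndarray) -> np.ndarray:
    """Rebuild phi as signed distance to its (sub-cell) zero contour.

    The contour is extracted by marching squares on the cell-centered field,
    so the interface position is preserved to linear-interpolation accuracy;
    distances are to the contour vertex set (spacing <= one cell).
    """
    inside = phi < 0
    if not inside.any() or inside.all():
        return phi
    contours = find_contours(phi, 0.0)
    if not contours:
        return phi
    pts = np.vstack(contours)  # (row, col) index coordinates
    tree = cKDTree(pts)
    n = grid.n_cells
    jj, ii = np.mgrid[0:n, 0:n]
    query = np.column_stack([jj.ravel(), ii.ravel()])
    d, _ = tree.query(query, workers=-1)
    d = d.reshape(grid.shape) * grid.spacing
    return np.where(inside, -d, d)


def advance_interface(
    state: TumorState,
    vx: np.ndarray,
    vy: np.ndarray,
    dt: float,
    *,
    reinit: bool = True,
) -> TumorState:
    """Advect the level set by the (extended) velocity with upwind substeps.

    Substeps enforce CFL <= 0.4; afterwards phi is re-initialized to signed
    distance. dt in days, velocity in model-length units per day.
    """
    grid = state.grid
    h = grid.spacing
    phi = state.phi
    vmax = max(np.max(np.abs(vx)), np.max(np.abs(vy)), 1e-30)
    n_sub = max(1, int(np.ceil(dt * vmax / (0.4 * h))))
    dtau = dt / n_sub
    for _ in range(n_sub):
        p = np.pad(phi, 1, mode="edge")
        dxm = (p[1:-1, 1:-1] - p[1:-1, :-2]) / h
        dxp = (p[1:-1, 2:] - p[1:-1, 1:-1]) / h
        dym = (p[1:-1, 1:-1] - p[:-2, 1:-1]) / h
        dyp = (p[2:, 1:-1] - p[1:-1, 1:-1]) / h
        adv = (
            np.maximum(vx, 0) * dxm + np.minimum(vx, 0) * dxp
            + np.maximum(vy, 0) * dym + np.minimum(vy, 0) * dyp
        )
        phi = phi - dtau * adv
    if reinit:
        phi = reinitialize(grid, phi)
    state.phi = phi
    return state
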