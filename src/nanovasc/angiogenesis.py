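"""Sprouting angiogenesis: TAF field and lattice tip migration.

Hypoxic tumor tissue releases tumor angiogenic factor (TAF), which diffuses
and decays; endothelial sprout tips nucleate on existing vessels where TAF is
high and execute a biased lattice random walk (Anderson-Chaplain style). The
move probabilities discretize the endothelial conservation law: a constant
random-motility weight D for staying/each direction, plus chemotactic
(up the TAF gradient, with receptor saturation chi/(1 + eta*T)) and
haptotactic (up the ECM gradient) contributions. A tip that steps onto an
existing vessel node anastomoses, closing a loop; flow is then re-solved so
the new path becomes perfused. Dead-end sprouts carry no flow, hence deliver
neither oxygen nor nanoparticles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import DiffusionStepper, GridSpec, ScalarField
from .vasculature import NEOVESSEL, VesselNetwork, solve_flow

__all__ = ["AngiogenesisParams", "SproutTip", "update_taf", "step_sprout_tips",
           "perfuse_new_vessels", "direction_probabilities", "spawn_sprouts"]

# lattice moves: +x, -x, +y, -y (grid columns i, rows j)
_MOVES = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class AngiogenesisParams:
    """Sprout/TAF parameters. Rates per day, lengths in model units."""

    taf_diffusivity: float = 20.0       # model-length^2 / day
    taf_decay: float = 10.0             # 1/day
    taf_source: float = 10.0            # 1/day, on hypoxic tissue
    motility: float = 1.0               # random-walk weight D
    chemotaxis: float = 12.0            # chi_sprout_T
    chemotaxis_saturation: float = 1.0  # eta in chi/(1 + eta T)
    haptotaxis: float = 0.0             # chi_sprout_E (ECM uniform by default)
    sprout_rate_per_day: float = 2.5    # tip nucleation rate per vessel cell at T=1
    taf_threshold: float = 0.08         # minimum TAF for nucleation
    tip_speed_mm_per_day: float = 0.45
    branch_prob_per_step: float = 0.0   # branching off by default (tip budget)
    neovessel_radius_m: float = 10e-6
    max_active_tips: int = 150
    max_neovessel_segments: int = 4000
    min_fuse_age: int = 3               # steps before a tip may anastomose

    def __post_init__(self) -> None:
        for name in ("taf_diffusivity", "taf_decay", "taf_source", "motility",
                     "chemotaxis", "haptotaxis", "sprout_rate_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SproutTip:
    """An active sprout tip walking on the lattice of cell centers."""

    path: list                 # [(i, j), ...] lattice trail, contiguous
    parent_node: int           # node id on the parent vessel
    active: bool = True
    age: int = 0


def update_taf(
    T: ScalarField,
    hypoxic_mask: np.ndarray,
    dt: float,
    params: AngiogenesisParams,
    stepper: DiffusionStepper | None = None,
) -> ScalarField:
    """One implicit step of TAF diffusion + hypoxic source + linear decay.

    The source is ``taf_source`` on hypoxic cells, so the steady field is
    bounded by taf_source / taf_decay; callers typically treat TAF in units
    of that bound.
    """
    if stepper is None:
        stepper = DiffusionStepper(T.grid, params.taf_diffusivity,
                                   params.taf_decay, dt)
    src = params.taf_source * np.asarray(hypoxic_mask, dtype=float)
    out = stepper.step(T.values, src)
    np.maximum(out, 0.0, out=out)
    return ScalarField(T.grid, out)


def direction_probabilities(D: float, contributions: np.ndarray) -> np.ndarray:
    """Normalized move probabilities [stay, +x, -x, +y, -y].

    ``contributions`` are the (non-negative) chemotactic + haptotactic
    weights for the four moves; each move weight is D + contribution and the
    stay weight is D. All-zero weights degenerate to certain stay.
    """
    c = np.maximum(np.asarray(contributions, dtype=float), 0.0)
    w = np.concatenate([[D], D + c])
    total = w.sum()
    if total <= 0:
        return np.array([1.0, 0, 0, 0, 0])
    return w / total


def _tip_contributions(i: int, j: int, T: np.ndarray, E: np.ndarray,
                       grid: GridSpec, params: AngiogenesisParams) -> np.ndarray:
    h = grid.spacing
    n = grid.n_cells
    Tc = T[j, i]
    chi_T = params.chemotaxis / (1.0 + params.chemotaxis_saturation * Tc)
    out = np.zeros(4)
    for k, (di, dj) in enumerate(_MOVES):
        ii, jj = i + di, j + dj
        if not (0 <= ii < n and 0 <= jj < n):
            out[k] = 0.0
            continue
        c = chi_T * (T[jj, ii] - Tc) / h
        if params.haptotaxis:
            c += params.haptotaxis * (E[jj, ii] - E[j, i]) / h
        out[k] = max(c, 0.0)
    return out


def spawn_sprouts(
    net: VesselNetwork,
    tips: list[SproutTip],
    T: ScalarField,
    dt: float,
    params: AngiogenesisParams,
    rng: np.random.Generator,
) -> list[SproutTip]:
    """Nucleate new tips on vessel nodes where TAF exceeds the threshold."""
    n_active = sum(t.active for t in tips)
    if n_active >= params.max_active_tips:
        return tips
    Tv = T.values
    occupied = {t.path[-1] for t in tips if t.active}
    items = list(net.lattice.items())
    order = rng.permutation(len(items))
    for k in order:
        (i, j), nid = items[k]
        if n_active >= params.max_active_tips:
            break
        t_loc = Tv[j, i]
        if t_loc < params.taf_threshold or (i, j) in occupied:
            continue
        p = 1.0 - np.exp(-params.sprout_rate_per_day * t_loc * dt)
        if rng.random() < p:
            tips.append(SproutTip(path=[(i, j)], parent_node=nid))
            occupied.add((i, j))
            n_active += 1
    return tips


def step_sprout_tips(
    tips: list[SproutTip],
    net: VesselNetwork,
    T: ScalarField,
    E: np.ndarray,
    dt: float,
    params: AngiogenesisParams,
    rng: np.random.Generator,
) -> bool:
    """Advance every active tip by (at most) one lattice move.

    A tip moves with probability tip_speed * dt / cell_size (time-scaled
    lattice walk), choosing stay/neighbor from :func:`direction_probabilities`.
    Moves lay down neovessel segments; stepping onto an existing vessel node
    (other than the tip's own recent trail) anastomoses and deactivates the
    tip. Returns True if the network gained any anastomosis (flow re-solve
    needed).
    """
    grid = net.grid
    h_mm = grid.spacing_mm
    p_move = min(1.0, params.tip_speed_mm_per_day * dt / h_mm)
    anastomosed = False
    n_cells = grid.n_cells
    for tip in tips:
        if not tip.active:
            continue
        if net.n_segments >= params.max_neovessel_segments:
            tip.active = False
            continue
        if rng.random() >= p_move:
            continue
        i, j = tip.path[-1]
        contribs = _tip_contributions(i, j, T.values, E, grid, params)
        probs = direction_probabilities(params.motility, contribs)
        choice = rng.choice(5, p=probs)
        tip.age += 1
        if choice == 0:
            continue
        di, dj = _MOVES[choice - 1]
        ii, jj = i + di, j + dj
        if not (0 <= ii < n_cells and 0 <= jj < n_cells):
            tip.active = False
            continue
        recent = set(tip.path[-3:])
        if (ii, jj) in recent:
            continue  # no immediate backtracking onto own trail
        cur_node = net.lattice.get((i, j))
        if cur_node is None:
            cur_node = net.add_node((i + 0.5) * h_mm, (j + 0.5) * h_mm,
                                    lattice_key=(i, j))
        target = net.lattice.get((ii, jj))
        seg_len_m = h_mm * 1e-3
        if target is not None:
            if tip.age <= params.min_fuse_age:
                continue  # too young to fuse (avoids trivial parent-line loops)
            net.add_segment(cur_node, target, params.neovessel_radius_m,
                            seg_len_m, NEOVESSEL)
            tip.active = False
            anastomosed = True
        else:
            new_node = net.add_node((ii + 0.5) * h_mm, (jj + 0.5) * h_mm,
                                    lattice_key=(ii, jj))
            net.add_segment(cur_node, new_node, params.neovessel_radius_m,
                            seg_len_m, NEOVESSEL)
            tip.path.append((ii, jj))
            if (params.branch_prob_per_step > 0
                    and rng.random() < params.branch_prob_per_step * T.values[jj, ii]):
                tips.append(SproutTip(path=[(ii, jj)], parent_node=new_node,
                                      age=tip.age))
    return anastomosed


def perfuse_new_vessels(net: VesselNetwork, p_in: float = 1.0, p_out: float = 0.0,
                        viscosity_pa_s: float = 3e-3) -> VesselNetwork:
    """Re-solve flow so anastomosed loops become perfused.

    Dead-end sprout branches end up with zero flow and zero shear: maximal
    adhesion probability but no advective nanoparticle supply.
    """
    return solve_flow(net, p_in, p_out, viscosity_pa_s)
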