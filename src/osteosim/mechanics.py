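"""Centre-based off-lattice mechanics: overlap detection and correction.

Agents are non-deformable spheres. Any pair closer than the sum of their
radii overlaps; interactions are corrected once per iteration by an
explicit scheme that displaces each *cell* by a restoring step built from
the signed gap O_ij:

    F_c,ij = s_ij * c_c,i * O_ij          (per axis c in {x, y, z})
    s_ij   = 1 / distance(i, j)
    c_c,i  = alpha * (c_j - c_i)

with alpha = 0.4 for true overlap (O_ij < 0) and alpha = 0.06 for in-range
separation (0 < O_ij <= 10 um); pairs with a gap above 10 um do not
interact. The signs make one formula cover both regimes: overlapping pairs
repel (hard, 0.4), separated pairs within the vicinity band are drawn back
together (soft, 0.06, cell-cell cohesion), so an isolated pair relaxes to
touching. Matrix agents (osteoid, mineralised osteoid) are immobile.
Positions are updated from the previous step's coordinates only and then
clamped to the dish; precursor cells are re-pinned to the monolayer plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Agent, AgentKind, SimulationConfig, WorldState, CELL_KINDS

#: centre distance below which a pair counts as degenerate (coincident)
DEGENERATE_DISTANCE = 1e-9
#: magnitude of the seeded random jitter applied to degenerate pairs, um
DEGENERATE_JITTER = 0.1


@dataclass
class GapResult:
    """Signed gap between two spheres: positive = separated, negative = overlap."""

    gap: float
    unit_separation: np.ndarray  # from j toward i; zero vector if degenerate
    distance: float


@dataclass
class Displacement:
    fx: float
    fy: float
    fz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz])


def pairwise_gap(a: Agent, b: Agent) -> GapResult:
    """Signed gap O_ij = |centre_i - centre_j| - (r_i + r_j) for a pair."""
    if a is b:
        raise ValueError("pairwise_gap needs two distinct agents")
    delta = np.asarray(a.position, float) - np.asarray(b.position, float)
    d = float(np.linalg.norm(delta))
    unit = delta / d if d > DEGENERATE_DISTANCE else np.zeros(3)
    return GapResult(gap=d - (a.radius + b.radius), unit_separation=unit, distance=d)


@dataclass
class NeighborResult:
    """Neighbours of one agent, split by the two rule-relevant bands.

    ``neighbors`` holds agents separated by 0 < gap <= gap_max (the
    proliferation "vicinity" band); ``contacts`` additionally includes
    touching/overlapping agents (gap <= 0), because differentiation rules
    phrased as "surrounded by"/"in contact with" count touching matrix too.
    """

    neighbors: np.ndarray  # indices into the state
    contacts: np.ndarray


def find_neighbors(state: WorldState, index: int, gap_max: float = 10.0) -> NeighborResult:
    """Neighbour/contact indices of agent ``index`` via the spatial index."""
    if gap_max <= 0:
        raise ValueError("gap_max must be positive")
    tree = cKDTree(state.pos)
    r = state.radius[index]
    reach = float(r + state.radius.max() + gap_max)
    cand = np.array(tree.query_ball_point(state.pos[index], reach), dtype=int)
    cand = cand[cand != index]
    if len(cand) == 0:
        return NeighborResult(neighbors=cand, contacts=cand)
    d = np.linalg.norm(state.pos[cand] - state.pos[index], axis=1)
    gaps = d - (state.radius[cand] + r)
    in_band = (gaps > 0) & (gaps <= gap_max)
    return NeighborResult(neighbors=cand[in_band], contacts=cand[gaps <= gap_max])


def repulsion_displacement(a: Agent, b: Agent, cfg: SimulationConfig) -> Displacement:
    """Restoring displacement of ``a`` due to ``b`` for one explicit step.

    Proportional to |O_ij|: directed away from ``b`` when the pair
    overlaps (alpha = 0.4), toward ``b`` when separated within the
    vicinity band (alpha = 0.06), zero when out of range
    (gap > cfg.neighbor_gap_max). Degenerate (coincident) pairs raise;
    the engine jitters them instead.
    """
    g = pairwise_gap(a, b)
    if g.gap > cfg.neighbor_gap_max:
        return Displacement(0.0, 0.0, 0.0)
    if g.distance <= DEGENERATE_DISTANCE:
        raise FloatingPointError("coincident centres; resolve_overlaps applies seeded jitter")
    alpha = cfg.alpha_overlap if g.gap < 0 else cfg.alpha_no_overlap
    # s_ij * (c_j - c_i) is the unit separation vector i -> j, so the
    # signed product with O_ij repels on overlap and attracts in-band
    vec = -alpha * g.gap * g.unit_separation
    return Displacement(*vec)


def pair_interactions(state: WorldState, gap_max: float = 10.0):
    """All interacting pairs (i, j, distance) with gap <= gap_max."""
    reach = float(2 * state.radius.max() + gap_max)
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(reach, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2), np.empty(0)
    delta = state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]]
    d = np.linalg.norm(delta, axis=1)
    keep = d - (state.radius[pairs[:, 0]] + state.radius[pairs[:, 1]]) <= gap_max
    return pairs[keep], d[keep]


def resolve_overlaps(state: WorldState, cfg: SimulationConfig, rng=None) -> WorldState:
    """One explicit overlap-correction pass (in place; also returns state).

    Sums the per-pair repulsive displacements computed from the previous
    positions, applies them to cell agents only, clamps into the dish and
    re-pins precursors to the monolayer plane. Residual overlaps may persist
    within one pass but shrink geometrically across passes.
    """
    if state.n == 0:
        return state
    pairs, d = pair_interactions(state, cfg.neighbor_gap_max)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        degenerate = d <= DEGENERATE_DISTANCE
        if np.any(degenerate):
            jit_rng = rng if rng is not None else np.random.default_rng(cfg.seed)
            for pi in i[degenerate]:
                state.pos[pi] += jit_rng.normal(scale=DEGENERATE_JITTER, size=3)
            pairs, d = pair_interactions(state, cfg.neighbor_gap_max)
            i, j = pairs[:, 0], pairs[:, 1]
        gaps = d - (state.radius[i] + state.radius[j])
        alpha = np.where(gaps < 0, cfg.alpha_overlap, cfg.alpha_no_overlap)
        unit = (state.pos[i] - state.pos[j]) / d[:, None]
        step = (-alpha * gaps)[:, None] * unit
        disp = np.zeros_like(state.pos)
        np.add.at(disp, i, step)
        np.add.at(disp, j, -step)
        movable = state.kind_mask(*CELL_KINDS)
        state.pos[movable] += disp[movable]
    state.pos = state.dish.clamp(state.pos, float(state.radius.max()))
    precursors = state.kind == int(AgentKind.PRECURSOR)
    state.pos[precursors, 2] = state.dish.floor_z + state.radius[precursors]
    return state
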