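"""Biological rules: proliferation, migration, differentiation, apoptosis,
hypothesis-specific osteoid deposition and mineralisation.

Every rule is gated on the condensation height — the maximum z-top of any
condensation agent above the dish floor. Pre-osteoblasts differentiate into
osteoblasts once the condensation reaches 50 um, osteoblasts deposit
osteoid from 70 um, proliferation stops at 90 um, mineralisation (and
osteoblast-to-osteocyte differentiation) starts at 100 um and all growth
ceases beyond 110 um. Apoptosis removes osteoblasts that failed to
differentiate once the nodule has acquired its maximum height.

The four entrapment hypotheses differ only in how an osteoblast acquires
its deposition direction (polarity): H1 redraws it at every deposition,
H2 draws it once per cell, H3 shares one direction per 20-um z-layer, and
H4 behaves like H3 but stochastically switches osteoblast secretion off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Agent,
    AgentKind,
    CELL_KINDS,
    CONDENSATION_KINDS,
    Dish,
    MATRIX_KINDS,
    SimulationConfig,
    WorldState,
)

#: extra slack (um) on top of touching distance when deciding a site is occupied
PLACEMENT_TOLERANCE = 1.0
#: a cell centre closer than this to a candidate deposition site blocks the
#: deposit (cells further out may overlap the new osteoid; mechanics relaxes it)
DEPOSITION_CELL_CLEARANCE = 5.0
#: minimum centre distance between two matrix agents; osteoid is an
#: arbitrary amount of homogeneous matrix, so it packs tighter than cells
MATRIX_SPACING = 11.5
#: contact distance slack for migration arrival, um
ARRIVAL_CONTACT_SLACK = 1.0
#: a cell must have its z-top above this to count as ensconced within the
#: condensation (the dish-adherent basal monolayer does not participate)
INTERIOR_MIN_TOP = 20.0
#: compass directions probed when asking whether a monolayer daughter fits
_COMPASS = np.array(
    [
        [np.cos(t), np.sin(t)]
        for t in np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
    ]
)


@dataclass
class CondensationGeometry:
    """Derived geometry of the condensation at one instant."""

    height: float  # max z-top above dish floor among condensation agents, um
    centroid_xy: np.ndarray  # (2,), um
    lateral_radius: float  # max radial extent from centroid, um
    member_indices: np.ndarray  # indices of condensation agents


def condensation_members(state: WorldState) -> np.ndarray:
    """Indices of agents belonging to the condensation.

    Membership: condensation kinds (everything except precursors) whose
    z-top clears one monolayer diameter — the basal monolayer does not
    participate in bone synthesis.
    """
    mono_top = state.dish.floor_z + 20.0
    mask = state.kind_mask(*CONDENSATION_KINDS) & (
        state.pos[:, 2] + state.radius > mono_top + 1e-9
    )
    return np.flatnonzero(mask)


def condensation_geometry(state: WorldState) -> CondensationGeometry:
    members = condensation_members(state)
    if len(members) == 0:
        return CondensationGeometry(
            height=0.0,
            centroid_xy=state.dish.focal_point.copy(),
            lateral_radius=0.0,
            member_indices=members,
        )
    tops = state.pos[members, 2] + state.radius[members] - state.dish.floor_z
    xy = state.pos[members, :2]
    centroid = xy.mean(axis=0)
    radial = np.linalg.norm(xy - centroid, axis=1)
    return CondensationGeometry(
        height=float(tops.max()),
        centroid_xy=centroid,
        lateral_radius=float(radial.max()),
        member_indices=members,
    )


def condensation_height(state: WorldState) -> float:
    """Max z-top above the floor over condensation agents; 0 when empty."""
    return condensation_geometry(state).height


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------

def _band_counts(tree: cKDTree, points: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """Number of tree points with inner < distance <= outer, per query point."""
    n_outer = tree.query_ball_point(points, outer, return_length=True)
    n_inner = tree.query_ball_point(points, inner, return_length=True)
    return np.asarray(n_outer) - np.asarray(n_inner)


def planar_neighbor_counts(state: WorldState, indices: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Monolayer neighbour counts (gap in (0, gap_max]) among precursors."""
    prec = np.flatnonzero(state.kind == int(AgentKind.PRECURSOR))
    if len(prec) == 0 or len(indices) == 0:
        return np.zeros(len(indices), dtype=int)
    tree = cKDTree(state.pos[prec, :2])
    touch = 2 * float(state.radius[indices].mean())
    return _band_counts(tree, state.pos[indices, :2], touch, touch + cfg.neighbor_gap_max)


def spatial_neighbor_counts(state: WorldState, indices: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """3D cell-neighbour counts (touching or within the vicinity band).

    Contact inhibition of pre-osteoblast proliferation counts neighbouring
    *cells* (touching included); matrix constrains division through the
    daughter-placement check instead, so a cell sitting on osteoid but with
    free space above keeps dividing.
    """
    cells = np.flatnonzero(state.kind_mask(*CELL_KINDS))
    if len(cells) == 0 or len(indices) == 0:
        return np.zeros(len(indices), dtype=int)
    tree = cKDTree(state.pos[cells])
    touch = 2 * float(state.radius[indices].mean())
    counts = np.asarray(
        tree.query_ball_point(
            state.pos[indices], touch + cfg.neighbor_gap_max, return_length=True
        )
    )
    return counts - 1  # self


def _site_free(
    state: WorldState,
    target: np.ndarray,
    radius: float,
    tree: Optional[cKDTree],
    extra_positions: list,
) -> bool:
    """A placement site is free when in-dish and not overlapping beyond tolerance."""
    if not state.dish.contains(target, radius):
        return False
    block = 2 * radius - PLACEMENT_TOLERANCE
    if tree is not None and tree.query_ball_point(target, block, return_length=True) > 0:
        return False
    for p in extra_positions:
        if np.linalg.norm(p - target) < block:
            return False
    return True


def is_confluent(state: WorldState, cfg: SimulationConfig) -> bool:
    """Whether the precursor monolayer can no longer grow.

    True when every precursor either has at least the critical number of
    planar neighbours or cannot fit a daughter in-plane (all compass
    directions blocked by other agents or the dish wall).
    """
    prec = np.flatnonzero(state.kind == int(AgentKind.PRECURSOR))
    if len(prec) == 0:
        return False
    counts = planar_neighbor_counts(state, prec, cfg)
    open_cells = prec[counts < cfg.critical_neighbors_2d]
    if len(open_cells) == 0:
        return True
    r = float(state.radius[open_cells].mean())
    compass3 = np.column_stack([_COMPASS, np.zeros(len(_COMPASS))])
    targets = (
        state.pos[open_cells][:, None, :] + 2 * r * compass3[None, :, :]
    ).reshape(-1, 3)
    lo = np.array([r, r, state.dish.floor_z + r])
    hi = state.dish.extent - r
    in_dish = np.all((targets >= lo - 1e-9) & (targets <= hi + 1e-9), axis=1)
    if not np.any(in_dish):
        return True
    tree = cKDTree(state.pos)
    occupied = (
        np.asarray(
            tree.query_ball_point(
                targets[in_dish], 2 * r - PLACEMENT_TOLERANCE, return_length=True
            )
        )
        > 0
    )
    return bool(occupied.all())


def attempt_division(
    index: int,
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    tree: Optional[cKDTree] = None,
    new_positions: Optional[list] = None,
    neighbor_count: Optional[int] = None,
) -> Optional[int]:
    """One division attempt for agent ``index``; returns the daughter index.

    Precursors place the daughter in-plane, pre-osteoblasts in a uniformly
    random 3D direction (only after arrival at the skeletogenic site, and
    only below the proliferation-stop height). A blocked attempt returns
    None and leaves the division timer untouched, so the agent retries next
    iteration; the timer is redrawn only on success.
    """
    kind = AgentKind(int(state.kind[index]))
    if kind not in (AgentKind.PRECURSOR, AgentKind.PRE_OSTEOBLAST):
        return None
    if state.next_division[index] > state.iteration:
        return None
    if new_positions is None:
        new_positions = []
    if tree is None:
        tree = cKDTree(state.pos)
    r = float(state.radius[index])
    # attempts are strictly periodic: the timer is redrawn whether or not
    # this attempt produces a daughter
    state.next_division[index] = state.iteration + cfg.division_interval_iters(rng)

    if kind is AgentKind.PRECURSOR:
        if neighbor_count is None:
            neighbor_count = int(planar_neighbor_counts(state, np.array([index]), cfg)[0])
        if neighbor_count >= cfg.critical_neighbors_2d:
            return None
        # monolayer cells keep probing directions until they find space,
        # so the dish fills completely rather than waiting on one lucky draw
        target = None
        for _ in range(4):
            theta = rng.uniform(0.0, 2 * np.pi)
            direction = np.array([np.cos(theta), np.sin(theta), 0.0])
            candidate = state.pos[index] + direction * 2 * r
            if _site_free(state, candidate, r, tree, new_positions):
                target = candidate
                break
        if target is None:
            return None
    else:
        if not state.arrived[index]:
            return None
        if neighbor_count is None:
            neighbor_count = int(spatial_neighbor_counts(state, np.array([index]), cfg)[0])
        if neighbor_count >= cfg.critical_neighbors_3d:
            return None
        vec = rng.normal(size=3)
        direction = vec / np.linalg.norm(vec)
        target = state.pos[index] + direction * 2 * r
        if not _site_free(state, target, r, tree, new_positions):
            return None

    daughter = state.add(
        kind,
        target,
        arrived=bool(state.arrived[index]),
        next_division=state.iteration + cfg.division_interval_iters(rng),
    )[0]
    new_positions.append(target)
    return int(daughter)


def division_phase(
    state: WorldState, cfg: SimulationConfig, rng: np.random.Generator, geom: CondensationGeometry
) -> int:
    """Run all due division attempts for one iteration; returns birth count."""
    due = state.next_division <= state.iteration
    prec = np.flatnonzero(due & (state.kind == int(AgentKind.PRECURSOR)))
    preob = np.flatnonzero(
        due & (state.kind == int(AgentKind.PRE_OSTEOBLAST)) & state.arrived
    )
    if geom.height >= cfg.height_proliferation_stop:
        preob = preob[:0]
    if len(prec) == 0 and len(preob) == 0:
        return 0
    tree = cKDTree(state.pos)
    counts_prec = planar_neighbor_counts(state, prec, cfg)
    counts_preob = spatial_neighbor_counts(state, preob, cfg)
    births = 0
    new_positions: list = []
    order = np.concatenate([prec, preob])
    counts = np.concatenate([counts_prec, counts_preob])
    perm = rng.permutation(len(order))
    for k in perm:
        i, c = int(order[k]), int(counts[k])
        if (
            attempt_division(
                i, state, cfg, rng, tree=tree, new_positions=new_positions, neighbor_count=c
            )
            is not None
        ):
            births += 1
    return births


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def migration_velocity(agent: Agent, dish: Dish, cfg: SimulationConfig) -> np.ndarray:
    """Planar velocity (um/iteration) of a migrating pre-osteoblast.

    Constant speed directed from the agent toward the skeletogenic focal
    point, independent of distance; zero once the agent is within one
    diameter of the focal point.
    """
    xy = np.asarray(agent.position, float)[:2]
    delta = dish.focal_point - xy
    dist = float(np.linalg.norm(delta))
    if dist <= 2 * agent.radius or dist < 1e-12:
        return np.zeros(2)
    return cfg.migration_step() * delta / dist


def migration_phase(state: WorldState, cfg: SimulationConfig) -> None:
    """Move not-yet-arrived pre-osteoblasts toward the focal point.

    Arrival is permanent and happens on reaching one diameter of the focal
    point or on touching an agent that already arrived (which seeds the
    growing aggregate).
    """
    migrating = np.flatnonzero(
        (state.kind == int(AgentKind.PRE_OSTEOBLAST)) & ~state.arrived
    )
    if len(migrating) == 0:
        return
    focal = state.dish.focal_point
    xy = state.pos[migrating, :2]
    dist_focal = np.linalg.norm(xy - focal, axis=1)
    arrived_now = dist_focal <= 2 * state.radius[migrating]
    anchors = np.flatnonzero(state.arrived)
    if len(anchors) > 0:
        tree = cKDTree(state.pos[anchors])
        touch = 2 * state.radius[migrating].mean() + ARRIVAL_CONTACT_SLACK
        n_contact = np.asarray(
            tree.query_ball_point(state.pos[migrating], touch, return_length=True)
        )
        arrived_now |= n_contact > 0
    state.arrived[migrating[arrived_now]] = True

    movers = migrating[~arrived_now]
    if len(movers) == 0:
        return
    delta = focal - state.pos[movers, :2]
    dist = np.linalg.norm(delta, axis=1)
    step = np.minimum(cfg.migration_step(), np.maximum(dist - 2 * state.radius[movers], 0.0))
    state.pos[movers, :2] += delta / dist[:, None] * step[:, None]


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def differentiate_precursors(
    state: WorldState, cfg: SimulationConfig, rng: np.random.Generator
) -> WorldState:
    """One-shot stochastic precursor -> pre-osteoblast conversion at confluence.

    A seeded-random subset of precursors (fraction
    ``cfg.precursor_to_preob_fraction``, drawn once) becomes migratory
    pre-osteoblasts; afterwards the rule never fires again, so precursors
    that later regrow the monolayer stay precursors.
    """
    if state.preobs_seeded:
        return state
    prec = np.flatnonzero(state.kind == int(AgentKind.PRECURSOR))
    count = int(round(cfg.precursor_to_preob_fraction * len(prec)))
    chosen = rng.choice(prec, size=min(count, len(prec)), replace=False)
    state.kind[chosen] = int(AgentKind.PRE_OSTEOBLAST)
    state.next_division[chosen] = state.iteration + cfg.division_interval_iters(rng)
    state.preobs_seeded = True
    return state


def is_interior(
    agent: Agent, geom: CondensationGeometry, cfg: SimulationConfig
) -> bool:
    """Whether an agent sits well inside (ensconced within) the condensation.

    Interior = z-top below the interior height gate (80 um) and at least
    ``interior_margin`` (20 um) away from the periphery — both the lateral
    rim and the top surface, since cells exposed at the top of the
    condensation stay pre-osteoblastic.
    """
    top = float(agent.position[2]) + agent.radius
    if top >= cfg.height_interior_max or top <= INTERIOR_MIN_TOP:
        return False
    if top > geom.height - cfg.interior_margin:
        return False
    radial = float(np.linalg.norm(np.asarray(agent.position)[:2] - geom.centroid_xy))
    return radial <= geom.lateral_radius - cfg.interior_margin


def sample_direction(
    rng: np.random.Generator, distribution: str, tilt: float = 0.5
) -> np.ndarray:
    """Draw one deposition direction from the configured direction set."""
    if distribution == "down":
        return np.array([0.0, 0.0, -1.0])
    if distribution == "tilted":
        # uniform azimuth at a fixed climb (z-component ``tilt``): deposition
        # is lateral into the layer with a steady apposition component
        # toward the top of the condensation
        phi = rng.uniform(0.0, 2 * np.pi)
        c = np.sqrt(1.0 - tilt * tilt)
        return np.array([c * np.cos(phi), c * np.sin(phi), tilt])
    if distribution in ("axis5", "axis6"):
        dirs = [
            np.array([1.0, 0, 0]),
            np.array([-1.0, 0, 0]),
            np.array([0, 1.0, 0]),
            np.array([0, -1.0, 0]),
            np.array([0, 0, 1.0]),
        ]
        if distribution == "axis6":
            dirs.append(np.array([0, 0, -1.0]))
        return dirs[rng.integers(len(dirs))]
    vec = rng.normal(size=3)
    vec /= np.linalg.norm(vec)
    if distribution == "hemisphere":
        vec[2] = abs(vec[2])
    return vec


def layer_region_index(z: float, cfg: SimulationConfig) -> int:
    """Index of the z-layer region containing z; clamped to the nearest region."""
    regions = cfg.layer_regions
    for k, (lo, hi) in enumerate(regions):
        if lo <= z < hi:
            return k
    if z < regions[0][0]:
        return 0
    return len(regions) - 1


def init_layer_polarities(
    state: WorldState, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    """Draw one polarity per z-layer region (H3/H4), once per run.

    With the "tilted" direction set each region draws its own azimuth at
    the climb given by ``cfg.polarity_tilt_profile`` for that region.
    """
    for k in range(len(cfg.layer_regions)):
        if k not in state.layer_polarities:
            tilt = cfg.polarity_tilt
            if cfg.polarity_distribution == "tilted" and k < len(cfg.polarity_tilt_profile):
                tilt = float(cfg.polarity_tilt_profile[k])
            state.layer_polarities[k] = sample_direction(
                rng, cfg.polarity_distribution, tilt
            )


def assign_polarity(
    index: int, state: WorldState, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Deposition direction of one osteoblast under the active hypothesis.

    H1: a fresh uniformly-random direction at every call. H2: drawn once at
    osteoblast creation and immutable thereafter. H3/H4: looked up from the
    shared per-z-layer polarity table (each region's direction drawn once,
    seeded, when the run starts).
    """
    if AgentKind(int(state.kind[index])) is not AgentKind.OSTEOBLAST:
        raise ValueError("only osteoblasts carry an active deposition polarity")
    if cfg.hypothesis == "H1":
        return sample_direction(rng, cfg.polarity_distribution, cfg.polarity_tilt)
    if cfg.hypothesis == "H2":
        if np.any(np.isnan(state.polarity[index])):
            state.polarity[index] = sample_direction(rng, cfg.polarity_distribution, cfg.polarity_tilt)
        return state.polarity[index].copy()
    # H3 / H4: layer polarity
    init_layer_polarities(state, cfg, rng)
    if np.any(np.isnan(state.polarity[index])):
        region = layer_region_index(float(state.pos[index, 2]), cfg)
        base = state.layer_polarities[region]
        if cfg.polarity_azimuth_jitter > 0:
            # cells in one layer secrete in roughly, not exactly, the same
            # direction; a small azimuthal scatter interleaves their seams
            delta = rng.uniform(-cfg.polarity_azimuth_jitter, cfg.polarity_azimuth_jitter)
            ca, sa = np.cos(delta), np.sin(delta)
            base = np.array(
                [ca * base[0] - sa * base[1], sa * base[0] + ca * base[1], base[2]]
            )
        state.polarity[index] = base
    return state.polarity[index].copy()


def differentiate_preosteoblasts(
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    geom: Optional[CondensationGeometry] = None,
) -> WorldState:
    """Pre-osteoblast <-> osteoblast transitions, gated at 50 um height.

    Interior pre-osteoblasts, and pre-osteoblasts in contact with more than
    four osteoblasts, become osteoblasts (acquiring their polarity);
    osteoblasts that end up at the lateral periphery revert. Both checks
    use the same geometry snapshot to avoid within-iteration oscillation.
    """
    if geom is None:
        geom = condensation_geometry(state)
    if geom.height < cfg.height_differentiation_start:
        return state
    members = set(geom.member_indices.tolist())
    preobs = np.flatnonzero(state.kind == int(AgentKind.PRE_OSTEOBLAST))
    promote = []
    if len(preobs):
        tops = state.pos[preobs, 2] + state.radius[preobs]
        radial = np.linalg.norm(state.pos[preobs, :2] - geom.centroid_xy, axis=1)
        interior = (
            (tops < cfg.height_interior_max)
            & (tops > INTERIOR_MIN_TOP)
            & (tops <= geom.height - cfg.interior_margin)
            & (radial <= geom.lateral_radius - cfg.interior_margin)
            & np.array([i in members for i in preobs])
        )
        obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
        contact = np.zeros(len(preobs), dtype=int)
        if len(obs):
            tree = cKDTree(state.pos[obs])
            # "in contact with" counts touching osteoblasts, not the whole
            # vicinity band: the looser band would cascade-convert every
            # pre-osteoblast near the osteoblastic core
            touch = 2 * state.radius[preobs].mean() + PLACEMENT_TOLERANCE
            contact = np.asarray(
                tree.query_ball_point(state.pos[preobs], touch, return_length=True)
            )
        eligible = preobs[interior | (contact > cfg.osteoblast_contact_for_differentiation)]
        # adopting the osteoblastic phenotype takes time: eligible cells
        # convert stochastically, which keeps a standing proliferative
        # pre-osteoblast population while the condensation still grows
        promote = eligible[rng.random(len(eligible)) < cfg.ob_differentiation_rate]
        for i in promote:
            state.kind[i] = int(AgentKind.OSTEOBLAST)
            state.next_deposit[i] = state.iteration + cfg.deposition_interval_iters(rng)
            state.polarity[i] = np.nan
            assign_polarity(int(i), state, cfg, rng)

    # periphery reversal, same geometry snapshot
    obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
    if len(obs):
        radial = np.linalg.norm(state.pos[obs, :2] - geom.centroid_xy, axis=1)
        revert = obs[radial > geom.lateral_radius - cfg.interior_margin]
        state.kind[revert] = int(AgentKind.PRE_OSTEOBLAST)
        state.polarity[revert] = np.nan
        state.next_division[revert] = state.iteration + cfg.division_interval_iters(rng)
    return state


# ---------------------------------------------------------------------------
# osteoid deposition, switch-off, mineralisation
# ---------------------------------------------------------------------------

def deposit_osteoid(
    index: int,
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    geom: Optional[CondensationGeometry] = None,
    matrix_tree: Optional[cKDTree] = None,
    all_tree: Optional[cKDTree] = None,
    new_positions: Optional[list] = None,
) -> Optional[int]:
    """One deposition attempt: extend the osteoblast's matrix seam by one
    osteoid agent along its polarity direction.

    The deposit lands on the first available site along the polarity ray
    (up to ``cfg.deposition_reach`` diameters out), so secretion in a fixed
    direction keeps adding to the same advancing seam. A site is available
    when no other matrix overlaps it (matrix is immobile, so matrix-matrix
    overlap is never created) and no cell core sits on it; cells merely
    nearby do not block — osteoid wedges into the interstices of the
    cellular fabric and the overlap mechanics relaxes the crowding, which
    is how osteoblasts end up caged in matrix without being displaced out
    of the condensation. Returns the new agent index, or None when gated
    (height window, H4 switch-off, timer) or blocked (no available site
    along the ray). Attempts are strictly periodic: the timer is redrawn
    whether or not osteoid was placed.
    """
    if AgentKind(int(state.kind[index])) is not AgentKind.OSTEOBLAST:
        return None
    if state.next_deposit[index] > state.iteration:
        return None
    if geom is None:
        geom = condensation_geometry(state)
    if not (cfg.height_deposition_start <= geom.height <= cfg.height_growth_stop):
        return None
    if state.switched_off_until[index] >= state.iteration:
        return None
    state.next_deposit[index] = state.iteration + cfg.deposition_interval_iters(rng)
    direction = assign_polarity(index, state, cfg, rng)
    r = float(state.radius[index])
    if new_positions is None:
        new_positions = []
    if all_tree is None:
        all_tree = cKDTree(state.pos)
    if matrix_tree is None:
        matrix = np.flatnonzero(state.kind_mask(*MATRIX_KINDS))
        matrix_tree = cKDTree(state.pos[matrix]) if len(matrix) else None

    def try_ray(ray: np.ndarray) -> Optional[int]:
        for k in range(1, cfg.deposition_reach + 1):
            target = state.pos[index] + ray * 2 * r * k
            if not state.dish.contains(target, r):
                return None
            occupied = (
                matrix_tree is not None
                and matrix_tree.query_ball_point(target, MATRIX_SPACING, return_length=True) > 0
            ) or any(np.linalg.norm(p - target) < MATRIX_SPACING for p in new_positions)
            if not occupied:
                near = np.array(
                    all_tree.query_ball_point(target, DEPOSITION_CELL_CLEARANCE), dtype=int
                )
                occupied = len(near) > 0 and bool(state.kind_mask(*CELL_KINDS)[near].any())
            if occupied:
                continue
            new = state.add(AgentKind.OSTEOID, target)[0]
            new_positions.append(target)
            return int(new)
        return None

    placed = try_ray(direction)
    if placed is None and direction[2] < 1.0:
        # the seam is saturated: secreted matrix cannot vanish, so the
        # overflow appositions onto the free surface above the osteoblast
        placed = try_ray(np.array([0.0, 0.0, 1.0]))
    return placed


def deposition_phase(
    state: WorldState, cfg: SimulationConfig, rng: np.random.Generator, geom: CondensationGeometry
) -> int:
    """All due deposition attempts for one iteration; returns deposit count."""
    if not (cfg.height_deposition_start <= geom.height <= cfg.height_growth_stop):
        return 0
    due = np.flatnonzero(
        (state.kind == int(AgentKind.OSTEOBLAST))
        & (state.next_deposit <= state.iteration)
        & (state.switched_off_until < state.iteration)
    )
    if len(due) == 0:
        return 0
    all_tree = cKDTree(state.pos)
    matrix = np.flatnonzero(state.kind_mask(*MATRIX_KINDS))
    matrix_tree = cKDTree(state.pos[matrix]) if len(matrix) else None
    new_positions: list = []
    deposits = 0
    for k in rng.permutation(len(due)):
        if (
            deposit_osteoid(
                int(due[k]),
                state,
                cfg,
                rng,
                geom=geom,
                matrix_tree=matrix_tree,
                all_tree=all_tree,
                new_positions=new_positions,
            )
            is not None
        ):
            deposits += 1
    return deposits


def h4_apply_switch_off(
    state: WorldState, cfg: SimulationConfig, rng: np.random.Generator
) -> WorldState:
    """Hypothesis-#4 secretion switch-off bookkeeping.

    From the onset iteration, every osteoblast is switched off with
    per-iteration probability equal to the population fraction, for the
    configured period (indefinite when the period is None); a fresh draw
    refreshes the off-window. With fraction 0 the rule is inert and H4
    reduces exactly to H3.
    """
    if cfg.hypothesis != "H4" or cfg.h4_switch_off_fraction <= 0:
        return state
    if state.iteration < cfg.h4_switch_off_onset:
        return state
    obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
    if len(obs) == 0:
        return state
    hit = obs[rng.random(len(obs)) < cfg.h4_switch_off_fraction]
    state.switched_off_until[hit] = state.iteration + cfg.h4_switch_off_period_iters
    return state


def mineralise_step(
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    geom: Optional[CondensationGeometry] = None,
) -> WorldState:
    """Stochastic osteoid mineralisation, gated at 100 um height.

    Each osteoid agent passes two sequential Bernoulli gates (probability
    ``cfg.mineral_gate_p`` per gate per iteration, one gate per iteration);
    passing both turns it into mineralised osteoid, so the fastest possible
    conversion takes two iterations and the mean time is ~2/p.
    """
    if geom is None:
        geom = condensation_geometry(state)
    if geom.height < cfg.height_mineralisation_start:
        return state
    osteoid = np.flatnonzero(state.kind == int(AgentKind.OSTEOID))
    if len(osteoid) == 0:
        return state
    draws = rng.random(len(osteoid)) < cfg.mineral_gate_p
    second = state.gate1[osteoid]
    mineralise = osteoid[second & draws]
    pass_first = osteoid[~second & draws]
    state.gate1[pass_first] = True
    state.kind[mineralise] = int(AgentKind.MINERALISED_OSTEOID)
    return state


def differentiate_osteoblasts(
    state: WorldState, cfg: SimulationConfig, geom: Optional[CondensationGeometry] = None
) -> WorldState:
    """Osteoblast -> osteocyte entrapment, gated at 100 um height.

    An osteoblast whose contact set (touching or within the vicinity band)
    holds at least ``cfg.mineralised_neighbors_for_osteocyte`` mineralised
    matrix agents terminally differentiates.
    """
    if geom is None:
        geom = condensation_geometry(state)
    if geom.height < cfg.height_mineralisation_start:
        return state
    obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
    mins = np.flatnonzero(state.kind == int(AgentKind.MINERALISED_OSTEOID))
    if len(obs) == 0 or len(mins) == 0:
        return state
    tree = cKDTree(state.pos[mins])
    touch = 2 * state.radius[obs].mean() + cfg.neighbor_gap_max
    counts = np.asarray(tree.query_ball_point(state.pos[obs], touch, return_length=True))
    entombed = obs[counts >= cfg.mineralised_neighbors_for_osteocyte]
    state.kind[entombed] = int(AgentKind.OSTEOCYTE)
    state.polarity[entombed] = np.nan
    return state


def apoptosis_step(
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    geom: Optional[CondensationGeometry] = None,
) -> int:
    """Stochastic removal of undifferentiated osteoblasts.

    Fires only after the nodule has acquired its maximum height (110 um);
    each osteoblast is removed with per-iteration probability
    ``cfg.apoptosis_rate``. Returns the number of removals.
    """
    if geom is None:
        geom = condensation_geometry(state)
    if geom.height < cfg.height_growth_stop:
        return 0
    obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
    if len(obs) == 0:
        return 0
    doomed = obs[rng.random(len(obs)) < cfg.apoptosis_rate]
    if len(doomed):
        mask = np.zeros(state.n, dtype=bool)
        mask[doomed] = True
        state.remove(mask)
    return len(doomed)
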