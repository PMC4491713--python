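"""Domain types, units and configuration for the condensation model.

The model simulates in vitro intramembranous osteogenesis in a cuboidal
virtual culture dish: a monolayer of precursor mesenchymal cells grows to
confluence, a stochastic subset differentiates into migratory
pre-osteoblasts that aggregate at the skeletogenic site (the dish centre),
proliferate in 3D into a condensation, differentiate into osteoblasts that
deposit osteoid, which mineralises and entraps osteoblasts as osteocytes.

All lengths are micrometres, all times are either hours (configuration) or
iterations (engine); one iteration corresponds to 20 physical minutes by
default, i.e. 72 iterations per simulated day.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml


class AgentKind(enum.IntEnum):
    """The six agent kinds of the model.

    Intermediate phenotypes (e.g. osteoid-osteocytes) are deliberately not
    modelled; matrix comes in exactly two flavours, unmineralised and
    mineralised.
    """

    PRECURSOR = 0
    PRE_OSTEOBLAST = 1
    OSTEOBLAST = 2
    OSTEOID = 3
    MINERALISED_OSTEOID = 4
    OSTEOCYTE = 5


#: kinds that are cells (displaceable by mechanics)
CELL_KINDS = frozenset(
    {AgentKind.PRECURSOR, AgentKind.PRE_OSTEOBLAST, AgentKind.OSTEOBLAST, AgentKind.OSTEOCYTE}
)
#: kinds that are extracellular matrix (immobile once placed)
MATRIX_KINDS = frozenset({AgentKind.OSTEOID, AgentKind.MINERALISED_OSTEOID})
#: kinds that can belong to the condensation (everything but the basal monolayer)
CONDENSATION_KINDS = frozenset(
    {
        AgentKind.PRE_OSTEOBLAST,
        AgentKind.OSTEOBLAST,
        AgentKind.OSTEOID,
        AgentKind.MINERALISED_OSTEOID,
        AgentKind.OSTEOCYTE,
    }
)

KIND_NAMES = {k: k.name.lower() for k in AgentKind}


class ConfigError(ValueError):
    """Raised for unknown variants/keys or out-of-range configuration values."""


@dataclass
class Agent:
    """A single spherical agent (cell or matrix voxel).

    This is a convenience record view; the engine stores the population in
    struct-of-arrays form (:class:`WorldState`).
    """

    id: int
    kind: AgentKind
    position: np.ndarray  # (3,) centre, um
    radius: float = 10.0
    polarity: Optional[np.ndarray] = None  # unit 3-vector, osteoid deposition direction
    age_iters: int = 0
    last_division_iter: int = 0
    deposition_timer: int = 0
    switched_off_until: Optional[float] = None
    mineral_gate1_passed: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("agent radius must be positive")
        if self.polarity is not None:
            self.polarity = np.asarray(self.polarity, dtype=float)
            n = np.linalg.norm(self.polarity)
            if not math.isclose(n, 1.0, rel_tol=1e-6):
                raise ValueError("polarity must be a unit vector")


@dataclass
class Dish:
    """The virtual culture dish: an axis-aligned box with hard walls."""

    extent: np.ndarray = field(default_factory=lambda: np.array([300.0, 300.0, 300.0]))
    focal_point: Optional[np.ndarray] = None  # (x, y) skeletogenic site; default centre
    floor_z: float = 0.0

    def __post_init__(self):
        self.extent = np.asarray(self.extent, dtype=float)
        if self.focal_point is None:
            self.focal_point = self.extent[:2] / 2.0
        else:
            self.focal_point = np.asarray(self.focal_point, dtype=float)

    def clamp(self, positions: np.ndarray, radius: float = 10.0) -> np.ndarray:
        """Clamp centres into [radius, extent - radius] per axis."""
        lo = np.array([radius, radius, self.floor_z + radius])
        hi = self.extent - radius
        return np.clip(positions, lo, hi)

    def contains(self, position: np.ndarray, radius: float = 10.0) -> bool:
        lo = np.array([radius, radius, self.floor_z + radius])
        hi = self.extent - radius
        return bool(np.all(position >= lo - 1e-9) and np.all(position <= hi + 1e-9))


class Hypothesis(str, enum.Enum):
    H1 = "H1"  # apolar: fresh random deposition direction every interval
    H2 = "H2"  # cell polarity: direction drawn once per osteoblast
    H3 = "H3"  # layer polarity: direction shared within a z-layer
    H4 = "H4"  # layer polarity + stochastic secretion switch-off


# (field, value) overrides per named variant; everything else is the h3 baseline
_VARIANTS = {
    "h1": {"hypothesis": "H1"},
    "h2": {"hypothesis": "H2"},
    "h3": {},
    "h4": {"hypothesis": "H4", "h4_switch_off_fraction": 0.30, "h4_switch_off_period_h": None},
    # Sensitivity suite: each row differs from h3 in exactly the fields below.
    "S1": {"division_jitter_h": 3.0},
    "S2": {"division_jitter_h": 1.0},
    "S3": {"division_interval_h": 8.0},
    "S4": {"mineralised_neighbors_for_osteocyte": 4},
    "S5": {"deposition_interval_h": 6.0},
    "S6": {"deposition_jitter_h": 3.0},
    "S7": {"deposition_interval_h": 1.0},
    "S8": {"deposition_interval_h": 1.0, "division_interval_h": 18.0},
    # Remodelling mechanisms: matrix overproduction / low osteoblast vigour.
    "r1": {"deposition_interval_h": 1.0},
    "r2": {"division_interval_h": 18.0, "deposition_interval_h": 36.0},
}

VARIANT_NAMES = tuple(_VARIANTS) + ("custom",)


@dataclass
class SimulationConfig:
    """Every tunable parameter of the model plus engine/RNG settings.

    Defaults reproduce the hypothesis-#3 baseline. Heights are gates on the
    condensation height (max z-top of condensation agents above the dish
    floor): differentiation starts at 50 um, osteoid deposition at 70 um,
    interior cells sit below 80 um, proliferation stops at 90 um,
    mineralisation starts at 100 um and all growth stops beyond 110 um.
    """

    hypothesis: str = "H3"
    minutes_per_iteration: float = 20.0
    n_iterations: int = 5000
    seed: int = 0

    # proliferation
    division_interval_h: float = 12.0
    division_jitter_h: float = 0.0
    critical_neighbors_2d: int = 4
    critical_neighbors_3d: int = 6

    # matrix deposition
    deposition_interval_h: float = 18.0
    deposition_jitter_h: float = 0.0

    # migration
    migration_speed: float = 0.2  # um per second (nominal in vitro speed)
    migration_step_um: float = 2.0  # effective planar displacement per iteration
    migration_literal: bool = False  # if True, use speed * 60 * minutes_per_iteration

    # mechanics
    neighbor_gap_max: float = 10.0
    alpha_no_overlap: float = 0.06
    alpha_overlap: float = 0.4

    # geometry gates (um)
    height_differentiation_start: float = 50.0
    height_deposition_start: float = 70.0
    height_interior_max: float = 80.0
    height_proliferation_stop: float = 90.0
    height_mineralisation_start: float = 100.0
    height_growth_stop: float = 110.0
    interior_margin: float = 20.0

    # differentiation
    ob_differentiation_rate: float = 0.007  # per-iteration prob. for eligible pre-osteoblasts
    mineralised_neighbors_for_osteocyte: int = 6
    osteoblast_contact_for_differentiation: int = 4  # "more than four" -> > 4
    layer_halfwidth: float = 10.0
    layer_regions: tuple = ((10.0, 30.0), (30.0, 50.0), (50.0, 70.0), (70.0, 90.0))

    # hypothesis #4 secretion switch-off
    h4_switch_off_fraction: float = 0.0
    h4_switch_off_period_h: Optional[float] = None  # None = indefinite
    h4_switch_off_onset: int = 0

    # calibration parameters (unreported in the source system; fixed once on
    # the h3 baseline and frozen for every other experiment)
    precursor_to_preob_fraction: float = 0.55
    mineral_gate_p: float = 0.03
    apoptosis_rate: float = 0.002
    polarity_distribution: str = "tilted"  # tilted | sphere | hemisphere | axis5 | axis6 | down
    polarity_tilt: float = 0.5  # z-component of the "tilted" direction set
    # per-z-region climb of the layer polarity (deep layers deposit nearly
    # laterally onto the substrate, upper layers toward the growing front)
    polarity_tilt_profile: tuple = (0.15, 0.3, 0.5, 0.5)
    polarity_azimuth_jitter: float = 0.7  # per-osteoblast scatter around the layer azimuth, rad
    deposition_reach: int = 7  # max seam advance along the polarity ray, diameters

    # dish
    dish_extent: tuple = (300.0, 300.0, 300.0)
    agent_radius: float = 10.0

    def __post_init__(self):
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.hypothesis not in ("H1", "H2", "H3", "H4"):
            raise ConfigError(f"hypothesis must be H1..H4, got {self.hypothesis!r}")
        heights = (
            self.height_differentiation_start,
            self.height_deposition_start,
            self.height_interior_max,
            self.height_proliferation_stop,
            self.height_mineralisation_start,
            self.height_growth_stop,
        )
        if not all(a < b for a, b in zip(heights, heights[1:])):
            raise ConfigError(f"height gates must be strictly increasing, got {heights}")
        for name in (
            "minutes_per_iteration",
            "division_interval_h",
            "deposition_interval_h",
            "migration_step_um",
            "neighbor_gap_max",
            "agent_radius",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "h4_switch_off_fraction",
            "precursor_to_preob_fraction",
            "mineral_gate_p",
            "apoptosis_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_iterations < 0:
            raise ConfigError("n_iterations must be >= 0")
        if self.division_jitter_h < 0 or self.deposition_jitter_h < 0:
            raise ConfigError("interval jitter must be >= 0")
        if self.polarity_distribution not in (
            "sphere",
            "hemisphere",
            "tilted",
            "axis5",
            "axis6",
            "down",
        ):
            raise ConfigError(f"unknown polarity_distribution {self.polarity_distribution!r}")

    # -- derived quantities ---------------------------------------------
    @property
    def iterations_per_day(self) -> int:
        return hours_to_iterations(24.0, self.minutes_per_iteration)

    def division_interval_iters(self, rng=None) -> int:
        return self._interval(self.division_interval_h, self.division_jitter_h, rng)

    def deposition_interval_iters(self, rng=None) -> int:
        return self._interval(self.deposition_interval_h, self.deposition_jitter_h, rng)

    def _interval(self, mean_h: float, jitter_h: float, rng) -> int:
        h = mean_h
        if jitter_h > 0 and rng is not None:
            h = rng.uniform(mean_h - jitter_h, mean_h + jitter_h)
        return max(1, hours_to_iterations(h, self.minutes_per_iteration))

    @property
    def h4_switch_off_period_iters(self) -> float:
        """Switch-off duration in iterations; math.inf when indefinite."""
        if self.h4_switch_off_period_h is None:
            return math.inf
        return hours_to_iterations(self.h4_switch_off_period_h, self.minutes_per_iteration)

    def migration_step(self) -> float:
        if self.migration_literal:
            return self.migration_speed * 60.0 * self.minutes_per_iteration
        return self.migration_step_um

    def make_dish(self) -> Dish:
        return Dish(extent=np.asarray(self.dish_extent, dtype=float))

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layer_regions"] = [list(r) for r in self.layer_regions]
        d["dish_extent"] = list(self.dish_extent)
        d["polarity_tilt_profile"] = list(self.polarity_tilt_profile)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "layer_regions" in d:
            d["layer_regions"] = tuple(tuple(r) for r in d["layer_regions"])
        if "dish_extent" in d:
            d["dish_extent"] = tuple(d["dish_extent"])
        if "polarity_tilt_profile" in d:
            d["polarity_tilt_profile"] = tuple(d["polarity_tilt_profile"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def hours_to_iterations(h: float, minutes_per_iteration: float = 20.0) -> int:
    """Convert hours to engine iterations (rounded to nearest)."""
    if h < 0:
        raise ValueError("hours must be >= 0")
    if minutes_per_iteration <= 0:
        raise ValueError("minutes_per_iteration must be > 0")
    return int(round(h * 60.0 / minutes_per_iteration))


def variant_overrides(variant_name: str) -> dict:
    """The (field, value) pairs by which a named variant differs from h3."""
    if variant_name not in _VARIANTS:
        raise ConfigError(
            f"unknown variant {variant_name!r}; expected one of {sorted(_VARIANTS)} or 'custom'"
        )
    return dict(_VARIANTS[variant_name])


def build_config(variant_name: str, overrides: Optional[dict] = None) -> SimulationConfig:
    """Build a validated configuration for a named variant.

    ``variant_name`` is one of h1..h4, S1..S8, r1, r2 or "custom"; unknown
    names and unknown override keys raise :class:`ConfigError`. With no
    overrides, "h3" yields the baseline model.
    """
    base: dict = {}
    if variant_name != "custom":
        base.update(variant_overrides(variant_name))
    if overrides:
        base.update(overrides)
    return SimulationConfig.from_dict(base)


class WorldState:
    """The whole simulated population in struct-of-arrays form.

    Per-agent columns: id, kind, position (N, 3), radius, polarity (N, 3;
    NaN when unset), arrived flag (pre-osteoblasts that reached the
    skeletogenic site), born_iter, next_division, next_deposit,
    switched_off_until (-inf when never switched off), mineral gate-1 flag.
    """

    _COLUMNS = (
        "ids",
        "kind",
        "pos",
        "radius",
        "polarity",
        "arrived",
        "born_iter",
        "next_division",
        "next_deposit",
        "switched_off_until",
        "gate1",
    )

    def __init__(self, dish: Dish, iteration: int = 0):
        self.dish = dish
        self.iteration = iteration
        self.confluent_since: Optional[int] = None
        self.preobs_seeded = False
        self.layer_polarities: dict[int, np.ndarray] = {}
        self.next_id = 0
        self.ids = np.empty(0, dtype=np.int64)
        self.kind = np.empty(0, dtype=np.int8)
        self.pos = np.empty((0, 3), dtype=float)
        self.radius = np.empty(0, dtype=float)
        self.polarity = np.empty((0, 3), dtype=float)
        self.arrived = np.empty(0, dtype=bool)
        self.born_iter = np.empty(0, dtype=np.int64)
        self.next_division = np.empty(0, dtype=np.int64)
        self.next_deposit = np.empty(0, dtype=np.int64)
        self.switched_off_until = np.empty(0, dtype=float)
        self.gate1 = np.empty(0, dtype=bool)

    # -- population management -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def add(
        self,
        kind: AgentKind,
        positions: np.ndarray,
        polarity: Optional[np.ndarray] = None,
        arrived: bool = False,
        next_division: int = np.iinfo(np.int64).max,
        next_deposit: int = np.iinfo(np.int64).max,
    ) -> np.ndarray:
        """Append agents of one kind; returns their integer indices."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        m = len(positions)
        new_ids = np.arange(self.next_id, self.next_id + m, dtype=np.int64)
        self.next_id += m
        self.ids = np.concatenate([self.ids, new_ids])
        self.kind = np.concatenate([self.kind, np.full(m, int(kind), dtype=np.int8)])
        self.pos = np.vstack([self.pos, positions])
        self.radius = np.concatenate([self.radius, np.full(m, 10.0)])
        pol = np.full((m, 3), np.nan) if polarity is None else np.atleast_2d(polarity)
        self.polarity = np.vstack([self.polarity, pol])
        self.arrived = np.concatenate([self.arrived, np.full(m, arrived)])
        self.born_iter = np.concatenate([self.born_iter, np.full(m, self.iteration, dtype=np.int64)])
        self.next_division = np.concatenate(
            [self.next_division, np.full(m, next_division, dtype=np.int64)]
        )
        self.next_deposit = np.concatenate(
            [self.next_deposit, np.full(m, next_deposit, dtype=np.int64)]
        )
        self.switched_off_until = np.concatenate([self.switched_off_until, np.full(m, -np.inf)])
        self.gate1 = np.concatenate([self.gate1, np.zeros(m, dtype=bool)])
        return np.arange(self.n - m, self.n)

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, dtype=bool)
        for col in self._COLUMNS:
            setattr(self, col, getattr(self, col)[keep])

    def copy(self) -> "WorldState":
        out = WorldState(Dish(self.dish.extent.copy(), self.dish.focal_point.copy(), self.dish.floor_z))
        out.iteration = self.iteration
        out.confluent_since = self.confluent_since
        out.preobs_seeded = self.preobs_seeded
        out.layer_polarities = {k: v.copy() for k, v in self.layer_polarities.items()}
        out.next_id = self.next_id
        for col in self._COLUMNS:
            setattr(out, col, getattr(self, col).copy())
        return out

    # -- queries -----------------------------------------------------------
    def census(self) -> dict[str, int]:
        counts = np.bincount(self.kind, minlength=len(AgentKind))
        return {KIND_NAMES[k]: int(counts[int(k)]) for k in AgentKind}

    def kind_mask(self, *kinds: AgentKind) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        for k in kinds:
            mask |= self.kind == int(k)
        return mask

    def get_agent(self, index: int) -> Agent:
        """Materialise one agent as an :class:`Agent` record."""
        pol = self.polarity[index]
        off = self.switched_off_until[index]
        return Agent(
            id=int(self.ids[index]),
            kind=AgentKind(int(self.kind[index])),
            position=self.pos[index].copy(),
            radius=float(self.radius[index]),
            polarity=None if np.any(np.isnan(pol)) else pol.copy(),
            age_iters=int(self.iteration - self.born_iter[index]),
            last_division_iter=int(self.next_division[index]),
            switched_off_until=None if off == -np.inf else float(off),
            mineral_gate1_passed=bool(self.gate1[index]),
        )

    def validate(self) -> None:
        assert len(np.unique(self.ids)) == self.n, "agent ids must be unique"
        assert sum(self.census().values()) == self.n
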