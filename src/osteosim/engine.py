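"""Synchronous, phase-ordered simulation engine.

One iteration applies the phases in a fixed order — migration, division,
precursor differentiation (at confluence), pre-osteoblast differentiation
and periphery reversal, H4 switch-off bookkeeping, osteoid deposition,
mineralisation, osteoblast entrapment, apoptosis, overlap resolution —
with within-phase agent order shuffled from the run's seeded RNG. All
stochastic draws come from named substreams of a single root seed, so a
(config, seed) pair fully determines the trajectory.

Days are 72 iterations (24 h at 20 min/iteration). Post-confluence days
("day N pc") count from the iteration at which the precursor monolayer
first becomes confluent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behaviors, mechanics
from .core import (
    AgentKind,
    Dish,
    KIND_NAMES,
    SimulationConfig,
    WorldState,
)

#: substreams, spawned in this fixed order from the root seed
SUBSTREAMS = (
    "init",
    "mechanics",
    "division",
    "differentiation",
    "polarity",
    "deposition",
    "mineralisation",
    "apoptosis",
    "h4",
    "resorption",
)

_EVENT_KINDS = {
    AgentKind.PRE_OSTEOBLAST: "first_pre_osteoblast",
    AgentKind.OSTEOBLAST: "first_osteoblast",
    AgentKind.OSTEOID: "first_osteoid",
    AgentKind.MINERALISED_OSTEOID: "first_mineralised",
    AgentKind.OSTEOCYTE: "first_osteocyte",
}


def make_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One named PCG64 substream per stochastic phase."""
    seqs = np.random.SeedSequence(seed).spawn(len(SUBSTREAMS))
    return {name: np.random.default_rng(seq) for name, seq in zip(SUBSTREAMS, seqs)}


def rng_states(rngs: dict) -> dict:
    return {name: rng.bit_generator.state for name, rng in rngs.items()}


def restore_rngs(states: dict) -> dict[str, np.random.Generator]:
    rngs = {}
    for name, st in states.items():
        gen = np.random.default_rng(0)
        gen.bit_generator.state = st
        rngs[name] = gen
    return rngs


@dataclass
class Trajectory:
    """Per-day census, condensation height series, event log and final state."""

    config: SimulationConfig
    records: list = field(default_factory=list)
    events: dict = field(default_factory=dict)
    confluent_since: Optional[int] = None
    final_state: Optional[WorldState] = None

    @property
    def census(self) -> pd.DataFrame:
        """Wide per-sample table: iteration, day, day_pc, height, one column per kind."""
        return pd.DataFrame(self.records)

    def counts(self, kind: AgentKind) -> pd.Series:
        df = self.census
        return df.set_index("iteration")[KIND_NAMES[kind]]

    def final_count(self, kind: AgentKind) -> int:
        if self.final_state is None:
            return int(self.records[-1][KIND_NAMES[kind]])
        return self.final_state.census()[KIND_NAMES[kind]]

    def day_pc(self, iteration: int) -> Optional[float]:
        if self.confluent_since is None or iteration < self.confluent_since:
            return None
        return (iteration - self.confluent_since) / self.config.iterations_per_day


def initial_state(cfg: SimulationConfig) -> WorldState:
    """Five precursor cells near one corner of an otherwise empty dish."""
    dish = cfg.make_dish()
    state = WorldState(dish)
    r = cfg.agent_radius
    z = dish.floor_z + r
    base = np.array([40.0, 40.0])
    offsets = np.array([[0, 0], [25, 0], [0, 25], [25, 25], [12.5, 12.5]], dtype=float)
    pos = np.column_stack([base[0] + offsets[:, 0], base[1] + offsets[:, 1], np.full(5, z)])
    state.add(AgentKind.PRECURSOR, pos, next_division=cfg.division_interval_iters())
    return state


def step(state: WorldState, cfg: SimulationConfig, rngs: dict) -> dict:
    """Advance the world by one iteration; returns the step's event counts.

    The agent ledger is conserved: agents after = before + births + deposits
    - apoptoses; no other phase creates or removes agents.
    """
    counts = {"births": 0, "deposits": 0, "apoptoses": 0}
    geom = behaviors.condensation_geometry(state)

    behaviors.migration_phase(state, cfg)
    counts["births"] = behaviors.division_phase(state, cfg, rngs["division"], geom)

    if state.confluent_since is None and behaviors.is_confluent(state, cfg):
        state.confluent_since = state.iteration
    if state.confluent_since is not None and not state.preobs_seeded:
        behaviors.differentiate_precursors(state, cfg, rngs["differentiation"])

    behaviors.differentiate_preosteoblasts(state, cfg, rngs["differentiation"], geom=geom)
    behaviors.h4_apply_switch_off(state, cfg, rngs["h4"])
    counts["deposits"] = behaviors.deposition_phase(state, cfg, rngs["deposition"], geom)
    behaviors.mineralise_step(state, cfg, rngs["mineralisation"], geom=geom)
    behaviors.differentiate_osteoblasts(state, cfg, geom=geom)
    counts["apoptoses"] = behaviors.apoptosis_step(state, cfg, rngs["apoptosis"], geom=geom)
    mechanics.resolve_overlaps(state, cfg, rngs["mechanics"])

    state.iteration += 1
    if not np.all(np.isfinite(state.pos)):
        raise FloatingPointError(
            f"non-finite agent position at iteration {state.iteration}"
        )
    return counts


def _record(traj: Trajectory, state: WorldState, cfg: SimulationConfig) -> None:
    ipd = cfg.iterations_per_day
    day_pc = None
    if state.confluent_since is not None and state.iteration >= state.confluent_since:
        day_pc = (state.iteration - state.confluent_since) // ipd
    traj.records.append(
        {
            "iteration": state.iteration,
            "day": state.iteration // ipd,
            "day_pc": day_pc,
            "height": behaviors.condensation_height(state),
            **state.census(),
        }
    )


def run(
    cfg: SimulationConfig,
    days_pc: Optional[int] = None,
    state: Optional[WorldState] = None,
    rngs: Optional[dict] = None,
    keep_final_state: bool = True,
) -> Trajectory:
    """Run the model and collect a per-day trajectory.

    Iterates :func:`step` until ``cfg.n_iterations`` or, when ``days_pc``
    is given, until that many 72-iteration days after first confluence
    (whichever comes first). ``state``/``rngs`` allow resuming a snapshot,
    e.g. after the resorption challenge.
    """
    cfg.validate()
    if state is None:
        state = initial_state(cfg)
    if rngs is None:
        rngs = make_rngs(cfg.seed)
    if cfg.hypothesis in ("H3", "H4"):
        behaviors.init_layer_polarities(state, cfg, rngs["polarity"])

    traj = Trajectory(config=cfg)
    traj.confluent_since = state.confluent_since
    ipd = cfg.iterations_per_day
    start_iter = state.iteration
    _record(traj, state, cfg)

    for kind, name in _EVENT_KINDS.items():
        if state.census()[KIND_NAMES[kind]] > 0:
            traj.events.setdefault(name, state.iteration)

    while state.iteration - start_iter < cfg.n_iterations:
        if days_pc is not None and state.confluent_since is not None:
            if state.iteration - state.confluent_since >= days_pc * ipd:
                break
        was_confluent = state.confluent_since is not None
        step(state, cfg, rngs)
        if not was_confluent and state.confluent_since is not None:
            traj.events["first_confluence"] = state.confluent_since
            traj.confluent_since = state.confluent_since
        census = state.census()
        for kind, name in _EVENT_KINDS.items():
            if name not in traj.events and census[KIND_NAMES[kind]] > 0:
                traj.events[name] = state.iteration
        anchor = state.confluent_since if state.confluent_since is not None else 0
        if (state.iteration - anchor) % ipd == 0:
            _record(traj, state, cfg)

    if traj.records[-1]["iteration"] != state.iteration:
        _record(traj, state, cfg)
    if keep_final_state:
        traj.final_state = state
    traj.rngs = rngs
    return traj


# ---------------------------------------------------------------------------
# snapshot I/O
# ---------------------------------------------------------------------------

_SNAPSHOT_COLUMNS = [
    "id",
    "kind",
    "x",
    "y",
    "z",
    "radius",
    "px",
    "py",
    "pz",
    "arrived",
    "born_iter",
    "next_division",
    "next_deposit",
    "switched_off_until",
    "gate1",
]


def write_snapshot(state: WorldState, path, rngs: Optional[dict] = None) -> None:
    """Write one agent per row (CSV) plus a JSON sidecar of world metadata.

    The round trip is lossless; serialising ``rngs`` as well makes a
    resumed run bitwise-identical to an uninterrupted one.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": state.ids,
            "kind": [AgentKind(int(k)).name for k in state.kind],
            "x": state.pos[:, 0],
            "y": state.pos[:, 1],
            "z": state.pos[:, 2],
            "radius": state.radius,
            "px": state.polarity[:, 0],
            "py": state.polarity[:, 1],
            "pz": state.polarity[:, 2],
            "arrived": state.arrived.astype(int),
            "born_iter": state.born_iter,
            "next_division": state.next_division,
            "next_deposit": state.next_deposit,
            "switched_off_until": state.switched_off_until,
            "gate1": state.gate1.astype(int),
        }
    )
    df.to_csv(path, index=False, columns=_SNAPSHOT_COLUMNS, float_format="%.17g")
    meta = {
        "iteration": state.iteration,
        "confluent_since": state.confluent_since,
        "preobs_seeded": state.preobs_seeded,
        "next_id": state.next_id,
        "dish_extent": state.dish.extent.tolist(),
        "focal_point": state.dish.focal_point.tolist(),
        "floor_z": state.dish.floor_z,
        "layer_polarities": {str(k): v.tolist() for k, v in state.layer_polarities.items()},
    }
    if rngs is not None:
        meta["rng_states"] = rng_states(rngs)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_snapshot(path):
    """Read a snapshot; returns (WorldState, rngs-or-None)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message plumbing
        raise ValueError(f"malformed snapshot {path}: {exc}") from exc
    missing = set(_SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed snapshot {path}: missing columns {sorted(missing)}")
    meta = json.loads(path.with_suffix(".json").read_text())
    dish = Dish(
        extent=np.array(meta["dish_extent"]),
        focal_point=np.array(meta["focal_point"]),
        floor_z=meta["floor_z"],
    )
    state = WorldState(dish, iteration=int(meta["iteration"]))
    state.confluent_since = meta["confluent_since"]
    state.preobs_seeded = bool(meta["preobs_seeded"])
    state.next_id = int(meta["next_id"])
    state.layer_polarities = {
        int(k): np.array(v) for k, v in meta["layer_polarities"].items()
    }
    state.ids = df["id"].to_numpy(np.int64)
    state.kind = np.array([int(AgentKind[name]) for name in df["kind"]], dtype=np.int8)
    state.pos = df[["x", "y", "z"]].to_numpy(float)
    state.radius = df["radius"].to_numpy(float)
    state.polarity = df[["px", "py", "pz"]].to_numpy(float)
    state.arrived = df["arrived"].to_numpy(bool)
    state.born_iter = df["born_iter"].to_numpy(np.int64)
    state.next_division = df["next_division"].to_numpy(np.int64)
    state.next_deposit = df["next_deposit"].to_numpy(np.int64)
    state.switched_off_until = df["switched_off_until"].to_numpy(float)
    state.gate1 = df["gate1"].to_numpy(bool)
    rngs = None
    if "rng_states" in meta:
        states = {}
        for name, st in meta["rng_states"].items():
            st = dict(st)
            if isinstance(st.get("state"), dict):
                st["state"] = {k: int(v) for k, v in st["state"].items()}
            states[name] = st
        rngs = restore_rngs(states)
    return state, rngs
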