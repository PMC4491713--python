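"""Named, reproducible experiment definitions.

Covers the hypothesis comparison (h1-h4), the sensitivity suite (S1-S8),
the H4 switch-off fraction/period sweep, and the resorption/remodelling
challenge (continue a resorbed condensation under h1-h4 or the two
pathological h3 variants r1 = matrix overproduction, r2 = low osteoblast
vigour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import behaviors, engine
from .core import AgentKind, SimulationConfig, build_config, WorldState

#: fraction of osteoblastic/pre-osteoblastic cells necrosed by the challenge
RESORPTION_NECROSIS_FRACTION = 0.5
#: condensation is cut down to this height by the challenge, um
RESORPTION_HEIGHT = 40.0


@dataclass
class ExperimentSpec:
    """A named configuration variant plus its replicate seeds."""

    name: str
    base_config: SimulationConfig
    seeds: list = field(default_factory=list)

    @property
    def replicates(self) -> int:
        return len(self.seeds)

    def config_for(self, seed: int) -> SimulationConfig:
        cfg = SimulationConfig.from_dict({**self.base_config.to_dict(), "seed": int(seed)})
        return cfg


def make_spec(name: str, seeds, overrides=None) -> ExperimentSpec:
    return ExperimentSpec(
        name=name, base_config=build_config(name, overrides or {}), seeds=list(seeds)
    )


def hypothesis_suite(seeds=range(11)) -> list[ExperimentSpec]:
    """The four entrapment hypotheses, n = 11 replicates each by default."""
    return [make_spec(name, seeds) for name in ("h1", "h2", "h3", "h4")]


def sensitivity_suite(seeds=range(3)) -> list[ExperimentSpec]:
    """S1-S8: the eight single-variation alterations of the h3 baseline.

    S1/S2 jitter the division interval (12 +- 3 / +- 1 h), S3 divides every
    8 h, S4 lowers the entrapment threshold to 4 mineralised neighbours,
    S5/S6/S7 alter the deposition interval (6 h, 18 +- 3 h, 1 h), and S8
    combines 1 h deposition with 18 h division.
    """
    return [make_spec(f"S{i}", seeds) for i in range(1, 9)]


def h4_sweep(seeds=range(3), onsets=(0, 300)) -> list[ExperimentSpec]:
    """The reported switch-off fraction x period grid, plus onset variants.

    Fractions 30%, 10% and 2% are crossed with indefinite, 2-day and 1-day
    switch-off periods; the 2%/1-day cell additionally varies the onset
    iteration, because its outcome depends on when the regime is applied.
    """
    specs = []
    periods = {"indef": None, "2d": 48.0, "1d": 24.0}
    for frac in (0.30, 0.10, 0.02):
        for pname, period in periods.items():
            name = f"h4_f{int(frac * 100)}_{pname}"
            overrides = {
                "h4_switch_off_fraction": frac,
                "h4_switch_off_period_h": period,
            }
            if frac == 0.02 and pname == "1d":
                for onset in onsets:
                    specs.append(
                        ExperimentSpec(
                            name=f"{name}_on{onset}",
                            base_config=build_config("h4", {**overrides, "h4_switch_off_onset": onset}),
                            seeds=list(seeds),
                        )
                    )
            else:
                specs.append(
                    ExperimentSpec(
                        name=name, base_config=build_config("h4", overrides), seeds=list(seeds)
                    )
                )
    return specs


def apply_resorption(
    state: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> WorldState:
    """The resorption challenge: cut the condensation down to 40 um.

    Removes every agent whose z-top exceeds 40 um, all mineralised osteoid
    and all osteocytes (necrosis), and a substantial seeded-random fraction
    of the remaining osteoblastic and pre-osteoblastic populations.
    Requires a mature condensation (>= 1 osteocyte).
    """
    census = state.census()
    if census["osteocyte"] < 1:
        raise ValueError("resorption challenge requires a mature condensation")
    tops = state.pos[:, 2] + state.radius - state.dish.floor_z
    doomed = tops > RESORPTION_HEIGHT
    doomed |= state.kind_mask(AgentKind.MINERALISED_OSTEOID, AgentKind.OSTEOCYTE)
    cells = np.flatnonzero(
        state.kind_mask(AgentKind.OSTEOBLAST, AgentKind.PRE_OSTEOBLAST) & ~doomed
    )
    if len(cells):
        necrosed = cells[rng.random(len(cells)) < RESORPTION_NECROSIS_FRACTION]
        doomed[necrosed] = True
    state.remove(doomed)
    # surviving osteoblasts resume deposition on their normal schedule
    obs = state.kind == int(AgentKind.OSTEOBLAST)
    state.next_deposit[obs] = np.minimum(
        state.next_deposit[obs], state.iteration + cfg.deposition_interval_iters()
    )
    return state


_REMODEL_VARIANTS = {"h1", "h2", "h3", "h4", "r1", "r2"}


def remodelling_experiment(
    mechanism: str,
    resorbed_state: WorldState,
    seed: int,
    days: int = 12,
) -> engine.Trajectory:
    """Continue a resorbed condensation under the chosen mechanism.

    r1 is h3 with sharply increased deposition (matrix overproduction); r2
    is h3 with slowed division and deposition (low osteoblast vigour).
    Recovery is recorded for ``days`` simulated days from the resumption.
    """
    if mechanism not in _REMODEL_VARIANTS:
        raise ValueError(f"mechanism must be one of {sorted(_REMODEL_VARIANTS)}")
    state = resorbed_state.copy()
    overrides = {"seed": int(seed)}
    if mechanism == "h4":
        overrides.update({"h4_switch_off_fraction": 0.30, "h4_switch_off_period_h": None})
    cfg = build_config(mechanism, overrides)
    cfg = SimulationConfig.from_dict(
        {**cfg.to_dict(), "n_iterations": days * cfg.iterations_per_day}
    )
    # recovery-time accounting starts at resumption
    return engine.run(cfg, state=state, rngs=engine.make_rngs(cfg.seed))


def run_spec(
    spec: ExperimentSpec, days_pc: int = 12, keep_final_state: bool = False
) -> list[engine.Trajectory]:
    """Run every replicate of one spec for ``days_pc`` post-confluence days."""
    out = []
    for seed in spec.seeds:
        cfg = spec.config_for(seed)
        out.append(engine.run(cfg, days_pc=days_pc, keep_final_state=keep_final_state))
    return out


def tidy_results(named_trajectories) -> "pd.DataFrame":
    """Long-format results table: spec, seed, day_pc, kind counts, height."""
    import pandas as pd

    rows = []
    for name, seed, traj in named_trajectories:
        for rec in traj.records:
            if rec["day_pc"] is None:
                continue
            for kind in AgentKind:
                rows.append(
                    {
                        "spec": name,
                        "seed": seed,
                        "day": int(rec["day_pc"]),
                        "kind": kind.name.lower(),
                        "count": rec[kind.name.lower()],
                        "height": rec["height"],
                    }
                )
    return pd.DataFrame(rows)


def mature_h3_state(seed: int, days_pc: int = 12) -> tuple[WorldState, SimulationConfig]:
    """A mature baseline condensation to challenge with resorption."""
    cfg = build_config("h3", {"seed": int(seed)})
    traj = engine.run(cfg, days_pc=days_pc)
    return traj.final_state, cfg
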