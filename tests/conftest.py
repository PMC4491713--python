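"""Shared fixtures: a session-scoped cache of full simulation runs.

Acceptance-level checks need many complete condensation runs (several
variants x several seeds); the cache makes every (variant, seed, days)
combination run exactly once per session, however many tests consume it.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteosim import build_config
from osteosim import engine
from osteosim.core import AgentKind, Dish, WorldState


class RunCache:
    def __init__(self):
        self._runs = {}

    def get(self, variant: str, seed: int, days_pc: int = 12, **overrides):
        key = (variant, seed, days_pc, tuple(sorted(overrides.items())))
        if key not in self._runs:
            cfg = build_config(variant, {"seed": seed, "n_iterations": 8000, **overrides})
            self._runs[key] = engine.run(cfg, days_pc=days_pc)
        return self._runs[key]

    def batch(self, variant: str, seeds, days_pc: int = 12, **overrides):
        return [self.get(variant, s, days_pc, **overrides) for s in seeds]


@pytest.fixture(scope="session")
def runcache():
    return RunCache()


@pytest.fixture
def empty_world():
    return WorldState(Dish())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_world(kinds_positions, dish=None) -> WorldState:
    """Small hand-built world: list of (AgentKind, (x, y, z)) tuples."""
    state = WorldState(dish or Dish())
    for kind, pos in kinds_positions:
        state.add(kind, np.asarray(pos, dtype=float))
    return state


@pytest.fixture
def tall_column():
    """Five stacked cells above the floor: condensation height 100 um."""
    return make_world(
        [(AgentKind.PRE_OSTEOBLAST, (150.0, 150.0, 10.0 + 20.0 * k)) for k in range(5)]
    )
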