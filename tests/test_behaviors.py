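"""Rule-level tests: proliferation, migration, differentiation, deposition,
switch-off, mineralisation and apoptosis."""

import numpy as np
import pytest

from osteosim.core import Agent, AgentKind, Dish, WorldState, build_config
from osteosim import behaviors
from osteosim.behaviors import (
    CondensationGeometry,
    apoptosis_step,
    assign_polarity,
    attempt_division,
    condensation_geometry,
    condensation_height,
    deposit_osteoid,
    differentiate_osteoblasts,
    differentiate_precursors,
    differentiate_preosteoblasts,
    h4_apply_switch_off,
    is_confluent,
    is_interior,
    layer_region_index,
    migration_phase,
    migration_velocity,
    mineralise_step,
    sample_direction,
)

from conftest import make_world


@pytest.fixture
def cfg():
    return build_config("h3")


def monolayer_grid(nx=6, ny=6, spacing=20.0, origin=(100.0, 100.0)):
    return make_world(
        [
            (AgentKind.PRECURSOR, (origin[0] + spacing * i, origin[1] + spacing * j, 10.0))
            for i in range(nx)
            for j in range(ny)
        ]
    )


class TestCondensationGeometry:
    def test_empty_world_has_zero_height(self, empty_world):
        assert condensation_height(empty_world) == 0.0

    def test_monolayer_alone_is_not_a_condensation(self):
        state = monolayer_grid()
        state.add(AgentKind.PRE_OSTEOBLAST, np.array([150.0, 150, 10]))
        assert condensation_height(state) == 0.0

    def test_five_stacked_cells_reach_100(self, tall_column):
        assert condensation_height(tall_column) == pytest.approx(100.0)

    def test_precursors_never_count(self):
        state = make_world([(AgentKind.PRECURSOR, (150, 150, 90))])
        assert condensation_height(state) == 0.0

    def test_geometry_centroid_and_radius(self):
        state = make_world(
            [
                (AgentKind.OSTEOBLAST, (100, 150, 50)),
                (AgentKind.OSTEOBLAST, (200, 150, 50)),
            ]
        )
        geom = condensation_geometry(state)
        np.testing.assert_allclose(geom.centroid_xy, [150, 150])
        assert geom.lateral_radius == pytest.approx(50.0)
        assert geom.height == pytest.approx(60.0)


class TestConfluence:
    def test_sparse_start_is_not_confluent(self, cfg):
        state = make_world(
            [(AgentKind.PRECURSOR, (40.0 + 25 * k, 40.0, 10.0)) for k in range(5)]
        )
        assert not is_confluent(state, cfg)

    def test_fully_packed_monolayer_is_confluent(self, cfg):
        state = make_world(
            [
                (AgentKind.PRECURSOR, (10.0 + 20 * i, 10.0 + 20 * j, 10.0))
                for i in range(15)
                for j in range(15)
            ]
        )
        assert is_confluent(state, cfg)

    def test_losing_interior_cells_reopens_the_monolayer(self, cfg):
        state = make_world(
            [
                (AgentKind.PRECURSOR, (10.0 + 20 * i, 10.0 + 20 * j, 10.0))
                for i in range(15)
                for j in range(15)
                if not (5 <= i <= 8 and 5 <= j <= 8)  # 16-cell hole
            ]
        )
        assert not is_confluent(state, cfg)


class TestDivision:
    def test_crowded_precursor_does_not_divide(self, cfg, rng):
        # plus-shape at 25-um spacing: centre has 4 in-band neighbours
        state = make_world(
            [
                (AgentKind.PRECURSOR, (150, 150, 10)),
                (AgentKind.PRECURSOR, (175, 150, 10)),
                (AgentKind.PRECURSOR, (125, 150, 10)),
                (AgentKind.PRECURSOR, (150, 175, 10)),
                (AgentKind.PRECURSOR, (150, 125, 10)),
            ]
        )
        state.next_division[:] = 0
        assert attempt_division(0, state, cfg, rng) is None
        assert state.n == 5

    def test_open_precursor_divides_in_plane(self, cfg, rng):
        state = make_world([(AgentKind.PRECURSOR, (150, 150, 10))])
        state.next_division[:] = 0
        daughter = attempt_division(0, state, cfg, rng)
        assert daughter == 1
        assert state.pos[1, 2] == 10.0  # same plane
        assert np.linalg.norm(state.pos[1] - state.pos[0]) == pytest.approx(20.0)
        assert state.next_division[0] > 0  # timer redrawn

    def test_division_timer_blocks_until_due(self, cfg, rng):
        state = make_world([(AgentKind.PRECURSOR, (150, 150, 10))])
        state.next_division[:] = 100
        assert attempt_division(0, state, cfg, rng) is None

    def test_unarrived_preosteoblast_does_not_divide(self, cfg, rng):
        state = make_world([(AgentKind.PRE_OSTEOBLAST, (150, 150, 10))])
        state.next_division[:] = 0
        assert attempt_division(0, state, cfg, rng) is None

    def test_arrived_preosteoblast_divides_in_3d(self, cfg, rng):
        state = make_world([(AgentKind.PRE_OSTEOBLAST, (150, 150, 50))])
        state.arrived[:] = True
        state.next_division[:] = 0
        daughter = attempt_division(0, state, cfg, rng)
        assert daughter == 1
        assert state.arrived[1]
        assert np.linalg.norm(state.pos[1] - state.pos[0]) == pytest.approx(20.0)

    def test_division_phase_respects_proliferation_stop_height(self, cfg, rng, tall_column):
        tall_column.arrived[:] = True
        tall_column.next_division[:] = 0
        geom = condensation_geometry(tall_column)  # height 100 >= 90
        births = behaviors.division_phase(tall_column, cfg, rng, geom)
        assert births == 0
        assert (tall_column.kind == int(AgentKind.PRE_OSTEOBLAST)).sum() == 5

    def test_osteoblasts_never_divide(self, cfg, rng):
        state = make_world([(AgentKind.OSTEOBLAST, (150, 150, 50))])
        state.next_division[:] = 0
        assert attempt_division(0, state, cfg, rng) is None


class TestMigration:
    def test_velocity_points_at_the_focal_point(self, cfg):
        agent = Agent(id=0, kind=AgentKind.PRE_OSTEOBLAST, position=[200.0, 200, 10])
        v = migration_velocity(agent, Dish(), cfg)
        np.testing.assert_allclose(v, cfg.migration_step() * np.array([-1, -1]) / np.sqrt(2))

    def test_speed_is_independent_of_distance(self, cfg):
        dish = Dish()
        near = Agent(id=0, kind=AgentKind.PRE_OSTEOBLAST, position=[180.0, 150, 10])
        far = Agent(id=1, kind=AgentKind.PRE_OSTEOBLAST, position=[280.0, 150, 10])
        assert np.linalg.norm(migration_velocity(near, dish, cfg)) == pytest.approx(
            np.linalg.norm(migration_velocity(far, dish, cfg))
        )

    def test_agent_at_focal_point_stops(self, cfg):
        agent = Agent(id=0, kind=AgentKind.PRE_OSTEOBLAST, position=[150.0, 150, 10])
        assert np.linalg.norm(migration_velocity(agent, Dish(), cfg)) == 0

    def test_phase_moves_and_arrives(self, cfg):
        state = make_world(
            [
                (AgentKind.PRE_OSTEOBLAST, (150, 155, 10)),  # within one diameter
                (AgentKind.PRE_OSTEOBLAST, (250, 150, 10)),  # far away
            ]
        )
        x_before = state.pos[1, 0]
        migration_phase(state, cfg)
        assert state.arrived[0]
        assert not state.arrived[1]
        assert state.pos[1, 0] == pytest.approx(x_before - cfg.migration_step())

    def test_contact_with_aggregate_is_arrival(self, cfg):
        state = make_world(
            [
                (AgentKind.PRE_OSTEOBLAST, (150, 150, 10)),
                (AgentKind.PRE_OSTEOBLAST, (170.5, 150, 10)),
            ]
        )
        state.arrived[0] = True
        migration_phase(state, cfg)
        assert state.arrived[1]


class TestPrecursorDifferentiation:
    def make_monolayer(self, n=225):
        return make_world(
            [
                (AgentKind.PRECURSOR, (10.0 + 20 * (k % 15), 10.0 + 20 * (k // 15), 10.0))
                for k in range(n)
            ]
        )

    @pytest.mark.parametrize("fraction, expected", [(0.0, 0), (1.0, 225), (0.2, 45)])
    def test_fraction_converted(self, fraction, expected, rng):
        cfg = build_config("h3", {"precursor_to_preob_fraction": fraction})
        state = self.make_monolayer()
        differentiate_precursors(state, cfg, rng)
        assert (state.kind == int(AgentKind.PRE_OSTEOBLAST)).sum() == expected

    def test_identical_seed_chooses_identical_cells(self):
        cfg = build_config("h3", {"precursor_to_preob_fraction": 0.2})
        picks = []
        for _ in range(2):
            state = self.make_monolayer()
            differentiate_precursors(state, cfg, np.random.default_rng(42))
            picks.append(frozenset(state.ids[state.kind == int(AgentKind.PRE_OSTEOBLAST)]))
        assert picks[0] == picks[1]

    def test_rule_fires_only_once(self, rng):
        cfg = build_config("h3", {"precursor_to_preob_fraction": 0.5})
        state = self.make_monolayer(100)
        differentiate_precursors(state, cfg, rng)
        converted = (state.kind == int(AgentKind.PRE_OSTEOBLAST)).sum()
        differentiate_precursors(state, cfg, rng)
        assert (state.kind == int(AgentKind.PRE_OSTEOBLAST)).sum() == converted


class TestInterior:
    geom = CondensationGeometry(
        height=90.0, centroid_xy=np.array([150.0, 150.0]), lateral_radius=80.0,
        member_indices=np.empty(0, dtype=int),
    )

    def agent(self, pos):
        return Agent(id=0, kind=AgentKind.PRE_OSTEOBLAST, position=np.asarray(pos, float))

    def test_central_mid_height_cell_is_interior(self, cfg):
        assert is_interior(self.agent([150, 150, 50]), self.geom, cfg)

    def test_cell_on_the_lateral_rim_is_not(self, cfg):
        assert not is_interior(self.agent([230, 150, 50]), self.geom, cfg)

    def test_cell_above_the_interior_gate_is_not(self, cfg):
        assert not is_interior(self.agent([150, 150, 75]), self.geom, cfg)  # top 85

    def test_cell_at_the_growing_top_surface_is_not(self, cfg):
        geom = CondensationGeometry(
            height=65.0, centroid_xy=np.array([150.0, 150.0]), lateral_radius=80.0,
            member_indices=np.empty(0, dtype=int),
        )
        assert not is_interior(self.agent([150, 150, 45]), geom, cfg)  # top 55 > 65-20

    def test_basal_plane_cell_is_not(self, cfg):
        assert not is_interior(self.agent([150, 150, 10]), self.geom, cfg)


class TestPolarity:
    @pytest.mark.parametrize("dist", ["sphere", "hemisphere", "tilted", "axis5", "axis6", "down"])
    def test_directions_are_unit_vectors(self, dist, rng):
        for _ in range(20):
            v = sample_direction(rng, dist, tilt=0.5)
            assert np.linalg.norm(v) == pytest.approx(1.0)
            if dist == "hemisphere":
                assert v[2] >= 0
            if dist == "tilted":
                assert v[2] == pytest.approx(0.5)
            if dist == "down":
                np.testing.assert_allclose(v, [0, 0, -1])

    def test_layer_region_lookup(self, cfg):
        assert layer_region_index(15, cfg) == 0
        assert layer_region_index(35, cfg) == 1
        assert layer_region_index(55, cfg) == 2
        assert layer_region_index(75, cfg) == 3
        assert layer_region_index(5, cfg) == 0  # clamped below
        assert layer_region_index(120, cfg) == 3  # clamped above

    def test_h2_polarity_is_immutable(self, rng):
        cfg = build_config("h2")
        state = make_world([(AgentKind.OSTEOBLAST, (150, 150, 50))])
        first = assign_polarity(0, state, cfg, rng)
        second = assign_polarity(0, state, cfg, rng)
        np.testing.assert_array_equal(first, second)

    def test_h1_redraws_every_call(self, rng):
        cfg = build_config("h1")
        state = make_world([(AgentKind.OSTEOBLAST, (150, 150, 50))])
        draws = np.array([assign_polarity(0, state, cfg, rng) for _ in range(10)])
        assert len(np.unique(draws.round(6), axis=0)) > 1

    def test_h1_sphere_draws_are_isotropic(self, rng):
        cfg = build_config("h1", {"polarity_distribution": "sphere"})
        state = make_world([(AgentKind.OSTEOBLAST, (150, 150, 50))])
        mean = np.mean([assign_polarity(0, state, cfg, rng) for _ in range(1000)], axis=0)
        assert np.linalg.norm(mean) < 0.1

    def test_h3_same_layer_shares_a_direction(self, rng):
        cfg = build_config("h3", {"polarity_azimuth_jitter": 0.0})
        state = make_world(
            [
                (AgentKind.OSTEOBLAST, (150, 150, 55)),
                (AgentKind.OSTEOBLAST, (170, 150, 60)),
                (AgentKind.OSTEOBLAST, (150, 170, 35)),
            ]
        )
        a = assign_polarity(0, state, cfg, rng)
        b = assign_polarity(1, state, cfg, rng)
        c = assign_polarity(2, state, cfg, rng)
        np.testing.assert_allclose(a, b)  # both in the 50-70 region
        assert not np.allclose(a, c)  # different region, different azimuth

    def test_non_osteoblast_rejected(self, cfg, rng):
        state = make_world([(AgentKind.PRECURSOR, (150, 150, 10))])
        with pytest.raises(ValueError):
            assign_polarity(0, state, cfg, rng)


def osteoblast_with_open_window(polarity=(0.0, 0.0, 1.0)):
    """One osteoblast plus enough matrix that the height sits in [70, 110]."""
    state = make_world(
        [(AgentKind.OSTEOBLAST, (150.0, 150.0, 50.0))]
        + [(AgentKind.MINERALISED_OSTEOID, (190.0, 150.0, 10.0 + 20 * k)) for k in range(4)]
    )
    state.polarity[0] = np.asarray(polarity)
    state.next_deposit[0] = 0
    return state


class TestDeposition:
    def test_deposit_extends_along_polarity(self, rng):
        cfg = build_config("h2")
        state = osteoblast_with_open_window()
        new = deposit_osteoid(0, state, cfg, rng)
        assert new is not None
        assert AgentKind(int(state.kind[new])) is AgentKind.OSTEOID
        np.testing.assert_allclose(state.pos[new], [150, 150, 70])
        assert state.next_deposit[0] > 0

    def test_below_the_window_nothing_is_deposited(self, rng):
        cfg = build_config("h2")
        state = make_world([(AgentKind.OSTEOBLAST, (150.0, 150.0, 30.0))])
        state.polarity[0] = [0, 0, 1.0]
        state.next_deposit[0] = 0
        assert deposit_osteoid(0, state, cfg, rng) is None  # height 40 < 70

    def test_seam_advances_past_existing_matrix(self, rng):
        cfg = build_config("h2")
        state = osteoblast_with_open_window()
        state.add(AgentKind.OSTEOID, np.array([150.0, 150.0, 70.0]))  # k=1 occupied
        new = deposit_osteoid(0, state, cfg, rng)
        np.testing.assert_allclose(state.pos[new], [150, 150, 90])

    def test_timer_gates_successive_deposits(self, rng):
        cfg = build_config("h2")
        state = osteoblast_with_open_window()
        assert deposit_osteoid(0, state, cfg, rng) is not None
        assert deposit_osteoid(0, state, cfg, rng) is None  # timer not due

    def test_only_osteoblasts_deposit(self, rng):
        cfg = build_config("h2")
        state = make_world([(AgentKind.PRE_OSTEOBLAST, (150, 150, 50))])
        state.next_deposit[0] = 0
        assert deposit_osteoid(0, state, cfg, rng) is None


class TestH4SwitchOff:
    def test_fraction_zero_is_inert(self, rng):
        cfg = build_config("h4", {"h4_switch_off_fraction": 0.0})
        state = osteoblast_with_open_window()
        h4_apply_switch_off(state, cfg, rng)
        assert np.all(state.switched_off_until == -np.inf)

    def test_fraction_one_silences_every_osteoblast(self, rng):
        cfg = build_config("h4", {"h4_switch_off_fraction": 1.0, "h4_switch_off_period_h": 24.0})
        state = osteoblast_with_open_window()
        h4_apply_switch_off(state, cfg, rng)
        assert state.switched_off_until[0] == state.iteration + 72
        assert deposit_osteoid(0, state, cfg, rng) is None

    def test_indefinite_period_never_expires(self, rng):
        cfg = build_config("h4", {"h4_switch_off_fraction": 1.0})
        state = osteoblast_with_open_window()
        h4_apply_switch_off(state, cfg, rng)
        assert np.isinf(state.switched_off_until[0])

    def test_onset_gates_the_rule(self, rng):
        cfg = build_config("h4", {"h4_switch_off_fraction": 1.0, "h4_switch_off_onset": 500})
        state = osteoblast_with_open_window()
        h4_apply_switch_off(state, cfg, rng)
        assert np.all(state.switched_off_until == -np.inf)

    def test_deposition_resumes_after_the_window(self, rng):
        cfg = build_config("h4", {"h4_switch_off_fraction": 1.0, "h4_switch_off_period_h": 24.0})
        state = osteoblast_with_open_window()
        h4_apply_switch_off(state, cfg, rng)
        state.iteration = 100  # past the 72-iteration window
        state.next_deposit[0] = 0
        assert deposit_osteoid(0, state, cfg, rng) is not None


def osteoid_field(n, include_roof=True):
    """n osteoid agents, plus a roof column so mineralisation is gated open."""
    agents = [(AgentKind.OSTEOID, (30.0 + 25 * (k % 50), 30.0 + 25 * (k // 50), 50.0)) for k in range(n)]
    if include_roof:
        agents.append((AgentKind.OSTEOID, (280.0, 280.0, 95.0)))  # top 105 >= 100
    return make_world(agents)


class TestMineralisation:
    def test_zero_probability_never_mineralises(self, rng):
        cfg = build_config("h3", {"mineral_gate_p": 0.0})
        state = osteoid_field(20)
        for _ in range(200):
            mineralise_step(state, cfg, rng)
        assert (state.kind == int(AgentKind.MINERALISED_OSTEOID)).sum() == 0

    def test_unit_probability_takes_exactly_two_iterations(self, rng):
        cfg = build_config("h3", {"mineral_gate_p": 1.0})
        state = osteoid_field(20)
        mineralise_step(state, cfg, rng)
        assert (state.kind == int(AgentKind.MINERALISED_OSTEOID)).sum() == 0
        assert state.gate1.sum() == 21
        mineralise_step(state, cfg, rng)
        assert (state.kind == int(AgentKind.OSTEOID)).sum() == 0

    def test_below_onset_height_nothing_happens(self, rng):
        cfg = build_config("h3", {"mineral_gate_p": 1.0})
        state = osteoid_field(10, include_roof=False)  # height 60 < 100
        mineralise_step(state, cfg, rng)
        assert state.gate1.sum() == 0

    def test_mean_time_matches_two_sequential_geometric_gates(self, rng):
        # closed-form oracle: time = G1 + G2, each geometric(p), mean 2/p
        p = 0.1
        cfg = build_config("h3", {"mineral_gate_p": p})
        state = osteoid_field(400)
        osteoid_ids = state.ids[state.kind == int(AgentKind.OSTEOID)].copy()
        converted_at = {}
        for t in range(1, 301):
            mineralise_step(state, cfg, rng)
            done = state.kind == int(AgentKind.MINERALISED_OSTEOID)
            for aid in state.ids[done]:
                converted_at.setdefault(int(aid), t)
        times = [converted_at[int(a)] for a in osteoid_ids if int(a) in converted_at]
        assert len(times) > 350
        assert np.mean(times) == pytest.approx(2 / p, rel=0.12)


def caged_osteoblast(n_contacts, roof=True, kind=AgentKind.MINERALISED_OSTEOID):
    """An osteoblast surrounded by n matrix agents one diameter away."""
    offsets = [
        (20, 0, 0), (-20, 0, 0), (0, 20, 0), (0, -20, 0), (0, 0, 20), (0, 0, -20),
    ]
    agents = [(AgentKind.OSTEOBLAST, (150.0, 150.0, 50.0))]
    agents += [
        (kind, (150.0 + dx, 150.0 + dy, 50.0 + dz)) for dx, dy, dz in offsets[:n_contacts]
    ]
    if roof:
        agents.append((AgentKind.MINERALISED_OSTEOID, (280.0, 280.0, 95.0)))
    return make_world(agents)


class TestOsteocyteFormation:
    def test_six_mineralised_contacts_entomb(self):
        cfg = build_config("h3")
        state = caged_osteoblast(6)
        differentiate_osteoblasts(state, cfg)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOCYTE

    def test_five_contacts_are_not_enough(self):
        cfg = build_config("h3")
        state = caged_osteoblast(5)
        differentiate_osteoblasts(state, cfg)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOBLAST

    def test_sensitivity_threshold_of_four(self):
        cfg = build_config("S4")
        state = caged_osteoblast(4)
        differentiate_osteoblasts(state, cfg)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOCYTE

    def test_unmineralised_osteoid_does_not_count(self):
        cfg = build_config("h3")
        state = caged_osteoblast(6, kind=AgentKind.OSTEOID)
        differentiate_osteoblasts(state, cfg)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOBLAST

    def test_gated_until_mineralisation_height(self):
        cfg = build_config("h3")
        state = caged_osteoblast(6, roof=False)  # height < 100
        differentiate_osteoblasts(state, cfg)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOBLAST


class TestApoptosis:
    def test_below_max_height_no_removals(self, rng):
        cfg = build_config("h3", {"apoptosis_rate": 1.0})
        state = caged_osteoblast(2)  # height 105 < 110
        assert apoptosis_step(state, cfg, rng) == 0

    def test_zero_rate_keeps_the_population(self, rng):
        cfg = build_config("h3", {"apoptosis_rate": 0.0})
        state = caged_osteoblast(2)
        state.add(AgentKind.MINERALISED_OSTEOID, np.array([280.0, 280.0, 105.0]))
        assert apoptosis_step(state, cfg, rng) == 0

    def test_unit_rate_removes_all_osteoblasts_above_the_gate(self, rng):
        cfg = build_config("h3", {"apoptosis_rate": 1.0})
        state = caged_osteoblast(2)
        state.add(AgentKind.MINERALISED_OSTEOID, np.array([280.0, 280.0, 105.0]))  # top 115
        removed = apoptosis_step(state, cfg, rng)
        assert removed == 1
        assert (state.kind == int(AgentKind.OSTEOBLAST)).sum() == 0
        assert (state.kind == int(AgentKind.MINERALISED_OSTEOID)).sum() > 0


class TestPreosteoblastDifferentiation:
    def wide_slab(self):
        # 9x9 slab of arrived pre-osteoblasts at z=30 over a column that
        # sets the height above the 50-um differentiation gate
        state = make_world(
            [
                (AgentKind.PRE_OSTEOBLAST, (70.0 + 20 * i, 70.0 + 20 * j, 30.0))
                for i in range(9)
                for j in range(9)
            ]
            + [(AgentKind.PRE_OSTEOBLAST, (150.0, 150.0, 50.0)),
               (AgentKind.PRE_OSTEOBLAST, (150.0, 150.0, 70.0))]
        )
        state.arrived[:] = True
        return state

    def test_gated_below_differentiation_height(self, rng):
        cfg = build_config("h3", {"ob_differentiation_rate": 1.0})
        state = make_world(
            [(AgentKind.PRE_OSTEOBLAST, (150.0, 150.0, 30.0))]
        )  # height 40 < 50
        differentiate_preosteoblasts(state, cfg, rng)
        assert (state.kind == int(AgentKind.OSTEOBLAST)).sum() == 0

    def test_interior_cells_convert_and_rim_cells_do_not(self, rng):
        cfg = build_config("h3", {"ob_differentiation_rate": 1.0})
        state = self.wide_slab()
        differentiate_preosteoblasts(state, cfg, rng)
        obs = state.kind == int(AgentKind.OSTEOBLAST)
        assert obs.sum() > 0
        radial = np.linalg.norm(state.pos[:, :2] - [150, 150], axis=1)
        assert radial[obs].max() < radial.max() - 10  # converts are central

    def test_converted_osteoblasts_acquire_polarity(self, rng):
        cfg = build_config("h3", {"ob_differentiation_rate": 1.0})
        state = self.wide_slab()
        differentiate_preosteoblasts(state, cfg, rng)
        obs = np.flatnonzero(state.kind == int(AgentKind.OSTEOBLAST))
        assert len(obs) and not np.any(np.isnan(state.polarity[obs]))

    def test_contact_with_five_osteoblasts_converts_anywhere(self, rng):
        cfg = build_config("h3", {"ob_differentiation_rate": 1.0})
        # a pre-osteoblast touching 5 osteoblasts, far from the interior
        state = make_world(
            [(AgentKind.PRE_OSTEOBLAST, (60.0, 60.0, 30.0))]
            + [
                (AgentKind.OSTEOBLAST, (60.0 + dx, 60.0 + dy, 30.0 + dz))
                for dx, dy, dz in [(20, 0, 0), (-20, 0, 0), (0, 20, 0), (0, -20, 0), (0, 0, 20)]
            ]
            + [(AgentKind.PRE_OSTEOBLAST, (250.0, 250.0, 70.0))]  # opens the height gate
        )
        differentiate_preosteoblasts(state, cfg, rng)
        assert AgentKind(int(state.kind[0])) is AgentKind.OSTEOBLAST
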