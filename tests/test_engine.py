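import math

import numpy as np
import pytest

from grasstox.engine import (
    DEFAULT_PARAMS,
    Grid,
    PlantIndividual,
    SimulationState,
    distribute_cell_resource,
    grow,
    run_simulation,
    weekly_step,
    zoi_cells,
)
from grasstox.experiments import init_monoculture
from grasstox.traits import PFTraits


def make_plant(pmap, name="S. nutans", x=3, y=3, shoot=10.0, root=10.0):
    return PlantIndividual(pmap[name], x, y, shoot, root)


def neutral_pft(name="n", **kw):
    base = dict(
        name=name, size_class="medium", growth_form="semi-rosette",
        resource_response="intermediate", grazing_response="intermediate",
    )
    base.update(kw)
    return PFTraits(**base)


class TestZoi:
    def test_zero_mass_covers_exactly_the_home_cell(self, pmap):
        grid = Grid(9, 9, 50, 50)
        p = make_plant(pmap, shoot=0.0, root=0.0, x=4, y=4)
        assert zoi_cells(p, "above", grid) == {(4, 4)}
        assert zoi_cells(p, "below", grid) == {(4, 4)}

    @pytest.mark.parametrize("mass", [50.0, 200.0, 1000.0])
    def test_cell_count_tracks_circle_area(self, pmap, mass):
        """Brute-force cell count approximates pi*r^2, and scaling the mass
        by 8 quadruples the covered area within discretization error."""
        grid = Grid(61, 61, 50, 50)
        small = make_plant(pmap, x=30, y=30, root=mass)
        big = make_plant(pmap, x=30, y=30, root=8.0 * mass)
        n_small = len(zoi_cells(small, "below", grid))
        n_big = len(zoi_cells(big, "below", grid))
        for n, m in ((n_small, mass), (n_big, 8 * mass)):
            area = DEFAULT_PARAMS.k_below * m ** (2 / 3)
            r = math.sqrt(area / math.pi)
            assert abs(n - area) <= 2 * math.pi * r + 4  # perimeter-order error
        assert abs(n_big - 4 * n_small) <= 0.25 * 4 * n_small

    def test_boundary_clipping_reduces_cover_at_the_corner(self, pmap):
        grid = Grid(15, 15, 50, 50)
        center = make_plant(pmap, x=7, y=7, root=500.0)
        corner = make_plant(pmap, x=0, y=0, root=500.0)
        assert len(zoi_cells(corner, "below", grid)) < len(
            zoi_cells(center, "below", grid)
        )


class TestDistribute:
    def test_single_claimant_takes_the_full_supply(self, pmap):
        p = make_plant(pmap)
        assert distribute_cell_resource([(p, 1.0)], 7.0) == [7.0]

    def test_identical_conspecifics_split_evenly(self, pmap):
        a, b = make_plant(pmap), make_plant(pmap)
        assert distribute_cell_resource([(a, 2.0), (b, 2.0)], 10.0) == [5.0, 5.0]

    def test_conspecific_shares_proportional_to_weights(self, pmap):
        a, b = make_plant(pmap), make_plant(pmap)
        shares = distribute_cell_resource([(a, 1.0), (b, 0.5)], 3.0)
        assert shares == pytest.approx([2.0, 1.0])

    def test_empty_claimant_list_allocates_nothing(self):
        assert distribute_cell_resource([], 5.0) == []

    def test_minority_species_benefits_from_weaker_interspecific_pressure(self, pmap):
        """With kappa < 1 a locally rare species keeps a larger share than
        under purely symmetric division."""
        a = make_plant(pmap, "S. nutans")
        b1 = make_plant(pmap, "G. mollugo")
        b2 = make_plant(pmap, "G. mollugo")
        shares = distribute_cell_resource([(a, 1.0), (b1, 1.0), (b2, 1.0)], 3.0)
        assert shares[0] > shares[1] == pytest.approx(shares[2])
        assert sum(shares) <= 3.0 + 1e-12

    def test_shares_never_exceed_supply(self, pmap):
        plants = [make_plant(pmap, n) for n in
                  ("S. nutans", "G. mollugo", "T. pratense", "S. nutans")]
        weights = [0.3, 1.2, 0.7, 2.0]
        shares = distribute_cell_resource(list(zip(plants, weights)), 4.0)
        assert sum(shares) <= 4.0 + 1e-12


class TestGrow:
    def test_gain_zero_at_mass_cap(self, pmap):
        p = make_plant(pmap, "G. mollugo")
        cap = p.pft.max_mass * DEFAULT_PARAMS.shoot_mass_fraction
        p.shoot_mass = cap
        grow(p, 100.0, 0.0, 1.0)
        assert p.shoot_mass == cap

    def test_full_suppression_freezes_masses(self, pmap):
        p = make_plant(pmap, "G. mollugo")
        s, r = p.shoot_mass, p.root_mass
        grow(p, 50.0, 50.0, 0.0)
        assert (p.shoot_mass, p.root_mass) == (s, r)

    def test_partial_effect_scales_the_gain(self, pmap):
        """An effect of 0.25 turns an 8 mg untreated gain into 6 mg."""
        a = make_plant(pmap, "G. mollugo", shoot=10.0)
        b = make_plant(pmap, "G. mollugo", shoot=10.0)
        grow(a, 80.0, 0.0, 1.0)
        untreated_gain = a.shoot_mass - 10.0
        grow(b, 80.0, 0.0, 0.75)
        assert b.shoot_mass - 10.0 == pytest.approx(0.75 * untreated_gain)
        assert untreated_gain > 0

    def test_negative_uptake_rejected(self, pmap):
        with pytest.raises(ValueError):
            grow(make_plant(pmap), -1.0, 0.0)

    def test_single_plant_trajectory_is_sigmoid(self):
        """Uncrowded growth: non-decreasing masses whose weekly increments
        rise (ZOI area ~ m^(2/3)) and then fall (saturation), i.e. the
        increment series is unimodal up to discretization jitter."""
        pft = neutral_pft(growth_form="erect")
        grid = Grid(31, 31, 75.0, 90.0)
        state = SimulationState(grid, [PlantIndividual(pft, 15, 15, 0.5, 0.5)])
        traj = run_simulation(state, 25)
        m = traj["shoot_mass_mg"].to_numpy()
        inc = np.diff(m)
        assert np.all(inc >= -1e-12)
        k = int(np.argmax(inc))
        assert 0 < k < len(inc) - 1
        tol = 0.15 * inc[k]
        assert np.all(np.diff(inc[: k + 1]) >= -tol)  # rising limb
        assert np.all(np.diff(inc[k:]) <= tol)  # falling limb
        assert inc[0] < 0.5 * inc[k] and inc[-1] < 0.9 * inc[k]


class TestWeeklyStep:
    def test_empty_community_only_advances_the_clock(self):
        state = SimulationState(Grid(5, 5, 10, 10), [])
        weekly_step(state)
        assert state.week == 1 and state.plants == []

    def test_non_overlapping_plants_grow_like_isolated_ones(self, pmap):
        grid = Grid(41, 41, 75, 90)
        pair = SimulationState(grid, [
            PlantIndividual(pmap["S. nutans"], 5, 5, 0.5, 0.5, plant_id=0),
            PlantIndividual(pmap["G. mollugo"], 35, 35, 0.5, 0.5, plant_id=1),
        ])
        t_pair = run_simulation(pair, 6)
        for name, (x, y) in (("S. nutans", (5, 5)), ("G. mollugo", (35, 35))):
            grid2 = Grid(41, 41, 75, 90)
            solo = SimulationState(
                grid2, [PlantIndividual(pmap[name], x, y, 0.5, 0.5, plant_id=0)]
            )
            t_solo = run_simulation(solo, 6)
            got = t_pair[t_pair["pft"] == name]["shoot_mass_mg"].to_numpy()
            want = t_solo["shoot_mass_mg"].to_numpy()
            np.testing.assert_array_equal(got, want)

    def test_all_ones_effect_map_equals_control(self, pmap, mono_grid):
        a = init_monoculture(pmap["B. erectus"], mono_grid)
        grid2 = Grid(7, 7, 75, 90)
        b = init_monoculture(pmap["B. erectus"], grid2)
        for _ in range(4):
            weekly_step(a, None)
            weekly_step(b, {"B. erectus": 1.0})
        for pa, pb in zip(a.plants, b.plants):
            assert pa.shoot_mass == pb.shoot_mass
            assert pa.root_mass == pb.root_mass

    def test_total_biomass_never_decreases(self, pmap, mono_grid):
        state = init_monoculture(pmap["T. pratense"], mono_grid)
        prev = sum(p.shoot_mass + p.root_mass for p in state.plants)
        for _ in range(8):
            weekly_step(state)
            tot = sum(p.shoot_mass + p.root_mass for p in state.plants)
            assert tot >= prev
            prev = tot


class TestRunSimulation:
    def test_zero_weeks_returns_only_the_initial_state(self, pmap, mono_grid):
        state = init_monoculture(pmap["B. erectus"], mono_grid)
        traj = run_simulation(state, 0)
        assert len(traj) == 4 and set(traj["week"]) == {0}

    def test_trajectory_row_count(self, pmap, mono_grid):
        state = init_monoculture(pmap["B. erectus"], mono_grid)
        traj = run_simulation(state, 6)
        assert len(traj) == 7 * 4

    def test_same_seed_reproduces_the_run(self, pmap):
        outs = []
        for _ in range(2):
            grid = Grid(7, 7, 75, 90)
            state = init_monoculture(pmap["L. hispidus"], grid, seed=11)
            outs.append(run_simulation(state, 8))
        assert outs[0].equals(outs[1])


class TestCompetitionInvariants:
    def test_lone_plant_outgrows_crowded_monoculture_mates(self, pmap):
        grid = Grid(7, 7, 75, 90)
        mono = run_simulation(init_monoculture(pmap["S. nutans"], grid), 6)
        crowded = mono[mono["week"] == 6]["shoot_mass_mg"]
        grid2 = Grid(7, 7, 75, 90)
        solo_state = SimulationState(
            grid2, [PlantIndividual(pmap["S. nutans"], 3, 3, 0.5, 0.5)]
        )
        solo = run_simulation(solo_state, 6)
        solo_mass = float(solo[solo["week"] == 6]["shoot_mass_mg"].iloc[0])
        assert (crowded < solo_mass).all()

    def test_doubling_resources_never_hurts(self, pmap):
        low = Grid(7, 7, 50, 60)
        high = Grid(7, 7, 100, 120)
        t_low = run_simulation(init_monoculture(pmap["T. pratense"], low), 6)
        t_high = run_simulation(init_monoculture(pmap["T. pratense"], high), 6)
        for w in range(7):
            lo = t_low[t_low["week"] == w]["shoot_mass_mg"].to_numpy()
            hi = t_high[t_high["week"] == w]["shoot_mass_mg"].to_numpy()
            assert np.all(hi >= lo)
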