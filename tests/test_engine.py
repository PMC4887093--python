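"""Engine invariants: matching oracle, binding/export effects, conservation,
region legality, determinism."""

import numpy as np
import pytest

from mapkcell import agents as ag
from mapkcell import geometry as geo
from mapkcell.agents import (
    ACTIVE,
    EXR,
    INACTIVE,
    MAPK,
    MAPKK,
    PopulationConfig,
    init_population,
)
from mapkcell.engine import (
    SimulationConfig,
    World,
    apply_binding_effects,
    apply_export,
    resolve_bindings,
    run_simulation,
)
from mapkcell.radp import Phase, PlateauTrigger, RadpConfig, RadpSchedule


def brute_force_matching(seekers, targets, radius):
    """O(n^3) oracle: repeatedly take the globally closest admissible pair."""
    seekers = np.asarray(seekers, dtype=float)
    targets = np.asarray(targets, dtype=float)
    s_used = [False] * len(seekers)
    t_used = [False] * len(targets)
    pairs = []
    while True:
        best = None
        for si in range(len(seekers)):
            if s_used[si]:
                continue
            for ti in range(len(targets)):
                if t_used[ti]:
                    continue
                d = float(np.linalg.norm(seekers[si] - targets[ti]))
                if d > radius:
                    continue
                key = (d, si, ti)
                if best is None or key < best:
                    best = key
        if best is None:
            return pairs
        _, si, ti = best
        pairs.append((si, ti))
        s_used[si] = True
        t_used[ti] = True


SMALL_POP = PopulationConfig(
    n_mapkk=40, n_mapk=40, n_exr_active=15, n_exr_dormant=15,
    exr_dormancy_s=30.0, initial_exr_dormancy_s=30.0,
    # start MAPKK active immediately: these tests exercise binding/export
    # mechanics, not the stimulus-propagation delay
    mapkk_active_fraction=1.0,
    initial_dormancy_s=0.0, initial_dormancy_lower_s=0.0,
)


class TestResolveBindings:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ns, nt = rng.integers(1, 21, size=2)
        seekers = rng.uniform(-1, 1, size=(ns, 3))
        targets = rng.uniform(-1, 1, size=(nt, 3))
        radius = float(rng.uniform(0.2, 1.5))
        got = resolve_bindings(seekers, targets, radius)
        assert got == brute_force_matching(seekers, targets, radius)

    def test_one_to_one(self):
        rng = np.random.default_rng(99)
        seekers = rng.uniform(-1, 1, size=(50, 3))
        targets = rng.uniform(-1, 1, size=(30, 3))
        pairs = resolve_bindings(seekers, targets, 1.0)
        s = [p[0] for p in pairs]
        t = [p[1] for p in pairs]
        assert len(set(s)) == len(s) and len(set(t)) == len(t)

    def test_respects_radius(self):
        seekers = np.array([[0.0, 0, 0]])
        targets = np.array([[0.5, 0, 0]])
        assert resolve_bindings(seekers, targets, 0.4) == []
        assert resolve_bindings(seekers, targets, 0.6) == [(0, 0)]

    def test_empty_inputs(self):
        assert resolve_bindings(np.empty((0, 3)), np.ones((3, 3)), 1.0) == []
        assert resolve_bindings(np.ones((3, 3)), np.empty((0, 3)), 1.0) == []

    def test_contested_target_goes_to_closest_seeker(self):
        seekers = np.array([[0.3, 0, 0], [-0.1, 0, 0]])
        targets = np.array([[0.0, 0, 0]])
        assert resolve_bindings(seekers, targets, 1.0) == [(1, 0)]


class TestBindingEffects:
    def make_pop(self, seed=0):
        g = geo.CellGeometry()
        pop = init_population(SMALL_POP, g, np.random.default_rng(seed))
        return pop, g

    def test_phosphorylation_and_translocation(self):
        pop, g = self.make_pop()
        kk = int(np.flatnonzero(pop.mask(MAPKK, ACTIVE))[0])
        k = int(np.flatnonzero(pop.mask(MAPK, INACTIVE))[0])
        radp = RadpConfig(mode="deterministic", upper=120.0)
        apply_binding_effects([(kk, k)], pop, radp, g, np.random.default_rng(1))
        assert pop.state[k] == ACTIVE
        assert np.linalg.norm(pop.pos[k]) <= g.nucleus_radius  # in the nucleus
        assert pop.state[kk] == INACTIVE and pop.dormancy[kk] == 120.0

    def test_constitutive_mapkk_stays_active(self):
        pop, g = self.make_pop()
        kk = int(np.flatnonzero(pop.mask(MAPKK, ACTIVE))[0])
        k = int(np.flatnonzero(pop.mask(MAPK, INACTIVE))[0])
        apply_binding_effects([(kk, k)], pop, RadpConfig(mode="constitutive"),
                              g, np.random.default_rng(1))
        assert pop.state[kk] == ACTIVE and pop.dormancy[kk] == 0.0

    def test_stochastic_radp_within_bounds(self):
        pop, g = self.make_pop()
        kks = np.flatnonzero(pop.mask(MAPKK, ACTIVE))[:20]
        ks = np.flatnonzero(pop.mask(MAPK, INACTIVE))[:20]
        radp = RadpConfig(mode="stochastic", lower=10.0, upper=20.0)
        apply_binding_effects(list(zip(kks, ks)), pop, radp, g,
                              np.random.default_rng(2))
        d = pop.dormancy[kks]
        assert np.all((d >= 10.0) & (d < 20.0))

    def test_conservation_after_binding(self):
        pop, g = self.make_pop()
        kk = int(np.flatnonzero(pop.mask(MAPKK, ACTIVE))[0])
        k = int(np.flatnonzero(pop.mask(MAPK, INACTIVE))[0])
        apply_binding_effects([(kk, k)], pop, RadpConfig(mode="constitutive"),
                              g, np.random.default_rng(1))
        pop.check_conservation()


class TestExportEffects:
    def test_export_returns_pmapk_to_cytoplasm(self):
        g = geo.CellGeometry()
        pop = init_population(SMALL_POP, g, np.random.default_rng(3))
        k = int(np.flatnonzero(pop.species == MAPK)[0])
        pop.state[k] = ACTIVE
        pop.pos[k] = np.zeros(3)
        e = int(np.flatnonzero(pop.mask(EXR, ACTIVE))[0])
        apply_export([(e, k)], pop, g, np.random.default_rng(4))
        assert pop.state[k] == INACTIVE
        assert geo.region_of(g, pop.pos[k]) == geo.CYTOPLASM
        assert pop.state[e] == INACTIVE
        lo = (1 - pop.exr_dormancy_jitter) * pop.exr_dormancy_s
        hi = (1 + pop.exr_dormancy_jitter) * pop.exr_dormancy_s
        assert lo <= pop.dormancy[e] <= hi

    def test_export_returns_to_home_compartment(self):
        g = geo.place_compartments(10, rng=0)
        cfg = PopulationConfig(n_mapkk=20, n_mapk=20, n_exr_active=10,
                               n_exr_dormant=0, require_compartments=True)
        pop = init_population(cfg, g, np.random.default_rng(5))
        k = int(np.flatnonzero(pop.species == MAPK)[0])
        home = int(pop.home[k])
        pop.state[k] = ACTIVE
        pop.pos[k] = np.zeros(3)
        e = int(np.flatnonzero(pop.mask(EXR, ACTIVE))[0])
        apply_export([(e, k)], pop, g, np.random.default_rng(6))
        assert geo.region_of(g, pop.pos[k]) == home


class TestRunSimulation:
    def small_config(self, **kw):
        # pin the ExR reach explicitly: the package default (sized for the
        # full-scale cell) spans most of this tiny geometry's nucleus and
        # would export every pMAPK the step after it appears
        base = dict(population=SMALL_POP, duration_min=3.0, seed=7,
                    exr_interaction_radius=0.4)
        base.update(kw)
        return SimulationConfig(**base)

    def test_deterministic_replay(self):
        a = run_simulation(self.small_config())
        b = run_simulation(self.small_config())
        assert a.df.equals(b.df)

    def test_different_seeds_differ(self):
        a = run_simulation(self.small_config(seed=1))
        b = run_simulation(self.small_config(seed=2))
        assert not a.df.equals(b.df)

    def test_conservation_every_recorded_row(self):
        ts = run_simulation(self.small_config())
        ts.check_conservation()
        assert ts.values("MAPK")[0] + ts.values("pMAPK")[0] == 40

    def test_activation_progresses(self):
        ts = run_simulation(self.small_config(duration_min=5.0))
        assert ts.values("pMAPK")[-1] > 0

    def test_region_legality_during_run(self):
        # every agent is in a legal region after every step of a short run
        cfg = self.small_config(duration_min=0.5)
        world = World(cfg)
        g = world.geometry
        pop = world.population
        for _ in range(cfg.n_steps):
            world.step()
            r = np.linalg.norm(pop.pos, axis=1)
            assert np.all(r <= g.cell_radius + 1e-6)
            # ExR stay in the nuclear-membrane shell
            m = pop.species == EXR
            assert np.all(r[m] <= g.nucleus_radius + 1e-6)
            assert np.all(r[m] >= g.nucleus_radius - pop.exr_shell_width - 1e-6)
            # pMAPK in the nucleus (instant entry), inactive MAPK outside it
            assert np.all(r[pop.mask(MAPK, ACTIVE)] <= g.nucleus_radius + 1e-6)
            assert np.all(r[pop.mask(MAPK, INACTIVE)] >= g.nucleus_radius - 1e-6)

    def test_region_legality_multi_compartment(self):
        cfg = SimulationConfig(
            n_compartments=10,
            population=PopulationConfig(
                n_mapkk=30, mapkk_active_fraction=0.5, n_mapk=30,
                n_exr_active=10, n_exr_dormant=10,
                exr_dormancy_s=30.0, require_compartments=True,
            ),
            duration_min=0.5,
            seed=3,
        )
        world = World(cfg)
        g, pop = world.geometry, world.population
        kin = (pop.species == MAPKK) | (pop.species == MAPK)
        for _ in range(cfg.n_steps):
            world.step()
            free = kin & ~pop.mask(MAPK, ACTIVE)
            labels = geo.region_of_many(g, pop.pos[free])
            np.testing.assert_array_equal(labels, pop.home[free])

    def test_dormant_mapkk_reactivates(self):
        cfg = self.small_config(
            schedule=RadpSchedule.single(
                RadpConfig(mode="deterministic", lower=0.0, upper=10.0)
            ),
            duration_min=4.0,
        )
        ts = run_simulation(cfg)
        dorm = ts.values("MAPKK_dormant")
        assert dorm.max() > 0  # some went dormant
        # with a 10 s delay, dormancy never accumulates to the whole pool
        assert dorm[-1] < 40

    def test_plateau_switch_logged(self):
        sched = RadpSchedule(phases=[
            Phase(RadpConfig(mode="constitutive")),
            Phase(RadpConfig(mode="deterministic", upper=600.0),
                  PlateauTrigger(species="pMAPK", window_min=1.0, rel_tol=10.0)),
        ])
        ts = run_simulation(self.small_config(schedule=sched, duration_min=5.0))
        assert ts.switch_log and ts.switch_log[0][1] == 1

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(nuclear_entry="warp").validate()
        from mapkcell.clusters import ClusterConfig
        with pytest.raises(ValueError, match="two-compartment"):
            SimulationConfig(n_compartments=5, clusters=ClusterConfig()).validate()

    def test_diffusive_nuclear_entry_runs(self):
        ts = run_simulation(self.small_config(nuclear_entry="diffusive",
                                              duration_min=2.0))
        ts.check_conservation()
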