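"""Synchronous per-step scheduler for the compartmentalised kinase cascade.

Each iteration performs, in fixed order:

1. proximity sensing and greedy one-to-one matching of active pMAPKK to
   inactive MAPK (positions as of the start of the step),
2. matching of active export receptors to nuclear pMAPK,
3. application of binding effects (MAPK phosphorylation + nuclear
   translocation, MAPKK dormancy draw) and export effects (pMAPK
   dephosphorylation + return to the cytoplasm or home compartment, ExR
   dormancy),
4. Brownian movement of every agent with reflection at its region boundaries,
5. dormancy clock ticks, and
6. evaluation of the RADP schedule's switch triggers.

The recorded output is a :class:`TimeSeries` of per-state agent counts; the
per-species totals are exact invariants.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import agents as ag
from . import geometry as geo
from .clusters import ClusterConfig, ClusterState, assemble_clusters, disassemble
from .radp import RadpConfig, RadpSchedule, ScheduleCursor, draw_radp

COUNT_COLUMNS = ["MAPK", "pMAPK", "pMAPKK", "MAPKK_dormant", "ExR", "dExR"]


@dataclass
class SimulationConfig:
    """Full specification of one run.

    Times are in seconds of simulated time (``dt`` seconds per step); lengths
    are in model units (cell radius 10 by default).  ``seed`` drives every
    stochastic element of the run; ``geometry_seed`` fixes the sub-compartment
    placement independently so that replicate runs share one cell layout.
    """

    # geometry
    cell_radius: float = 10.0
    nucleus_radius: float = 3.0
    n_compartments: int = 0
    compartment_radius: float = 1.5
    geometry_seed: int = 0

    # agents
    population: ag.PopulationConfig = field(default_factory=ag.two_compartment_counts)

    # RADP
    schedule: RadpSchedule = field(
        default_factory=lambda: RadpSchedule.single(RadpConfig(mode="constitutive"))
    )

    # signalosome clusters (two-compartment only)
    clusters: ClusterConfig | None = None

    # kinetics
    dt: float = 1.0
    sigma_kinase: float = 0.4
    sigma_pmapk: float = 1.0
    sigma_exr: float = 0.3
    interaction_radius: float = 0.25
    exr_interaction_radius: float = 0.07
    #: "instant" teleports fresh pMAPK into the nucleus; "diffusive" lets it
    #: walk there and be absorbed on contact
    nuclear_entry: str = "instant"

    duration_min: float = 90.0
    seed: int = 0
    record_every: int = 5
    record_compartments: bool = False

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.interaction_radius <= 0 or self.exr_interaction_radius <= 0:
            raise ValueError("interaction radii must be positive")
        if self.duration_min < 0:
            raise ValueError("duration must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.nuclear_entry not in ("instant", "diffusive"):
            raise ValueError("nuclear_entry must be 'instant' or 'diffusive'")
        if self.clusters is not None and self.clusters.enabled and self.n_compartments > 0:
            raise ValueError("signalosome clusters apply to the two-compartment model only")
        self.population.validate()

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_min * 60.0 / self.dt))


class TimeSeries:
    """Recorded per-step state counts of a run (totals conserved by row)."""

    def __init__(self, df: pd.DataFrame, switch_log: list[tuple[float, int]] | None = None):
        self.df = df
        self.switch_log = switch_log or []

    def __len__(self) -> int:
        return len(self.df)

    @property
    def time_min(self) -> np.ndarray:
        return self.df["time_min"].to_numpy()

    def values(self, species: str) -> np.ndarray:
        return self.df[species].to_numpy(dtype=float)

    def total(self, species: str) -> int:
        """Conserved pool size for a state pair, e.g. MAPK + pMAPK."""
        pairs = {
            "MAPK": ("MAPK", "pMAPK"),
            "pMAPK": ("MAPK", "pMAPK"),
            "pMAPKK": ("pMAPKK", "MAPKK_dormant"),
            "MAPKK_dormant": ("pMAPKK", "MAPKK_dormant"),
            "ExR": ("ExR", "dExR"),
            "dExR": ("ExR", "dExR"),
        }
        a, b = pairs[species]
        return int(self.df[a].iloc[0] + self.df[b].iloc[0])

    def check_conservation(self) -> None:
        for a, b in (("MAPK", "pMAPK"), ("pMAPKK", "MAPKK_dormant"), ("ExR", "dExR")):
            sums = self.df[a].to_numpy() + self.df[b].to_numpy()
            if len(sums) and not np.all(sums == sums[0]):
                raise AssertionError(f"{a}+{b} not conserved across rows")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        return cls(pd.read_csv(path))


class World:
    """Mutable state of a running simulation."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.geometry = geo.place_compartments(
            config.n_compartments,
            cell_radius=config.cell_radius,
            nucleus_radius=config.nucleus_radius,
            compartment_radius=config.compartment_radius,
            rng=np.random.default_rng(config.geometry_seed),
        )
        self.population = ag.init_population(config.population, self.geometry, self.rng)
        self.cursor = ScheduleCursor(config.schedule)
        self.cluster_state: ClusterState | None = None
        if config.clusters is not None and config.clusters.enabled:
            self.cluster_state = assemble_clusters(
                self.population, self.geometry, config.clusters, self.rng
            )
        self.step_index = 0
        self._rec_times: list[float] = []
        self._rec_rows: list[dict] = []
        self._record()

    # -- time ---------------------------------------------------------------
    @property
    def t_seconds(self) -> float:
        return self.step_index * self.config.dt

    @property
    def t_min(self) -> float:
        return self.t_seconds / 60.0

    # -- recording ----------------------------------------------------------
    def _record(self) -> None:
        row = {"step": self.step_index, "time_min": self.t_min}
        row.update(self.population.counts())
        if self.config.record_compartments and self.geometry.n_compartments:
            row.update(self.population.compartment_counts(self.geometry.n_compartments))
        self._rec_times.append(self.t_min)
        self._rec_rows.append(row)

    def _recorded_series(self, species: str) -> np.ndarray:
        return np.array([r[species] for r in self._rec_rows], dtype=float)

    # -- stepping -----------------------------------------------------------
    def step(self) -> None:
        cfg = self.config
        pop = self.population
        rng = self.rng

        # masks as of the start of the step (synchronous update)
        seekers = np.flatnonzero(pop.mask(ag.MAPKK, ag.ACTIVE))
        targets = np.flatnonzero(pop.mask(ag.MAPK, ag.INACTIVE))
        pmapk = np.flatnonzero(pop.mask(ag.MAPK, ag.ACTIVE))
        if cfg.nuclear_entry == "diffusive" and pmapk.size:
            r = np.linalg.norm(pop.pos[pmapk], axis=1)
            pmapk = pmapk[r <= self.geometry.nucleus_radius]
        exr = np.flatnonzero(pop.mask(ag.EXR, ag.ACTIVE))

        bind_pairs = resolve_bindings(
            pop.pos[seekers], pop.pos[targets], cfg.interaction_radius
        )
        export_pairs = resolve_bindings(
            pop.pos[exr], pop.pos[pmapk], cfg.exr_interaction_radius
        )

        apply_binding_effects(
            [(seekers[i], targets[j]) for i, j in bind_pairs],
            pop,
            self.cursor.active,
            self.geometry,
            rng,
            nuclear_entry=cfg.nuclear_entry,
        )
        apply_export(
            [(exr[i], pmapk[j]) for i, j in export_pairs],
            pop,
            self.geometry,
            rng,
            cluster_state=self.cluster_state,
        )

        self._move_all()
        pop.tick_clocks(cfg.dt)
        self.step_index += 1

        if self.cluster_state is not None and not self.cluster_state.disassembled:
            if self.t_min >= cfg.clusters.disassembly_time_min:
                disassemble(pop, self.cluster_state, self.t_min)

        if self.step_index % cfg.record_every == 0:
            self._record()
            times = np.array(self._rec_times)
            series = {c: self._recorded_series(c) for c in COUNT_COLUMNS}
            if self.cursor.update(self.t_min, times, series):
                t, idx = self.cursor.switch_log[-1]
                print(
                    f"[mapkcell] t={t:.2f} min: RADP schedule advanced to phase {idx}",
                    file=sys.stderr,
                )

    def _move_all(self) -> None:
        cfg = self.config
        pop = self.population
        gm = self.geometry
        n = len(pop)
        if n == 0:
            return
        steps = self.rng.normal(size=(n, 3))
        sigma = np.full(n, cfg.sigma_kinase)
        m_pmapk = pop.mask(ag.MAPK, ag.ACTIVE)
        m_exr = pop.species == ag.EXR
        sigma[m_pmapk] = cfg.sigma_pmapk
        sigma[m_exr] = cfg.sigma_exr
        steps *= sigma[:, None]

        # export receptors: thin shell at the nuclear membrane
        if m_exr.any():
            pop.pos[m_exr] = geo.reflect_step(
                pop.pos[m_exr],
                steps[m_exr],
                r_out=gm.nucleus_radius,
                r_in=gm.nucleus_radius - pop.exr_shell_width,
            )

        # pMAPK
        if m_pmapk.any():
            if cfg.nuclear_entry == "instant":
                pop.pos[m_pmapk] = geo.reflect_step(
                    pop.pos[m_pmapk], steps[m_pmapk], r_out=gm.nucleus_radius
                )
            else:
                idx = np.flatnonzero(m_pmapk)
                r = np.linalg.norm(pop.pos[idx], axis=1)
                inside = r <= gm.nucleus_radius
                if inside.any():
                    ii = idx[inside]
                    pop.pos[ii] = geo.reflect_step(
                        pop.pos[ii], steps[ii], r_out=gm.nucleus_radius
                    )
                if (~inside).any():  # in transit: free in the whole cell
                    ii = idx[~inside]
                    pop.pos[ii] = geo.reflect_step(
                        pop.pos[ii], steps[ii], r_out=gm.cell_radius
                    )

        # kinases (MAPKK both states + inactive MAPK)
        m_kin = (pop.species == ag.MAPKK) | pop.mask(ag.MAPK, ag.INACTIVE)
        idx = np.flatnonzero(m_kin)
        if idx.size:
            clustered = pop.cluster[idx] >= 0
            if self.cluster_state is not None and not self.cluster_state.disassembled:
                for k in np.unique(pop.cluster[idx][clustered]):
                    ii = idx[pop.cluster[idx] == k]
                    c = self.cluster_state.centers[k]
                    pop.pos[ii] = geo.reflect_step(
                        pop.pos[ii],
                        steps[ii],
                        r_out=self.cluster_state.radius,
                        center=c,
                    )
                idx = idx[~clustered]
            for home in np.unique(pop.home[idx]):
                ii = idx[pop.home[idx] == home]
                if home == geo.CYTOPLASM:
                    pop.pos[ii] = geo.reflect_step(
                        pop.pos[ii],
                        steps[ii],
                        r_out=gm.cell_radius,
                        r_in=gm.nucleus_radius,
                    )
                else:
                    c = gm.compartment_by_id(int(home))
                    pop.pos[ii] = geo.reflect_step(
                        pop.pos[ii], steps[ii], r_out=c.radius, center=c.center
                    )

    # -- results ------------------------------------------------------------
    def timeseries(self) -> TimeSeries:
        ts = TimeSeries(pd.DataFrame(self._rec_rows), switch_log=list(self.cursor.switch_log))
        return ts


def resolve_bindings(
    seeker_pos: np.ndarray, target_pos: np.ndarray, interaction_radius: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-pair matching within the interaction radius.

    Repeatedly matches the globally closest (seeker, target) pair with
    distance <= radius and removes both.  Ties break to the lower seeker
    index, then the lower target index.  Returns (seeker_idx, target_idx)
    pairs into the given position arrays.
    """
    ns, nt = len(seeker_pos), len(target_pos)
    if ns == 0 or nt == 0:
        return []
    tree = cKDTree(np.asarray(target_pos, dtype=float))
    cand = tree.query_ball_point(np.asarray(seeker_pos, dtype=float), interaction_radius)
    entries = []
    for si, t_idx in enumerate(cand):
        if not t_idx:
            continue
        d = np.linalg.norm(target_pos[t_idx] - seeker_pos[si], axis=1)
        for ti, dist in zip(t_idx, d):
            entries.append((dist, si, int(ti)))
    entries.sort()
    pairs = []
    s_used = np.zeros(ns, dtype=bool)
    t_used = np.zeros(nt, dtype=bool)
    for dist, si, ti in entries:
        if not s_used[si] and not t_used[ti]:
            pairs.append((si, ti))
            s_used[si] = True
            t_used[ti] = True
    return pairs


def apply_binding_effects(
    matching: list[tuple[int, int]],
    population: ag.Population,
    radp_config: RadpConfig,
    geometry: geo.CellGeometry,
    rng: np.random.Generator,
    nuclear_entry: str = "instant",
) -> ag.Population:
    """Apply pMAPKK–MAPK binding outcomes for matched (kinase, substrate) pairs.

    Each matched MAPK is phosphorylated and (in the default instant-entry
    model) relocated uniformly inside the nucleus; each matched pMAPKK draws a
    re-activation delay and goes dormant unless the RADP mode is constitutive.
    """
    if not matching:
        return population
    kk_idx = np.array([m[0] for m in matching])
    k_idx = np.array([m[1] for m in matching])
    population.state[k_idx] = ag.ACTIVE
    if nuclear_entry == "instant":
        population.pos[k_idx] = geo.sample_in_sphere(
            rng, geometry.nucleus_radius, len(k_idx)
        )
    if radp_config.mode != "constitutive":
        population.state[kk_idx] = ag.INACTIVE
        population.dormancy[kk_idx] = draw_radp(radp_config, rng, size=len(kk_idx))
    return population


def apply_export(
    matching: list[tuple[int, int]],
    population: ag.Population,
    geometry: geo.CellGeometry,
    rng: np.random.Generator,
    cluster_state: ClusterState | None = None,
) -> ag.Population:
    """Apply ExR-mediated nuclear export for matched (ExR, pMAPK) pairs.

    Exported pMAPK reverts to inactive MAPK and is returned to its home
    region (the cytoplasm, its sub-compartment, or — while signalosome
    clusters are assembled — its cluster sphere); the receptor goes dormant
    for its recovery period.
    """
    if not matching:
        return population
    e_idx = np.array([m[0] for m in matching])
    p_idx = np.array([m[1] for m in matching])
    population.state[p_idx] = ag.INACTIVE
    for i in p_idx:
        home = population.home[i]
        if (
            cluster_state is not None
            and not cluster_state.disassembled
            and population.cluster[i] >= 0
        ):
            c = cluster_state.centers[population.cluster[i]]
            population.pos[i] = geo.sample_in_sphere(rng, cluster_state.radius, 1, c)[0]
        elif home == geo.CYTOPLASM:
            population.pos[i] = geo.sample_in_cytoplasm(rng, geometry, 1)[0]
        else:
            c = geometry.compartment_by_id(int(home))
            population.pos[i] = geo.sample_in_sphere(rng, c.radius, 1, c.center)[0]
    population.state[e_idx] = ag.INACTIVE
    mean = population.exr_dormancy_s
    j = population.exr_dormancy_jitter
    if j > 0 and mean > 0:
        population.dormancy[e_idx] = rng.uniform(
            (1 - j) * mean, (1 + j) * mean, size=len(e_idx)
        )
    else:
        population.dormancy[e_idx] = mean
    return population


def step(world: World) -> World:
    """Advance the world by one synchronous iteration."""
    world.step()
    return world


def run_simulation(config: SimulationConfig, progress: bool = False) -> TimeSeries:
    """Run a full simulation and return its recorded time series."""
    world = World(config)
    n = config.n_steps
    for _ in range(n):
        world.step()
    world.population.check_conservation()
    ts = world.timeseries()
    ts.check_conservation()
    return ts
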