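"""Agent populations and state machines for the two-tier kinase cascade.

Three agent kinds are modelled:

* **MAPKK** — cycles between an active, phosphorylated form (pMAPKK) that can
  bind and phosphorylate MAPK, and a dormant form whose re-activation delay
  clock must run out before it becomes pMAPKK again.
* **MAPK** — inactive MAPK lives in the cytoplasm (or is confined to its home
  sub-compartment in the multi-compartment model); on phosphorylation it
  becomes pMAPK and translocates to the nucleus.
* **ExR** — the nuclear export receptor, diffusing in a thin shell at the
  inner face of the nuclear membrane.  An active ExR that captures a nuclear
  pMAPK returns it to the cytoplasm as inactive MAPK and itself goes dormant
  for a fixed recovery period.

No agents are created or destroyed during a run: the per-species totals are
exact invariants of the simulation.

The performance-critical representation is :class:`Population`, a
struct-of-arrays container updated with vectorised numpy operations; the
per-agent dataclasses (:class:`KinaseAgent`, :class:`ExporterAgent`) are
lightweight views used in the public API and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo

# species codes
MAPKK = 0
MAPK = 1
EXR = 2

# state codes (ACTIVE means pMAPKK / pMAPK / ExR; INACTIVE means dormant
# MAPKK, unphosphorylated MAPK, dExR)
INACTIVE = 0
ACTIVE = 1

SPECIES_NAMES = {MAPKK: "MAPKK", MAPK: "MAPK", EXR: "ExR"}


@dataclass
class KinaseAgent:
    id: int
    species: int  # MAPKK or MAPK
    state: int
    position: np.ndarray
    home_compartment: int = geo.CYTOPLASM
    dormancy_remaining: float = 0.0


@dataclass
class ExporterAgent:
    id: int
    state: int
    position: np.ndarray
    dormancy_remaining: float = 0.0


def tick_dormancy(agent, dt: float):
    """Advance one agent's dormancy clock by ``dt`` seconds (floored at zero).

    A dormant MAPKK or dExR whose clock reaches zero on this tick flips to its
    active state.  MAPK has no clock and is never flipped here.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    agent.dormancy_remaining = max(agent.dormancy_remaining - dt, 0.0)
    clocked = isinstance(agent, ExporterAgent) or agent.species == MAPKK
    if clocked and agent.state == INACTIVE and agent.dormancy_remaining == 0.0:
        agent.state = ACTIVE
    return agent


@dataclass
class PopulationConfig:
    """Initial agent counts and placement parameters.

    The two-compartment default mirrors the saturating-stimulus setup: 500
    MAPKK that all activate synchronously when the upstream stimulus arrives
    (80 s initial dormancy with equal bounds) and 500 inactive MAPK free in
    the cytoplasm, with 180 active plus 180 dormant export receptors.  The
    multi-compartment preset instead distributes 120 MAPKK (5% initially
    active) and 500 inactive MAPK across the sub-compartments.
    """

    n_mapkk: int = 500
    mapkk_active_fraction: float = 0.0
    n_mapk: int = 500
    mapk_active_fraction: float = 0.0
    n_exr_active: int = 180
    n_exr_dormant: int = 180
    #: mean recovery period of an export receptor after each export event (s);
    #: short enough that export is capture-limited, never renewal-limited
    exr_dormancy_s: float = 30.0
    #: relative half-width of the uniform recovery-period draw: each dormancy
    #: is U[(1-j), (1+j)] * exr_dormancy_s
    exr_dormancy_jitter: float = 1.0
    #: thickness of the shell at the nuclear membrane ExR agents move in
    exr_shell_width: float = 0.5
    #: initially dormant ExR wake uniformly over [0, this] seconds
    initial_exr_dormancy_s: float = 30.0
    #: initially dormant MAPKK wake uniformly over
    #: [initial_dormancy_lower_s, initial_dormancy_s] seconds; equal bounds
    #: model a synchronous upstream stimulus arriving after that delay
    initial_dormancy_s: float = 80.0
    initial_dormancy_lower_s: float = 80.0
    #: set by the multi-compartment preset: geometry must have sub-compartments
    require_compartments: bool = False

    def validate(self) -> None:
        for name in ("n_mapkk", "n_mapk", "n_exr_active", "n_exr_dormant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("mapkk_active_fraction", "mapk_active_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.initial_exr_dormancy_s < 0:
            raise ValueError("dormancy periods must be non-negative")
        if self.exr_dormancy_s < 0 or self.initial_dormancy_s < 0:
            raise ValueError("dormancy periods must be non-negative")
        if not 0.0 <= self.initial_dormancy_lower_s <= self.initial_dormancy_s:
            raise ValueError(
                "initial_dormancy_lower_s must be in [0, initial_dormancy_s]"
            )
        if not 0.0 <= self.exr_dormancy_jitter <= 1.0:
            raise ValueError("exr_dormancy_jitter must be in [0, 1]")


def two_compartment_counts() -> PopulationConfig:
    """Saturating-stimulus preset: 500 MAPKK, 500 MAPK, 180+180 ExR.

    The full MAPKK pool is switched on synchronously by the upstream stimulus
    after the calibrated propagation delay (80 s); thereafter the stimulus is
    saturating (constitutive activity unless a RADP schedule is set).
    """
    return PopulationConfig(n_mapkk=500, mapkk_active_fraction=0.0, n_mapk=500)


def multi_compartment_counts(initial_active_fraction: float = 0.05) -> PopulationConfig:
    """Resting-cell preset: 120 MAPKK (5% active), 500 inactive MAPK.

    The resting 95% of the MAPKK pool is triggered synchronously by the
    arriving stimulus after the same calibrated 80 s propagation delay.
    """
    return PopulationConfig(
        n_mapkk=120,
        mapkk_active_fraction=initial_active_fraction,
        n_mapk=500,
        require_compartments=True,
    )


def stationary_radp_counts(radp_upper_s: float) -> PopulationConfig:
    """Two-compartment preset with stationary (desynchronised) MAPKK phases.

    Models a pool that has been cycling through its re-activation delay long
    before the observation starts: every MAPKK begins dormant with a residual
    clock drawn uniformly over one full delay period, so activation rises
    gradually and no synchronised binding bursts ever form.
    """
    return PopulationConfig(
        n_mapkk=500,
        mapkk_active_fraction=0.0,
        n_mapk=500,
        initial_dormancy_lower_s=0.0,
        initial_dormancy_s=radp_upper_s,
    )


class Population:
    """Struct-of-arrays container for all agents in a run."""

    def __init__(
        self,
        species: np.ndarray,
        state: np.ndarray,
        pos: np.ndarray,
        home: np.ndarray,
        dormancy: np.ndarray,
        exr_dormancy_s: float,
        exr_shell_width: float,
        exr_dormancy_jitter: float = 1.0,
    ):
        self.species = np.asarray(species, dtype=np.int8)
        self.state = np.asarray(state, dtype=np.int8)
        self.pos = np.asarray(pos, dtype=float)
        self.home = np.asarray(home, dtype=np.int64)
        self.dormancy = np.asarray(dormancy, dtype=float)
        self.exr_dormancy_s = float(exr_dormancy_s)
        self.exr_shell_width = float(exr_shell_width)
        self.exr_dormancy_jitter = float(exr_dormancy_jitter)
        # cluster index per agent (-1 = unconfined); used by signalosome mode
        self.cluster = np.full(len(self.species), -1, dtype=np.int64)
        self.totals = {
            s: int(np.sum(self.species == s)) for s in (MAPKK, MAPK, EXR)
        }

    def __len__(self) -> int:
        return len(self.species)

    # -- masks -------------------------------------------------------------
    def mask(self, species: int, state: int | None = None) -> np.ndarray:
        m = self.species == species
        if state is not None:
            m &= self.state == state
        return m

    # -- counts ------------------------------------------------------------
    def counts(self) -> dict[str, int]:
        return {
            "MAPK": int(np.sum(self.mask(MAPK, INACTIVE))),
            "pMAPK": int(np.sum(self.mask(MAPK, ACTIVE))),
            "pMAPKK": int(np.sum(self.mask(MAPKK, ACTIVE))),
            "MAPKK_dormant": int(np.sum(self.mask(MAPKK, INACTIVE))),
            "ExR": int(np.sum(self.mask(EXR, ACTIVE))),
            "dExR": int(np.sum(self.mask(EXR, INACTIVE))),
        }

    def compartment_counts(self, n_compartments: int) -> dict[str, int]:
        """Inactive-MAPK count per home sub-compartment."""
        out = {}
        m = self.mask(MAPK, INACTIVE)
        for k in range(n_compartments):
            out[f"cmpt_{k}_MAPK"] = int(np.sum(m & (self.home == k)))
        return out

    def check_conservation(self) -> None:
        for s, total in self.totals.items():
            now = int(np.sum(self.species == s))
            if now != total:
                raise AssertionError(
                    f"{SPECIES_NAMES[s]} total changed: {total} -> {now}"
                )

    # -- clocks ------------------------------------------------------------
    def tick_clocks(self, dt: float) -> None:
        """Vectorised dormancy tick: decrement, floor at zero, wake at zero."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        np.maximum(self.dormancy - dt, 0.0, out=self.dormancy)
        clocked = (self.species == MAPKK) | (self.species == EXR)
        wake = clocked & (self.state == INACTIVE) & (self.dormancy == 0.0)
        self.state[wake] = ACTIVE

    # -- single-agent views --------------------------------------------------
    def agent(self, i: int):
        if self.species[i] == EXR:
            return ExporterAgent(
                id=i,
                state=int(self.state[i]),
                position=self.pos[i].copy(),
                dormancy_remaining=float(self.dormancy[i]),
            )
        return KinaseAgent(
            id=i,
            species=int(self.species[i]),
            state=int(self.state[i]),
            position=self.pos[i].copy(),
            home_compartment=int(self.home[i]),
            dormancy_remaining=float(self.dormancy[i]),
        )


def init_population(
    pop_config: PopulationConfig,
    geometry: geo.CellGeometry,
    rng: np.random.Generator,
) -> Population:
    """Create and place all agents for a run.

    In a multi-compartment geometry every kinase agent is assigned a home
    sub-compartment uniformly at random and placed uniformly inside it; in the
    two-compartment geometry kinases are placed uniformly in the cytoplasmic
    shell.  Export receptors start in the thin shell at the nuclear membrane.
    Initially active MAPK (pMAPK) starts in the nucleus.
    """
    pop_config.validate()
    n_cmpt = geometry.n_compartments
    multi = n_cmpt > 0
    if pop_config.require_compartments and not multi:
        raise ValueError(
            "multi-compartment population preset requires a geometry with "
            "sub-compartments (n_compartments > 0)"
        )

    species_l, state_l, pos_l, home_l, dorm_l = [], [], [], [], []

    def _place_kinase(n: int) -> tuple[np.ndarray, np.ndarray]:
        if multi:
            homes = rng.integers(0, n_cmpt, size=n)
            pts = np.empty((n, 3))
            for k in range(n_cmpt):
                m = homes == k
                c = geometry.compartments[k]
                pts[m] = geo.sample_in_sphere(rng, c.radius, int(m.sum()), c.center)
            return pts, homes
        pts = geo.sample_in_cytoplasm(rng, geometry, n)
        return pts, np.full(n, geo.CYTOPLASM, dtype=np.int64)

    # MAPKK ------------------------------------------------------------------
    n_kk = pop_config.n_mapkk
    n_kk_active = int(round(pop_config.mapkk_active_fraction * n_kk))
    pts, homes = _place_kinase(n_kk)
    kk_state = np.zeros(n_kk, dtype=np.int8)
    kk_state[:n_kk_active] = ACTIVE
    kk_dorm = np.zeros(n_kk)
    n_dormant = n_kk - n_kk_active
    if n_dormant > 0 and pop_config.initial_dormancy_s > 0:
        kk_dorm[n_kk_active:] = rng.uniform(
            pop_config.initial_dormancy_lower_s,
            pop_config.initial_dormancy_s,
            size=n_dormant,
        )
    species_l.append(np.full(n_kk, MAPKK))
    state_l.append(kk_state)
    pos_l.append(pts)
    home_l.append(homes)
    dorm_l.append(kk_dorm)

    # MAPK -------------------------------------------------------------------
    n_k = pop_config.n_mapk
    n_k_active = int(round(pop_config.mapk_active_fraction * n_k))
    pts, homes = _place_kinase(n_k)
    if n_k_active > 0:  # initially phosphorylated MAPK sits in the nucleus
        pts[:n_k_active] = geo.sample_in_sphere(
            rng, geometry.nucleus_radius, n_k_active
        )
    k_state = np.zeros(n_k, dtype=np.int8)
    k_state[:n_k_active] = ACTIVE
    species_l.append(np.full(n_k, MAPK))
    state_l.append(k_state)
    pos_l.append(pts)
    home_l.append(homes)
    dorm_l.append(np.zeros(n_k))

    # ExR --------------------------------------------------------------------
    n_e = pop_config.n_exr_active + pop_config.n_exr_dormant
    pts = geo.sample_in_membrane_shell(rng, geometry, n_e, pop_config.exr_shell_width)
    e_state = np.zeros(n_e, dtype=np.int8)
    e_state[: pop_config.n_exr_active] = ACTIVE
    e_dorm = np.zeros(n_e)
    if pop_config.n_exr_dormant > 0 and pop_config.initial_exr_dormancy_s > 0:
        e_dorm[pop_config.n_exr_active :] = rng.uniform(
            0.0, pop_config.initial_exr_dormancy_s, size=pop_config.n_exr_dormant
        )
    species_l.append(np.full(n_e, EXR))
    state_l.append(e_state)
    pos_l.append(pts)
    home_l.append(np.full(n_e, geo.NUCLEUS, dtype=np.int64))
    dorm_l.append(e_dorm)

    return Population(
        species=np.concatenate(species_l),
        state=np.concatenate(state_l),
        pos=np.vstack(pos_l) if pos_l else np.empty((0, 3)),
        home=np.concatenate(home_l),
        dormancy=np.concatenate(dorm_l),
        exr_dormancy_s=pop_config.exr_dormancy_s,
        exr_shell_width=pop_config.exr_shell_width,
        exr_dormancy_jitter=pop_config.exr_dormancy_jitter,
    )
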