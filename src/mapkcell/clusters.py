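"""Signalosome clusters for the two-compartment model.

At signal arrival all kinase agents are gathered into a small number of
co-localised clusters (the model's rendering of Ras/Raf-style nanocluster
assembly); close packing makes the first activation phase fast.  At a fixed
disassembly time the confinement is lifted and the components diffuse out
into the cytoplasm, producing the tailing-off second phase.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from . import agents as ag
from . import geometry as geo


@dataclass
class ClusterConfig:
    enabled: bool = True
    n_clusters: int = 10
    cluster_radius: float = 1.5
    disassembly_time_min: float = 10.0

    def validate(self) -> None:
        if self.enabled and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1 when clusters are enabled")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.disassembly_time_min < 0:
            raise ValueError("disassembly_time_min must be non-negative")


@dataclass
class ClusterState:
    centers: np.ndarray  # (n_clusters, 3)
    radius: float
    disassembled: bool = False
    disassembled_at_min: float | None = None


def assemble_clusters(
    population: ag.Population,
    geometry: geo.CellGeometry,
    config: ClusterConfig,
    rng: np.random.Generator,
) -> ClusterState:
    """Gather all kinase agents into ``n_clusters`` cytoplasmic clusters.

    Cluster centres are sampled uniformly over the band of radii where the
    whole cluster sphere fits in the cytoplasmic shell (clusters may touch
    each other).  MAPKK and MAPK agents are shuffled and dealt round-robin to
    clusters, then placed uniformly within their cluster sphere.  Confinement
    holds until :func:`disassemble`.
    """
    config.validate()
    if geometry.n_compartments > 0:
        raise ValueError("signalosome clusters apply to the two-compartment model only")
    r_lo = geometry.nucleus_radius + config.cluster_radius
    r_hi = geometry.cell_radius - config.cluster_radius
    if r_lo >= r_hi:
        # degenerate: one cell-scale cluster is equivalent to free placement
        r_lo = geometry.nucleus_radius
        r_hi = geometry.cell_radius
    u = rng.random(config.n_clusters)
    radii = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    dirs = rng.normal(size=(config.n_clusters, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    centers = radii[:, None] * dirs

    # all MAPKK plus cytoplasmic (inactive) MAPK; nuclear pMAPK is never pulled in
    kin = np.flatnonzero(
        (population.species == ag.MAPKK) | population.mask(ag.MAPK, ag.INACTIVE)
    )
    order = rng.permutation(kin)
    assign = np.arange(len(order)) % config.n_clusters
    population.cluster[order] = assign
    for k in range(config.n_clusters):
        members = order[assign == k]
        population.pos[members] = geo.sample_in_sphere(
            rng, config.cluster_radius, len(members), centers[k]
        )
    return ClusterState(centers=centers, radius=config.cluster_radius)


def disassemble(
    population: ag.Population, state: ClusterState, t_min: float
) -> ClusterState:
    """Lift cluster confinement; agents thereafter roam the whole cytoplasm."""
    if not state.disassembled:
        population.cluster[:] = -1
        state.disassembled = True
        state.disassembled_at_min = t_min
        print(f"[mapkcell] t={t_min:.2f} min: signalosome clusters disassembled", file=sys.stderr)
    return state
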