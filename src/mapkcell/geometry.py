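"""Spherical cell world: nucleus, cytoplasm, and randomly placed sub-compartments.

The cell is a sphere centred on the origin containing a concentric nuclear
sphere; the cytoplasm is the shell between the two.  A multi-compartment
geometry additionally carries a set of non-overlapping spherical
sub-compartments placed entirely inside the cytoplasmic shell.  Absolute
length is arbitrary (only ratios matter for the dynamics); the defaults are
cell radius 10, nucleus radius 3, sub-compartment radius 1.5 model units.

Region labels are small integers so that agent arrays can store them:
``CYTOPLASM = -1``, ``NUCLEUS = -2``, and sub-compartment ids ``0..k-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CYTOPLASM = -1
NUCLEUS = -2

#: interior clamp used when iterative reflection fails to land inside
EPS = 1e-6


@dataclass(frozen=True)
class Compartment:
    """A spherical region of the cell."""

    id: int
    center: np.ndarray
    radius: float
    kind: str = "subcompartment"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"compartment radius must be positive, got {self.radius}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass
class CellGeometry:
    """Spherical cell with a concentric nucleus and optional sub-compartments."""

    cell_radius: float = 10.0
    nucleus_radius: float = 3.0
    nucleus_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    compartments: list[Compartment] = field(default_factory=list)

    def __post_init__(self):
        self.nucleus_center = np.asarray(self.nucleus_center, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.nucleus_radius < self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        ids = [c.id for c in self.compartments]
        if len(ids) != len(set(ids)):
            raise ValueError("compartment ids must be unique")
        for c in self.compartments:
            r = float(np.linalg.norm(c.center - self.nucleus_center))
            if r + c.radius > self.cell_radius or r - c.radius < self.nucleus_radius:
                raise ValueError(
                    f"compartment {c.id} does not lie entirely in the cytoplasmic shell"
                )
        for i, a in enumerate(self.compartments):
            for b in self.compartments[i + 1 :]:
                if np.linalg.norm(a.center - b.center) <= a.radius + b.radius:
                    raise ValueError(f"compartments {a.id} and {b.id} overlap")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def compartment_by_id(self, cid: int) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(f"no compartment with id {cid}")


def place_compartments(
    n_compartments: int,
    cell_radius: float = 10.0,
    nucleus_radius: float = 3.0,
    compartment_radius: float = 1.5,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 100_000,
) -> CellGeometry:
    """Place ``n_compartments`` non-overlapping spheres in the cytoplasmic shell.

    Rejection sampling: candidate centres are drawn uniformly over the band of
    radii for which the whole compartment sphere fits between the nuclear and
    plasma membranes, and rejected if they overlap a previously placed
    compartment.  Reproducible for a fixed ``rng`` seed.
    """
    if n_compartments < 0:
        raise ValueError("n_compartments must be non-negative")
    rng = np.random.default_rng(rng)
    r_lo = nucleus_radius + compartment_radius
    r_hi = cell_radius - compartment_radius
    if n_compartments > 0 and r_lo >= r_hi:
        raise ValueError(
            f"compartment_radius={compartment_radius} leaves no room between "
            f"nucleus_radius={nucleus_radius} and cell_radius={cell_radius}"
        )
    placed: list[Compartment] = []
    attempts = 0
    while len(placed) < n_compartments:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_compartments} compartments of radius "
                f"{compartment_radius} in shell [{nucleus_radius}, {cell_radius}] "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        center = _sample_in_shell(rng, r_lo, r_hi, 1)[0]
        ok = all(
            np.linalg.norm(center - c.center) > 2 * compartment_radius
            for c in placed
        )
        if ok:
            placed.append(
                Compartment(id=len(placed), center=center, radius=compartment_radius)
            )
    return CellGeometry(
        cell_radius=cell_radius,
        nucleus_radius=nucleus_radius,
        compartments=placed,
    )


def region_of(geometry: CellGeometry, p: np.ndarray) -> int:
    """Region label of a single point (nucleus, sub-compartment id, or cytoplasm)."""
    return int(region_of_many(geometry, np.asarray(p, dtype=float)[None, :])[0])


def region_of_many(geometry: CellGeometry, pts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`region_of` for an ``(n, 3)`` array of points."""
    pts = np.asarray(pts, dtype=float)
    r = np.linalg.norm(pts - geometry.nucleus_center, axis=1)
    if np.any(r > geometry.cell_radius * (1 + 1e-9)):
        raise ValueError("point(s) outside the cell")
    labels = np.full(len(pts), CYTOPLASM, dtype=np.int64)
    labels[r <= geometry.nucleus_radius] = NUCLEUS
    for c in geometry.compartments:
        inside = np.linalg.norm(pts - c.center, axis=1) <= c.radius
        labels[inside] = c.id
    return labels


def reflect_step(
    p: np.ndarray,
    step: np.ndarray,
    r_out: float,
    r_in: float = 0.0,
    center: np.ndarray | None = None,
    max_iter: int = 16,
) -> np.ndarray:
    """Move points by ``step`` with specular reflection at spherical boundaries.

    The allowed region is ``r_in <= |x - center| <= r_out`` (a full sphere when
    ``r_in`` is 0).  Endpoints already inside are returned unchanged.  A point
    beyond a boundary is mirrored radially across that boundary; this is
    iterated until the point is inside or ``max_iter`` is reached, after which
    the radius is clamped to the interior by :data:`EPS`.  Accepts a single
    point or an ``(n, 3)`` array.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    x = np.atleast_2d(p + step).astype(float).copy()
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    d = x - c
    for _ in range(max_iter):
        r = np.linalg.norm(d, axis=1)
        over = r > r_out
        under = r < r_in
        if not (over.any() or under.any()):
            break
        safe = np.where(r > 0, r, 1.0)
        if over.any():
            d[over] *= ((2 * r_out - r[over]) / safe[over])[:, None]
        if under.any():
            # radius 0 has no direction to mirror along; leave for the clamp
            fix = under & (r > 0)
            d[fix] *= ((2 * r_in - r[fix]) / safe[fix])[:, None]
        r = np.linalg.norm(d, axis=1)
        # a mirrored radius can itself be out of band (thin shells); loop handles it
    r = np.linalg.norm(d, axis=1)
    bad_hi = r > r_out
    bad_lo = r < r_in
    if bad_hi.any():
        safe = np.where(r > 0, r, 1.0)
        d[bad_hi] *= ((r_out - EPS) / safe[bad_hi])[:, None]
    if bad_lo.any():
        zero = bad_lo & (np.linalg.norm(d, axis=1) == 0)
        if zero.any():
            d[zero] = np.array([r_in + EPS, 0.0, 0.0])
        bad_lo = np.linalg.norm(d, axis=1) < r_in
        if bad_lo.any():
            r2 = np.linalg.norm(d[bad_lo], axis=1)
            d[bad_lo] *= ((r_in + EPS) / r2)[:, None]
    x = c + d
    return x[0] if single else x


# ---------------------------------------------------------------------------
# uniform sampling helpers

def _sample_in_shell(rng: np.random.Generator, r_in: float, r_out: float, n: int) -> np.ndarray:
    """Uniform points in the spherical shell r_in <= r <= r_out (origin-centred)."""
    u = rng.random(n)
    radii = (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
    return radii[:, None] * _random_directions(rng, n)


def sample_in_sphere(
    rng: np.random.Generator, radius: float, n: int, center: np.ndarray | None = None
) -> np.ndarray:
    """Uniform points inside a sphere."""
    pts = _sample_in_shell(rng, 0.0, radius, n)
    if center is not None:
        pts = pts + np.asarray(center, dtype=float)
    return pts


def sample_in_cytoplasm(rng: np.random.Generator, geometry: CellGeometry, n: int) -> np.ndarray:
    """Uniform points in the cytoplasmic shell (sub-compartments not excluded)."""
    return _sample_in_shell(rng, geometry.nucleus_radius, geometry.cell_radius, n)


def sample_in_membrane_shell(
    rng: np.random.Generator, geometry: CellGeometry, n: int, width: float
) -> np.ndarray:
    """Uniform points in the thin shell just inside the nuclear membrane."""
    return _sample_in_shell(rng, geometry.nucleus_radius - width, geometry.nucleus_radius, n)


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    return v / norms[:, None]
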