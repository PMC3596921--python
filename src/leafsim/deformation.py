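"""Mask-controlled mass-spring deformation of a leaf mesh.

Mesh vertices become particles, mesh edges become springs at their initial
rest length.  Particle masses are read from a grayscale mask map through the
per-vertex texture coordinates: mass = 0.5 where the pixel is black, and
ln(gray + 1) otherwise, so darker (lighter-mass) regions accelerate more
under the same force and the leaf curls differentially — edges and corners
first if the mask darkens them, vein flanks if the vein is painted bright.

Integration is explicit Euler in the order: acceleration from the forces at
time t, velocity from the new acceleration, position from the new velocity.
Naive explicit integration lets springs stretch without bound
("over-elasticity"); after the velocity update, a velocity-constraint sweep
projects relative velocities so that no spring's predicted next length
exceeds (1 + tau_c) times its rest length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidInputError,
    NumericalInstabilityError,
)
from .meshing import TriMesh

__all__ = [
    "MaskMap",
    "ParticleSystem",
    "SpringConstraints",
    "SimConfig",
    "constant_force",
    "build_constraints",
    "mass_from_mask",
    "euler_step",
    "constrain_velocities",
    "simulate",
]

logger = logging.getLogger(__name__)

ForceField = Callable[[np.ndarray, float], np.ndarray]


def constant_force(vector) -> ForceField:
    """A uniform field force: every particle receives ``vector``, always.

    Note this is a *force*, not an acceleration — under equal force, lighter
    particles accelerate more, which is what the mask map exploits.
    """
    v = np.asarray(vector, dtype=float).reshape(3)

    def field_fn(positions: np.ndarray, t: float) -> np.ndarray:
        return np.broadcast_to(v, positions.shape)

    return field_fn


@dataclass
class MaskMap:
    """An 8-bit grayscale grid addressed by texture coordinates.

    Row 0 is the top image row; uv (0, 0) addresses the lower-left pixel.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("mask must be a non-empty 2D grid")
        if px.min() < 0 or px.max() > 255:
            raise InvalidInputError("mask values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def values_at_uv(self, uv: np.ndarray) -> np.ndarray:
        """Nearest-pixel grayscale lookup for an (n, 2) uv array."""
        uv = np.asarray(uv, dtype=float)
        if uv.min() < 0.0 or uv.max() > 1.0:
            raise InvalidInputError("uv coordinates must lie in [0, 1]^2")
        col = np.minimum((uv[:, 0] * self.width).astype(int), self.width - 1)
        row_b = np.minimum((uv[:, 1] * self.height).astype(int), self.height - 1)
        return self.pixels[self.height - 1 - row_b, col].astype(int)


@dataclass
class ParticleSystem:
    """Per-particle state of the mass-spring model."""

    masses: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    fixed: np.ndarray

    @classmethod
    def from_mesh(
        cls, mesh: TriMesh, masses: np.ndarray, fixed: Optional[np.ndarray] = None
    ) -> "ParticleSystem":
        n = len(mesh.vertices)
        masses = np.asarray(masses, dtype=float)
        if np.any(masses <= 0):
            raise InvalidInputError("particle masses must be positive")
        if fixed is None:
            fixed = np.zeros(n, dtype=bool)
        return cls(
            masses=masses,
            positions=mesh.vertices3.astype(float).copy(),
            velocities=np.zeros((n, 3)),
            accelerations=np.zeros((n, 3)),
            fixed=np.asarray(fixed, dtype=bool),
        )

    def kinetic_energy(self) -> float:
        v2 = np.einsum("ij,ij->i", self.velocities, self.velocities)
        return float(0.5 * np.sum(self.masses * v2))


@dataclass
class SpringConstraints:
    """Spring constraints: one per unique undirected mesh edge."""

    pairs: np.ndarray  # (m, 2) particle indices
    rest_lengths: np.ndarray  # (m,)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise InvalidInputError("spring endpoints must differ")
        if np.any(self.rest_lengths <= 0):
            raise InvalidInputError("rest lengths must be positive")

    def __len__(self) -> int:
        return len(self.pairs)

    def current_lengths(self, positions: np.ndarray) -> np.ndarray:
        d = positions[self.pairs[:, 0]] - positions[self.pairs[:, 1]]
        return np.linalg.norm(d, axis=1)


@dataclass
class SimConfig:
    """Integration and material parameters.

    dt must be small relative to sqrt(mass/stiffness) for the explicit
    scheme to stay stable; the defaults satisfy that for mask-derived
    masses (>= 0.5) and the default stiffness.
    """

    dt: float = 0.005
    tau_c: float = 0.1
    stiffness: float = 50.0
    damping: float = 0.1
    external_force: Optional[ForceField] = None
    n_constraint_passes: int = 3

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")
        if self.tau_c < 0:
            raise InvalidInputError("tau_c must be >= 0")
        if self.damping < 0:
            raise InvalidInputError("damping must be >= 0")
        if self.n_constraint_passes < 1:
            raise InvalidInputError("n_constraint_passes must be >= 1")


# ---------------------------------------------------------------------------
# constraint construction (flag traversal over mesh adjacency)
# ---------------------------------------------------------------------------

def build_constraints(mesh: TriMesh) -> SpringConstraints:
    """One spring per unique mesh edge, via the flag-traversal procedure.

    Each particle is visited once in index order; constraints are created
    only toward adjacent particles that have not yet been traversed, so no
    undirected pair is duplicated.
    """
    n = len(mesh.vertices)
    adjacent: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in mesh.triangles:
        adjacent[a].update((b, c))
        adjacent[b].update((a, c))
        adjacent[c].update((a, b))
    traversed = np.zeros(n, dtype=bool)
    pairs = []
    for i in range(n):
        for j in sorted(adjacent[i]):
            if not traversed[j]:
                pairs.append((i, j))
        traversed[i] = True
    pairs = np.array(pairs, dtype=np.int64)
    P = mesh.vertices3
    rest = np.linalg.norm(P[pairs[:, 0]] - P[pairs[:, 1]], axis=1)
    return SpringConstraints(pairs=pairs, rest_lengths=rest)


def mass_from_mask(mesh: TriMesh, mask: MaskMap) -> np.ndarray:
    """Particle masses from mask grayscale: 0.5 at black, else ln(gray+1).

    The explicit branch at gray = 0 avoids ln(1) = 0, i.e. massless
    particles; masses lie in [0.5, ln 256] and increase with brightness.
    """
    gray = mask.values_at_uv(mesh.uv)
    return np.where(gray == 0, 0.5, np.log(gray + 1.0))


# ---------------------------------------------------------------------------
# explicit Euler integration with velocity constraints
# ---------------------------------------------------------------------------

def _forces(
    ps: ParticleSystem, constraints: SpringConstraints, config: SimConfig, t: float
) -> np.ndarray:
    u = constraints.pairs[:, 0]
    v = constraints.pairs[:, 1]
    d = ps.positions[u] - ps.positions[v]
    length = np.linalg.norm(d, axis=1)
    safe = np.where(length > 0, length, 1.0)
    direction = d / safe[:, None]
    fmag = -config.stiffness * (length - constraints.rest_lengths)
    f = fmag[:, None] * direction
    F = np.zeros_like(ps.positions)
    np.add.at(F, u, f)
    np.add.at(F, v, -f)
    F -= config.damping * ps.velocities
    if config.external_force is not None:
        F = F + config.external_force(ps.positions, t)
    return F


def _check_finite(arr: np.ndarray, what: str, step: Optional[int]):
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0][0])
        where = f" at step {step}" if step is not None else ""
        raise NumericalInstabilityError(
            f"non-finite {what} for particle {bad}{where}; reduce dt"
        )


def _velocity_update(ps, constraints, config, t, step=None):
    F = _forces(ps, constraints, config, t)
    _check_finite(F, "force", step)
    free = ~ps.fixed
    ps.accelerations[:] = 0.0
    ps.accelerations[free] = F[free] / ps.masses[free, None]
    ps.velocities[free] += config.dt * ps.accelerations[free]
    ps.velocities[ps.fixed] = 0.0


def _position_update(ps, config):
    free = ~ps.fixed
    ps.positions[free] += config.dt * ps.velocities[free]


def euler_step(
    ps: ParticleSystem,
    constraints: SpringConstraints,
    config: SimConfig,
    t: float = 0.0,
    step: Optional[int] = None,
) -> ParticleSystem:
    """One unconstrained explicit Euler step, in place.

    Update order: a <- F(t)/mu, v <- v + dt a, P <- P + dt v (the position
    uses the freshly updated velocity).  Fixed particles never move.
    """
    _velocity_update(ps, constraints, config, t, step)
    _position_update(ps, config)
    return ps


def constrain_velocities(
    ps: ParticleSystem, constraints: SpringConstraints, config: SimConfig
) -> ParticleSystem:
    """Clamp over-elasticity by correcting tentative velocities, in place.

    For each spring, the predicted relative position P(t) + V(t+dt) dt must
    not exceed (1 + tau_c) L.  Offenders have their relative velocity
    reduced along the predicted axis so the next length lands exactly on
    the bound; the correction splits equally between two free endpoints and
    falls entirely on the free one when the other is anchored.  Sweeps run
    in ascending constraint order, ``n_constraint_passes`` times and then
    until no violation remains.
    """
    dt = config.dt
    u = constraints.pairs[:, 0]
    v = constraints.pairs[:, 1]
    bound = (1.0 + config.tau_c) * constraints.rest_lengths
    both_fixed = ps.fixed[u] & ps.fixed[v]
    # heavily loaded meshes can need a few hundred sweeps before every
    # spring's prediction is inside its bound
    hard_cap = config.n_constraint_passes + 2000
    for sweep in range(hard_cap):
        rel_p = ps.positions[u] - ps.positions[v]
        rel_v = ps.velocities[u] - ps.velocities[v]
        pred = rel_p + rel_v * dt
        pred_len = np.linalg.norm(pred, axis=1)
        # relative slack of 1e-10 absorbs the floating-point limit cycle of
        # repeated projections; well inside the 1e-9 elongation tolerance
        violated = pred_len > bound * (1.0 + 1e-10)
        if not violated.any():
            if sweep >= config.n_constraint_passes:
                break
            continue
        if np.any(violated & both_fixed):
            bad = int(np.nonzero(violated & both_fixed)[0][0])
            raise ConfigurationError(
                f"spring {bad} joins two fixed particles but violates its bound"
            )
        for c in np.nonzero(violated)[0]:
            iu, iv = u[c], v[c]
            q = (ps.positions[iu] - ps.positions[iv]) + (
                ps.velocities[iu] - ps.velocities[iv]
            ) * dt
            qlen = float(np.linalg.norm(q))
            if qlen <= bound[c]:
                continue
            corr = (qlen - bound[c]) / dt * (q / qlen)
            if ps.fixed[iu]:
                ps.velocities[iv] += corr
            elif ps.fixed[iv]:
                ps.velocities[iu] -= corr
            else:
                ps.velocities[iu] -= 0.5 * corr
                ps.velocities[iv] += 0.5 * corr
    else:
        raise NumericalInstabilityError(
            "velocity constraints did not converge; reduce dt or stiffness"
        )
    return ps


def simulate(
    mesh: TriMesh,
    mask: MaskMap,
    config: SimConfig,
    n_steps: int,
    snapshot_every: int = 1,
    petiole: Optional[Sequence[float]] = None,
    anchor_radius: float = 0.0,
    log_every: int = 100,
) -> list[TriMesh]:
    """Run the full deformation and return mesh snapshots.

    Snapshot 0 is the undeformed mesh; one further snapshot is stored every
    ``snapshot_every`` steps.  Initial velocities and accelerations are
    zero.  Vertices within ``anchor_radius`` of the planar ``petiole``
    point are fixed for the whole run.
    """
    if n_steps < 0:
        raise InvalidInputError("n_steps must be >= 0")
    if snapshot_every < 1:
        raise InvalidInputError("snapshot_every must be >= 1")
    masses = mass_from_mask(mesh, mask)
    fixed = np.zeros(len(mesh.vertices), dtype=bool)
    if petiole is not None:
        p = np.asarray(petiole, dtype=float).reshape(2)
        d = np.linalg.norm(mesh.vertices2 - p, axis=1)
        fixed = d <= anchor_radius
    ps = ParticleSystem.from_mesh(mesh, masses, fixed)
    constraints = build_constraints(mesh)
    snapshots = [mesh.with_vertices(ps.positions.copy())]
    for step in range(1, n_steps + 1):
        t = (step - 1) * config.dt
        _velocity_update(ps, constraints, config, t, step)
        constrain_velocities(ps, constraints, config)
        _position_update(ps, config)
        _check_finite(ps.positions, "position", step)
        if step % log_every == 0:
            lengths = constraints.current_lengths(ps.positions)
            elong = float(
                np.max((lengths - constraints.rest_lengths) / constraints.rest_lengths)
            )
            logger.info(
                "step=%d max_elongation=%.4g kinetic_energy=%.4g",
                step, elong, ps.kinetic_energy(),
            )
        if step % snapshot_every == 0:
            snapshots.append(mesh.with_vertices(ps.positions.copy()))
    return snapshots
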