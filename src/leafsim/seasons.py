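"""Environment-conditioned Markov senescence of leaf populations.

Each leaf occupies one of n discrete states (a texture label plus an
optional deformation snapshot).  The probability of staying in state i over
a step of duration t is the exponential survival P_ii(e, t) =
exp(-ln2 / tau_i(e) * t), where the half-life tau_i(e) is the bilinear
interpolation, over normalized temperature and humidness, of four constants
specified at the environmental extremes (dry-cold, dry-warm, wet-cold,
wet-warm).  The leaving probability 1 - P_ii is split among successor
states j by interpolated weights X_ij(e), renormalized so each matrix row
is stochastic.  Populations evolve by sampling every leaf independently
once per epoch of an environment schedule.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError, SpecificationError

__all__ = [
    "CORNER_ORDER",
    "Environment",
    "LeafState",
    "SenescenceSpec",
    "LeafPopulation",
    "bilinear_interp",
    "p_stay",
    "transition_matrix",
    "evolve_population",
]

#: fixed ordering of the four environmental extremes in all corner arrays
CORNER_ORDER = ("dry-cold", "dry-warm", "wet-cold", "wet-warm")

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Environment:
    """Normalized environment: temperature and humidness in [0, 1].

    0 means cold / dry, 1 means warm / wet.  Physical units (degrees C,
    relative humidity) should be mapped linearly onto [0, 1] by the caller.
    """

    temperature: float
    humidness: float

    def __post_init__(self):
        for name in ("temperature", "humidness"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise InvalidInputError(f"{name}={val} outside [0, 1]")


@dataclass(frozen=True)
class LeafState:
    index: int
    name: str = ""
    texture_label: str = ""
    deformation_snapshot: Optional[str] = None


def bilinear_interp(env: Environment, corners: Sequence[float]) -> float:
    """Bilinear interpolation of four corner constants at ``env``.

    Corners are ordered (dry-cold, dry-warm, wet-cold, wet-warm); the
    temperature axis runs cold -> warm, the humidness axis dry -> wet.  At
    each corner the interpolant returns that corner's constant exactly.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4,):
        raise InvalidInputError("exactly four corner constants required")
    w = env.temperature
    h = env.humidness
    c_dc, c_dw, c_wc, c_ww = corners
    return float(
        (1 - h) * (1 - w) * c_dc
        + (1 - h) * w * c_dw
        + h * (1 - w) * c_wc
        + h * w * c_ww
    )


@dataclass
class SenescenceSpec:
    """States, half-life corner constants, and transition corner weights.

    tau_corners: (n, 4) positive half-lives at the four extremes (time
    units).  X_corners: (n, n, 4) weights in [0, 1]; entry (i, j) holds the
    corner constants for the i -> j transition, diagonal unused.  Absorbing
    states never leave (diagonal probability 1).
    """

    states: list[LeafState]
    tau_corners: np.ndarray
    X_corners: np.ndarray
    absorbing: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        n = len(self.states)
        if n < 1:
            raise SpecificationError("at least one state required")
        if [s.index for s in self.states] != list(range(n)):
            raise SpecificationError("state indices must be 0..n-1 without gaps")
        self.tau_corners = np.asarray(self.tau_corners, dtype=float)
        self.X_corners = np.asarray(self.X_corners, dtype=float)
        if self.tau_corners.shape != (n, 4):
            raise SpecificationError(f"tau_corners must have shape ({n}, 4)")
        if np.any(self.tau_corners <= 0):
            raise SpecificationError("all tau corners must be positive")
        if self.X_corners.shape != (n, n, 4):
            raise SpecificationError(f"X_corners must have shape ({n}, {n}, 4)")
        if self.X_corners.min() < 0 or self.X_corners.max() > 1:
            raise SpecificationError("X corners must lie in [0, 1]")
        self.absorbing = frozenset(int(i) for i in self.absorbing)
        if any(i < 0 or i >= n for i in self.absorbing):
            raise SpecificationError("absorbing indices out of range")

    @property
    def n_states(self) -> int:
        return len(self.states)

    # -- JSON dialect -------------------------------------------------------

    @classmethod
    def from_json(cls, source) -> "SenescenceSpec":
        """Load from the JSON dialect (mapping, JSON string, or file path)."""
        if isinstance(source, (str, bytes)):
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        elif hasattr(source, "read"):
            data = json.load(source)
        else:
            data = source
        states = [
            LeafState(
                index=i,
                name=s.get("name", f"state_{i}"),
                texture_label=s.get("texture_label", ""),
                deformation_snapshot=s.get("snapshot"),
            )
            for i, s in enumerate(data["states"])
        ]
        n = len(states)
        name_to_idx = {s.name: s.index for s in states}

        def resolve(key):
            if key in name_to_idx:
                return name_to_idx[key]
            return int(key)

        tau = np.ones((n, 4))
        for key, vals in data["tau_corners"].items():
            tau[resolve(key)] = vals
        X = np.zeros((n, n, 4))
        for key, vals in data.get("X_corners", {}).items():
            a, b = key.split("->")
            X[resolve(a.strip()), resolve(b.strip())] = vals
        absorbing = frozenset(resolve(k) for k in data.get("absorbing", []))
        return cls(states=states, tau_corners=tau, X_corners=X, absorbing=absorbing)

    def to_json(self) -> dict:
        out = {
            "states": [
                {
                    "name": s.name,
                    "texture_label": s.texture_label,
                    "snapshot": s.deformation_snapshot,
                }
                for s in self.states
            ],
            "tau_corners": {
                s.name: list(self.tau_corners[s.index]) for s in self.states
            },
            "X_corners": {},
            "absorbing": [self.states[i].name for i in sorted(self.absorbing)],
        }
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j and np.any(self.X_corners[i, j] > 0):
                    key = f"{self.states[i].name}->{self.states[j].name}"
                    out["X_corners"][key] = list(self.X_corners[i, j])
        return out


@dataclass
class LeafPopulation:
    """Per-leaf state assignments plus the epoch-by-epoch count history."""

    assignments: np.ndarray
    rng_seed: int = 0
    history: Optional[np.ndarray] = None  # (n_epochs + 1, n_states)

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.size == 0:
            raise InvalidInputError("population must be non-empty")

    @classmethod
    def uniform(cls, n_leaves: int, state: int = 0, rng_seed: int = 0):
        return cls(np.full(n_leaves, state, dtype=np.int64), rng_seed=rng_seed)

    def history_rows(self):
        """Yield (epoch, state, count) rows for CSV export."""
        if self.history is None:
            return
        for epoch, counts in enumerate(self.history):
            for state, count in enumerate(counts):
                yield epoch, state, int(count)


def p_stay(
    env: Environment, t: float, state_index: int, spec: SenescenceSpec
) -> float:
    """Self-retention probability exp(-ln2 / tau_i(e) * t) in (0, 1].

    At t equal to the interpolated half-life the value is exactly 0.5.
    """
    if t < 0:
        raise InvalidInputError("elapsed time must be >= 0")
    tau = bilinear_interp(env, spec.tau_corners[state_index])
    return float(np.exp(-_LN2 / tau * t))


def transition_matrix(
    env: Environment, t: float, spec: SenescenceSpec
) -> np.ndarray:
    """Row-stochastic n x n matrix for one step of duration ``t``.

    Diagonal entries are the self-retention probabilities (1 for absorbing
    states); the leaving mass 1 - P_ii of each transient row is split
    among j != i proportionally to the interpolated X_ij weights,
    renormalized to sum to one.
    """
    if t < 0:
        raise InvalidInputError("step duration must be >= 0")
    n = spec.n_states
    M = np.zeros((n, n))
    for i in range(n):
        if i in spec.absorbing:
            M[i, i] = 1.0
            continue
        pii = p_stay(env, t, i, spec)
        M[i, i] = pii
        if n == 1:
            M[i, i] = 1.0
            continue
        x = np.array(
            [bilinear_interp(env, spec.X_corners[i, j]) if j != i else 0.0
             for j in range(n)]
        )
        total = x.sum()
        if total <= 0.0:
            raise SpecificationError(
                f"state {i} is not absorbing but all X_{i}j weights are zero; "
                "the leaf must be able to leave the state"
            )
        M[i] += (1.0 - pii) * x / total
    return M


def evolve_population(
    pop: LeafPopulation,
    schedule: Sequence[tuple[Environment, float]],
    spec: SenescenceSpec,
    seed: Optional[int] = None,
) -> LeafPopulation:
    """Evolve every leaf independently through an environment schedule.

    One epoch = one (environment, duration) pair; each leaf samples its
    next state from its current row of that epoch's transition matrix.
    Randomness comes from a per-epoch substream of ``seed`` (default: the
    population's rng_seed), with the uniform draw for leaf k taken at
    vector position k — results do not depend on processing order and are
    bit-reproducible for identical inputs.
    """
    if seed is None:
        seed = pop.rng_seed
    seed = int(seed)
    n = spec.n_states
    assignments = pop.assignments.copy()
    if assignments.min() < 0 or assignments.max() >= n:
        raise InvalidInputError("population contains invalid state indices")
    history = [np.bincount(assignments, minlength=n)]
    for epoch_index, (env, duration) in enumerate(schedule):
        if duration <= 0:
            raise InvalidInputError("epoch durations must be positive")
        M = transition_matrix(env, float(duration), spec)
        cum = np.cumsum(M, axis=1)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(epoch_index,))
        )
        u = rng.random(len(assignments))
        assignments = np.minimum(
            (cum[assignments] < u[:, None]).sum(axis=1), n - 1
        ).astype(np.int64)
        history.append(np.bincount(assignments, minlength=n))
    return LeafPopulation(
        assignments=assignments,
        rng_seed=seed,
        history=np.array(history, dtype=np.int64),
    )
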