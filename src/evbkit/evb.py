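"""Diabatic states, mapping potentials and adiabatic ground surfaces.

The reaction is represented in the empirical valence bond (EVB) picture: a
small set of diabatic (valence-bond) states, each with a fixed bonding
arrangement and its own analytic potential surface, mixed by off-diagonal
couplings.  The adiabatic ground surface is the lowest eigenvalue of the
Hamiltonian whose diagonal holds the diabat energies plus per-state
gas-phase shifts (alpha) and whose off-diagonal holds the couplings (H_ij).

The model coordinate is one-dimensional and dimensionless; diabats are
harmonic by default with an optional quartic term.  This is the minimal
structure carrying the Marcus/EVB phenomenology the downstream free-energy
machinery depends on: displaced parabolas give a reorganization energy
``lambda_reorg = f*d**2/2``, their crossing gives the uncoupled barrier, and
the coupling lowers the barrier at the crossing.

Sign convention for the energy-gap reaction coordinate: ``gap = (eps_i +
alpha_i) - (eps_j + alpha_j)`` for the pair ``(i, j)``, so a positive gap
means the second state of the pair lies below the first, and the reactant
basin sits at negative gap.

Units: energies kcal/mol, coupling kcal/mol, temperature kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .constants import R_KCAL  # noqa: F401  (re-exported for convenience)
from .errors import ConfigurationError, ValidationError

Role = Literal["reactant", "intermediate", "product"]
_ROLES = ("reactant", "intermediate", "product")

#: Tolerance for lambda-vector normalization checks.
LAMBDA_TOL = 1e-9


@dataclass(frozen=True)
class DiabaticState:
    """One valence-bond state as an analytic 1-D energy surface.

    Parameters
    ----------
    id:
        Short label, e.g. ``"reactant"`` or ``"PO3-"``.
    role:
        One of ``reactant``, ``intermediate``, ``product``.
    x0:
        Minimum position in model-coordinate units.
    f:
        Harmonic force constant, kcal mol^-1 unit^-2; must be positive.
    c:
        Constant energy offset, kcal/mol.
    quartic:
        Optional quartic coefficient, kcal mol^-1 unit^-4 (anharmonicity).
    description:
        Free text, e.g. ``"ATP + TyrOH + Asp-"``.
    """

    id: str
    role: Role
    x0: float
    f: float
    c: float = 0.0
    quartic: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigurationError(
                f"state {self.id!r}: role must be one of {_ROLES}, got {self.role!r}"
            )
        if not np.isfinite([self.x0, self.f, self.c, self.quartic]).all():
            raise ConfigurationError(f"state {self.id!r}: non-finite surface parameter")
        if self.f <= 0:
            raise ConfigurationError(
                f"state {self.id!r}: harmonic force constant must be positive, got {self.f}"
            )
        if self.quartic < 0:
            raise ConfigurationError(
                f"state {self.id!r}: quartic coefficient must be >= 0, got {self.quartic}"
            )

    def energy(self, x):
        """Surface value at coordinate ``x`` (scalar or array), kcal/mol."""
        dx = np.asarray(x, dtype=float) - self.x0
        e = 0.5 * self.f * dx * dx + self.c
        if self.quartic:
            e = e + self.quartic * dx**4
        return e if e.ndim else float(e)

    def derivative(self, x):
        """dE/dx at ``x`` (scalar or array)."""
        dx = np.asarray(x, dtype=float) - self.x0
        d = self.f * dx
        if self.quartic:
            d = d + 4.0 * self.quartic * dx**3
        return d if d.ndim else float(d)

    @property
    def is_harmonic(self) -> bool:
        return self.quartic == 0.0

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "role": self.role,
            "x0": float(self.x0),
            "f": float(self.f),
            "c": float(self.c),
            "quartic": float(self.quartic),
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiabaticState":
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"malformed state definition: {exc}") from exc


@dataclass(frozen=True)
class EVBTopology:
    """Ordered diabatic states plus gas-phase shifts and couplings.

    ``alpha[0]`` is fixed at 0 by convention: the first state is the energy
    reference and only relative shifts are physical.  The coupling matrix is
    symmetric with a zero diagonal and non-negative entries.  This object is
    what calibration tunes (``alpha`` of the final state and the coupling of
    the driven pair).
    """

    states: tuple[DiabaticState, ...]
    alpha: tuple[float, ...]
    coupling: tuple[tuple[float, ...], ...]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        k = len(self.states)
        if k not in (2, 3):
            raise ConfigurationError(f"topology needs 2 or 3 states, got {k}")
        object.__setattr__(self, "states", tuple(self.states))
        alpha = tuple(float(a) for a in self.alpha)
        if len(alpha) != k:
            raise ConfigurationError(f"alpha has length {len(alpha)}, expected {k}")
        if alpha[0] != 0.0:
            raise ConfigurationError(f"alpha[0] must be exactly 0, got {alpha[0]}")
        if not np.isfinite(alpha).all():
            raise ConfigurationError("non-finite gas-phase shift")
        object.__setattr__(self, "alpha", alpha)
        H = np.asarray(self.coupling, dtype=float)
        if H.shape != (k, k):
            raise ConfigurationError(f"coupling has shape {H.shape}, expected {(k, k)}")
        if not np.isfinite(H).all():
            raise ConfigurationError("non-finite coupling")
        if not np.array_equal(H, H.T):
            raise ConfigurationError("coupling matrix must be symmetric")
        if np.diagonal(H).any():
            raise ConfigurationError("coupling diagonal must be zero")
        if (H < 0).any():
            raise ConfigurationError("couplings must be non-negative")
        object.__setattr__(
            self, "coupling", tuple(tuple(float(v) for v in row) for row in H)
        )
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be positive, got {self.temperature}")

    # -- basic views -------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def alpha_array(self) -> np.ndarray:
        return np.asarray(self.alpha, dtype=float)

    @property
    def coupling_array(self) -> np.ndarray:
        return np.asarray(self.coupling, dtype=float)

    def shifted_energies(self, x) -> np.ndarray:
        """Shifted diabat energies ``eps_i(x) + alpha_i``.

        Returns shape ``(k,)`` for scalar ``x`` or ``(n, k)`` for an array.
        """
        x = np.asarray(x, dtype=float)
        cols = [s.energy(x) + a for s, a in zip(self.states, self.alpha)]
        return np.stack([np.asarray(c, dtype=float) for c in cols], axis=-1)

    def with_params(
        self,
        alpha: Sequence[float] | None = None,
        coupling: np.ndarray | Sequence | None = None,
    ) -> "EVBTopology":
        """Copy of this topology with replaced shifts and/or couplings."""
        kwargs: dict = {}
        if alpha is not None:
            kwargs["alpha"] = tuple(float(a) for a in alpha)
        if coupling is not None:
            H = np.asarray(coupling, dtype=float)
            kwargs["coupling"] = tuple(tuple(row) for row in H)
        return replace(self, **kwargs)

    def with_offset_jitter(self, deltas: Sequence[float]) -> "EVBTopology":
        """Copy with per-state additive offsets on the diabat constants ``c``.

        Used by the surrogate sampler to emulate replicate-to-replicate
        conformational heterogeneity; the gas-phase shifts are untouched.
        """
        if len(deltas) != self.n_states:
            raise ConfigurationError("jitter vector length mismatch")
        states = tuple(
            replace(s, c=s.c + float(d)) for s, d in zip(self.states, deltas)
        )
        return replace(self, states=states)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": [s.to_dict() for s in self.states],
            "alpha": list(self.alpha),
            "coupling": [list(row) for row in self.coupling],
            "temperature": float(self.temperature),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EVBTopology":
        try:
            states = tuple(DiabaticState.from_dict(s) for s in d["states"])
            return cls(
                states=states,
                alpha=tuple(d["alpha"]),
                coupling=tuple(tuple(row) for row in d["coupling"]),
                temperature=float(d.get("temperature", 300.0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed topology definition: {exc}") from exc


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def diabat_energy(state: DiabaticState, x) -> float:
    """Analytic diabat energy at ``x``: ``f/2*(x-x0)**2 + c (+ quartic)``."""
    if not np.isfinite(x).all() if hasattr(x, "__len__") else not np.isfinite(x):
        raise ValidationError("coordinate must be finite")
    return state.energy(x)


def validate_lambda(lam, n_states: int) -> np.ndarray:
    """Check a lambda vector: non-negative, normalized, right length."""
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (n_states,):
        raise ValidationError(
            f"lambda vector has shape {lam.shape}, expected ({n_states},)"
        )
    if (lam < -LAMBDA_TOL).any():
        raise ValidationError(f"lambda components must be >= 0, got {lam}")
    s = float(lam.sum())
    if abs(s - 1.0) > LAMBDA_TOL:
        raise ValidationError(f"lambda vector must sum to 1, got sum={s!r}")
    return lam


def mapping_energy(topology: EVBTopology, lam, x):
    """Mapping potential ``eps_m(x) = sum_i lam_i * (eps_i(x) + alpha_i)``.

    The FEP driver samples on this potential; at unit lambda vectors it
    recovers the corresponding shifted diabat exactly.
    """
    lam = validate_lambda(lam, topology.n_states)
    eps = topology.shifted_energies(x)
    out = eps @ lam
    return float(out) if np.ndim(out) == 0 else out


def pair_ground(e1, e2, h):
    """Lowest eigenvalue of the 2x2 Hamiltonian ``[[e1, h], [h, e2]]``.

    Closed form ``(e1+e2)/2 - sqrt((e1-e2)**2/4 + h**2)``; vectorized.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    avg = 0.5 * (e1 + e2)
    out = avg - np.sqrt(0.25 * (e1 - e2) ** 2 + h * h)
    return float(out) if np.ndim(out) == 0 else out


def ground_from_eps(eps: np.ndarray, coupling: np.ndarray) -> np.ndarray:
    """Adiabatic ground energy per frame from shifted diabat energies.

    ``eps`` has shape ``(n, k)``; uses the 2x2 closed form for k=2 and a
    batched symmetric eigensolve for k=3.
    """
    eps = np.atleast_2d(np.asarray(eps, dtype=float))
    k = eps.shape[1]
    if k == 2:
        return pair_ground(eps[:, 0], eps[:, 1], float(coupling[0][1]))
    H = np.zeros((eps.shape[0], k, k))
    H[:] = np.asarray(coupling, dtype=float)
    idx = np.arange(k)
    H[:, idx, idx] = eps
    return np.linalg.eigvalsh(H)[:, 0]


def adiabatic_ground(topology: EVBTopology, x, active="all"):
    """Adiabatic ground-state energy at ``x``.

    ``active`` is either ``"all"`` (lowest eigenvalue of the full shifted
    Hamiltonian) or a pair of state indices, in which case the 2x2 closed
    form ``(e_i+e_j)/2 - sqrt(((e_i-e_j)/2)**2 + H_ij**2)`` is used.  The
    result never exceeds the lowest shifted diabat among the active states,
    with equality iff the relevant couplings vanish.
    """
    eps = topology.shifted_energies(x)
    scalar = eps.ndim == 1
    eps2 = np.atleast_2d(eps)
    if active == "all":
        out = ground_from_eps(eps2, topology.coupling_array)
    else:
        i, j = _check_pair(topology, active)
        h = topology.coupling_array[i, j]
        out = pair_ground(eps2[:, i], eps2[:, j], h)
    return float(out[0]) if scalar else np.asarray(out)


def _check_pair(topology: EVBTopology, pair) -> tuple[int, int]:
    try:
        i, j = (int(pair[0]), int(pair[1]))
    except (TypeError, IndexError, ValueError) as exc:
        raise ValidationError(f"state pair must be two indices, got {pair!r}") from exc
    k = topology.n_states
    if not (0 <= i < k and 0 <= j < k) or i == j:
        raise ValidationError(f"invalid state pair {pair!r} for {k} states")
    return i, j


def energy_gap(topology: EVBTopology, pair, x):
    """Energy-gap reaction coordinate ``(eps_i+alpha_i) - (eps_j+alpha_j)``.

    Antisymmetric under pair swap and zero at the diabatic crossing; the
    reactant basin of a (reactant, product) pair sits at negative gap.
    """
    i, j = _check_pair(topology, pair)
    eps = topology.shifted_energies(x)
    scalar = eps.ndim == 1
    eps2 = np.atleast_2d(eps)
    out = eps2[:, i] - eps2[:, j]
    return float(out[0]) if scalar else out
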