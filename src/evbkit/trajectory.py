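"""Per-window trajectory records — the unit of I/O between stages.

A :class:`WindowTrajectory` holds the post-equilibration frames sampled at
one lambda vector under one seed: coordinate, shifted diabat energies,
mapping energy and energy-gap value per frame, plus the gas-phase shift
vector that was in force at sampling time (needed for post-hoc
recalibration, which subtracts it to recover raw diabat energies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

#: Internal-consistency tolerance: e_map must equal lam . eps per frame.
EMAP_TOL = 1e-9


@dataclass(frozen=True)
class WindowTrajectory:
    """Frames sampled on one mapping potential.

    Attributes
    ----------
    lam:
        Lambda vector of the window, shape ``(k,)``.
    x:
        Coordinate per frame, shape ``(n,)``.
    eps:
        Shifted diabat energies ``eps_i + alpha_i`` per frame, ``(n, k)``.
    e_map:
        Mapping energy ``lam . eps`` per frame, ``(n,)``.
    gap:
        Energy-gap coordinate ``eps[:, 0] - eps[:, -1]`` per frame, ``(n,)``.
    seed:
        The integer seed the noise stream was built from.
    sampling_alpha:
        Gas-phase shifts in force when the frames were generated, ``(k,)``.
    """

    lam: np.ndarray
    x: np.ndarray
    eps: np.ndarray
    e_map: np.ndarray
    gap: np.ndarray
    seed: int
    sampling_alpha: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lam", "x", "eps", "e_map", "gap", "sampling_alpha"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_states(self) -> int:
        return self.eps.shape[1]

    def validate(self) -> None:
        """Raise :class:`DataError` on shape/finite/consistency violations."""
        n, k = self.eps.shape
        if self.lam.shape != (k,) or self.sampling_alpha.shape != (k,):
            raise DataError("lambda/alpha length does not match eps columns")
        for name in ("x", "e_map", "gap"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"field {name!r} has wrong length")
        for name in ("x", "eps", "e_map", "gap"):
            if not np.isfinite(getattr(self, name)).all():
                raise DataError(f"non-finite values in field {name!r}")
        if n == 0:
            raise DataError("empty trajectory")
        resid = np.max(np.abs(self.e_map - self.eps @ self.lam)) if n else 0.0
        if resid > EMAP_TOL:
            raise DataError(
                f"e_map inconsistent with lam . eps (max residual {resid:.3e})"
            )

    def with_alpha(self, new_alpha) -> "WindowTrajectory":
        """Re-shift stored energies to a new gas-phase shift vector.

        Exact no-op (bitwise) when ``new_alpha == sampling_alpha``; otherwise
        adds the difference to each state column and recomputes ``e_map`` and
        ``gap`` from the updated columns.
        """
        new_alpha = np.asarray(new_alpha, dtype=float)
        delta = new_alpha - self.sampling_alpha
        if not delta.any():
            return self
        eps = self.eps + delta
        return WindowTrajectory(
            lam=self.lam,
            x=self.x,
            eps=eps,
            e_map=eps @ self.lam,
            gap=eps[:, 0] - eps[:, -1],
            seed=self.seed,
            sampling_alpha=new_alpha,
        )
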