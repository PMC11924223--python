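"""Overdamped Langevin sampling on mapping potentials.

This is the synthetic-data stage: it generates Boltzmann-distributed frames
on each window's mapping potential, standing in for the all-atom MD/FEP
engine that produced the original per-window energy records.  Only the
configurational distribution matters for the downstream FEP and umbrella
sampling estimators, so position (overdamped) Langevin dynamics suffices:

    x <- x - beta*D * dE_lam/dx * dt + sqrt(2*D*dt) * eta,   eta ~ N(0, 1)

whose stationary density is proportional to exp(-beta * E_lam(x)).

For purely harmonic topologies the drift is linear in x and the whole
update is a first-order linear recurrence, which is evaluated with
``scipy.signal.lfilter`` for speed; anharmonic (quartic) states fall back
to an explicit step loop.  Both paths are bit-reproducible for a fixed
seed.

Seed scheme (splittable): every window draws its noise from
``numpy.random.SeedSequence([master_seed, replicate_index, leg_index,
window_index])``, so adding replicates, legs or windows never perturbs
existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .constants import beta as beta_of
from .errors import SamplerInstabilityError, ValidationError
from .evb import EVBTopology, validate_lambda
from .trajectory import WindowTrajectory


@dataclass(frozen=True)
class SamplerParams:
    """Langevin integrator controls.

    dt:
        Step size (dimensionless time).  Stability requires
        ``beta*D*f_max*dt`` well below 1; the default keeps it near 0.04
        for the stiffest built-in diabat (f = 200 at 300 K), which bounds
        the Euler discretization bias on sampled variances to ~2%.
    diffusion:
        Diffusion constant D.
    steps_per_window:
        Langevin steps per lambda window (before discarding equilibration).
    equilibration_fraction:
        Leading fraction of steps discarded from every window.
    x_bound:
        Divergence guard; a trajectory leaving ``|x| <= x_bound`` aborts.
    """

    dt: float = 2.5e-4
    diffusion: float = 1.0
    steps_per_window: int = 2000
    equilibration_fraction: float = 0.1
    x_bound: float = 50.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.diffusion <= 0:
            raise ValidationError(f"diffusion must be positive, got {self.diffusion}")
        if self.steps_per_window < 10:
            raise ValidationError(
                f"steps_per_window must be >= 10, got {self.steps_per_window}"
            )
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ValidationError(
                "equilibration_fraction must be in [0, 1), got "
                f"{self.equilibration_fraction}"
            )

    @property
    def n_keep(self) -> int:
        """Frames retained per window: floor(steps * (1 - equil_fraction))."""
        return int(np.floor(self.steps_per_window * (1.0 - self.equilibration_fraction)))


def window_seed(
    master_seed: int, replicate_index: int, window_index: int, leg_index: int = 0
) -> int:
    """Derive the integer seed of one window's noise stream (< 2**31)."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(replicate_index), int(leg_index), int(window_index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def jitter_deltas(
    master_seed: int, replicate_index: int, n_states: int, sd: float
) -> np.ndarray:
    """Per-replicate diabat-offset jitter (zero for the reference state).

    Drawn from a stream keyed off (master_seed, replicate, sentinel) so it is
    independent of every window's noise.  Emulates replicate-to-replicate
    conformational heterogeneity; off by default (sd = 0).
    """
    if sd == 0.0:
        return np.zeros(n_states)
    ss = np.random.SeedSequence([int(master_seed), int(replicate_index), 999_983])
    rng = np.random.default_rng(ss)
    d = rng.normal(0.0, sd, size=n_states)
    d[0] = 0.0
    return d


def langevin_window(
    topology: EVBTopology,
    lam,
    params: SamplerParams,
    seed: int,
    x_init: float | None = None,
) -> WindowTrajectory:
    """Sample one window on the mapping potential of ``lam``.

    Returns the post-equilibration frames with per-frame shifted diabat
    energies, mapping energy and gap coordinate.  Deterministic for a fixed
    seed.  ``x_init`` defaults to the center of the state with the largest
    lambda weight (sequential FEP callers pass the previous window's final
    coordinate instead).
    """
    lam = validate_lambda(lam, topology.n_states)
    b = beta_of(topology.temperature)
    D = params.diffusion
    dt = params.dt
    steps = params.steps_per_window
    if x_init is None:
        x_init = topology.states[int(np.argmax(lam))].x0

    rng = np.random.default_rng(int(seed))
    noise = rng.standard_normal(steps) * np.sqrt(2.0 * D * dt)
    drift = b * D * dt

    if all(s.is_harmonic for s in topology.states):
        # dE/dx = sum_i lam_i f_i (x - x0_i) = F1*x - F0: linear recurrence
        # x_t = a*x_{t-1} + u_t with a = 1 - drift*F1, u_t = drift*F0 + eta_t.
        F1 = float(sum(l * s.f for l, s in zip(lam, topology.states)))
        F0 = float(sum(l * s.f * s.x0 for l, s in zip(lam, topology.states)))
        a = 1.0 - drift * F1
        u = drift * F0 + noise
        x_path, _ = lfilter([1.0], [1.0, -a], u, zi=np.array([a * float(x_init)]))
    else:
        x_path = np.empty(steps)
        x = float(x_init)
        for t in range(steps):
            grad = sum(l * s.derivative(x) for l, s in zip(lam, topology.states))
            x = x - drift * grad + noise[t]
            x_path[t] = x

    if not np.isfinite(x_path).all() or np.max(np.abs(x_path)) > params.x_bound:
        fmax = max(s.f for s in topology.states)
        raise SamplerInstabilityError(
            f"trajectory diverged (|x| > {params.x_bound}) at dt={dt} with "
            f"stiffest force constant f={fmax}; reduce dt below "
            f"{0.1 / (b * D * fmax):.2e}"
        )

    kept = x_path[steps - params.n_keep :]
    eps = topology.shifted_energies(kept)
    return WindowTrajectory(
        lam=lam,
        x=kept,
        eps=eps,
        e_map=eps @ lam,
        gap=eps[:, 0] - eps[:, -1],
        seed=int(seed),
        sampling_alpha=topology.alpha_array,
    )


def sample_all_windows(
    topology: EVBTopology,
    schedule,
    params: SamplerParams,
    master_seed: int,
    replicate_index: int = 0,
    leg_index: int = 0,
) -> list[WindowTrajectory]:
    """Sample every window of a lambda schedule sequentially.

    One :class:`WindowTrajectory` per lambda vector; each window is seeded
    independently from ``(master_seed, replicate, leg, window)`` and starts
    at the final coordinate of the previous window (sequential FEP driving).
    Reproducible from ``(master_seed, replicate_index)``.
    """
    vectors = np.asarray(schedule.vectors, dtype=float)
    if vectors.shape[1] != topology.n_states:
        raise ValidationError(
            f"schedule has {vectors.shape[1]} lambda components, topology has "
            f"{topology.n_states} states"
        )
    out: list[WindowTrajectory] = []
    x_prev: float | None = None
    for w, lam in enumerate(vectors):
        seed = window_seed(master_seed, replicate_index, w, leg_index)
        try:
            traj = langevin_window(topology, lam, params, seed, x_init=x_prev)
        except SamplerInstabilityError as exc:
            raise SamplerInstabilityError(f"window {w}: {exc}") from exc
        x_prev = float(traj.x[-1])
        out.append(traj)
    return out
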