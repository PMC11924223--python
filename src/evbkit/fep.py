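"""Lambda schedules and free-energy perturbation accumulation.

The system is driven between diabatic states on mapping potentials
``eps_m = sum_i lam_i (eps_i + alpha_i)``.  Adjacent windows are bridged by
the Zwanzig (exponential-averaging) estimator

    dG(m -> m+1) = -(1/beta) * ln < exp(-beta * (eps_{m+1} - eps_m)) >_m

evaluated over the frames of window m with a max-shifted log-sum-exp; the
cumulative sums of these increments anchor the umbrella-sampling profile.

Forward-only accumulation is the default, mirroring a sequentially driven
protocol; a bidirectional average (mean of forward and time-reversed
increments) is available behind a flag for users but is not part of the
reference analysis path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import beta as beta_of
from .errors import AlignmentError, DataError, ScheduleError, ValidationError
from .evb import EVBTopology, validate_lambda
from .trajectory import WindowTrajectory

logger = logging.getLogger(__name__)

#: Effective-sample-size threshold below which an increment logs a warning.
ESS_WARN = 10.0


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda vectors from the initial to the final state.

    The first vector is the unit vector on the initial state and the last
    the unit vector on the final state; components lie in [0, 1] and each
    vector sums to 1.
    """

    vectors: np.ndarray
    mechanism: str = "dissociative"

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ScheduleError(f"schedule needs >= 2 lambda vectors, got shape {v.shape}")
        for row in v:
            validate_lambda(row, v.shape[1])
        first, last = v[0], v[-1]
        if not (first[0] == 1.0 and last[-1] == 1.0):
            raise ScheduleError(
                "schedule must start on the initial state and end on the final state"
            )
        if (np.abs(np.diff(v, axis=0)).max(axis=1) == 0).any():
            raise ScheduleError("consecutive lambda vectors must differ")
        object.__setattr__(self, "vectors", v)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_states(self) -> int:
        return self.vectors.shape[1]

    @property
    def progress(self) -> np.ndarray:
        """Scalar driving parameter: weight on the final state."""
        return self.vectors[:, -1]


@dataclass(frozen=True)
class FepResult:
    """Cumulative FEP free energies, one value per window.

    ``cumulative[0] == 0`` and ``cumulative[m]`` is the sum of the first m
    increments; ``counts`` holds frames per window.
    """

    cumulative: np.ndarray
    increments: np.ndarray
    counts: np.ndarray
    schedule: LambdaSchedule

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative, dtype=float)
        inc = np.asarray(self.increments, dtype=float)
        if c[0] != 0.0:
            raise DataError("cumulative[0] must be 0")
        if c.shape[0] != inc.shape[0] + 1:
            raise DataError("cumulative/increment length mismatch")
        if not np.allclose(np.cumsum(inc), c[1:], rtol=0, atol=1e-10):
            raise DataError("cumulative is not the running sum of increments")
        object.__setattr__(self, "cumulative", c)
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))

    @property
    def total(self) -> float:
        """End-to-end free-energy difference, kcal/mol."""
        return float(self.cumulative[-1])

    def to_frame(self):
        """CSV-ready table (window, lambda, dG_increment, dG_cumulative, n_frames)."""
        import pandas as pd

        inc = np.concatenate([[np.nan], self.increments])
        return pd.DataFrame(
            {
                "window": np.arange(self.schedule.n_windows),
                "lambda": self.schedule.progress,
                "dG_increment": inc,
                "dG_cumulative": self.cumulative,
                "n_frames": self.counts,
            }
        )


def make_schedule(
    mechanism: str = "dissociative",
    n_base: int = 101,
    densify_after: float | None = None,
    n_extra: int = 0,
) -> LambdaSchedule:
    """Build the two-state lambda schedule of a driven reaction step.

    The base grid is ``n_base`` uniform values of the driving parameter in
    [0, 1] (101 windows at 0.01 increments by default).  For the associative
    mechanism the default adds ``n_extra`` (30) additional values spaced
    linearly in the open interval ``(densify_after, 1)`` (default 0.3),
    merged and sorted into the base grid — 131 windows in total.  The extra
    points are interior to the interval; merging never duplicates a value.
    """
    if n_base < 2:
        raise ScheduleError(f"n_base must be >= 2, got {n_base}")
    if n_extra < 0:
        raise ScheduleError(f"n_extra must be >= 0, got {n_extra}")
    grid = np.linspace(0.0, 1.0, n_base)
    if mechanism == "associative" and densify_after is None and n_extra == 0:
        densify_after, n_extra = 0.3, 30
    if n_extra:
        if densify_after is None:
            densify_after = 0.3
        if not (0.0 <= densify_after < 1.0):
            raise ScheduleError(f"densify_after must be in [0, 1), got {densify_after}")
        extra = np.linspace(densify_after, 1.0, n_extra + 2)[1:-1]
        merged = np.sort(np.concatenate([grid, extra]))
        if (np.diff(merged) < 1e-12).any():
            raise ScheduleError("duplicate lambda values after densification merge")
        grid = merged
    vectors = np.column_stack([1.0 - grid, grid])
    return LambdaSchedule(vectors=vectors, mechanism=mechanism)


def zwanzig_from_work(work, temperature: float) -> float:
    """Zwanzig estimator on raw work samples: ``-(1/beta) ln<exp(-beta w)>``.

    Uses a max-shifted log-sum-exp; for Gaussian work of mean mu and
    variance s2 it converges to ``mu - beta*s2/2``.
    """
    work = np.asarray(work, dtype=float)
    if work.size == 0:
        raise DataError("empty work sample")
    if not np.isfinite(work).all():
        raise DataError("non-finite work values")
    b = beta_of(temperature)
    return float(-(logsumexp(-b * work) - np.log(work.size)) / b)


def _effective_sample_size(work: np.ndarray, b: float) -> float:
    lw = -b * work
    return float(np.exp(2.0 * logsumexp(lw) - logsumexp(2.0 * lw)))


def zwanzig_increment(
    traj_m: WindowTrajectory,
    lam_next,
    topology: EVBTopology | None = None,
    direction: str = "forward",
) -> float:
    """Free-energy increment from window m to the next lambda vector.

    The perturbed mapping energy is re-evaluated on the stored shifted
    diabat components (``eps @ lam_next``), so no resampling is needed.
    ``direction="reverse"`` estimates the same increment from the far
    window's frames with the sign flipped (used by bidirectional averaging).
    """
    if traj_m.n_frames == 0:
        raise DataError("empty trajectory")
    lam_next = validate_lambda(lam_next, traj_m.n_states)
    temperature = topology.temperature if topology is not None else 300.0
    if not (np.isfinite(traj_m.eps).all() and np.isfinite(traj_m.e_map).all()):
        raise DataError("non-finite energies in trajectory")
    work = traj_m.eps @ lam_next - traj_m.e_map
    if direction == "reverse":
        work = -work
    elif direction != "forward":
        raise ValidationError(f"direction must be forward or reverse, got {direction!r}")
    b = beta_of(temperature)
    ess = _effective_sample_size(work, b)
    if ess < ESS_WARN:
        logger.warning(
            "low overlap: effective sample size %.1f (< %.0f) for increment "
            "toward lambda=%s",
            ess,
            ESS_WARN,
            np.round(lam_next, 4).tolist(),
        )
    dg = zwanzig_from_work(work, temperature)
    return -dg if direction == "reverse" else dg


def accumulate_fep(
    trajectories: list[WindowTrajectory],
    schedule: LambdaSchedule,
    topology: EVBTopology | None = None,
    bidirectional: bool = False,
) -> FepResult:
    """Accumulate window-by-window increments into a cumulative profile.

    Requires one trajectory per schedule vector, in order.  Default is
    forward-only Zwanzig; with ``bidirectional=True`` each increment is the
    average of the forward estimate from window m and the reverse estimate
    from window m+1.
    """
    vectors = np.asarray(schedule.vectors, dtype=float)
    if len(trajectories) != vectors.shape[0]:
        raise AlignmentError(
            f"{len(trajectories)} trajectories for {vectors.shape[0]} schedule windows"
        )
    for m, traj in enumerate(trajectories):
        if not np.array_equal(np.asarray(traj.lam, dtype=float), vectors[m]):
            raise AlignmentError(f"window {m}: trajectory lambda differs from schedule")
    increments = np.empty(vectors.shape[0] - 1)
    for m in range(vectors.shape[0] - 1):
        fwd = zwanzig_increment(trajectories[m], vectors[m + 1], topology)
        if bidirectional:
            # estimate of dG(m -> m+1) from the far window's frames
            rev = -zwanzig_increment(trajectories[m + 1], vectors[m], topology)
            increments[m] = 0.5 * (fwd + rev)
        else:
            increments[m] = fwd
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    counts = np.array([t.n_frames for t in trajectories])
    return FepResult(
        cumulative=cumulative, increments=increments, counts=counts, schedule=schedule
    )
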