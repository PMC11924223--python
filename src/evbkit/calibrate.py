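"""Reference-reaction calibration of gas-phase shifts and couplings.

EVB's two per-leg knobs — the gas-phase shift alpha of the final state and
the off-diagonal coupling H of the driven pair — are fitted so that the
reference (solution) reaction profile reproduces experimentally anchored
activation and reaction free energies.  Calibration is *post hoc*: the
stored trajectories keep their raw diabat components, so new (alpha, H)
re-shift the energies, re-accumulate the FEP anchors and re-profile without
any resampling.  The sampling distribution remains that of the provisional
parameters — the standard approximation of EVB post-processing; the fit is
therefore deterministic and fast, and alpha moves the profile's reaction
free energy essentially one-to-one (exactly so for the end-to-end FEP
total, by the telescoping identity).

The solver is a damped two-variable Broyden (secant) iteration on the
residual vector (achieved dG_ddagger - target, achieved dG0-or-offset -
target), started from alpha implied by the target reaction free energy and
H = 0, with a finite-difference initial Jacobian.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .evb import EVBTopology
from .fep import FepResult, accumulate_fep
from .profiles import (
    DEFAULT_BINS,
    DEFAULT_MIN_COUNT,
    FreeEnergyProfile,
    evb_us_profile,
)
from .trajectory import WindowTrajectory


@dataclass(frozen=True)
class CalibrationTarget:
    """Targets for one reaction leg, kcal/mol.

    Exactly one of ``dG0_target`` (reaction free energy) or
    ``intermediate_offset_below_max`` (how far the intermediate plateau sits
    below the profile maximum — used for a high-lying intermediate leg) must
    be given alongside the activation target.
    """

    dG_ddagger_target: float
    dG0_target: float | None = None
    intermediate_offset_below_max: float | None = None
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError(f"tolerance must be positive, got {self.tolerance}")
        given = (self.dG0_target is not None) + (
            self.intermediate_offset_below_max is not None
        )
        if given != 1:
            raise ConfigurationError(
                "exactly one of dG0_target / intermediate_offset_below_max required"
            )

    @property
    def implied_dG0(self) -> float:
        """The reaction free energy the two targets jointly imply."""
        if self.dG0_target is not None:
            return self.dG0_target
        return self.dG_ddagger_target - self.intermediate_offset_below_max

    def to_dict(self) -> dict:
        return {
            "dG_ddagger_target": self.dG_ddagger_target,
            "dG0_target": self.dG0_target,
            "intermediate_offset_below_max": self.intermediate_offset_below_max,
            "tolerance": self.tolerance,
        }


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted parameters with residual diagnostics.

    ``converged`` implies ``max |residual| <= tolerance``; a failed fit
    returns best-effort parameters with ``converged=False`` rather than
    raising.
    """

    alpha: tuple[float, ...]
    coupling: tuple[tuple[float, ...], ...]
    residuals: tuple[float, float]
    iterations: int
    converged: bool
    profile: FreeEnergyProfile | None = None

    def parameter_block(self) -> dict:
        return {"alpha": list(self.alpha), "coupling": [list(r) for r in self.coupling]}

    def checksum(self) -> str:
        """Stable digest of the fitted parameter block (transfer contract)."""
        payload = json.dumps(self.parameter_block(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def recalibrate_profile(
    trajectories: Sequence[WindowTrajectory],
    fep: FepResult,
    topology: EVBTopology,
    new_alpha: Sequence[float],
    new_H: float,
    bins: int = DEFAULT_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[FreeEnergyProfile, FepResult]:
    """Profile the stored trajectories under new (alpha, H).

    Re-shifts every frame's diabat components from the recorded
    ``sampling_alpha`` to ``new_alpha``, recomputes mapping energies, gap
    values and FEP increments, and rebuilds the profile with the driven
    pair's coupling set to ``new_H``.  Bitwise no-op when the parameters
    equal the sampling parameters.
    """
    if not trajectories:
        raise DataError("no trajectories to recalibrate")
    for t in trajectories:
        if t.eps.ndim != 2:
            raise DataError(
                "trajectory lacks per-state energy components; re-export with "
                "full eps columns"
            )
    new_alpha = tuple(float(a) for a in new_alpha)
    k = topology.n_states
    H = topology.coupling_array.copy()
    H[0, -1] = H[-1, 0] = float(new_H)
    topo = topology.with_params(alpha=new_alpha, coupling=H)
    shifted = [t.with_alpha(np.asarray(new_alpha)) for t in trajectories]
    new_fep = accumulate_fep(shifted, fep.schedule, topo)
    profile = evb_us_profile(shifted, new_fep, topo, bins=bins, min_count=min_count)
    return profile, new_fep


def _mean_features(profiles: Sequence[FreeEnergyProfile]) -> tuple[float, float]:
    """Ensemble-mean (dG_ddagger, dG0) over recalibrated replicate profiles."""
    bars = [p.features.dG_ddagger for p in profiles]
    dg0s = [p.features.dG0 for p in profiles]
    return float(np.mean(bars)), float(np.mean(dg0s))


def _residuals(
    achieved: tuple[float, float], target: CalibrationTarget
) -> tuple[float, float]:
    dg_ddagger, dg0 = achieved
    r1 = dg_ddagger - target.dG_ddagger_target
    if target.dG0_target is not None:
        r2 = dg0 - target.dG0_target
    else:
        achieved_offset = dg_ddagger - dg0
        r2 = achieved_offset - target.intermediate_offset_below_max
    return float(r1), float(r2)


def fit_alpha_H(
    trajectories: Sequence[WindowTrajectory],
    fep: FepResult,
    topology: EVBTopology,
    target: CalibrationTarget,
    max_iter: int = 40,
    fd_step: float = 0.25,
    max_step: float = 8.0,
    bins: int = DEFAULT_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
    replicates: Sequence[tuple[Sequence[WindowTrajectory], FepResult]] | None = None,
) -> CalibrationResult:
    """Fit (alpha_final, H) so the profile meets the calibration targets.

    Derivative-free damped Broyden iteration on the two-residual vector;
    the initial alpha comes from the target reaction free energy (linearity
    of dG0 in alpha makes this nearly exact), the initial coupling is 0.
    With ``replicates`` (a list of per-replicate ``(trajectories, fep)``
    pairs) the fitted quantities are the ensemble means of the replicate
    profile features, matching a reference protocol that parametrizes on
    the whole trajectory ensemble; otherwise the single given window set is
    used.  Returns best-effort parameters with ``converged=False`` after
    ``max_iter`` evaluations instead of raising.
    """
    tol = target.tolerance
    if replicates is None:
        replicates = [(trajectories, fep)]
    sampling_alpha = np.asarray(replicates[0][0][0].sampling_alpha, dtype=float)

    def evaluate(theta: np.ndarray):
        alpha = sampling_alpha.copy()
        alpha[-1] = theta[0]
        h = max(theta[1], 0.0)
        profs = [
            recalibrate_profile(
                trajs, f, topology, alpha, h, bins=bins, min_count=min_count
            )[0]
            for trajs, f in replicates
        ]
        achieved = _mean_features(profs)
        return np.array(_residuals(achieved, target)), profs[0], alpha, h

    # initial guess: alpha from the implied dG0, H = 0
    profs0 = [
        recalibrate_profile(
            trajs, f, topology, sampling_alpha, 0.0, bins=bins, min_count=min_count
        )[0]
        for trajs, f in replicates
    ]
    theta = np.array(
        [
            sampling_alpha[-1] + (target.implied_dG0 - _mean_features(profs0)[1]),
            0.0,
        ]
    )
    r, profile, alpha, h = evaluate(theta)
    iterations = 1
    best = (np.max(np.abs(r)), theta.copy(), r, profile, alpha, h)

    # finite-difference initial Jacobian
    J = np.zeros((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = fd_step
        r_j, *_ = evaluate(theta + step)
        iterations += 1
        J[:, j] = (r_j - r) / fd_step

    while iterations < max_iter and np.max(np.abs(r)) > tol:
        try:
            delta = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            break
        norm = np.max(np.abs(delta))
        if norm > max_step:
            delta *= max_step / norm
        theta_new = theta + delta
        theta_new[1] = max(theta_new[1], 0.0)
        dtheta = theta_new - theta
        if np.max(np.abs(dtheta)) < 1e-12:
            break
        r_new, profile, alpha, h = evaluate(theta_new)
        iterations += 1
        # Broyden rank-1 secant update
        denom = float(dtheta @ dtheta)
        J += np.outer(r_new - r - J @ dtheta, dtheta) / denom
        theta, r = theta_new, r_new
        if np.max(np.abs(r)) < best[0]:
            best = (np.max(np.abs(r)), theta.copy(), r, profile, alpha, h)

    _, theta, r, profile, alpha, h = best
    H = topology.coupling_array.copy()
    H[0, -1] = H[-1, 0] = h
    return CalibrationResult(
        alpha=tuple(float(a) for a in alpha),
        coupling=tuple(tuple(row) for row in H),
        residuals=(float(r[0]), float(r[1])),
        iterations=iterations,
        converged=bool(np.max(np.abs(r)) <= tol),
        profile=profile,
    )
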