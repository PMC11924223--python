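"""Umbrella-sampling free-energy profiles along the energy-gap coordinate.

The EVB umbrella-sampling estimator reweights every mapping-potential frame
onto the adiabatic ground surface and anchors windows with their FEP free
energies.  With occupancy weighting (window weights proportional to frame
counts in each bin) the per-bin expression collapses to a single sum over
all frames landing in bin X:

    dG(X) = -(1/beta) * ln [ (1/N(X)) * sum_{frames in X}
                              exp(-beta*(dG_fep[m] + E_g - eps_m)) ]

where m is the frame's window, eps_m its mapping energy and E_g the ground
eigenvalue recomputed from the stored shifted diabat components.  All sums
run in log space with per-bin max shifts, so arbitrarily large reweighting
exponents are safe.

The profile is anchored at the reactant minimum (dG = 0 there), bins with
fewer than ``min_count`` frames are masked (never silently interpolated),
and features are detected as discrete local extrema after a 3-bin moving
average — the smoothing is used for *detection* only; reported free
energies come from the unsmoothed bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import beta as beta_of
from .errors import CompositionError, NoBarrierError, UndersamplingError, ValidationError
from .evb import EVBTopology, ground_from_eps
from .fep import FepResult
from .trajectory import WindowTrajectory

#: Default number of uniform gap bins.
DEFAULT_BINS = 200
#: Minimum frames for a bin to be reported.
DEFAULT_MIN_COUNT = 25
#: Moving-average width (bins) used for extremum detection.
SMOOTH_BINS = 3
#: Gap ranges narrower than this are treated as degenerate (flat profile).
DEGENERATE_GAP = 1e-8


@dataclass(frozen=True)
class ProfileFeatures:
    """Extracted reaction features of a profile (kcal/mol, anchored at 0)."""

    reactant_min_index: int
    barrier_index: int
    product_min_index: int
    reactant_min: float
    barrier_top: float
    product_min: float
    dG_ddagger: float
    dG0: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "reactant_min": self.reactant_min,
            "barrier_top": self.barrier_top,
            "product_min": self.product_min,
            "dG_ddagger": self.dG_ddagger,
            "dG0": self.dG0,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Binned free energy vs energy-gap coordinate.

    ``dG`` is NaN in masked (undersampled) bins and zero at the reactant
    minimum by construction.  ``roles`` carries the (reactant-side,
    product-side) diabat roles so that leg profiles can be joined.
    """

    bin_centers: np.ndarray
    dG: np.ndarray
    counts: np.ndarray
    features: ProfileFeatures | None = None
    roles: tuple[str, str] = ("reactant", "product")
    coordinate: str = "energy_gap"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "dG", np.asarray(self.dG, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if not (self.bin_centers.shape == self.dG.shape == self.counts.shape):
            raise ValidationError("profile arrays must share one shape")

    @property
    def n_bins(self) -> int:
        return self.bin_centers.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.dG)

    def with_features(self, features: ProfileFeatures) -> "FreeEnergyProfile":
        return FreeEnergyProfile(
            bin_centers=self.bin_centers,
            dG=self.dG,
            counts=self.counts,
            features=features,
            roles=self.roles,
            coordinate=self.coordinate,
        )

    def to_frame(self):
        """CSV-ready table (bin_center, dG, n)."""
        import pandas as pd

        return pd.DataFrame(
            {"bin_center": self.bin_centers, "dG": self.dG, "n": self.counts}
        )


def evb_us_profile(
    trajectories: Sequence[WindowTrajectory],
    fep: FepResult,
    topology: EVBTopology,
    bins: int = DEFAULT_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
) -> FreeEnergyProfile:
    """Construct the umbrella-sampling profile from window trajectories.

    ``fep`` must be aligned with the trajectories (same schedule order); the
    ground surface is recomputed per frame from the stored shifted diabat
    components and the topology's coupling matrix, so the same trajectories
    can be profiled under recalibrated parameters.
    """
    if len(trajectories) != fep.schedule.n_windows:
        raise ValidationError(
            f"{len(trajectories)} trajectories for {fep.schedule.n_windows} FEP windows"
        )
    b = beta_of(topology.temperature)
    H = topology.coupling_array

    gap_all = np.concatenate([t.gap for t in trajectories])
    # per-frame log weight: -beta * (dG_fep[m] + E_g - eps_m)
    scores = []
    for m, traj in enumerate(trajectories):
        eg = ground_from_eps(traj.eps, H)
        scores.append(-b * (fep.cumulative[m] + eg - traj.e_map))
    score_all = np.concatenate(scores)

    lo, hi = float(gap_all.min()), float(gap_all.max())
    if hi - lo < DEGENERATE_GAP:
        # identical (or fully degenerate) diabats: the gap carries no
        # information, the landscape is a single flat point
        features = ProfileFeatures(0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
        return FreeEnergyProfile(
            bin_centers=np.array([0.5 * (lo + hi)]),
            dG=np.array([0.0]),
            counts=np.array([gap_all.size]),
            features=features,
            roles=(topology.states[0].role, topology.states[-1].role),
        )

    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.searchsorted(edges, gap_all, side="right") - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)

    # grouped log-sum-exp: per-bin max shift, then exp-sum
    bin_max = np.full(bins, -np.inf)
    np.maximum.at(bin_max, idx, score_all)
    shifted = np.exp(score_all - np.where(np.isfinite(bin_max), bin_max, 0.0)[idx])
    sums = np.zeros(bins)
    np.add.at(sums, idx, shifted)
    with np.errstate(divide="ignore", invalid="ignore"):
        dG = -(bin_max + np.log(sums) - np.log(counts)) / b
    dG[counts < min_count] = np.nan

    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = FreeEnergyProfile(
        bin_centers=centers,
        dG=dG,
        counts=counts,
        roles=(topology.states[0].role, topology.states[-1].role),
    )
    _check_barrier_coverage(profile)
    features = extract_features(profile)
    anchored = profile.dG - features.reactant_min - 0.0
    anchored_profile = FreeEnergyProfile(
        bin_centers=centers,
        dG=anchored,
        counts=counts,
        roles=profile.roles,
    )
    feats = ProfileFeatures(
        reactant_min_index=features.reactant_min_index,
        barrier_index=features.barrier_index,
        product_min_index=features.product_min_index,
        reactant_min=0.0,
        barrier_top=features.barrier_top - features.reactant_min,
        product_min=features.product_min - features.reactant_min,
        dG_ddagger=features.dG_ddagger,
        dG0=features.dG0,
    )
    return anchored_profile.with_features(feats)


def _largest_valid_run(valid: np.ndarray) -> tuple[int, int]:
    """Bounds (inclusive) of the longest contiguous run of valid bins."""
    best = (0, -1)
    start = None
    for i, v in enumerate(valid):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best[1] - best[0] + 1:
                best = (start, i - 1)
            start = None
    if start is not None and len(valid) - start > best[1] - best[0] + 1:
        best = (start, len(valid) - 1)
    return best


def _check_barrier_coverage(profile: FreeEnergyProfile) -> None:
    """Raise if the populated bins do not contiguously cover the crossing.

    Sparse tail bins outside the main populated block are tolerated (they
    stay masked); a masked hole at the diabatic crossing (gap = 0) means
    the barrier region was never sampled and the profile cannot be
    stitched together.
    """
    valid = profile.valid
    if not valid.any():
        raise UndersamplingError("no bin reaches the minimum frame count")
    lo, hi = _largest_valid_run(valid)
    centers = profile.bin_centers
    straddles = centers[0] < 0.0 < centers[-1]
    if straddles and not (centers[lo] <= 0.0 <= centers[hi]):
        raise UndersamplingError(
            "empty bins across the barrier region: the contiguous populated "
            f"block spans gap [{centers[lo]:.3g}, {centers[hi]:.3g}] kcal/mol "
            "and misses the diabatic crossing; increase steps_per_window or "
            "window density"
        )


def _moving_average(y: np.ndarray, width: int = SMOOTH_BINS) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    if width <= 1 or y.size < width:
        return y.copy()
    kernel = np.ones(width) / width
    out = np.convolve(y, kernel, mode="same")
    # fix edges (convolve divides by full width there)
    half = width // 2
    for i in range(half):
        out[i] = y[: i + half + 1].mean()
        out[-(i + 1)] = y[-(i + half + 1) :].mean()
    return out


def extract_features(profile: FreeEnergyProfile, smooth: int = SMOOTH_BINS) -> ProfileFeatures:
    """Locate reactant/product minima and the separating maximum.

    Extrema are detected on the ``smooth``-bin moving average of the valid
    (contiguous) bins; free energies are reported from the unsmoothed bins.
    ``dG_ddagger = dG(barrier) - dG(reactant_min)`` and ``dG0 =
    dG(product_min) - dG(reactant_min)``.  Ties at the barrier are broken by
    the bin nearest the diabatic crossing (gap = 0).  A degenerate
    (single-bin) profile returns all-zero features; a profile without two
    minima separated by a maximum raises :class:`NoBarrierError`.
    """
    if profile.features is not None and profile.features.degenerate:
        return profile.features
    valid = profile.valid
    if valid.sum() < 3:
        if profile.n_bins == 1:
            return ProfileFeatures(0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
        raise NoBarrierError("fewer than 3 populated bins; no extrema resolvable")
    first, last = _largest_valid_run(valid)
    y = profile.dG[first : last + 1]
    centers = profile.bin_centers[first : last + 1]
    # smoothing a profile with only a handful of bins erases its extrema;
    # detection falls back to the raw bins there
    ys = _moving_average(y, smooth) if y.size >= 5 * smooth else y.copy()

    minima, maxima = _local_extrema(ys)
    if len(minima) < 2 or len(maxima) < 1:
        raise NoBarrierError(
            "profile is monotone or single-welled along the gap coordinate"
        )
    i_reac = minima[0]
    i_prod = minima[-1]
    between = [i for i in maxima if i_reac < i < i_prod]
    if not between:
        raise NoBarrierError("no maximum between the outer minima")
    top = max(ys[i] for i in between)
    ties = [i for i in between if ys[i] == top]
    i_bar = min(ties, key=lambda i: abs(centers[i]))

    reac, bar, prod = float(y[i_reac]), float(y[i_bar]), float(y[i_prod])
    return ProfileFeatures(
        reactant_min_index=first + i_reac,
        barrier_index=first + i_bar,
        product_min_index=first + i_prod,
        reactant_min=reac,
        barrier_top=bar,
        product_min=prod,
        dG_ddagger=bar - reac,
        dG0=prod - reac,
    )


def _local_extrema(y: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of discrete local minima and maxima (plateau-tolerant).

    Endpoints count as minima/maxima when the profile runs downhill/uphill
    into them, so a basin truncated by the sampled range is still a basin.
    """
    n = y.size
    minima: list[int] = []
    maxima: list[int] = []
    for i in range(n):
        left = y[i - 1] if i > 0 else np.inf
        right = y[i + 1] if i < n - 1 else np.inf
        if y[i] <= left and y[i] <= right and (y[i] < left or y[i] < right):
            minima.append(i)
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] >= left and y[i] >= right and (y[i] > left or y[i] > right):
            maxima.append(i)
    # collapse plateau runs to a single representative
    minima = _collapse_runs(minima)
    maxima = _collapse_runs(maxima)
    return minima, maxima


def _collapse_runs(indices: list[int]) -> list[int]:
    if not indices:
        return indices
    out = [indices[0]]
    for i in indices[1:]:
        if i == out[-1] + 1:
            out[-1] = i  # keep the last of a contiguous run
        else:
            out.append(i)
    return out


def join_legs(leg1: FreeEnergyProfile, leg2: FreeEnergyProfile) -> FreeEnergyProfile:
    """Compose two sequential reaction-step profiles into one.

    Leg 2 is rigidly offset so that its reactant (intermediate) minimum sits
    at leg 1's product free energy, and its coordinate axis is appended
    after leg 1's product-minimum bin.  The composite profile's overall
    activation free energy is the global maximum relative to the leg-1
    reactant minimum.
    """
    if leg1.roles[1] != leg2.roles[0]:
        raise CompositionError(
            f"cannot join: leg 1 ends in role {leg1.roles[1]!r} but leg 2 "
            f"starts in role {leg2.roles[0]!r}"
        )
    f1 = leg1.features if leg1.features is not None else extract_features(leg1)
    f2 = leg2.features if leg2.features is not None else extract_features(leg2)
    offset = leg1.dG[f1.product_min_index] - leg2.dG[f2.reactant_min_index]

    i1 = f1.product_min_index
    i2 = f2.reactant_min_index
    c1 = leg1.bin_centers[: i1 + 1]
    d1 = leg1.dG[: i1 + 1]
    n1 = leg1.counts[: i1 + 1]
    step = np.median(np.diff(leg1.bin_centers)) if leg1.n_bins > 1 else 1.0
    # leg-1's product bin already represents the junction minimum; leg 2
    # contributes the bins beyond its (coincident) reactant minimum
    c2 = leg2.bin_centers[i2 + 1 :] - leg2.bin_centers[i2] + c1[-1]
    d2 = leg2.dG[i2 + 1 :] + offset
    n2 = leg2.counts[i2 + 1 :]

    composite = FreeEnergyProfile(
        bin_centers=np.concatenate([c1, c2]),
        dG=np.concatenate([d1, d2]),
        counts=np.concatenate([n1, n2]),
        roles=(leg1.roles[0], leg2.roles[1]),
        coordinate="composite",
    )
    valid = composite.valid
    idx = np.flatnonzero(valid)
    i_reac = f1.reactant_min_index  # leg-1 bins below i1 keep their indices
    i_bar = int(idx[np.argmax(composite.dG[idx])])
    i_prod = i1 + (f2.product_min_index - i2)  # leg-2 product min, re-indexed
    reac = float(composite.dG[i_reac])
    bar = float(composite.dG[i_bar])
    prod = float(composite.dG[i_prod])
    features = ProfileFeatures(
        reactant_min_index=int(i_reac),
        barrier_index=int(i_bar),
        product_min_index=int(i_prod),
        reactant_min=reac,
        barrier_top=bar,
        product_min=prod,
        dG_ddagger=bar - reac,
        dG0=prod - reac,
    )
    return composite.with_features(features)
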