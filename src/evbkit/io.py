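"""On-disk formats: window CSV dialect, sidecar metadata, configs, profiles.

Window-trajectory sets travel as one CSV per leg with header

    window, lam_1..lam_k, step, eps_1..eps_k, e_map, gap, x

(column order free — parsing is header-driven) plus a required JSON sidecar
``<file>.meta.json`` carrying the seeds, sampling alpha vector, schedule
and provenance.  Floats are written with 17 significant digits, so a
write/read round trip is lossless.  A compact binary container (``.npz``)
is available for large runs.

Topologies, scenarios and run configs serialize to YAML (plain-text,
human-editable, nested key-value); round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .evb import EVBTopology
from .fep import LambdaSchedule
from .profiles import FreeEnergyProfile
from .trajectory import WindowTrajectory

_FLOAT_FMT = "%.17g"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_windows(
    trajectories: Sequence[WindowTrajectory],
    path,
    scenario: str = "",
    leg: int = 0,
    schedule: LambdaSchedule | None = None,
    topology: EVBTopology | None = None,
) -> None:
    """Write a window-trajectory set as the documented CSV dialect + sidecar."""
    path = Path(path)
    k = trajectories[0].n_states
    frames = []
    for w, t in enumerate(trajectories):
        n = t.n_frames
        block = {"window": np.full(n, w, dtype=int), "step": np.arange(n)}
        for i in range(k):
            block[f"lam_{i + 1}"] = np.full(n, t.lam[i])
        for i in range(k):
            block[f"eps_{i + 1}"] = t.eps[:, i]
        block["e_map"] = t.e_map
        block["gap"] = t.gap
        block["x"] = t.x
        frames.append(pd.DataFrame(block))
    table = pd.concat(frames, ignore_index=True)
    cols = (
        ["window"]
        + [f"lam_{i + 1}" for i in range(k)]
        + ["step"]
        + [f"eps_{i + 1}" for i in range(k)]
        + ["e_map", "gap", "x"]
    )
    table[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)

    meta = {
        "format": "evbkit-windows-v1",
        "scenario": scenario,
        "leg": leg,
        "n_states": k,
        "n_windows": len(trajectories),
        "seeds": [t.seed for t in trajectories],
        "sampling_alpha": trajectories[0].sampling_alpha.tolist(),
        "schedule": None
        if schedule is None
        else {
            "mechanism": schedule.mechanism,
            "vectors": schedule.vectors.tolist(),
        },
        "topology": None if topology is None else topology.to_dict(),
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_windows(path) -> tuple[list[WindowTrajectory], dict]:
    """Read a window CSV + sidecar back into trajectories.

    Header-driven (column order free).  Raises :class:`FormatError` naming
    the offending line for missing columns, non-finite energies or a
    missing sidecar.
    """
    path = Path(path)
    mpath = _meta_path(path)
    if not mpath.exists():
        raise FormatError(f"missing sidecar metadata file {mpath}")
    meta = json.loads(mpath.read_text())
    k = int(meta["n_states"])
    expected = (
        {"window", "step", "e_map", "gap", "x"}
        | {f"lam_{i + 1}" for i in range(k)}
        | {f"eps_{i + 1}" for i in range(k)}
    )
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = expected - set(table.columns)
    if missing:
        raise FormatError(f"{path}: header missing columns {sorted(missing)}")
    num_cols = sorted(expected - {"window", "step"})
    bad = ~np.isfinite(table[num_cols].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        line = int(np.argmax(bad)) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: non-finite or missing value at line {line}")

    seeds = meta["seeds"]
    alpha = np.asarray(meta["sampling_alpha"], dtype=float)
    out: list[WindowTrajectory] = []
    for w, group in table.groupby("window", sort=True):
        group = group.sort_values("step")
        lam = group[[f"lam_{i + 1}" for i in range(k)]].iloc[0].to_numpy(dtype=float)
        eps = group[[f"eps_{i + 1}" for i in range(k)]].to_numpy(dtype=float)
        traj = WindowTrajectory(
            lam=lam,
            x=group["x"].to_numpy(dtype=float),
            eps=eps,
            e_map=group["e_map"].to_numpy(dtype=float),
            gap=group["gap"].to_numpy(dtype=float),
            seed=int(seeds[int(w)]) if int(w) < len(seeds) else -1,
            sampling_alpha=alpha,
        )
        traj.validate()
        out.append(traj)
    if len(out) != int(meta["n_windows"]):
        raise FormatError(
            f"{path}: {len(out)} windows found, sidecar promises {meta['n_windows']} "
            f"(file truncated near line {len(table) + 2}?)"
        )
    return out, meta


def write_windows_npz(trajectories: Sequence[WindowTrajectory], path) -> None:
    """Compact binary container for large runs (single .npz file)."""
    arrays = {}
    for w, t in enumerate(trajectories):
        arrays[f"x_{w}"] = t.x
        arrays[f"eps_{w}"] = t.eps
        arrays[f"lam_{w}"] = t.lam
    arrays["seeds"] = np.array([t.seed for t in trajectories])
    arrays["sampling_alpha"] = trajectories[0].sampling_alpha
    np.savez_compressed(path, **arrays)


def read_windows_npz(path) -> list[WindowTrajectory]:
    with np.load(path) as data:
        seeds = data["seeds"]
        alpha = data["sampling_alpha"]
        out = []
        for w in range(seeds.shape[0]):
            eps = data[f"eps_{w}"]
            lam = data[f"lam_{w}"]
            out.append(
                WindowTrajectory(
                    lam=lam,
                    x=data[f"x_{w}"],
                    eps=eps,
                    e_map=eps @ lam,
                    gap=eps[:, 0] - eps[:, -1],
                    seed=int(seeds[w]),
                    sampling_alpha=alpha,
                )
            )
    return out


def save_topology(topology: EVBTopology, path) -> None:
    """Write a topology to the YAML key-value config format."""
    Path(path).write_text(yaml.safe_dump(topology.to_dict(), sort_keys=False))


def load_topology(path) -> EVBTopology:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise FormatError(f"{path}: topology config must be a mapping")
    return EVBTopology.from_dict(d)


def write_profile(profile: FreeEnergyProfile, path) -> None:
    """Profile CSV (bin_center, dG, n); features go in run reports."""
    profile.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fep(fep, path) -> None:
    """FEP CSV (window, lambda, dG_increment, dG_cumulative, n_frames)."""
    fep.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
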