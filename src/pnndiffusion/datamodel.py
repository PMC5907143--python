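"""Domain types and point-table I/O for post-detection diffusion analysis.

Unit conventions are fixed across the package: lengths in micrometres (μm),
time in seconds, densities in particles/μm².  Coordinates are continuous
(sub-pixel localisation is assumed to have happened upstream); no pixel grid
is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default acquisition interval, seconds (20 ms frame rate typical of
#: single-molecule TIRF time-lapse data).
DEFAULT_DT = 0.02


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, μm. Used for areas of interest and windows."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("rectangle must have positive area")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def expand(self, margin: float) -> "Rect":
        if margin < 0:
            raise ValueError("margin must be non-negative")
        return Rect(self.xmin - margin, self.ymin - margin,
                    self.xmax + margin, self.ymax + margin)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of the (n, 2) positions inside the rectangle."""
        p = np.asarray(positions, dtype=float).reshape(-1, 2)
        return ((p[:, 0] >= self.xmin) & (p[:, 0] <= self.xmax)
                & (p[:, 1] >= self.ymin) & (p[:, 1] <= self.ymax))


@dataclass
class ParticleFrame:
    """Detected particle positions at one time point.

    Parameters
    ----------
    frame_index : int
        Non-negative index of the frame in the acquisition.
    positions : (n, 2) ndarray
        Detected 2D coordinates, μm. May be empty.
    time : float, optional
        Acquisition time in seconds.
    """

    frame_index: int
    positions: np.ndarray
    time: float | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        pos = np.asarray(self.positions, dtype=float)
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class FramePair:
    """A preceding/subsequent frame pair separated by a lag ``dt`` (seconds)."""

    pre: ParticleFrame
    post: ParticleFrame
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pre.time is not None and self.post.time is not None:
            if not np.isclose(self.pre.time + self.dt, self.post.time):
                raise ValueError("pre.time + dt must equal post.time")


@dataclass
class Dataset:
    """An ordered collection of frames with shared acquisition metadata.

    ``area_of_interest`` restricts which preceding-frame particles are
    analysed; nearest-neighbour searches in the subsequent frame use the
    rectangle expanded by ``margin`` so that particles near the edge can still
    find their true nearest neighbour.
    """

    frames: list[ParticleFrame]
    dt: float
    area_of_interest: Rect | None = None
    margin: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frames must be sorted by strictly increasing frame_index")
        if self.margin is not None and self.margin < 0:
            raise ValueError("margin must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def make_frame_pairs(dataset: Dataset, lag: int = 1) -> list[FramePair]:
    """Pair frame ``k`` with frame ``k + lag`` for every valid ``k``.

    Produces ``max(0, n_frames - lag)`` pairs with ``dt = lag * dataset.dt``.
    Spatial filtering (area of interest, margin) is applied later, when
    nearest-neighbour records are built, so pairs carry the full frames.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    frames = dataset.frames
    return [FramePair(frames[k], frames[k + lag], lag * dataset.dt)
            for k in range(max(0, len(frames) - lag))]


def pairwise_frame_pairs(dataset: Dataset) -> list[FramePair]:
    """Pairs (0,1), (2,3), ... for datasets generated by the pairwise
    simulation protocol, where consecutive even/odd frames form independent
    experiments rather than one continuous time course."""
    if dataset.n_frames % 2 != 0:
        raise ValueError("pairwise dataset must contain an even number of frames")
    f = dataset.frames
    return [FramePair(f[2 * k], f[2 * k + 1], dataset.dt)
            for k in range(dataset.n_frames // 2)]


# ---------------------------------------------------------------------------
# Point-table I/O
# ---------------------------------------------------------------------------

def read_point_table(path, dt: float = DEFAULT_DT, *,
                     frame_col: str = "frame", x_col: str = "x", y_col: str = "y",
                     scale: float = 1.0,
                     area_of_interest: Rect | None = None,
                     margin: float | None = None) -> Dataset:
    """Read a CSV point table (one detected particle per row) into a Dataset.

    The expected columns are ``frame`` (int), ``x`` and ``y`` (float, μm);
    coordinates are multiplied by ``scale`` if the table is in other units.
    """
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty point table: {path}") from exc
    missing = [c for c in (frame_col, x_col, y_col) if c not in table.columns]
    if missing:
        raise ValueError(f"point table {path} is missing columns {missing}; "
                         f"found {list(table.columns)}")
    if len(table) == 0:
        raise ValueError(f"point table {path} contains no rows")
    for col in (x_col, y_col):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric coordinate in column {col!r} at data row {row}")
        table[col] = coerced
    frames = []
    for fi, grp in table.groupby(table[frame_col].astype(int), sort=True):
        pos = grp[[x_col, y_col]].to_numpy(dtype=float) * scale
        time = fi * dt
        frames.append(ParticleFrame(frame_index=int(fi), positions=pos, time=time))
    return Dataset(frames=frames, dt=dt, area_of_interest=area_of_interest,
                   margin=margin)


def write_point_table(dataset: Dataset, path) -> None:
    """Write a Dataset as a CSV point table with header ``frame,x,y``.

    Numeric formatting uses ``repr``-level precision so a read/write round
    trip is exact at double precision. Empty frames contribute no rows.
    """
    rows = []
    for frame in dataset.frames:
        for x, y in frame.positions:
            rows.append((frame.frame_index, x, y))
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    df["frame"] = df["frame"].astype(int) if len(df) else df["frame"]
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class EstimateReport:
    """Result of a diffusion-constant fit.

    ``diffusion_constants`` may contain ``inf`` for the disappearing-particle
    (false-detection) state. ``posteriors`` is a per-record table of state
    probabilities (columns ``p_state_1``..) when the fit produces them.
    """

    method: str
    diffusion_constants: list[float]
    weights: list[float]
    log_likelihood: float | None
    aic: float | None
    n_obs: int
    iterations: int = 0
    converged: bool = True
    dt: float = DEFAULT_DT
    posteriors: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "diffusion_constants": [float(d) for d in self.diffusion_constants],
            "weights": [float(w) for w in self.weights],
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_obs": int(self.n_obs),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "dt": float(self.dt),
            **({"extra": self.extra} if self.extra else {}),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True,
                      default=lambda o: float(o))

    @classmethod
    def from_json(cls, path) -> "EstimateReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(method=d["method"],
                   diffusion_constants=[float(x) for x in d["diffusion_constants"]],
                   weights=[float(w) for w in d["weights"]],
                   log_likelihood=d.get("log_likelihood"),
                   aic=d.get("aic"),
                   n_obs=d.get("n_obs", 0),
                   iterations=d.get("iterations", 0),
                   converged=d.get("converged", True),
                   dt=d.get("dt", DEFAULT_DT),
                   extra=d.get("extra", {}))
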