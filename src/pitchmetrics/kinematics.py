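"""Individual kinematics: speed, pace classes, distance by pace, heat maps.

Speed is the per-frame Euclidean step distance divided by the step
duration, optionally smoothed with a centered moving average. Speeds are
discretized into five named paces — Standing, Walking, Jogging, Running,
Sprinting — separated at 0.2, 2.1, 3.8 and 6.1 m/s; intervals are
half-open ``[lower, upper)`` so the map is total and monotone (a speed of
exactly 2.1 m/s is Jogging, not Walking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, InsufficientDataError
from .positional import GroupSelection, PositionalDataset

PACE_LABELS = ("Standing", "Walking", "Jogging", "Running", "Sprinting")
PACE_THRESHOLDS = (0.2, 2.1, 3.8, 6.1)


@dataclass(frozen=True)
class PaceScheme:
    """Ordered speed thresholds mapping speed (m/s) to one of five paces."""

    thresholds: tuple[float, float, float, float] = PACE_THRESHOLDS
    labels: tuple[str, str, str, str, str] = PACE_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 5:
            raise ValueError("a pace scheme has exactly 5 labels")
        if len(self.thresholds) != 4:
            raise ValueError("a pace scheme has exactly 4 thresholds")
        t = self.thresholds
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if t[0] < 0:
            raise ValueError("thresholds must be non-negative")

    def classify(self, speed):
        return classify_pace(speed, self)

    def classify_array(self, speeds: np.ndarray) -> np.ndarray:
        return classify_pace_indices(speeds, self)


DEFAULT_PACE_SCHEME = PaceScheme()


@dataclass
class SpeedSeries:
    """Per-frame speed (m/s) of one player."""

    times: np.ndarray
    speeds: np.ndarray
    player_id: str
    smoothing_window_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.times.shape != self.speeds.shape:
            raise ValueError("times and speeds must have equal length")
        if (self.speeds < 0).any():
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "speed_mps": self.speeds})


@dataclass
class PaceDistanceSummary:
    """Distance covered (m) in each pace class plus the total."""

    distances: dict[str, float]
    total: float
    player_id: str

    def fraction(self, label: str) -> float:
        if label not in self.distances:
            raise DomainError(f"unknown pace label {label!r}")
        return self.distances[label] / self.total if self.total > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "player_id": self.player_id,
            "total_m": self.total,
            "by_pace_m": dict(self.distances),
        }


@dataclass
class HeatmapGrid:
    """Occupancy or time-at-pace counts over a regular grid on the pitch.

    ``values[i, j]`` covers x in ``[x_edges[i], x_edges[i+1])`` and y in
    ``[y_edges[j], y_edges[j+1])``; the last row/column may be a partial
    bin clipped at the pitch boundary.
    """

    values: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    mode: str
    pace: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average; windows are truncated at the edges."""
    if window_samples <= 1:
        return np.asarray(values, dtype=float)
    s = pd.Series(values)
    return s.rolling(window_samples, center=True, min_periods=1).mean().to_numpy()


def compute_speed(
    dataset: PositionalDataset,
    player: str,
    smoothing_window: float = 0.5,
) -> SpeedSeries:
    """Per-frame speed of one player from finite position differences.

    The speed at frame i (i >= 1) is the Euclidean distance from frame i-1
    divided by the elapsed time; the first frame duplicates the second so
    the series has one value per sample. ``smoothing_window`` (seconds) is
    the span of a centered moving average (0 disables smoothing); at 10 Hz
    the default 0.5 s is a 5-tap filter.
    """
    sub = dataset.player_frame(player)
    if len(sub) < 2:
        raise InsufficientDataError(
            f"player {player!r} has {len(sub)} sample(s); speed needs at least 2"
        )
    t = sub["time_s"].to_numpy(dtype=float)
    x = sub["x_m"].to_numpy(dtype=float)
    y = sub["y_m"].to_numpy(dtype=float)
    step = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(t)
    raw = step / dt
    speeds = np.concatenate([[raw[0]], raw])
    if smoothing_window > 0:
        w = int(round(smoothing_window * dataset.rate))
        if w % 2 == 0:
            w += 1  # keep the filter centered
        speeds = moving_average(speeds, w)
    return SpeedSeries(
        times=t, speeds=speeds, player_id=player, smoothing_window_s=smoothing_window
    )


def classify_pace_indices(speeds, scheme: PaceScheme = DEFAULT_PACE_SCHEME) -> np.ndarray:
    """Vectorized pace-class index (0..4) for an array of speeds."""
    s = np.asarray(speeds, dtype=float)
    if (s < 0).any():
        raise DomainError("speed must be non-negative")
    return np.searchsorted(np.asarray(scheme.thresholds), s, side="right")


def classify_pace(speed: float, scheme: PaceScheme = DEFAULT_PACE_SCHEME) -> str:
    """Pace label of the half-open interval [t_k, t_{k+1}) containing speed."""
    idx = classify_pace_indices(np.asarray([speed]), scheme)[0]
    return scheme.labels[idx]


def distance_by_pace(
    speed_series: SpeedSeries, scheme: PaceScheme = DEFAULT_PACE_SCHEME
) -> PaceDistanceSummary:
    """Accumulate each inter-frame step's distance into its pace class.

    Step i (frame i-1 -> i) contributes ``speed[i] * dt[i]`` meters to the
    class of ``speed[i]``; the per-pace sums therefore conserve the total
    distance exactly.
    """
    if len(speed_series) == 0:
        raise EmptyInputError("empty speed series")
    t = speed_series.times
    v = speed_series.speeds
    dist = {label: 0.0 for label in scheme.labels}
    if len(speed_series) > 1:
        dt = np.diff(t)
        step = v[1:] * dt
        idx = classify_pace_indices(v[1:], scheme)
        for k, label in enumerate(scheme.labels):
            dist[label] = float(step[idx == k].sum())
    total = float(sum(dist.values()))
    return PaceDistanceSummary(
        distances=dist, total=total, player_id=speed_series.player_id
    )


def _grid_edges(extent: float, bin_size: float) -> np.ndarray:
    n = int(np.ceil(extent / bin_size - 1e-9))
    edges = np.arange(n + 1, dtype=float) * bin_size
    edges[-1] = extent  # last bin may be partial
    return edges


def heatmap(
    dataset: PositionalDataset,
    player: str,
    bin_size: float = 1.0,
    mode: str = "occupancy",
    pace: str | None = None,
    scheme: PaceScheme = DEFAULT_PACE_SCHEME,
    smoothing_window: float = 0.5,
) -> HeatmapGrid:
    """Spatial occupancy of one player over a regular grid on the pitch.

    ``mode="occupancy"`` counts samples per bin (the grid total equals the
    number of samples); ``mode="pace"`` accumulates time (s) spent in bins
    while moving at the given pace.
    """
    if mode not in ("occupancy", "pace"):
        raise DomainError(f"unknown heatmap mode {mode!r}")
    if bin_size <= 0:
        raise DomainError("bin_size must be positive")
    sub = dataset.player_frame(player)
    x = sub["x_m"].to_numpy(dtype=float)
    y = sub["y_m"].to_numpy(dtype=float)
    x_edges = _grid_edges(dataset.pitch.length, bin_size)
    y_edges = _grid_edges(dataset.pitch.width, bin_size)
    if mode == "occupancy":
        weights = None
    else:
        if pace is None or pace not in scheme.labels:
            raise DomainError(
                f"pace mode needs a pace label from {scheme.labels}, got {pace!r}"
            )
        speeds = compute_speed(dataset, player, smoothing_window).speeds
        idx = classify_pace_indices(speeds, scheme)
        at_pace = idx == scheme.labels.index(pace)
        weights = at_pace.astype(float) / dataset.rate  # seconds per sample
    values, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=weights)
    return HeatmapGrid(
        values=values,
        x_edges=x_edges,
        y_edges=y_edges,
        bin_size=bin_size,
        mode=mode,
        pace=pace,
    )


def write_heatmap_csv(grid: HeatmapGrid, path) -> None:
    """Dense-matrix CSV with a two-line comment header (bin size, grid)."""
    with open(path, "w") as fh:
        fh.write(f"# bin_size_m={grid.bin_size},mode={grid.mode},pace={grid.pace}\n")
        fh.write(
            f"# x_extent_m={grid.x_edges[-1]},y_extent_m={grid.y_edges[-1]},"
            f"shape={grid.values.shape[0]}x{grid.values.shape[1]}\n"
        )
        np.savetxt(fh, grid.values, delimiter=",", fmt="%.12g")


def distance_to_point(
    dataset: PositionalDataset,
    players: GroupSelection,
    point: tuple[float, float],
    *,
    allow_outside: bool = False,
) -> pd.DataFrame:
    """Per-frame Euclidean distance of each selected player to a pitch point.

    Returns a DataFrame with ``time_s`` plus one ``dist_<player>_m`` column
    per group member.
    """
    px, py = float(point[0]), float(point[1])
    if not allow_outside and not dataset.pitch.contains(px, py):
        raise DomainError(f"point ({px}, {py}) lies outside the pitch")
    times, X, Y = dataset.pivot(players)
    out = {"time_s": times}
    for j, pid in enumerate(players.player_ids):
        out[f"dist_{pid}_m"] = np.hypot(X[:, j] - px, Y[:, j] - py)
    return pd.DataFrame(out)


def attach_paces(
    dataset: PositionalDataset,
    scheme: PaceScheme = DEFAULT_PACE_SCHEME,
    smoothing_window: float = 0.5,
) -> PositionalDataset:
    """Eagerly classify every sample's pace and cache it in the dataset.

    Discretization happens once, at import time; analyses reuse the cached
    labels, and re-classification requires an explicit re-import with a new
    scheme.
    """
    frame = dataset.frame.copy()
    frame["pace"] = ""
    for player in dataset.players:
        speeds = compute_speed(dataset, player, smoothing_window)
        idx = classify_pace_indices(speeds.speeds, scheme)
        labels = np.asarray(scheme.labels)[idx]
        sel = frame["player_id"] == player
        order = frame.loc[sel, "time_s"].argsort()
        frame.loc[frame.index[sel][order], "pace"] = labels
    return PositionalDataset(frame=frame, rate=dataset.rate, pitch=dataset.pitch)
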