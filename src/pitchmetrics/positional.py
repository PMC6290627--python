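"""Positional tracking data: pitch model, dataset container, CSV I/O, slicing.

The on-disk interchange format is a long-form CSV with header
``time_s,player_id,team,x_m,y_m``: one row per (player, frame), time in
seconds from period start, coordinates in meters with the origin at a pitch
corner — x longitudinal in [0, length], y transverse in [0, width].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyInputError,
    EmptySelectionError,
    FormatError,
    SelectionError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("time_s", "player_id", "team", "x_m", "y_m")


@dataclass(frozen=True)
class PitchModel:
    """Rectangular pitch, dimensions in meters.

    ``length`` is the longitudinal extent (goal to goal, x axis) and
    ``width`` the transverse extent (touchline to touchline, y axis).
    The default 105 x 68 m is the standard full-size pitch.
    """

    length: float = 105.0
    width: float = 68.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("pitch dimensions must be positive")

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.length and 0.0 <= y <= self.width


@dataclass(frozen=True)
class TimeInterval:
    """Half-open analysis interval [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class GroupSelection:
    """Ordered set of player ids defining an analysis group.

    Group composition is free (e.g. "3 forwards vs 4 defenders"); the only
    constraint is the minimum group size, which depends on the metric:
    2 for centroid-based measures, 3 for hull areas.
    """

    player_ids: tuple[str, ...]
    min_size: int = 2

    def __post_init__(self) -> None:
        ids = tuple(str(p) for p in self.player_ids)
        if len(set(ids)) != len(ids):
            raise SelectionError(f"duplicate player ids in group: {ids}")
        object.__setattr__(self, "player_ids", ids)
        if len(ids) < self.min_size:
            raise SelectionError(
                f"group has {len(ids)} players, fewer than min_size={self.min_size}"
            )

    def __len__(self) -> int:
        return len(self.player_ids)

    def validate_against(self, dataset: "PositionalDataset") -> None:
        known = set(dataset.players)
        missing = [p for p in self.player_ids if p not in known]
        if missing:
            raise SelectionError(f"unknown player ids: {missing}")


@dataclass
class PositionalDataset:
    """Long-form table of (time, player, team, x, y) samples at a fixed rate.

    Invariants (enforced by :func:`read_positional_csv` / ``validate``):
    per-player times strictly increasing and uniformly spaced at 1/rate,
    all players on a common time grid, every sample inside the pitch.
    """

    frame: pd.DataFrame
    rate: float
    pitch: PitchModel = field(default_factory=PitchModel)

    @property
    def players(self) -> list[str]:
        return sorted(self.frame["player_id"].unique())

    @property
    def teams(self) -> list[str]:
        return sorted(self.frame["team"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_s"].unique())

    @property
    def span(self) -> tuple[float, float]:
        t = self.frame["time_s"]
        return float(t.min()), float(t.max())

    def __len__(self) -> int:
        return len(self.frame)

    def player_frame(self, player_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["player_id"] == player_id]
        if sub.empty:
            raise EmptySelectionError(f"no records for player {player_id!r}")
        return sub.sort_values("time_s").reset_index(drop=True)

    def pivot(self, group: GroupSelection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (times, X, Y) with X, Y of shape (n_frames, n_players),
        player columns ordered as in ``group``.

        Raises :class:`ValidationError` if any selected player is missing
        at any frame of the slice.
        """
        group.validate_against(self)
        sub = self.frame[self.frame["player_id"].isin(group.player_ids)]
        px = sub.pivot(index="time_s", columns="player_id", values="x_m")
        py = sub.pivot(index="time_s", columns="player_id", values="y_m")
        px = px.reindex(columns=list(group.player_ids))
        py = py.reindex(columns=list(group.player_ids))
        if px.isna().any().any():
            bad = sorted(px.columns[px.isna().any()].tolist())
            raise ValidationError(
                f"players missing at some frames of the selection: {bad}"
            )
        times = px.index.to_numpy(dtype=float)
        return times, px.to_numpy(dtype=float), py.to_numpy(dtype=float)

    def slice(
        self,
        interval: TimeInterval | None = None,
        group: GroupSelection | None = None,
    ) -> "PositionalDataset":
        return slice_dataset(self, interval, group)

    def validate(self, tol: float | None = None) -> None:
        """Check the dataset invariants, raising on violation."""
        if self.frame.empty:
            raise EmptyInputError("dataset has no records")
        dt = 1.0 / self.rate
        tol = dt / 2.0 if tol is None else tol
        dup = self.frame.duplicated(subset=["player_id", "time_s"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise ValidationError(
                f"duplicated timestamp for player {row['player_id']!r} "
                f"at t={row['time_s']}s"
            )
        grid = self.times
        if len(grid) > 1:
            steps = np.diff(grid)
            if np.any(np.abs(steps - dt) > 1e-6 * max(1.0, dt)):
                raise AlignmentError("time grid is not uniform at 1/rate")
        x = self.frame["x_m"].to_numpy()
        y = self.frame["y_m"].to_numpy()
        if (
            (x < -1e-9).any()
            or (x > self.pitch.length + 1e-9).any()
            or (y < -1e-9).any()
            or (y > self.pitch.width + 1e-9).any()
        ):
            raise ValidationError("records outside pitch bounds")


def slice_dataset(
    dataset: PositionalDataset,
    interval: TimeInterval | None = None,
    group: GroupSelection | None = None,
) -> PositionalDataset:
    """Restrict a dataset to ``start <= time < end`` and/or selected players.

    Rate and pitch are preserved. Raises :class:`EmptySelectionError` when
    nothing matches.
    """
    frame = dataset.frame
    if interval is not None:
        t = frame["time_s"]
        frame = frame[(t >= interval.start) & (t < interval.end)]
    if group is not None:
        group.validate_against(dataset)
        frame = frame[frame["player_id"].isin(group.player_ids)]
    if frame.empty:
        raise EmptySelectionError(
            "selection matched no records "
            f"(interval={interval}, group={group.player_ids if group else None})"
        )
    return PositionalDataset(
        frame=frame.reset_index(drop=True), rate=dataset.rate, pitch=dataset.pitch
    )


def _interpolate_gaps(
    sub: pd.DataFrame, grid: np.ndarray, rate: float, max_gap_s: float, player: str
) -> pd.DataFrame:
    """Fill missing grid times inside a player's span by linear interpolation."""
    t0, t1 = sub["time_s"].iloc[0], sub["time_s"].iloc[-1]
    want = grid[(grid >= t0) & (grid <= t1)]
    if len(want) == len(sub):
        return sub
    have = sub["time_s"].to_numpy()
    missing = np.setdiff1d(want, have)
    # largest contiguous run of missing samples determines the gap length
    gaps = np.diff(have)
    worst = float(gaps.max()) - 1.0 / rate
    if worst > max_gap_s + 1e-9:
        raise ValidationError(
            f"player {player!r} has a {worst:.2f}s gap, "
            f"exceeding the {max_gap_s}s interpolation limit"
        )
    xi = np.interp(missing, have, sub["x_m"].to_numpy())
    yi = np.interp(missing, have, sub["y_m"].to_numpy())
    fill = pd.DataFrame(
        {
            "time_s": missing,
            "player_id": player,
            "team": sub["team"].iloc[0],
            "x_m": xi,
            "y_m": yi,
        }
    )
    logger.warning("player %s: interpolated %d missing samples", player, len(missing))
    out = pd.concat([sub, fill], ignore_index=True).sort_values("time_s")
    return out.reset_index(drop=True)


def read_positional_csv(
    path: str | Path,
    pitch: PitchModel,
    rate: float,
    *,
    strict_bounds: bool = False,
    max_gap_s: float = 0.5,
) -> PositionalDataset:
    """Read and validate a positional CSV into a :class:`PositionalDataset`.

    Players are snapped onto the time grid of the first player (mismatch
    beyond half a sample period is an error), out-of-bounds samples are
    clamped to the pitch with a logged warning (rejected if
    ``strict_bounds``), and interior gaps up to ``max_gap_s`` are filled by
    linear interpolation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype={"player_id": str, "team": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path} lacks required columns {missing}")
    if raw.empty:
        raise EmptyInputError(f"{path} contains a header but no records")
    raw = raw[list(CSV_COLUMNS)].copy()
    if raw[["time_s", "x_m", "y_m"]].isna().any().any():
        raise FormatError(f"{path} has non-numeric or missing numeric fields")

    dup = raw.duplicated(subset=["player_id", "time_s"])
    if dup.any():
        row = raw[dup].iloc[0]
        raise ValidationError(
            f"duplicated timestamp for player {row['player_id']!r} at t={row['time_s']}s"
        )

    dt = 1.0 / rate
    first = raw["player_id"].iloc[0]
    t_ref = float(raw.loc[raw["player_id"] == first, "time_s"].min())
    k = np.round((raw["time_s"].to_numpy() - t_ref) * rate)
    snapped = t_ref + k / rate
    off = np.abs(raw["time_s"].to_numpy() - snapped)
    if (off > dt / 2.0 + 1e-9).any():
        i = int(np.argmax(off))
        raise AlignmentError(
            f"timestamp {raw['time_s'].iloc[i]}s (player {raw['player_id'].iloc[i]!r}) "
            f"is off the common grid by more than {dt / 2.0:.3f}s"
        )
    raw["time_s"] = snapped

    # clamp or reject out-of-bounds positions
    oob = (
        (raw["x_m"] < 0)
        | (raw["x_m"] > pitch.length)
        | (raw["y_m"] < 0)
        | (raw["y_m"] > pitch.width)
    )
    n_oob = int(oob.sum())
    if n_oob:
        if strict_bounds:
            row = raw[oob].iloc[0]
            raise ValidationError(
                f"{n_oob} records outside pitch bounds (first: player "
                f"{row['player_id']!r} at ({row['x_m']}, {row['y_m']}))"
            )
        logger.warning("clamped %d out-of-bounds records to pitch bounds", n_oob)
        raw["x_m"] = raw["x_m"].clip(0.0, pitch.length)
        raw["y_m"] = raw["y_m"].clip(0.0, pitch.width)

    # the reference grid is the full uniform lattice spanning the data, so
    # samples a player is missing entirely still count as gaps; times are
    # re-derived as t_lo + k/rate so grid membership is exact float equality
    t_lo = float(raw["time_s"].min())
    kk = np.round((raw["time_s"].to_numpy() - t_lo) * rate).astype(np.int64)
    raw["time_s"] = t_lo + kk / rate
    collided = raw.duplicated(subset=["player_id", "time_s"])
    if collided.any():
        row = raw[collided].iloc[0]
        raise AlignmentError(
            f"samples of player {row['player_id']!r} collide at grid time "
            f"t={row['time_s']}s after snapping; sampling is not uniform at {rate} Hz"
        )
    grid = t_lo + np.arange(int(kk.max()) + 1) / rate
    parts = []
    for player, sub in raw.groupby("player_id", sort=False):
        sub = sub.sort_values("time_s").reset_index(drop=True)
        if len(sub) > 1 and not (np.diff(sub["time_s"].to_numpy()) > 0).all():
            raise ValidationError(f"non-monotone timestamps for player {player!r}")
        parts.append(_interpolate_gaps(sub, grid, rate, max_gap_s, str(player)))
    frame = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["time_s", "player_id"])
        .reset_index(drop=True)
    )
    dataset = PositionalDataset(frame=frame, rate=rate, pitch=pitch)
    dataset.validate()
    return dataset


def write_positional_csv(dataset: PositionalDataset, path: str | Path) -> Path:
    """Write a dataset in the interchange CSV layout (stable formatting)."""
    path = Path(path)
    frame = dataset.frame.sort_values(["time_s", "player_id"]).reset_index(drop=True)
    frame.to_csv(path, index=False, float_format="%.12g", columns=list(CSV_COLUMNS))
    return path


def write_series_csv(series, path: str | Path) -> Path:
    """Write a per-frame metric series to CSV, ``time_s`` column first.

    ``series`` may be a DataFrame or any object exposing ``to_frame()``.
    """
    frame = series.to_frame() if hasattr(series, "to_frame") else series
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot write series of type {type(series).__name__}")
    if frame.empty:
        raise EmptyInputError("refusing to write an empty series")
    if frame.columns[0] != "time_s":
        if "time_s" not in frame.columns:
            raise FormatError("series lacks a time_s column")
        cols = ["time_s"] + [c for c in frame.columns if c != "time_s"]
        frame = frame[cols]
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_series_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if frame.columns[0] != "time_s":
        raise FormatError(f"{path} is not a metric-series CSV (no leading time_s)")
    return frame


def dataset_from_records(
    records: Iterable[tuple[float, str, str, float, float]],
    rate: float,
    pitch: PitchModel | None = None,
) -> PositionalDataset:
    """Build a dataset from (time_s, player_id, team, x_m, y_m) tuples."""
    frame = pd.DataFrame(list(records), columns=list(CSV_COLUMNS))
    frame["player_id"] = frame["player_id"].astype(str)
    frame["team"] = frame["team"].astype(str)
    frame = frame.sort_values(["time_s", "player_id"]).reset_index(drop=True)
    ds = PositionalDataset(frame=frame, rate=rate, pitch=pitch or PitchModel())
    ds.validate()
    return ds
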