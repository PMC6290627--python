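import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pitchmetrics as pm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(
    positions: dict[str, tuple[np.ndarray, np.ndarray]],
    rate: float = 10.0,
    pitch: pm.PitchModel | None = None,
    team: str = "h",
) -> pm.PositionalDataset:
    """Dataset from per-player (x, y) arrays on the grid t = k/rate."""
    frames = []
    for pid, (x, y) in positions.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = np.arange(len(x), dtype=float) / rate
        frames.append(
            pd.DataFrame(
                {"time_s": t, "player_id": pid, "team": team, "x_m": x, "y_m": y}
            )
        )
    frame = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["time_s", "player_id"])
        .reset_index(drop=True)
    )
    return pm.PositionalDataset(
        frame=frame, rate=rate, pitch=pitch or pm.PitchModel()
    )


def static_dataset(points: dict[str, tuple[float, float]], n_frames: int = 20,
                   rate: float = 10.0) -> pm.PositionalDataset:
    """Every player frozen at one position for n_frames."""
    return make_dataset(
        {
            pid: (np.full(n_frames, x), np.full(n_frames, y))
            for pid, (x, y) in points.items()
        },
        rate=rate,
    )


@pytest.fixture
def square_dataset() -> pm.PositionalDataset:
    """Four players on the corners of a 2 x 2 square centered at (41, 31)."""
    return static_dataset(
        {"p1": (40.0, 30.0), "p2": (42.0, 30.0), "p3": (40.0, 32.0), "p4": (42.0, 32.0)}
    )


@pytest.fixture
def square_group() -> pm.GroupSelection:
    return pm.GroupSelection(("p1", "p2", "p3", "p4"), min_size=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180512)
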