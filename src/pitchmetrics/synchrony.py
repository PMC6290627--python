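"""Inter-player coordination: analytic-signal relative phase and ApEn.

Relative phase treats two movement signals (here, each player's distance
to the group centroid) as coupled oscillators: the instantaneous phase of
each is taken from its analytic signal (Hilbert transform) and their
difference, in degrees, quantifies coordination — values near 0° mean the
players move in-phase, values near 180° anti-phase. Approximate Entropy
(ApEn) then measures the regularity of that phase series: the logarithmic
likelihood that patterns of m contiguous observations which match within a
tolerance r keep matching one step further. Perfectly repeatable series
score exactly 0; typical movement data fall between 0 and 2.

Signals are mean-centered before the analytic-signal transform (the
Hilbert phase of an offset oscillation is distorted), and because the
transform is unreliable near the series ends, the first and last 5% of
frames are flagged as edge frames and excluded from circular summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _detrend
from scipy.signal import hilbert

from .errors import (
    AlignmentError,
    DegenerateSignalError,
    EmptyInputError,
    InsufficientDataError,
)
from .positional import GroupSelection, PositionalDataset

EDGE_FRACTION = 0.05  # fraction of frames flagged as unreliable at each end


@dataclass(frozen=True)
class ApEnParams:
    """ApEn parameters: embedding length m and tolerance r.

    ``r_mode="sd"`` interprets r as a fraction of the series' standard
    deviation (the field-standard choice is m=2, r=0.2 SD);
    ``r_mode="absolute"`` uses r in the units of the series.
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.r_mode not in ("sd", "absolute"):
            raise ValueError("r_mode must be 'sd' or 'absolute'")


@dataclass
class CircularStats:
    """Circular mean direction (degrees) and mean resultant length in [0, 1].

    When the resultant length is numerically zero the mean direction is
    undefined; ``defined`` is False and the angle reported as NaN.
    """

    mean_deg: float
    resultant_length: float
    defined: bool = True


@dataclass
class PhaseSeries:
    """Per-frame relative phase (degrees, wrapped to (-180, 180])."""

    times: np.ndarray
    phase_deg: np.ndarray
    signal_pair: tuple[str, str]
    edge_fraction: float = EDGE_FRACTION

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask excluding the edge frames at both ends."""
        n = len(self.phase_deg)
        k = int(np.floor(n * self.edge_fraction))
        mask = np.zeros(n, dtype=bool)
        mask[k : n - k if k else n] = True
        return mask

    def circular_summary(self) -> CircularStats:
        return circular_mean(self.phase_deg[self.interior])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "relative_phase_deg": self.phase_deg})


def wrap_degrees(angles) -> np.ndarray:
    """Wrap angles (degrees) to the interval (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(w, -180.0), 180.0, w)


def _analytic(signal: np.ndarray, detrend: bool) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if len(x) < 8:
        raise InsufficientDataError(f"phase needs >= 8 samples, got {len(x)}")
    if np.ptp(x) < 1e-12:
        raise DegenerateSignalError("constant signal: instantaneous phase undefined")
    x = _detrend(x, type="linear") if detrend else x - x.mean()
    return hilbert(x)


def instantaneous_phase(
    signal, rate: float | None = None, detrend: bool = False
) -> np.ndarray:
    """Instantaneous phase (degrees, wrapped to (-180, 180]) of a real signal.

    The signal is mean-centered (or linearly detrended) and transformed to
    its analytic representation; the phase is the complex argument.
    ``rate`` is accepted for interface symmetry but the phase itself is
    sample-indexed.
    """
    return wrap_degrees(np.degrees(np.angle(_analytic(signal, detrend))))


def relative_phase(
    signal_a,
    signal_b,
    times=None,
    labels: tuple[str, str] = ("a", "b"),
    detrend: bool = False,
) -> PhaseSeries:
    """Relative phase phi_a - phi_b per frame, wrapped to (-180, 180].

    Computed as the argument of ``h_a * conj(h_b)`` of the two analytic
    signals, which is the exactly-wrapped phase difference (no unwrap
    artifacts). Invariant to positive rescaling and offsets of either
    input.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"signal lengths differ: {a.shape} vs {b.shape}")
    ha = _analytic(a, detrend)
    hb = _analytic(b, detrend)
    phase = wrap_degrees(np.degrees(np.angle(ha * np.conj(hb))))
    if times is None:
        times = np.arange(len(a), dtype=float)
    return PhaseSeries(times=np.asarray(times, float), phase_deg=phase, signal_pair=labels)


def circular_mean(phases_deg) -> CircularStats:
    """Mean direction and resultant length of a sample of angles (degrees)."""
    p = np.asarray(phases_deg, dtype=float)
    if p.size == 0:
        raise EmptyInputError("circular mean of an empty sample")
    z = np.exp(1j * np.radians(p)).mean()
    r = float(abs(z))
    if r < 1e-12:
        return CircularStats(mean_deg=float("nan"), resultant_length=r, defined=False)
    return CircularStats(
        mean_deg=float(wrap_degrees(np.degrees(np.angle(z)))), resultant_length=r
    )


def apen(series, params: ApEnParams | None = None) -> float:
    """Approximate Entropy (classic Pincus formulation, self-matches included).

    ApEn = Phi^m(r) - Phi^(m+1)(r), where Phi^k(r) is the mean log of
    C_i^k(r), the fraction of length-k windows within Chebyshev distance r
    of window i. Self-matches keep every C_i positive (no log 0); a
    constant series scores exactly 0. At practical series lengths the
    estimator is non-negative; if r is so tight that windows match only
    themselves it can dip marginally below zero, bounded by
    ln((N-m)/(N-m+1)), an artifact of the differing window counts at m
    and m+1.
    """
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= params.m + 1:
        raise InsufficientDataError(
            f"ApEn with m={params.m} needs more than {params.m + 1} samples, got {n}"
        )
    r = params.r
    if params.r_mode == "sd":
        sd = float(x.std())
        if sd < 1e-15:
            raise DegenerateSignalError(
                "constant series has zero SD; use an absolute tolerance"
            )
        r = params.r * sd
    return _phi(x, params.m, r) - _phi(x, params.m + 1, r)


def _phi(x: np.ndarray, k: int, r: float) -> float:
    n = len(x) - k + 1
    diff = np.abs(x[:, None] - x[None, :])
    cheb = diff[:n, :n].copy()
    for o in range(1, k):
        np.maximum(cheb, diff[o : o + n, o : o + n], out=cheb)
    counts = np.count_nonzero(cheb <= r, axis=1)
    return float(np.mean(np.log(counts / n)))


@dataclass
class CoordinationResult:
    """Pairwise coordination profile: phase series plus summaries."""

    phase: PhaseSeries
    circular: CircularStats
    apen: float
    apen_params: ApEnParams

    def to_dict(self) -> dict:
        return {
            "pair": list(self.phase.signal_pair),
            "circular_mean_deg": self.circular.mean_deg,
            "circular_mean_abs_deg": abs(self.circular.mean_deg)
            if self.circular.defined
            else None,
            "resultant_length": self.circular.resultant_length,
            "mean_defined": self.circular.defined,
            "apen": self.apen,
            "apen_m": self.apen_params.m,
            "apen_r": self.apen_params.r,
            "apen_r_mode": self.apen_params.r_mode,
        }


def coordination_profile(
    dataset: PositionalDataset,
    player_a: str,
    player_b: str,
    group: GroupSelection,
    apen_params: ApEnParams | None = None,
    detrend: bool = True,
) -> CoordinationResult:
    """Coordination between two players of a group.

    Each player's distance-to-group-centroid series is the oscillating
    signal; their relative phase quantifies pairwise coordination and the
    ApEn of the phase series its unpredictability (higher = more chaotic
    coordination relative to the group center).
    """
    for p in (player_a, player_b):
        if p not in group.player_ids:
            raise AlignmentError(f"player {p!r} is not part of the analysis group")
    from .collective import radial_distances

    rd = radial_distances(dataset, group)
    da = rd[f"dist_{player_a}_m"].to_numpy()
    db = rd[f"dist_{player_b}_m"].to_numpy()
    phase = relative_phase(
        da, db, times=rd["time_s"].to_numpy(), labels=(player_a, player_b),
        detrend=detrend,
    )
    params = apen_params or ApEnParams()
    value = apen(phase.phase_deg, params)
    return CoordinationResult(
        phase=phase, circular=phase.circular_summary(), apen=value, apen_params=params
    )
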