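"""Landmark streams, tapping amplitude signals, and prominence-based peak detection.

The measurement chain mirrors video-based finger-tapping analysis: a hand
tracker emits 21 three-dimensional landmarks per frame with x, y in [0, 1]
and z a relative depth; the thumb-tip/index-tip Euclidean distance is the
tapping amplitude; each hand's amplitude series is max-normalized to a
0-100 scale; taps are local maxima that clear a topographic-prominence
threshold (0.3 on the unit scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

THUMB_TIP = 4
INDEX_TIP = 8
N_LANDMARKS = 21

#: Default topographic-prominence threshold on the unit (0-1) amplitude scale.
DEFAULT_PROMINENCE = 0.3

Scale = Literal["raw", "unit", "percent"]


class DegenerateSignalError(ValueError):
    """Raised when a signal carries no tapping information (constant / all zero)."""


class MissingLandmarkError(ValueError):
    """Raised when a frame lacks valid tip coordinates under the 'fail' policy."""


@dataclass
class LandmarkSeries:
    """Per-hand stream of 21 landmark points per frame.

    ``coords`` has shape (n_frames, 21, 3) holding (x, y, z) per landmark,
    with x, y normalized to [0, 1] by the tracker and z a relative depth.
    """

    subject_id: str
    hand: str
    coords: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 3):
            raise ValueError(
                f"coords must have shape (n_frames, {N_LANDMARKS}, 3); "
                f"got {self.coords.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject_id, hand, frame, time_s, landmark_id, x, y, z."""
        n, k = self.n_frames, N_LANDMARKS
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_id, n * k),
                "hand": np.repeat(self.hand, n * k),
                "frame": np.repeat(np.arange(n), k),
                "time_s": np.repeat(self.timestamps, k),
                "landmark_id": np.tile(np.arange(k), n),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
                "z": self.coords[:, :, 2].ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fps: float = 30.0) -> "LandmarkSeries":
        """Rebuild a single-hand series from the long CSV dialect."""
        ids = df["subject_id"].unique()
        hands = df["hand"].unique()
        if len(ids) != 1 or len(hands) != 1:
            raise ValueError("from_frame expects exactly one subject_id and hand")
        df = df.sort_values(["frame", "landmark_id"])
        frames = df["frame"].to_numpy()
        n = int(frames.max()) + 1
        if len(df) != n * N_LANDMARKS:
            raise ValueError("every frame must carry exactly 21 landmarks")
        coords = df[["x", "y", "z"]].to_numpy().reshape(n, N_LANDMARKS, 3)
        return cls(subject_id=str(ids[0]), hand=str(hands[0]), coords=coords, fps=fps)


@dataclass
class TappingSignal:
    """1-D thumb-index amplitude series for one hand.

    ``scale`` tracks the unit convention: "raw" distances straight from the
    landmark geometry, "unit" after division by the series maximum, and
    "percent" (0-100) as used for all reported features.
    """

    subject_id: str
    hand: str
    amplitude: np.ndarray
    fps: float = 30.0
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.amplitude)

    @property
    def duration_s(self) -> float:
        return len(self.amplitude) / self.fps

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.amplitude)) / self.fps

    def to_frame(self) -> pd.DataFrame:
        col = "amplitude_pct" if self.scale == "percent" else "amplitude_raw"
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "hand": self.hand,
                "frame": np.arange(len(self.amplitude)),
                "time_s": self.timestamps,
                col: self.amplitude,
            }
        )


@dataclass
class PeakSet:
    """Accepted peaks (taps) and the valleys between them, on the percent scale."""

    peak_indices: np.ndarray
    peak_amplitudes: np.ndarray
    valley_indices: np.ndarray
    prominence_threshold: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        self.valley_indices = np.asarray(self.valley_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.peak_indices)


def tip_distance(
    series: LandmarkSeries, missing: Literal["fail", "drop"] = "fail"
) -> TappingSignal:
    """Per-frame 3-D Euclidean distance between thumb tip and index-finger tip.

    ``missing`` controls frames whose tip coordinates contain NaN: "fail"
    raises, "drop" removes those frames from the output.
    """
    tips = series.coords[:, [THUMB_TIP, INDEX_TIP], :]
    bad = np.isnan(tips).any(axis=(1, 2))
    if bad.any():
        if missing == "fail":
            raise MissingLandmarkError(
                f"{int(bad.sum())} frame(s) with missing tip coordinates "
                f"(subject {series.subject_id}, hand {series.hand})"
            )
        tips = tips[~bad]
    diff = tips[:, 0, :] - tips[:, 1, :]
    dist = np.sqrt((diff**2).sum(axis=1))
    return TappingSignal(
        subject_id=series.subject_id,
        hand=series.hand,
        amplitude=dist,
        fps=series.fps,
        scale="raw",
    )


def normalize_signal(signal: TappingSignal) -> TappingSignal:
    """Max-normalize to the percent scale: 100 * value / max(series).

    The maximum of the output is exactly 100; order and amplitude ratios are
    preserved. A constant or non-positive series carries no tapping and
    raises :class:`DegenerateSignalError`.
    """
    x = signal.amplitude
    if len(x) == 0:
        raise DegenerateSignalError("empty signal")
    m = np.max(x)
    if not np.isfinite(m) or m <= 0:
        raise DegenerateSignalError("signal maximum must be positive and finite")
    if np.min(x) == m:
        raise DegenerateSignalError("constant signal: no tapping present")
    if m == 100.0:  # already max-normalized: exact no-op keeps idempotency
        return replace(signal, amplitude=x.copy(), scale="percent")
    return replace(signal, amplitude=100.0 * (x / m), scale="percent")


def _leftmost_plateau_peaks(x: np.ndarray, prominence: float) -> np.ndarray:
    """find_peaks with plateau peaks reported at their leftmost sample."""
    idx, props = find_peaks(x, prominence=prominence, plateau_size=(1, None))
    return props["left_edges"]


def detect_peaks(
    signal: TappingSignal, prominence: float = DEFAULT_PROMINENCE
) -> PeakSet:
    """Detect taps as local maxima with topographic prominence >= threshold.

    ``prominence`` is expressed on the unit (0-1) scale regardless of the
    signal's scale and rescaled internally. Detection runs on the
    unit-normalized series so the threshold discriminates real open-close
    cycles from frame noise. Plateau maxima are reported at their leftmost
    sample; valleys are the (leftmost) minima between consecutive accepted
    peaks. Reported amplitudes are on the percent scale.
    """
    if signal.scale == "raw":
        raise ValueError("detect_peaks expects a unit- or percent-scale signal")
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    x = np.asarray(signal.amplitude, dtype=float)
    if len(x) < 3:
        raise ValueError("signal shorter than 3 samples")
    m = np.max(x)
    if m <= 0:
        raise DegenerateSignalError("signal maximum must be positive")
    unit = x / m
    peaks = _leftmost_plateau_peaks(unit, prominence)
    pct = 100.0 * unit
    valleys = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        valleys.append(a + 1 + int(np.argmin(x[a + 1 : b])))
    return PeakSet(
        peak_indices=peaks,
        peak_amplitudes=pct[peaks],
        valley_indices=np.array(valleys, dtype=int),
        prominence_threshold=prominence,
    )


# ---------------------------------------------------------------------------
# CSV dialects

def signals_to_csv(signals: list[TappingSignal], path) -> None:
    pd.concat([s.to_frame() for s in signals], ignore_index=True).to_csv(
        path, index=False
    )


def signals_from_csv(path, fps: float = 30.0, scale: Scale = "percent") -> list[TappingSignal]:
    df = pd.read_csv(path)
    col = "amplitude_pct" if "amplitude_pct" in df.columns else "amplitude_raw"
    scale = "percent" if col == "amplitude_pct" else "raw"
    out = []
    for (sid, hand), g in df.groupby(["subject_id", "hand"], sort=True):
        g = g.sort_values("frame")
        out.append(
            TappingSignal(
                subject_id=str(sid),
                hand=str(hand),
                amplitude=g[col].to_numpy(),
                fps=fps,
                scale=scale,
            )
        )
    return out


def landmarks_to_csv(series_list: list[LandmarkSeries], path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )


def landmarks_from_csv(path, fps: float = 30.0) -> list[LandmarkSeries]:
    df = pd.read_csv(path)
    return [
        LandmarkSeries.from_frame(g, fps=fps)
        for _, g in df.groupby(["subject_id", "hand"], sort=True)
    ]
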