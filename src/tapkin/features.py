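"""Per-hand and per-subject finger-tapping features.

From each hand's detected peaks: the tapping score TS (taps per window),
mean tapping amplitude TA, tapping variation TV (SD of peak amplitudes),
and amplitude decrements AmpD-5/-7/-10 (first-minus-kth peak amplitude,
the sequence effect). Per subject, both hands plus the inter-hand
tap-count difference TD form a 13-value feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import DEFAULT_PROMINENCE, PeakSet, TappingSignal, detect_peaks, normalize_signal

log = logging.getLogger(__name__)

#: Canonical flattened feature order (versioned model I/O contract).
FEATURE_COLUMNS = [
    "ts_right", "ts_left", "td",
    "ta_right", "ta_left",
    "tv_right", "tv_left",
    "ampd5_right", "ampd5_left",
    "ampd7_right", "ampd7_left",
    "ampd10_right", "ampd10_left",
]


@dataclass
class HandFeatures:
    """One hand's tapping features over a fixed window.

    ``ok`` is a quality flag: False when fewer than 2 peaks were detected,
    in which case TV and the decrements are 0 by convention.
    """

    ts: int
    ta: float
    tv: float
    ampd5: float
    ampd7: float
    ampd10: float
    ok: bool = True


@dataclass
class SubjectFeatures:
    subject_id: str
    label: str
    right: HandFeatures
    left: HandFeatures

    @property
    def td(self) -> int:
        return abs(self.right.ts - self.left.ts)

    @property
    def ok(self) -> bool:
        return self.right.ok and self.left.ok

    def to_row(self) -> dict:
        r, l = self.right, self.left
        return {
            "subject_id": self.subject_id,
            "label": self.label,
            "ts_right": r.ts, "ts_left": l.ts, "td": self.td,
            "ta_right": r.ta, "ta_left": l.ta,
            "tv_right": r.tv, "tv_left": l.tv,
            "ampd5_right": r.ampd5, "ampd5_left": l.ampd5,
            "ampd7_right": r.ampd7, "ampd7_left": l.ampd7,
            "ampd10_right": r.ampd10, "ampd10_left": l.ampd10,
        }


def _ampd(amps: np.ndarray, k: int) -> float:
    """First-minus-kth peak amplitude with a saturating index.

    When fewer than k peaks exist the last peak stands in for the kth, so
    feature vectors stay complete for classification.
    """
    return float(amps[0] - amps[min(k, len(amps)) - 1])


def extract_hand_features(peaks: PeakSet, duration_s: float = 10.0) -> HandFeatures:
    """Compute one hand's features from its detected peaks.

    TS is the peak count; TA the mean peak amplitude; TV the n-1 SD of peak
    amplitudes; AmpD-k the first-minus-kth peak amplitude. With < 2 peaks
    the variation/decrement features are 0 and the hand is flagged.
    """
    amps = np.asarray(peaks.peak_amplitudes, dtype=float)
    n = len(amps)
    if n == 0:
        return HandFeatures(ts=0, ta=np.nan, tv=0.0, ampd5=0.0, ampd7=0.0,
                            ampd10=0.0, ok=False)
    if n == 1:
        return HandFeatures(ts=1, ta=float(amps[0]), tv=0.0, ampd5=0.0,
                            ampd7=0.0, ampd10=0.0, ok=False)
    return HandFeatures(
        ts=n,
        ta=float(np.mean(amps)),
        tv=float(np.std(amps, ddof=1)),
        ampd5=_ampd(amps, 5),
        ampd7=_ampd(amps, 7),
        ampd10=_ampd(amps, 10),
    )


def combine_hands(
    right: HandFeatures, left: HandFeatures, subject_id: str = "", label: str = "control"
) -> SubjectFeatures:
    """Pair both hands into the per-subject feature vector (TD included)."""
    return SubjectFeatures(subject_id=subject_id, label=label, right=right, left=left)


def features_from_signals(
    right: TappingSignal,
    left: TappingSignal,
    subject_id: str,
    label: str,
    prominence: float = DEFAULT_PROMINENCE,
) -> SubjectFeatures:
    """Normalize, detect peaks and extract features for one subject."""
    hands = {}
    for sig in (right, left):
        s = normalize_signal(sig) if sig.scale == "raw" else sig
        hands[sig.hand] = extract_hand_features(
            detect_peaks(s, prominence=prominence), duration_s=s.duration_s
        )
    return combine_hands(hands["right"], hands["left"], subject_id, label)


def build_feature_table(
    subjects: list[tuple[TappingSignal, TappingSignal, str, str]] | "object",
    prominence: float = DEFAULT_PROMINENCE,
) -> pd.DataFrame:
    """Assemble the cohort feature table, one row per subject.

    Accepts either a :class:`tapkin.synthetic.Cohort` or a list of
    (right_signal, left_signal, subject_id, label) tuples. Subjects whose
    hands yield fewer than 2 peaks each are excluded with a logged warning
    (mirroring the exclusion of videos where tapping cannot be detected).
    Rows are ordered by subject_id; output is deterministic.
    """
    if hasattr(subjects, "subjects"):  # Cohort
        items = [(s.right, s.left, s.subject_id, s.label) for s in subjects.subjects]
    else:
        items = list(subjects)
    rows = []
    for right, left, sid, label in items:
        sf = features_from_signals(right, left, sid, label, prominence=prominence)
        if not sf.ok:
            log.warning("subject %s excluded: undetectable tapping on >=1 hand", sid)
            continue
        rows.append(sf.to_row())
    df = pd.DataFrame(rows, columns=["subject_id", "label"] + FEATURE_COLUMNS)
    return df.sort_values("subject_id", ignore_index=True)
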