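"""Synthetic finger-tapping signal generator.

Emulates 10-second, 30 fps thumb-index tapping recordings for two groups:
healthy controls and Parkinsonian (bradykinetic) hands. Each hand is
commanded by interpretable kinematic parameters — taps per window, mean and
SD of peak amplitude (as % of the initial full stretch), a linear per-tap
amplitude decrement (the sequence effect), inter-tap timing jitter,
optional halts, and frame-level noise — so every downstream stage
(normalization, peak detection, feature extraction, classification) can be
exercised and validated against the commanded ground truth.

The default group presets (``CLINICAL_PRESETS``) encode group-level summary
statistics typical of video-based finger-tapping studies of PD patients and
healthy controls: controls tap ~24.6 times per 10 s at ~85% amplitude with
little decrement or inter-hand asymmetry; bradykinetic hands tap ~17.9
times at ~71-75% amplitude with a pronounced first-to-tenth-tap decrement
(~20%) and a mean inter-hand tap-count gap of ~2.8.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import N_LANDMARKS, INDEX_TIP, THUMB_TIP, LandmarkSeries, TappingSignal

#: Valley level between taps, % of full stretch (fingers nearly closed).
VALLEY_PCT = 2.0
#: Duration of the initial full-stretch descent into the first tap, seconds.
LEAD_IN_S = 0.2
#: Minimum frames per open-close cycle for a representable tap.
MIN_CYCLE_FRAMES = 3


class InfeasibleParametersError(ValueError):
    """Commanded taps cannot be represented at the given fps and duration."""


@dataclass
class HandKinematicParams:
    """Commanded kinematics of one hand over the recording window.

    Parameters
    ----------
    tap_count : taps in the window (>= 1).
    amp_mean_pct : mean commanded peak amplitude, % of full stretch.
    amp_sd_pct : SD of the amplitude noise around the commanded trend, %.
    decrement_per_tap_pct : mean linear decline of the commanded peak
        amplitude per successive tap, % (the sequence effect). The expected
        first-minus-tenth peak difference is 9x this value.
    halt_prob : probability per inter-tap interval of an inserted pause.
    timing_jitter_cv : coefficient of variation of inter-tap intervals.
    noise_sd_pct : additive frame-level Gaussian noise SD, %.
    """

    tap_count: int
    amp_mean_pct: float = 85.0
    amp_sd_pct: float = 5.0
    decrement_per_tap_pct: float = 0.0
    halt_prob: float = 0.0
    timing_jitter_cv: float = 0.08
    noise_sd_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.tap_count < 1:
            raise ValueError("tap_count must be >= 1")
        if not (0 < self.amp_mean_pct <= 100):
            raise ValueError("amp_mean_pct must lie in (0, 100]")
        if self.amp_sd_pct < 0 or self.noise_sd_pct < 0:
            raise ValueError("SDs must be non-negative")
        if not (0 <= self.halt_prob < 1):
            raise ValueError("halt_prob must lie in [0, 1)")
        if self.timing_jitter_cv < 0:
            raise ValueError("timing_jitter_cv must be non-negative")


@dataclass
class SubjectParams:
    """Commanded kinematics for both hands plus the class label."""

    right: HandKinematicParams
    left: HandKinematicParams
    label: str = "control"

    def __post_init__(self) -> None:
        if self.label not in ("control", "bradykinesia"):
            raise ValueError("label must be 'control' or 'bradykinesia'")

    @property
    def tap_count_asymmetry(self) -> int:
        return abs(self.right.tap_count - self.left.tap_count)


@dataclass
class HandDistribution:
    """Group-level distribution over one hand's kinematic parameters.

    ``amp_sd`` pairs describe the across-subject distribution of the
    per-hand peak-amplitude SD (the tapping-variation feature); the
    per-subject residual amplitude noise is re-derived from it by removing
    the variance contributed by the commanded linear decrement, so the
    *extracted* variation matches the commanded statistic.
    """

    ts_mean: float
    ts_sd: float
    amp_mean: float
    amp_mean_sd: float
    amp_sd_mean: float
    amp_sd_sd: float
    ampd10_mean: float
    ampd10_sd: float


@dataclass
class GroupPreset:
    """Sampling distributions for one group's subjects (both hands)."""

    name: str
    right: HandDistribution
    left: HandDistribution
    asymmetry_mean: float
    halt_prob: float = 0.0
    timing_jitter_cv: float = 0.08
    noise_sd_pct: float = 1.0

    def sample_subject(self, rng: np.random.Generator) -> SubjectParams:
        """Draw one subject's commanded parameters.

        Right-hand tap count is drawn from the group normal (rounded,
        clipped to >= 5); the left count is the right count offset by a
        half-normal rounded asymmetry with random sign, so both hands share
        the group mean. Per-hand amplitude decrement is drawn from the
        group first-to-tenth decrement distribution divided by 9.
        """
        ts_r = int(np.clip(round(rng.normal(self.right.ts_mean, self.right.ts_sd)), 5, None))
        asym = int(round(abs(rng.normal(0.0, self.asymmetry_mean * math.sqrt(math.pi / 2)))))
        sign = 1 if rng.random() < 0.5 else -1
        ts_l = int(np.clip(ts_r - sign * asym, 5, None))
        hands = {}
        for hand, dist, ts in (("right", self.right, ts_r), ("left", self.left, ts_l)):
            d = rng.normal(dist.ampd10_mean, dist.ampd10_sd) / 9.0
            amp = float(np.clip(rng.normal(dist.amp_mean, dist.amp_mean_sd), 30.0, 100.0))
            tv = max(rng.normal(dist.amp_sd_mean, dist.amp_sd_sd), 0.5)
            resid = residual_amp_sd(tv, d, ts)
            hands[hand] = HandKinematicParams(
                tap_count=ts,
                amp_mean_pct=amp,
                amp_sd_pct=resid,
                decrement_per_tap_pct=d,
                halt_prob=self.halt_prob,
                timing_jitter_cv=self.timing_jitter_cv,
                noise_sd_pct=self.noise_sd_pct,
            )
        label = "control" if self.name == "control" else "bradykinesia"
        return SubjectParams(right=hands["right"], left=hands["left"], label=label)


def residual_amp_sd(total_sd: float, decrement_per_tap: float, tap_count: int) -> float:
    """Amplitude-noise SD left after removing the linear decrement trend.

    A linear trend with slope d over T taps contributes variance
    d^2 (T^2 - 1) / 12 to the peak-amplitude SD; the commanded noise is the
    residual so that the extracted SD matches ``total_sd``. Floored at 0.5%.
    """
    trend_var = decrement_per_tap**2 * (tap_count**2 - 1) / 12.0
    return math.sqrt(max(total_sd**2 - trend_var, 0.25))


#: Group presets anchored to published control vs PD tapping summary statistics.
CLINICAL_PRESETS: dict[str, GroupPreset] = {
    "control": GroupPreset(
        name="control",
        right=HandDistribution(24.6, 7.3, 85.4, 6.9, 7.9, 3.9, 2.6, 15.6),
        left=HandDistribution(24.6, 7.2, 83.2, 8.0, 8.0, 4.0, 0.4, 11.3),
        asymmetry_mean=0.4,
    ),
    "pd": GroupPreset(
        name="pd",
        right=HandDistribution(17.9, 7.8, 71.4, 16.0, 14.4, 10.0, 20.5, 28.5),
        left=HandDistribution(17.9, 5.6, 75.3, 10.7, 13.1, 8.2, 17.6, 24.6),
        asymmetry_mean=2.8,
    ),
}


@dataclass
class CohortSpec:
    """Size, presets, seed and recording geometry of a synthetic cohort."""

    n_control: int = 47
    n_pd: int = 53
    presets: dict[str, GroupPreset] = field(
        default_factory=lambda: dict(CLINICAL_PRESETS)
    )
    seed: int = 0
    fps: float = 30.0
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_pd < 1:
            raise ValueError("both classes must be present (n >= 1 each)")


@dataclass
class Subject:
    subject_id: str
    label: str
    right: TappingSignal
    left: TappingSignal
    params: SubjectParams


@dataclass
class Cohort:
    subjects: list[Subject]
    spec: CohortSpec

    def manifest(self) -> pd.DataFrame:
        """Commanded per-hand parameters, one row per subject (for recovery tests)."""
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "label": s.label,
                   "tap_count_asymmetry": s.params.tap_count_asymmetry}
            for hand in ("right", "left"):
                hp: HandKinematicParams = getattr(s.params, hand)
                for f in dataclasses.fields(hp):
                    row[f"{f.name}_{hand}"] = getattr(hp, f.name)
            rows.append(row)
        return pd.DataFrame(rows)

    def signals(self) -> list[TappingSignal]:
        out = []
        for s in self.subjects:
            out.extend([s.right, s.left])
        return out


def _cycle_frames(
    rng: np.random.Generator,
    params: HandKinematicParams,
    n_frames: int,
    lead_frames: int,
    fps: float,
) -> tuple[np.ndarray, list[int]]:
    """Allocate frames to tap cycles (and halts) over the recording window."""
    halts: list[int] = []
    halt_total = 0
    for _ in range(params.tap_count - 1):
        if params.halt_prob > 0 and rng.random() < params.halt_prob:
            h = int(round(rng.uniform(0.3, 1.0) * fps))
            halts.append(h)
            halt_total += h
        else:
            halts.append(0)
    # reserve a short valley tail so the last cycle's descent completes and
    # its peak keeps full prominence
    tail = max(1, int(round(0.05 * fps)))
    budget = n_frames - lead_frames - halt_total - tail
    if budget < MIN_CYCLE_FRAMES * params.tap_count:
        raise InfeasibleParametersError(
            f"{params.tap_count} taps cannot fit in {budget} frames "
            f"(>= {MIN_CYCLE_FRAMES} frames per cycle required)"
        )
    w = rng.normal(1.0, params.timing_jitter_cv, size=params.tap_count)
    w = np.clip(w, 0.3, None)
    target = w / w.sum() * budget
    lengths = np.floor(target).astype(int)
    # largest-remainder rounding, then enforce the per-cycle minimum
    rem = target - lengths
    for i in np.argsort(-rem)[: budget - lengths.sum()]:
        lengths[i] += 1
    while (short := np.flatnonzero(lengths < MIN_CYCLE_FRAMES)).size:
        donor = int(np.argmax(lengths))
        if lengths[donor] <= MIN_CYCLE_FRAMES:
            raise InfeasibleParametersError("tap cycles shorter than 3 frames")
        lengths[donor] -= 1
        lengths[short[0]] += 1
    return lengths, halts


def generate_hand_signal(
    params: HandKinematicParams,
    fps: float = 30.0,
    duration_s: float = 10.0,
    seed: int | np.random.Generator = 0,
    stretch_distance: float = 0.25,
) -> TappingSignal:
    """Synthesize one hand's raw tapping-amplitude series.

    The series opens at the full-stretch posture (frame 0 at 100% of
    ``stretch_distance``) and descends monotonically into the first valley;
    because a boundary sample is never a topographic peak, this anchors the
    downstream max-normalization without adding a spurious tap. It then
    contains exactly ``params.tap_count`` raised-cosine open-close cycles
    whose commanded peak amplitudes follow the configured mean, SD, and
    linear decrement (clipped to the physical range), with valleys near
    2% of stretch, optional halts, and additive frame noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(fps * duration_s))
    if n_frames < 10:
        raise InfeasibleParametersError("fps * duration_s must be >= 10 frames")
    lead_frames = max(2, int(round(LEAD_IN_S * fps)))

    T = params.tap_count
    # commanded peaks: linear decrement centered so the mean equals amp_mean_pct
    trend = params.decrement_per_tap_pct * ((T + 1) / 2.0 - np.arange(1, T + 1))
    peaks = params.amp_mean_pct + trend + rng.normal(0.0, params.amp_sd_pct, size=T)
    peaks = np.clip(peaks, VALLEY_PCT + 2.0, 100.0)

    lengths, halts = _cycle_frames(rng, params, n_frames, lead_frames, fps)

    # lead-in: half-cosine descent from exactly 100 to the valley
    t = np.arange(lead_frames) / lead_frames
    pct = [100.0 - (100.0 - VALLEY_PCT) * (1 - np.cos(np.pi * t)) / 2.0]
    for i, m in enumerate(lengths):
        j = np.arange(m)
        w = (1 - np.cos(2 * np.pi * j / m)) / 2.0
        w /= w.max()  # peak frame carries exactly the commanded amplitude
        pct.append(VALLEY_PCT + (peaks[i] - VALLEY_PCT) * w)
        if i < T - 1 and halts[i]:
            pct.append(np.full(halts[i], VALLEY_PCT))
    x = np.concatenate(pct)
    if len(x) < n_frames:  # trailing frames rest at the valley
        x = np.concatenate([x, np.full(n_frames - len(x), VALLEY_PCT)])
    x = x[:n_frames]
    if params.noise_sd_pct > 0:
        x = x + rng.normal(0.0, params.noise_sd_pct, size=n_frames)
    raw = np.clip(x, 0.0, None) / 100.0 * stretch_distance
    return TappingSignal(
        subject_id="synthetic", hand="right", amplitude=raw, fps=fps, scale="raw"
    )


def generate_subject(
    params: SubjectParams,
    fps: float = 30.0,
    duration_s: float = 10.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s000",
) -> Subject:
    """Generate the two independent hand signals of one subject."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hands = {}
    for hand in ("right", "left"):
        sig = generate_hand_signal(getattr(params, hand), fps, duration_s, rng)
        sig.subject_id = subject_id
        sig.hand = hand
        hands[hand] = sig
    return Subject(
        subject_id=subject_id,
        label=params.label,
        right=hands["right"],
        left=hands["left"],
        params=params,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labeled cohort, reproducible for a fixed ``spec.seed``.

    One global seed fans out through a seed sequence into independent
    per-subject streams, so cohorts are bit-identical across runs and
    subjects are statistically independent.
    """
    ss = np.random.SeedSequence(spec.seed)
    groups = [("control", spec.n_control), ("pd", spec.n_pd)]
    n_total = spec.n_control + spec.n_pd
    children = ss.spawn(n_total)
    subjects = []
    i = 0
    for group, n in groups:
        preset = spec.presets[group]
        for _ in range(n):
            rng = np.random.default_rng(children[i])
            sp = preset.sample_subject(rng)
            subjects.append(
                generate_subject(
                    sp, spec.fps, spec.duration_s, rng, subject_id=f"s{i:03d}"
                )
            )
            i += 1
    return Cohort(subjects=subjects, spec=spec)


# ---------------------------------------------------------------------------
# Landmark rendering

#: Static hand template: plausible resting landmark positions (x, y, z) in
#: the tracker's normalized image coordinates. Only the index tip moves.
def _hand_template() -> np.ndarray:
    pts = np.zeros((N_LANDMARKS, 3))
    pts[:, 0] = 0.45 + 0.01 * np.arange(N_LANDMARKS) % 0.2
    pts[:, 1] = 0.65
    pts[THUMB_TIP] = (0.5, 0.6, 0.0)
    pts[INDEX_TIP] = (0.5, 0.4, 0.0)
    return pts


def render_landmarks(signal: TappingSignal) -> LandmarkSeries:
    """Embed a raw tapping signal as a 21-landmark stream.

    The thumb tip stays fixed and the index tip moves vertically so their
    Euclidean distance reproduces the signal sample-for-sample; the other
    19 landmarks are static. This exercises the landmark-to-distance stage
    of the pipeline on synthetic data.
    """
    if signal.scale != "raw":
        raise ValueError("render_landmarks expects a raw-scale signal")
    n = len(signal)
    coords = np.broadcast_to(_hand_template(), (n, N_LANDMARKS, 3)).copy()
    coords[:, INDEX_TIP, 1] = coords[:, THUMB_TIP, 1] - signal.amplitude
    return LandmarkSeries(
        subject_id=signal.subject_id, hand=signal.hand, coords=coords, fps=signal.fps
    )
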