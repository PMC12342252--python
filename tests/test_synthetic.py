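"""Generator properties: commanded kinematics must be recoverable downstream."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tapkin import (
    CLINICAL_PRESETS,
    CohortSpec,
    HandKinematicParams,
    InfeasibleParametersError,
    SubjectParams,
    detect_peaks,
    extract_hand_features,
    features_from_signals,
    generate_cohort,
    generate_hand_signal,
    generate_subject,
    normalize_signal,
    render_landmarks,
    tip_distance,
)
from tapkin.synthetic import residual_amp_sd


def _features(params, seed=0):
    sig = generate_hand_signal(params, seed=seed)
    return extract_hand_features(detect_peaks(normalize_signal(sig)))


class TestHandSignal:
    def test_opens_at_full_stretch(self, noiseless_params):
        sig = generate_hand_signal(noiseless_params, seed=0)
        assert sig.amplitude[0] == sig.amplitude.max()
        assert normalize_signal(sig).amplitude[0] == 100.0

    def test_noiseless_tap_count_roundtrip(self, noiseless_params):
        assert _features(noiseless_params).ts == noiseless_params.tap_count

    def test_zero_variation_features(self, noiseless_params):
        f = _features(noiseless_params)
        assert f.tv == 0.0
        assert f.ampd10 == 0.0
        assert f.ta == pytest.approx(noiseless_params.amp_mean_pct)

    def test_linear_decrement_closed_form(self, noiseless_params):
        d = 1.7
        p = dataclasses.replace(noiseless_params, decrement_per_tap_pct=d)
        f = _features(p)
        assert f.ampd10 == pytest.approx(9 * d, abs=1e-9)
        assert f.ampd5 == pytest.approx(4 * d, abs=1e-9)
        assert f.ampd7 == pytest.approx(6 * d, abs=1e-9)

    def test_decrement_monotonicity(self, noiseless_params):
        """Expected extracted AmpD-10 is non-decreasing in the commanded slope."""
        vals = []
        for d in (0.0, 0.5, 1.0, 2.0, 3.0):
            p = dataclasses.replace(
                noiseless_params, decrement_per_tap_pct=d, noise_sd_pct=0.5
            )
            vals.append(_features(p, seed=5).ampd10)
        assert vals == sorted(vals)

    def test_halts_preserve_tap_count(self, noiseless_params):
        p = dataclasses.replace(noiseless_params, tap_count=10, halt_prob=0.5)
        assert _features(p, seed=3).ts == 10

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(InfeasibleParametersError):
            generate_hand_signal(
                HandKinematicParams(tap_count=150, amp_mean_pct=80.0), seed=0
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HandKinematicParams(tap_count=0)
        with pytest.raises(ValueError):
            HandKinematicParams(tap_count=5, amp_mean_pct=120.0)
        with pytest.raises(ValueError):
            HandKinematicParams(tap_count=5, halt_prob=1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        tap_count=st.integers(1, 40),
        amp=st.floats(45.0, 95.0),
        decrement=st.floats(0.0, 0.4),
        jitter=st.floats(0.0, 0.15),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_property(self, tap_count, amp, decrement, jitter, seed):
        """Noiseless extracted TS equals commanded tap_count for any feasible
        draw whose commanded peaks stay above the prominence threshold."""
        p = HandKinematicParams(
            tap_count=tap_count,
            amp_mean_pct=amp,
            amp_sd_pct=0.0,
            decrement_per_tap_pct=decrement,
            timing_jitter_cv=jitter,
            noise_sd_pct=0.0,
        )
        assert _features(p, seed=seed).ts == tap_count


class TestSubjectAndCohort:
    def _hand(self, tap_count):
        return HandKinematicParams(
            tap_count=tap_count, amp_mean_pct=75.0, amp_sd_pct=0.0,
            timing_jitter_cv=0.0, noise_sd_pct=0.0,
        )

    def test_symmetric_hands_give_zero_td(self):
        sp = SubjectParams(right=self._hand(20), left=self._hand(20))
        s = generate_subject(sp, seed=1)
        sf = features_from_signals(s.right, s.left, s.subject_id, s.label)
        assert sf.td == 0

    def test_commanded_asymmetry_recovered(self):
        sp = SubjectParams(right=self._hand(20), left=self._hand(17),
                           label="bradykinesia")
        assert sp.tap_count_asymmetry == 3
        s = generate_subject(sp, seed=1)
        sf = features_from_signals(s.right, s.left, s.subject_id, s.label)
        assert sf.td == 3

    def test_cohort_is_deterministic(self):
        spec = CohortSpec(n_control=3, n_pd=3, seed=99)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        for a, b in zip(c1.subjects, c2.subjects):
            assert np.array_equal(a.right.amplitude, b.right.amplitude)
            assert np.array_equal(a.left.amplitude, b.left.amplitude)
        assert c1.manifest().equals(c2.manifest())

    def test_cohort_counts_and_shapes(self, small_cohort):
        labels = [s.label for s in small_cohort.subjects]
        assert labels.count("control") == 12
        assert labels.count("bradykinesia") == 12
        assert len(small_cohort.signals()) == 48
        assert all(len(s.right.amplitude) == 300 for s in small_cohort.subjects)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_control=0, n_pd=5)

    def test_pd_asymmetry_tracks_preset(self):
        """Monte-Carlo: mean commanded tap-count gap near the preset mean."""
        rng = np.random.default_rng(7)
        preset = CLINICAL_PRESETS["pd"]
        gaps = [preset.sample_subject(rng).tap_count_asymmetry for _ in range(400)]
        assert np.mean(gaps) == pytest.approx(preset.asymmetry_mean, abs=0.5)


class TestLandmarkRendering:
    def test_roundtrip_through_distance_and_normalization(self, noiseless_params):
        sig = generate_hand_signal(noiseless_params, seed=4)
        lm = render_landmarks(sig)
        rebuilt = normalize_signal(tip_distance(lm))
        expected = normalize_signal(sig)
        assert np.allclose(rebuilt.amplitude, expected.amplitude, atol=1e-9)
        assert lm.coords.shape == (300, 21, 3)
        xy = lm.coords[:, :, :2]
        assert xy.min() >= 0.0 and xy.max() <= 1.0


def test_residual_amp_sd_removes_trend_variance():
    """Commanded noise + linear trend reproduce the total peak-amplitude SD."""
    total, d, taps = 12.0, 1.5, 20
    resid = residual_amp_sd(total, d, taps)
    trend = d * ((taps + 1) / 2.0 - np.arange(1, taps + 1))
    implied = np.sqrt(resid**2 + trend.var(ddof=0))
    assert implied == pytest.approx(total, rel=0.02)
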