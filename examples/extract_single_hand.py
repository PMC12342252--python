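"""One hand end to end: landmarks -> distance -> peaks -> features.

Synthesizes a single bradykinetic hand with a commanded sequence effect,
renders it as a 21-landmark stream, then recovers the tapping features.
"""

from tapkin import (
    HandKinematicParams,
    detect_peaks,
    extract_hand_features,
    generate_hand_signal,
    normalize_signal,
    render_landmarks,
    tip_distance,
)

params = HandKinematicParams(
    tap_count=16,
    amp_mean_pct=70.0,
    amp_sd_pct=5.0,
    decrement_per_tap_pct=2.0,   # expected first-minus-tenth decrement = 18%
    noise_sd_pct=1.0,
)
signal = generate_hand_signal(params, fps=30, duration_s=10, seed=42)

landmarks = render_landmarks(signal)                 # 300 x 21 x (x, y, z)
amplitude = normalize_signal(tip_distance(landmarks))  # thumb-index distance, 0-100
peaks = detect_peaks(amplitude, prominence=0.3)
f = extract_hand_features(peaks)

print(f"commanded taps {params.tap_count}, detected TS = {f.ts}")
print(f"mean amplitude TA = {f.ta:.1f}% (commanded {params.amp_mean_pct}%)")
print(f"variation TV = {f.tv:.1f}%")
print(f"decrements AmpD-5/-7/-10 = {f.ampd5:.1f} / {f.ampd7:.1f} / {f.ampd10:.1f}%")
# AmpD-10 should sit near 9 x the commanded per-tap decrement (= 18%):
# successive peaks decline linearly, so peak1 - peak10 spans nine steps.
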