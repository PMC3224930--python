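import numpy as np
import pytest

from tonoscan import ScanRecording
from tonoscan.matching import (
    ReferencePattern,
    TemplateError,
    correlation_profile,
    select_reference_x,
    select_reference_z,
    sliding_correlation,
    template_score,
)
from tonoscan.simulate import generate_pulse_cycle

from conftest import make_step


def brute_force_sliding(x, y):
    """Independent oracle: literal per-lag Pearson loop."""
    n = len(x)
    out = np.empty(len(y) - n + 1)
    for k in range(len(out)):
        w = y[k:k + n]
        if np.std(w) == 0 or np.std(x) == 0:
            out[k] = 0.0
        else:
            out[k] = np.corrcoef(x, w)[0, 1]
    return out


def pulse_step(position_mm=0.0, hr=70, amplitude=30.0, noise=0.0, seed=0,
               phase=0, distortion=0.0, baseline=60.0, n=2000):
    cyc = generate_pulse_cycle(hr, amplitude, distortion)
    m = len(cyc)
    sig = baseline + cyc[(np.arange(n) + phase) % m]
    if noise:
        sig = sig + np.random.default_rng(seed).normal(0, noise, n)
    return make_step(position_mm, n=n, pressure=sig, adcw=0.2 * (sig - baseline),
                     cp=np.full(n, 80.0))


def reference_from_cycle(hr=70, amplitude=30.0, position=0.0, axis="X"):
    return ReferencePattern(
        samples=generate_pulse_cycle(hr, amplitude) + 60.0,
        source_position_mm=position,
        source_axis=axis,
    )


class TestSlidingCorrelation:
    def test_matches_bruteforce_oracle_on_seeded_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            x = rng.normal(size=40)
            y = rng.normal(size=300)
            fast = sliding_correlation(x, y)
            slow = brute_force_sliding(x, y)
            assert len(fast) == 261
            assert np.max(np.abs(fast - slow)) < 1e-12

    def test_exact_copy_scores_one_at_its_offset(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = rng.normal(size=400)
        y[100:150] = x
        assert sliding_correlation(x, y)[100] == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 3.5 * np.concatenate([x, rng.normal(size=100)]) + 7.0
        assert sliding_correlation(x, y)[0] == 1.0

    def test_anticorrelated_windows_score_minus_one(self):
        x = np.arange(60.0)
        y = 100.0 - 2.0 * np.arange(300.0)  # every window anti-affine to x
        r = sliding_correlation(x, y)
        assert np.all(r == -1.0)

    def test_zero_variance_window_scores_zero_with_flag(self):
        x = np.arange(30.0)
        y = np.concatenate([np.full(60, 5.0), np.arange(30.0)])
        r, flags = sliding_correlation(x, y, return_flags=True)
        assert r[0] == 0.0 and flags[0]
        assert r[-1] == 1.0 and not flags[-1]

    def test_bounds_respected(self):
        rng = np.random.default_rng(3)
        r = sliding_correlation(rng.normal(size=20), rng.normal(size=500))
        assert np.all(r >= -1.0) and np.all(r <= 1.0)

    def test_signal_shorter_than_template_rejected(self):
        with pytest.raises(ValueError, match="at least as long"):
            sliding_correlation(np.arange(10.0), np.arange(5.0))


class TestTemplateScore:
    def test_step_replaying_reference_scores_exactly_one(self):
        x = reference_from_cycle()
        step = pulse_step()
        assert template_score(x, step) == 1.0

    def test_score_matches_bruteforce_oracle(self):
        """Same reduction applied to a literal per-lag Pearson curve."""
        from tonoscan.beats import detect_beats

        x = reference_from_cycle()
        step = pulse_step(noise=0.5, seed=7, phase=123, distortion=0.3)
        beats = detect_beats(step.pressure, 500.0)
        slow = brute_force_sliding(x.samples, step.pressure)
        lo = beats[0].onset_index
        hi = min(beats[-1].offset_index, len(slow))
        assert template_score(x, step) == pytest.approx(
            np.max(slow[lo:hi]), abs=1e-12
        )
        per_beat = [
            np.max(slow[b.onset_index:min(b.offset_index, len(slow))])
            for b in beats
        ]
        assert template_score(x, step, reduction="mean") == pytest.approx(
            np.mean(per_beat), abs=1e-12
        )

    def test_score_decreases_with_distortion_severity(self):
        x = reference_from_cycle()
        scores = [
            template_score(x, pulse_step(distortion=s, noise=0.2, seed=4))
            for s in (0.0, 0.2, 0.4, 0.8)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_scale_and_offset_invariance(self):
        x = reference_from_cycle()
        base = pulse_step(noise=0.3, seed=9, distortion=0.2)
        scaled = make_step(
            0.0, n=2000, pressure=2.5 * base.pressure + 11.0,
            adcw=base.adcw, cp=base.contact_pressure,
        )
        assert template_score(x, scaled) == pytest.approx(
            template_score(x, base), abs=1e-9
        )

    def test_flat_step_returns_nan(self):
        x = reference_from_cycle()
        step = make_step(0.0, n=2000, pressure=np.full(2000, 90.0),
                         adcw=np.zeros(2000), cp=np.full(2000, 60.0))
        assert np.isnan(template_score(x, step))

    def test_unknown_reduction_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            template_score(reference_from_cycle(), pulse_step(), reduction="median")


class TestReferenceSelection:
    def test_reference_pattern_must_vary_and_span_a_cycle(self):
        with pytest.raises(TemplateError, match="constant"):
            ReferencePattern(np.full(300, 5.0), 0.0, "X")
        with pytest.raises(TemplateError, match="shorter"):
            ReferencePattern(np.arange(50.0), 0.0, "X")

    def test_x_reference_comes_from_segment_containing_x0(self):
        steps = [pulse_step(i * 0.25, phase=37 * i) for i in range(17)]
        scan = ScanRecording(axis="X", steps=steps)
        for x0, expected in [(3.50, 3.50), (3.62, 3.50)]:
            ref = select_reference_x(scan, x0)
            assert ref.source_position_mm == pytest.approx(expected)
            assert ref.source_axis == "X"

    def test_x_reference_out_of_range_rejected(self):
        steps = [pulse_step(i * 0.25) for i in range(5)]
        scan = ScanRecording(axis="X", steps=steps)
        with pytest.raises(Exception, match="outside"):
            select_reference_x(scan, 9.0)

    def test_x_reference_requires_x_axis(self):
        steps = [pulse_step(i * 0.125) for i in range(3)]
        scan = ScanRecording(axis="Z", steps=steps)
        with pytest.raises(TemplateError, match="X-axis"):
            select_reference_x(scan, 0.125)

    def test_z_reference_is_max_amplitude_step(self):
        amps = [10.0, 20.0, 12.0]
        steps = [
            pulse_step(i * 0.125, amplitude=a, phase=55 * i)
            for i, a in enumerate(amps)
        ]
        scan = ScanRecording(axis="Z", steps=steps)
        ref = select_reference_z(scan)
        assert ref.source_position_mm == pytest.approx(0.125)

    def test_z_reference_tie_breaks_to_earlier_step(self):
        steps = [pulse_step(i * 0.125, amplitude=15.0, phase=0) for i in range(3)]
        scan = ScanRecording(axis="Z", steps=steps)
        assert select_reference_z(scan).source_position_mm == 0.0

    def test_z_reference_all_flat_rejected(self):
        steps = [
            make_step(i * 0.125, n=2000, pressure=np.full(2000, 90.0),
                      adcw=np.zeros(2000), cp=np.full(2000, 60.0))
            for i in range(3)
        ]
        scan = ScanRecording(axis="Z", steps=steps)
        with pytest.raises(TemplateError, match="invalid"):
            select_reference_z(scan)


class TestCorrelationProfile:
    def test_replayed_reference_gives_all_ones(self):
        steps = [pulse_step(i * 0.25, phase=71 * i) for i in range(5)]
        scan = ScanRecording(axis="X", steps=steps)
        x = select_reference_x(scan, 0.50)
        prof = correlation_profile(scan, x)
        assert len(prof.r) == scan.n_steps
        assert np.all(prof.r == 1.0)

    def test_profile_unimodal_with_peak_at_reference(self, x_scan):
        x = select_reference_x(x_scan, 4.0)
        prof = correlation_profile(x_scan, x)
        i_ref = int(np.argmax(prof.r))
        assert prof.positions_mm[i_ref] == pytest.approx(4.0)
        assert prof.r_at(4.0) == 1.0
        assert prof.r_at(0.0) < prof.r_at(3.5)
        assert prof.r_at(8.0) < prof.r_at(4.5)
        assert np.all((prof.r >= -1) & (prof.r <= 1))

    def test_invalid_steps_flagged_not_dropped(self):
        steps = [pulse_step(0.0), pulse_step(0.25, phase=99)]
        steps.append(
            make_step(0.50, n=2000, pressure=np.full(2000, 90.0),
                      adcw=np.zeros(2000), cp=np.full(2000, 60.0))
        )
        scan = ScanRecording(axis="X", steps=steps)
        x = select_reference_x(scan, 0.0)
        prof = correlation_profile(scan, x)
        assert len(prof.r) == 3
        assert not prof.valid[2] and np.isnan(prof.r[2])
        assert prof.flags

    def test_sampling_rate_mismatch_rejected(self, x_scan):
        x = select_reference_x(x_scan, 4.0)
        x.sampling_rate_hz = 250.0
        with pytest.raises(TemplateError, match="sampling"):
            correlation_profile(x_scan, x)
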