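"""Pulse-cycle segmentation and per-step amplitude features.

Each 4-second capture holds three to four complete pulse cycles.  Beats
are delimited by systolic upstroke onsets found on the pressure channel;
the same onset indices are then applied to the synchronous ADCW channel,
so amplitude features of both channels come from identical windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from tonoscan.io import StepSegment

__all__ = ["Beat", "StepFeatures", "detect_beats", "peak_to_peak", "step_features"]

#: refractory period between upstrokes, s (max heart rate 180 BPM)
MIN_CYCLE_S = 0.33
#: longest admissible cycle, s (min heart rate 30 BPM)
MAX_CYCLE_S = 2.0
#: upstroke threshold as a fraction of a high percentile of the smoothed
#: derivative; the systolic upstroke occupies only a few percent of samples,
#: so the 99th percentile tracks its slope while the reflected-wave and
#: dicrotic rises stay well below the threshold
UPSTROKE_THRESHOLD_FRACTION = 0.5
UPSTROKE_PERCENTILE = 99.0
#: moving-average window applied to the first difference, s; matches the
#: 40 Hz upper edge of the acquisition's analog band so broadband sensor
#: noise cannot masquerade as an upstroke
DERIVATIVE_SMOOTH_S = 0.025


class FeatureError(ValueError):
    """A feature is requested from input that cannot supply it."""


@dataclass
class Beat:
    """One complete pulse cycle, onset-to-onset."""

    onset_index: int
    offset_index: int
    cycle: np.ndarray

    def __post_init__(self) -> None:
        if self.onset_index >= self.offset_index:
            raise ValueError("onset_index must precede offset_index")
        if len(self.cycle) != self.offset_index - self.onset_index:
            raise ValueError("cycle length must equal offset - onset")

    def __len__(self) -> int:
        return self.offset_index - self.onset_index


@dataclass
class StepFeatures:
    """Per-step amplitude summary.

    ``valid`` is False when no complete beat could be segmented (e.g. a
    flat off-artery capture); invalid steps keep their position in
    tables but are excluded from fits and statistics.
    """

    position_mm: float
    mean_contact_pressure_mmHg: float
    adcw_amplitude: float
    pressure_amplitude_mmHg: float
    n_beats: int
    valid: bool = True


def detect_beats(signal, sampling_rate_hz: float) -> list[Beat]:
    """Segment a pulse signal into complete onset-to-onset cycles.

    Upstroke onsets are maxima of the first difference exceeding an
    adaptive threshold (a fraction of a high percentile of the derivative),
    separated by at least the 0.33 s refractory period.  Partial cycles
    at either end are discarded; cycles outside the physiological
    0.33-2.0 s range are dropped.  A signal with no detectable
    periodicity yields an empty list.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2 * sampling_rate_hz:
        raise ValueError("signal must be at least 2 s long")
    d = np.diff(signal)
    win = max(int(round(DERIVATIVE_SMOOTH_S * sampling_rate_hz)), 1)
    d = np.convolve(d, np.ones(win) / win, mode="same")
    scale = np.percentile(d, UPSTROKE_PERCENTILE)
    if not np.isfinite(scale) or scale <= 0 or np.ptp(signal) == 0:
        return []
    min_dist = int(round(MIN_CYCLE_S * sampling_rate_hz))
    onsets, _ = find_peaks(
        d, height=UPSTROKE_THRESHOLD_FRACTION * scale, distance=min_dist
    )
    # an upstroke truncated by a capture edge cannot be anchored; cycles
    # starting there are treated as partial and discarded
    margin = 2 * win
    onsets = onsets[(onsets >= margin) & (onsets <= len(d) - margin)]
    if len(onsets) < 2:
        return []
    intervals = np.diff(onsets)
    if len(intervals) >= 2 and np.std(intervals) / np.mean(intervals) > 0.25:
        # irregular onset spacing: broadband noise, not a pulse train
        return []
    # genuine pulse trains repeat at the onset interval; broadband noise
    # has no autocorrelation there even when refractory-limited peak
    # spacing looks regular
    period = int(np.median(intervals))
    a, b = signal[:-period], signal[period:]
    if np.std(a) == 0 or np.std(b) == 0:
        return []
    if np.corrcoef(a, b)[0, 1] < 0.3:
        return []
    max_len = int(round(MAX_CYCLE_S * sampling_rate_hz))
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if min_dist <= b - a <= max_len:
            beats.append(Beat(int(a), int(b), signal[a:b]))
    # spurious intra-cycle triggers (e.g. a noise-boosted dicrotic rise)
    # produce off-length cycles; enforce consistency with the median
    if len(beats) >= 3:
        lengths = np.array([len(b) for b in beats])
        med = np.median(lengths)
        beats = [b for b, L in zip(beats, lengths) if abs(L - med) <= 0.15 * med]
    return beats


def peak_to_peak(beats: list[Beat]) -> float:
    """Mean over beats of the within-cycle max minus min."""
    if not beats:
        raise FeatureError("peak_to_peak is undefined for an empty beat sequence")
    return float(np.mean([np.ptp(b.cycle) for b in beats]))


def step_features(step: StepSegment) -> StepFeatures:
    """Amplitude features of one step.

    Beats are detected on the pressure channel and the same windows are
    applied to the ADCW channel.  The mean contact pressure is the mean
    of the full contact-pressure series.
    """
    mean_cp = float(np.mean(step.contact_pressure))
    beats = detect_beats(step.pressure, step.sampling_rate_hz)
    if not beats:
        return StepFeatures(
            position_mm=step.position_mm,
            mean_contact_pressure_mmHg=mean_cp,
            adcw_amplitude=np.nan,
            pressure_amplitude_mmHg=np.nan,
            n_beats=0,
            valid=False,
        )
    adcw_beats = [
        Beat(b.onset_index, b.offset_index, step.adcw[b.onset_index:b.offset_index])
        for b in beats
    ]
    return StepFeatures(
        position_mm=step.position_mm,
        mean_contact_pressure_mmHg=mean_cp,
        adcw_amplitude=peak_to_peak(adcw_beats),
        pressure_amplitude_mmHg=peak_to_peak(beats),
        n_beats=len(beats),
    )
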