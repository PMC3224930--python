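"""Template matching of a reference pulse cycle against pressure signals.

A single "optimal" pulse cycle x (length N) is slid over the whole
pressure signal y and the Pearson correlation coefficient r_xy[k] is
computed at every lag k.  The per-segment template correlation
coefficient r summarises how faithfully that segment reproduces the
reference morphology; r degrades as the sensor leaves the artery (X
axis) or compresses it (Z axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from tonoscan.beats import detect_beats, step_features
from tonoscan.io import ScanRecording, StepSegment

__all__ = [
    "ReferencePattern",
    "CorrelationProfile",
    "sliding_correlation",
    "template_score",
    "select_reference_x",
    "select_reference_z",
    "correlation_profile",
]

#: scores within this distance of +/-1 are an exact self/anti match up to
#: floating-point rounding of the normalisation and are snapped to +/-1
_UNIT_SNAP_TOL = 1e-12


class TemplateError(ValueError):
    pass


@dataclass
class ReferencePattern:
    """One extracted pulse cycle used as the matching template x."""

    samples: np.ndarray
    source_position_mm: float
    source_axis: str
    sampling_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.ptp(self.samples) == 0:
            raise TemplateError("reference pattern must not be constant")
        if len(self.samples) < 0.33 * self.sampling_rate_hz:
            raise TemplateError(
                "reference pattern shorter than a physiological cycle"
            )

    @property
    def length_N(self) -> int:
        return len(self.samples)


@dataclass
class CorrelationProfile:
    """Template correlation coefficient per step, in position order."""

    positions_mm: np.ndarray
    r: np.ndarray
    valid: np.ndarray
    flags: list[str] = field(default_factory=list)
    lag_curves: list | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_mm": self.positions_mm, "r": self.r, "valid": self.valid}
        )

    def r_at(self, position_mm: float) -> float:
        i = np.flatnonzero(np.isclose(self.positions_mm, position_mm))
        if len(i) == 0:
            raise KeyError(f"no step at position {position_mm} mm")
        return float(self.r[int(i[0])])


def sliding_correlation(x, y, *, return_flags: bool = False):
    """Pearson correlation of template ``x`` with every N-window of ``y``.

    Returns r_xy of length ``len(y) - N + 1``; entry k is the
    correlation between x and ``y[k:k+N]``.  Windows with zero variance
    are scored 0 (and flagged when ``return_flags``), never NaN.
    """
    x = x.samples if isinstance(x, ReferencePattern) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) < n:
        raise ValueError("signal y must be at least as long as the template")
    xc = x - x.mean()
    sx = np.sqrt(np.sum(xc * xc))
    windows = sliding_window_view(y, n)
    wc = windows - windows.mean(axis=1, keepdims=True)
    cov = wc @ xc
    sw = np.sqrt(np.sum(wc * wc, axis=1))
    degenerate = (sw == 0) | (sx == 0)
    denom = np.where(degenerate, 1.0, sw * sx)
    r = np.clip(cov / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    # an exact (anti-)copy of x correlates +/-1 up to rounding of sw*sx
    r[np.abs(r - 1.0) < _UNIT_SNAP_TOL] = 1.0
    r[np.abs(r + 1.0) < _UNIT_SNAP_TOL] = -1.0
    if return_flags:
        return r, degenerate
    return r


def template_score(
    x: ReferencePattern, step: StepSegment, *, reduction: str = "max"
) -> float:
    """Reduce the lag-correlation curve of one step to a single r.

    Lags are restricted to the span of complete beats (partial end
    cycles carry no usable morphology).  ``reduction="max"`` (default)
    takes the maximum of r_xy over that span, so the step the template
    was cut from scores exactly 1; ``reduction="mean"`` averages each
    complete beat's own maximum over its onset-to-onset lag window.
    Returns NaN when the step has no detectable beats.
    """
    beats = detect_beats(step.pressure, step.sampling_rate_hz)
    if not beats:
        return float("nan")
    r = sliding_correlation(x, step.pressure)
    n_lags = len(r)
    if reduction == "max":
        lo = beats[0].onset_index
        hi = min(beats[-1].offset_index, n_lags)
        if lo >= hi:
            lo, hi = 0, n_lags
        return float(np.max(r[lo:hi]))
    if reduction == "mean":
        maxima = []
        for b in beats:
            lo = min(b.onset_index, n_lags - 1)
            hi = min(b.offset_index, n_lags)
            if lo < hi:
                maxima.append(np.max(r[lo:hi]))
        if not maxima:
            return float(np.max(r))
        return float(np.mean(maxima))
    raise ValueError(f"unknown reduction {reduction!r}")


def _most_self_consistent_cycle(step: StepSegment) -> np.ndarray:
    """Pick the beat with the highest mean correlation to its peers.

    Objective proxy for the "optimal" complete cycle: compare all beats
    over their common leading length and keep the one most similar, on
    average, to the others.
    """
    beats = detect_beats(step.pressure, step.sampling_rate_hz)
    if not beats:
        raise TemplateError(
            f"step at {step.position_mm} mm has no detectable beats"
        )
    if len(beats) == 1:
        return beats[0].cycle
    L = min(len(b) for b in beats)
    mat = np.array([b.cycle[:L] for b in beats])
    c = np.corrcoef(mat)
    mean_peer = (c.sum(axis=1) - 1.0) / (len(beats) - 1)
    return beats[int(np.argmax(mean_peer))].cycle


def select_reference_x(scan: ScanRecording, X0_mm: float) -> ReferencePattern:
    """Reference cycle from the segment containing the arterial middle X0."""
    if scan.axis != "X":
        raise TemplateError("select_reference_x requires an X-axis scan")
    step = scan.step_at(X0_mm)
    cycle = _most_self_consistent_cycle(step)
    return ReferencePattern(
        samples=cycle,
        source_position_mm=step.position_mm,
        source_axis="X",
        sampling_rate_hz=step.sampling_rate_hz,
    )


def select_reference_z(scan: ScanRecording) -> ReferencePattern:
    """Reference cycle from the maximum-pressure-amplitude segment.

    Ties (to machine precision) resolve to the earlier, lower-pressure
    step.
    """
    if scan.axis != "Z":
        raise TemplateError("select_reference_z requires a Z-axis scan")
    best = None
    best_amp = -np.inf
    for step in scan.steps:
        f = step_features(step)
        if f.valid and f.pressure_amplitude_mmHg > best_amp:
            best, best_amp = step, f.pressure_amplitude_mmHg
    if best is None:
        raise TemplateError("all steps invalid: no beats detected anywhere")
    cycle = _most_self_consistent_cycle(best)
    return ReferencePattern(
        samples=cycle,
        source_position_mm=best.position_mm,
        source_axis="Z",
        sampling_rate_hz=best.sampling_rate_hz,
    )


def correlation_profile(
    scan: ScanRecording, x: ReferencePattern, *, reduction: str = "max"
) -> CorrelationProfile:
    """Template correlation coefficient at every step of a scan."""
    if not np.isclose(x.sampling_rate_hz, scan.sampling_rate_hz):
        raise TemplateError("scan and reference pattern sampling rates differ")
    rs, valid, flags = [], [], []
    for step in scan.steps:
        r = template_score(x, step, reduction=reduction)
        ok = np.isfinite(r)
        if not ok:
            flags.append(f"step at {step.position_mm} mm: no beats")
        rs.append(r)
        valid.append(ok)
    return CorrelationProfile(
        positions_mm=scan.positions_mm,
        r=np.array(rs),
        valid=np.array(valid),
        flags=flags,
    )
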