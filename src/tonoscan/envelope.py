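"""Gaussian envelope of ADCW amplitude across the artery; width estimation.

As the sensor moves laterally across the radial artery, the measured
arterial-diameter-change amplitude rises and falls because only the
vertical component D_ver = D_act * cos(theta) of the wall displacement
reaches the strain gauge.  The spatial amplitude profile is well
described by

    ADCW(X) = ADCW_max * exp(-(X - X0)^2 / (2 sigma^2))

whose centre X0 estimates the middle of the artery and whose standard
deviation sigma scales with the arterial width.  The width estimate uses
the empirical, ultrasound-calibrated Width_Index (0.355):

    width = (2 + Width_Index) * sigma

The estimated boundaries X0 -/+ width/2 are snapped inward to the motor
step grid, mirroring how a mechanism with finite resolution picks the
boundary segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

__all__ = [
    "GaussianEnvelope",
    "GaussianEnvelopeFit",
    "EnvelopeFit",
    "fit_gaussian_envelope",
    "estimate_width",
    "snap_boundaries",
    "DEFAULT_WIDTH_INDEX",
]

#: ultrasound-calibrated cohort mean of the Width_Index
DEFAULT_WIDTH_INDEX = 0.355


class EnvelopeFitError(RuntimeError):
    pass


class EnvelopeDataError(ValueError):
    pass


def gaussian(x, amp, x0, sigma):
    return amp * np.exp(-((x - x0) ** 2) / (2.0 * sigma**2))


@dataclass
class GaussianEnvelopeFit:
    """Fitted envelope parameters with standard errors and fit quality.

    ``R`` is the Pearson correlation between fitted and observed
    amplitudes (the curve-fitting correlation coefficient), clipped to
    [0, 1].
    """

    ADCW_max: float
    X0_mm: float
    sigma_mm: float
    R: float
    se: dict
    n_points: int
    positions_mm: np.ndarray
    amplitudes: np.ndarray

    def predict(self, positions_mm) -> np.ndarray:
        return gaussian(np.asarray(positions_mm, float),
                        self.ADCW_max, self.X0_mm, self.sigma_mm)

    def width(self, width_index: float = DEFAULT_WIDTH_INDEX) -> float:
        return estimate_width(self.sigma_mm, width_index)

    def summary(self) -> str:
        lines = [
            "Gaussian ADCW envelope fit",
            "=" * 42,
            f"{'n points':<22}{self.n_points:>20d}",
            f"{'ADCW_max (a.u.)':<22}{self.ADCW_max:>20.4f}",
            f"{'  std err':<22}{self.se['ADCW_max']:>20.4f}",
            f"{'X0 (mm)':<22}{self.X0_mm:>20.4f}",
            f"{'  std err':<22}{self.se['X0_mm']:>20.4f}",
            f"{'sigma (mm)':<22}{self.sigma_mm:>20.4f}",
            f"{'  std err':<22}{self.se['sigma_mm']:>20.4f}",
            f"{'R (fit correlation)':<22}{self.R:>20.4f}",
            f"{'width (WI=0.355), mm':<22}{self.width():>20.4f}",
        ]
        return "\n".join(lines)


class GaussianEnvelope:
    """Model of the ADCW amplitude profile across the artery.

    Parameters
    ----------
    positions_mm, amplitudes : array-like
        Per-step sensor positions and averaged peak-to-peak ADCW
        amplitudes.  Non-finite amplitudes (flagged invalid steps) are
        dropped before fitting.
    """

    def __init__(self, positions_mm, amplitudes):
        pos = np.asarray(positions_mm, dtype=float)
        amp = np.asarray(amplitudes, dtype=float)
        keep = np.isfinite(amp) & np.isfinite(pos)
        self.positions_mm = pos[keep]
        self.amplitudes = amp[keep]
        if len(self.positions_mm) < 4:
            raise EnvelopeDataError("need at least 4 valid (position, amplitude) pairs")
        if np.ptp(self.amplitudes) == 0:
            raise EnvelopeDataError("amplitudes are all equal; no envelope to fit")
        if np.all(self.amplitudes <= 0):
            raise EnvelopeDataError("amplitudes are non-positive")

    def _start(self) -> tuple[float, float, float]:
        # moment-based start: weighted mean / SD of positions
        w = np.clip(self.amplitudes, 0, None)
        w = w / w.sum()
        x0 = float(np.sum(w * self.positions_mm))
        var = float(np.sum(w * (self.positions_mm - x0) ** 2))
        sigma = max(np.sqrt(var), np.diff(np.sort(self.positions_mm)).min())
        return float(self.amplitudes.max()), x0, sigma

    def fit(self) -> GaussianEnvelopeFit:
        p0 = self._start()
        span = np.ptp(self.positions_mm)
        try:
            popt, pcov = curve_fit(
                gaussian,
                self.positions_mm,
                self.amplitudes,
                p0=p0,
                bounds=(
                    [0.0, self.positions_mm.min() - span, 1e-6],
                    [np.inf, self.positions_mm.max() + span, 10 * span + 1.0],
                ),
                maxfev=10000,
            )
        except RuntimeError as e:
            raise EnvelopeFitError(
                f"Gaussian envelope fit did not converge (start={p0})"
            ) from e
        amp, x0, sigma = popt
        fitted = gaussian(self.positions_mm, *popt)
        if np.ptp(fitted) == 0:
            raise EnvelopeFitError("degenerate fit: constant fitted curve")
        R = float(np.clip(pearsonr(fitted, self.amplitudes)[0], 0.0, 1.0))
        perr = np.sqrt(np.diag(pcov))
        return GaussianEnvelopeFit(
            ADCW_max=float(amp),
            X0_mm=float(x0),
            sigma_mm=float(sigma),
            R=R,
            se={"ADCW_max": perr[0], "X0_mm": perr[1], "sigma_mm": perr[2]},
            n_points=len(self.positions_mm),
            positions_mm=self.positions_mm,
            amplitudes=self.amplitudes,
        )


def fit_gaussian_envelope(positions_mm, amplitudes) -> GaussianEnvelopeFit:
    """Nonlinear least-squares Gaussian fit of an ADCW amplitude profile."""
    return GaussianEnvelope(positions_mm, amplitudes).fit()


def estimate_width(sigma_mm: float, width_index: float = DEFAULT_WIDTH_INDEX) -> float:
    """Arterial width from the envelope SD: width = (2 + Width_Index) * sigma."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if width_index <= 0:
        raise ValueError("width_index must be positive")
    return (2.0 + width_index) * sigma_mm


def snap_boundaries(
    X0_mm: float, width_mm: float, grid
) -> tuple[float, float, bool]:
    """Snap the ideal boundaries X0 -/+ width/2 to segment starts.

    Boundaries snap INWARD (left up, right down) so the chosen segments
    lie within the estimated artery, matching how boundary segments are
    picked at the 0.25 mm motor resolution.  An ideal boundary already
    on a segment start stays put.  Boundaries beyond the scanned range
    are clamped to the end segments, with a warning flag in the third
    return value.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) < 2:
        raise ValueError("grid needs at least 2 segment starts")
    if width_mm <= 0:
        raise ValueError("width_mm must be positive")
    step = float(np.min(np.diff(grid)))
    ideal_left = X0_mm - width_mm / 2.0
    ideal_right = X0_mm + width_mm / 2.0

    def snap(ideal: float, direction: int) -> float:
        # direction +1 snaps up (left boundary), -1 snaps down (right)
        k = (ideal - grid[0]) / step
        k = np.ceil(k - 1e-9) if direction > 0 else np.floor(k + 1e-9)
        return grid[0] + step * k

    clamped = False
    left = snap(ideal_left, +1)
    right = snap(ideal_right, -1)
    if left < grid[0]:
        left, clamped = grid[0], True
    if right > grid[-1]:
        right, clamped = grid[-1], True
    if left >= right:
        # artery narrower than two motor steps: take the segments
        # flanking X0 so order is preserved
        left = max(grid[0], snap(X0_mm, -1) - step)
        right = min(grid[-1], left + 2 * step)
        left = right - 2 * step if right - 2 * step >= grid[0] else left
        if left >= right:
            left, right = grid[0], grid[-1]
        clamped = True
    return float(left), float(right), clamped


# backwards-compatible alias used by the pipeline result containers
EnvelopeFit = GaussianEnvelopeFit
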