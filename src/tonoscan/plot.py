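"""Diagnostic plots for envelope fits and correlation profiles.

matplotlib is imported lazily so the analysis stack stays importable in
headless batch environments without a plotting backend configured.
"""

from __future__ import annotations

import numpy as np


def plot_envelope(fit, ax=None):
    """ADCW amplitude profile with the fitted Gaussian envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fit.positions_mm, fit.amplitudes, "ko", label="measured ADCW p2p")
    xs = np.linspace(fit.positions_mm.min(), fit.positions_mm.max(), 200)
    ax.plot(xs, fit.predict(xs), "-", label=f"Gaussian fit (R={fit.R:.3f})")
    ax.axvline(fit.X0_mm, ls="--", color="grey", label=f"X0={fit.X0_mm:.2f} mm")
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("ADCW amplitude (a.u.)")
    ax.legend()
    return ax


def plot_profile(profile, ax=None, anchor_mm: float | None = None):
    """Template correlation coefficient vs step position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = profile.valid
    ax.plot(profile.positions_mm[ok], profile.r[ok], "o-")
    if anchor_mm is not None:
        ax.axvline(anchor_mm, ls="--", color="grey")
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("template correlation r")
    ax.set_ylim(None, 1.02)
    return ax


def plot_excess_pressure(table, ax=None):
    """Template correlation vs excess contact pressure."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hasattr(table, "to_frame"):
        df = table.to_frame()
        ax.plot(df["delta_mmHg"], df["r"], "s-")
    else:
        ax.errorbar(table["delta_mmHg"], table["mean_r"], yerr=table["sd_r"],
                    fmt="s-", capsize=3)
    ax.set_xlabel("excess contact pressure (mmHg)")
    ax.set_ylabel("template correlation r")
    return ax
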