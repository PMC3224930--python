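"""End-to-end X-axis and Z-axis scan analyses and cohort aggregation.

The X-axis analysis finds where to place the sensor: per-step amplitude
features -> Gaussian envelope fit of the ADCW profile -> arterial width
and middle position X0 -> reference pulse cycle at X0 -> template
correlation profile -> boundary segments and their correlations.

The Z-axis analysis finds how hard to press: the maximum-amplitude step
supplies the reference cycle and its mean contact pressure is the
criterion level; the excess-pressure table reports the template
correlation at +50/100/150/200 mmHg above it.

Cohort aggregation re-indexes each subject's profile to a relative
position (0 mm at the alignment anchor) and reports n, mean and SD of
the template correlation per relative position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tonoscan.beats import StepFeatures, step_features
from tonoscan.envelope import (
    DEFAULT_WIDTH_INDEX,
    EnvelopeDataError,
    EnvelopeFitError,
    GaussianEnvelope,
    GaussianEnvelopeFit,
    estimate_width,
    snap_boundaries,
)
from tonoscan.io import CohortTable, ScanRecording
from tonoscan.matching import (
    CorrelationProfile,
    ReferencePattern,
    correlation_profile,
    select_reference_x,
    select_reference_z,
)

__all__ = [
    "XScanModel",
    "ZScanModel",
    "XScanResults",
    "ZScanResults",
    "ExcessPressureTable",
    "analyze_x_scan",
    "analyze_z_scan",
    "cohort_aggregate",
    "cohort_excess_pressure",
    "filter_results",
]

logger = logging.getLogger("tonoscan")

DEFAULT_DELTAS_MMHG = (50.0, 100.0, 150.0, 200.0)


def _features_frame(feats: list[StepFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position_mm": [f.position_mm for f in feats],
            "mean_contact_pressure_mmHg": [f.mean_contact_pressure_mmHg for f in feats],
            "adcw_amplitude": [f.adcw_amplitude for f in feats],
            "pressure_amplitude_mmHg": [f.pressure_amplitude_mmHg for f in feats],
            "n_beats": [f.n_beats for f in feats],
            "valid": [f.valid for f in feats],
        }
    )


@dataclass
class ExcessPressureTable:
    """Template correlation at fixed excess-contact-pressure levels.

    Per level Delta, the segment whose mean contact pressure is closest
    to (reference contact pressure + Delta) is selected; levels beyond
    the scanned pressure range are flagged unavailable.
    """

    delta_mmHg: np.ndarray
    r: np.ndarray
    selected_position_mm: np.ndarray
    selected_contact_pressure_mmHg: np.ndarray
    available: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_mmHg": self.delta_mmHg,
                "r": self.r,
                "selected_position_mm": self.selected_position_mm,
                "selected_contact_pressure_mmHg": self.selected_contact_pressure_mmHg,
                "available": self.available,
            }
        )


@dataclass
class XScanResults:
    """Fitted results of one X-axis scan analysis."""

    features: pd.DataFrame
    envelope: GaussianEnvelopeFit | None
    reference: ReferencePattern | None
    profile: CorrelationProfile | None
    width_index: float
    width_mm: float | None = None
    left_boundary_mm: float | None = None
    right_boundary_mm: float | None = None
    boundary_clamped: bool = False
    boundary_r: tuple[float, float] | None = None
    error: str | None = None
    subject_id: str = "anonymous"
    metadata: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def summary(self) -> str:
        lines = [
            f"X-axis scan analysis  (subject {self.subject_id})",
            "=" * 48,
            f"{'steps (valid/total)':<28}"
            f"{int(self.features['valid'].sum()):d}/{len(self.features):d}",
        ]
        if self.envelope is not None:
            e = self.envelope
            lines += [
                f"{'X0, arterial middle (mm)':<28}{e.X0_mm:>12.3f}",
                f"{'sigma (mm)':<28}{e.sigma_mm:>12.3f}",
                f"{'R, envelope fit':<28}{e.R:>12.3f}",
                f"{'Width_Index':<28}{self.width_index:>12.3f}",
                f"{'estimated width (mm)':<28}{self.width_mm:>12.3f}",
                f"{'left boundary segment (mm)':<28}{self.left_boundary_mm:>12.2f}",
                f"{'right boundary segment (mm)':<28}{self.right_boundary_mm:>12.2f}",
            ]
        if self.boundary_r is not None:
            lines += [
                f"{'r at left boundary':<28}{self.boundary_r[0]:>12.3f}",
                f"{'r at right boundary':<28}{self.boundary_r[1]:>12.3f}",
            ]
        if self.error:
            lines.append(f"ERROR: {self.error}")
        return "\n".join(lines)


@dataclass
class ZScanResults:
    """Fitted results of one Z-axis (hold-down pressure) scan analysis."""

    features: pd.DataFrame
    reference: ReferencePattern | None
    profile: CorrelationProfile | None
    reference_contact_pressure_mmHg: float | None
    excess_table: ExcessPressureTable | None
    error: str | None = None
    subject_id: str = "anonymous"
    metadata: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None

    def split_before_after(self) -> tuple[np.ndarray, np.ndarray]:
        """Template correlations strictly before vs strictly after the base.

        "Before" means segments scanned at lower contact pressure than
        the maximum-amplitude (base) segment; "after" means higher.
        Invalid steps are excluded.
        """
        if self.profile is None or self.reference is None:
            raise ValueError("analysis failed; no profile to split")
        base = self.reference.source_position_mm
        pos, r, ok = self.profile.positions_mm, self.profile.r, self.profile.valid
        return r[(pos < base) & ok], r[(pos > base) & ok]

    def summary(self) -> str:
        lines = [
            f"Z-axis scan analysis  (subject {self.subject_id})",
            "=" * 48,
            f"{'steps (valid/total)':<28}"
            f"{int(self.features['valid'].sum()):d}/{len(self.features):d}",
        ]
        if self.reference is not None:
            lines += [
                f"{'base segment (mm)':<28}{self.reference.source_position_mm:>12.3f}",
                f"{'criterion pressure (mmHg)':<28}"
                f"{self.reference_contact_pressure_mmHg:>12.1f}",
            ]
        if self.excess_table is not None:
            lines.append("excess pressure -> r:")
            for d, r, avail in zip(
                self.excess_table.delta_mmHg,
                self.excess_table.r,
                self.excess_table.available,
            ):
                val = f"{r:.3f}" if avail else "unavailable"
                lines.append(f"  +{d:>5.0f} mmHg{val:>16}")
        if self.error:
            lines.append(f"ERROR: {self.error}")
        return "\n".join(lines)


class XScanModel:
    """X-axis placement analysis of one scan.

    Parameters
    ----------
    scan : ScanRecording
        An X-axis scan.
    width_index : float
        Dimensionless factor relating the envelope SD to the arterial
        width (default 0.355).
    """

    def __init__(self, scan: ScanRecording, width_index: float = DEFAULT_WIDTH_INDEX):
        if scan.axis != "X":
            raise ValueError("XScanModel requires an X-axis scan")
        self.scan = scan
        self.width_index = width_index

    def fit(self) -> XScanResults:
        feats = [step_features(s) for s in self.scan.steps]
        fdf = _features_frame(feats)
        try:
            env = GaussianEnvelope(
                fdf["position_mm"], fdf["adcw_amplitude"].where(fdf["valid"])
            ).fit()
        except (EnvelopeDataError, EnvelopeFitError) as e:
            logger.warning("subject %s: envelope fit failed: %s",
                           self.scan.subject_id, e)
            return XScanResults(
                features=fdf, envelope=None, reference=None, profile=None,
                width_index=self.width_index, error=str(e),
                subject_id=self.scan.subject_id, metadata=dict(self.scan.metadata),
            )
        width = estimate_width(env.sigma_mm, self.width_index)
        reference = select_reference_x(self.scan, env.X0_mm)
        profile = correlation_profile(self.scan, reference)
        left, right, clamped = snap_boundaries(
            env.X0_mm, width, self.scan.positions_mm
        )
        boundary_r = (profile.r_at(left), profile.r_at(right))
        return XScanResults(
            features=fdf,
            envelope=env,
            reference=reference,
            profile=profile,
            width_index=self.width_index,
            width_mm=width,
            left_boundary_mm=left,
            right_boundary_mm=right,
            boundary_clamped=clamped,
            boundary_r=boundary_r,
            subject_id=self.scan.subject_id,
            metadata=dict(self.scan.metadata),
        )


class ZScanModel:
    """Z-axis hold-down-pressure analysis of one scan.

    Parameters
    ----------
    scan : ScanRecording
        A Z-axis scan.
    deltas : sequence of float
        Excess-contact-pressure levels (mmHg above the criterion level)
        at which to report the template correlation.
    """

    def __init__(self, scan: ScanRecording, deltas=DEFAULT_DELTAS_MMHG):
        if scan.axis != "Z":
            raise ValueError("ZScanModel requires a Z-axis scan")
        self.scan = scan
        self.deltas = np.asarray(deltas, dtype=float)

    def fit(self) -> ZScanResults:
        feats = [step_features(s) for s in self.scan.steps]
        fdf = _features_frame(feats)
        try:
            reference = select_reference_z(self.scan)
        except Exception as e:
            logger.warning("subject %s: Z reference selection failed: %s",
                           self.scan.subject_id, e)
            return ZScanResults(
                features=fdf, reference=None, profile=None,
                reference_contact_pressure_mmHg=None, excess_table=None,
                error=str(e), subject_id=self.scan.subject_id,
                metadata=dict(self.scan.metadata),
            )
        profile = correlation_profile(self.scan, reference)
        ref_row = fdf.loc[
            np.isclose(fdf["position_mm"], reference.source_position_mm)
        ].iloc[0]
        p_ref = float(ref_row["mean_contact_pressure_mmHg"])
        excess = self._excess_table(fdf, profile, p_ref)
        return ZScanResults(
            features=fdf,
            reference=reference,
            profile=profile,
            reference_contact_pressure_mmHg=p_ref,
            excess_table=excess,
            subject_id=self.scan.subject_id,
            metadata=dict(self.scan.metadata),
        )

    def _excess_table(
        self, fdf: pd.DataFrame, profile: CorrelationProfile, p_ref: float
    ) -> ExcessPressureTable:
        valid = fdf[fdf["valid"]].reset_index(drop=True)
        cps = valid["mean_contact_pressure_mmHg"].to_numpy()
        increments = np.diff(np.sort(cps))
        slack = np.median(increments) / 2.0 if len(increments) else 0.0
        rs, pos_sel, cp_sel, avail = [], [], [], []
        for d in self.deltas:
            target = p_ref + d
            if target > cps.max() + slack or target < cps.min() - slack:
                rs.append(np.nan)
                pos_sel.append(np.nan)
                cp_sel.append(np.nan)
                avail.append(False)
                continue
            dist = np.abs(cps - target)
            # nearest segment; ties resolve to the lower-pressure one
            best = np.flatnonzero(np.isclose(dist, dist.min()))
            i = int(best[np.argmin(cps[best])])
            pos = float(valid["position_mm"].iloc[i])
            rs.append(profile.r_at(pos))
            pos_sel.append(pos)
            cp_sel.append(float(cps[i]))
            avail.append(True)
        return ExcessPressureTable(
            delta_mmHg=self.deltas.copy(),
            r=np.array(rs),
            selected_position_mm=np.array(pos_sel),
            selected_contact_pressure_mmHg=np.array(cp_sel),
            available=np.array(avail),
        )


def analyze_x_scan(
    scan: ScanRecording, width_index: float = DEFAULT_WIDTH_INDEX
) -> XScanResults:
    """Run the full X-axis placement analysis on one scan."""
    return XScanModel(scan, width_index).fit()


def analyze_z_scan(scan: ScanRecording, deltas=DEFAULT_DELTAS_MMHG) -> ZScanResults:
    """Run the full Z-axis hold-down-pressure analysis on one scan."""
    return ZScanModel(scan, deltas).fit()


# ---------------------------------------------------------------------------
# cohort aggregation

def _anchor_position(result, alignment: str) -> float | None:
    if alignment == "reference":
        return None if result.reference is None else result.reference.source_position_mm
    if alignment in ("left_boundary", "right_boundary"):
        if not isinstance(result, XScanResults):
            raise ValueError("boundary alignment applies to X-axis results only")
        return (
            result.left_boundary_mm
            if alignment == "left_boundary"
            else result.right_boundary_mm
        )
    raise ValueError(f"unknown alignment {alignment!r}")


def cohort_aggregate(results, alignment: str = "reference") -> CohortTable:
    """Aggregate per-subject correlation profiles on a relative-position grid.

    Each profile is re-indexed so the alignment anchor (the subject's
    reference segment, or a boundary segment) sits at 0 mm; positions
    scanned before the anchor are negative.  Relative positions are
    exact multiples of the axis step size — no interpolation.  Per
    position the table reports n, mean and sample SD over the subjects
    whose scans cover that position; subjects whose analysis failed (or
    whose anchor is missing) are excluded with a log entry.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("cohort aggregation needs at least 2 results")
    axes = {"X" if isinstance(r, XScanResults) else "Z" for r in results}
    if len(axes) > 1:
        raise ValueError("cannot aggregate X and Z results together")
    axis = axes.pop()
    step = 0.25 if axis == "X" else 0.125
    buckets: dict[int, list[float]] = {}
    for res in results:
        if not res.ok or res.profile is None:
            logger.info("cohort: excluding subject %s (%s)", res.subject_id, res.error)
            continue
        anchor = _anchor_position(res, alignment)
        if anchor is None or not np.isfinite(anchor):
            logger.info("cohort: subject %s has no %s anchor", res.subject_id, alignment)
            continue
        pos, r, ok = res.profile.positions_mm, res.profile.r, res.profile.valid
        k = np.rint((pos - anchor) / step).astype(int)
        for ki, ri, oki in zip(k, r, ok):
            if oki:
                buckets.setdefault(int(ki), []).append(float(ri))
    if not buckets:
        raise ValueError("no subject contributed a usable profile")
    keys = sorted(buckets)
    rel = np.array([k * step for k in keys])
    n = np.array([len(buckets[k]) for k in keys])
    mean = np.array([np.mean(buckets[k]) for k in keys])
    sd = np.array(
        [np.std(buckets[k], ddof=1) if len(buckets[k]) > 1 else 0.0 for k in keys]
    )
    return CohortTable(
        relative_position_mm=rel, n=n, mean_r=mean, sd_r=sd,
        alignment=alignment, axis=axis,
    )


def cohort_excess_pressure(results) -> pd.DataFrame:
    """Cohort mean +/- SD of r per excess-contact-pressure level.

    Levels unavailable for a subject (pressure range not scanned) do
    not count toward that level's n; a level available in no subject is
    omitted with a warning.
    """
    results = [r for r in results if isinstance(r, ZScanResults)]
    if len(results) < 2:
        raise ValueError("cohort excess-pressure analysis needs at least 2 Z results")
    buckets: dict[float, list[float]] = {}
    for res in results:
        if not res.ok or res.excess_table is None:
            logger.info("cohort: excluding subject %s (%s)", res.subject_id, res.error)
            continue
        t = res.excess_table
        for d, r, avail in zip(t.delta_mmHg, t.r, t.available):
            if avail and np.isfinite(r):
                buckets.setdefault(float(d), []).append(float(r))
    requested = {float(d) for res in results if res.excess_table is not None
                 for d in res.excess_table.delta_mmHg}
    for d in sorted(requested - set(buckets)):
        logger.warning("excess level +%g mmHg available in no subject; omitted", d)
    deltas = sorted(buckets)
    return pd.DataFrame(
        {
            "delta_mmHg": deltas,
            "n": [len(buckets[d]) for d in deltas],
            "mean_r": [np.mean(buckets[d]) for d in deltas],
            "sd_r": [
                np.std(buckets[d], ddof=1) if len(buckets[d]) > 1 else 0.0
                for d in deltas
            ],
        }
    )


def filter_results(results, **metadata):
    """Subjects whose scan metadata matches all given key=value pairs.

    Supports sub-cohort views (e.g. ``hypertensive=True``) without any
    group-difference statistics.
    """
    return [
        r for r in results
        if all(r.metadata.get(k) == v for k, v in metadata.items())
    ]
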