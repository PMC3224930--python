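"""Data model and serialization for two-axis tonometric scan recordings.

A scan is an ordered sequence of step segments along one motor axis (X:
lateral, across the radial artery; Z: vertical, into the tissue).  Each
step holds a 4-second, 500 Hz capture of three synchronous channels:
the arterial pressure waveform (mmHg), the arterial-diameter-change
waveform (ADCW, arbitrary strain-gauge units) and the contact pressure
(mmHg).  Two on-disk dialects are supported: a self-describing HDF5
container and a plain-text CSV export (one row per sample).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "StepSegment",
    "ScanRecording",
    "CohortTable",
    "read_scan",
    "write_scan",
    "write_manifest",
    "ScanFormatError",
    "ScanValidationError",
]

#: motor step size per axis, mm
AXIS_STEP_MM = {"X": 0.25, "Z": 0.125}

DEFAULT_SAMPLING_RATE_HZ = 500.0
DEFAULT_DURATION_S = 4.0


class ScanFormatError(ValueError):
    """A scan file does not conform to the container layout."""


class ScanValidationError(ValueError):
    """A recording violates a structural invariant."""


@dataclass
class StepSegment:
    """One motor step: a fixed-duration capture of the three channels.

    ``position_mm`` labels the START of the segment along the scan axis
    (the 3.50-3.75 mm segment is stored as 3.50).
    """

    position_mm: float
    pressure: np.ndarray
    adcw: np.ndarray
    contact_pressure: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.adcw = np.asarray(self.adcw, dtype=float)
        self.contact_pressure = np.asarray(self.contact_pressure, dtype=float)
        n = len(self.pressure)
        if len(self.adcw) != n or len(self.contact_pressure) != n:
            raise ScanValidationError(
                "pressure, adcw and contact_pressure must have identical length"
            )
        if not (np.all(np.isfinite(self.pressure))
                and np.all(np.isfinite(self.contact_pressure))):
            raise ScanValidationError("pressure channels must be finite")
        if np.any(self.contact_pressure < 0):
            raise ScanValidationError("contact_pressure must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.pressure)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def __eq__(self, other) -> bool:
        if not isinstance(other, StepSegment):
            return NotImplemented
        return (
            self.position_mm == other.position_mm
            and self.sampling_rate_hz == other.sampling_rate_hz
            and np.array_equal(self.pressure, other.pressure)
            and np.array_equal(self.adcw, other.adcw)
            and np.array_equal(self.contact_pressure, other.contact_pressure)
        )


@dataclass
class ScanRecording:
    """Ordered per-step captures along one axis for one subject.

    Invariants (checked on construction): the axis determines the step
    size (X: 0.25 mm, Z: 0.125 mm), consecutive positions differ by
    exactly that step size, and there are at least 3 steps.
    """

    axis: str
    steps: list[StepSegment]
    step_size_mm: float | None = None
    subject_id: str = "anonymous"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in AXIS_STEP_MM:
            raise ScanValidationError(f"axis must be 'X' or 'Z', got {self.axis!r}")
        expected = AXIS_STEP_MM[self.axis]
        if self.step_size_mm is None:
            self.step_size_mm = expected
        if not np.isclose(self.step_size_mm, expected):
            raise ScanValidationError(
                f"axis {self.axis} requires step_size_mm={expected}, "
                f"got {self.step_size_mm}"
            )
        if len(self.steps) < 3:
            raise ScanValidationError("a scan needs at least 3 steps")
        pos = self.positions_mm
        gaps = np.diff(pos)
        if not np.allclose(gaps, self.step_size_mm, atol=1e-9):
            bad = int(np.argmax(~np.isclose(gaps, self.step_size_mm, atol=1e-9)))
            raise ScanValidationError(
                f"steps {bad} and {bad + 1} are {gaps[bad]:.6g} mm apart, "
                f"expected {self.step_size_mm} mm"
            )

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([s.position_mm for s in self.steps])

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def sampling_rate_hz(self) -> float:
        return self.steps[0].sampling_rate_hz

    def step_at(self, position_mm: float) -> StepSegment:
        """Return the step whose segment interval contains ``position_mm``.

        Falls back to the nearest segment start when the position lies
        on no interval (e.g. just past the last segment's start).
        """
        pos = self.positions_mm
        lo, hi = pos[0], pos[-1] + self.step_size_mm
        if not (lo - self.step_size_mm / 2 <= position_mm <= hi):
            raise ScanValidationError(
                f"position {position_mm} mm outside scanned range [{lo}, {hi}) mm"
            )
        idx = int(np.floor((position_mm - pos[0]) / self.step_size_mm))
        idx = min(max(idx, 0), self.n_steps - 1)
        return self.steps[idx]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScanRecording):
            return NotImplemented
        return (
            self.axis == other.axis
            and self.step_size_mm == other.step_size_mm
            and self.subject_id == other.subject_id
            and self.metadata == other.metadata
            and len(self.steps) == len(other.steps)
            and all(a == b for a, b in zip(self.steps, other.steps))
        )


@dataclass
class CohortTable:
    """Per-relative-position cohort statistics of template correlations.

    ``relative_position_mm`` is 0 at the alignment anchor (each subject's
    reference segment or a boundary segment); positions scanned before
    the anchor are negative.
    """

    relative_position_mm: np.ndarray
    n: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    alignment: str = "reference"
    axis: str = "X"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_position_mm": self.relative_position_mm,
                "n": self.n,
                "mean_r": self.mean_r,
                "sd_r": self.sd_r,
            }
        )

    def at(self, relative_position_mm: float) -> dict:
        """Row (n, mean_r, sd_r) at one relative position."""
        i = np.flatnonzero(
            np.isclose(self.relative_position_mm, relative_position_mm)
        )
        if len(i) == 0:
            raise KeyError(f"no row at relative position {relative_position_mm}")
        i = int(i[0])
        return {
            "n": int(self.n[i]),
            "mean_r": float(self.mean_r[i]),
            "sd_r": float(self.sd_r[i]),
        }


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = [
    "step_index",
    "position_mm",
    "sample_index",
    "pressure",
    "adcw",
    "contact_pressure",
]


def write_scan(recording: ScanRecording, path) -> Path:
    """Write a scan to ``path``; dialect chosen by extension.

    ``.h5``/``.hdf5`` writes the hierarchical container; ``.csv`` writes
    the one-row-per-sample tabular export with metadata in ``#`` header
    lines.  Writes are deterministic: two writes of the same recording
    are byte-identical.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(recording, path)
    elif path.suffix == ".csv":
        _write_csv(recording, path)
    else:
        raise ScanFormatError(f"unsupported scan container extension {path.suffix!r}")
    return path


def read_scan(path) -> ScanRecording:
    """Read a scan written by :func:`write_scan`; validates all invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if path.suffix == ".csv":
        return _read_csv(path)
    raise ScanFormatError(f"unsupported scan container extension {path.suffix!r}")


def _write_hdf5(rec: ScanRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["axis"] = rec.axis
        f.attrs["step_size_mm"] = rec.step_size_mm
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["metadata_json"] = json.dumps(rec.metadata, sort_keys=True)
        f.attrs["pressure_units"] = "mmHg"
        f.attrs["adcw_units"] = "arbitrary"
        steps = f.create_group("steps")
        for i, s in enumerate(rec.steps):
            g = steps.create_group(f"{i:04d}")
            g.attrs["position_mm"] = s.position_mm
            g.attrs["sampling_rate_hz"] = s.sampling_rate_hz
            for name in ("pressure", "adcw", "contact_pressure"):
                g.create_dataset(name, data=getattr(s, name), track_times=False)


def _require_attr(obj, name: str, path: Path):
    if name not in obj.attrs:
        raise ScanFormatError(f"{path}: missing required field {name!r}")
    return obj.attrs[name]


def _read_hdf5(path: Path) -> ScanRecording:
    with h5py.File(path, "r") as f:
        axis = str(_require_attr(f, "axis", path))
        step_size = float(_require_attr(f, "step_size_mm", path))
        subject = str(_require_attr(f, "subject_id", path))
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
        if "steps" not in f:
            raise ScanFormatError(f"{path}: missing required field 'steps'")
        steps = []
        for key in sorted(f["steps"]):
            g = f["steps"][key]
            for name in ("pressure", "adcw", "contact_pressure"):
                if name not in g:
                    raise ScanFormatError(
                        f"{path}: step {key} missing required field {name!r}"
                    )
            steps.append(
                StepSegment(
                    position_mm=float(_require_attr(g, "position_mm", path)),
                    pressure=g["pressure"][:],
                    adcw=g["adcw"][:],
                    contact_pressure=g["contact_pressure"][:],
                    sampling_rate_hz=float(_require_attr(g, "sampling_rate_hz", path)),
                )
            )
    return ScanRecording(
        axis=axis,
        steps=steps,
        step_size_mm=step_size,
        subject_id=subject,
        metadata=metadata,
    )


def _write_csv(rec: ScanRecording, path: Path) -> None:
    header = {
        "axis": rec.axis,
        "step_size_mm": rec.step_size_mm,
        "subject_id": rec.subject_id,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "metadata": rec.metadata,
    }
    with open(path, "w", newline="") as fh:
        fh.write("# tonoscan scan export\n")
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        for i, s in enumerate(rec.steps):
            pos = repr(float(s.position_mm))
            for j in range(s.n_samples):
                fh.write(
                    f"{i},{pos},{j},{float(s.pressure[j])!r},"
                    f"{float(s.adcw[j])!r},{float(s.contact_pressure[j])!r}\n"
                )


def _read_csv(path: Path) -> ScanRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ScanFormatError(f"{path}: missing '#' header line")
        header_line = fh.readline()
    try:
        header = json.loads(header_line.lstrip("# ").strip())
    except json.JSONDecodeError as e:
        raise ScanFormatError(f"{path}: malformed metadata header: {e}") from e
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ScanFormatError(f"{path}: missing required field {missing[0]!r}")
    rate = float(header["sampling_rate_hz"])
    steps = []
    for _, grp in df.groupby("step_index", sort=True):
        grp = grp.sort_values("sample_index")
        steps.append(
            StepSegment(
                position_mm=float(grp["position_mm"].iloc[0]),
                pressure=grp["pressure"].to_numpy(),
                adcw=grp["adcw"].to_numpy(),
                contact_pressure=grp["contact_pressure"].to_numpy(),
                sampling_rate_hz=rate,
            )
        )
    return ScanRecording(
        axis=str(header["axis"]),
        steps=steps,
        step_size_mm=float(header["step_size_mm"]),
        subject_id=str(header["subject_id"]),
        metadata=dict(header.get("metadata", {})),
    )


def write_manifest(path, *, seed: int | None, config: dict, extra: dict | None = None) -> Path:
    """Write a JSON run manifest (seed, config, software version)."""
    from tonoscan import __version__

    manifest = {"seed": seed, "config": config, "software_version": __version__}
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1, default=float))
    return path
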