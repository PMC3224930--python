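"""Seeded generator of two-axis tonometric scan recordings.

Emulates the structure the analysis relies on:

* a radial-pulse-like pressure cycle (fast systolic upstroke, reflected
  wave, dicrotic notch) whose shape degrades continuously under a
  distortion operator (notch suppression + peak broadening);
* an X-axis scan in which the ADCW amplitude follows a Gaussian spatial
  envelope centred on the artery (equivalently the D_ver = D_act cos(theta)
  geometry) and waveform distortion grows with lateral offset;
* a Z-axis scan in which contact pressure rises monotonically with
  depth, pulse amplitude follows an inverted-U ("bell") curve of contact
  pressure peaking at P_opt, and distortion grows with excess pressure
  above P_opt (and, mildly, at very low contact pressure);
* a cohort generator drawing subject parameters from configured
  distributions whose defaults match the study population: estimated
  arterial width 3.64 +/- 0.83 mm, optimal contact pressure
  161 +/- 69 mmHg, MAP 103 +/- 16 mmHg, age 51 +/- 11 years.

Everything is fully determined by the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from tonoscan.envelope import DEFAULT_WIDTH_INDEX
from tonoscan.io import ScanRecording, StepSegment

__all__ = [
    "SubjectModel",
    "SyntheticConfig",
    "generate_pulse_cycle",
    "vertical_displacement",
    "simulate_x_scan",
    "simulate_z_scan",
    "generate_cohort",
    "cohort_manifest",
]


@dataclass
class SubjectModel:
    """Ground-truth physiological parameters of one synthetic subject."""

    heart_rate_bpm: float = 72.0
    map_mmHg: float = 103.0
    pulse_pressure_mmHg: float = 56.0
    X0_true_mm: float = 4.0
    sigma_true_mm: float = 3.64 / (2.0 + DEFAULT_WIDTH_INDEX)
    D_act: float = 8.0           # peak ADCW amplitude, sensor units
    P_opt_mmHg: float = 161.0    # contact pressure of maximum pulse amplitude
    amp_width_mmHg: float = 60.0  # SD of the amplitude-vs-pressure bell
    distortion_rate: float = 0.002   # distortion per mmHg of excess pressure
    noise_sd: float = 0.01       # additive waveform noise, fraction of amplitude
    age_years: float = 51.0
    sbp_mmHg: float = 140.0
    dbp_mmHg: float = 84.0

    def __post_init__(self) -> None:
        for name in ("heart_rate_bpm", "map_mmHg", "pulse_pressure_mmHg",
                     "sigma_true_mm", "D_act", "P_opt_mmHg", "amp_width_mmHg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 30 <= self.heart_rate_bpm <= 180:
            raise ValueError("heart_rate_bpm outside the supported 30-180 range")

    @property
    def width_true_mm(self) -> float:
        return (2.0 + DEFAULT_WIDTH_INDEX) * self.sigma_true_mm


@dataclass
class SyntheticConfig:
    """Cohort-level generator configuration.

    Distribution means/SDs default to the study population; scan
    geometry defaults to the acquisition protocol (4 s captures at
    500 Hz; 0.25 mm X steps, 0.125 mm Z steps).
    """

    n_subjects: int = 42
    seed: int = 0
    duration_s: float = 4.0
    sampling_rate_hz: float = 500.0
    # X-axis geometry: 33 steps of 0.25 mm span 0-8 mm
    n_steps_x: int = 33
    # Z-axis geometry
    n_steps_z: int = 24
    cp_step_mmHg: float = 15.0       # mean contact-pressure rise per Z step
    z_reference_step: int = 8        # Z step index aimed at P_opt
    x_contact_pressure_mmHg: float = 80.0
    x_distortion_per_mm: float = 0.08
    low_pressure_distortion_ratio: float = 0.2
    amplitude_noise_sd: float = 0.02  # per-step multiplicative envelope noise
    # cohort distributions: (mean, sd, low clip, high clip)
    heart_rate: tuple = (72.0, 10.0, 45.0, 110.0)
    width_mm: tuple = (3.64, 0.830, 2.0, 6.0)
    sbp: tuple = (140.0, 21.0, 90.0, 200.0)
    dbp: tuple = (84.0, 16.0, 45.0, 120.0)
    d_act: tuple = (8.0, 2.0, 3.0, 15.0)
    p_opt: tuple = (161.0, 69.0, 70.0, 280.0)
    amp_width: tuple = (60.0, 15.0, 35.0, 110.0)
    age: tuple = (51.0, 11.0, 25.0, 85.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.n_steps_x < 3 or self.n_steps_z < 3:
            raise ValueError("scans need at least 3 steps")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# waveform morphology

# lobe centres/widths/gains on the unit cycle phase: systolic peak,
# reflected wave, dicrotic component
_SHARP_LOBES = ((0.15, 0.05, 1.00), (0.42, 0.09, 0.42), (0.62, 0.045, 0.18))
# fully distorted limit: a single broad hump, notch gone, peak smeared
_BROAD_LOBES = ((0.32, 0.20, 1.00),)


def _lobe_sum(phase: np.ndarray, lobes) -> np.ndarray:
    out = np.zeros_like(phase)
    for c, w, g in lobes:
        out += g * np.exp(-((phase - c) ** 2) / (2.0 * w**2))
    return out


def generate_pulse_cycle(
    heart_rate_bpm: float,
    amplitude: float,
    distortion: float = 0.0,
    sampling_rate_hz: float = 500.0,
) -> np.ndarray:
    """One pulse cycle with the requested peak-to-peak amplitude.

    ``distortion`` in [0, 1] morphs the shape linearly from the
    undistorted radial pulse (distortion 0) towards a featureless broad
    hump (distortion 1); the Pearson correlation with the undistorted
    cycle is strictly decreasing in ``distortion``.  Peak-to-peak
    amplitude is renormalised after morphing, so the returned cycle's
    p2p equals ``amplitude`` exactly.
    """
    if not 0.0 <= distortion <= 1.0:
        raise ValueError("distortion must lie in [0, 1]")
    if not 30 <= heart_rate_bpm <= 180:
        raise ValueError("heart_rate_bpm outside the supported 30-180 range")
    n = int(round(60.0 / heart_rate_bpm * sampling_rate_hz))
    phase = np.arange(n) / n
    sharp = _lobe_sum(phase, _SHARP_LOBES)
    broad = _lobe_sum(phase, _BROAD_LOBES)
    shape = (1.0 - distortion) * sharp + distortion * broad
    shape = shape - shape.min()
    return shape * (amplitude / np.ptp(shape))


def vertical_displacement(D_act: float, theta_deg: float) -> float:
    """Vertically sensed component of the arterial wall displacement.

    D_ver = D_act * cos(theta), where theta is the angle between the
    arterial mid-position and the sensor's offset position.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta_deg must lie in [0, 90]")
    return D_act * np.cos(np.deg2rad(theta_deg))


# ---------------------------------------------------------------------------
# scan synthesis

def _render_step(
    rng: np.random.Generator,
    subject: SubjectModel,
    config: SyntheticConfig,
    *,
    position_mm: float,
    pressure_amp: float,
    adcw_amp: float,
    distortion: float,
    contact_pressure: float,
) -> StepSegment:
    """Tile a (possibly distorted) cycle into one capture on all channels."""
    fs = config.sampling_rate_hz
    n_total = int(round(config.duration_s * fs))
    cycle = generate_pulse_cycle(
        subject.heart_rate_bpm, 1.0, min(distortion, 1.0), fs
    )
    n_cyc = len(cycle)
    # random phase so template lags differ across steps
    phase0 = rng.integers(0, n_cyc)
    idx = (np.arange(n_total) + phase0) % n_cyc
    unit = cycle[idx]
    baseline = subject.map_mmHg - pressure_amp / 3.0
    noise_p = subject.noise_sd * max(pressure_amp, 1.0)
    noise_a = subject.noise_sd * max(adcw_amp, 0.1 * subject.D_act)
    pressure = baseline + pressure_amp * unit + rng.normal(0, noise_p, n_total)
    adcw = adcw_amp * unit + rng.normal(0, noise_a, n_total)
    cp = np.clip(
        contact_pressure + rng.normal(0, 1.0, n_total), 0.0, None
    )
    return StepSegment(
        position_mm=position_mm,
        pressure=pressure,
        adcw=adcw,
        contact_pressure=cp,
        sampling_rate_hz=fs,
    )


def simulate_x_scan(
    subject: SubjectModel, config: SyntheticConfig, seed: int
) -> ScanRecording:
    """X-axis scan across the artery.

    Per step at position X: ADCW amplitude follows the Gaussian envelope
    exp(-(X - X0)^2 / (2 sigma^2)); the pressure amplitude follows a
    scaled copy of the same envelope over a nonzero floor (the pulse
    stays detectable off-artery); distortion grows linearly with
    |X - X0|; contact pressure is held roughly constant.
    """
    rng = np.random.default_rng(seed)
    steps = []
    for i in range(config.n_steps_x):
        x = i * 0.25
        env = np.exp(
            -((x - subject.X0_true_mm) ** 2) / (2.0 * subject.sigma_true_mm**2)
        )
        gain = rng.normal(1.0, config.amplitude_noise_sd)
        adcw_amp = max(subject.D_act * env * gain, 0.0)
        p_amp = subject.pulse_pressure_mmHg * (0.3 + 0.7 * env) * max(gain, 0.1)
        dist = min(1.0, config.x_distortion_per_mm * abs(x - subject.X0_true_mm))
        steps.append(
            _render_step(
                rng,
                subject,
                config,
                position_mm=x,
                pressure_amp=p_amp,
                adcw_amp=adcw_amp,
                distortion=dist,
                contact_pressure=config.x_contact_pressure_mmHg,
            )
        )
    return ScanRecording(axis="X", steps=steps)


def simulate_z_scan(
    subject: SubjectModel, config: SyntheticConfig, seed: int
) -> ScanRecording:
    """Z-axis scan: hold-down pressure sweep at the arterial middle.

    Mean contact pressure rises monotonically step by step; pulse
    amplitude is a bell-shaped function of contact pressure peaking at
    the subject's P_opt; distortion grows with excess pressure above
    P_opt at ``distortion_rate`` per mmHg, and more mildly (scaled by
    ``low_pressure_distortion_ratio``) below it.
    """
    rng = np.random.default_rng(seed)
    cp_start = max(15.0, subject.P_opt_mmHg - config.z_reference_step * config.cp_step_mmHg)
    steps = []
    for i in range(config.n_steps_z):
        z = i * 0.125
        cp = cp_start + i * config.cp_step_mmHg + rng.normal(0, 2.0)
        env = np.exp(
            -((cp - subject.P_opt_mmHg) ** 2) / (2.0 * subject.amp_width_mmHg**2)
        )
        gain = rng.normal(1.0, config.amplitude_noise_sd)
        # near-occlusion and barely-touching contact both almost erase the
        # pulse, so the bell rides on a low floor
        p_amp = subject.pulse_pressure_mmHg * (0.08 + 0.92 * env) * max(gain, 0.1)
        adcw_amp = max(subject.D_act * env * gain, 0.0)
        excess = max(0.0, cp - subject.P_opt_mmHg)
        deficit = max(0.0, subject.P_opt_mmHg - cp)
        dist = subject.distortion_rate * (
            excess + config.low_pressure_distortion_ratio * deficit
        )
        steps.append(
            _render_step(
                rng,
                subject,
                config,
                position_mm=z,
                pressure_amp=p_amp,
                adcw_amp=adcw_amp,
                distortion=min(1.0, dist),
                contact_pressure=max(cp, 0.0),
            )
        )
    return ScanRecording(axis="Z", steps=steps)


# ---------------------------------------------------------------------------
# cohort

def _draw(rng: np.random.Generator, spec: tuple) -> float:
    mean, sd, lo, hi = spec
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def draw_subject(rng: np.random.Generator, config: SyntheticConfig) -> SubjectModel:
    """One subject from the configured cohort distributions."""
    sbp = _draw(rng, config.sbp)
    dbp = min(_draw(rng, config.dbp), sbp - 20.0)
    width = _draw(rng, config.width_mm)
    x_centre = (config.n_steps_x - 1) * 0.25 / 2.0
    return SubjectModel(
        heart_rate_bpm=_draw(rng, config.heart_rate),
        map_mmHg=dbp + (sbp - dbp) / 3.0,
        pulse_pressure_mmHg=sbp - dbp,
        X0_true_mm=x_centre + rng.uniform(-0.5, 0.5),
        sigma_true_mm=width / (2.0 + DEFAULT_WIDTH_INDEX),
        D_act=_draw(rng, config.d_act),
        P_opt_mmHg=_draw(rng, config.p_opt),
        amp_width_mmHg=_draw(rng, config.amp_width),
        age_years=_draw(rng, config.age),
        sbp_mmHg=sbp,
        dbp_mmHg=dbp,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> list[tuple[SubjectModel, ScanRecording, ScanRecording]]:
    """Independent seeded subjects, each with an X and a Z scan.

    Subject parameters, and per-scan noise streams, derive from
    ``config.seed`` through a spawned seed sequence, so the same config
    always reproduces the same cohort.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    cohort = []
    for i, child in enumerate(children):
        param_rng = np.random.default_rng(child)
        subject = draw_subject(param_rng, config)
        sx, sz = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        x_scan = simulate_x_scan(subject, config, sx)
        z_scan = simulate_z_scan(subject, config, sz)
        sid = f"S{i:03d}"
        for scan in (x_scan, z_scan):
            scan.subject_id = sid
            scan.metadata = {
                "age": subject.age_years,
                "SBP": subject.sbp_mmHg,
                "DBP": subject.dbp_mmHg,
                "MAP": subject.map_mmHg,
                "heart_rate": subject.heart_rate_bpm,
                "hypertensive": bool(
                    subject.sbp_mmHg > 140.0 or subject.dbp_mmHg > 90.0
                ),
            }
        cohort.append((subject, x_scan, z_scan))
    return cohort


def cohort_manifest(config: SyntheticConfig, cohort) -> dict:
    """True-parameter manifest of a generated cohort, with a stable digest."""
    subjects = [
        {"subject_id": x.subject_id, **asdict(subj)} for subj, x, _ in cohort
    ]
    body = {"config": config.to_dict(), "subjects": subjects}
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=float).encode()
    ).hexdigest()
    return {**body, "digest": digest}
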