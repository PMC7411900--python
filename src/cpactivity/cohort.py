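"""Synthetic cohort and raw tri-axial accelerometer signal generation.

Emulates a structured laboratory protocol (five 6-minute activity trials) and a
simulated free-living sequence for children with cerebral palsy at GMFCS levels
I-III, wearing a 30 Hz tri-axial accelerometer on the wrist, hip, and ankle.

The signal model is deliberately simple: a gravity baseline (Y-axis vertical
when upright), plus a class-specific movement process --

* SED : band-limited residual movement (postural sway, fidgeting, tremor) at
        the subject's low resting amplitude,
* SUM : the same band-limited process at the subject's larger utilitarian
        amplitude (wiping a table, playing an active video game) -- amplitude,
        not spectral shape, is what separates the two classes,
* WALK: a quasi-periodic oscillation at the subject's step frequency, with
        cycle-to-cycle frequency/amplitude jitter controlled by a
        gait-irregularity parameter that increases with GMFCS level.

The three placements of one subject share a single event timeline (bout
boundaries, walking phase modulation, posture tilts) but carry
placement-specific amplitude scalings and independent sensor noise, mirroring a
single body moving.  Between-subject parameter dispersion is the heterogeneity
the personalized-model comparison rests on, and is widest at GMFCS III.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

SAMPLE_RATE = 30.0
CLASSES = ("SED", "SUM", "WALK")
PLACEMENTS = ("wrist", "hip", "ankle")
GMFCS_LEVELS = ("I", "II", "III")

# Placement scalings for the walking oscillation (ankle > hip > wrist) and for
# standing utilitarian movement (arm-dominant; hip and ankle see weight shifts).
WALK_PLACEMENT_SCALE = {"wrist": 0.45, "hip": 0.6, "ankle": 1.0}
SUM_PLACEMENT_SCALE = {"wrist": 1.2, "hip": 0.5, "ankle": 0.5}

# Broadband gait-noise multiplier per placement: arm swing in children with
# CP is voluntary and irregular (many ambulate with devices or a hemiplegic
# arm), so the wrist sees the noisiest walking signal; the ankle the
# cleanest, rhythmic one.
GAIT_NOISE_PLACEMENT_SCALE = {"wrist": 2.2, "hip": 1.0, "ankle": 0.7}

# Relative axis weights (x = medio-lateral, y = vertical, z = antero-posterior).
_WALK_AXIS_WEIGHT = np.array([0.5, 1.0, 0.35])
_SUM_AXIS_WEIGHT = np.array([1.0, 0.7, 0.9])

# Baseline sensor noise present in every recording, in g.
SENSOR_NOISE_G = 0.002

# Default per-GMFCS-level generative parameter ranges.  Half-widths are scaled
# by the cohort ``heterogeneity`` dispersion factor.  Units: Hz for frequency,
# g for amplitudes; sum_multiplier is the ratio of SUM movement amplitude to
# resting residual-movement amplitude (dimensionless).  The ranges widen with
# impairment level so that between-subject class-amplitude overlap — one
# child's quiet utilitarian movement resembling another's restless sitting —
# is strongest at GMFCS III.
DEFAULT_LEVEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "I": {
        "step_frequency": (1.8, 2.3),
        "step_amplitude": (0.70, 1.00),
        "gait_irregularity": (0.03, 0.10),
        "sed_noise_scale": (0.004, 0.012),
        "sum_multiplier": (4.0, 8.0),
    },
    "II": {
        "step_frequency": (1.4, 2.2),
        "step_amplitude": (0.55, 0.90),
        "gait_irregularity": (0.08, 0.25),
        "sed_noise_scale": (0.004, 0.018),
        "sum_multiplier": (3.0, 7.0),
    },
    "III": {
        "step_frequency": (0.9, 2.0),
        "step_amplitude": (0.45, 0.70),
        "gait_irregularity": (0.20, 0.45),
        "sed_noise_scale": (0.003, 0.030),
        "sum_multiplier": (2.5, 6.0),
    },
}

# SUM movement amplitude is capped at this fraction of the subject's walking
# amplitude so the within-subject energy ordering SED < SUM < WALK holds at
# every placement (the binding case is the wrist, where utilitarian movement
# is largest and the walking oscillation smallest).
SUM_AMPLITUDE_CAP_FRACTION = 1.0 / 5.5

# Free-living bout duration ranges in seconds for the repeating
# SED -> WALK -> SUM -> WALK sequence (sit on a bench, walk weaving around
# cones to a table, stand completing a puzzle, walk back).  Sitting and
# standing phases run a couple of minutes; walks are short (~10 m with
# weaving).  Sub-window bouts remain reachable through configuration.
DEFAULT_BOUT_RANGES: dict[str, tuple[float, float]] = {
    "SED": (75.0, 105.0),
    "WALK": (12.0, 20.0),
    "SUM": (75.0, 105.0),
}

DEFAULT_DOMAIN_SHIFT = 0.75
BRISK_FREQUENCY_SCALE = 1.25
BRISK_AMPLITUDE_SCALE = 1.15


class CohortError(ValueError):
    """Invalid cohort or simulation request."""


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one synthetic subject."""

    subject_id: str
    gmfcs_level: str
    step_frequency: float        # Hz, fundamental of comfortable walking
    step_amplitude: float        # g, vertical ankle oscillation amplitude
    gait_irregularity: float     # [0, 1], cycle-to-cycle jitter
    sum_movement_scale: float    # g, standing-utilitarian movement amplitude
    sed_noise_scale: float       # g, residual tremor at rest
    rng_seed: int
    sitting_tilt_deg: float = 15.0   # trunk tilt when seated
    standing_tilt_deg: float = 5.0   # trunk tilt when standing
    protocol_id: int = 1

    def __post_init__(self) -> None:
        if self.gmfcs_level not in GMFCS_LEVELS:
            raise CohortError(f"unknown GMFCS level {self.gmfcs_level!r}")
        if self.step_frequency <= 0:
            raise CohortError("step_frequency must be positive")
        for name in ("step_amplitude", "sum_movement_scale", "sed_noise_scale"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be non-negative")
        if not 0.0 <= self.gait_irregularity <= 1.0:
            raise CohortError("gait_irregularity must lie in [0, 1]")


@dataclass(frozen=True)
class RawRecording:
    """One subject x placement tri-axial recording at a fixed sample rate."""

    subject_id: str
    placement: str
    sample_rate: float
    start_time: str                 # ISO-8601, informational
    samples: np.ndarray             # shape (n, 3), g

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise CohortError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(arr)):
            raise CohortError("samples must be finite")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class LabelTrack:
    """Ordered, non-overlapping half-open labeled intervals, in seconds."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, cls in self.intervals:
            if cls not in CLASSES:
                raise CohortError(f"unknown activity class {cls!r}")
            if end <= start:
                raise CohortError(f"interval ({start}, {end}) has non-positive duration")
            if start < prev_end:
                raise CohortError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def total_duration(self) -> float:
        return sum(e - s for s, e, _ in self.intervals)

    def classes(self) -> list[str]:
        return [cls for _, _, cls in self.intervals]


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _scaled_range(lo: float, hi: float, heterogeneity: float) -> tuple[float, float]:
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    half *= heterogeneity
    return mid - half, mid + half


def make_cohort(
    n_per_level: Mapping[str, int],
    master_seed: int,
    level_params: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    heterogeneity: float = 1.0,
    protocol_assignment: str = "protocol1",
) -> list[SubjectProfile]:
    """Draw a deterministic cohort of subject profiles.

    ``heterogeneity`` scales the half-width of every per-level parameter range
    about its midpoint, widening (or narrowing) between-subject dispersion
    without moving the level means.

    ``protocol_assignment`` fixes which structured protocol each subject
    completes: ``"protocol1"`` (default; includes the sitting trial, so every
    child's training data covers the seated posture met in free living),
    ``"protocol2"``, or ``"alternate"`` (half the cohort each).
    """
    params = level_params or DEFAULT_LEVEL_PARAMS
    if protocol_assignment not in ("protocol1", "protocol2", "alternate"):
        raise CohortError(
            f"unknown protocol_assignment {protocol_assignment!r}")
    for level in GMFCS_LEVELS:
        n = int(n_per_level.get(level, 0))
        if n < 1:
            raise CohortError(f"n_per_level[{level}] must be >= 1, got {n}")
    ss = np.random.SeedSequence(master_seed)
    profiles: list[SubjectProfile] = []
    idx = 0
    for level in GMFCS_LEVELS:
        for _ in range(int(n_per_level[level])):
            idx += 1
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            p = params[level]

            def draw(key: str, lo_clip: float = 1e-4) -> float:
                lo, hi = _scaled_range(*p[key], heterogeneity)
                return float(max(lo_clip, rng.uniform(lo, hi)))

            step_freq = draw("step_frequency", 0.4)
            step_amp = draw("step_amplitude", 0.05)
            irregularity = float(np.clip(
                rng.uniform(*_scaled_range(*p["gait_irregularity"], heterogeneity)),
                0.0, 1.0))
            sed_noise = draw("sed_noise_scale", 5e-4)
            sum_scale = min(sed_noise * draw("sum_multiplier", 1.5),
                            SUM_AMPLITUDE_CAP_FRACTION * step_amp)
            profiles.append(SubjectProfile(
                subject_id=f"S{idx:02d}",
                gmfcs_level=level,
                step_frequency=step_freq,
                step_amplitude=step_amp,
                gait_irregularity=irregularity,
                sum_movement_scale=sum_scale,
                sed_noise_scale=sed_noise,
                rng_seed=int(child.generate_state(1)[0] % (2**31)),
                sitting_tilt_deg=float(rng.uniform(2.0, 25.0)),
                standing_tilt_deg=float(rng.uniform(0.0, 18.0)),
                protocol_id={"protocol1": 1, "protocol2": 2,
                             "alternate": 1 + idx % 2}[protocol_assignment],
            ))
    return profiles


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _gravity(posture: str, tilt_deg: float, n: int) -> np.ndarray:
    """Static gravity baseline, shape (n, 3).

    Upright postures put ~1 g on the Y axis (device Y pointing vertically);
    supine rest rotates gravity onto the Z axis.  ``tilt_deg`` tips the trunk
    in the sagittal (Y-Z) plane.
    """
    t = np.deg2rad(tilt_deg)
    if posture == "supine":
        vec = np.array([0.0, np.sin(t), np.cos(t)])
    else:  # sitting / standing
        vec = np.array([0.0, np.cos(t), np.sin(t)])
    return np.broadcast_to(vec, (n, 3)).copy()


def _bandlimited_noise(rng: np.random.Generator, n: int, ncol: int = 3) -> np.ndarray:
    """Unit-variance band-limited (0.3-5 Hz) aperiodic movement, shape (n, ncol)."""
    white = rng.standard_normal((max(n, 64), ncol))
    b, a = _sig.butter(4, [0.3, 5.0], btype="bandpass", fs=SAMPLE_RATE)
    out = _sig.filtfilt(b, a, white, axis=0)[:n]
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _smoothed_modulation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Slowly varying unit-variance modulation signal (cut-off ~0.5 Hz)."""
    white = rng.standard_normal(max(n, 64))
    b, a = _sig.butter(2, 0.5, btype="lowpass", fs=SAMPLE_RATE)
    out = _sig.filtfilt(b, a, white)[:n]
    sd = out.std() or 1.0
    return out / sd


def _walk_components(
    profile: SubjectProfile,
    n: int,
    timeline_rng: np.random.Generator,
    frequency_scale: float,
    amplitude_scale: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared walking kinematics: phase, amplitude envelope, harmonic phases.

    Drawn from the timeline stream so all three placements see the same gait
    events.  Instantaneous step frequency wanders around the subject's
    fundamental with an excursion proportional to gait_irregularity.
    """
    irr = profile.gait_irregularity
    f0 = profile.step_frequency * frequency_scale
    mod = _smoothed_modulation(timeline_rng, n)
    inst_freq = np.maximum(f0 * (1.0 + 0.4 * irr * mod), 0.2)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / SAMPLE_RATE
    amp_mod = _smoothed_modulation(timeline_rng, n)
    amp = profile.step_amplitude * amplitude_scale * np.clip(
        1.0 + 0.6 * irr * amp_mod, 0.25, 2.0)
    harmonic_phases = timeline_rng.uniform(0, 2 * np.pi, size=4)
    return phase, amp, harmonic_phases


def _synth_segment(
    profile: SubjectProfile,
    placement: str,
    activity_class: str,
    n: int,
    posture: str,
    timeline_rng: np.random.Generator,
    noise_rng: np.random.Generator,
    frequency_scale: float = 1.0,
    amplitude_scale: float = 1.0,
    sed_scale_override: float | None = None,
    sum_scale_override: float | None = None,
    sum_lateral_factor: float = 1.0,
) -> np.ndarray:
    """One labeled segment for one placement, shape (n, 3), in g.

    The timeline stream must be advanced identically for every placement of
    one subject; placement-dependent draws come only from ``noise_rng``.
    """
    tilt = profile.sitting_tilt_deg if posture == "sitting" else (
        profile.standing_tilt_deg if posture != "supine" else
        0.3 * profile.standing_tilt_deg)
    tilt += timeline_rng.normal(0.0, 1.5)
    out = _gravity(posture, tilt, n)
    out += SENSOR_NOISE_G * noise_rng.standard_normal((n, 3))

    if activity_class == "SED":
        # Residual movement at rest (postural sway, fidgeting, tremor) is
        # the same band-limited, arm-dominant process as utilitarian
        # movement; amplitude is the only within-subject discriminator.
        scale = (profile.sed_noise_scale if sed_scale_override is None
                 else sed_scale_override)
        move = _bandlimited_noise(noise_rng, n) * _SUM_AXIS_WEIGHT
        out += scale * SUM_PLACEMENT_SCALE[placement] * move
    elif activity_class == "SUM":
        scale = (profile.sum_movement_scale if sum_scale_override is None
                 else sum_scale_override)
        move = _bandlimited_noise(noise_rng, n) * _SUM_AXIS_WEIGHT
        move[:, 0] *= sum_lateral_factor
        move[:, 2] *= sum_lateral_factor
        out += scale * SUM_PLACEMENT_SCALE[placement] * move
        # residual resting movement persists underneath
        out += (profile.sed_noise_scale * SUM_PLACEMENT_SCALE[placement]
                * _bandlimited_noise(noise_rng, n) * _SUM_AXIS_WEIGHT)
    elif activity_class == "WALK":
        phase, amp, hp = _walk_components(
            profile, n, timeline_rng, frequency_scale, amplitude_scale)
        amp = amp * WALK_PLACEMENT_SCALE[placement]
        vertical = amp * (np.sin(phase + hp[0])
                          + 0.35 * np.sin(2.0 * phase + hp[1]))
        out[:, 0] += _WALK_AXIS_WEIGHT[0] * amp * np.sin(0.5 * phase + hp[2])
        out[:, 1] += _WALK_AXIS_WEIGHT[1] * vertical
        out[:, 2] += _WALK_AXIS_WEIGHT[2] * amp * np.sin(0.5 * phase + hp[3])
        # Broadband gait noise grows with irregularity, smearing the
        # spectral peak for the most impaired walkers; strongest at the
        # wrist, weakest at the ankle.
        out += (0.6 * GAIT_NOISE_PLACEMENT_SCALE[placement]
                * profile.gait_irregularity * amp[:, None]
                * _bandlimited_noise(noise_rng, n))
        out += profile.sed_noise_scale * noise_rng.standard_normal((n, 3))
    else:
        raise CohortError(f"unknown activity class {activity_class!r}")
    return out


def _default_posture(activity_class: str) -> str:
    return {"SED": "sitting", "SUM": "standing", "WALK": "standing"}[activity_class]


def simulate_trial(
    profile: SubjectProfile,
    placement: str,
    activity_class: str,
    duration_s: float,
    seed: int,
    posture: str | None = None,
    frequency_scale: float = 1.0,
    amplitude_scale: float = 1.0,
) -> tuple[RawRecording, LabelTrack]:
    """Simulate a single constant-activity trial for one placement.

    Deterministic given (profile, seed).  The gait/posture event timeline is
    derived from ``seed`` alone, so calling with a different ``placement`` but
    the same seed yields the same underlying movement events.
    """
    if placement not in PLACEMENTS:
        raise CohortError(f"unknown placement {placement!r}")
    if activity_class not in CLASSES:
        raise CohortError(f"unknown activity class {activity_class!r}")
    if duration_s < 10:
        raise CohortError("duration_s must be >= 10 (one full analysis window)")
    n = int(round(duration_s * SAMPLE_RATE))
    timeline_rng = np.random.default_rng([int(seed), 1001])
    noise_rng = np.random.default_rng([int(seed), 1002, PLACEMENTS.index(placement)])
    samples = _synth_segment(
        profile, placement, activity_class, n,
        posture or _default_posture(activity_class),
        timeline_rng, noise_rng,
        frequency_scale=frequency_scale, amplitude_scale=amplitude_scale)
    rec = RawRecording(profile.subject_id, placement, SAMPLE_RATE,
                       "2020-01-01T10:00:00", samples)
    track = LabelTrack(((0.0, n / SAMPLE_RATE, activity_class),))
    return rec, track


# (trial name, activity class, posture, frequency scale, amplitude scale)
PROTOCOLS: dict[int, tuple[tuple[str, str, str, float, float], ...]] = {
    1: (
        ("supine_rest", "SED", "supine", 1.0, 1.0),
        ("sitting_coloring", "SED", "sitting", 1.0, 1.0),
        ("video_game", "SUM", "standing", 1.0, 1.0),
        ("comfortable_walk", "WALK", "standing", 1.0, 1.0),
        ("brisk_walk", "WALK", "standing", BRISK_FREQUENCY_SCALE, BRISK_AMPLITUDE_SCALE),
    ),
    2: (
        ("supine_rest", "SED", "supine", 1.0, 1.0),
        ("wiping_table", "SUM", "standing", 1.0, 1.0),
        ("video_game", "SUM", "standing", 1.0, 1.0),
        ("comfortable_walk", "WALK", "standing", 1.0, 1.0),
        ("brisk_walk", "WALK", "standing", BRISK_FREQUENCY_SCALE, BRISK_AMPLITUDE_SCALE),
    ),
}


def _trial_seed(base_seed: int, tag: int) -> int:
    return int(np.random.SeedSequence(entropy=int(base_seed),
                                      spawn_key=(int(tag),)).generate_state(1)[0]
               % (2**31))


def simulate_structured_protocol(
    profile: SubjectProfile,
    protocol_id: int | None = None,
    seed: int | None = None,
    trial_duration_s: float = 360.0,
) -> dict[str, list[tuple[str, RawRecording, LabelTrack]]]:
    """Simulate the five structured 6-min activity trials for all placements.

    Returns ``{placement: [(trial_name, recording, track), ...]}``.  Protocol 1
    includes sitting/coloring as a second SED trial; protocol 2 replaces it
    with wiping a table (SUM).  The brisk walk runs at a step frequency
    multiplier > 1 relative to the comfortable walk.
    """
    pid = profile.protocol_id if protocol_id is None else int(protocol_id)
    if pid not in PROTOCOLS:
        raise CohortError(f"unknown protocol {pid!r}")
    base = profile.rng_seed if seed is None else int(seed)
    out: dict[str, list[tuple[str, RawRecording, LabelTrack]]] = {
        p: [] for p in PLACEMENTS}
    for i, (name, cls, posture, fscale, ascale) in enumerate(PROTOCOLS[pid]):
        tseed = _trial_seed(base, i)
        for placement in PLACEMENTS:
            rec, track = simulate_trial(
                profile, placement, cls, trial_duration_s, tseed,
                posture=posture, frequency_scale=fscale, amplitude_scale=ascale)
            out[placement].append((name, rec, track))
    return out


def simulate_free_living(
    profile: SubjectProfile,
    seed: int | None = None,
    duration_s: float = 360.0,
    domain_shift: float = DEFAULT_DOMAIN_SHIFT,
    bout_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, RawRecording], LabelTrack]:
    """Simulate the free-living sequence: SED -> WALK -> SUM -> WALK, repeated.

    ``domain_shift`` in [0, 1] morphs the SED and SUM generative amplitudes
    toward each other (free-living children fidget while seated and perform
    utilitarian movements with less lateral motion), reproducing the
    lab-to-free-living accuracy decline as a tunable phenomenon.  At 0 the
    per-class signal distributions match the structured trials exactly.
    """
    base = profile.rng_seed if seed is None else int(seed)
    ranges = dict(DEFAULT_BOUT_RANGES)
    if bout_ranges:
        ranges.update({k: tuple(v) for k, v in bout_ranges.items()})
    shift = float(np.clip(domain_shift, 0.0, 1.0))

    sched_rng = np.random.default_rng([int(base), 2001])
    pattern = ("SED", "WALK", "SUM", "WALK")
    bouts: list[tuple[float, float, str]] = []
    t = 0.0
    i = 0
    while t < duration_s:
        cls = pattern[i % 4]
        dur = float(sched_rng.uniform(*ranges[cls]))
        end = min(t + dur, duration_s)
        bouts.append((t, end, cls))
        t = end
        i += 1
    track = LabelTrack(tuple(bouts))

    sed = profile.sed_noise_scale
    sum_ = profile.sum_movement_scale
    sed_fl = sed + shift * 0.35 * (sum_ - sed)
    sum_fl = sum_ - shift * 0.45 * (sum_ - sed)
    lateral = 1.0 - 0.5 * shift

    recs: dict[str, RawRecording] = {}
    n_total = int(round(duration_s * SAMPLE_RATE))
    for pidx, placement in enumerate(PLACEMENTS):
        parts: list[np.ndarray] = []
        for b, (s, e, cls) in enumerate(bouts):
            n = (int(round(e * SAMPLE_RATE)) - int(round(s * SAMPLE_RATE)))
            tl = np.random.default_rng([int(base), 3001, b])
            nz = np.random.default_rng([int(base), 3002, b, pidx])
            seg = _synth_segment(
                profile, placement, cls, n,
                _default_posture(cls), tl, nz,
                sed_scale_override=sed_fl if cls == "SED" else None,
                sum_scale_override=sum_fl if cls == "SUM" else None,
                sum_lateral_factor=lateral if cls == "SUM" else 1.0)
            if cls == "SED" and shift > 0:
                # Intermittent fidgeting bursts while seated.
                burst_rng = np.random.default_rng([int(base), 3003, b, pidx])
                mask = _burst_mask(np.random.default_rng([int(base), 3004, b]), n)
                burst = _bandlimited_noise(burst_rng, n) * _SUM_AXIS_WEIGHT
                seg += (0.7 * shift * sum_ * SUM_PLACEMENT_SCALE[placement]
                        * mask[:, None] * burst)
            parts.append(seg)
        samples = np.concatenate(parts, axis=0)[:n_total]
        recs[placement] = RawRecording(profile.subject_id, placement,
                                       SAMPLE_RATE, "2020-01-01T14:00:00",
                                       samples)
    return recs, track


def _burst_mask(rng: np.random.Generator, n: int) -> np.ndarray:
    """0/1 mask of short fidgeting bursts (on 1-3 s, off 5-15 s)."""
    mask = np.zeros(n)
    t = int(rng.uniform(2, 8) * SAMPLE_RATE)
    while t < n:
        on = int(rng.uniform(1.0, 3.0) * SAMPLE_RATE)
        mask[t:t + on] = 1.0
        t += on + int(rng.uniform(5.0, 15.0) * SAMPLE_RATE)
    return mask


# ---------------------------------------------------------------------------
# File output (ActiGraph-style raw CSV + label CSV)
# ---------------------------------------------------------------------------

def write_raw_csv(recording: RawRecording, path: str | Path,
                  decimals: int = 4) -> None:
    """Write an ActiGraph-style raw CSV: header block, then one X,Y,Z row per
    sample (implicit sample index, values in g)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("# cpactivity raw accelerometer CSV v1\n")
        fh.write(f"# start_time: {recording.start_time}\n")
        fh.write(f"# sample_rate_hz: {recording.sample_rate:g}\n")
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# placement: {recording.placement}\n")
        fh.write("X,Y,Z\n")
        fmt = f"%.{decimals}f"
        np.savetxt(fh, recording.samples, fmt=fmt, delimiter=",")


def write_label_csv(track: LabelTrack, subject_id: str, path: str | Path,
                    placement_scope: str = "all") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", "placement_scope", "start_s", "end_s", "class"])
        for s, e, cls in track.intervals:
            w.writerow([subject_id, placement_scope, f"{s:.3f}", f"{e:.3f}", cls])


def write_cohort_manifest(profiles: Sequence[SubjectProfile],
                          files: Mapping[str, Sequence[str]],
                          path: str | Path) -> None:
    """Delimited manifest of subjects, GMFCS levels, and generated file paths."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", "gmfcs_level", "protocol_id", "files"])
        for p in profiles:
            w.writerow([p.subject_id, p.gmfcs_level, p.protocol_id,
                        ";".join(files.get(p.subject_id, []))])


def profile_to_dict(profile: SubjectProfile) -> dict:
    return asdict(profile)
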