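"""Synthetic wrist-accelerometer recordings for the ten scripted activities.

The generator emulates a laboratory protocol in which each participant wears
a watch on the dominant wrist and performs ten scripted activities — four
face-touching (FT) and six non-face-touching (NFT) — for three minutes each,
in randomized order, sampled at 30 Hz in units of gravity (g).

Signal model
------------
Every activity is modelled as

    a(t) = gravity(orientation(t)) + movement(t) + noise(t)

where the orientation is parameterized by the pitch of the device x-axis
(the forearm axis) against the horizontal and a roll angle distributing the
remaining gravity over y/z.  Movement components by activity class:

* static postures (lying flat): none — the noise floor only;
* sedentary tasks (phone, computer, writing): low-amplitude jitter bursts;
* leisure walk: sinusoidal arm swing near 2 Hz on two axes;
* hand-to-face excursions (the four FT activities) and the moving-items
  task: repeated raise → dwell → lower cycles that rotate the x-axis toward
  vertical.  The moving-items profile deliberately mimics the FT excursion
  (similar raised pitch) but with a slower cycle and longer dwell, so its
  gravity-angle statistics overlap the FT ones while the leisure walk stays
  clearly distinct.

Per-participant random effects — log-normal amplitude and tempo multipliers
and a small (≤15°) baseline orientation rotation — create between-subject
variance so leave-one-subject-out folds are non-trivial.  All randomness is
threaded through a single ``numpy`` generator seeded from the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .labels import ACTIVITIES, ActivityLabel

__all__ = [
    "ActivitySignalParams",
    "ParticipantEffects",
    "SimulationConfig",
    "TriaxialRecording",
    "AnnotationLog",
    "simulate_activity",
    "simulate_dataset",
    "write_recording_csv",
    "write_annotations_csv",
]


@dataclass(frozen=True)
class ActivitySignalParams:
    """Signal-model parameters for one activity.

    Angles are in degrees, amplitudes in g, rates in events per minute.
    ``pitch_deg`` is the resting angle between the device x-axis and the
    horizontal plane, so the gravity reaction along x is ``sin(pitch)``.
    """

    pitch_deg: float
    roll_deg: float
    noise_sigma: float
    # slow posture wobble (all activities)
    wobble_deg: float = 2.0
    wobble_hz: float = 0.05
    # sedentary jitter bursts
    jitter_amp: float = 0.0
    burst_rate_per_min: float = 0.0
    burst_s: float = 0.8
    # periodic arm swing (walk)
    osc_freq_hz: float = 0.0
    osc_amp: float = 0.0
    # hand-to-face / carry excursions
    event_rate_per_min: float = 0.0
    raise_s: float = 0.0
    dwell_s: float = 0.0
    lower_s: float = 0.0
    face_pitch_deg: float = 0.0
    dwell_jitter_amp: float = 0.0
    move_amp: float = 0.0


# Defaults chosen so that (a) a threshold on SD(vm) trivially separates the
# static postures from the walk, and (b) the moving-items gravity-angle
# trajectory overlaps the FT distribution far more than the walk does.
DEFAULT_ACTIVITY_PARAMS: dict[str, ActivitySignalParams] = {
    "Using mobile phone": ActivitySignalParams(
        pitch_deg=20.0, roll_deg=10.0, noise_sigma=0.015,
        jitter_amp=0.03, burst_rate_per_min=20.0),
    "Lying flat on the back": ActivitySignalParams(
        pitch_deg=5.0, roll_deg=60.0, noise_sigma=0.01, wobble_deg=0.5),
    "Computer tasks": ActivitySignalParams(
        pitch_deg=5.0, roll_deg=35.0, noise_sigma=0.015,
        jitter_amp=0.04, burst_rate_per_min=30.0),
    "Writing": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=-30.0, noise_sigma=0.015,
        jitter_amp=0.05, burst_rate_per_min=25.0),
    "Leisure walk": ActivitySignalParams(
        pitch_deg=-75.0, roll_deg=20.0, noise_sigma=0.03,
        osc_freq_hz=2.0, osc_amp=0.3),
    "Moving items from one location to another": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=0.0, noise_sigma=0.025,
        event_rate_per_min=12.0, raise_s=0.7, dwell_s=2.2, lower_s=0.7,
        face_pitch_deg=55.0, dwell_jitter_amp=0.05, move_amp=0.2),
    "Repeated face touching": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=5.0, noise_sigma=0.02,
        event_rate_per_min=10.0, raise_s=0.5, dwell_s=0.8, lower_s=0.5,
        face_pitch_deg=65.0, dwell_jitter_amp=0.08, move_amp=0.2),
    "Eating and drinking": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=5.0, noise_sigma=0.02,
        event_rate_per_min=7.0, raise_s=0.6, dwell_s=1.5, lower_s=0.6,
        face_pitch_deg=60.0, dwell_jitter_amp=0.06, move_amp=0.2),
    "Simulated smoking": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=5.0, noise_sigma=0.02,
        event_rate_per_min=5.0, raise_s=0.6, dwell_s=3.5, lower_s=0.6,
        face_pitch_deg=62.0, dwell_jitter_amp=0.04, move_amp=0.2),
    "Adjusting eyeglass": ActivitySignalParams(
        pitch_deg=10.0, roll_deg=5.0, noise_sigma=0.02,
        event_rate_per_min=8.0, raise_s=0.5, dwell_s=0.5, lower_s=0.5,
        face_pitch_deg=68.0, dwell_jitter_amp=0.07, move_amp=0.2),
}

# Human walking cadence band; participant tempo multipliers are clipped to it.
WALK_FREQ_BAND = (1.8, 2.2)


@dataclass(frozen=True)
class ParticipantEffects:
    """Random effects applied on top of the activity defaults."""

    amp_mult: float = 1.0
    freq_mult: float = 1.0
    pitch_offset_deg: float = 0.0
    roll_offset_deg: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol configuration.

    Defaults mirror the laboratory protocol: 10 participants, 10 activities
    of 180 s each at 30 Hz, with a 10 s idle gap between activities.
    """

    n_participants: int = 10
    activity_duration: float = 180.0
    sampling_rate: float = 30.0
    seed: int = 0
    idle_gap: float = 10.0
    trim_front: float = 20.0
    trim_back: float = 5.0
    amp_sigma: float = 0.15
    freq_sigma: float = 0.15
    orientation_jitter_deg: float = 15.0
    activity_params: dict[str, ActivitySignalParams] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PARAMS))

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.activity_duration <= self.trim_front + self.trim_back:
            raise ConfigurationError(
                "activity_duration must exceed trim_front + trim_back")
        for name, p in self.activity_params.items():
            for amp in (p.noise_sigma, p.jitter_amp, p.osc_amp,
                        p.dwell_jitter_amp, p.move_amp):
                if amp < 0:
                    raise ConfigurationError(
                        f"negative amplitude for activity {name!r}")


@dataclass
class TriaxialRecording:
    """One participant's continuous tri-axial stream in g."""

    participant_id: str
    sampling_rate: float
    t: np.ndarray        # seconds, strictly increasing, spacing 1/rate
    xyz: np.ndarray      # shape (n, 3)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AnnotationLog:
    """Per-participant (activity, start, end) intervals in seconds."""

    participant_id: str
    entries: list[tuple[ActivityLabel, float, float]]


def _gravity(pitch_rad: np.ndarray, roll_rad: float) -> np.ndarray:
    """Gravity reaction in the device frame, shape (n, 3), unit norm."""
    gx = np.sin(pitch_rad)
    c = np.cos(pitch_rad)
    gy = c * math.cos(roll_rad)
    gz = c * math.sin(roll_rad)
    return np.column_stack([gx, gy, gz])


def _excursion_pitch(t: np.ndarray, rest: float, face: float,
                     rate_per_min: float, raise_s: float, dwell_s: float,
                     lower_s: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pitch trajectory (radians) for repeated raise–dwell–lower cycles.

    Returns the pitch series and a 0/1 mask of dwell samples (used to add
    touch-gesture jitter while the hand is at the face).
    """
    duration = t[-1] - t[0] + (t[1] - t[0]) if len(t) > 1 else 0.0
    period = 60.0 / rate_per_min
    n_events = int(duration / period)
    pitch = np.full_like(t, rest)
    dwell_mask = np.zeros_like(t, dtype=bool)
    event_len = raise_s + dwell_s + lower_s
    for k in range(n_events):
        # jittered regular schedule, kept inside the segment
        start = k * period + rng.uniform(0.0, max(period - event_len, 1e-3))
        u = t - t[0] - start
        up = (u >= 0) & (u < raise_s)
        pitch[up] = rest + (face - rest) * (u[up] / raise_s)
        hold = (u >= raise_s) & (u < raise_s + dwell_s)
        pitch[hold] = face
        dwell_mask |= hold
        down = (u >= raise_s + dwell_s) & (u < event_len)
        pitch[down] = face - (face - rest) * ((u[down] - raise_s - dwell_s)
                                              / lower_s)
    return pitch, dwell_mask


def simulate_activity(label: ActivityLabel, cfg: SimulationConfig,
                      effects: ParticipantEffects,
                      rng: np.random.Generator,
                      duration: float | None = None) -> np.ndarray:
    """Generate one activity segment; returns acceleration of shape (n, 3).

    ``n = duration * sampling_rate`` exactly; timestamps are implicit
    (``arange(n) / rate``, offset by the caller).
    """
    cfg.validate()
    duration = cfg.activity_duration if duration is None else duration
    rate = cfg.sampling_rate
    n = round(duration * rate)
    if n <= 0:
        raise ConfigurationError("duration × sampling_rate must be positive")
    try:
        p = cfg.activity_params[label.name]
    except KeyError:
        raise ConfigurationError(f"no signal parameters for {label.name!r}")

    t = np.arange(n) / rate
    pitch0 = math.radians(p.pitch_deg + effects.pitch_offset_deg)
    roll = math.radians(p.roll_deg + effects.roll_offset_deg)

    # slow posture wobble around the resting pitch
    wobble = (math.radians(p.wobble_deg)
              * np.sin(2 * math.pi * p.wobble_hz * t
                       + rng.uniform(0, 2 * math.pi)))
    pitch = np.full(n, pitch0) + wobble
    move = np.zeros((n, 3))

    if p.event_rate_per_min > 0:
        face = math.radians(p.face_pitch_deg + effects.pitch_offset_deg)
        exc, dwell = _excursion_pitch(
            t, pitch0, face, p.event_rate_per_min * effects.freq_mult,
            p.raise_s, p.dwell_s, p.lower_s, rng)
        pitch = exc + wobble
        # transient push along the forearm while the pitch changes
        dpitch = np.gradient(exc, 1.0 / rate)
        move[:, 0] += (p.move_amp * effects.amp_mult
                       * dpitch / max(np.abs(dpitch).max(), 1e-9))
        move[dwell] += rng.normal(
            0.0, p.dwell_jitter_amp * effects.amp_mult, (int(dwell.sum()), 3))

    if p.osc_amp > 0:
        f = min(max(p.osc_freq_hz * effects.freq_mult, WALK_FREQ_BAND[0]),
                WALK_FREQ_BAND[1])
        amp = p.osc_amp * effects.amp_mult
        phase = rng.uniform(0, 2 * math.pi)
        move[:, 0] += 0.5 * amp * np.sin(2 * math.pi * f * t + phase)
        move[:, 1] += amp * np.sin(2 * math.pi * f * t + phase + 1.0)
        move[:, 2] += 0.5 * amp * np.cos(2 * math.pi * f * t + phase)

    if p.jitter_amp > 0 and p.burst_rate_per_min > 0:
        n_bursts = rng.poisson(p.burst_rate_per_min * duration / 60.0)
        burst_n = max(round(p.burst_s * rate), 1)
        for start in rng.uniform(0, max(duration - p.burst_s, 0), n_bursts):
            i0 = int(start * rate)
            sl = slice(i0, min(i0 + burst_n, n))
            width = sl.stop - sl.start
            move[sl] += rng.normal(
                0.0, p.jitter_amp * effects.amp_mult, (width, 3))

    accel = _gravity(pitch, roll) + move
    accel += rng.normal(0.0, p.noise_sigma, (n, 3))
    return accel


def draw_participant_effects(cfg: SimulationConfig,
                             rng: np.random.Generator) -> ParticipantEffects:
    jit = cfg.orientation_jitter_deg
    return ParticipantEffects(
        amp_mult=float(rng.lognormal(0.0, cfg.amp_sigma)),
        freq_mult=float(rng.lognormal(0.0, cfg.freq_sigma)),
        pitch_offset_deg=float(rng.uniform(-jit, jit)),
        roll_offset_deg=float(rng.uniform(-jit, jit)),
    )


# quiet-sitting parameters for the idle gaps between activities
_IDLE_PARAMS = ActivitySignalParams(pitch_deg=0.0, roll_deg=20.0,
                                    noise_sigma=0.01, wobble_deg=1.0)


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[list[TriaxialRecording], list[AnnotationLog]]:
    """Simulate the full protocol: one recording + one annotation log per
    participant, activity order randomized per participant.

    A fixed idle gap (quiet sitting) separates consecutive activities so
    downstream annotation alignment is exercised on realistic streams.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.sampling_rate
    recordings: list[TriaxialRecording] = []
    logs: list[AnnotationLog] = []
    gap_n = round(cfg.idle_gap * rate)

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:02d}"
        effects = draw_participant_effects(cfg, rng)
        order = rng.permutation(len(ACTIVITIES))
        chunks: list[np.ndarray] = []
        entries: list[tuple[ActivityLabel, float, float]] = []
        cursor_n = 0
        for j, idx in enumerate(order):
            label = ACTIVITIES[idx]
            seg = simulate_activity(label, cfg, effects, rng)
            start = cursor_n / rate
            entries.append((label, start, start + cfg.activity_duration))
            chunks.append(seg)
            cursor_n += len(seg)
            if j < len(order) - 1 and gap_n > 0:
                gap_cfg = replace(cfg, activity_params={"idle": _IDLE_PARAMS})
                gap = simulate_activity(
                    ActivityLabel("idle", "NFT"), gap_cfg, effects, rng,
                    duration=cfg.idle_gap)
                chunks.append(gap)
                cursor_n += len(gap)
        xyz = np.vstack(chunks)
        t = np.arange(len(xyz)) / rate
        recordings.append(TriaxialRecording(pid, rate, t, xyz))
        logs.append(AnnotationLog(pid, entries))
    return recordings, logs


def write_recording_csv(recording: TriaxialRecording, path: str | Path) -> None:
    """Write `timestamp,x,y,z` rows; timestamps in seconds, 6 decimals."""
    arr = np.column_stack([recording.t, recording.xyz])
    np.savetxt(path, arr, fmt="%.6f", delimiter=",",
               header="timestamp,x,y,z", comments="")


def write_annotations_csv(log: AnnotationLog, path: str | Path) -> None:
    """Write `participant_id,activity,start,end`; names exactly as scripted."""
    with open(path, "w") as fh:
        fh.write("participant_id,activity,start,end\n")
        for label, start, end in log.entries:
            fh.write(f"{log.participant_id},{label.name},"
                     f"{start:.6f},{end:.6f}\n")
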