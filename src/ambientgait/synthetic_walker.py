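"""Synthetic hallway walking trials with full ground truth.

The study design this emulates: a participant walks the length of an
instrumented hallway (14 m by default); the first and last 3.5 m are
acceleration/deceleration zones and the middle 7 m is the monitored
steady-state zone.  Two contactless modalities record the walk:

* a depth camera streaming 32 joint positions at ~30 fps, with frame
  dropouts (heaviest at the range extremes, where tracking locks on late
  and drops off early);
* seven floor-mounted accelerometers in a 2x3 grid (5.0 m along-hallway
  by 3.5 m across) plus one duplicate sensor co-located with its
  across-hallway partner but wired to the *other* wireless acquisition
  unit, so the two units' independent clocks can be synchronized offline.

Heel strikes occur at the cadence interval at positions one step length
apart inside the monitored zone; each strike injects a damped (Gaussian-
windowed) 80 Hz oscillation into every sensor with amplitude decaying as
exp(-alpha * d / 2) (energy as exp(-alpha * d)) with distance d from the
strike.  All randomness flows from one seed; identical seeds give
bit-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    AZURE_KINECT_JOINTS,
    JointStream,
    TrialConfig,
    VibrationRecord,
)

__all__ = [
    "WalkerParams",
    "VibeParams",
    "CohortParams",
    "TrialTruth",
    "default_sensor_layout",
    "simulate_trial",
    "simulate_cohort",
    "static_skeleton_stream",
]


@dataclass
class WalkerParams:
    """Kinematics, body geometry and camera noise of one simulated walker.

    ``step_length`` defaults to ``speed / (cadence / 60)`` so that the
    generated step times and positions are exactly consistent with the
    stated speed and cadence.
    """

    speed: float = 1.2            # m/s, steady-state
    cadence: float = 111.0        # steps/min
    step_length: float | None = None  # m; None = derived from speed/cadence
    start_u: float = 0.0          # m, start line position
    joint_noise_sd: float = 0.005  # m, isotropic per-coordinate camera noise
    dropout_prob: float = 0.02    # per frame-joint tracking loss
    fps: float = 30.0
    timestamp_jitter_sd: float = 0.002  # s, camera frame-interval jitter
    accel_tail_s: float = 1.0     # duration of speed ramp at each end
    lead_dropout_s: float = 0.5   # forced tracking loss entering the range
    tail_dropout_s: float = 0.5   # forced tracking loss leaving the range
    torso: float = 0.55           # m, pelvis-to-neck
    leg: float = 0.85             # m, hip-knee plus knee-ankle
    shoulder: float = 0.38        # m, shoulder-to-shoulder
    sway_amp: float = 0.02        # m, lateral pelvis sway at step frequency
    bob_amp: float = 0.015        # m, vertical pelvis bob at step frequency
    swing_amp: float = 0.12       # m, ankle-pelvis distance swing (stride freq)

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.cadence <= 0:
            raise ValueError("speed and cadence must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.step_length is None:
            self.step_length = self.speed / (self.cadence / 60.0)


@dataclass
class VibeParams:
    """Footstep impulse model and acquisition noise of the floor array."""

    amplitude: float = 1.0        # impulse amplitude at the source
    decay_alpha: float = 0.35     # 1/m, energy decay rate across the floor
    center_freq: float = 80.0     # Hz, impulse oscillation (inside passband)
    burst_sd: float = 0.010       # s, Gaussian envelope width
    amp_jitter: float = 0.10      # lognormal sd of per-step amplitude
    noise_sd: float = 0.01        # additive Gaussian sensor noise
    daq_lag: float = 0.0          # s, second DAQ group clock offset
    sample_rate: float = 16384.0  # Hz
    distance_mode: str = "axial"  # axial | euclidean

    def __post_init__(self) -> None:
        if not 5.0 < self.center_freq < 250.0:
            raise ValueError("center frequency must lie inside the 5-250 Hz passband")
        if self.sample_rate < 2000.0:
            raise ValueError("sample_rate must be >= 2 kHz")


@dataclass
class TrialTruth:
    """Ground truth of one simulated trial."""

    speed: float
    cadence: float
    step_times: np.ndarray
    step_positions: np.ndarray
    daq_lag: float
    dropout_mask: np.ndarray | None = None  # (frames, joints), True = dropped

    def to_json_dict(self) -> dict:
        return {
            "speed": self.speed,
            "cadence": self.cadence,
            "step_times": list(map(float, self.step_times)),
            "step_positions": list(map(float, self.step_positions)),
            "daq_lag": self.daq_lag,
        }


def default_sensor_layout(config: TrialConfig | None = None,
                          grid_du: float = 5.0, grid_dv: float = 3.5
                          ) -> tuple[np.ndarray, tuple[str, ...], tuple[int, int]]:
    """The 2x3 sensor grid plus the duplicate synchronization sensor.

    Channels 1-3 sit on the left wall (one DAQ), channels 5-7 on the right
    wall (the other DAQ); channel 4 is co-located with channel 5 but wired
    to the left DAQ purely for clock synchronization.  Returns (layout,
    daq_group, sync_pair) with 0-based sync indices.
    """
    length = (config or TrialConfig()).hallway_length
    u0 = (length - 2 * grid_du) / 2.0
    us = [u0, u0 + grid_du, u0 + 2 * grid_du]
    layout = np.array(
        [[us[0], 0.0], [us[1], 0.0], [us[2], 0.0],        # ch1-3, left
         [us[0], grid_dv],                                # ch4, duplicate
         [us[0], grid_dv], [us[1], grid_dv], [us[2], grid_dv]]  # ch5-7, right
    )
    groups = ("left", "left", "left", "left", "right", "right", "right")
    return layout, groups, (3, 4)


def _trajectory(speed: float, tail: float, length: float):
    """Piecewise linear-ramp trajectory u(t) over the hallway.

    The walker accelerates linearly from rest for ``tail`` seconds,
    holds ``speed``, and decelerates to rest over the last ``tail``
    seconds, covering ``length`` meters in total.
    """
    ramp_dist = speed * tail / 2.0
    steady = length - 2 * ramp_dist
    if steady <= 0:
        raise ValueError("walk does not fit in hallway at this speed")
    t_steady = steady / speed
    total = tail + t_steady + tail

    def u_of_t(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.empty_like(t)
        a = t <= tail
        b = (t > tail) & (t <= tail + t_steady)
        c = t > tail + t_steady
        u[a] = 0.5 * speed / tail * t[a] ** 2
        u[b] = ramp_dist + speed * (t[b] - tail)
        tc = np.minimum(total - t[c], tail)
        u[c] = length - 0.5 * speed / tail * tc**2
        return u

    def t_of_u_steady(u: np.ndarray) -> np.ndarray:
        return tail + (np.asarray(u, dtype=float) - ramp_dist) / speed

    return u_of_t, t_of_u_steady, total


def _skeleton_positions(t: np.ndarray, pelvis: np.ndarray, w: WalkerParams
                        ) -> np.ndarray:
    """Build the (n, 32, 3) joint array around a pelvis trajectory.

    Coordinates are hallway-frame: x across the hallway, y vertical,
    z along the walking direction.  Ankles swing so that the ankle-pelvis
    distance is exactly leg + swing_amp * sin(2*pi*f_stride*t + phase)
    with opposite phase per side (one oscillation per stride).
    """
    n = len(t)
    J = {name: i for i, name in enumerate(AZURE_KINECT_JOINTS)}
    pos = np.empty((n, len(J), 3))
    f_stride = w.cadence / 120.0

    def put(name: str, offset) -> None:
        pos[:, J[name], :] = pelvis + np.asarray(offset, dtype=float)

    put("pelvis", (0.0, 0.0, 0.0))
    put("spine_navel", (0.0, w.torso * 0.3, 0.0))
    put("spine_chest", (0.0, w.torso * 0.7, 0.0))
    put("neck", (0.0, w.torso, 0.0))
    put("head", (0.0, w.torso + 0.20, 0.0))
    put("nose", (0.0, w.torso + 0.22, 0.05))
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        put(f"clavicle_{side}", (sgn * 0.08, w.torso - 0.03, 0.0))
        put(f"shoulder_{side}", (sgn * w.shoulder / 2, w.torso - 0.05, 0.0))
        put(f"elbow_{side}", (sgn * (w.shoulder / 2 + 0.02), w.torso - 0.35, 0.0))
        put(f"wrist_{side}", (sgn * (w.shoulder / 2 + 0.03), w.torso - 0.60, 0.0))
        put(f"hand_{side}", (sgn * (w.shoulder / 2 + 0.03), w.torso - 0.68, 0.02))
        put(f"handtip_{side}", (sgn * (w.shoulder / 2 + 0.03), w.torso - 0.74, 0.04))
        put(f"thumb_{side}", (sgn * (w.shoulder / 2 + 0.01), w.torso - 0.66, 0.04))
        put(f"eye_{side}", (sgn * 0.03, w.torso + 0.24, 0.04))
        put(f"ear_{side}", (sgn * 0.07, w.torso + 0.22, 0.0))
        phase = 0.0 if side == "left" else np.pi
        hip = pelvis + np.array([sgn * 0.09, -0.05, 0.0])
        put(f"hip_{side}", (sgn * 0.09, -0.05, 0.0))
        # radial ankle swing: |ankle - pelvis| == r(t) exactly
        r = w.leg + w.swing_amp * np.sin(2 * np.pi * f_stride * t + phase)
        theta = 0.35 * np.sin(2 * np.pi * f_stride * t + phase)
        direction = np.stack(
            [np.zeros(n), -np.cos(theta), np.sin(theta)], axis=1)
        ankle = pelvis + r[:, None] * direction
        pos[:, J[f"ankle_{side}"], :] = ankle
        pos[:, J[f"knee_{side}"], :] = 0.5 * (hip + ankle)
        pos[:, J[f"foot_{side}"], :] = ankle + np.array([0.0, -0.05, 0.10])
    return pos


def simulate_trial(walker: WalkerParams | None = None,
                   vibe: VibeParams | None = None,
                   config: TrialConfig | None = None,
                   seed: int | np.random.Generator | None = None,
                   ) -> tuple[JointStream, VibrationRecord | None, TrialTruth]:
    """Simulate one hallway trial: skeleton stream, vibration record, truth.

    ``vibe=None`` skips the floor-array half (cheap skeleton-only trials).
    """
    w = walker or WalkerParams()
    cfg = config or TrialConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    u_of_t, t_of_u, total = _trajectory(w.speed, w.accel_tail_s,
                                        cfg.hallway_length)
    if w.speed * w.accel_tail_s / 2.0 > cfg.accel_zone:
        raise ValueError("acceleration ramp exceeds the acceleration zone")

    # -- ground-truth heel strikes: inside the monitored zone, one step
    #    length apart, so that speed = d(position)/d(time) exactly.
    sl = w.step_length
    n_steps = int(np.floor(cfg.monitored_zone / sl)) + 1
    step_u = cfg.monitored_start + sl * np.arange(n_steps)
    step_t = t_of_u(step_u)

    # -- skeleton stream
    n_frames = int(np.floor(total * w.fps)) + 1
    dt = np.full(n_frames, 1.0 / w.fps)
    dt[1:] += rng.normal(0.0, w.timestamp_jitter_sd, n_frames - 1)
    dt = np.maximum(dt, 1e-4)
    t_frames = np.cumsum(dt) - dt[0]
    u = u_of_t(t_frames)
    f_step = w.cadence / 60.0
    pelvis = np.stack(
        [w.sway_amp * np.sin(2 * np.pi * f_step * t_frames / 2.0),
         0.95 + w.bob_amp * np.sin(2 * np.pi * f_step * t_frames),
         w.start_u + u],
        axis=1,
    )
    pos = _skeleton_positions(t_frames, pelvis, w)
    pos += rng.normal(0.0, w.joint_noise_sd, pos.shape)
    drop = rng.random((n_frames, pos.shape[1])) < w.dropout_prob
    drop[t_frames < w.lead_dropout_s, :] = True
    drop[t_frames > total - w.tail_dropout_s, :] = True
    pos[drop] = np.nan
    stream = JointStream(t_frames, pos)

    truth = TrialTruth(speed=w.speed, cadence=w.cadence, step_times=step_t,
                       step_positions=step_u, daq_lag=0.0, dropout_mask=drop)
    if vibe is None:
        return stream, None, truth

    # -- floor-vibration record
    v = vibe
    layout, groups, sync_pair = default_sensor_layout(cfg)
    fs = v.sample_rate
    n = int(np.ceil(total * fs))
    data = rng.normal(0.0, v.noise_sd, (len(groups), n)) if v.noise_sd > 0 \
        else np.zeros((len(groups), n))
    half_span = 5.0 * v.burst_sd
    v_walk = layout[:, 1].mean()
    for k in range(n_steps):
        amp_k = v.amplitude * float(np.exp(rng.normal(0.0, v.amp_jitter))) \
            if v.amp_jitter > 0 else v.amplitude
        for c in range(len(groups)):
            if v.distance_mode == "euclidean":
                d = float(np.hypot(step_u[k] - layout[c, 0],
                                   v_walk - layout[c, 1]))
            else:
                d = float(abs(step_u[k] - layout[c, 0]))
            a = amp_k * np.exp(-v.decay_alpha * d / 2.0)
            # a sensor on the late-clock DAQ records event tau at tau - lag
            tau = step_t[k] - (v.daq_lag if groups[c] == "right" else 0.0)
            i0 = max(0, int(np.floor((tau - half_span) * fs)))
            i1 = min(n, int(np.ceil((tau + half_span) * fs)) + 1)
            ts = np.arange(i0, i1) / fs - tau
            data[c, i0:i1] += a * np.exp(-0.5 * (ts / v.burst_sd) ** 2) \
                * np.sin(2 * np.pi * v.center_freq * ts)
    record = VibrationRecord(sample_rate=fs, data=data, layout=layout,
                             daq_group=groups, sync_pair=sync_pair)
    truth.daq_lag = v.daq_lag
    return stream, record, truth


def static_skeleton_stream(torso: float = 0.6, leg: float = 0.9,
                           shoulder: float = 0.4, n_frames: int = 100,
                           noise_sd: float = 0.0, fps: float = 30.0,
                           seed: int | np.random.Generator | None = None
                           ) -> JointStream:
    """A rigid standing skeleton with known geometry (for body-dimension
    checks): torso = pelvis-to-neck, each leg = hip-to-knee plus
    knee-to-ankle exactly, shoulders ``shoulder`` apart; no gait, optional
    isotropic joint noise."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    w = WalkerParams(torso=torso, leg=leg, shoulder=shoulder, swing_amp=0.0,
                     sway_amp=0.0, bob_amp=0.0)
    pelvis = np.tile(np.array([0.0, 0.95, 2.0]), (n_frames, 1))
    pos = _skeleton_positions(t, pelvis, w)
    J = {name: i for i, name in enumerate(AZURE_KINECT_JOINTS)}
    for side in ("left", "right"):  # straight legs: segment sum == leg
        hip = pos[:, J[f"hip_{side}"], :]
        pos[:, J[f"ankle_{side}"], :] = hip + np.array([0.0, -leg, 0.0])
        pos[:, J[f"knee_{side}"], :] = hip + np.array([0.0, -leg / 2, 0.0])
    if noise_sd > 0:
        pos += rng.normal(0.0, noise_sd, pos.shape)
    return JointStream(t, pos)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Generating model for a synthetic surgical cohort.

    Subject-level true gait parameters follow the regular-pace cohort
    distributions (speed mean 1.2 m/s, SD 0.27; cadence mean 111
    steps/min, SD 11), with age pulling both down.  Fast-pace trials
    scale speed by 1.25 and cadence by 1.14.  Each metric is observed
    through its device: the skeleton camera measures speed precisely but
    cadence poorly; the floor array measures cadence precisely but speed
    noisily; the stopwatch adds reading error (and occasional gross
    errors) to the full-hallway walk time, which also includes the
    acceleration tails.  Frailty scores and the postoperative recovery
    questionnaire are generated by monotone links to the gait metrics.
    """

    n: int = 77
    speed_mean: float = 1.2
    speed_sd: float = 0.27
    cadence_mean: float = 111.0
    cadence_sd: float = 11.0
    within_subject_speed_sd: float = 0.04
    within_subject_cadence_sd: float = 1.5
    kinect_speed_noise_sd: float = 0.01    # precise pelvis fit
    kinect_cadence_noise_sd: float = 30.0  # poor ankle tracking: ICC ~ 0.1
    accel_speed_noise_sd: float = 0.25     # noisy localization: ICC ~ 0.5
    accel_cadence_noise_sd: float = 1.0    # crisp heel strikes
    stopwatch_reading_sd_s: float = 0.3
    stopwatch_gross_error_prob: float = 0.05
    fast_speed_factor: float = 1.25
    fast_cadence_factor: float = 1.14
    age_mean: float = 66.0
    age_sd: float = 13.0
    male_frac: float = 0.6
    age_speed_slope: float = -0.007   # m/s per year
    age_cadence_slope: float = -0.22  # steps/min per year
    female_area_mean: float = 0.72    # m^2
    female_area_sd: float = 0.06
    male_area_shift_sd: float = 1.5   # in female-SD units
    hallway_length: float = 14.0
    accel_penalty_s: float = 1.0      # extra stopwatch time from the ramps
    qor_interaction_logodds: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        for name in ("speed_sd", "cadence_sd", "within_subject_speed_sd",
                     "within_subject_cadence_sd", "stopwatch_reading_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_cohort(params: CohortParams | None = None,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: subjects table + trial-level gait measurements.

    Every subject performs 2 repeats x 2 paces.  Returns ``(subjects,
    trials)`` data frames; ``trials`` holds per-trial true values and the
    per-device observed values (kinect/accelerometer/stopwatch).
    """
    c = params or CohortParams()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = c.n

    age = np.clip(rng.normal(c.age_mean, c.age_sd, n), 25.0, 95.0)
    male = rng.random(n) < c.male_frac
    resid_speed_sd = np.sqrt(max(c.speed_sd**2
                                 - (c.age_speed_slope * c.age_sd) ** 2, 1e-6))
    resid_cad_sd = np.sqrt(max(c.cadence_sd**2
                               - (c.age_cadence_slope * c.age_sd) ** 2, 1e-6))
    speed = (c.speed_mean + c.age_speed_slope * (age - c.age_mean)
             + rng.normal(0.0, resid_speed_sd, n))
    speed = np.clip(speed, 0.3, None)
    cadence = (c.cadence_mean + c.age_cadence_slope * (age - c.age_mean)
               + rng.normal(0.0, resid_cad_sd, n))
    cadence = np.clip(cadence, 60.0, None)
    area = (c.female_area_mean
            + male * c.male_area_shift_sd * c.female_area_sd
            + rng.normal(0.0, c.female_area_sd, n))

    # frailty: slower, older subjects score higher (monotone link + noise)
    latent = (-(speed - c.speed_mean) / c.speed_sd
              + 0.3 * (age - c.age_mean) / c.age_sd
              + rng.normal(0.0, 0.8, n))
    fried = np.clip(np.round(1.0 + 1.1 * latent), 0, 5).astype(int)

    # postoperative recovery: the speed x cadence interaction drives the
    # odds of a good-recovery questionnaire score
    zs = (speed - c.speed_mean) / c.speed_sd
    zc = (cadence - c.cadence_mean) / c.cadence_sd
    eta = 0.4 + 0.2 * zs + 0.2 * zc + c.qor_interaction_logodds * zs * zc
    good = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    qor15 = np.where(good, rng.integers(122, 151, n), rng.integers(70, 122, n))

    activity = rng.choice([">3x_week", "1-2x_week", "1-3x_month", "hardly_ever"],
                          size=n, p=[0.43, 0.19, 0.08, 0.30])
    subjects = pd.DataFrame({
        "id": [f"S{i:03d}" for i in range(n)],
        "age": age,
        "sex": np.where(male, "M", "F"),
        "fried_score": fried,
        "qor15": qor15,
        "activity_level": activity,
        "true_speed": speed,
        "true_cadence": cadence,
        "body_area": area,
    })

    rows = []
    for i in range(n):
        for pace, (fv, fc) in (("regular", (1.0, 1.0)),
                               ("fast", (c.fast_speed_factor,
                                         c.fast_cadence_factor))):
            for rep in (1, 2):
                s_true = speed[i] * fv + rng.normal(0.0, c.within_subject_speed_sd)
                k_true = cadence[i] * fc + rng.normal(0.0, c.within_subject_cadence_sd)
                s_true = max(s_true, 0.2)
                walk_time = (c.hallway_length / s_true + c.accel_penalty_s
                             + rng.normal(0.0, c.stopwatch_reading_sd_s))
                if rng.random() < c.stopwatch_gross_error_prob:
                    walk_time *= rng.uniform(0.35, 0.6)
                rows.append({
                    "id": subjects.at[i, "id"],
                    "pace": pace,
                    "repeat": rep,
                    "true_speed": s_true,
                    "true_cadence": k_true,
                    "kinect_speed": s_true + rng.normal(0.0, c.kinect_speed_noise_sd),
                    "accel_speed": s_true + rng.normal(0.0, c.accel_speed_noise_sd),
                    "accel_cadence": k_true + rng.normal(0.0, c.accel_cadence_noise_sd),
                    "kinect_cadence": k_true + rng.normal(0.0, c.kinect_cadence_noise_sd),
                    "stopwatch_speed": c.hallway_length / max(walk_time, 1.0),
                })
    return subjects, pd.DataFrame(rows)
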