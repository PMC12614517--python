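"""Footstep detection, cadence, localization and speed from floor vibration.

Processing chain for one trial of a floor-mounted accelerometer array:

1. ``preprocess`` -- linear detrend, then zero-phase (forward-backward)
   Butterworth filtering: 5 Hz high-pass and 250 Hz low-pass, order 2 each.
2. ``synchronize`` -- the two wireless acquisition units run independent
   clocks; their offset is the lag of the maximum cross-correlation
   between the two physically co-located sensors, applied to the second
   unit's channels, after which the redundant duplicate sensor is dropped.
3. ``snr_max`` -- per-sensor mean power (acceleration squared) in
   non-overlapping 0.02 s windows, each sensor normalized by its own
   median power so that quiet floor has SNR ~ 1; SNRmax is the per-window
   maximum across sensors.
4. ``detect_steps`` -- peaks of SNRmax at least 9 robust standard
   deviations above the median, spaced >= 0.3 s apart; peak times are the
   heel strikes.
5. ``localize_steps`` -- per-step window energies across sensors fall off
   exponentially with distance from the strike; a log-linear least-squares
   fit along the hallway axis places each step.
6. ``kalman_speed`` -- a constant-speed Kalman filter over the noisy step
   positions (with innovation gating against gross mislocalizations)
   yields the floor-only gait-speed estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io_model import GaitMetrics, VibrationRecord

__all__ = [
    "VibrationError",
    "SnrSeries",
    "StepSeries",
    "StepCadence",
    "KalmanResult",
    "preprocess",
    "synchronize",
    "snr_max",
    "detect_steps",
    "cadence_from_steps",
    "instantaneous_cadence_z",
    "localize_steps",
    "kalman_speed",
    "floor_metrics",
]


class VibrationError(ValueError):
    """Raised when a record cannot support the requested computation."""


@dataclass
class SnrSeries:
    """Windowed, median-normalized signal power across sensors."""

    window_times: np.ndarray       # centers of consecutive windows, s
    snr_max: np.ndarray            # per-window max across sensors
    per_sensor_snr: np.ndarray     # (windows, sensors)
    window_s: float

    def __post_init__(self) -> None:
        if self.per_sensor_snr.shape[0] != len(self.window_times):
            raise VibrationError("per_sensor_snr rows must match window count")


@dataclass
class StepSeries:
    """Detected heel strikes, optionally localized along the hallway."""

    step_times: np.ndarray                 # s, strictly increasing
    step_positions: np.ndarray | None = None   # m along hallway (NaN = failed)
    decay_alpha: float | None = None       # fitted energy decay rate, 1/m

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if self.step_times.size and np.any(np.diff(self.step_times) <= 0):
            raise VibrationError("step times must be strictly increasing")
        if self.step_positions is not None:
            self.step_positions = np.asarray(self.step_positions, dtype=float)
            if self.step_positions.shape != self.step_times.shape:
                raise VibrationError("positions must match step times")

    @property
    def n_steps(self) -> int:
        return self.step_times.size

    @property
    def delta_t(self) -> np.ndarray:
        """Seconds between consecutive detected steps."""
        return np.diff(self.step_times)


@dataclass
class StepCadence:
    cadence: float        # steps/min
    n_gaps_used: int
    n_outliers: int
    n_missed: int         # steps inferred hidden inside outlier gaps


@dataclass
class KalmanResult:
    speed: float                   # m/s, terminal smoothed speed
    smoothed_positions: np.ndarray
    n_gated: int                   # observations rejected by innovation gating
    measurement_sd: float


# ---------------------------------------------------------------------------
# preprocessing and synchronization
# ---------------------------------------------------------------------------

def preprocess(record: VibrationRecord, hp_hz: float = 5.0,
               lp_hz: float = 250.0, order: int = 2,
               edge_taper_s: float = 0.25) -> VibrationRecord:
    """Detrend and zero-phase band-limit every channel.

    Each channel is linearly detrended (removing offset and slope), then
    forward-backward filtered with a high-pass at ``hp_hz`` and a low-pass
    at ``lp_hz`` (Butterworth, given order).  The forward-backward pass
    squares each filter's magnitude response and cancels its phase, so
    impulse timing is preserved.  A half-cosine taper over the first and
    last ``edge_taper_s`` seconds suppresses the filter's edge transient,
    which would otherwise mimic an impulsive event at the record
    boundaries (or inside the record, once synchronization shifts a
    channel).
    """
    if record.sample_rate <= 500.0:
        raise VibrationError("sample rate must exceed 500 Hz")
    sos_hp = sps.butter(order, hp_hz, btype="highpass", fs=record.sample_rate,
                        output="sos")
    sos_lp = sps.butter(order, lp_hz, btype="lowpass", fs=record.sample_rate,
                        output="sos")
    if record.n_samples < 3 * 2 * order + 3:
        raise VibrationError("channel shorter than filter warm-up length")
    out = np.empty_like(record.data)
    for c in range(record.n_channels):
        x = sps.detrend(record.data[c], type="linear")
        x = sps.sosfiltfilt(sos_hp, x)
        x = sps.sosfiltfilt(sos_lp, x)
        out[c] = x
    n_taper = int(round(edge_taper_s * record.sample_rate))
    if 0 < n_taper < record.n_samples // 2:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))
        out[:, :n_taper] *= ramp[None, :]
        out[:, -n_taper:] *= ramp[::-1][None, :]
    return replace(record, data=out)


def synchronize(record: VibrationRecord) -> tuple[VibrationRecord, float]:
    """Align the two acquisition units' clocks and drop the duplicate sensor.

    The lag maximizing the cross-correlation between the co-located
    ``sync_pair`` channels is applied (as an integer-sample shift) to every
    channel of the second pair member's DAQ group; the first pair member --
    the redundant duplicate wired to the other unit purely for
    synchronization -- is then removed from the record.

    Returns the synchronized record (one channel fewer) and the recovered
    lag in seconds (positive = second group's clock started late).
    """
    if record.sync_pair is None:
        raise VibrationError("record has no sync_pair")
    i_dup, i_ref = record.sync_pair
    a = record.data[i_dup]
    b = record.data[i_ref]
    if not (np.any(a) and np.any(b)):
        raise VibrationError("sync channels are silent")
    cc = sps.correlate(a, b, mode="full", method="fft")
    if np.ptp(cc) <= 1e-12 * max(1.0, float(np.max(np.abs(cc)))):
        raise VibrationError("flat cross-correlation: no footsteps on sync channels")
    lag_samples = int(np.argmax(cc)) - (len(b) - 1)
    lag_s = lag_samples / record.sample_rate

    shifted = record.data.copy()
    group = record.daq_group[i_ref]
    for c in range(record.n_channels):
        if record.daq_group[c] == group:
            shifted[c] = _shift(record.data[c], lag_samples)
    keep = [c for c in range(record.n_channels) if c != i_dup]
    return (
        VibrationRecord(
            sample_rate=record.sample_rate,
            data=shifted[keep],
            layout=record.layout[keep],
            daq_group=tuple(record.daq_group[c] for c in keep),
            sync_pair=None,
        ),
        lag_s,
    )


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift a series by k samples (positive = delay), zero-filled."""
    out = np.zeros_like(x)
    if k > 0:
        out[k:] = x[:-k]
    elif k < 0:
        out[:k] = x[-k:]
    else:
        out[:] = x
    return out


# ---------------------------------------------------------------------------
# footstep detection
# ---------------------------------------------------------------------------

def snr_max(record: VibrationRecord, window_s: float = 0.02) -> SnrSeries:
    """Median-normalized windowed power, maximized across sensors.

    Mean power (acceleration squared) is computed in non-overlapping
    ``window_s`` windows per sensor, divided by that sensor's median
    window power (so each sensor's SNR series has median exactly 1 and is
    invariant to any per-channel gain), and the per-window maximum across
    sensors forms the detection statistic SNRmax.
    """
    win = int(round(window_s * record.sample_rate))
    if win < 1 or record.n_samples < win:
        raise VibrationError("record shorter than one window")
    n_win = record.n_samples // win
    x = record.data[:, : n_win * win]
    power = (x**2).reshape(record.n_channels, n_win, win).mean(axis=2)
    med = np.median(power, axis=1, keepdims=True)
    if np.any(med <= 0):
        raise VibrationError("a channel has zero median power")
    snr = power / med
    centers = (np.arange(n_win) + 0.5) * win / record.sample_rate
    return SnrSeries(window_times=centers, snr_max=snr.max(axis=0),
                     per_sensor_snr=snr.T, window_s=win / record.sample_rate)


def detect_steps(snr: SnrSeries, k_sigma: float = 9.0, mad_cut: float = 3.0,
                 min_dist_s: float = 0.3) -> StepSeries:
    """Adaptive-threshold peak detection on SNRmax.

    The noise scale sigma_SNR is the standard deviation of SNRmax after
    one-sided exclusion of points above median + ``mad_cut`` * MAD (the
    footstep peaks themselves are positive excursions).  Peaks must reach
    median(SNRmax) + ``k_sigma`` * sigma_SNR and be at least ``min_dist_s``
    apart (highest-first suppression).
    """
    x = snr.snr_max
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    keep = x <= med + mad_cut * mad
    sigma = float(np.std(x[keep]))
    if sigma == 0.0:
        raise VibrationError("degenerate constant SNR signal")
    height = med + k_sigma * sigma
    distance = max(1, int(round(min_dist_s / snr.window_s)))
    peaks, _ = sps.find_peaks(x, height=height, distance=distance)
    return StepSeries(step_times=snr.window_times[peaks])


def _mad_outlier_mask(dt: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """True = keep.  Median +/- n_mad * MAD; MAD = 0 falls back to a
    one-sided 1.5 * median rule (handles perfectly periodic data)."""
    med = float(np.median(dt))
    mad = float(np.median(np.abs(dt - med)))
    if mad > 0:
        return np.abs(dt - med) <= n_mad * mad
    return dt <= 1.5 * med


def cadence_from_steps(steps: StepSeries, n_mad: float = 3.0) -> StepCadence:
    """Cadence in steps/min as 60 / mean(delta-t) after outlier removal.

    Missed steps and pauses inflate individual inter-step gaps; gaps
    outside median +/- ``n_mad`` MADs are removed before averaging.  Each
    removed long gap implies round(gap/median) - 1 hidden steps, reported
    as ``n_missed``.
    """
    if steps.n_steps < 4:
        raise VibrationError("need >= 4 detected steps for cadence")
    dt = steps.delta_t
    keep = _mad_outlier_mask(dt, n_mad)
    if not np.any(keep):
        raise VibrationError("all inter-step gaps removed as outliers")
    med = float(np.median(dt[keep]))
    long_gaps = dt[~keep & (dt > med)]
    n_missed = int(np.sum(np.maximum(np.round(long_gaps / med) - 1, 1)))
    return StepCadence(cadence=60.0 / float(np.mean(dt[keep])),
                       n_gaps_used=int(keep.sum()),
                       n_outliers=int((~keep).sum()),
                       n_missed=n_missed)


def instantaneous_cadence_z(steps: StepSeries) -> np.ndarray:
    """Per-gap instantaneous cadence (60/delta-t), Z-scored within trial.

    Missed steps double a gap and so produce strongly negative Z-scores;
    the Z distribution over a cohort is the step-capture quality check.
    """
    if steps.n_steps < 3:
        raise VibrationError("need >= 3 steps for instantaneous cadence")
    c = 60.0 / steps.delta_t
    sd = float(np.std(c))
    if sd == 0.0:
        raise VibrationError("zero variance in instantaneous cadence")
    return (c - float(np.mean(c))) / sd


# ---------------------------------------------------------------------------
# localization and speed
# ---------------------------------------------------------------------------

def _step_energies(record: VibrationRecord, step_times: np.ndarray,
                   window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-step, per-sensor energy in +/-window_s around each step time,
    normalized by each sensor's median window energy (gain cancels).
    Returns (energies (steps, sensors), noise_floor per sensor)."""
    fs = record.sample_rate
    half = max(1, int(round(window_s * fs)))
    n = record.n_samples
    # background scale: median energy of disjoint windows of the same length
    n_bg = n // (2 * half)
    bg = (record.data[:, : n_bg * 2 * half] ** 2).reshape(
        record.n_channels, n_bg, 2 * half).sum(axis=2)
    floor = np.median(bg, axis=1)
    # a silent (noiseless) channel has zero background; leave it unscaled
    scale = np.where(floor > 0, floor, 1.0)
    energies = np.empty((len(step_times), record.n_channels))
    for k, t in enumerate(step_times):
        c = int(round(t * fs))
        a, b = max(0, c - half), min(n, c + half)
        energies[k] = (record.data[:, a:b] ** 2).sum(axis=1)
    return energies / scale[None, :], floor


def _fit_position(log_e: np.ndarray, u_sensors: np.ndarray,
                  u_grid: np.ndarray, alpha: float | None) -> tuple[float, float]:
    """1-D maximum of the exponential-decay model log E = log E0 - alpha*d.

    For each candidate position the decay fit is linear (closed form); the
    returned position minimizes the residual sum of squares, with alpha
    profiled out (constrained >= 0) unless fixed.
    """
    best = (np.inf, np.nan, 0.0)
    for u in u_grid:
        d = np.abs(u - u_sensors)
        if alpha is None:
            dc = d - d.mean()
            yc = log_e - log_e.mean()
            denom = float(np.sum(dc**2))
            slope = float(np.sum(dc * yc)) / denom if denom > 0 else 0.0
            a = max(0.0, -slope)
        else:
            a = alpha
        resid = log_e - (np.mean(log_e + a * d) - a * d)
        sse = float(np.sum(resid**2))
        if sse < best[0]:
            best = (sse, float(u), a)
    return best[1], best[2]


def localize_steps(record: VibrationRecord, steps: StepSeries,
                   decay_alpha: float | None = None,
                   window_s: float = 0.05, grid_step: float = 0.02,
                   floor_factor: float = 3.0) -> StepSeries:
    """Place each detected step on the hallway axis from sensor energies.

    The footstep energy observed at sensor s is modelled as
    E_s = E_0 * exp(-alpha * d_s) with d_s the along-hallway distance from
    the strike; positions come from a profile least-squares fit of
    log E_s over a fine grid of candidate positions (the across-hallway
    offset is absorbed into the effective decay).  Energies are normalized
    per sensor by the sensor's median window energy, which cancels any
    per-channel gain.  ``decay_alpha=None`` fits the decay rate per trial
    jointly with the positions, since floors are not homogeneous media.

    Steps whose energies never rise above ``floor_factor`` times the noise
    floor on any sensor get NaN positions.
    """
    if steps.n_steps == 0:
        return replace(steps, step_positions=np.empty(0))
    energies, floor = _step_energies(record, steps.step_times, window_s)
    noisy = bool(np.all(floor > 0))
    u_sensors = record.layout[:, 0]
    lo = float(u_sensors.min()) - 2.0
    hi = float(u_sensors.max()) + 2.0
    coarse = np.arange(lo, hi + grid_step / 2, grid_step)
    positions = np.full(steps.n_steps, np.nan)
    alphas = []
    for k in range(steps.n_steps):
        e = np.maximum(energies[k], 1e-300)
        if noisy and np.all(e < floor_factor):
            continue  # below noise floor everywhere
        log_e = np.log(e)
        u0, a0 = _fit_position(log_e, u_sensors, coarse, decay_alpha)
        fine = np.arange(u0 - grid_step, u0 + grid_step, grid_step / 10)
        u1, a1 = _fit_position(log_e, u_sensors, fine, decay_alpha)
        positions[k] = u1
        alphas.append(a1)
    if not alphas:
        raise VibrationError("all steps below noise floor")
    return replace(steps, step_positions=positions,
                   decay_alpha=float(np.median(alphas)))


def kalman_speed(steps: StepSeries, process_var: float = 1e-4,
                 measurement_var: float | None = None,
                 gate_sigma: float = 3.0, gate_floor: float = 0.5) -> KalmanResult:
    """Gait speed from localized steps via a constant-speed Kalman filter.

    State [position, speed] evolves with a constant-speed kinematic model;
    the noisy step positions are the observations.  The measurement
    variance defaults to a robust (MAD-based) estimate from the residuals
    of a Theil-Sen pre-fit, and observations whose innovation exceeds
    ``gate_sigma`` standard deviations are skipped -- this absorbs steps
    mistakenly localized far from the track.  Because the robust noise
    estimate can collapse on small trials, the gate never narrows below
    ``gate_floor`` meters (gross mislocalizations are meters off; genuine
    localization scatter is decimeters).  The reported speed is the
    terminal speed of the Rauch-Tung-Striebel smoother (the slope of the
    smoothed positions).
    """
    if steps.step_positions is None:
        raise VibrationError("steps have no positions; run localize_steps first")
    t = steps.step_times
    z = steps.step_positions
    ok = np.isfinite(z)
    t, z = t[ok], z[ok]
    if len(t) < 4:
        raise VibrationError("need >= 4 localized steps")
    if np.any(np.diff(t) <= 0):
        raise VibrationError("non-increasing step times")

    slope, intercept, *_ = stats.theilslopes(z, t)
    resid = z - (slope * t + intercept)
    robust_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if measurement_var is not None:
        R = measurement_var
    else:
        # variance of the pre-fit residuals, with only gross outliers
        # (beyond the gate floor / 3 MADs) excluded -- the raw MAD alone
        # can collapse on small trials and starve the filter via gating
        inlier = np.abs(resid - np.median(resid)) <= max(3 * robust_sd,
                                                         gate_floor)
        r_in = resid[inlier]
        R = max(float(np.var(r_in, ddof=1)) if len(r_in) > 1 else 0.0, 1e-10)

    n = len(t)
    x = np.array([slope * t[0] + intercept, slope])
    P = np.diag([R, 4.0 * R])
    H = np.array([1.0, 0.0])
    xs_f = np.empty((n, 2))
    Ps_f = np.empty((n, 2, 2))
    xs_p = np.empty((n, 2))
    Ps_p = np.empty((n, 2, 2))
    Fs = np.empty((n, 2, 2))
    n_gated = 0
    for k in range(n):
        if k == 0:
            F = np.eye(2)
            Q = np.zeros((2, 2))
        else:
            dt = t[k] - t[k - 1]
            F = np.array([[1.0, dt], [0.0, 1.0]])
            Q = process_var * np.array([[dt**3 / 3, dt**2 / 2],
                                        [dt**2 / 2, dt]])
        xp = F @ x
        Pp = F @ P @ F.T + Q
        Fs[k], xs_p[k], Ps_p[k] = F, xp, Pp
        S = float(H @ Pp @ H) + R
        innov = z[k] - float(H @ xp)
        gate = max(gate_sigma * np.sqrt(S), gate_floor)
        if k > 0 and abs(innov) > gate:
            # skipped observation: inflate uncertainty so that consecutive
            # gating widens the gate and the filter re-acquires the track
            # instead of locking onto a bad prediction
            x, P = xp, 4.0 * Pp
            n_gated += 1
        else:
            K = (Pp @ H) / S
            x = xp + K * innov
            P = (np.eye(2) - np.outer(K, H)) @ Pp
        xs_f[k], Ps_f[k] = x, P
    # RTS smoother
    xs_s = xs_f.copy()
    Ps_s = Ps_f.copy()
    for k in range(n - 2, -1, -1):
        G = Ps_f[k] @ Fs[k + 1].T @ np.linalg.inv(Ps_p[k + 1])
        xs_s[k] = xs_f[k] + G @ (xs_s[k + 1] - xs_p[k + 1])
        Ps_s[k] = Ps_f[k] + G @ (Ps_s[k + 1] - Ps_p[k + 1]) @ G.T
    return KalmanResult(speed=float(xs_s[-1, 1]),
                        smoothed_positions=xs_s[:, 0],
                        n_gated=n_gated,
                        measurement_sd=float(np.sqrt(R)))


def floor_metrics(record: VibrationRecord, k_sigma: float = 9.0,
                  mad_cut: float = 3.0, min_dist_s: float = 0.3,
                  decay_alpha: float | None = None) -> GaitMetrics:
    """Run the full floor pipeline on one raw trial: cadence + speed."""
    rec = preprocess(record)
    if rec.sync_pair is not None:
        rec, _ = synchronize(rec)
    steps = detect_steps(snr_max(rec), k_sigma=k_sigma, mad_cut=mad_cut,
                         min_dist_s=min_dist_s)
    if steps.n_steps < 4:
        return GaitMetrics(n_steps_detected=steps.n_steps,
                           source={"speed": "accelerometer",
                                   "cadence": "accelerometer"},
                           quality_flag="too_few_steps")
    cad = cadence_from_steps(steps)
    steps = localize_steps(rec, steps, decay_alpha=decay_alpha)
    speed = kalman_speed(steps).speed
    return GaitMetrics(
        speed=max(speed, 0.0),
        cadence=cad.cadence,
        n_steps_detected=steps.n_steps,
        source={"speed": "accelerometer", "cadence": "accelerometer"},
        quality_flag="ok",
    )
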