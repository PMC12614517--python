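"""Gait speed, cadence, and body dimensions from skeleton joint streams.

Gait speed
----------
The 3-D displacement of the pelvis from its first tracked position,

    d_i = || p_i - p_0 ||_2 ,

grows linearly in time during steady-state walking, so gait speed is the
slope of an ordinary least-squares fit d_i = gs * t_i + d_0.  Acceleration
and deceleration at the ends of the hallway bend the series away from a
line; the fit is therefore trimmed iteratively (one sample from each end
per iteration) until R^2 of the linear fit exceeds a threshold (default
0.98).  If the minimum fit length is reached first, the fit is flagged
``trim_failed`` instead of being trimmed by hand.

Cadence
-------
The "foot swing" signal FS_i = || ankle_i - pelvis_i ||_2 of each foot
oscillates at the stride frequency (one stride = two steps).  Cadence in
steps/min is 120 * f_max_avg, where f_max_avg averages the dominant FFT
frequency of the left and right FS signals inside a physiological search
band.

Dropout handling: gaps of <= 2 frames are linearly interpolated; longer
interior gaps split the series and the longest clean segment is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import GaitMetrics, JointStream

__all__ = [
    "GaitError",
    "DistanceSeries",
    "SpeedFit",
    "FootSwingSignal",
    "CadenceFFT",
    "pelvis_distance",
    "clean_distance",
    "fit_gait_speed",
    "foot_swing",
    "cadence_fft",
    "body_dimensions",
    "normalize_body_area",
    "skeleton_metrics",
]


class GaitError(ValueError):
    """Raised when a stream cannot support the requested estimate."""


@dataclass
class DistanceSeries:
    """Pelvis displacement-from-start over time, with validity mask."""

    timestamps: np.ndarray
    distance: np.ndarray
    clean_mask: np.ndarray
    flag: str = "ok"  # ok | split

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.clean_mask = np.asarray(self.clean_mask, dtype=bool)
        if not (len(self.timestamps) == len(self.distance) == len(self.clean_mask)):
            raise GaitError("distance series fields must have equal length")


@dataclass
class SpeedFit:
    """Result of the trimmed least-squares speed fit."""

    gs: float          # gait speed, m/s (slope)
    d0: float          # intercept, m
    r2: float
    n_kept: int
    trim_left: int
    trim_right: int
    converged: bool


@dataclass
class FootSwingSignal:
    """Ankle-to-pelvis 3-D distance per side; NaN where untracked."""

    timestamps: np.ndarray
    fs_left: np.ndarray
    fs_right: np.ndarray


@dataclass
class CadenceFFT:
    cadence: float     # steps/min
    f_left: float      # dominant stride frequency, Hz
    f_right: float
    df: float          # FFT bin width, Hz


def pelvis_distance(stream: JointStream) -> DistanceSeries:
    """Euclidean pelvis displacement from its first tracked position."""
    p = stream.joint("pelvis")
    valid = ~np.isnan(p[:, 0])
    if valid.sum() < 2:
        raise GaitError("need >= 2 frames with a tracked pelvis")
    p0 = p[np.argmax(valid)]
    d = np.linalg.norm(p - p0[None, :], axis=1)
    d[~valid] = np.nan
    return DistanceSeries(stream.timestamps.copy(), d, valid)


def _interp_gaps(t: np.ndarray, x: np.ndarray, valid: np.ndarray,
                 max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior invalid runs of length <= max_gap."""
    x = x.copy()
    valid = valid.copy()
    n = len(x)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        interior = i > 0 and j < n
        if interior and (j - i) <= max_gap:
            x[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [x[i - 1], x[j]])
            valid[i:j] = True
        i = j
    return x, valid


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def clean_distance(series: DistanceSeries, max_gap: int = 2,
                   min_points: int = 30) -> DistanceSeries:
    """Remove edge dropouts and fill or split around interior ones.

    Leading/trailing dropout runs are removed; interior runs of at most
    ``max_gap`` samples are linearly interpolated from their neighbours;
    a longer interior run splits the series, in which case the longest
    contiguous clean segment is kept and the result flagged ``"split"``.
    """
    t, d, valid = series.timestamps, series.distance, series.clean_mask
    d, valid = _interp_gaps(t, d, valid, max_gap)
    segments = _runs(valid)
    if not segments:
        raise GaitError("no clean segment in distance series")
    lengths = [b - a for a, b in segments]
    a, b = segments[int(np.argmax(lengths))]
    if b - a < min_points:
        raise GaitError(
            f"longest clean segment has {b - a} samples (< {min_points})"
        )
    flag = "ok" if len(segments) == 1 else "split"
    # re-reference distance to the segment if its start moved is NOT done:
    # d is displacement from the first tracked pelvis position, which stays
    # a valid (affine) regressor for the slope fit.
    return DistanceSeries(t[a:b].copy(), d[a:b].copy(),
                          np.ones(b - a, dtype=bool), flag)


def _ols_line(t: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, r2).

    R^2 is the coefficient of determination, identical to the squared
    Pearson correlation of fit vs data for a simple linear regression.
    """
    slope, intercept = np.polyfit(t, d, 1)
    resid = d - (slope * t + intercept)
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0.0:
        return slope, intercept, 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), max(0.0, min(1.0, r2))


def fit_gait_speed(series: DistanceSeries, r2_threshold: float = 0.98,
                   min_points: int = 30, refine_tol: float = 1e-6) -> SpeedFit:
    """Trimmed least-squares gait-speed fit on a cleaned distance series.

    While R^2 of the linear fit stays at or below ``r2_threshold`` and more
    than ``min_points`` samples remain, one sample is removed from each end
    and the line refit.  Reaching the floor without exceeding the threshold
    marks the fit not converged (an automated stand-in for trimming by
    hand).

    Once the threshold is met, trimming continues as long as each further
    step still improves R^2 by more than ``refine_tol``: residual
    acceleration/deceleration tails keep R^2 climbing while they are being
    consumed, whereas on steady-state data (where residuals are pure
    noise) R^2 plateaus immediately.  This refinement removes the tail
    remnant that a 0.98 threshold alone can leave behind on long trials,
    where the tails are a small share of the total variance.
    """
    keep = series.clean_mask
    t = series.timestamps[keep]
    d = series.distance[keep]
    n0 = len(t)
    if n0 < min_points:
        raise GaitError(f"only {n0} samples (< {min_points}) to fit")
    lo, hi = 0, n0
    while True:
        slope, intercept, r2 = _ols_line(t[lo:hi], d[lo:hi])
        if r2 > r2_threshold:
            converged = True
            break
        if (hi - lo) - 2 < min_points:
            converged = False
            break
        lo += 1
        hi -= 1
    while converged and (hi - lo) - 2 >= min_points:
        s_next, i_next, r2_next = _ols_line(t[lo + 1:hi - 1], d[lo + 1:hi - 1])
        if r2_next <= r2 + refine_tol:
            break
        slope, intercept, r2 = s_next, i_next, r2_next
        lo += 1
        hi -= 1
    return SpeedFit(gs=slope, d0=intercept, r2=r2, n_kept=hi - lo,
                    trim_left=lo, trim_right=n0 - hi, converged=converged)


def foot_swing(stream: JointStream, max_gap: int = 2,
               min_coverage: float = 0.5) -> FootSwingSignal:
    """Ankle-to-pelvis distance per side, with short gaps interpolated."""
    for j in ("ankle_left", "ankle_right"):
        if j not in stream.joint_names:
            raise GaitError("ankle joints absent from stream")
    pelvis = stream.joint("pelvis")
    t = stream.timestamps
    out = {}
    for side in ("left", "right"):
        ankle = stream.joint(f"ankle_{side}")
        valid = ~np.isnan(ankle[:, 0]) & ~np.isnan(pelvis[:, 0])
        if valid.mean() < min_coverage:
            raise GaitError(
                f"ankle_{side}/pelvis tracked on {valid.mean():.0%} of frames "
                f"(< {min_coverage:.0%})"
            )
        fs = np.linalg.norm(ankle - pelvis, axis=1)
        fs[~valid] = np.nan
        fs, valid = _interp_gaps(t, fs, valid, max_gap)
        fs[~valid] = np.nan
        out[side] = fs
    return FootSwingSignal(t.copy(), out["left"], out["right"])


def _dominant_frequency(t: np.ndarray, x: np.ndarray,
                        band_hz: tuple[float, float],
                        min_duration_s: float,
                        pad_to_s: float) -> tuple[float, float]:
    """Dominant FFT frequency of an irregularly sampled signal.

    The signal is mean-removed, resampled onto a uniform grid at the
    median frame interval, and zero-padded so that the FFT bin width is at
    most ``1 / pad_to_s`` Hz.  Ties take the earliest frequency.
    """
    valid = np.isfinite(x)
    tv, xv = t[valid], x[valid]
    if len(tv) < 4 or tv[-1] - tv[0] < min_duration_s:
        raise GaitError(f"signal shorter than {min_duration_s} s")
    dt = float(np.median(np.diff(t)))
    grid = np.arange(tv[0], tv[-1] + dt / 2, dt)
    xi = np.interp(grid, tv, xv)
    xi = xi - xi.mean()
    nfft = 1
    while nfft < max(len(xi), int(np.ceil(pad_to_s / dt))):
        nfft *= 2
    freqs = np.fft.rfftfreq(nfft, dt)
    mag = np.abs(np.fft.rfft(xi, nfft))
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(sel):
        raise GaitError("empty frequency search band")
    idx = np.flatnonzero(sel)[np.argmax(mag[sel])]
    return float(freqs[idx]), float(freqs[1] - freqs[0])


def cadence_fft(fs: FootSwingSignal, band_hz: tuple[float, float] = (0.5, 1.5),
                min_duration_s: float = 3.0, pad_to_s: float = 100.0) -> CadenceFFT:
    """Cadence (steps/min) as 120 * mean dominant FS frequency.

    The default band 0.5-1.5 Hz spans stride frequencies for cadences of
    60-180 steps/min; DC is excluded by mean removal.  Zero-padding to a
    >= ``pad_to_s`` second window keeps the cadence granularity at or
    below 120 / pad_to_s steps/min (1.2 by default).
    """
    f_l, df = _dominant_frequency(fs.timestamps, fs.fs_left, band_hz,
                                  min_duration_s, pad_to_s)
    f_r, _ = _dominant_frequency(fs.timestamps, fs.fs_right, band_hz,
                                 min_duration_s, pad_to_s)
    return CadenceFFT(cadence=120.0 * 0.5 * (f_l + f_r),
                      f_left=f_l, f_right=f_r, df=df)


_DIM_JOINTS = ("pelvis", "neck", "shoulder_left", "shoulder_right",
               "hip_left", "knee_left", "ankle_left",
               "hip_right", "knee_right", "ankle_right")


def body_dimensions(stream: JointStream,
                    min_frames: int = 10) -> tuple[float, float, float]:
    """Estimate (body_length, shoulder_width, body_area) from a stream.

    Per frame: torso length = pelvis-to-neck distance; leg length =
    hip-to-knee plus knee-to-ankle, averaged over sides; shoulder width =
    left-right shoulder distance.  Medians over frames are combined as
    body_length = torso + mean leg and body_area = shoulder_width *
    body_length (m^2).
    """
    for j in _DIM_JOINTS:
        if j not in stream.joint_names:
            raise GaitError(f"required joint {j!r} untracked")
    P = {j: stream.joint(j) for j in _DIM_JOINTS}
    valid = np.ones(stream.n_frames, dtype=bool)
    for arr in P.values():
        valid &= ~np.isnan(arr[:, 0])
    if valid.sum() < min_frames:
        raise GaitError(f"only {int(valid.sum())} frames with all joints tracked")

    def seg(a: str, b: str) -> np.ndarray:
        return np.linalg.norm(P[a][valid] - P[b][valid], axis=1)

    torso = seg("pelvis", "neck")
    shoulder = seg("shoulder_left", "shoulder_right")
    leg = 0.5 * (seg("hip_left", "knee_left") + seg("knee_left", "ankle_left")
                 + seg("hip_right", "knee_right") + seg("knee_right", "ankle_right"))
    body_length = float(np.median(torso) + np.median(leg))
    shoulder_width = float(np.median(shoulder))
    return body_length, shoulder_width, shoulder_width * body_length


def normalize_body_area(areas: np.ndarray, reference_mask: np.ndarray) -> np.ndarray:
    """Z-score body areas against a reference subset (e.g. female subjects).

    z = (area - mean_ref) / sd_ref with the sample (ddof=1) SD of the
    reference subset.
    """
    areas = np.asarray(areas, dtype=float)
    ref = areas[np.asarray(reference_mask, dtype=bool)]
    if len(ref) < 2:
        raise GaitError("reference subset must have >= 2 members")
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise GaitError("degenerate reference variance")
    return (areas - float(np.mean(ref))) / sd


def skeleton_metrics(stream: JointStream, r2_threshold: float = 0.98,
                     min_points: int = 30,
                     band_hz: tuple[float, float] = (0.5, 1.5)) -> GaitMetrics:
    """Run the full skeleton pipeline on one trial: speed + cadence."""
    series = clean_distance(pelvis_distance(stream), min_points=min_points)
    fit = fit_gait_speed(series, r2_threshold=r2_threshold, min_points=min_points)
    try:
        cad = cadence_fft(foot_swing(stream), band_hz=band_hz).cadence
    except GaitError:
        cad = np.nan
    n0 = int(series.clean_mask.sum())
    return GaitMetrics(
        speed=max(fit.gs, 0.0),
        cadence=cad,
        speed_r2=fit.r2,
        trimmed_fraction=(fit.trim_left + fit.trim_right) / n0,
        n_steps_detected=0,
        source={"speed": "kinect", "cadence": "kinect"},
        quality_flag="ok" if fit.converged else "trim_failed",
    )
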