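"""Kinematic indexes for 3D drawing tasks: speed-accuracy trade-off and SPARC.

Pipeline: the raw controller trajectory is low-pass filtered with a
zero-phase Butterworth filter (60 Hz sampling, 10 Hz cutoff, 4th order
applied forward-backward), speed is the Euclidean norm of the position
derivative, and two scalar indexes summarise a task:

* **SAT** (speed-accuracy trade-off, arbitrary units): mean speed in cm/s
  divided by the RMS deviation from the ideal shape in cm (floored to avoid
  division by ~0 for perfect traces).  Higher SAT = a more efficient balance
  of speed and accuracy.
* **SPARC** (spectral arc length, dimensionless, <= 0): the negative arc
  length of the amplitude-normalised magnitude spectrum of the speed signal
  over an adaptively chosen frequency band.  Fragmented (multi-submovement)
  speed profiles spread spectral content to higher frequencies and yield
  more negative values; values nearer 0 mean smoother movement.

Straight-line error is evaluated in a 2D assessment plane (line direction
plus the dominant orthogonal deviation direction); circle error is the full
3D distance to the ideal circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import signal

from .errors import IntegrityError, ParameterError
from .io_session import Trajectory

M_TO_CM = 100.0


# --- ideal shapes ----------------------------------------------------------

@dataclass(frozen=True)
class LineShape:
    """Ideal straight line from ``p0`` to ``p1`` (metres)."""

    p0: Tuple[float, float, float]
    p1: Tuple[float, float, float]
    kind: str = "line"

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ParameterError("line endpoints must differ")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.p1, float) - np.asarray(self.p0, float)))


@dataclass(frozen=True)
class CircleShape:
    """Ideal circle: centre ``c``, radius ``r`` (m), unit plane normal ``n``."""

    c: Tuple[float, float, float]
    r: float
    n: Tuple[float, float, float]
    kind: str = "circle"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ParameterError("circle radius must be positive")
        norm = float(np.linalg.norm(self.n))
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ParameterError("circle normal must be a unit vector")

    def plane_basis(self) -> Tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane axes (deterministic given the normal)."""
        n = np.asarray(self.n, float)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    @property
    def length(self) -> float:
        return float(2.0 * math.pi * self.r)


IdealShape = Union[LineShape, CircleShape]


@dataclass
class SpeedSeries:
    """Speed magnitude (m/s) on the trajectory's time grid."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if self.t.shape != self.v.shape:
            raise IntegrityError("t and v must have the same length")
        if np.any(self.v < -1e-12):
            raise IntegrityError("speed must be non-negative")


@dataclass
class SpeedSpectrum:
    """Magnitude spectrum of the speed signal, normalised to V(0) = 1."""

    omega: np.ndarray  # Hz, non-negative, increasing
    vhat: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, float)
        self.vhat = np.asarray(self.vhat, float)
        if self.omega.shape != self.vhat.shape:
            raise IntegrityError("omega and vhat must have the same length")


@dataclass
class KinematicResult:
    """Scalar summary of one drawing task."""

    sat: float  # arbitrary units, > 0
    sparc: float  # dimensionless, <= 0
    mean_speed: float  # m/s
    error_cm: float  # RMS deviation from the ideal path, cm
    duration_s: float

    def __post_init__(self) -> None:
        if not self.sat > 0:
            raise IntegrityError(f"SAT must be positive, got {self.sat}")
        if self.sparc > 1e-12:
            raise IntegrityError(f"SPARC must be <= 0, got {self.sparc}")
        if self.error_cm < 0:
            raise IntegrityError("error must be non-negative")


# --- filtering and differentiation -----------------------------------------

def lowpass_filter(
    traj: Trajectory, cutoff_hz: float = 10.0, order: int = 4
) -> Trajectory:
    """Zero-phase Butterworth low-pass of each coordinate.

    The filter is applied forward-backward (``filtfilt``), so the effective
    magnitude response is the square of the single-pass Butterworth
    response and the phase is zero.  Timestamps are unchanged.
    """
    if not (0 < cutoff_hz < traj.nominal_rate / 2):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={traj.nominal_rate / 2} Hz)"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=traj.nominal_rate)
    padlen = 3 * max(len(a), len(b))
    if traj.n_samples <= padlen:
        raise ParameterError(
            f"trajectory of {traj.n_samples} samples is shorter than the "
            f"filter warm-up ({padlen + 1} samples)"
        )
    xyz = signal.filtfilt(b, a, traj.xyz, axis=0)
    return Trajectory(
        t=traj.t.copy(),
        xyz=xyz,
        nominal_rate=traj.nominal_rate,
        task=traj.task,
        hand=traj.hand,
        quality=traj.quality,
    )


def butterworth_gain(f_hz: float, cutoff_hz: float, order: int, passes: int = 2) -> float:
    """Analytic Butterworth magnitude response, ``passes``-times applied."""
    single = 1.0 / math.sqrt(1.0 + (f_hz / cutoff_hz) ** (2 * order))
    return single**passes


def speed_profile(traj: Trajectory, gap_tolerance: float = 1.5, resample: bool = False) -> SpeedSeries:
    """Speed = Euclidean norm of the position derivative on the sample grid.

    Central finite differences in the interior, one-sided at the ends.  Gaps
    larger than ``gap_tolerance`` times the median interval raise an error
    unless ``resample`` is set, in which case the trajectory is linearly
    resampled to a uniform grid first.
    """
    if traj.n_samples < 3:
        raise ParameterError("speed profile needs at least 3 samples")
    t, xyz = traj.t, traj.xyz
    dt = np.diff(t)
    med = np.median(dt)
    if np.any(dt > gap_tolerance * med):
        if not resample:
            raise IntegrityError(
                "non-uniform sampling beyond tolerance; pass resample=True "
                "to interpolate onto a uniform grid"
            )
        n = int(round(traj.duration / med)) + 1
        tu = t[0] + np.arange(n) * med
        xyz = np.column_stack([np.interp(tu, t, xyz[:, k]) for k in range(3)])
        t = tu
    deriv = np.gradient(xyz, t, axis=0)
    v = np.linalg.norm(deriv, axis=1)
    return SpeedSeries(t=t, v=v)


# --- error against the ideal shape -----------------------------------------

def _line_error_m(xyz: np.ndarray, shape: LineShape) -> float:
    """RMS deviation from the line, measured in the 2D assessment plane.

    Residuals orthogonal to the line are projected onto their dominant
    direction (first right singular vector of the uncentred residual
    matrix), reflecting an assessment that scores line drawing in two
    dimensions; out-of-plane wobble in the remaining direction is ignored.
    """
    p0 = np.asarray(shape.p0, float)
    u = shape.direction
    rel = xyz - p0
    resid = rel - np.outer(rel @ u, u)
    norms = np.linalg.norm(resid, axis=1)
    if float(np.sqrt(np.mean(norms**2))) < 1e-12:
        return 0.0
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    w = vt[0]
    dev = resid @ w
    return float(np.sqrt(np.mean(dev**2)))


def _circle_error_m(xyz: np.ndarray, shape: CircleShape) -> float:
    """RMS 3D distance to the ideal circle."""
    c = np.asarray(shape.c, float)
    n = np.asarray(shape.n, float)
    rel = xyz - c
    h = rel @ n  # out-of-plane offset
    in_plane = rel - np.outer(h, n)
    rho = np.linalg.norm(in_plane, axis=1)
    d = np.sqrt((rho - shape.r) ** 2 + h**2)
    return float(np.sqrt(np.mean(d**2)))


def path_error(traj: Trajectory, ideal: IdealShape, method: str = "deviation_rms") -> float:
    """Movement-accuracy error against the ideal shape.

    The default (``deviation_rms``) is the RMS orthogonal deviation of the
    samples from the ideal path, in cm.  The alternative
    ``path_length_ratio`` scores curvature rather than offset: the excess
    of the travelled path over the ideal length, as a percentage (0 for a
    perfect trace); it is provided for sensitivity analyses and is not the
    default.
    """
    if traj.task != ideal.kind:
        raise ParameterError(
            f"trajectory task {traj.task!r} does not match shape kind {ideal.kind!r}"
        )
    if method == "path_length_ratio":
        return max(path_length(traj) / ideal.length - 1.0, 0.0) * 100.0
    if method != "deviation_rms":
        raise ParameterError(f"unknown error method {method!r}")
    if isinstance(ideal, LineShape):
        err_m = _line_error_m(traj.xyz, ideal)
    elif isinstance(ideal, CircleShape):
        err_m = _circle_error_m(traj.xyz, ideal)
    else:  # pragma: no cover - typing guard
        raise ParameterError(f"unknown ideal shape {type(ideal).__name__}")
    return err_m * M_TO_CM


def path_length(traj: Trajectory) -> float:
    """Total travelled path length in metres."""
    return float(np.sum(np.linalg.norm(np.diff(traj.xyz, axis=0), axis=1)))


# --- SAT -------------------------------------------------------------------

def compute_sat(
    traj: Trajectory,
    ideal: IdealShape,
    error_floor_cm: float = 0.1,
    error_method: str = "deviation_rms",
) -> float:
    """Speed-accuracy trade-off: mean speed (cm/s) / path error (cm).

    Mean speed is path length over duration (one robust scalar per task);
    the error floor guards perfect traces against division by ~0.
    ``error_method`` switches the error definition (see :func:`path_error`).
    """
    if error_floor_cm <= 0:
        raise ParameterError("error_floor_cm must be positive")
    if traj.duration <= 0:
        raise IntegrityError("degenerate trajectory with zero duration")
    mean_speed_cms = path_length(traj) / traj.duration * M_TO_CM
    err = max(path_error(traj, ideal, method=error_method), error_floor_cm)
    return mean_speed_cms / err


# --- SPARC -----------------------------------------------------------------

def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def speed_spectrum(series: SpeedSeries, pad_factor: int = 4) -> SpeedSpectrum:
    """Zero-padded magnitude spectrum of the speed signal, V(0) = 1.

    The signal is padded to ``pad_factor`` times the next power of two to
    give the spectral curve a fine frequency grid, then normalised by its
    zero-frequency magnitude (the speed signal is non-negative, so this is
    also its maximum).
    """
    v = series.v
    if v.size < 8:
        raise ParameterError("speed spectrum needs at least 8 samples")
    if not np.any(v > 0):
        raise ParameterError("all-zero speed signal: normalisation undefined")
    if pad_factor < 1:
        raise ParameterError("pad_factor must be >= 1")
    dt = float(np.median(np.diff(series.t)))
    nfft = pad_factor * _next_pow2(v.size)
    vhat = np.abs(np.fft.rfft(v, n=nfft))
    vhat = vhat / vhat[0]
    omega = np.fft.rfftfreq(nfft, d=dt)
    return SpeedSpectrum(omega=omega, vhat=vhat)


def sparc(
    series: SpeedSeries,
    amp_threshold: float = 0.05,
    max_cutoff_hz: float = 20.0,
    pad_factor: int = 4,
) -> float:
    """Spectral arc length of the speed signal (negative; 0 = smoothest).

    The normalised spectrum is restricted to [0, ``max_cutoff_hz``], then an
    adaptive cutoff keeps frequencies up to the last point whose magnitude
    still reaches ``amp_threshold``.  The arc length of the resulting curve
    (frequency axis rescaled to [0, 1]) is returned with a negative sign, so
    fragmented, intermittent speed profiles score more negative.
    """
    spec = speed_spectrum(series, pad_factor=pad_factor)
    in_band = spec.omega <= max_cutoff_hz
    f, m = spec.omega[in_band], spec.vhat[in_band]
    if f.size < 2:
        raise ParameterError("max_cutoff_hz leaves fewer than 2 spectral points")
    above = np.nonzero(m >= amp_threshold)[0]
    stop = int(above[-1]) + 1 if above.size else f.size
    stop = max(stop, 2)
    f, m = f[:stop], m[:stop]
    f_range = f[-1] - f[0]
    arc = np.sum(np.sqrt((np.diff(f) / f_range) ** 2 + np.diff(m) ** 2))
    return float(-arc)


# --- pipeline composition ---------------------------------------------------

def analyze_task(
    traj: Trajectory,
    ideal: IdealShape,
    cutoff_hz: float = 10.0,
    order: int = 4,
    error_floor_cm: float = 0.1,
    amp_threshold: float = 0.05,
    max_cutoff_hz: float = 20.0,
) -> KinematicResult:
    """Full per-task analysis: filter -> speed -> SAT and SPARC.

    Any stage failure is re-raised with the stage name prefixed.
    """
    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    filtered = _stage("lowpass_filter", lowpass_filter, traj, cutoff_hz, order)
    series = _stage("speed_profile", speed_profile, filtered)
    sat = _stage("compute_sat", compute_sat, filtered, ideal, error_floor_cm)
    sp = _stage(
        "sparc", sparc, series, amp_threshold=amp_threshold, max_cutoff_hz=max_cutoff_hz
    )
    err = max(_stage("path_error", path_error, filtered, ideal), 0.0)
    mean_speed = path_length(filtered) / filtered.duration
    return KinematicResult(
        sat=sat,
        sparc=min(sp, 0.0),
        mean_speed=mean_speed,
        error_cm=err,
        duration_s=filtered.duration,
    )
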