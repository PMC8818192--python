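"""Dual-input two-tissue-compartment FDG kinetic model for liver PET.

The liver receives blood from the hepatic artery and the portal vein; the
effective tracer input is the HPI-weighted mixture of the two.  Tracer
exchanges between blood and a free-tracer tissue pool (k1, k2), is
phosphorylated into a trapped pool (k3) and dephosphorylated back (k4).
The tissue curve is the convolution of the mixed blood input with a
bi-exponential impulse response whose macro rates ``alpha1 <= alpha2`` are
the roots of ``x^2 - (k2+k3+k4) x + k2 k4 = 0``.

Conventions
-----------
* Rate constants are per **minute** (k1 in ml/min/ml); time grids and frame
  schedules are in **seconds**.  Conversion happens inside the model.
* Continuous curves are stored on a dense uniform grid with linear
  interpolation between samples and value 0 before t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "KineticParams",
    "InputFunction",
    "FrameSchedule",
    "TissueCurve",
    "blood_input",
    "macro_rates",
    "model_tac",
    "sample_frames",
    "default_grid",
    "exp_conv",
]

#: default dense-grid spacing (seconds); fine relative to the fastest
#: plausible rate (~3/min, i.e. a 20 s time constant)
DEFAULT_DT = 0.1
#: default scan length (seconds)
DEFAULT_SPAN = 300.0

_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class KineticParams:
    """The five-parameter vector of the dual-input liver model.

    Parameters
    ----------
    k1 : float
        Blood-to-tissue transport rate, ml/min/ml.
    k2 : float
        Tissue-to-blood clearance rate, 1/min.
    k3 : float
        Phosphorylation rate, 1/min.
    k4 : float
        Dephosphorylation rate, 1/min.
    hpi : float
        Hepatic arterial perfusion index: arterial fraction of total
        hepatic blood inflow, dimensionless in [0, 1].
    """

    k1: float
    k2: float
    k3: float
    k4: float
    hpi: float

    def __post_init__(self) -> None:
        vec = (self.k1, self.k2, self.k3, self.k4, self.hpi)
        if not all(math.isfinite(v) for v in vec):
            raise ValueError(f"non-finite kinetic parameters: {vec}")
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError(f"rate constants must be >= 0, got {vec[:4]}")
        if not 0.0 <= self.hpi <= 1.0:
            raise ValueError(f"hpi must lie in [0, 1], got {self.hpi}")

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "KineticParams":
        k1, k2, k3, k4, hpi = (float(v) for v in x)
        return cls(k1, k2, k3, k4, hpi)

    def to_vector(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.hpi])


class InputFunction:
    """A continuous-time activity curve on a dense uniform grid.

    Evaluation between samples is linear interpolation; the curve is 0
    before its first time point (pre-injection) and held at its last
    value after the final one.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("an input function needs at least two samples")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(values)):
            raise ValueError("input-function values must be finite")
        if np.any(values < 0):
            raise ValueError("input-function values must be non-negative")
        self.times = times
        self.values = values
        self.dt = float(dt[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values, left=0.0)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FrameSchedule:
    """An ordered, contiguous list of PET frames (start, duration) in seconds."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape or starts.size == 0:
            raise ValueError("starts and durations must be matching 1-D arrays")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if starts[0] != 0:
            raise ValueError("first frame must start at t = 0")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_run_lengths(cls, spec: Sequence[Sequence[float]]) -> "FrameSchedule":
        """Build from a run-length list like ``[[12, 5], [4, 60]]``."""
        durations = np.concatenate([[dur] * int(n) for n, dur in spec]).astype(float)
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 16-frame, 300 s schedule: 12 frames of 5 s then 4 of 60 s."""
        return cls.from_run_lengths([[12, 5], [4, 60]])

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.end_times[-1])

    def __len__(self) -> int:
        return self.starts.size


@dataclass
class TissueCurve:
    """Per-frame tissue activity (SUV units) on a frame schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schedule),):
            raise ValueError(
                f"expected {len(self.schedule)} frame values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tissue-curve values must be finite")


def default_grid(span: float = DEFAULT_SPAN, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform time grid [0, span] seconds with spacing dt."""
    n = int(round(span / dt))
    return np.linspace(0.0, n * dt, n + 1)


def blood_input(arterial: InputFunction, portal: InputFunction, hpi: float) -> InputFunction:
    """HPI-weighted dual blood input ``C_B = hpi * A + (1 - hpi) * P``."""
    if not 0.0 <= hpi <= 1.0:
        raise ValueError(f"hpi must lie in [0, 1], got {hpi}")
    if arterial.span != portal.span or len(arterial) != len(portal):
        raise ValueError(
            "arterial and portal curves must share a time span: "
            f"arterial {arterial.span}, portal {portal.span}"
        )
    mixed = hpi * arterial.values + (1.0 - hpi) * portal.values
    return InputFunction(arterial.times, mixed)


def macro_rates(k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Macro rate constants (alpha1, alpha2), the eigen-rates of the tissue system.

    They are the roots of ``x^2 - (k2+k3+k4) x + k2 k4 = 0``; the
    discriminant is >= (k2 - k4)^2 >= 0 for non-negative rates, so both
    roots are real, with ``0 <= alpha1 <= alpha2``.
    """
    if min(k2, k3, k4) < 0:
        raise ValueError(f"rate constants must be >= 0, got k2={k2}, k3={k3}, k4={k4}")
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    root = math.sqrt(max(disc, 0.0))
    return (s - root) / 2.0, (s + root) / 2.0


def exp_conv(x: np.ndarray, lam: float, dt: float) -> np.ndarray:
    """Trapezoid-rule convolution of ``x`` with ``exp(-lam * t)`` on a uniform grid.

    Implemented as the exactly equivalent one-pole recursion
    ``y[n] = E y[n-1] + dt/2 (x[n] + E x[n-1])`` with ``E = exp(-lam dt)``,
    which is O(n) instead of O(n^2).
    """
    x = np.asarray(x, dtype=float)
    e = math.exp(-lam * dt)
    y = lfilter([dt / 2.0, dt / 2.0 * e], [1.0, -e], x)
    if x[0] != 0.0:
        # the filter's startup assumes a sample before t=0; remove its
        # transient so y[0] = 0 (an empty integral), as trapezoid requires
        y -= 0.5 * dt * x[0] * np.exp(-lam * dt * np.arange(x.size))
    return y


# alpha2 - alpha1 below this (1/min) switches to the repeated-root limit form
_REPEATED_ROOT_TOL = 1e-9


def _tissue_response(params: KineticParams, cb: np.ndarray, t: np.ndarray, dt: float) -> np.ndarray:
    """Convolve the impulse response for ``params`` with a gridded blood input."""
    a1_m, a2_m = macro_rates(params.k2, params.k3, params.k4)
    # work in per-second rates on the seconds grid
    k1 = params.k1 / _SECONDS_PER_MINUTE
    k34 = (params.k3 + params.k4) / _SECONDS_PER_MINUTE
    a1 = a1_m / _SECONDS_PER_MINUTE
    a2 = a2_m / _SECONDS_PER_MINUTE
    if a2_m - a1_m < _REPEATED_ROOT_TOL:
        # limit form K1 [1 + (k3+k4-alpha) t] e^{-alpha t}; the t-weighted
        # convolution uses (r e^{-ar}) * x = t (e * x) - e * (t x)
        base = exp_conv(cb, a1, dt)
        ramp = t * base - exp_conv(t * cb, a1, dt)
        out = k1 * (base + (k34 - a1) * ramp)
    else:
        out = (k1 / (a2 - a1)) * (
            (k34 - a1) * exp_conv(cb, a1, dt) + (a2 - k34) * exp_conv(cb, a2, dt)
        )
    # trapezoid convolution of non-negative signals can dip ~eps below 0
    return np.maximum(out, 0.0)


def model_tac(
    params: KineticParams,
    arterial: InputFunction,
    portal: InputFunction,
    grid: np.ndarray | None = None,
) -> InputFunction:
    """Model tissue curve: impulse response convolved with the dual blood input.

    ``C_T(t) = K1/(a2-a1) [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}] (x) C_B(t)``
    evaluated by discrete trapezoid convolution on ``grid`` (seconds).
    """
    if grid is None:
        grid = arterial.times
    grid = np.asarray(grid, dtype=float)
    dt = float(grid[1] - grid[0])
    cb = blood_input(arterial, portal, params.hpi)
    cbv = cb(grid)
    return InputFunction(grid, _tissue_response(params, cbv, grid, dt))


def sample_frames(curve: InputFunction, schedule: FrameSchedule) -> np.ndarray:
    """Reduce a continuous curve to per-frame time-averages.

    Each frame value is ``(1/dur) * integral of the curve over
    [start, start+dur]`` (PET frames integrate activity over the frame).
    """
    t0, t1 = curve.span
    if schedule.starts[0] < t0 - 1e-9 or schedule.end_times[-1] > t1 + 1e-9:
        raise ValueError(
            f"schedule [0, {schedule.end_times[-1]} s] extends past the "
            f"curve domain [{t0}, {t1} s]"
        )
    # cumulative trapezoid integral is exact for the piecewise-linear curve
    cum = np.concatenate(
        [[0.0], np.cumsum((curve.values[1:] + curve.values[:-1]) / 2.0 * curve.dt)]
    )
    lo = np.interp(schedule.starts, curve.times, cum)
    hi = np.interp(schedule.end_times, curve.times, cum)
    return (hi - lo) / schedule.durations
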