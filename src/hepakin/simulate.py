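"""Synthetic dual-input dynamic-PET cohorts.

Emulates short (5-minute) dynamic FDG liver studies: an idealized arterial
bolus, a portal-vein curve obtained by dispersing the arterial one through
a single-exponential transit kernel, and two tissue groups — HCC lesions
and background liver — whose kinetic parameters are drawn from truncated
normal distributions anchored to clinically plausible values.  HCC tissue
has higher transport (k1), phosphorylation (k3) and arterial fraction
(HPI) than background liver, and lower dephosphorylation (k4); background
liver is predominantly portal-fed (HPI ~ 0.3).

Tissue curves are the frame-averaged model output plus zero-mean Gaussian
noise whose per-frame standard deviation is ``noise_level * value /
sqrt(duration / 5 s)`` — longer frames integrate more counts and are
proportionally less noisy.  Everything is reproducible from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .model import (
    DEFAULT_DT,
    FrameSchedule,
    InputFunction,
    KineticParams,
    TissueCurve,
    default_grid,
    model_tac,
    sample_frames,
)
from .optim import SearchSpace

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SyntheticSubject",
    "arterial_input",
    "portal_from_arterial",
    "apply_frame_noise",
    "generate_cohort",
    "default_cohort_spec",
]

_PARAM_NAMES = ("k1", "k2", "k3", "k4", "hpi")

# group parameter anchors (means and sds) for the two tissue classes,
# on the clinical scale: HCC hyperperfused/hypermetabolic, liver portal-fed
HCC_MEANS = (0.651, 0.592, 0.137, 0.064, 0.667)
HCC_SDS = (0.013, 0.012, 0.024, 0.003, 0.183)
LIVER_MEANS = (0.628, 0.620, 0.075, 0.090, 0.310)
LIVER_SDS = (0.015, 0.013, 0.024, 0.009, 0.092)


@dataclass(frozen=True)
class GroupSpec:
    """Truncated-normal parameter distribution for one tissue group."""

    label: str
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.means) != 5 or len(self.sds) != 5:
            raise ValueError("means and sds must have 5 entries (k1..k4, hpi)")
        if any(s < 0 for s in self.sds):
            raise ValueError("parameter sds must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a reproducible synthetic cohort."""

    groups: tuple[GroupSpec, ...]
    n_per_group: int = 20
    noise_level: float = 0.05
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=FrameSchedule.default)
    space: SearchSpace = field(default_factory=SearchSpace.default)
    aif_jitter: float = 0.1  # lognormal sigma on arterial amplitude per subject

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        for g in self.groups:
            lo, hi = self.space.lower, self.space.upper
            if np.any(np.asarray(g.means) < lo) or np.any(np.asarray(g.means) > hi):
                raise ValueError(f"group {g.label!r} means fall outside the search bounds")


@dataclass
class SyntheticSubject:
    """One simulated lesion/tissue ROI with its ground truth."""

    subject_id: str
    group: str
    true_params: KineticParams
    arterial: InputFunction
    portal: InputFunction
    tissue: TissueCurve


def default_cohort_spec(
    n_per_group: int = 20, noise_level: float = 0.05, seed: int = 0
) -> CohortSpec:
    """Two-group HCC vs background-liver cohort with the default anchors."""
    return CohortSpec(
        groups=(
            GroupSpec("HCC", HCC_MEANS, HCC_SDS),
            GroupSpec("liver", LIVER_MEANS, LIVER_SDS),
        ),
        n_per_group=n_per_group,
        noise_level=noise_level,
        seed=seed,
    )


def arterial_input(
    peak_time: float = 25.0,
    amplitude: float = 20.0,
    decay_rates: tuple[float, float] = (2.0, 0.01),
    slow_fraction: float = 0.2,
    rise_power: float = 2.0,
    grid: np.ndarray | None = None,
) -> InputFunction:
    """Idealized arterial bolus: power-law rise, bi-exponential washout.

    The curve rises as ``(t / peak_time)^rise_power`` to its single peak of
    height ``amplitude`` exactly at ``peak_time`` (seconds), then washes
    out as a two-exponential mixture with the given decay rates (1/min,
    fast then slow) and slow-component fraction.  A compact Feng-style
    surrogate: zero at t = 0, one early peak, long tail.
    """
    if peak_time <= 0 or amplitude < 0 or rise_power <= 0:
        raise ValueError("peak_time and rise_power must be positive, amplitude >= 0")
    fast, slow = decay_rates
    if fast <= 0 or slow <= 0 or not 0.0 <= slow_fraction <= 1.0:
        raise ValueError("decay rates must be positive and slow_fraction in [0, 1]")
    if grid is None:
        grid = default_grid()
    t = np.asarray(grid, dtype=float)
    rise = np.power(np.clip(t / peak_time, 0.0, 1.0), rise_power)
    dt_min = np.maximum(t - peak_time, 0.0) / 60.0
    wash = (1.0 - slow_fraction) * np.exp(-fast * dt_min) + slow_fraction * np.exp(
        -slow * dt_min
    )
    values = amplitude * np.where(t <= peak_time, rise, wash)
    return InputFunction(t, values)


def portal_from_arterial(arterial: InputFunction, dispersion_rate: float = 1.5) -> InputFunction:
    """Portal-vein curve: arterial curve dispersed through the gut compartment.

    Convolves the arterial curve with the unit-area kernel
    ``k e^{-k t}`` (k = ``dispersion_rate`` in 1/min), delaying and
    broadening the bolus while preserving its area.  Discretised with an
    exponential-integrator recursion (piecewise-linear input, exact kernel
    integrals) so the delta-kernel limit of very large k is handled
    without error blow-up.
    """
    if dispersion_rate <= 0:
        raise ValueError(f"dispersion_rate must be positive, got {dispersion_rate}")
    k = dispersion_rate / 60.0  # per second
    dt = arterial.dt
    e = math.exp(-k * dt)
    kdt = k * dt
    # y_n = E y_{n-1} + b0 x_n + b1 x_{n-1}, exact for piecewise-linear x
    b1 = (1.0 - e * (1.0 + kdt)) / kdt
    b0 = (1.0 - e) - b1
    values = lfilter([b0, b1], [1.0, -e], arterial.values)
    return InputFunction(arterial.times, np.maximum(values, 0.0))


def apply_frame_noise(
    values: np.ndarray,
    durations: np.ndarray,
    noise_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add zero-mean Gaussian noise with sd = noise_level * value / sqrt(dur/5)."""
    sd = noise_level * np.abs(values) / np.sqrt(np.asarray(durations) / 5.0)
    return values + rng.normal(0.0, 1.0, size=values.shape) * sd


def _draw_params(group: GroupSpec, space: SearchSpace, rng: np.random.Generator) -> KineticParams:
    out = np.empty(5)
    for d, (mu, sd) in enumerate(zip(group.means, group.sds)):
        lo, hi = space.lower[d], space.upper[d]
        if sd == 0:
            out[d] = mu
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[d] = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    return KineticParams.from_vector(out)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Simulate a full two-group cohort, reproducibly from ``spec.seed``.

    Each subject gets its own arterial/portal input pair (amplitude
    jittered log-normally across subjects), true parameters drawn from its
    group's truncated-normal spec, and a tissue curve equal to the
    frame-sampled model output plus frame-duration-weighted noise.
    """
    rng = np.random.default_rng(spec.seed)
    grid = default_grid(spec.schedule.total_duration, DEFAULT_DT)
    subjects: list[SyntheticSubject] = []
    for group in spec.groups:
        for i in range(spec.n_per_group):
            amp = 20.0 * float(np.exp(rng.normal(0.0, spec.aif_jitter)))
            arterial = arterial_input(amplitude=amp, grid=grid)
            portal = portal_from_arterial(arterial)
            params = _draw_params(group, spec.space, rng)
            clean = sample_frames(model_tac(params, arterial, portal, grid), spec.schedule)
            noisy = apply_frame_noise(clean, spec.schedule.durations, spec.noise_level, rng)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{group.label}_{i:03d}",
                    group=group.label,
                    true_params=params,
                    arterial=arterial,
                    portal=portal,
                    tissue=TissueCurve(spec.schedule, noisy, label=group.label),
                )
            )
    return subjects
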