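"""Time-course integration, oscillation metrics and steady states.

The integrator defaults are deliberately tight (LSODA, rtol 1e-8,
atol 1e-10) so that periods and amplitudes of the relaxation oscillations
are reproducible to well under 0.1% when tolerances are halved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .model import ModelDefinition, jacobian, rhs

__all__ = [
    "TimeCourse",
    "OscillationMetrics",
    "FixedPoint",
    "IntegrationError",
    "integrate",
    "classify_oscillation",
    "steady_state",
    "no_stress_fixed_point",
]

#: Default solver settings.
T_END = 500.0
DT_OUT = 0.1
RTOL = 1e-8
ATOL = 1e-10
TRANSIENT_FRAC = 0.5
AMP_MIN = 0.01
PROMINENCE = 1e-3


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:g})")
        self.last_time = last_time


@dataclass
class TimeCourse:
    """A time grid plus per-species activity trajectories (a.u.)."""

    times: np.ndarray
    activities: np.ndarray          # shape (n_species, n_times)
    species_names: tuple[str, ...]
    model_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.atleast_2d(np.asarray(self.activities, dtype=float))
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def activity(self, species: str) -> np.ndarray:
        return self.activities[self.species_names.index(species)]

    @property
    def final_state(self) -> np.ndarray:
        return self.activities[:, -1]


@dataclass
class OscillationMetrics:
    """Classification plus period and peak-to-trough amplitude."""

    classification: str             # "steady" | "oscillatory" | "irregular"
    period_mean: float = float("nan")
    period_sd: float = float("nan")
    amplitude: float = 0.0
    n_cycles_analyzed: int = 0


@dataclass
class FixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    species_names: tuple[str, ...] = field(default=())

    def activity(self, species: str) -> float:
        return float(self.state[self.species_names.index(species)])


def integrate(model: ModelDefinition, t_end: float = T_END, dt_out: float = DT_OUT,
              rtol: float = RTOL, atol: float = ATOL,
              x0: np.ndarray | None = None, method: str = "LSODA") -> TimeCourse:
    """Integrate the model ODEs and sample on an equispaced output grid.

    With ``t_end = 0`` the initial condition is returned on the grid {0}.
    """
    if t_end < 0 or rtol <= 0 or atol <= 0:
        raise ValueError("t_end must be >= 0 and tolerances > 0")
    if x0 is None:
        x0 = model.initial_state()
    x0 = np.asarray(x0, dtype=float)
    fp = model.fingerprint()
    if t_end == 0:
        return TimeCourse(np.array([0.0]), x0[:, None], model.species_names, fp)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t_end)
    fun = lambda t, x: rhs(model, x, check=False)
    sol = solve_ivp(fun, (0.0, t_end), x0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(sol.message, last)
    acts = sol.y
    totals = model.totals[:, None]
    if np.any(acts < -1e-6) or np.any(acts > totals + 1e-6):
        raise IntegrationError("activities left [0, total] beyond 1e-6", sol.t[-1])
    return TimeCourse(sol.t, acts, model.species_names, fp)


def classify_oscillation(tc: TimeCourse, species: str,
                         transient_frac: float = TRANSIENT_FRAC,
                         amp_min: float = AMP_MIN,
                         prominence: float = PROMINENCE) -> OscillationMetrics:
    """Classify the post-transient segment of one species' trajectory.

    Peaks are local maxima with the given prominence; the period is the
    mean inter-peak interval and the amplitude the mean peak-to-following-
    trough drop.  ``oscillatory`` requires >= 3 analyzed cycles, period
    CV < 10% and amplitude above ``amp_min``; a flat segment (total
    variation < ``amp_min``) is ``steady``; anything else ``irregular``.
    """
    if not 0 <= transient_frac < 1:
        raise ValueError("transient_frac must be in [0, 1)")
    x = tc.activity(species)          # raises KeyError-like ValueError if absent
    n0 = int(len(tc.times) * transient_frac)
    t, x = tc.times[n0:], x[n0:]
    if len(t) < 10:
        raise ValueError("need >= 10 samples after transient removal")
    total_variation = float(x.max() - x.min())
    peaks, _ = find_peaks(x, prominence=prominence)
    if len(peaks) >= 3:
        periods = np.diff(t[peaks])
        period_mean = float(periods.mean())
        period_sd = float(periods.std())
        drops = []
        for i in range(len(peaks) - 1):
            trough = x[peaks[i]:peaks[i + 1] + 1].min()
            drops.append(x[peaks[i]] - trough)
        amplitude = float(np.mean(drops))
        n_cycles = len(periods)
        if period_sd / period_mean < 0.10 and amplitude > amp_min:
            return OscillationMetrics("oscillatory", period_mean, period_sd,
                                      amplitude, n_cycles)
    if total_variation < amp_min:
        return OscillationMetrics("steady", amplitude=0.0)
    return OscillationMetrics("irregular", amplitude=total_variation)


def steady_state(model: ModelDefinition, n_starts: int = 64,
                 seed: int = 0, residual_tol: float = 1e-10,
                 merge_tol: float = 1e-6) -> list[FixedPoint]:
    """Locate fixed points by multistart root finding; classify stability.

    Starts are drawn uniformly in the state box (seeded) plus the endpoint
    of a long integration, which reliably seeds the basin attractor.
    Duplicates within ``merge_tol`` (max-norm) are merged.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    totals = model.totals
    fun = lambda x: rhs(model, x, check=False)
    starts = list(rng.uniform(0.0, 1.0, (n_starts, len(totals))) * totals)
    try:
        tc = integrate(model, t_end=400.0)
        starts.append(tc.final_state)
    except IntegrationError:
        pass
    points: list[np.ndarray] = []
    for x0 in starts:
        sol = root(fun, x0, method="hybr", tol=1e-13)
        x = sol.x
        if np.max(np.abs(fun(x))) >= residual_tol:
            continue
        if np.any(x < -merge_tol) or np.any(x > totals + merge_tol):
            continue
        if any(np.max(np.abs(x - q)) < merge_tol for q in points):
            continue
        points.append(np.clip(x, 0.0, totals))
    if not points:
        warnings.warn("no fixed point found from any start", stacklevel=2)
    out = []
    for x in points:
        ev = np.linalg.eigvals(jacobian(model, x))
        out.append(FixedPoint(x, ev, bool(np.all(ev.real < 0)),
                              model.species_names))
    out.sort(key=lambda fp: tuple(fp.state))
    return out


def no_stress_fixed_point(model: ModelDefinition, **kwargs) -> FixedPoint:
    """The resting state used as default initial condition for scenarios."""
    from .model import build_model
    params = model.parameters.with_updates(stress=0.0, stress1=0.0)
    rest = model.with_parameters(params)
    fps = steady_state(rest, **kwargs)
    stable = [fp for fp in fps if fp.stable]
    if len(stable) != 1:
        raise RuntimeError(
            f"expected a unique stable resting state, found {len(stable)}")
    return stable[0]
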