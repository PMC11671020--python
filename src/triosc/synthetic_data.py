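"""Noisy synthetic observations of model time courses, and parameter
recovery by multistart nonlinear least squares.

No raw experimental time courses are deposited for this system, so the
identifiability analysis runs on synthetic data: a clean trajectory of the
model sampled at equispaced times plus independent Gaussian observation
noise, clipped to the physical range [0, total].  Rate constants are
fitted in log space, which enforces positivity by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import ModelDefinition
from .simulate import integrate

__all__ = [
    "ObservationSet",
    "FitResult",
    "generate_observations",
    "fit_parameters",
    "DEFAULT_FREE_PARAMS",
]

#: The two contested edge weights: how strongly ULK1 shuts AMPK down, and
#: how strongly the delayed intermediate drives ULK1.
DEFAULT_FREE_PARAMS = ("k_ulk1_ampk", "k_prot_ulk1")


@dataclass
class ObservationSet:
    times: np.ndarray
    observations: np.ndarray          # (n_species, n_obs), noisy
    clean: np.ndarray                 # (n_species, n_obs), noise-free
    species_names: tuple[str, ...]
    noise_sd: float
    seed: int
    parameter_fingerprint: str

    def to_tsv(self, path) -> None:
        from .io import fmt
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} noise_sd={fmt(self.noise_sd)} "
                     f"fingerprint={self.parameter_fingerprint}\n")
            fh.write("time\t" + "\t".join(self.species_names) + "\n")
            for i, t in enumerate(self.times):
                row = [fmt(t)] + [fmt(v) for v in self.observations[:, i]]
                fh.write("\t".join(row) + "\n")


@dataclass
class FitResult:
    estimates: dict[str, float]
    residual: float
    n_starts: int
    converged: bool
    trace: list = field(default_factory=list)   # (start index, residual)


def generate_observations(model: ModelDefinition, n_obs: int = 200,
                          t_end: float = 100.0, noise_sd: float = 0.01,
                          seed: int = 0, x0=None) -> ObservationSet:
    """Sample the model at ``n_obs`` equispaced times with Gaussian noise."""
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dt = t_end / (n_obs - 1)
    tc = integrate(model, t_end=t_end, dt_out=dt, x0=x0)
    clean = tc.activities[:, :n_obs]
    times = tc.times[:n_obs]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    obs = np.clip(clean + noise, 0.0, model.totals[:, None])
    return ObservationSet(times, obs, clean, tc.species_names, noise_sd, seed,
                          model.fingerprint())


def _simulate_at(model: ModelDefinition, names, log_values,
                 times: np.ndarray, x0) -> np.ndarray:
    updates = {n: float(np.exp(v)) for n, v in zip(names, log_values)}
    m = model.with_parameters(
        model.parameters.with_updates(rate_constants=updates))
    dt = times[1] - times[0]
    tc = integrate(m, t_end=float(times[-1]), dt_out=float(dt), x0=x0)
    return tc.activities[:, :len(times)]


def fit_parameters(obs: ObservationSet, model: ModelDefinition,
                   free_params=DEFAULT_FREE_PARAMS,
                   bounds: dict[str, tuple[float, float]] | None = None,
                   n_starts: int = 4, seed: int = 0, x0=None) -> FitResult:
    """Least-squares recovery of selected rate constants from observations.

    Minimizes the summed squared residual between simulated and observed
    activities over ``free_params`` (in log space, within ``bounds``);
    the best of ``n_starts`` seeded multistart runs is returned.  With an
    empty ``free_params`` the residual at the model's own parameters is
    reported and no optimization runs.
    """
    free_params = tuple(free_params)
    for name in free_params:
        if name not in model.parameters.rate_constants:
            raise ValueError(f"free parameter {name!r} not a rate constant")
    if not free_params:
        sim = _simulate_at(model, (), (), obs.times, x0)
        resid = float(np.sum((sim - obs.observations) ** 2))
        return FitResult({}, resid, 0, True)

    truth_like = np.array([model.parameters.get(n) for n in free_params])
    if bounds is None:
        bounds = {n: (v / 30.0, v * 30.0) for n, v in zip(free_params, truth_like)}
    lo = np.log([bounds[n][0] for n in free_params])
    hi = np.log([bounds[n][1] for n in free_params])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite and positive")

    def residuals(logv):
        try:
            sim = _simulate_at(model, free_params, logv, obs.times, x0)
        except Exception:
            return np.full(obs.observations.size, 1e3)
        return (sim - obs.observations).ravel()

    # Multistarts perturb the model's stored values (log-normal, sd 0.4,
    # i.e. typically +-50%); the sum-of-squares surface of an oscillatory
    # trajectory is multimodal in period, so distant starts mislead.
    rng = np.random.default_rng(seed)
    best = None
    trace = []
    for i in range(n_starts):
        start = np.clip(np.log(truth_like) + rng.normal(0, 0.4, len(free_params)),
                        lo, hi)
        sol = least_squares(residuals, start, bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        cost = 2.0 * sol.cost
        trace.append((i, float(cost)))
        if best is None or cost < best[0]:
            best = (cost, sol)
    cost, sol = best
    if not sol.success and cost > 1e2:
        raise RuntimeError(f"optimizer failed on all starts: {trace}")
    estimates = {n: float(np.exp(v)) for n, v in zip(free_params, sol.x)}
    return FitResult(estimates, float(cost), n_starts, bool(sol.success), trace)
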