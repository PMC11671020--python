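"""Signal-response analysis: one-parameter sweeps and boundary bracketing.

A sweep integrates the model past its transient for each grid value of one
parameter (or species total), classifies the attractor, and records the
post-transient envelope per species.  Warm starts (the previous attractor
state seeds the next grid point) keep transients cheap; a cold-start mode
re-integrates from the model's initial state for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConfigurationError, ModelDefinition
from .simulate import (
    AMP_MIN,
    PROMINENCE,
    TRANSIENT_FRAC,
    classify_oscillation,
    integrate,
)

__all__ = ["SweepResult", "sweep", "locate_transition", "set_parameter"]


@dataclass
class SweepPoint:
    value: float
    classification: str
    period: float                        # nan unless oscillatory
    envelope: dict[str, tuple[float, float]]   # species -> (min, max)


@dataclass
class SweepResult:
    parameter: str
    points: list[SweepPoint]

    def classifications(self) -> list[str]:
        return [p.classification for p in self.points]


def set_parameter(model: ModelDefinition, name: str, value: float) -> ModelDefinition:
    """Return a copy of the model with one rate constant, stress input or
    species total replaced."""
    params = model.parameters
    if name in ("stress", "stress1"):
        params = params.with_updates(**{name: value})
    elif name in params.rate_constants:
        params = params.with_updates(rate_constants={name: value})
    elif name.endswith("T") and name[:-1] in model.species_names:
        params = params.with_updates(totals={name[:-1]: value})
    elif name in model.species_names:
        params = params.with_updates(totals={name: value})
    else:
        raise ConfigurationError(f"unknown sweep parameter {name!r}")
    return model.with_parameters(params)


def _classify_point(model: ModelDefinition, t_end: float, x0,
                    transient_frac: float) -> SweepPoint:
    tc = integrate(model, t_end=t_end, x0=x0)
    n0 = int(len(tc.times) * transient_frac)
    envelope = {}
    classification = "steady"
    period = float("nan")
    # ULK1 is the lead oscillation readout; fall back to AMPK
    for probe in ("ULK1", "AMPK"):
        m = classify_oscillation(tc, probe, transient_frac=transient_frac)
        if m.classification != "steady":
            classification = m.classification
            period = m.period_mean
            break
    for j, name in enumerate(tc.species_names):
        seg = tc.activities[j, n0:]
        envelope[name] = (float(seg.min()), float(seg.max()))
    return SweepPoint(float("nan"), classification, period, envelope), tc.final_state


def sweep(model: ModelDefinition, parameter: str, grid,
          t_end: float = 300.0, warm_start: bool = True,
          transient_frac: float = TRANSIENT_FRAC) -> SweepResult:
    """Classify the attractor along a parameter grid."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    points = []
    x0 = None
    for value in grid:
        m = set_parameter(model, parameter, float(value))
        start = x0 if (warm_start and x0 is not None) else None
        if start is not None:
            start = np.minimum(start, m.totals)  # totals may have shrunk
        pt, x_end = _classify_point(m, t_end, start, transient_frac)
        pt.value = float(value)
        points.append(pt)
        x0 = x_end
    return SweepResult(parameter, points)


def locate_transition(model: ModelDefinition, parameter: str,
                      lo: float, hi: float, eps: float = 1e-3,
                      t_end: float = 300.0) -> float:
    """Bisect a steady <-> oscillatory boundary bracketed by (lo, hi).

    Classification at each probe is recomputed by cold-start simulation,
    so the result is deterministic and independent of probe order.
    """
    def classify(value: float) -> str:
        m = set_parameter(model, parameter, value)
        pt, _ = _classify_point(m, t_end, None, TRANSIENT_FRAC)
        return pt.classification

    c_lo, c_hi = classify(lo), classify(hi)
    if c_lo == c_hi:
        raise ValueError(
            f"no bracket: classification {c_lo!r} at both ends [{lo}, {hi}]")
    while hi - lo > eps:
        mid = 0.5 * (lo + hi)
        if classify(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_sweep_tsv(result: SweepResult, path) -> None:
    from .io import fmt
    names = sorted({n for p in result.points for n in p.envelope})
    header = ["param_value", "classification", "period"]
    for n in names:
        header += [f"{n}_min", f"{n}_max"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in result.points:
            row = [fmt(p.value), p.classification,
                   fmt(p.period) if np.isfinite(p.period) else "nan"]
            for n in names:
                lo, hi = p.envelope[n]
                row += [fmt(lo), fmt(hi)]
            fh.write("\t".join(row) + "\n")
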