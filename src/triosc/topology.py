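"""Topology-variant comparison: the wiring experiments behind the
amplified-negative-feedback story.

All variants are run under the identical stressed reference parameters;
only the optional AMPK/ULK1 edges (and the F-variant weight override)
differ.  The report records per-variant oscillation metrics for AMPK,
ULK1 and AUTOPHAGY, and evaluates the qualitative amplitude ordering the
wiring analysis predicts:

    amp(B) < amp(A), amp(C) < amp(A), amp(D) maximal among {A, B, C, D},
    amp(F_strong) < 0.5 * amp(F_weak)

with "amplitude" meaning ULK1 peak-to-trough.  These orderings are
properties of the reference parameterization, not universal theorems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelDefinition, ParameterSet, build_model
from .simulate import (
    IntegrationError,
    OscillationMetrics,
    classify_oscillation,
    integrate,
    no_stress_fixed_point,
)

__all__ = ["ComparisonReport", "OrderingCheck", "compare_variants"]

REPORT_SPECIES = ("AMPK", "ULK1", "AUTOPHAGY")


@dataclass
class OrderingCheck:
    name: str
    passed: bool
    detail: str


@dataclass
class ComparisonReport:
    metrics: dict[str, dict[str, OscillationMetrics]]   # variant -> species -> m
    failures: dict[str, str] = field(default_factory=dict)
    orderings: list[OrderingCheck] = field(default_factory=list)

    def amplitude(self, variant: str, species: str = "ULK1") -> float:
        m = self.metrics[variant][species]
        return m.amplitude if m.classification == "oscillatory" else 0.0

    def summary(self) -> str:
        lines = ["variant  species    class         period    amplitude"]
        for v, per_species in self.metrics.items():
            for s, m in per_species.items():
                per = f"{m.period_mean:8.2f}" if np.isfinite(m.period_mean) else "       -"
                lines.append(f"{v:<8} {s:<10} {m.classification:<12} {per}  "
                             f"{m.amplitude:9.4f}")
        for v, msg in self.failures.items():
            lines.append(f"{v:<8} FAILED: {msg}")
        lines.append("")
        for chk in self.orderings:
            lines.append(f"[{'PASS' if chk.passed else 'FAIL'}] {chk.name}: {chk.detail}")
        return "\n".join(lines)


def _run_variant(variant_id: str, params: ParameterSet, t_end: float):
    model = build_model(variant_id, params)
    rest = no_stress_fixed_point(model)
    tc = integrate(model, t_end=t_end, x0=rest.state)
    return {s: classify_oscillation(tc, s) for s in REPORT_SPECIES}


def compare_variants(params: ParameterSet, variants=("A", "B", "C", "D", "F_weak", "F_strong"),
                     t_end: float = 400.0) -> ComparisonReport:
    """Run each variant under the given (stressed) parameters and compare.

    Variants that fail to integrate are recorded and excluded from the
    ordering checks; the comparison continues.
    """
    variants = list(variants)
    if len(variants) < 2:
        raise ValueError("need >= 2 variants to compare")
    report = ComparisonReport(metrics={})
    for v in variants:
        try:
            report.metrics[v] = _run_variant(v, params, t_end)
        except (IntegrationError, RuntimeError) as exc:
            report.failures[v] = str(exc)
    amp = report.amplitude
    have = set(report.metrics)

    def check(name: str, needed: set[str], fn, detail_fn) -> None:
        if needed <= have:
            report.orderings.append(OrderingCheck(name, bool(fn()), detail_fn()))

    check("amp(B) < amp(A)", {"A", "B"},
          lambda: amp("B") < amp("A"),
          lambda: f"{amp('B'):.4f} vs {amp('A'):.4f}")
    check("amp(C) < amp(A)", {"A", "C"},
          lambda: amp("C") < amp("A"),
          lambda: f"{amp('C'):.4f} vs {amp('A'):.4f}")
    check("amp(D) maximal among A,B,C,D", {"A", "B", "C", "D"},
          lambda: amp("D") >= max(amp(v) for v in "ABCD"),
          lambda: ", ".join(f"{v}={amp(v):.4f}" for v in "ABCD"))
    check("amp(F_strong) < 0.5*amp(F_weak)", {"F_weak", "F_strong"},
          lambda: amp("F_strong") < 0.5 * amp("F_weak"),
          lambda: f"{amp('F_strong'):.4f} vs 0.5*{amp('F_weak'):.4f}")
    return report


def write_report_tsv(report: ComparisonReport, path) -> None:
    from .io import fmt
    with open(path, "w") as fh:
        fh.write("variant\tspecies\tclassification\tperiod_mean\tperiod_sd\t"
                 "amplitude\tn_cycles\n")
        for v, per_species in report.metrics.items():
            for s, m in per_species.items():
                fh.write("\t".join([
                    v, s, m.classification,
                    fmt(m.period_mean) if np.isfinite(m.period_mean) else "nan",
                    fmt(m.period_sd) if np.isfinite(m.period_sd) else "nan",
                    fmt(m.amplitude), str(m.n_cycles_analyzed)]) + "\n")
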