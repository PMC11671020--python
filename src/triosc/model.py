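"""Core model definition for the mTORC1-AMPK-ULK1 regulatory triangle.

The network couples the two master energy/growth regulators (AMPK, mTORC1)
to the autophagy-initiating kinase ULK1 and a delayed intermediate PROT
("extra protein") that carries AMPK's slow positive effect on ULK1.
AUTOPHAGY is a pure readout requiring both AMPK and ULK1 while being
inhibited by mTORC1.

Every species ``X`` with pool size ``X_T`` follows a Michaelis-Menten
activation/inactivation pair

    dX/dt = a(X) * (X_T - X) / (J_act + X_T - X)  -  i(X) * X / (J_inact + X)

where the activation rate ``a`` collects a basal rate plus one mass-action
term per positive incoming edge (weight times source activity), and the
inactivation rate ``i`` symmetrically collects the negative edges.  The
saturating prefactors vanish at the respective pool boundary, so the box
``prod_i [0, total_i]`` is forward invariant by construction.

Two dimensionless stress inputs enter the rate sums directly: ``stress``
adds to AMPK's activation rate and ``stress1`` to mTORC1's inactivation
rate (both points of action are configurable).  Rapamycin treatment is
modelled purely as a reduction of the mTORC1 pool total.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES_NAMES",
    "SpeciesSpec",
    "RegulatoryEdge",
    "TopologyVariant",
    "ParameterSet",
    "ModelDefinition",
    "ConfigurationError",
    "build_model",
    "rhs",
    "jacobian",
    "reference_parameters",
    "VARIANT_IDS",
]

SPECIES_NAMES = ("mTORC1", "AMPK", "ULK1", "PROT", "AUTOPHAGY")

#: Recognized topology variant identifiers (the wiring-comparison panels).
VARIANT_IDS = ("A", "B", "C", "D", "E", "F_weak", "F_strong", "custom")


class ConfigurationError(ValueError):
    """Raised for an invalid model/variant/parameter configuration."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One protein pool: name, total size and initial activity (a.u.)."""

    name: str
    total: float = 1.0
    initial_activity: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in SPECIES_NAMES:
            raise ConfigurationError(f"unknown species {self.name!r}")
        if not self.total > 0:
            raise ConfigurationError(f"{self.name}: total must be > 0")
        if not 0 <= self.initial_activity <= self.total:
            raise ConfigurationError(
                f"{self.name}: initial_activity {self.initial_activity} "
                f"outside [0, {self.total}]"
            )


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed regulatory edge.

    ``source`` may be a single species or a ``"X*Y"`` product (AND gate,
    used for the joint AMPK*ULK1 requirement on AUTOPHAGY).  By the sign
    convention of this package, positive edges scale the target's
    activation rate and negative edges its inactivation rate.
    """

    source: str
    target: str
    sign: str                      # "positive" | "negative"
    weight_param: str
    optional: bool = False

    def __post_init__(self) -> None:
        for s in self.sources:
            if s not in SPECIES_NAMES:
                raise ConfigurationError(f"edge source {s!r} not a species")
        if self.target not in SPECIES_NAMES:
            raise ConfigurationError(f"edge target {self.target!r} not a species")
        if self.sign not in ("positive", "negative"):
            raise ConfigurationError(f"edge sign {self.sign!r} invalid")

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(s.strip() for s in self.source.split("*"))

    @property
    def action(self) -> str:
        return "scales_activation" if self.sign == "positive" else "scales_inactivation"

    @property
    def key(self) -> str:
        arrow = "->" if self.sign == "positive" else "-|"
        return f"{self.source}{arrow}{self.target}"


#: The always-present wiring (loops 1-3 plus the AUTOPHAGY readout).
MANDATORY_EDGES = (
    RegulatoryEdge("AMPK", "mTORC1", "negative", "k_ampk_mtorc1"),
    RegulatoryEdge("mTORC1", "AMPK", "negative", "k_mtorc1_ampk"),
    RegulatoryEdge("ULK1", "mTORC1", "negative", "k_ulk1_mtorc1"),
    RegulatoryEdge("mTORC1", "ULK1", "negative", "k_mtorc1_ulk1"),
    RegulatoryEdge("AMPK", "PROT", "positive", "k_ampk_prot"),
    RegulatoryEdge("PROT", "ULK1", "positive", "k_prot_ulk1"),
    RegulatoryEdge("ULK1", "AMPK", "negative", "k_ulk1_ampk"),
    RegulatoryEdge("AMPK*ULK1", "AUTOPHAGY", "positive", "k_ampkulk1_auto"),
    RegulatoryEdge("mTORC1", "AUTOPHAGY", "negative", "k_mtorc1_auto"),
)

#: Optional edges toggled by topology variants.
OPTIONAL_EDGES = (
    RegulatoryEdge("AMPK", "ULK1", "negative", "k_ampk_ulk1_inh", optional=True),
    RegulatoryEdge("AMPK", "ULK1", "positive", "k_ampk_ulk1_act", optional=True),
    RegulatoryEdge("ULK1", "AMPK", "positive", "k_ulk1_ampk_act", optional=True),
)
_OPTIONAL_BY_KEY = {e.key: e for e in OPTIONAL_EDGES}

AMPK_INHIBITS_ULK1 = "AMPK-|ULK1"
AMPK_ACTIVATES_ULK1 = "AMPK->ULK1"
ULK1_ACTIVATES_AMPK = "ULK1->AMPK"

#: Which optional edges each named variant enables.  A is the reference
#: "amplified negative feedback" wiring; B drops the
#: AMPK-|ULK1 arm (simple delayed loop); C adds the counter-operating
#: AMPK->ULK1; D adds ULK1->AMPK; E and F add both (F with weak/strong
#: AMPK->ULK1 weight overrides relative to the ULK1-|AMPK weight).
VARIANT_EDGE_SETS: dict[str, frozenset[str]] = {
    "A": frozenset({AMPK_INHIBITS_ULK1}),
    "B": frozenset(),
    "C": frozenset({AMPK_INHIBITS_ULK1, AMPK_ACTIVATES_ULK1}),
    "D": frozenset({AMPK_INHIBITS_ULK1, ULK1_ACTIVATES_AMPK}),
    "E": frozenset({AMPK_INHIBITS_ULK1, AMPK_ACTIVATES_ULK1, ULK1_ACTIVATES_AMPK}),
    "F_weak": frozenset({AMPK_INHIBITS_ULK1, AMPK_ACTIVATES_ULK1, ULK1_ACTIVATES_AMPK}),
    "F_strong": frozenset({AMPK_INHIBITS_ULK1, AMPK_ACTIVATES_ULK1, ULK1_ACTIVATES_AMPK}),
}

#: F variants override the AMPK->ULK1 weight to 0.1x / 10x the variant-A
#: ULK1-|AMPK weight (a weak and a strong positive-loop regime).
F_WEAK_FACTOR = 0.1
F_STRONG_FACTOR = 10.0


@dataclass(frozen=True)
class TopologyVariant:
    """A named rewiring of the optional edges, plus weight overrides."""

    id: str = "A"
    enabled_optional_edges: frozenset[str] = field(default_factory=frozenset)
    weight_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id not in VARIANT_IDS:
            raise ConfigurationError(
                f"unknown variant id {self.id!r}; expected one of {VARIANT_IDS}"
            )
        for key in self.enabled_optional_edges:
            if key not in _OPTIONAL_BY_KEY:
                raise ConfigurationError(f"unknown optional edge {key!r}")

    @classmethod
    def named(cls, variant_id: str, params: "ParameterSet | None" = None,
              **weight_overrides: float) -> "TopologyVariant":
        """Build one of the named wiring-comparison variants.

        For F_weak/F_strong the AMPK->ULK1 weight override is derived from
        the ULK1-|AMPK weight in ``params`` unless given explicitly.
        """
        if variant_id == "custom":
            return cls("custom", frozenset(), dict(weight_overrides))
        if variant_id not in VARIANT_EDGE_SETS:
            raise ConfigurationError(f"unknown variant id {variant_id!r}")
        overrides = dict(weight_overrides)
        if variant_id in ("F_weak", "F_strong") and "k_ampk_ulk1_act" not in overrides:
            if params is None:
                raise ConfigurationError(
                    f"{variant_id} needs params to derive the AMPK->ULK1 weight"
                )
            factor = F_WEAK_FACTOR if variant_id == "F_weak" else F_STRONG_FACTOR
            overrides["k_ampk_ulk1_act"] = factor * params.get("k_ulk1_ampk")
        return cls(variant_id, VARIANT_EDGE_SETS[variant_id], overrides)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants (1/time), Michaelis constants (dimensionless),
    stress inputs and pool totals."""

    rate_constants: dict[str, float]
    michaelis_constants: dict[str, float]
    stress: float = 0.0
    stress1: float = 0.0
    totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.rate_constants.items():
            if v < 0:
                raise ConfigurationError(f"rate constant {name} = {v} < 0")
        for name, v in self.michaelis_constants.items():
            if not v > 0:
                raise ConfigurationError(f"Michaelis constant {name} = {v} <= 0")
        if self.stress < 0 or self.stress1 < 0:
            raise ConfigurationError("stress inputs must be >= 0")
        for name, v in self.totals.items():
            if not v > 0:
                raise ConfigurationError(f"total for {name} = {v} <= 0")

    def get(self, name: str) -> float:
        if name in self.rate_constants:
            return self.rate_constants[name]
        if name in self.michaelis_constants:
            return self.michaelis_constants[name]
        raise ConfigurationError(f"unknown parameter {name!r}")

    def total(self, species: str) -> float:
        return self.totals.get(species, 1.0)

    def with_updates(self, rate_constants: dict[str, float] | None = None,
                     stress: float | None = None, stress1: float | None = None,
                     totals: dict[str, float] | None = None) -> "ParameterSet":
        rc = dict(self.rate_constants)
        rc.update(rate_constants or {})
        tot = dict(self.totals)
        tot.update(totals or {})
        return ParameterSet(
            rate_constants=rc,
            michaelis_constants=dict(self.michaelis_constants),
            stress=self.stress if stress is None else stress,
            stress1=self.stress1 if stress1 is None else stress1,
            totals=tot,
        )


@dataclass(frozen=True)
class ModelDefinition:
    """Species + edges + parameters + active topology variant.

    Single source of truth for the ODE right-hand side.  ``stress_points``
    maps each stress input to its (species, rate-sum) point of action.
    """

    species: tuple[SpeciesSpec, ...]
    edges: tuple[RegulatoryEdge, ...]
    parameters: ParameterSet
    variant: TopologyVariant
    stress_points: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "stress": ("AMPK", "activation"),
            "stress1": ("mTORC1", "inactivation"),
        }
    )

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if list(names) != list(SPECIES_NAMES):
            raise ConfigurationError(
                f"species must be exactly {SPECIES_NAMES} in order, got {names}"
            )
        mandatory = {e.key for e in MANDATORY_EDGES}
        present = {e.key for e in self.edges}
        missing = mandatory - present
        if missing:
            raise ConfigurationError(f"mandatory edges missing: {sorted(missing)}")
        for e in self.edges:
            try:
                self.weight(e)
            except ConfigurationError:
                raise ConfigurationError(
                    f"edge {e.key}: weight parameter {e.weight_param!r} "
                    "missing from ParameterSet"
                ) from None
        for inp, (sp, which) in self.stress_points.items():
            if sp not in SPECIES_NAMES or which not in ("activation", "inactivation"):
                raise ConfigurationError(f"bad stress point {inp}: {(sp, which)}")

    # -- lookups -----------------------------------------------------------

    def weight(self, edge: RegulatoryEdge) -> float:
        if edge.weight_param in self.variant.weight_overrides:
            return self.variant.weight_overrides[edge.weight_param]
        return self.parameters.get(edge.weight_param)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def totals(self) -> np.ndarray:
        return np.array([s.total for s in self.species])

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_activity for s in self.species])

    def fingerprint(self) -> str:
        """Stable hash of everything that defines the dynamics."""
        payload = {
            "species": [(s.name, s.total, s.initial_activity) for s in self.species],
            "edges": [(e.key, e.weight_param, self.weight(e)) for e in self.edges],
            "rates": sorted(self.parameters.rate_constants.items()),
            "michaelis": sorted(self.parameters.michaelis_constants.items()),
            "stress": (self.parameters.stress, self.parameters.stress1),
            "totals": sorted(self.parameters.totals.items()),
            "variant": (self.variant.id, sorted(self.variant.enabled_optional_edges),
                        sorted(self.variant.weight_overrides.items())),
            "stress_points": sorted(self.stress_points.items()),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_parameters(self, params: ParameterSet) -> "ModelDefinition":
        species = tuple(
            replace(s, total=params.total(s.name)) if s.name in params.totals else s
            for s in self.species
        )
        return replace(self, species=species, parameters=params)

    # -- compiled right-hand side -----------------------------------------

    def _compiled(self):
        """Precompute per-species edge terms; cached on first use."""
        cache = self.__dict__.get("_rhs_cache")
        if cache is not None:
            return cache
        n = len(self.species)
        act_terms: list[list[tuple[float, tuple[int, ...]]]] = [[] for _ in range(n)]
        inact_terms: list[list[tuple[float, tuple[int, ...]]]] = [[] for _ in range(n)]
        for e in self.edges:
            w = self.weight(e)
            srcs = tuple(self.index(s) for s in e.sources)
            t = self.index(e.target)
            (act_terms if e.sign == "positive" else inact_terms)[t].append((w, srcs))
        base_act = np.array(
            [self.parameters.get(f"k_act_{s.name}") for s in self.species])
        base_inact = np.array(
            [self.parameters.get(f"k_inact_{s.name}") for s in self.species])
        for inp, value in (("stress", self.parameters.stress),
                           ("stress1", self.parameters.stress1)):
            sp, which = self.stress_points[inp]
            i = self.index(sp)
            if which == "activation":
                base_act = base_act.copy()
                base_act[i] += value
            else:
                base_inact = base_inact.copy()
                base_inact[i] += value
        j_act = np.array(
            [self.parameters.get(f"J_act_{s.name}") for s in self.species])
        j_inact = np.array(
            [self.parameters.get(f"J_inact_{s.name}") for s in self.species])
        cache = (act_terms, inact_terms, base_act, base_inact, j_act, j_inact,
                 self.totals)
        self.__dict__["_rhs_cache"] = cache
        return cache

    def rates(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Total activation and inactivation rate sums at ``state``."""
        act_terms, inact_terms, base_act, base_inact, *_ = self._compiled()
        x = np.asarray(state, dtype=float)
        act = base_act.copy()
        inact = base_inact.copy()
        for i in range(len(x)):
            for w, srcs in act_terms[i]:
                prod = w
                for s in srcs:
                    prod *= x[s]
                act[i] += prod
            for w, srcs in inact_terms[i]:
                prod = w
                for s in srcs:
                    prod *= x[s]
                inact[i] += prod
        return act, inact


def build_model(variant: TopologyVariant | str, params: ParameterSet,
                initial_activities: dict[str, float] | None = None,
                stress_points: dict[str, tuple[str, str]] | None = None,
                ) -> ModelDefinition:
    """Assemble a :class:`ModelDefinition` for a topology variant.

    ``variant`` may be a :class:`TopologyVariant` or a variant id string.
    Optional edges are included iff enabled by the variant.
    """
    if isinstance(variant, str):
        variant = TopologyVariant.named(variant, params)
    edges = list(MANDATORY_EDGES)
    for key in sorted(variant.enabled_optional_edges):
        edges.append(_OPTIONAL_BY_KEY[key])
    init = initial_activities or {}
    species = tuple(
        SpeciesSpec(name, total=params.total(name),
                    initial_activity=init.get(name, 0.0))
        for name in SPECIES_NAMES
    )
    kwargs = {}
    if stress_points is not None:
        kwargs["stress_points"] = stress_points
    return ModelDefinition(species=species, edges=tuple(edges),
                           parameters=params, variant=variant, **kwargs)


def rhs(model: ModelDefinition, state: np.ndarray, *, tol: float = 1e-6,
        check: bool = True) -> np.ndarray:
    """Per-species derivative vector dX/dt at ``state``.

    Each derivative is (activation term) - (inactivation term); the
    saturating prefactors guarantee forward invariance of the box.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(model.species),):
        raise ValueError(
            f"state has shape {x.shape}, expected ({len(model.species)},)")
    totals = model.totals
    if check and (np.any(x < -tol) or np.any(x > totals + tol)):
        raise ValueError(f"state {x} outside [0, totals] beyond tol={tol}")
    *_, j_act, j_inact, _ = model._compiled()
    act, inact = model.rates(x)
    headroom = np.clip(totals - x, 0.0, None)
    occupancy = np.clip(x, 0.0, None)
    return act * headroom / (j_act + headroom) - inact * occupancy / (j_inact + occupancy)


def jacobian(model: ModelDefinition, state: np.ndarray,
             rel_step: float = 1e-6, abs_floor: float = 1e-8) -> np.ndarray:
    """Jacobian of the RHS by central finite differences.

    Relative step ``rel_step`` with absolute floor ``abs_floor``; steps are
    taken without the domain check so boundary states remain usable.
    """
    x = np.asarray(state, dtype=float)
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        h = max(rel_step * abs(x[j]), abs_floor)
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        fp = rhs(model, xp, check=False)
        fm = rhs(model, xm, check=False)
        J[:, j] = (fp - fm) / (2 * h)
    return J


def reference_parameters() -> ParameterSet:
    """The package's reference parameterization (see data/reference_model.yaml)."""
    from .io import load_config, reference_config_path
    return load_config(reference_config_path()).parameters
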