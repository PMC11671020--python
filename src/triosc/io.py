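"""Configuration I/O, TSV serialization and XPP-AUT export.

Model configs are YAML or JSON documents with sections ``species``,
``edges``, ``parameters``, ``variant`` (and optionally ``stress_points``).
All numbers are serialized with 12 significant digits so that repeated
exports diff cleanly.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import yaml

from .model import (
    ConfigurationError,
    ModelDefinition,
    ParameterSet,
    RegulatoryEdge,
    SpeciesSpec,
    TopologyVariant,
    SPECIES_NAMES,
)

__all__ = [
    "load_config",
    "save_config",
    "reference_config_path",
    "reference_model",
    "export_xpp_ode",
    "write_timecourse",
    "read_timecourse",
    "fmt",
]

#: Significant digits used for every serialized number.
SIG_DIGITS = 12


def fmt(x: float) -> str:
    """Render a number with 12 significant digits, trimming trailing zeros."""
    s = f"{float(x):.{SIG_DIGITS}g}"
    return s


def reference_config_path() -> Path:
    """Path of the packaged reference model configuration."""
    return Path(importlib.resources.files("triosc") / "data" / "reference_model.yaml")


def reference_model(variant: str = "A", *, stress: float | None = None,
                    stress1: float | None = None,
                    mtorc1_total: float | None = None) -> ModelDefinition:
    """Load the reference model, optionally overriding scenario inputs.

    ``mtorc1_total`` models rapamycin treatment (a reduced mTORC1 pool).
    """
    model = load_config(reference_config_path())
    params = model.parameters
    totals = {"mTORC1": mtorc1_total} if mtorc1_total is not None else None
    params = params.with_updates(stress=stress, stress1=stress1, totals=totals)
    from .model import build_model
    return build_model(variant, params)


def _parse_params(section: dict) -> ParameterSet:
    return ParameterSet(
        rate_constants={k: float(v) for k, v in section.get("rate_constants", {}).items()},
        michaelis_constants={k: float(v) for k, v in section.get("michaelis_constants", {}).items()},
        stress=float(section.get("stress", 0.0)),
        stress1=float(section.get("stress1", 0.0)),
        totals={k: float(v) for k, v in section.get("totals", {}).items()},
    )


def load_config(path: str | Path) -> ModelDefinition:
    """Read a model configuration (YAML or JSON) into a ModelDefinition."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    for section in ("species", "parameters", "variant"):
        if section not in doc:
            raise ConfigurationError(f"{path}: missing section {section!r}")
    params = _parse_params(doc["parameters"])
    vsec = doc["variant"]
    variant = TopologyVariant.named(
        vsec.get("id", "A"), params,
        **{k: float(v) for k, v in vsec.get("weight_overrides", {}).items()},
    ) if vsec.get("id", "A") != "custom" else TopologyVariant(
        "custom",
        frozenset(vsec.get("enabled_optional_edges", [])),
        {k: float(v) for k, v in vsec.get("weight_overrides", {}).items()},
    )
    species = tuple(
        SpeciesSpec(
            name,
            total=float(doc["species"][name].get("total", params.total(name))),
            initial_activity=float(doc["species"][name].get("initial_activity", 0.0)),
        )
        for name in SPECIES_NAMES
    )
    edges = None
    if "edges" in doc:
        edges = tuple(
            RegulatoryEdge(e["source"], e["target"], e["sign"], e["weight_param"],
                           bool(e.get("optional", False)))
            for e in doc["edges"]
        )
    kwargs = {}
    if "stress_points" in doc:
        kwargs["stress_points"] = {
            k: (v[0], v[1]) for k, v in doc["stress_points"].items()
        }
    if edges is None:
        from .model import build_model
        base = build_model(variant, params,
                           initial_activities={s.name: s.initial_activity for s in species},
                           **kwargs)
        return base
    return ModelDefinition(species=species, edges=edges, parameters=params,
                           variant=variant, **kwargs)


def save_config(model: ModelDefinition, path: str | Path) -> None:
    """Write a ModelDefinition back to YAML/JSON. Round-trips the fingerprint."""
    doc = {
        "species": {
            s.name: {"total": float(fmt(s.total)),
                     "initial_activity": float(fmt(s.initial_activity))}
            for s in model.species
        },
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign,
             "weight_param": e.weight_param, "optional": e.optional}
            for e in model.edges
        ],
        "parameters": {
            "rate_constants": {k: float(fmt(v))
                               for k, v in sorted(model.parameters.rate_constants.items())},
            "michaelis_constants": {k: float(fmt(v))
                                    for k, v in sorted(model.parameters.michaelis_constants.items())},
            "stress": float(fmt(model.parameters.stress)),
            "stress1": float(fmt(model.parameters.stress1)),
            "totals": {k: float(fmt(v)) for k, v in sorted(model.parameters.totals.items())},
        },
        "variant": {
            "id": model.variant.id,
            "enabled_optional_edges": sorted(model.variant.enabled_optional_edges),
            "weight_overrides": {k: float(fmt(v))
                                 for k, v in sorted(model.variant.weight_overrides.items())},
        },
        "stress_points": {k: list(v) for k, v in sorted(model.stress_points.items())},
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# TSV time courses

def write_timecourse(tc, path: str | Path) -> None:
    """TSV with header time<TAB><species...>, 12 significant digits."""
    path = Path(path)
    names = tc.species_names
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(names) + "\n")
        for i, t in enumerate(tc.times):
            row = [fmt(t)] + [fmt(tc.activities[j, i]) for j in range(len(names))]
            fh.write("\t".join(row) + "\n")


def read_timecourse(path: str | Path):
    from .simulate import TimeCourse
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    return TimeCourse(times=data[:, 0], activities=data[:, 1:].T,
                      species_names=tuple(header[1:]), model_fingerprint="")


# ---------------------------------------------------------------------------
# XPP-AUT export

def _xpp_name(species: str) -> str:
    return species


def _total_param(species: str) -> str:
    return f"{species}T"


def _rate_expr(model: ModelDefinition, species: str) -> str:
    """Build the dX/dt expression using parameter *names* (overrides inlined)."""
    act_terms = [f"k_act_{species}"]
    inact_terms = [f"k_inact_{species}"]
    for inp, (sp, which) in sorted(model.stress_points.items()):
        if sp == species:
            (act_terms if which == "activation" else inact_terms).append(inp)
    for e in model.edges:
        if e.target != species:
            continue
        if e.weight_param in model.variant.weight_overrides:
            w = fmt(model.variant.weight_overrides[e.weight_param])
        else:
            w = e.weight_param
        term = w + "*" + "*".join(_xpp_name(s) for s in e.sources)
        (act_terms if e.sign == "positive" else inact_terms).append(term)
    act = " + ".join(act_terms)
    inact = " + ".join(inact_terms)
    x = _xpp_name(species)
    xt = _total_param(species)
    return (f"({act})*({xt}-{x})/(J_act_{species}+{xt}-{x})"
            f" - ({inact})*{x}/(J_inact_{species}+{x})")


def export_xpp_ode(model: ModelDefinition) -> str:
    """Emit an XPP-AUT .ode document equivalent to the model RHS.

    One ``dX/dt`` line per species, one ``par`` line per parameter
    (12 significant digits), ``init`` lines and a terminating ``done``.
    """
    lines = ["# autophagy-induction oscillator model export"]
    for s in model.species:
        lines.append(f"d{_xpp_name(s.name)}/dt = {_rate_expr(model, s.name)}")
    for s in model.species:
        lines.append(f"init {_xpp_name(s.name)}={fmt(s.initial_activity)}")
    for name, value in sorted(model.parameters.rate_constants.items()):
        lines.append(f"par {name}={fmt(value)}")
    for name, value in sorted(model.parameters.michaelis_constants.items()):
        lines.append(f"par {name}={fmt(value)}")
    lines.append(f"par stress={fmt(model.parameters.stress)}")
    lines.append(f"par stress1={fmt(model.parameters.stress1)}")
    for s in model.species:
        lines.append(f"par {_total_param(s.name)}={fmt(s.total)}")
    lines.append("done")
    return "\n".join(lines) + "\n"
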