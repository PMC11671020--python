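"""Candidate filter for the "extra protein" on signed interaction tables.

The model's delayed positive arm AMPK -> PROT -> ULK1 predicts a concrete
signature for the intermediate's identity in curated autophagy interaction
networks: a protein qualifies as an "extra protein" candidate if it is
(1) stimulated by ULK1 and (2) itself stimulates AMPK, both as direct
signed interactions.  Layer labels (core / direct / additional) are
carried as metadata and reported but do not restrict the filter.

Input tables are delimited text (TSV or CSV) with mandatory columns
``source``, ``target``, ``sign``, ``layer``; extra columns are ignored.
A seeded synthetic-table generator with planted true candidates and
near-miss decoys provides a ground-truth test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "CandidateReport",
    "FormatError",
    "load_interactions",
    "write_interactions",
    "filter_candidates",
    "generate_synthetic_network",
    "write_candidate_report",
]

SIGNS = ("stimulation", "inhibition", "unknown")
LAYERS = ("core", "direct", "additional")


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    source: str
    target: str
    sign: str
    layer: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise FormatError("protein symbols must be nonempty")
        if self.sign not in SIGNS:
            raise FormatError(f"sign {self.sign!r} not in {SIGNS}")
        if self.layer not in LAYERS:
            raise FormatError(f"layer {self.layer!r} not in {LAYERS}")


@dataclass
class CandidateReport:
    candidates: list[str]                                  # sorted, unique
    support: dict[str, list[InteractionRecord]] = field(default_factory=dict)

    def n_edges(self, candidate: str, kind: str) -> int:
        recs = self.support.get(candidate, [])
        if kind == "ulk1":
            return sum(1 for r in recs if r.target == candidate)
        return sum(1 for r in recs if r.source == candidate)


def load_interactions(path: str | Path) -> tuple[list[InteractionRecord], list[str]]:
    """Read a TSV/CSV interaction table.

    Returns (records, errors): malformed rows are collected as messages
    rather than aborting the load.  Sign and layer values are case-folded.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"source", "target", "sign", "layer"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    records: list[InteractionRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            records.append(InteractionRecord(
                source=row["source"].strip(),
                target=row["target"].strip(),
                sign=row["sign"].strip().lower(),
                layer=row["layer"].strip().lower(),
            ))
        except FormatError as exc:
            errors.append(f"row {i + 2}: {exc}")
    return records, errors


def write_interactions(records, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame([{"source": r.source, "target": r.target,
                        "sign": r.sign, "layer": r.layer} for r in records])
    df.to_csv(path, sep=sep, index=False)


def filter_candidates(records, ulk1_symbol: str = "ULK1",
                      ampk_symbol: str = "AMPK") -> CandidateReport:
    """Select proteins stimulated by ULK1 that stimulate AMPK.

    A pure set operation: order and duplication of the input rows never
    change the result.  Unknown-sign records never qualify, and the
    anchors themselves are excluded from candidacy.
    """
    induced = {}      # protein -> supporting ULK1 -> protein records
    activates = {}    # protein -> supporting protein -> AMPK records
    for r in records:
        if r.sign != "stimulation":
            continue
        if r.source == ulk1_symbol and r.target not in (ulk1_symbol, ampk_symbol):
            induced.setdefault(r.target, []).append(r)
        if r.target == ampk_symbol and r.source not in (ulk1_symbol, ampk_symbol):
            activates.setdefault(r.source, []).append(r)
    names = sorted(set(induced) & set(activates))
    support = {n: sorted(set(induced[n]) | set(activates[n]),
                         key=lambda r: (r.source, r.target, r.layer))
               for n in names}
    return CandidateReport(candidates=names, support=support)


def generate_synthetic_network(n_proteins: int = 60, n_planted: int = 8,
                               n_decoys: int = 500, seed: int = 0,
                               ulk1_symbol: str = "ULK1",
                               ampk_symbol: str = "AMPK",
                               ) -> tuple[list[InteractionRecord], set[str]]:
    """Seeded interaction table with planted candidates and decoys.

    Planted proteins receive both qualifying edges (ULK1 -> X stimulation
    and X -> AMPK stimulation).  Decoys are near-misses drawn uniformly
    from: one qualifying edge only, wrong sign, wrong direction, or an
    unrelated random edge.  Deterministic for a given seed.
    """
    if n_planted > n_proteins:
        raise ValueError("n_planted must be <= n_proteins")
    if n_proteins < 1 or n_decoys < 0:
        raise ValueError("inconsistent counts")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    planted = set(rng.choice(proteins, size=n_planted, replace=False).tolist())
    others = [p for p in proteins if p not in planted]
    records: list[InteractionRecord] = []

    def layer() -> str:
        return LAYERS[rng.integers(0, len(LAYERS))]

    for p in sorted(planted):
        records.append(InteractionRecord(ulk1_symbol, p, "stimulation", layer()))
        records.append(InteractionRecord(p, ampk_symbol, "stimulation", layer()))
    kinds = ("only_first", "only_second", "wrong_sign_first", "wrong_sign_second",
             "reversed", "random")
    for _ in range(n_decoys):
        kind = kinds[rng.integers(0, len(kinds))]
        if others:
            p = others[rng.integers(0, len(others))]
        else:
            p = proteins[rng.integers(0, len(proteins))]
        if kind == "only_first":
            records.append(InteractionRecord(ulk1_symbol, p, "stimulation", layer()))
        elif kind == "only_second":
            records.append(InteractionRecord(p, ampk_symbol, "stimulation", layer()))
        elif kind == "wrong_sign_first":
            records.append(InteractionRecord(ulk1_symbol, p, "inhibition", layer()))
            records.append(InteractionRecord(p, ampk_symbol, "stimulation", layer()))
        elif kind == "wrong_sign_second":
            records.append(InteractionRecord(ulk1_symbol, p, "stimulation", layer()))
            records.append(InteractionRecord(p, ampk_symbol, "inhibition", layer()))
        elif kind == "reversed":
            records.append(InteractionRecord(p, ulk1_symbol, "stimulation", layer()))
            records.append(InteractionRecord(ampk_symbol, p, "stimulation", layer()))
        else:
            a = proteins[rng.integers(0, len(proteins))]
            b = proteins[rng.integers(0, len(proteins))]
            if a != b:
                records.append(InteractionRecord(
                    a, b, SIGNS[rng.integers(0, len(SIGNS))], layer()))
    # near-miss decoys must not accidentally complete a qualifying pair
    got = {c for c in filter_candidates(records, ulk1_symbol, ampk_symbol).candidates}
    spurious = got - planted
    if spurious:
        records = [r for r in records
                   if not (r.source == ulk1_symbol and r.target in spurious
                           and r.sign == "stimulation")]
    return records, planted


def write_candidate_report(report: CandidateReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate\tn_ulk1_edges\tn_ampk_edges\tlayers_seen\n")
        for c in report.candidates:
            layers = sorted({r.layer for r in report.support.get(c, [])})
            fh.write(f"{c}\t{report.n_edges(c, 'ulk1')}\t"
                     f"{report.n_edges(c, 'ampk')}\t{','.join(layers)}\n")
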