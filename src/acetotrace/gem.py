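"""Flux balance analysis and the one-at-a-time carbon-source screen.

A genome-scale metabolic model (GEM) is a stoichiometric network with
reaction bounds and a biomass objective. FBA maximises biomass flux subject
to steady state (S v = 0) and the bounds, here by linear programming
(HiGHS via scipy). The screen opens carbon-source exchange reactions one at
a time on a basal medium, records growth, then re-runs with an acetate
exchange additionally opened, and classifies each condition:

* growth below ``no_growth_threshold`` (default 0.001 /hr) is "no growth";
* acetate "has an effect" if it raises growth by at least
  ``effect_threshold`` (default 0.0001 /hr).

Carbon influx caps are expressed in mmol carbon/gDW/hr: a cap of 100 gives
a C3 source a molar influx bound of 100/3 mmol/gDW/hr, equalising carbon
supply across sources.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import chem

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ScreenResult",
    "read_model",
    "write_model",
    "fba",
    "apply_medium",
    "classify_growth",
    "cometabolism_screen",
]

DEFAULT_BOUND = 1000.0
FEASIBILITY_TOL = 1e-9
GROWTH_DECIMALS = 12  # growth rounded before threshold comparison


@dataclass(frozen=True)
class Metabolite:
    id: str
    formula: str | None = None
    compartment: str | None = None
    name: str = ""

    @property
    def carbons(self) -> int:
        return chem.carbon_count(self.formula) if self.formula else 0


@dataclass(frozen=True)
class Reaction:
    id: str
    metabolites: dict  # metabolite id -> stoichiometric coefficient
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound exceeds upper bound")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        return len(self.metabolites) == 1


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric model with exactly one biomass objective reaction."""

    id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    objective: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        for rxn in self.reactions:
            for met in rxn.metabolites:
                if met not in met_ids:
                    raise ValueError(
                        f"reaction {rxn.id} references undefined metabolite {met!r}"
                    )
        if self.objective not in rxn_ids:
            raise ValueError(f"no objective: reaction {self.objective!r} not in model")

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    @property
    def exchanges(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def exchange_for(self, met_id: str) -> Reaction:
        """The exchange reaction whose single participant is ``met_id``."""
        for rxn in self.exchanges:
            if met_id in rxn.metabolites:
                return rxn
        raise KeyError(f"metabolite {met_id!r} has no exchange reaction")

    def stoichiometric_matrix(self) -> pd.DataFrame:
        S = pd.DataFrame(
            0.0,
            index=[m.id for m in self.metabolites],
            columns=[r.id for r in self.reactions],
        )
        for rxn in self.reactions:
            for met, coef in rxn.metabolites.items():
                S.loc[met, rxn.id] = coef
        return S

    def with_bounds(self, overrides: dict) -> "MetabolicModel":
        """Copy with ``{reaction id: (lower, upper)}`` bound overrides."""
        new = []
        for rxn in self.reactions:
            if rxn.id in overrides:
                lb, ub = overrides[rxn.id]
                rxn = replace(rxn, lower_bound=float(lb), upper_bound=float(ub))
            new.append(rxn)
        missing = set(overrides) - {r.id for r in self.reactions}
        if missing:
            raise KeyError(f"unknown reaction(s) in bound overrides: {sorted(missing)}")
        return replace(self, reactions=tuple(new))


@dataclass(frozen=True)
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    growth_rate: float | None
    fluxes: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class ScreenResult:
    """Per-source growth with/without the co-substrate plus classifications."""

    table: pd.DataFrame
    no_growth_threshold: float
    effect_threshold: float
    warnings: tuple[str, ...] = ()


def read_model(path) -> MetabolicModel:
    """Read a COBRA-style JSON model.

    The biomass objective is taken from a top-level ``objective`` field or,
    failing that, from the unique reaction with ``objective_coefficient`` 1.
    """
    with open(path) as fh:
        doc = json.load(fh)
    mets = tuple(
        Metabolite(
            id=m["id"],
            formula=m.get("formula"),
            compartment=m.get("compartment"),
            name=m.get("name", ""),
        )
        for m in doc["metabolites"]
    )
    rxns = tuple(
        Reaction(
            id=r["id"],
            metabolites={k: float(v) for k, v in r["metabolites"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
            name=r.get("name", ""),
        )
        for r in doc["reactions"]
    )
    objective = doc.get("objective")
    if objective is None:
        flagged = [
            r["id"] for r in doc["reactions"] if r.get("objective_coefficient", 0)
        ]
        if len(flagged) != 1:
            raise ValueError(f"no objective in {path}: expected exactly one, got {flagged}")
        objective = flagged[0]
    return MetabolicModel(
        id=doc.get("id", "model"), metabolites=mets, reactions=rxns, objective=objective
    )


def write_model(model: MetabolicModel, path) -> None:
    """Write COBRA-style JSON (readable back by :func:`read_model` and by cobrapy)."""
    doc = {
        "id": model.id,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment or "c",
                "formula": m.formula or "",
                "charge": 0,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.metabolites,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": "",
                "objective_coefficient": 1 if r.id == model.objective else 0,
            }
            for r in model.reactions
        ],
        "genes": [],
        "compartments": {
            c: c for c in sorted({m.compartment or "c" for m in model.metabolites})
        },
        "objective": model.objective,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximise the biomass objective subject to S v = 0 and the bounds."""
    S = model.stoichiometric_matrix().to_numpy()
    n = len(model.reactions)
    c = np.zeros(n)
    c[[r.id for r in model.reactions].index(model.objective)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", growth_rate=None)
    if res.status == 3:
        return FluxSolution(status="unbounded", growth_rate=None)
    if not res.success:
        return FluxSolution(status="infeasible", growth_rate=None)
    fluxes = pd.Series(res.x, index=[r.id for r in model.reactions])
    if np.max(np.abs(S @ res.x)) > 1e-6:
        raise RuntimeError("LP solution violates steady state beyond tolerance")
    return FluxSolution(status="optimal", growth_rate=float(-res.fun), fluxes=fluxes)


def apply_medium(
    model: MetabolicModel,
    basal: set[str] | list[str] = (),
    carbon_sources: set[str] | list[str] = (),
    carbon_influx_cap: float = 100.0,
) -> MetabolicModel:
    """Configure exchange bounds for a growth medium.

    Influx is the negative direction of an exchange reaction. Basal
    metabolites get unrestricted influx; each carbon source gets a molar
    influx bound of ``carbon_influx_cap / carbon count``; every other
    carbon-containing exchange is closed to influx. Secretion is left
    unrestricted. Idempotent.
    """
    basal = set(basal)
    carbon_sources = set(carbon_sources)
    overrides: dict[str, tuple[float, float]] = {}
    configured: set[str] = set()
    for met_id in basal:
        rxn = model.exchange_for(met_id)
        overrides[rxn.id] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        configured.add(met_id)
    for met_id in carbon_sources:
        n_c = model.metabolite(met_id).carbons
        if n_c == 0:
            raise ValueError(f"carbon source {met_id!r} contains no carbon")
        rxn = model.exchange_for(met_id)
        overrides[rxn.id] = (-carbon_influx_cap / n_c, DEFAULT_BOUND)
        configured.add(met_id)
    for rxn in model.exchanges:
        (met_id,) = rxn.metabolites
        if met_id in configured:
            continue
        if model.metabolite(met_id).carbons > 0:
            overrides[rxn.id] = (0.0, DEFAULT_BOUND)
    return model.with_bounds(overrides)


def classify_growth(
    growth_without: float,
    growth_with: float,
    no_growth_threshold: float = 0.001,
    effect_threshold: float = 0.0001,
) -> dict:
    """Pure threshold classification of one screen row."""
    gw = round(growth_without, GROWTH_DECIMALS)
    ga = round(growth_with, GROWTH_DECIMALS)
    return {
        "grows_without": gw >= no_growth_threshold,
        "grows_with": ga >= no_growth_threshold,
        "acetate_effect": round(ga - gw, GROWTH_DECIMALS) >= effect_threshold,
    }


def cometabolism_screen(
    model: MetabolicModel,
    carbon_sources: list[str],
    basal: set[str] | list[str] = (),
    co_substrate: str = "ac_e",
    carbon_influx_cap: float = 100.0,
    no_growth_threshold: float = 0.001,
    effect_threshold: float = 0.0001,
) -> ScreenResult:
    """One-at-a-time carbon-source screen with and without the co-substrate.

    For each source: FBA on basal + source, then FBA with the co-substrate
    (acetate) exchange additionally opened under the same per-metabolite
    carbon cap. Opening an exchange relaxes the LP, so growth with the
    co-substrate can never be lower; this is asserted per row.
    """
    model.exchange_for(co_substrate)  # fail early if acetate is not exchangeable
    notes: list[str] = []
    full = apply_medium(model, basal, set(carbon_sources) | {co_substrate}, carbon_influx_cap)
    sol_full = fba(full)
    if not sol_full.optimal or sol_full.growth_rate < no_growth_threshold:
        msg = "model does not grow even with every screened source open"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    rows = []
    for source in sorted(carbon_sources):
        without = fba(apply_medium(model, basal, {source}, carbon_influx_cap))
        with_co = fba(
            apply_medium(model, basal, {source, co_substrate}, carbon_influx_cap)
        )
        gw = without.growth_rate if without.optimal else 0.0
        ga = with_co.growth_rate if with_co.optimal else 0.0
        if ga < gw - FEASIBILITY_TOL:
            raise RuntimeError(
                f"relaxation monotonicity violated for {source}: {ga} < {gw}"
            )
        row = {
            "carbon_source": source,
            "growth_without_acetate": round(gw, GROWTH_DECIMALS) + 0.0,
            "growth_with_acetate": round(ga, GROWTH_DECIMALS) + 0.0,
        }
        row.update(classify_growth(gw, ga, no_growth_threshold, effect_threshold))
        rows.append(row)
    return ScreenResult(
        table=pd.DataFrame(rows),
        no_growth_threshold=no_growth_threshold,
        effect_threshold=effect_threshold,
        warnings=tuple(notes),
    )
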