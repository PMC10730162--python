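"""Stoichiometric model handling and the metabolite-producibility screen.

The screen asks, for each (source metabolite, oxygen scenario): after
constraining the model to a minimal medium plus the source at a fixed uptake
rate, and requiring at least a fraction of the maximal growth rate, what is
the maximum attainable production flux of each target metabolite?  A target
is called producible when that maximum exceeds a small epsilon.  Oxygen is
varied over anoxic / microaerobic / aerobic uptake allowances.

All optimisation is plain linear programming (steady state S.v = 0 with flux
bounds) solved with HiGHS via scipy.  Only optimal objective values are
contractual; flux vectors are solver-dependent under degeneracy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from xml.etree import ElementTree as ET

import numpy as np
from scipy.optimize import linprog

from ._util import ValidationError

#: default oxygen uptake allowances, mmol h^-1 gDW^-1
OXYGEN_LEVELS = {"anoxic": 0.0, "microaerobic": 1.0, "aerobic": 10.0}


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]  # metabolite -> coefficient (negative = consumed)
    lb: float
    ub: float

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub)


@dataclass
class MetabolicModel:
    metabolites: list[str]
    reactions: list[Reaction]
    biomass: str
    exchanges: dict[str, str] = field(default_factory=dict)  # metabolite -> reaction id
    notes: dict = field(default_factory=dict)

    def validate(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValidationError("duplicate reaction ids")
        if self.biomass not in rids:
            raise ValidationError(f"biomass reaction {self.biomass!r} missing")
        met_set = set(self.metabolites)
        used: set[str] = set()
        for r in self.reactions:
            if r.lb > r.ub:
                raise ValidationError(f"reaction {r.id}: lower bound exceeds upper")
            for met, coef in r.stoich.items():
                if coef == 0:
                    raise ValidationError(f"reaction {r.id}: zero coefficient for {met}")
                if met not in met_set:
                    raise ValidationError(f"reaction {r.id}: unknown metabolite {met}")
                used.add(met)
        dangling = sorted(met_set - used)
        if dangling:
            raise ValidationError(f"dangling metabolites: {dangling}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolites),
            [r.copy() for r in self.reactions],
            self.biomass,
            dict(self.exchanges),
            dict(self.notes),
        )

    def stoichiometric_matrix(self) -> np.ndarray:
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        s = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                s[met_index[met], j] = coef
        return s

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metabolites": list(self.metabolites),
            "reactions": [
                {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub}
                for r in self.reactions
            ],
            "biomass": self.biomass,
            "exchanges": dict(self.exchanges),
            "notes": self.notes,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def save_sbml(self, path: str | Path) -> None:
        """Write the SBML-subset dialect (species, reactions, stoichiometry,
        reversibility; bounds carried as reaction attributes)."""
        sbml = ET.Element("sbml", level="3", version="1")
        model = ET.SubElement(sbml, "model", id="model", biomass=self.biomass)
        species_list = ET.SubElement(model, "listOfSpecies")
        for met in self.metabolites:
            ET.SubElement(species_list, "species", id=met)
        rxn_list = ET.SubElement(model, "listOfReactions")
        for r in self.reactions:
            rxn = ET.SubElement(
                rxn_list,
                "reaction",
                id=r.id,
                reversible=str(r.reversible).lower(),
                lb=repr(r.lb),
                ub=repr(r.ub),
            )
            reactants = ET.SubElement(rxn, "listOfReactants")
            products = ET.SubElement(rxn, "listOfProducts")
            for met, coef in r.stoich.items():
                parent = reactants if coef < 0 else products
                ET.SubElement(
                    parent, "speciesReference", species=met, stoichiometry=repr(abs(coef))
                )
        ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="unicode")


def _detect_exchanges(model: MetabolicModel) -> dict[str, str]:
    exchanges = {}
    for r in model.reactions:
        if r.id == model.biomass:
            continue
        if len(r.stoich) == 1:
            met = next(iter(r.stoich))
            exchanges.setdefault(met, r.id)
    return exchanges


def load_model(path: str | Path, dialect: str = "json") -> MetabolicModel:
    """Load a model from the JSON dialect or the SBML subset.

    Exchanges are auto-detected as single-metabolite boundary reactions when
    the file does not annotate them.
    """
    path = Path(path)
    if dialect == "json":
        raw = json.loads(path.read_text())
        if "biomass" not in raw:
            raise ValidationError("model file missing biomass reaction id")
        model = MetabolicModel(
            metabolites=list(raw["metabolites"]),
            reactions=[
                Reaction(r["id"], {m: float(c) for m, c in r["stoich"].items()},
                         float(r["lb"]), float(r["ub"]))
                for r in raw["reactions"]
            ],
            biomass=raw["biomass"],
            exchanges={str(k): str(v) for k, v in raw.get("exchanges", {}).items()},
            notes=raw.get("notes", {}),
        )
    elif dialect == "sbml-subset":
        root = ET.parse(path).getroot()
        model_el = root.find("model")
        if model_el is None or "biomass" not in model_el.attrib:
            raise ValidationError("SBML subset missing model/biomass")
        mets = [s.get("id") for s in model_el.find("listOfSpecies")]
        reactions = []
        for rxn in model_el.find("listOfReactions"):
            stoich: dict[str, float] = {}
            for ref in rxn.find("listOfReactants") or []:
                stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - float(
                    ref.get("stoichiometry", "1")
                )
            for ref in rxn.find("listOfProducts") or []:
                stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + float(
                    ref.get("stoichiometry", "1")
                )
            reactions.append(
                Reaction(rxn.get("id"), stoich, float(rxn.get("lb")), float(rxn.get("ub")))
            )
        model = MetabolicModel(mets, reactions, model_el.get("biomass"))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    if not model.exchanges:
        model.exchanges = _detect_exchanges(model)
    model.validate()
    return model


@dataclass(frozen=True)
class FvaConfig:
    """Screen configuration (rates in mmol h^-1 gDW^-1).

    ``medium`` maps exchanged metabolites to their maximum uptake in the
    minimal medium; a glucose entry is removed by default so the source
    metabolite is the sole added carbon.
    """

    medium: Mapping[str, float] = field(default_factory=dict)
    remove_glucose: bool = True
    glucose_id: str = "glc__D"
    oxygen_id: str = "o2"
    oxygen_levels: Mapping[str, float] = field(default_factory=lambda: dict(OXYGEN_LEVELS))
    source_uptake: float = 100.0
    growth_fraction: float = 0.5
    producibility_epsilon: float = 1e-6
    solver_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.growth_fraction <= 1:
            raise ValidationError("growth_fraction must be in (0, 1]")
        if any(v < 0 for v in self.medium.values()) or self.source_uptake < 0:
            raise ValidationError("uptake rates must be nonnegative")


@dataclass
class ScreenResult:
    source: str
    target: str
    oxygen_scenario: str
    max_production_flux: float
    producible: bool
    status: str = "optimal"  # optimal | zero_growth | infeasible


def _ensure_exchange(model: MetabolicModel, metabolite: str) -> str:
    """Return the exchange reaction id for ``metabolite``, adding one if absent."""
    if metabolite in model.exchanges:
        return model.exchanges[metabolite]
    rxn_id = f"EX_{metabolite}"
    if any(r.id == rxn_id for r in model.reactions):
        rxn_id = f"EX_{metabolite}_auto"
    model.reactions.append(Reaction(rxn_id, {metabolite: -1.0}, 0.0, 1e6))
    model.exchanges[metabolite] = rxn_id
    return rxn_id


def apply_medium(
    model: MetabolicModel, cfg: FvaConfig, oxygen_scenario: str, source: str
) -> MetabolicModel:
    """Constrain exchanges to minimal medium + oxygen scenario + one source.

    All exchange uptakes are closed, then medium components reopened at their
    configured rates (glucose removed when requested), oxygen set to the
    scenario allowance, and the source allowed uptake at ``source_uptake``.
    """
    if source not in model.metabolites:
        raise ValidationError(f"source {source!r} not in model")
    if oxygen_scenario not in cfg.oxygen_levels:
        raise ValidationError(f"unknown oxygen scenario {oxygen_scenario!r}")
    constrained = model.copy()
    for rxn_id in constrained.exchanges.values():
        constrained.reaction(rxn_id).lb = 0.0
    medium = dict(cfg.medium)
    if cfg.remove_glucose:
        medium.pop(cfg.glucose_id, None)
    for met, rate in medium.items():
        if met in constrained.exchanges:
            constrained.reaction(constrained.exchanges[met]).lb = -float(rate)
    if cfg.oxygen_id in constrained.exchanges:
        constrained.reaction(constrained.exchanges[cfg.oxygen_id]).lb = -float(
            cfg.oxygen_levels[oxygen_scenario]
        )
    src_rxn = _ensure_exchange(constrained, source)
    constrained.reaction(src_rxn).lb = -float(cfg.source_uptake)
    return constrained


def _solve(model: MetabolicModel, objective_rxn: str, sense: str = "max") -> tuple[float, str]:
    s = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    j = [r.id for r in model.reactions].index(objective_rxn)
    c[j] = -1.0 if sense == "max" else 1.0
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs")
    if res.status == 0:
        value = res.x[j]
        return float(value), "optimal"
    if res.status == 2:
        return math.nan, "infeasible"
    if res.status == 3:
        return math.inf if sense == "max" else -math.inf, "unbounded"
    return math.nan, "failed"


def max_growth(model: MetabolicModel) -> tuple[float, str]:
    """Maximal biomass flux under steady state and bounds.

    Returns (value, status); infeasibility is reported as a status, never an
    exception.
    """
    return _solve(model, model.biomass, sense="max")


def flux_epsilon_call(flux: float, cfg: FvaConfig) -> bool:
    """Producibility call: strictly greater than epsilon, after clamping
    solver noise in (-tolerance, 0) to zero."""
    if -cfg.solver_tolerance < flux < 0:
        flux = 0.0
    return flux > cfg.producibility_epsilon


def production_screen(
    model: MetabolicModel,
    cfg: FvaConfig,
    sources: Sequence[str],
    targets: Sequence[str],
    oxygen_scenarios: Sequence[str] | None = None,
) -> list[ScreenResult]:
    """Maximum production flux of each target from each source per oxygen level.

    For each (source, oxygen): constrain the medium, maximize growth, pin
    biomass to at least ``growth_fraction`` of that optimum (vacuously when
    the optimum is zero, flagged ``zero_growth``), then maximize the flux of
    each target's exchange reaction, adding a demand reaction when the model
    has none.  All scenarios are always reported.
    """
    scenarios = list(oxygen_scenarios or cfg.oxygen_levels)
    results: list[ScreenResult] = []
    for source in sources:
        for scenario in scenarios:
            constrained = apply_medium(model, cfg, scenario, source)
            mu, status = max_growth(constrained)
            flag = "optimal"
            if status != "optimal":
                for target in targets:
                    results.append(ScreenResult(source, target, scenario, 0.0, False, status))
                continue
            if mu > cfg.solver_tolerance:
                constrained.reaction(constrained.biomass).lb = cfg.growth_fraction * mu
            else:
                flag = "zero_growth"
            for target in targets:
                probe = constrained.copy()
                rxn_id = _ensure_exchange(probe, target)
                value, tstatus = _solve(probe, rxn_id, sense="max")
                if tstatus != "optimal":
                    results.append(
                        ScreenResult(source, target, scenario, 0.0, False, tstatus)
                    )
                    continue
                if -cfg.solver_tolerance < value < 0:
                    value = 0.0
                value += 0.0  # normalize -0.0
                results.append(
                    ScreenResult(
                        source, target, scenario, value, flux_epsilon_call(value, cfg), flag
                    )
                )
    return results


def screen_to_frame(results: Sequence[ScreenResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            (r.source, r.target, r.oxygen_scenario, r.max_production_flux, r.producible, r.status)
            for r in results
        ],
        columns=["source", "target", "oxygen", "max_flux", "producible", "status"],
    )
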