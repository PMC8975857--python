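"""Core containers: universal reaction database and genus-level stoichiometric models.

The universal database plays the role of a reference reaction catalogue
(metabolites with elemental composition, reactions with stoichiometries and
gap-filling penalties, a role -> complex -> reaction annotation map, and
Gram-specific biomass templates).  Genus models are drawn from it and carry
their own flux bounds, biomass reaction and uptake (exchange) reactions.

Both containers serialize to a small JSON dialect with sorted keys so that a
write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "BIOMASS_MET",
    "Metabolite",
    "Reaction",
    "ReactionComplex",
    "UniversalReactionDB",
    "ModelReaction",
    "StoichiometricModel",
    "atoms_from_formula",
    "uptake_id",
]

#: id of the biomass pseudo-metabolite produced by biomass template reactions
BIOMASS_MET = "biomass"

#: default bound (mmol gDW^-1 h^-1) for internal reactions
DEFAULT_INTERNAL_BOUND = 1000.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def atoms_from_formula(formula: str, element: str) -> int:
    """Count atoms of ``element`` in a molecular formula string like ``C6H12O6``."""
    total = 0
    for sym, count in _FORMULA_RE.findall(formula or ""):
        if sym == element:
            total += int(count) if count else 1
    return total


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    carbon_atoms: int = -1  # -1: derive from formula
    nitrogen_atoms: int = -1
    compartment: str = "c"  # "c" cytosol, "e" external

    def __post_init__(self):
        if self.carbon_atoms < 0:
            object.__setattr__(self, "carbon_atoms", atoms_from_formula(self.formula, "C"))
        if self.nitrogen_atoms < 0:
            object.__setattr__(self, "nitrogen_atoms", atoms_from_formula(self.formula, "N"))
        if self.compartment not in ("c", "e"):
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")


@dataclass(frozen=True)
class Reaction:
    """A reaction of the universal database.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``penalty`` is the non-negative gap-filling cost.  Transport
    reactions move exactly one external metabolite across the boundary.
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    penalty: float = 1.0
    is_transport: bool = False
    subsystem: str = ""

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError(f"reaction {self.id}: penalty must be >= 0")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


@dataclass(frozen=True)
class ReactionComplex:
    id: str
    reactions: frozenset[str]
    required_roles: frozenset[str]


@dataclass
class UniversalReactionDB:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    role_map: dict[str, frozenset[str]]  # role id -> complex ids
    complexes: dict[str, ReactionComplex]
    biomass_templates: dict[str, dict[str, float]]  # "positive"/"negative"

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rxn.id} references unknown metabolite {met}")
            if rxn.is_transport:
                ext = [m for m in rxn.stoichiometry if self.metabolites[m].compartment == "e"]
                if len(ext) != 1:
                    raise ValueError(
                        f"transport reaction {rxn.id} must touch exactly one external metabolite"
                    )
        for role, cpxs in self.role_map.items():
            for cpx in cpxs:
                if cpx not in self.complexes:
                    raise ValueError(f"role {role} references unknown complex {cpx}")
        for cpx in self.complexes.values():
            for rid in cpx.reactions:
                if rid not in self.reactions:
                    raise ValueError(f"complex {cpx.id} references unknown reaction {rid}")
        for gram, stoich in self.biomass_templates.items():
            consumed = [m for m, c in stoich.items() if c < 0]
            if not consumed:
                raise ValueError(f"biomass template {gram} consumes no metabolite")
            if stoich.get(BIOMASS_MET, 0) <= 0:
                raise ValueError(f"biomass template {gram} must produce {BIOMASS_MET!r}")

    # -- convenience --------------------------------------------------------

    def transported_metabolite(self, rxn_id: str) -> str:
        """External metabolite moved by a transport reaction."""
        rxn = self.reactions[rxn_id]
        if not rxn.is_transport:
            raise ValueError(f"{rxn_id} is not a transport reaction")
        return next(m for m in rxn.stoichiometry if self.metabolites[m].compartment == "e")

    def external_metabolites(self) -> list[str]:
        return sorted(m for m, met in self.metabolites.items() if met.compartment == "e")

    def transporter_backed_externals(self) -> set[str]:
        """External metabolites with at least one transport reaction in the db."""
        return {
            self.transported_metabolite(rid)
            for rid, rxn in self.reactions.items()
            if rxn.is_transport
        }

    # -- JSON dialect -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "formula": m.formula,
                    "carbon_atoms": m.carbon_atoms,
                    "nitrogen_atoms": m.nitrogen_atoms,
                    "compartment": m.compartment,
                }
                for m in (self.metabolites[k] for k in sorted(self.metabolites))
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "reversible": r.reversible,
                    "penalty": r.penalty,
                    "is_transport": r.is_transport,
                    "subsystem": r.subsystem,
                }
                for r in (self.reactions[k] for k in sorted(self.reactions))
            ],
            "role_map": {k: sorted(v) for k, v in sorted(self.role_map.items())},
            "complexes": [
                {
                    "id": c.id,
                    "reactions": sorted(c.reactions),
                    "required_roles": sorted(c.required_roles),
                }
                for c in (self.complexes[k] for k in sorted(self.complexes))
            ],
            "biomass_templates": {
                g: {k: v for k, v in sorted(st.items())}
                for g, st in sorted(self.biomass_templates.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UniversalReactionDB":
        db = cls(
            metabolites={m["id"]: Metabolite(**m) for m in d["metabolites"]},
            reactions={r["id"]: Reaction(**r) for r in d["reactions"]},
            role_map={k: frozenset(v) for k, v in d["role_map"].items()},
            complexes={
                c["id"]: ReactionComplex(
                    c["id"], frozenset(c["reactions"]), frozenset(c["required_roles"])
                )
                for c in d["complexes"]
            },
            biomass_templates={g: dict(st) for g, st in d["biomass_templates"].items()},
        )
        db.validate()
        return db

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "UniversalReactionDB":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ModelReaction:
    id: str
    stoichiometry: Mapping[str, float]
    lb: float
    ub: float

    def __post_init__(self):
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb > ub")


def uptake_id(metabolite: str) -> str:
    return f"UP_{metabolite}"


@dataclass
class StoichiometricModel:
    """One genus's reaction network with bounds, biomass and uptake reactions.

    Uptake reactions are sources: ``UP_m`` produces the external metabolite m
    with flux in [0, bound]; transport reactions then carry it into the
    cytosol.  Only metabolites with a transport reaction in the reconstruction
    get an uptake.  ``external_atoms`` caches (carbon, nitrogen) atom counts
    of external metabolites for the elemental-budget phenotype screens.
    """

    genus: str
    reactions: dict[str, ModelReaction]
    biomass_reaction: str
    uptakes: dict[str, str]  # uptake reaction id -> external metabolite id
    gram: str = "negative"
    external_atoms: dict[str, tuple[int, int]] = field(default_factory=dict)
    added_by_gapfill: frozenset[str] = frozenset()

    def validate(self) -> None:
        if self.biomass_reaction not in self.reactions:
            raise ValueError(f"model {self.genus}: biomass reaction missing")
        for rid in self.uptakes:
            if rid not in self.reactions:
                raise ValueError(f"model {self.genus}: uptake {rid} not among reactions")
        for rxn in self.reactions.values():
            if rxn.lb > rxn.ub:
                raise ValueError(f"model {self.genus}: {rxn.id} has lb > ub")

    def metabolite_ids(self) -> list[str]:
        mets: set[str] = set()
        for rxn in self.reactions.values():
            mets.update(rxn.stoichiometry)
        return sorted(mets)

    def uptake_metabolites(self) -> set[str]:
        return set(self.uptakes.values())

    def uptake_for(self, metabolite: str) -> str | None:
        rid = uptake_id(metabolite)
        return rid if rid in self.uptakes else None

    def with_reactions(self, extra: Iterable[ModelReaction]) -> "StoichiometricModel":
        reactions = dict(self.reactions)
        for rxn in extra:
            reactions[rxn.id] = rxn
        return replace(self, reactions=reactions)

    # -- JSON dialect -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "gram": self.gram,
            "biomass_reaction": self.biomass_reaction,
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "lb": r.lb,
                    "ub": r.ub,
                }
                for r in (self.reactions[k] for k in sorted(self.reactions))
            ],
            "uptakes": {k: v for k, v in sorted(self.uptakes.items())},
            "external_atoms": {k: list(v) for k, v in sorted(self.external_atoms.items())},
            "added_by_gapfill": sorted(self.added_by_gapfill),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StoichiometricModel":
        model = cls(
            genus=d["genus"],
            gram=d["gram"],
            biomass_reaction=d["biomass_reaction"],
            reactions={r["id"]: ModelReaction(**r) for r in d["reactions"]},
            uptakes=dict(d["uptakes"]),
            external_atoms={k: (int(v[0]), int(v[1])) for k, v in d["external_atoms"].items()},
            added_by_gapfill=frozenset(d["added_by_gapfill"]),
        )
        model.validate()
        return model

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "StoichiometricModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_flat_tsv(self) -> str:
        """Flat human-readable export: reaction, equation string, lb, ub."""
        lines = ["reaction\tequation\tlb\tub"]
        for rid in sorted(self.reactions):
            rxn = self.reactions[rid]
            lhs = " + ".join(
                f"{-c:g} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c < 0
            )
            rhs = " + ".join(
                f"{c:g} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c > 0
            )
            arrow = "<=>" if rxn.lb < 0 else "-->"
            lines.append(f"{rid}\t{lhs} {arrow} {rhs}\t{rxn.lb:g}\t{rxn.ub:g}")
        return "\n".join(lines) + "\n"
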