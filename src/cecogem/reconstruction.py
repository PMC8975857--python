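"""Genus-level draft metabolic reconstruction and penalty-weighted gap-filling.

Pipeline: a genus role profile (annotation-derived functional roles, usually
incomplete) is first topped up with the most probable missing roles under a
reference co-occurrence model, then mapped through the universal database's
role -> complex -> reaction annotation to a draft reaction set, equipped with
a Gram-matched biomass template and transporter-derived uptake reactions, and
finally gap-filled: a linear program over the universal network finds the
cheapest (penalty + bonus weighted) flux pattern that sustains a minimum
biomass production on complete media, and every extra reaction carrying flux
is grafted onto the draft.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .db import (
    BIOMASS_MET,
    DEFAULT_INTERNAL_BOUND,
    ModelReaction,
    Reaction,
    StoichiometricModel,
    UniversalReactionDB,
    uptake_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenusRoleProfile",
    "CooccurrenceModel",
    "GapfillError",
    "fit_cooccurrence",
    "impute_roles",
    "roles_to_reactions",
    "build_draft_model",
    "gapfill",
]

BIOMASS_RXN = "bio1"
BIOMASS_SINK = "SINK_biomass"


@dataclass(frozen=True)
class GenusRoleProfile:
    """Functional roles annotated to one genus plus its expected role count.

    ``target_role_count`` is the expected number of metabolic roles from
    fully sequenced reference genomes of the genus; imputation tops the
    observed set up to this size.
    """

    genus: str
    roles: frozenset[str]
    gram: str = "negative"
    target_role_count: int = 0

    def __post_init__(self):
        object.__setattr__(self, "roles", frozenset(self.roles))


class GapfillError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Role co-occurrence model (reference-genome based imputation)
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceModel:
    """Laplace-smoothed marginal and pairwise role frequencies.

    A deliberately simple conditional-probability scorer standing in for a
    full latent-variable model of binary presence/absence data: the score of
    an absent role j given an observed set O is mean_{i in O} p(j | i) with
    p(j | i) = p(i, j) / p(i) from pseudocount-smoothed frequencies.
    """

    roles: list[str]
    marginals: pd.Series
    joints: pd.DataFrame
    pseudocount: float

    def conditional(self, j: str, i: str) -> float:
        return float(self.joints.at[i, j] / self.marginals.at[i])

    def score(self, candidate: str, observed: frozenset[str]) -> float:
        obs = [i for i in observed if i in self.joints.index]
        if not obs:
            return float(self.marginals.at[candidate])
        return float((self.joints.loc[obs, candidate] / self.marginals.loc[obs]).mean())


def fit_cooccurrence(reference: pd.DataFrame, pseudocount: float = 1.0) -> CooccurrenceModel:
    """Fit smoothed role frequencies from a genomes x roles binary matrix.

    Marginals p(j) = (n_j + c) / (N + 2c); pairwise joints use the same
    pseudocount scheme, p(i, j) = (n_ij + c) / (N + 2c), which keeps every
    conditional p(j | i) within [0, 1].
    """
    if reference.shape[0] < 2:
        raise ValueError("co-occurrence fit needs at least 2 reference genomes")
    if reference.shape[1] < 2:
        raise ValueError("co-occurrence fit needs at least 2 roles")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = (reference.to_numpy() > 0).astype(float)
    n = X.shape[0]
    denom = n + 2 * pseudocount
    marg = pd.Series((X.sum(axis=0) + pseudocount) / denom, index=reference.columns)
    joint = pd.DataFrame(
        (X.T @ X + pseudocount) / denom, index=reference.columns, columns=reference.columns
    )
    return CooccurrenceModel(
        roles=list(reference.columns), marginals=marg, joints=joint, pseudocount=pseudocount
    )


def impute_roles(profile: GenusRoleProfile, model: CooccurrenceModel) -> GenusRoleProfile:
    """Add the most probable absent roles up to the profile's target count.

    Candidates are scored by their mean conditional probability given the
    observed roles; ties break lexicographically by role id.  If the target
    is already met the profile is returned unchanged.
    """
    n_add = profile.target_role_count - len(profile.roles)
    if n_add <= 0:
        return profile
    observed = frozenset(r for r in profile.roles if r in model.joints.index)
    candidates = [r for r in model.roles if r not in profile.roles]
    scored = sorted(
        ((model.score(c, observed), c) for c in candidates),
        key=lambda t: (-t[0], t[1]),
    )
    added = frozenset(c for _, c in scored[:n_add])
    return replace(profile, roles=profile.roles | added)


# ---------------------------------------------------------------------------
# Role -> reaction mapping and draft model assembly
# ---------------------------------------------------------------------------


def roles_to_reactions(
    profile: GenusRoleProfile,
    db: UniversalReactionDB,
    complex_mode: str = "all_roles",
) -> set[str]:
    """Map a role set to reactions via the annotation complexes.

    ``all_roles``: a reaction is included iff some complex pointing to it has
    *every* required role present.  ``any_role``: one present role suffices.
    Roles absent from the database's role map are counted and logged.
    """
    if complex_mode not in ("all_roles", "any_role"):
        raise ValueError(f"unknown complex_mode {complex_mode!r}")
    unknown = sum(1 for r in profile.roles if r not in db.role_map)
    if unknown:
        logger.info("%s: %d roles not in the role map (ignored)", profile.genus, unknown)
    reactions: set[str] = set()
    for cpx in db.complexes.values():
        present = cpx.required_roles & profile.roles
        if complex_mode == "all_roles":
            ok = present == cpx.required_roles
        else:
            ok = bool(present)
        if ok:
            reactions |= cpx.reactions
    return reactions


def build_draft_model(
    reaction_set: set[str],
    profile: GenusRoleProfile,
    db: UniversalReactionDB,
    default_uptake_bound: float = 100.0,
    internal_bound: float = DEFAULT_INTERNAL_BOUND,
) -> StoichiometricModel:
    """Assemble a draft model: reactions, Gram biomass template, uptakes.

    An uptake reaction (bounds [0, ``default_uptake_bound``]) is created for
    every external metabolite touched by an included transport reaction; no
    other exchanges exist, so media are defined by the transporter repertoire.
    """
    if profile.gram not in db.biomass_templates:
        raise ValueError(f"unknown gram status {profile.gram!r} for {profile.genus}")
    reactions: dict[str, ModelReaction] = {}
    for rid in sorted(reaction_set):
        rxn = db.reactions[rid]
        lb = -internal_bound if rxn.reversible else 0.0
        reactions[rid] = ModelReaction(rid, rxn.stoichiometry, lb, internal_bound)
    reactions[BIOMASS_RXN] = ModelReaction(
        BIOMASS_RXN, db.biomass_templates[profile.gram], 0.0, internal_bound
    )
    reactions[BIOMASS_SINK] = ModelReaction(
        BIOMASS_SINK, {BIOMASS_MET: -1.0}, 0.0, internal_bound
    )
    uptakes: dict[str, str] = {}
    for rid in sorted(reaction_set):
        if db.reactions[rid].is_transport:
            met = db.transported_metabolite(rid)
            uid = uptake_id(met)
            if uid not in reactions:
                reactions[uid] = ModelReaction(uid, {met: 1.0}, 0.0, default_uptake_bound)
                uptakes[uid] = met
    external_atoms = {
        m: (db.metabolites[m].carbon_atoms, db.metabolites[m].nitrogen_atoms)
        for rxn in reactions.values()
        for m in rxn.stoichiometry
        if m in db.metabolites and db.metabolites[m].compartment == "e"
    }
    model = StoichiometricModel(
        genus=profile.genus,
        reactions=reactions,
        biomass_reaction=BIOMASS_RXN,
        uptakes=uptakes,
        gram=profile.gram,
        external_atoms=external_atoms,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Gap-filling
# ---------------------------------------------------------------------------


def extend_model(
    model: StoichiometricModel,
    rids: list[str] | set[str],
    db: UniversalReactionDB,
    internal_bound: float = DEFAULT_INTERNAL_BOUND,
    uptake_bound: float = 100.0,
) -> StoichiometricModel:
    """Graft database reactions onto a model, creating uptakes for any new
    transporters and refreshing the external-atom cache."""
    reactions = dict(model.reactions)
    uptakes = dict(model.uptakes)
    external_atoms = dict(model.external_atoms)
    for rid in sorted(rids):
        rxn = db.reactions[rid]
        lb = -internal_bound if rxn.reversible else 0.0
        reactions[rid] = ModelReaction(rid, rxn.stoichiometry, lb, internal_bound)
        for m in rxn.stoichiometry:
            if m in db.metabolites and db.metabolites[m].compartment == "e":
                external_atoms[m] = (
                    db.metabolites[m].carbon_atoms,
                    db.metabolites[m].nitrogen_atoms,
                )
        if rxn.is_transport:
            met = db.transported_metabolite(rid)
            uid = uptake_id(met)
            if uid not in reactions:
                reactions[uid] = ModelReaction(uid, {met: 1.0}, 0.0, uptake_bound)
                uptakes[uid] = met
    extended = replace(
        model, reactions=reactions, uptakes=uptakes, external_atoms=external_atoms
    )
    extended.validate()
    return extended


def _candidate_weight(
    rxn: Reaction, draft_subsystems: set[str], bonus_factor: float, bonus_eps: float
) -> float:
    w = rxn.penalty
    if rxn.subsystem and rxn.subsystem in draft_subsystems:
        w *= bonus_factor
    return max(w, bonus_eps)


def gapfill(
    model: StoichiometricModel,
    db: UniversalReactionDB,
    biomass_min: float = 0.001,
    bonus_factor: float = 0.5,
    bonus_eps: float = 1e-3,
    flux_tol: float = 1e-6,
    uptake_bound: float = 100.0,
    internal_bound: float = DEFAULT_INTERNAL_BOUND,
) -> tuple[StoichiometricModel, frozenset[str]]:
    """Penalty-weighted LP gap-filling against the universal network.

    Minimizes sum over candidate (non-draft) reactions of w_r (v_r+ + v_r-)
    subject to S v = 0, v_biomass >= ``biomass_min`` and reversibility-aware
    bounds, on complete media (an uptake, bounded by ``uptake_bound``, is
    open for every external metabolite with a transporter anywhere in the
    universal network, so new transporters can be recruited).  Candidate
    weights are database penalties reduced multiplicatively (``bonus_factor``)
    for reactions whose subsystem is already represented in the draft,
    floored at ``bonus_eps``.  Reactions with |flux| > ``flux_tol`` are added
    to the reconstruction.
    """
    if model.biomass_reaction not in model.reactions:
        raise ValueError(f"model {model.genus} lacks its biomass reaction")
    candidates = sorted(set(db.reactions) - set(model.reactions))
    draft_subsystems = {
        db.reactions[rid].subsystem
        for rid in model.reactions
        if rid in db.reactions and db.reactions[rid].subsystem
    }

    # column layout: forward/backward halves per reaction, then uptakes
    cols: list[tuple[str, int]] = []  # (reaction id, +1 forward / -1 backward)
    weights: list[float] = []
    bounds: list[tuple[float, float]] = []

    def add_col(rid: str, sign: int, hi: float, w: float, lo: float = 0.0):
        cols.append((rid, sign))
        bounds.append((lo, hi))
        weights.append(w)

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        fwd_lb = biomass_min if rid == model.biomass_reaction else max(rxn.lb, 0.0)
        add_col(rid, +1, rxn.ub, 0.0, lo=fwd_lb)
        if rxn.lb < 0:
            add_col(rid, -1, -rxn.lb, 0.0)
    stoich_src: dict[str, dict[str, float]] = {
        rid: dict(model.reactions[rid].stoichiometry) for rid in model.reactions
    }
    for rid in candidates:
        rxn = db.reactions[rid]
        w = _candidate_weight(rxn, draft_subsystems, bonus_factor, bonus_eps)
        add_col(rid, +1, internal_bound, w)
        if rxn.reversible:
            add_col(rid, -1, internal_bound, w)
        stoich_src[rid] = dict(rxn.stoichiometry)

    # complete media over the universal network
    open_mets = db.transporter_backed_externals() | model.uptake_metabolites()
    uptake_cols: dict[str, int] = {}
    for met in sorted(open_mets):
        uid = uptake_id(met)
        if uid in model.reactions:
            continue  # already a model reaction column
        uptake_cols[met] = len(cols)
        add_col(uid, +1, uptake_bound, 0.0)
        stoich_src[uid] = {met: 1.0}
    # open the model's own uptakes at the gap-fill bound
    for j, (rid, sign) in enumerate(cols):
        if rid in model.uptakes and sign > 0:
            bounds[j] = (bounds[j][0], max(bounds[j][1], uptake_bound))

    mets = sorted({m for st in stoich_src.values() for m in st})
    met_index = {m: i for i, m in enumerate(mets)}
    A = np.zeros((len(mets), len(cols)))
    for j, (rid, sign) in enumerate(cols):
        for met, coef in stoich_src[rid].items():
            A[met_index[met], j] = sign * coef

    res = linprog(
        np.asarray(weights),
        A_eq=A,
        b_eq=np.zeros(len(mets)),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise GapfillError(f"ungapfillable: {model.genus} cannot reach biomass "
                           f">= {biomass_min} even over the universal network")
    if res.status != 0:
        raise RuntimeError(f"gap-fill LP failed (status {res.status}): {res.message}")

    flux_by_rid: dict[str, float] = {}
    for j, (rid, sign) in enumerate(cols):
        flux_by_rid[rid] = flux_by_rid.get(rid, 0.0) + abs(res.x[j])
    added = frozenset(rid for rid in candidates if flux_by_rid.get(rid, 0.0) > flux_tol)

    filled = extend_model(model, added, db, internal_bound=internal_bound)
    filled = replace(filled, added_by_gapfill=model.added_by_gapfill | added)
    filled.validate()
    return filled, added
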