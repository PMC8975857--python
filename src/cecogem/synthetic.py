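"""Synthetic study generator with recomputable ground truth.

Everything the pipeline consumes can be generated here at toy scale: a
universal reaction database with planted carbon/nitrogen utilization routes,
genus role profiles realizing chosen capability plans (optionally with random
role omissions to exercise imputation and gap-filling), community abundance
studies with a treatment effect tilted toward low-demand genera, gene count
tables with universal single-copy genes, and log-normal metabolite intensity
matrices with planted differential sets.

The database layout keeps every genus at ten or fewer transporters so exact
enumeration over all uptake subsets remains a practical oracle for the
random-media essentiality screen, and gap-fill toy instances stay small
enough for exhaustive subset search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .db import (
    BIOMASS_MET,
    Metabolite,
    ModelReaction,
    Reaction,
    ReactionComplex,
    StoichiometricModel,
    UniversalReactionDB,
)
from .fba import FBAProblem
from .phenotypes import VIABILITY_FLOOR, exact_essentiality
from .profiles import AbundanceTable
from .reconstruction import (
    GenusRoleProfile,
    build_draft_model,
    extend_model,
    roles_to_reactions,
)

__all__ = [
    "GenusSpec",
    "GenusTruth",
    "SyntheticStudy",
    "make_universal_db",
    "make_genus",
    "make_reference_matrix",
    "make_community_study",
    "default_genus_specs",
    "make_gapfill_instance",
    "enumerate_gapfill_optimum",
]


# ---------------------------------------------------------------------------
# Universal database
# ---------------------------------------------------------------------------


def make_universal_db(
    seed: int = 0,
    n_carbon_sources: int = 8,
    n_nitrogen_sources: int = 4,
    n_mixed_sources: int = 2,
    n_distractor_mets: int = 12,
    n_distractor_rxns: int = 24,
) -> UniversalReactionDB:
    """Toy universal reaction database with planted utilization routes.

    Externals: carbon sources ``CsrcNN`` (2-6 C atoms), nitrogen sources
    ``NsrcNN`` (1-2 N), mixed amino-acid-like sources ``MixNN`` (C and N,
    route to carbon only), and a mineral ``Min`` consumed directly by biomass.
    Each source has a transporter and a one- or two-step conversion to the
    carbon skeleton precursor ``CP_c`` (yield = carbon atoms) or the nitrogen
    carrier ``NP_c`` (yield = nitrogen atoms), giving every precursor several
    alternative routes.  Distractor reactions among dead-end cytosolic
    metabolites pad the network and can never carry steady-state flux.
    Penalties are sampled uniformly from [0.5, 5].
    """
    rng = np.random.default_rng(seed)
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    role_map: dict[str, frozenset[str]] = {}
    complexes: dict[str, ReactionComplex] = {}

    def add_met(mid: str, formula: str, compartment: str, name: str = "") -> None:
        mets[mid] = Metabolite(id=mid, name=name or mid, formula=formula,
                               compartment=compartment)

    def add_role_complex(rid: str, roles: tuple[str, ...], cpx_suffix: str = "") -> None:
        cid = f"cx_{rid}{cpx_suffix}"
        complexes[cid] = ReactionComplex(cid, frozenset({rid}), frozenset(roles))
        for role in roles:
            role_map[role] = role_map.get(role, frozenset()) | {cid}

    add_met("CP_c", "CH2O", "c", "carbon skeleton unit")
    add_met("NP_c", "H3N", "c", "nitrogen carrier")
    add_met(BIOMASS_MET, "", "c", "biomass")
    add_met("Min_e", "O4P", "e", "mineral")
    add_met("Min_c", "O4P", "c")

    def penalty() -> float:
        return float(np.round(rng.uniform(0.5, 5.0), 3))

    sources: list[tuple[str, str, int, int]] = []  # (ext id, kind, c, n)
    for i in range(n_carbon_sources):
        c = int(rng.integers(2, 7))
        sources.append((f"Csrc{i + 1:02d}", "carbon", c, 0))
    for i in range(n_nitrogen_sources):
        n = int(rng.integers(1, 3))
        sources.append((f"Nsrc{i + 1:02d}", "nitrogen", 0, n))
    for i in range(n_mixed_sources):
        c = int(rng.integers(2, 5))
        sources.append((f"Mix{i + 1:02d}", "mixed", c, 1))

    conv_idx = 0
    for base, kind, c, n in sources:
        if kind == "carbon":
            formula = f"C{c}H{2 * c}O{c}"
        elif kind == "nitrogen":
            formula = f"H{3 * n}N{n}"
        else:
            formula = f"C{c}H{2 * c + 1}N{n}O2"
        add_met(f"{base}_e", formula, "e")
        add_met(f"{base}_c", formula, "c")
        tid = f"T_{base}"
        rxns[tid] = Reaction(tid, {f"{base}_e": -1.0, f"{base}_c": 1.0},
                             penalty=penalty(), is_transport=True, subsystem="transport")
        add_role_complex(tid, (f"r_{tid}",))
        target, yield_ = ("NP_c", n) if kind == "nitrogen" else ("CP_c", c)
        subsystem = "nitrogen_utilization" if kind == "nitrogen" else "carbon_utilization"
        two_step = conv_idx % 2 == 1
        if two_step:
            inter = f"Int_{base}_c"
            add_met(inter, "", "c")
            r1, r2 = f"V1_{base}", f"V2_{base}"
            rxns[r1] = Reaction(r1, {f"{base}_c": -1.0, inter: 1.0},
                                penalty=penalty(), subsystem=subsystem)
            rxns[r2] = Reaction(r2, {inter: -1.0, target: float(yield_)},
                                penalty=penalty(), subsystem=subsystem)
            if conv_idx % 4 == 3:  # a multi-role complex now and then
                add_role_complex(r1, (f"r_{r1}_a", f"r_{r1}_b"))
            else:
                add_role_complex(r1, (f"r_{r1}",))
            add_role_complex(r2, (f"r_{r2}",))
        else:
            r = f"V_{base}"
            rxns[r] = Reaction(r, {f"{base}_c": -1.0, target: float(yield_)},
                               penalty=penalty(), subsystem=subsystem)
            add_role_complex(r, (f"r_{r}",))
            if conv_idx == 0:  # one reaction reachable through two complexes
                add_role_complex(r, (f"r_{r}_alt",), cpx_suffix="_alt")
        conv_idx += 1

    tid = "T_Min"
    rxns[tid] = Reaction(tid, {"Min_e": -1.0, "Min_c": 1.0},
                         penalty=penalty(), is_transport=True, subsystem="transport")
    add_role_complex(tid, (f"r_{tid}",))

    for i in range(n_distractor_mets):
        add_met(f"Dst{i + 1:02d}_c", "", "c")
    for i in range(n_distractor_rxns):
        a, b = rng.choice(n_distractor_mets, size=2, replace=False) + 1
        rid = f"D_{i + 1:02d}"
        rxns[rid] = Reaction(
            rid, {f"Dst{a:02d}_c": -1.0, f"Dst{b:02d}_c": 1.0},
            reversible=bool(rng.random() < 0.5), penalty=penalty(), subsystem="misc",
        )
        add_role_complex(rid, (f"r_{rid}",))

    biomass_templates = {
        "positive": {"CP_c": -10.0, "NP_c": -2.0, "Min_c": -0.1, BIOMASS_MET: 1.0},
        "negative": {"CP_c": -8.0, "NP_c": -3.0, "Min_c": -0.15, BIOMASS_MET: 1.0},
    }
    db = UniversalReactionDB(mets, rxns, role_map, complexes, biomass_templates)
    db.validate()
    return db


def _roles_for_reaction(db: UniversalReactionDB, rid: str) -> frozenset[str]:
    """Roles of the lexicographically first complex enabling a reaction."""
    for cid in sorted(db.complexes):
        if rid in db.complexes[cid].reactions:
            return db.complexes[cid].required_roles
    raise KeyError(f"no complex maps to reaction {rid}")


def _route_reactions(db: UniversalReactionDB, source: str) -> list[str]:
    """Conversion reaction ids for a source, by the generator's naming scheme."""
    if f"V_{source}" in db.reactions:
        return [f"V_{source}"]
    if f"V1_{source}" in db.reactions:
        return [f"V1_{source}", f"V2_{source}"]
    return []


# ---------------------------------------------------------------------------
# Genus construction with ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenusSpec:
    """Capability plan for one synthetic genus.

    ``carbon_sources``/``nitrogen_sources`` are usable main sources (with a
    complete transport + conversion route); ``decoy_transporters`` are taken
    up but not convertible, so they are never usable and never essential.
    """

    genus: str
    carbon_sources: tuple[str, ...]
    nitrogen_sources: tuple[str, ...]
    decoy_transporters: tuple[str, ...] = ()
    gram: str = "negative"


@dataclass
class GenusTruth:
    """A generated genus plus its recomputable ground truth."""

    spec: GenusSpec
    profile: GenusRoleProfile  # pipeline input (possibly gapped)
    full_profile: GenusRoleProfile
    model: StoichiometricModel  # built from the un-gapped role set
    usable_carbon: frozenset[str]
    usable_nitrogen: frozenset[str]
    essentiality: pd.Series
    mean_essentiality: float


def make_genus(
    db: UniversalReactionDB,
    plan: GenusSpec,
    gap_fraction: float = 0.0,
    seed: int = 0,
    p: float = 0.9,
) -> GenusTruth:
    """Realize a capability plan as a role set with exact ground truth.

    The full role set enables the plan's transporters and conversions (plus
    the mandatory mineral transporter); ``gap_fraction`` of the roles are
    then deleted at random to produce the pipeline-facing profile.  Usable
    sources follow from the plan by construction; essentiality is computed
    exactly on the un-gapped model by enumeration over all uptake subsets
    with binomial(p) weights.
    """
    rng = np.random.default_rng(seed)
    rids: set[str] = {"T_Min"}
    for src in plan.carbon_sources + plan.nitrogen_sources:
        route = _route_reactions(db, src)
        if f"T_{src}" not in db.reactions or not route:
            raise ValueError(f"plan for {plan.genus} unrealizable: no route for {src}")
        rids.add(f"T_{src}")
        rids.update(route)
    for src in plan.decoy_transporters:
        if f"T_{src}" not in db.reactions:
            raise ValueError(f"plan for {plan.genus} unrealizable: no transporter for {src}")
        rids.add(f"T_{src}")
    roles: set[str] = set()
    for rid in sorted(rids):
        roles |= _roles_for_reaction(db, rid)
    full_profile = GenusRoleProfile(
        genus=plan.genus, roles=frozenset(roles), gram=plan.gram,
        target_role_count=len(roles),
    )
    model = build_draft_model(
        roles_to_reactions(full_profile, db, "all_roles"), full_profile, db
    )
    if FBAProblem(model).max_biomass() < VIABILITY_FLOOR:
        raise ValueError(f"plan for {plan.genus} unrealizable: no growth on complete media")
    ess = exact_essentiality(model, p=p)
    usable_c = frozenset(
        s for s in plan.carbon_sources if db.metabolites[f"{s}_e"].carbon_atoms >= 1
    )
    usable_n = frozenset(
        s for s in plan.nitrogen_sources if db.metabolites[f"{s}_e"].nitrogen_atoms >= 1
    )
    profile = full_profile
    n_gap = int(round(gap_fraction * len(roles)))
    if n_gap:
        dropped = rng.choice(sorted(roles), size=n_gap, replace=False)
        profile = replace(full_profile, roles=frozenset(roles) - set(dropped))
    scored = ess.dropna()
    return GenusTruth(
        spec=plan,
        profile=profile,
        full_profile=full_profile,
        model=model,
        usable_carbon=frozenset(f"{s}_e" for s in usable_c),
        usable_nitrogen=frozenset(f"{s}_e" for s in usable_n),
        essentiality=ess,
        mean_essentiality=float(scored.mean()),
    )


def make_reference_matrix(
    db: UniversalReactionDB,
    specs: list[GenusSpec],
    n_genomes: int = 24,
    drop_prob: float = 0.05,
    add_prob: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference genomes x roles binary matrix for co-occurrence fitting.

    Genomes cycle through the capability plans; each inherits the plan's full
    role set with small random dropouts and additions.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(db.role_map)
    rows = []
    for g in range(n_genomes):
        spec = specs[g % len(specs)]
        truth_roles = set()
        rids = {"T_Min"}
        for src in spec.carbon_sources + spec.nitrogen_sources:
            rids.add(f"T_{src}")
            rids.update(_route_reactions(db, src))
        for src in spec.decoy_transporters:
            rids.add(f"T_{src}")
        for rid in sorted(rids):
            truth_roles |= _roles_for_reaction(db, rid)
        row = np.zeros(len(universe), dtype=int)
        for j, role in enumerate(universe):
            if role in truth_roles:
                row[j] = int(rng.random() >= drop_prob)
            else:
                row[j] = int(rng.random() < add_prob)
        rows.append(row)
    return pd.DataFrame(
        rows, index=[f"genome{g + 1:02d}" for g in range(n_genomes)], columns=universe
    )


# ---------------------------------------------------------------------------
# Gap-fill toy instances and enumeration oracle
# ---------------------------------------------------------------------------


def make_gapfill_instance(
    seed: int = 0, max_candidates: int = 8
) -> tuple[StoichiometricModel, UniversalReactionDB]:
    """Random toy gap-fill instance with few candidate reactions.

    A single carbon source feeds 2-3 alternative linear paths (1-3 unit-
    stoichiometry reactions each) to the sole biomass precursor; the draft
    model has only the transporter, so the cheapest path must be recruited.
    A couple of dead-end distractor candidates are thrown in.  All candidate
    counts stay at or below ``max_candidates`` so exhaustive subset search is
    a practical optimum oracle.
    """
    rng = np.random.default_rng(seed)
    mets = {
        "S_e": Metabolite("S_e", formula="C3H6O3", compartment="e"),
        "S_c": Metabolite("S_c", formula="C3H6O3", compartment="c"),
        "CP_c": Metabolite("CP_c", formula="CH2O", compartment="c"),
        BIOMASS_MET: Metabolite(BIOMASS_MET, compartment="c"),
        "X1_c": Metabolite("X1_c", compartment="c"),
        "X2_c": Metabolite("X2_c", compartment="c"),
    }
    rxns = {
        "T_S": Reaction("T_S", {"S_e": -1.0, "S_c": 1.0}, is_transport=True, penalty=1.0),
    }
    n_paths = int(rng.integers(2, 4))
    budget = max_candidates - 2  # leave room for 2 distractors
    path_lens = []
    for i in range(n_paths):
        remaining_paths = n_paths - i - 1
        hi = max(1, min(3, budget - remaining_paths))
        length = int(rng.integers(1, hi + 1))
        path_lens.append(length)
        budget -= length
    n_inter = 0
    for pi, length in enumerate(path_lens):
        prev = "S_c"
        for step in range(length):
            last = step == length - 1
            if last:
                nxt = "CP_c"
            else:
                n_inter += 1
                nxt = f"I{n_inter}_c"
                mets[nxt] = Metabolite(nxt, compartment="c")
            rid = f"P{pi + 1}_{step + 1}"
            rxns[rid] = Reaction(rid, {prev: -1.0, nxt: 1.0},
                                 penalty=float(np.round(rng.uniform(0.5, 5.0), 3)))
            prev = nxt
    for d in range(2):
        rid = f"D{d + 1}"
        rxns[rid] = Reaction(rid, {"X1_c": -1.0, "X2_c": 1.0},
                             reversible=bool(rng.random() < 0.5),
                             penalty=float(np.round(rng.uniform(0.5, 5.0), 3)))
    role_map: dict[str, frozenset[str]] = {}
    complexes: dict[str, ReactionComplex] = {}
    for rid in rxns:
        cid = f"cx_{rid}"
        complexes[cid] = ReactionComplex(cid, frozenset({rid}), frozenset({f"r_{rid}"}))
        role_map[f"r_{rid}"] = frozenset({cid})
    templates = {
        g: {"CP_c": -1.0, BIOMASS_MET: 1.0} for g in ("positive", "negative")
    }
    db = UniversalReactionDB(mets, rxns, role_map, complexes, templates)
    db.validate()
    profile = GenusRoleProfile(genus=f"toy{seed}", roles=frozenset({"r_T_S"}),
                               gram="negative")
    model = build_draft_model({"T_S"}, profile, db)
    return model, db


def enumerate_gapfill_optimum(
    model: StoichiometricModel,
    db: UniversalReactionDB,
    biomass_min: float = 0.001,
    uptake_bound: float = 100.0,
) -> tuple[float, frozenset[str]]:
    """Exhaustive-subset gap-fill optimum: the minimum total penalty over all
    candidate-reaction subsets restoring growth on complete media.

    Intended for toy instances (at most ~12 candidates).  Subsets are pruned
    by their penalty against the best solution found so far.
    """
    candidates = sorted(set(db.reactions) - set(model.reactions))
    if len(candidates) > 12:
        raise ValueError("too many candidates for exhaustive search")
    best_cost = np.inf
    best_set: frozenset[str] = frozenset()
    for mask in range(2 ** len(candidates)):
        subset = [candidates[i] for i in range(len(candidates)) if mask >> i & 1]
        cost = sum(db.reactions[r].penalty for r in subset)
        if cost >= best_cost:
            continue
        extended = extend_model(model, subset, db)
        prob = FBAProblem(extended)
        media = prob.complete_media(uptake_bound=uptake_bound)
        # open also externals whose transporter came with the subset
        if prob.max_biomass(media) >= biomass_min:
            best_cost = cost
            best_set = frozenset(subset)
    if not np.isfinite(best_cost):
        raise RuntimeError("no candidate subset restores growth")
    return float(best_cost), best_set


# ---------------------------------------------------------------------------
# Community studies
# ---------------------------------------------------------------------------


def default_genus_specs(db: UniversalReactionDB) -> list[GenusSpec]:
    """Six genera spanning generalists (low metabolite demand) to specialists."""
    return [
        GenusSpec("g01_generalist", ("Csrc01", "Csrc02", "Csrc03", "Csrc04"),
                  ("Nsrc01", "Nsrc02"), ("Csrc05",), "negative"),
        GenusSpec("g02_versatile", ("Csrc03", "Csrc04", "Csrc05", "Csrc06"),
                  ("Nsrc02", "Nsrc03"), (), "positive"),
        GenusSpec("g03_moderate", ("Csrc01", "Csrc07"), ("Nsrc01",), (), "negative"),
        GenusSpec("g04_moderate", ("Csrc02", "Csrc08", "Mix01"), ("Nsrc04",),
                  (), "positive"),
        GenusSpec("g05_specialist", ("Csrc05",), ("Nsrc03",), (), "negative"),
        GenusSpec("g06_specialist", ("Csrc06",), ("Nsrc04",), ("Nsrc01",), "positive"),
    ]


@dataclass
class SyntheticStudy:
    """A full synthetic study: inputs for every pipeline stage plus truth."""

    db: UniversalReactionDB
    genera: dict[str, GenusTruth]
    abundance: AbundanceTable
    gene_counts: pd.DataFrame  # samples x genes
    gene_meta: pd.DataFrame  # gene_id, length_bp, role, genus
    uscg_ids: tuple[str, ...]
    metabolites: pd.DataFrame  # samples x metabolites, NaN = missing
    metabolite_sets: dict[str, set[str]]
    shifted_sets: dict[str, float]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.db.save(out / "universal.json")
        roles_dir = out / "roles"
        roles_dir.mkdir(exist_ok=True)
        for genus, truth in sorted(self.genera.items()):
            lines = [f"{genus}\t{r}" for r in sorted(truth.profile.roles)]
            (roles_dir / f"{genus}.tsv").write_text(
                "genus\trole\n" + "\n".join(lines) + "\n"
            )
        self.abundance.abundance.to_csv(out / "abundance.tsv", sep="\t")
        meta = pd.DataFrame({
            "treatment": self.abundance.treatment,
            "weight_g": self.abundance.weight,
        })
        meta.index.name = "sample_id"
        meta.to_csv(out / "samples.tsv", sep="\t")
        self.gene_counts.to_csv(out / "genes.tsv", sep="\t")
        self.gene_meta.to_csv(out / "gene_meta.tsv", sep="\t", index=False)
        (out / "uscg.txt").write_text("\n".join(self.uscg_ids) + "\n")
        self.metabolites.to_csv(out / "metabolites.tsv", sep="\t")
        from .gsea import write_gmt

        write_gmt(self.metabolite_sets, out / "sets.gmt")
        truth = {
            g: {
                "usable_carbon": sorted(t.usable_carbon),
                "usable_nitrogen": sorted(t.usable_nitrogen),
                "essentiality": {k: v for k, v in t.essentiality.dropna().items()},
                "mean_essentiality": t.mean_essentiality,
            }
            for g, t in sorted(self.genera.items())
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))


DEFAULT_DEMAND_EFFECT = 1.0


def make_community_study(
    seed: int = 0,
    db: UniversalReactionDB | None = None,
    genus_specs: list[GenusSpec] | None = None,
    genera: dict[str, GenusTruth] | None = None,
    n_per_group: int = 15,
    demand_effect: float = DEFAULT_DEMAND_EFFECT,
    concentration: float = 60.0,
    gap_fraction: float = 0.0,
    depth: float = 200.0,
    n_metabolites: int = 60,
    n_sets: int = 8,
    set_size: int = 6,
    metabolite_shift: float = 0.7,
    missing_quantile: float = 0.05,
) -> SyntheticStudy:
    """Generate a two-arm community study with planted treatment effects.

    Control abundances are Dirichlet around decreasing base proportions (the
    top genera cover roughly 90% cumulative abundance); treated abundances
    tilt the base proportions toward low-mean-essentiality genera by
    ``demand_effect`` (log-linear in centered essentiality).  Per-sample host
    weights are negatively tied to the generating-model demand plus noise.
    Gene counts are Poisson around abundance x gene-length expectations with
    ten universal single-copy roles at one copy per genome.  Metabolite
    intensities are log-normal with two planted set shifts (one down, one up
    in treated) and left-censored missingness.

    Passing ``genera`` reuses previously built genus ground truths (fast
    replicate cohorts that share the same generating model).
    """
    rng = np.random.default_rng(seed)
    if db is None:
        db = make_universal_db(seed=seed)
    specs = genus_specs or default_genus_specs(db)
    if genera is None:
        genera = {
            spec.genus: make_genus(
                db, spec, gap_fraction=gap_fraction,
                seed=int(rng.integers(2**31)),
            )
            for spec in specs
        }
    names = sorted(genera)
    base = np.array([0.30, 0.22, 0.16, 0.13, 0.11, 0.08][: len(names)])
    if len(base) < len(names):
        extra = np.full(len(names) - len(base), base[-1] / 2)
        base = np.concatenate([base, extra])
    base = base / base.sum()
    e = np.array([genera[g].mean_essentiality for g in names])
    e_bar = float(base @ e)
    tilt = base * np.exp(demand_effect * (e_bar - e))
    tilt = tilt / tilt.sum()

    samples, labels, rows = [], [], []
    for i in range(n_per_group):
        samples.append(f"C{i + 1:02d}")
        labels.append("control")
        rows.append(rng.dirichlet(base * concentration))
    for i in range(n_per_group):
        samples.append(f"T{i + 1:02d}")
        labels.append("treated")
        rows.append(rng.dirichlet(tilt * concentration))
    abund_df = pd.DataFrame(rows, index=samples, columns=names)
    demand_true = abund_df.to_numpy() @ e
    weight = pd.Series(
        2600.0 - 1200.0 * demand_true + rng.normal(0.0, 80.0, size=len(samples)),
        index=samples, name="weight_g",
    )
    treatment = pd.Series(labels, index=samples, name="treatment")
    abundance = AbundanceTable(abund_df, treatment=treatment, weight=weight)

    # gene count table: one gene per (genus, role) plus USCGs per genus
    uscg_ids = tuple(f"USCG{i + 1:02d}" for i in range(10))
    gene_rows = []
    for g in names:
        for role in sorted(genera[g].full_profile.roles) + list(uscg_ids):
            gene_rows.append({
                "gene_id": f"{g}|{role}",
                "length_bp": int(rng.integers(600, 3000)),
                "role": role,
                "genus": g,
            })
    gene_meta = pd.DataFrame(gene_rows)
    lam = (
        depth
        * abund_df.to_numpy()[:, [names.index(g) for g in gene_meta["genus"]]]
        * (gene_meta["length_bp"].to_numpy() / 1000.0)
    )
    gene_counts = pd.DataFrame(
        rng.poisson(lam), index=samples, columns=gene_meta["gene_id"].tolist()
    )

    # metabolite intensities with planted differential sets
    met_ids = [f"met{i + 1:03d}" for i in range(n_metabolites)]
    sets = {
        f"pathway_{s + 1:02d}": set(met_ids[s * set_size:(s + 1) * set_size])
        for s in range(n_sets)
    }
    shifted = {"pathway_01": -metabolite_shift, "pathway_02": +metabolite_shift}
    mu = rng.normal(13.8, 1.5, size=n_metabolites)
    sigma = 0.4
    shifts = np.zeros(n_metabolites)
    for sname, delta in shifted.items():
        for m in sets[sname]:
            shifts[met_ids.index(m)] = delta
    treated_mask = np.array([t == "treated" for t in labels], dtype=float)
    log_int = (
        mu[None, :]
        + shifts[None, :] * treated_mask[:, None]
        + rng.normal(0.0, sigma, size=(len(samples), n_metabolites))
    )
    intensities = np.exp(log_int)
    # left-censored missingness: the dimmest tail of each metabolite drops out
    cut = np.exp(mu + sigma * float(_norm_ppf(missing_quantile)))
    censored = intensities < cut[None, :]
    for j in range(n_metabolites):  # keep at least one observation
        if censored[:, j].all():
            censored[int(np.argmax(intensities[:, j])), j] = False
    metabolites = pd.DataFrame(
        np.where(censored, np.nan, intensities), index=samples, columns=met_ids
    )

    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "demand_effect": demand_effect,
        "concentration": concentration,
        "gap_fraction": gap_fraction,
        "depth": depth,
        "n_metabolites": n_metabolites,
        "n_sets": n_sets,
        "set_size": set_size,
        "metabolite_shift": metabolite_shift,
        "missing_quantile": missing_quantile,
        "base_proportions": base.tolist(),
        "tilted_proportions": tilt.tolist(),
        "genus_mean_essentiality": {g: genera[g].mean_essentiality for g in names},
    }
    return SyntheticStudy(
        db=db,
        genera=genera,
        abundance=abundance,
        gene_counts=gene_counts,
        gene_meta=gene_meta,
        uscg_ids=uscg_ids,
        metabolites=metabolites,
        metabolite_sets=sets,
        shifted_sets=shifted,
        manifest=manifest,
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
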