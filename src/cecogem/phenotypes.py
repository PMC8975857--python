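"""Phenotype screens: main carbon/nitrogen source utilization and random-media
metabolite essentiality.

Carbon (nitrogen) screen: growth is maximized with the total uptake of
carbon-(nitrogen-)containing compounds capped at an elemental budget; a
compound is a usable *main* source if exempting it from the budget (with its
own generous uptake bound) raises maximal growth to at least twice the
baseline.

Essentiality screen: media are sampled by opening each transporter-backed
uptake independently with probability p; in every viable medium each open
metabolite is closed singly, and its essentiality score is the fraction of
viable media containing it in which closing it abolishes growth.  Because a
medium minus one metabolite is itself a medium, viability results are
memoized by uptake set, which also makes the exact enumeration oracle
(:func:`exact_essentiality`) cheap for models with few transporters.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .db import StoichiometricModel, UniversalReactionDB, uptake_id
from .fba import FBAProblem, MediaCondition

logger = logging.getLogger(__name__)

__all__ = [
    "UtilizationProfile",
    "EssentialityProfile",
    "carbon_source_usable",
    "nitrogen_source_usable",
    "sample_random_media",
    "metabolite_essentiality",
    "exact_essentiality",
    "phenotype_all",
    "genus_seed",
]

VIABILITY_FLOOR = 0.001  # mmol gDW^-1 h^-1; also the gap-fill biomass floor


@dataclass
class UtilizationProfile:
    """Per-compound main-source usability for one genus.

    ``carbon``/``nitrogen`` are DataFrames indexed by compound with columns
    usable (bool), baseline and test (biomass rates, mmol gDW^-1 h^-1).
    """

    genus: str
    carbon: pd.DataFrame
    nitrogen: pd.DataFrame

    def usable_carbon(self) -> frozenset[str]:
        return frozenset(self.carbon.index[self.carbon["usable"]])

    def usable_nitrogen(self) -> frozenset[str]:
        return frozenset(self.nitrogen.index[self.nitrogen["usable"]])

    def to_tsv(self) -> str:
        rows = []
        for element, df in (("carbon", self.carbon), ("nitrogen", self.nitrogen)):
            for compound, r in df.iterrows():
                rows.append(
                    f"{self.genus}\t{element}\t{compound}\t{int(r['usable'])}"
                    f"\t{r['baseline']:.6g}\t{r['test']:.6g}"
                )
        return "genus\telement\tcompound\tusable\tbaseline\ttest\n" + "\n".join(rows) + "\n"


@dataclass
class EssentialityProfile:
    """Per-metabolite essentiality fractions for one genus.

    ``scores[m]`` = n_media_essential[m] / n_media_present[m] over viable
    sampled media; ``mean_essentiality`` is the unweighted mean over scored
    metabolites (those present in at least one viable medium).
    """

    genus: str
    scores: pd.Series
    n_present: pd.Series
    n_essential: pd.Series
    mean_essentiality: float
    params: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["genus\tmetabolite\tscore\tn_present\tn_essential"]
        for m in self.scores.index:
            lines.append(
                f"{self.genus}\t{m}\t{self.scores[m]:.6g}"
                f"\t{int(self.n_present[m])}\t{int(self.n_essential[m])}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Carbon / nitrogen main-source screens
# ---------------------------------------------------------------------------


def _element_uptake_atoms(model: StoichiometricModel, element_idx: int) -> dict[str, int]:
    """Uptake metabolite -> atom count, for metabolites carrying the element."""
    out = {}
    for met in model.uptake_metabolites():
        atoms = model.external_atoms.get(met, (0, 0))[element_idx]
        if atoms >= 1:
            out[met] = atoms
    return out


def _source_usable(
    model: StoichiometricModel,
    compound: str,
    element_idx: int,
    total_limit: float,
    fold: float,
    exempt_bound: float,
    viability_floor: float,
    strict: bool,
    problem: FBAProblem | None,
) -> tuple[bool, float, float]:
    atoms = _element_uptake_atoms(model, element_idx)
    element = "carbon" if element_idx == 0 else "nitrogen"
    known = model.external_atoms.get(compound)
    if known is not None and known[element_idx] < 1:
        raise ValueError(f"{compound} carries no {element}; not a candidate source")
    prob = problem or FBAProblem(model)
    budget_all = {uptake_id(m): float(a) for m, a in atoms.items()}
    baseline = prob.solve(extra_constraints=[(budget_all, total_limit)]).objective
    if compound not in atoms:
        # unknown to the model or no transporter for it: cannot be a source
        if strict:
            raise ValueError(f"{model.genus}: no uptake reaction for {compound}")
        return False, baseline, 0.0
    budget_rest = {k: v for k, v in budget_all.items() if k != uptake_id(compound)}
    test = prob.solve(
        extra_constraints=[(budget_rest, total_limit)],
        bound_overrides={uptake_id(compound): (0.0, exempt_bound)},
    ).objective
    usable = test >= max(fold * baseline, viability_floor)
    return usable, baseline, test


def carbon_source_usable(
    model: StoichiometricModel,
    compound: str,
    total_c_limit: float = 10.0,
    fold: float = 2.0,
    exempt_bound: float = 100.0,
    viability_floor: float = VIABILITY_FLOOR,
    strict: bool = False,
    problem: FBAProblem | None = None,
) -> tuple[bool, float, float]:
    """Can ``compound`` serve as the main carbon source?

    Baseline: max biomass with total carbon uptake (atoms x flux summed over
    carbon-containing uptakes) capped at ``total_c_limit``.  Test: the same
    LP with the compound exempted from the cap and its uptake bounded by
    ``exempt_bound``.  Usable iff test >= max(fold x baseline, floor).
    """
    return _source_usable(
        model, compound, 0, total_c_limit, fold, exempt_bound, viability_floor, strict, problem
    )


def nitrogen_source_usable(
    model: StoichiometricModel,
    compound: str,
    total_n_limit: float = 10.0,
    fold: float = 2.0,
    exempt_bound: float = 100.0,
    viability_floor: float = VIABILITY_FLOOR,
    strict: bool = False,
    problem: FBAProblem | None = None,
) -> tuple[bool, float, float]:
    """Nitrogen analogue of :func:`carbon_source_usable`."""
    return _source_usable(
        model, compound, 1, total_n_limit, fold, exempt_bound, viability_floor, strict, problem
    )


# ---------------------------------------------------------------------------
# Random media and essentiality
# ---------------------------------------------------------------------------


def sample_random_media(
    model: StoichiometricModel,
    p: float = 0.9,
    q: float = 0.0,
    rng: np.random.Generator | None = None,
    uptake_bound: float = 10.0,
    transporterless_mets: tuple[str, ...] = (),
) -> MediaCondition:
    """Open each transporter-backed uptake independently with probability p.

    With q > 0, each metabolite in ``transporterless_mets`` gains a direct
    uptake opened independently with probability q (the robustness variant
    compensating for transporters missed by annotation).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    rng = rng or np.random.default_rng()
    mets = sorted(model.uptake_metabolites())
    open_mets = frozenset(m for m in mets if rng.random() < p)
    direct = frozenset(m for m in sorted(transporterless_mets) if rng.random() < q)
    return MediaCondition(
        open_uptakes=open_mets,
        uptake_bound=uptake_bound,
        direct_uptakes=direct,
        includes_transporterless=q > 0,
        q=q,
    )


class _ViabilityCache:
    """Memoized medium -> viability map over one FBA problem."""

    def __init__(self, problem: FBAProblem, uptake_bound: float, floor: float):
        self.problem = problem
        self.uptake_bound = uptake_bound
        self.floor = floor
        self._cache: dict[tuple[frozenset, frozenset], bool] = {}
        self.n_solves = 0

    def viable(self, open_mets: frozenset[str], direct: frozenset[str] = frozenset()) -> bool:
        key = (open_mets, direct)
        if key not in self._cache:
            media = MediaCondition(
                open_uptakes=open_mets,
                uptake_bound=self.uptake_bound,
                direct_uptakes=direct,
            )
            self.n_solves += 1
            self._cache[key] = self.problem.max_biomass(media) >= self.floor
        return self._cache[key]


def _score_frame(
    genus: str,
    present: dict[str, int],
    essential: dict[str, int],
    params: dict,
) -> EssentialityProfile:
    mets = sorted(present)
    n_present = pd.Series({m: present[m] for m in mets}, dtype=int)
    n_essential = pd.Series({m: essential.get(m, 0) for m in mets}, dtype=int)
    scores = n_essential / n_present.where(n_present > 0)
    scored = scores.dropna()
    return EssentialityProfile(
        genus=genus,
        scores=scores.fillna(0.0),
        n_present=n_present,
        n_essential=n_essential,
        mean_essentiality=float(scored.mean()) if len(scored) else float("nan"),
        params=params,
    )


def metabolite_essentiality(
    model: StoichiometricModel,
    n_media: int = 1000,
    p: float = 0.9,
    q: float = 0.0,
    seed: int | None = None,
    viability_floor: float = VIABILITY_FLOOR,
    uptake_bound: float = 10.0,
    transporterless_mets: tuple[str, ...] = (),
    max_attempts_factor: int = 50,
) -> EssentialityProfile:
    """Monte-Carlo metabolite essentiality across binomially sampled media.

    Media are drawn until ``n_media`` viable ones accumulate (growth >=
    ``viability_floor``), capped at ``max_attempts_factor x n_media``
    attempts.  Within each viable medium every open metabolite is closed
    singly and marked essential if growth drops below the floor.
    """
    rng = np.random.default_rng(seed)
    targets = dict(transporterless_mets) if isinstance(transporterless_mets, dict) else None
    direct_cands = tuple(sorted(transporterless_mets)) if q > 0 else ()
    problem = FBAProblem(
        model, direct_uptake_mets=direct_cands, direct_uptake_targets=targets
    )
    cache = _ViabilityCache(problem, uptake_bound, viability_floor)
    present: dict[str, int] = {}
    essential: dict[str, int] = {}
    viable_count = 0
    attempts = 0
    max_attempts = max_attempts_factor * n_media
    while viable_count < n_media:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"{model.genus}: only {viable_count}/{n_media} viable media after "
                f"{attempts} attempts (viability fraction {viable_count / attempts:.3f})"
            )
        media = sample_random_media(
            model, p=p, q=q, rng=rng,
            uptake_bound=uptake_bound, transporterless_mets=direct_cands,
        )
        attempts += 1
        if not cache.viable(media.open_uptakes, media.direct_uptakes):
            continue
        viable_count += 1
        for m in sorted(media.open_uptakes):
            present[m] = present.get(m, 0) + 1
            if not cache.viable(media.open_uptakes - {m}, media.direct_uptakes):
                essential[m] = essential.get(m, 0) + 1
        for m in sorted(media.direct_uptakes):
            present[m] = present.get(m, 0) + 1
            if not cache.viable(media.open_uptakes, media.direct_uptakes - {m}):
                essential[m] = essential.get(m, 0) + 1
    params = {
        "n_media": n_media, "p": p, "q": q, "seed": seed,
        "uptake_bound": uptake_bound, "viability_floor": viability_floor,
        "attempts": attempts,
    }
    return _score_frame(model.genus, present, essential, params)


def exact_essentiality(
    model: StoichiometricModel,
    p: float = 0.9,
    q: float = 0.0,
    viability_floor: float = VIABILITY_FLOOR,
    uptake_bound: float = 10.0,
    transporterless_mets: tuple[str, ...] = (),
    max_uptakes: int = 14,
) -> pd.Series:
    """Exact essentiality by enumeration over all uptake subsets.

    For each metabolite m: score = P(closing m kills growth | medium viable
    and m open) under independent Bernoulli(p) openings (Bernoulli(q) for
    direct uptakes).  Closing m in medium S is the medium S \\ {m}, so a
    single viability table over all 2^k subsets suffices.  Only sensible for
    models with at most ``max_uptakes`` uptakes.
    """
    t_mets = sorted(model.uptake_metabolites())
    d_mets = sorted(transporterless_mets) if q > 0 else []
    targets = dict(transporterless_mets) if isinstance(transporterless_mets, dict) else None
    k = len(t_mets) + len(d_mets)
    if k > max_uptakes:
        raise ValueError(f"{model.genus}: {k} uptakes is too many for exact enumeration")
    problem = FBAProblem(
        model, direct_uptake_mets=tuple(d_mets), direct_uptake_targets=targets
    )
    cache = _ViabilityCache(problem, uptake_bound, viability_floor)
    present_mass: dict[str, float] = {m: 0.0 for m in t_mets + d_mets}
    essential_mass: dict[str, float] = {m: 0.0 for m in t_mets + d_mets}
    for bits in itertools.product((0, 1), repeat=k):
        w = 1.0
        for b, prob in zip(bits, [p] * len(t_mets) + [q] * len(d_mets)):
            w *= prob if b else (1 - prob)
        if w == 0.0:
            continue
        open_t = frozenset(m for m, b in zip(t_mets, bits[: len(t_mets)]) if b)
        open_d = frozenset(m for m, b in zip(d_mets, bits[len(t_mets):]) if b)
        if not cache.viable(open_t, open_d):
            continue
        for m in open_t:
            present_mass[m] += w
            if not cache.viable(open_t - {m}, open_d):
                essential_mass[m] += w
        for m in open_d:
            present_mass[m] += w
            if not cache.viable(open_t, open_d - {m}):
                essential_mass[m] += w
    scores = {
        m: (essential_mass[m] / present_mass[m]) if present_mass[m] > 0 else np.nan
        for m in present_mass
    }
    return pd.Series(scores).sort_index()


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------


def genus_seed(master_seed: int, genus: str) -> int:
    """Stable per-genus child seed below 2^31."""
    h = hashlib.blake2b(f"{master_seed}:{genus}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


def phenotype_all(
    models: list[StoichiometricModel],
    db: UniversalReactionDB,
    n_media: int = 1000,
    p: float = 0.9,
    q: float = 0.0,
    seed: int = 0,
    total_limit: float = 10.0,
    fold: float = 2.0,
    exempt_bound: float = 100.0,
    viability_floor: float = VIABILITY_FLOOR,
    cache_dir: str | Path | None = None,
) -> tuple[list[UtilizationProfile], list[EssentialityProfile], dict[str, str]]:
    """Run both phenotype screens on every model.

    Candidate compounds are all external metabolites of the database with at
    least one carbon (nitrogen) atom.  Per-genus failures are logged and
    reported in the returned failure map without aborting the batch.  With
    ``cache_dir`` set, per-genus results are written as TSV plus a JSON run
    manifest.
    """
    carbon_cands = sorted(
        m for m in db.external_metabolites() if db.metabolites[m].carbon_atoms >= 1
    )
    nitrogen_cands = sorted(
        m for m in db.external_metabolites() if db.metabolites[m].nitrogen_atoms >= 1
    )
    utilization: list[UtilizationProfile] = []
    essentiality: list[EssentialityProfile] = []
    failures: dict[str, str] = {}
    for model in sorted(models, key=lambda m: m.genus):
        try:
            problem = FBAProblem(model)
            rows_c, rows_n = {}, {}
            for compound in carbon_cands:
                usable, base, test = carbon_source_usable(
                    model, compound, total_limit, fold, exempt_bound,
                    viability_floor, problem=problem,
                )
                rows_c[compound] = {"usable": usable, "baseline": base, "test": test}
            for compound in nitrogen_cands:
                usable, base, test = nitrogen_source_usable(
                    model, compound, total_limit, fold, exempt_bound,
                    viability_floor, problem=problem,
                )
                rows_n[compound] = {"usable": usable, "baseline": base, "test": test}
            util = UtilizationProfile(
                genus=model.genus,
                carbon=pd.DataFrame.from_dict(rows_c, orient="index"),
                nitrogen=pd.DataFrame.from_dict(rows_n, orient="index"),
            )
            ess = metabolite_essentiality(
                model, n_media=n_media, p=p, q=q,
                seed=genus_seed(seed, model.genus),
                viability_floor=viability_floor,
            )
        except Exception as exc:  # noqa: BLE001 - batch must not abort
            logger.warning("phenotyping failed for %s: %s", model.genus, exc)
            failures[model.genus] = str(exc)
            continue
        utilization.append(util)
        essentiality.append(ess)
        if cache_dir is not None:
            out = Path(cache_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"{model.genus}.utilization.tsv").write_text(util.to_tsv())
            (out / f"{model.genus}.essentiality.tsv").write_text(ess.to_tsv())
    if cache_dir is not None:
        manifest = {
            "seed": seed, "p": p, "q": q, "n_media": n_media,
            "total_limit": total_limit, "fold": fold, "exempt_bound": exempt_bound,
            "viability_floor": viability_floor,
            "failures": failures,
        }
        Path(cache_dir, "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return utilization, essentiality, failures
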