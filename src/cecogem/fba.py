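"""Flux balance analysis over :class:`~cecogem.db.StoichiometricModel`.

FBA maximizes the biomass flux subject to steady state (S v = 0) and flux
bounds.  Media are expressed as the set of external metabolites whose uptake
reactions are open; everything else is closed (upper bound 0).  A
:class:`FBAProblem` caches the constraint matrix of one model so that
thousands of media variants (the random-media essentiality screen) re-solve
with only the bound vector changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .db import StoichiometricModel, uptake_id

__all__ = ["MediaCondition", "FBAProblem", "FBAResult", "FBAInfeasibleError", "fba"]


class FBAInfeasibleError(RuntimeError):
    """The LP has no feasible point (conflicting constraints).

    Distinct from a feasible solution with zero growth, which is returned
    as a normal result with objective 0.
    """


@dataclass(frozen=True)
class MediaCondition:
    """A growth medium: which uptakes are open and at what rate.

    ``open_uptakes`` are external metabolite ids whose transporter-backed
    uptake reactions are open with bound ``uptake_bound``.  ``direct_uptakes``
    name transporter-less external metabolites granted an ad-hoc direct
    uptake (the robustness variant sampled with probability q); the consuming
    :class:`FBAProblem` must have been built with those candidate columns.
    """

    open_uptakes: frozenset[str]
    uptake_bound: float = 10.0
    direct_uptakes: frozenset[str] = frozenset()
    includes_transporterless: bool = False
    q: float = 0.0

    def all_open(self) -> frozenset[str]:
        return self.open_uptakes | self.direct_uptakes


@dataclass
class FBAResult:
    objective: float
    fluxes: dict[str, float]
    status: int = 0


def _direct_uptake_id(metabolite: str) -> str:
    return f"DUP_{metabolite}"


class FBAProblem:
    """Reusable LP for one model; media only move bounds.

    Parameters
    ----------
    model:
        The genus model.  Its uptake reactions define the transporter-backed
        media space.
    direct_uptake_mets:
        External metabolites (typically transporter-less ones from the
        universal database) for which an extra direct-uptake column is added;
        closed unless a medium opens them.
    direct_uptake_targets:
        Optional map from a direct-uptake metabolite to the model metabolite
        its flux feeds (e.g. the cytosolic form, so a missing transporter is
        bypassed); defaults to the metabolite itself.
    """

    def __init__(
        self,
        model: StoichiometricModel,
        direct_uptake_mets: tuple[str, ...] = (),
        direct_uptake_targets: dict[str, str] | None = None,
    ):
        model.validate()
        self.model = model
        self.direct_uptake_mets = tuple(direct_uptake_mets)
        self.direct_uptake_targets = dict(direct_uptake_targets or {})
        rids = sorted(model.reactions)
        cols: list[str] = list(rids)
        self._direct_cols: dict[str, int] = {}
        for met in self.direct_uptake_mets:
            self._direct_cols[met] = len(cols)
            cols.append(_direct_uptake_id(met))
        self.columns = cols
        self.met_index = {m: i for i, m in enumerate(model.metabolite_ids())}
        n_m, n_r = len(self.met_index), len(cols)
        A = np.zeros((n_m, n_r))
        lb = np.zeros(n_r)
        ub = np.zeros(n_r)
        for j, rid in enumerate(rids):
            rxn = model.reactions[rid]
            for met, coef in rxn.stoichiometry.items():
                A[self.met_index[met], j] = coef
            lb[j], ub[j] = rxn.lb, rxn.ub
        for met, j in self._direct_cols.items():
            target = self.direct_uptake_targets.get(met, met)
            if target in self.met_index:
                A[self.met_index[target], j] = 1.0
            # bounds stay [0, 0] until a medium opens the direct uptake
        self.A_eq = A
        self.base_lb = lb
        self.base_ub = ub
        self.col_index = {c: i for i, c in enumerate(cols)}
        self.biomass_col = self.col_index[model.biomass_reaction]
        self._uptake_cols = {
            met: self.col_index[rid] for rid, met in model.uptakes.items()
        }

    # -----------------------------------------------------------------

    def _bounds_for(self, media: MediaCondition | None) -> tuple[np.ndarray, np.ndarray]:
        lb = self.base_lb.copy()
        ub = self.base_ub.copy()
        if media is not None:
            for met, j in self._uptake_cols.items():
                ub[j] = media.uptake_bound if met in media.open_uptakes else 0.0
            for met in media.direct_uptakes:
                if met not in self._direct_cols:
                    raise ValueError(
                        f"direct uptake for {met} not provisioned in this FBA problem"
                    )
                ub[self._direct_cols[met]] = media.uptake_bound
        return lb, ub

    def solve(
        self,
        media: MediaCondition | None = None,
        extra_constraints: list[tuple[dict[str, float], float]] | None = None,
        objective: str | None = None,
        bound_overrides: dict[str, tuple[float, float]] | None = None,
    ) -> FBAResult:
        """Maximize biomass (or ``objective`` reaction) under a medium.

        ``extra_constraints`` is a list of (coefficients-by-reaction-id,
        upper bound) rows, e.g. the total-carbon uptake budget.
        ``bound_overrides`` pins individual reaction bounds after media are
        applied.  ``media=None`` leaves the model's stored bounds (complete
        media for a freshly built model, whose uptakes are open by default).
        """
        lb, ub = self._bounds_for(media)
        if bound_overrides:
            for rid, (lo, hi) in bound_overrides.items():
                j = self.col_index[rid]
                lb[j], ub[j] = lo, hi
        c = np.zeros(len(self.columns))
        obj_col = self.col_index[objective] if objective else self.biomass_col
        c[obj_col] = -1.0
        A_ub = b_ub = None
        if extra_constraints:
            A_ub = np.zeros((len(extra_constraints), len(self.columns)))
            b_ub = np.zeros(len(extra_constraints))
            for i, (coefs, rhs) in enumerate(extra_constraints):
                for rid, coef in coefs.items():
                    A_ub[i, self.col_index[rid]] = coef
                b_ub[i] = rhs
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.A_eq,
            b_eq=np.zeros(self.A_eq.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 2:
            raise FBAInfeasibleError(
                f"FBA infeasible for {self.model.genus}: conflicting constraints"
            )
        if res.status != 0:
            raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
        fluxes = {cid: float(res.x[j]) for j, cid in enumerate(self.columns)}
        return FBAResult(objective=-float(res.fun), fluxes=fluxes)

    def max_biomass(self, media: MediaCondition | None = None, **kw) -> float:
        return self.solve(media=media, **kw).objective

    def complete_media(self, uptake_bound: float = 10.0, q_mets: bool = False) -> MediaCondition:
        """Medium with every transporter-backed uptake open."""
        direct = frozenset(self.direct_uptake_mets) if q_mets else frozenset()
        return MediaCondition(
            open_uptakes=frozenset(self.model.uptake_metabolites()),
            uptake_bound=uptake_bound,
            direct_uptakes=direct,
        )


def fba(
    model: StoichiometricModel,
    media: MediaCondition | None = None,
    extra_constraints: list[tuple[dict[str, float], float]] | None = None,
) -> FBAResult:
    """One-shot FBA; see :class:`FBAProblem` for repeated solves."""
    direct = tuple(sorted(media.direct_uptakes)) if media is not None else ()
    return FBAProblem(model, direct_uptake_mets=direct).solve(
        media=media, extra_constraints=extra_constraints
    )
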