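"""Functional-profile normalization and core-microbiome accounting.

Read counts per gene are TPM-normalized with gene lengths, aggregated to
functional roles, and rescaled so the per-sample median abundance of a set of
universal single-copy genes (USCGs) equals 1 — putting role abundances on a
mean copies-per-genome scale.  The core microbiome is the smallest set of
genera whose cumulative mean relative abundance reaches a threshold (default
90%); core relative abundances renormalize each sample over the core.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "CoreDefinition",
    "CommunityAbundance",
    "CopyNumberTable",
    "tpm_normalize",
    "sum_by_role",
    "copies_per_genome",
    "filter_taxa",
    "define_core_genera",
    "core_relative_abundance",
    "genus_function_contribution",
    "spearman_with_p",
]


@dataclass
class AbundanceTable:
    """Samples x genera relative abundances with per-sample metadata.

    Rows may sum to less than one when rare taxa were filtered out.
    ``weight`` holds per-sample host weights (grams) for correlation rankings.
    """

    abundance: pd.DataFrame
    treatment: pd.Series | None = None
    weight: pd.Series | None = None

    def __post_init__(self):
        a = self.abundance
        if (a.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if (a.sum(axis=1) > 1 + 1e-9).any():
            bad = a.index[a.sum(axis=1) > 1 + 1e-9][0]
            raise ValueError(f"sample {bad}: abundances sum to more than 1")


@dataclass(frozen=True)
class CoreDefinition:
    core_genera: tuple[str, ...]  # descending mean abundance
    cumulative_threshold: float


@dataclass
class CommunityAbundance:
    """Core-renormalized abundances: per sample, core genera sum to 1."""

    abundance: pd.DataFrame
    treatment: pd.Series | None = None
    weight: pd.Series | None = None


@dataclass
class CopyNumberTable:
    """Samples x roles in mean copies per genome; USCG median is 1 per sample."""

    copies: pd.DataFrame
    uscg_ids: tuple[str, ...]


# ---------------------------------------------------------------------------


def tpm_normalize(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """TPM-normalize a samples x genes count matrix with gene lengths (bp).

    Per sample: rate_g = count_g / length_kb_g, tpm_g = 1e6 rate_g / sum(rates);
    every sample row sums to 1e6.
    """
    lengths = lengths_bp.reindex(counts.columns)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"gene {missing} has no length")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    vals = counts.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("counts must be finite and non-negative")
    rates = vals / (lengths.to_numpy() / 1000.0)
    totals = rates.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0][0]
        raise ValueError(f"sample {bad} has all-zero counts")
    tpm = rates / totals[:, None] * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def sum_by_role(
    tpm: pd.DataFrame, gene_roles: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Aggregate gene-level TPM to roles (a gene counts once per assigned role).

    ``gene_roles`` maps gene id to a role id or a ';'-separated list of roles;
    genes without a role are dropped.
    """
    mapping = pd.Series(gene_roles)
    cols: dict[str, list[str]] = {}
    for gene, roles in mapping.dropna().items():
        for role in str(roles).split(";"):
            role = role.strip()
            if role:
                cols.setdefault(role, []).append(gene)
    out = {
        role: tpm[[g for g in genes if g in tpm.columns]].sum(axis=1)
        for role, genes in cols.items()
    }
    return pd.DataFrame(out, index=tpm.index).sort_index(axis=1)


def copies_per_genome(tpm: pd.DataFrame, uscg_ids: list[str]) -> CopyNumberTable:
    """Rescale each sample so the median over USCG features is exactly 1."""
    uscg = [u for u in uscg_ids if u in tpm.columns]
    if not uscg:
        raise ValueError("none of the USCG ids are present in the table")
    med = tpm[uscg].median(axis=1)
    if (med <= 0).any():
        bad = tpm.index[med <= 0][0]
        raise ValueError(f"sample {bad}: all USCGs have zero abundance")
    copies = tpm.div(med, axis=0)
    return CopyNumberTable(copies=copies, uscg_ids=tuple(uscg))


def filter_taxa(abund: AbundanceTable, min_mean_abundance: float = 1e-4) -> AbundanceTable:
    """Drop genera whose mean relative abundance falls below a floor."""
    keep = abund.abundance.columns[abund.abundance.mean(axis=0) > min_mean_abundance]
    return AbundanceTable(abund.abundance[keep], abund.treatment, abund.weight)


def define_core_genera(
    abund: AbundanceTable, cumulative_threshold: float = 0.90
) -> CoreDefinition:
    """Smallest prefix of the descending-mean genus ranking reaching the threshold.

    Cumulative mean abundance is expressed as a fraction of the total mean
    abundance.  Genera tied in mean with the boundary genus are all included,
    which keeps the definition order-independent.
    """
    if not 0 < cumulative_threshold <= 1:
        raise ValueError("cumulative_threshold must be in (0, 1]")
    means = abund.abundance.mean(axis=0)
    total = means.sum()
    if total <= 0:
        raise ValueError("no genus with positive mean abundance")
    order = means.sort_values(ascending=False, kind="stable")
    order = order.iloc[np.lexsort((order.index, -order.to_numpy()))]
    cum = order.cumsum() / total
    n_core = int(np.searchsorted(cum.to_numpy(), cumulative_threshold - 1e-12) + 1)
    n_core = min(n_core, len(order))
    boundary = order.iloc[n_core - 1]
    while n_core < len(order) and order.iloc[n_core] == boundary:
        n_core += 1
    return CoreDefinition(tuple(order.index[:n_core]), cumulative_threshold)


def core_relative_abundance(
    abund: AbundanceTable, core: CoreDefinition
) -> CommunityAbundance:
    """Renormalize each sample over the core genera (rows sum to 1)."""
    sub = abund.abundance[list(core.core_genera)]
    totals = sub.sum(axis=1)
    if (totals <= 0).any():
        bad = sub.index[totals <= 0][0]
        raise ValueError(f"sample {bad} has zero total core abundance")
    return CommunityAbundance(
        abundance=sub.div(totals, axis=0),
        treatment=abund.treatment,
        weight=abund.weight,
    )


# ---------------------------------------------------------------------------


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p: t-approximation for n >= 5, exact
    permutation enumeration below."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if n >= 5:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        perms = list(itertools.permutations(ry))
        for perm in perms:
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if r >= obs - 1e-12:
                count += 1
        p = count / len(perms)
    return rho, p


def genus_function_contribution(
    stratified: pd.DataFrame,
    core: CoreDefinition,
    role_sets: dict[str, list[str]],
    core_abund: CommunityAbundance,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genus functional contributions and their abundance correlations.

    ``stratified`` is a samples x (genus, role) copy-number table (MultiIndex
    columns).  The contribution of a genus to a role group in a sample is the
    mean copy number it contributes across the group's roles (roles missing
    for the genus count as 0).  For each (genus, group) the Spearman
    correlation across samples between the genus's core relative abundance
    and its contribution is reported with a two-sided p-value.  Groups with
    no member roles anywhere in the table are skipped with a warning.
    """
    if not isinstance(stratified.columns, pd.MultiIndex):
        raise ValueError("stratified table needs (genus, role) MultiIndex columns")
    if not stratified.index.equals(core_abund.abundance.index):
        stratified = stratified.reindex(core_abund.abundance.index)
        if stratified.isna().any().any():
            raise ValueError("stratified table samples do not match the abundance table")
    all_roles = set(stratified.columns.get_level_values(1))
    contrib_cols = {}
    corr_rows = []
    for group, roles in sorted(role_sets.items()):
        present = sorted(set(roles) & all_roles)
        if not present:
            warnings.warn(f"role group {group!r} has no member roles in the table; skipped")
            continue
        for genus in core.core_genera:
            vals = pd.DataFrame(
                {r: stratified.get((genus, r), pd.Series(0.0, index=stratified.index))
                 for r in present}
            )
            contribution = vals.mean(axis=1)
            contrib_cols[(genus, group)] = contribution
            rho, p = spearman_with_p(
                core_abund.abundance[genus].to_numpy(), contribution.to_numpy()
            )
            corr_rows.append({"genus": genus, "group": group, "rho": rho, "p": p})
    contrib = pd.DataFrame(contrib_cols, index=stratified.index)
    contrib.columns = pd.MultiIndex.from_tuples(contrib.columns, names=["genus", "group"])
    corr = pd.DataFrame(corr_rows)
    return contrib, corr
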