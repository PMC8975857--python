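"""Sample-level community metrics and the supporting statistics stage.

Aggregates single-genus phenotype predictions to sample-level quantities by
abundance weighting: the *utilization potential* of a compound is the summed
core relative abundance of genera able to use it as a main carbon or nitrogen
source, and the *total metabolic demand* is the abundance-weighted mean
metabolite essentiality — the probability that a random nutrient is required
by a random core community member.  Also houses the group-comparison and
ranking statistics: exact/asymptotic Mann-Whitney U, two-group Z ranking,
abundance-weight correlation ranking, metabolomics median scaling with
minimum imputation, and Welch t ranking with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phenotypes import EssentialityProfile, UtilizationProfile
from .profiles import CommunityAbundance

logger = logging.getLogger(__name__)

__all__ = [
    "RankedFeatureList",
    "utilization_potential",
    "total_metabolic_demand",
    "metabolite_demand",
    "mann_whitney",
    "zscore_rank",
    "correlation_rank",
    "scale_and_impute",
    "welch_rank",
]

#: sentinel replacing an infinite Z (zero pooled variance, unequal means)
Z_MAX = 1e6


@dataclass
class RankedFeatureList:
    """Features ordered by a ranking statistic, descending.

    Ties are broken by feature id (ascending) so the order is deterministic;
    non-finite statistics are excluded before ranking.
    """

    features: tuple[str, ...]
    stats: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedFeatureList":
        s = s[np.isfinite(s)]
        order = np.lexsort((s.index.astype(str), -s.to_numpy(dtype=float)))
        s = s.iloc[order]
        return cls(tuple(s.index), s.to_numpy(dtype=float))

    def as_series(self) -> pd.Series:
        return pd.Series(self.stats, index=list(self.features))

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# Abundance-weighted community metrics
# ---------------------------------------------------------------------------


def _check_cover(core_abund: CommunityAbundance, have: set[str], what: str) -> None:
    missing = [g for g in core_abund.abundance.columns if g not in have]
    if missing:
        raise ValueError(f"genus {missing[0]} lacks a {what} profile")


def utilization_potential(
    core_abund: CommunityAbundance,
    usable: list[UtilizationProfile],
    compound: str,
    element: str = "carbon",
) -> pd.Series:
    """Per-sample summed core abundance of genera able to use ``compound``."""
    if element not in ("carbon", "nitrogen"):
        raise ValueError("element must be 'carbon' or 'nitrogen'")
    by_genus = {u.genus: u for u in usable}
    _check_cover(core_abund, set(by_genus), "utilization")
    users = [
        g for g in core_abund.abundance.columns
        if compound in (by_genus[g].usable_carbon() if element == "carbon"
                        else by_genus[g].usable_nitrogen())
    ]
    out = core_abund.abundance[users].sum(axis=1)
    out.name = f"utilization_potential:{compound}"
    return out


def total_metabolic_demand(
    core_abund: CommunityAbundance, ess: list[EssentialityProfile]
) -> pd.Series:
    """Per-sample abundance-weighted mean essentiality across core genera."""
    by_genus = {e.genus: e for e in ess}
    _check_cover(core_abund, set(by_genus), "essentiality")
    means = pd.Series(
        {g: by_genus[g].mean_essentiality for g in core_abund.abundance.columns}
    )
    out = core_abund.abundance.mul(means, axis=1).sum(axis=1)
    out.name = "total_metabolic_demand"
    return out


def metabolite_demand(
    core_abund: CommunityAbundance, ess: list[EssentialityProfile], metabolite: str
) -> pd.Series:
    """Per-sample abundance-weighted essentiality of one metabolite.

    Genera without a score for the metabolite (no transporter for it)
    contribute 0 — absence of demand, not missing data.
    """
    by_genus = {e.genus: e for e in ess}
    _check_cover(core_abund, set(by_genus), "essentiality")
    scores = pd.Series(
        {g: float(by_genus[g].scores.get(metabolite, 0.0))
         for g in core_abund.abundance.columns}
    ).fillna(0.0)
    out = core_abund.abundance.mul(scores, axis=1).sum(axis=1)
    out.name = f"metabolite_demand:{metabolite}"
    return out


# ---------------------------------------------------------------------------
# Group comparison and ranking statistics
# ---------------------------------------------------------------------------


def mann_whitney(
    values_a: np.ndarray, values_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (statistic for the first sample) and its p-value.

    Exact p by enumeration of all group assignments for n_a + n_b <= 12
    (ties handled via mid-ranks inside the enumeration); normal approximation
    with tie correction above.  ``alternative='greater'`` tests whether the
    first sample tends larger.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    if n_a + n_b <= 12:
        us = np.array([
            sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2
            for idx in itertools.combinations(range(n_a + n_b), n_a)
        ])
        eps = 1e-9
        p_greater = float(np.mean(us >= u_a - eps))
        p_less = float(np.mean(us <= u_a + eps))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2 * min(p_greater, p_less))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative=alternative,
                                     method="asymptotic").pvalue)
    return u_a, p


def zscore_rank(
    copies: pd.DataFrame,
    groups: pd.Series,
    treatment: str,
    control: str = "control",
    min_nonzero_samples: int = 2,
) -> RankedFeatureList:
    """Rank features by the two-group Z of their normalized abundances.

    Z = (mu_t - mu_c) / sqrt(s2_t/n_t + s2_c/n_c) with unbiased sample
    variances.  ``copies`` is samples x features; features with copy numbers
    above zero in fewer than ``min_nonzero_samples`` samples are dropped.
    Zero pooled variance gives Z = 0 for equal means and a +/-``Z_MAX``
    sentinel otherwise (logged).
    """
    t = copies.loc[groups == treatment]
    c = copies.loc[groups == control]
    if len(t) < 2 or len(c) < 2:
        raise ValueError("both groups need at least 2 samples")
    keep = (copies > 0).sum(axis=0) >= min_nonzero_samples
    t, c = t.loc[:, keep], c.loc[:, keep]
    diff = t.mean(axis=0) - c.mean(axis=0)
    se = np.sqrt(t.var(axis=0, ddof=1) / len(t) + c.var(axis=0, ddof=1) / len(c))
    z = diff / se
    degenerate = se == 0
    if degenerate.any():
        n_sent = int((degenerate & (diff != 0)).sum())
        if n_sent:
            logger.info("zscore_rank: %d features with zero pooled variance "
                        "replaced by +/-%g sentinel", n_sent, Z_MAX)
        z[degenerate] = np.sign(diff[degenerate]) * Z_MAX
    return RankedFeatureList.from_series(z)


def correlation_rank(
    features: pd.DataFrame,
    weights: pd.Series,
    method: str = "spearman",
    min_nonzero_samples: int = 3,
) -> RankedFeatureList:
    """Rank features by correlation with per-sample weights.

    ``spearman`` ranks raw abundances (features nonzero in fewer than
    ``min_nonzero_samples`` samples are dropped); ``pearson_log`` correlates
    natural-log intensities with weight.  Constant features are excluded with
    a warning.
    """
    if method not in ("spearman", "pearson_log"):
        raise ValueError(f"unknown method {method!r}")
    w = weights.reindex(features.index)
    if w.isna().any():
        raise ValueError("weights missing for some samples")
    if len(features) < 3:
        raise ValueError("need at least 3 paired observations")
    if method == "spearman":
        keep = (features > 0).sum(axis=0) >= min_nonzero_samples
        features = features.loc[:, keep]
    consts = features.nunique(axis=0) <= 1
    if consts.any():
        warnings.warn(f"{int(consts.sum())} constant features excluded from ranking")
        features = features.loc[:, ~consts]
    if method == "spearman":
        coefs = features.apply(lambda col: stats.spearmanr(col, w).statistic)
    else:
        coefs = np.log(features).apply(lambda col: stats.pearsonr(col, w).statistic)
    return RankedFeatureList.from_series(coefs)


# ---------------------------------------------------------------------------
# Metabolomics statistics
# ---------------------------------------------------------------------------


def scale_and_impute(auc: pd.DataFrame) -> pd.DataFrame:
    """Median-scale metabolite intensities and impute missing values.

    Each metabolite (column) is divided by its median over observed samples,
    making the observed median 1; missing entries are then imputed with the
    minimum scaled observed value of that metabolite.
    """
    never = auc.notna().sum(axis=0) == 0
    if never.any():
        raise ValueError(f"metabolite {auc.columns[never][0]} is never observed")
    med = auc.median(axis=0, skipna=True)
    scaled = auc.div(med, axis=1)
    return scaled.fillna(scaled.min(axis=0, skipna=True))


def welch_rank(
    scaled: pd.DataFrame, groups: pd.Series, treatment: str, control: str = "control"
) -> tuple[RankedFeatureList, pd.DataFrame]:
    """Welch t per metabolite on natural-log scaled values, with BH q-values.

    Returns the t-ranked feature list and a per-metabolite table with t,
    Welch-Satterthwaite df, two-sided p and Benjamini-Hochberg q.  A
    metabolite with zero variance in both groups and equal means gets
    t = 0, p = 1.
    """
    logged = np.log(scaled)
    a = logged.loc[groups == treatment]
    b = logged.loc[groups == control]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    diff = m1 - m2
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * Z_MAX
    df[degenerate] = n1 + n2 - 2
    p = pd.Series(2 * stats.t.sf(np.abs(t), df), index=t.index)
    p[degenerate & (diff == 0)] = 1.0
    q = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
    table = pd.DataFrame({"t": t, "df": df, "p": p, "q": q})
    return RankedFeatureList.from_series(t), table
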