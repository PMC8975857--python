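"""Preranked gene-set enrichment analysis (weighted Kolmogorov-Smirnov).

Given a feature list ranked by a statistic and named feature sets, the
enrichment score (ES) is the maximum deviation from zero of a running sum
that steps up by the (|statistic| ** weight_exponent)-weighted mass at set
members and down by 1/(N - |S|) elsewhere.  Significance comes from
feature-label permutations: random same-size sets drawn from the ranked
universe.  NES normalizes ES against the mean of same-sign null scores, and
the FDR q follows the sign-stratified convention of the original method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .community import RankedFeatureList

__all__ = ["EnrichmentResult", "gsea_prerank", "read_gmt", "write_gmt"]


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int
    leading_edge: tuple[str, ...]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: set name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _es_and_peak(
    weights: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, int]:
    """Enrichment score and the index of the running-sum extremum."""
    n = len(weights)
    n_hit = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member stats zero: no signal
        return 0.0, 0
    miss_step = 1.0 / max(n - n_hit, 1)
    running = np.cumsum(hit_w / total - np.where(hit_mask, 0.0, miss_step))
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def gsea_prerank(
    ranked: RankedFeatureList,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = 3,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a ranked feature list.

    Sets are intersected with the ranked universe; those smaller than
    ``min_set_size`` are dropped.  The null distribution pools ``n_perm``
    random same-size member selections per set; nominal p and NES use the
    same-sign portion of the set's own null, FDR q the sign-stratified pooled
    null across sets.  Deterministic under a fixed seed.
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked feature universe")
    rng = np.random.default_rng(seed)
    features = np.asarray(ranked.features)
    weights = np.abs(ranked.stats) ** weight_exponent
    index = {f: i for i, f in enumerate(features)}
    n = len(features)

    kept = {
        name: sorted(members & set(features))
        for name, members in sorted(sets.items())
    }
    kept = {k: v for k, v in kept.items() if len(v) >= min_set_size}

    observed: dict[str, tuple[float, int, list[str]]] = {}
    null_es: dict[str, np.ndarray] = {}
    for name, members in kept.items():
        mask = np.zeros(n, dtype=bool)
        mask[[index[m] for m in members]] = True
        es, peak = _es_and_peak(weights, mask)
        if es >= 0:
            lead = [f for f in features[: peak + 1] if mask[index[f]]]
        else:
            lead = [f for f in features[peak:] if mask[index[f]]]
        observed[name] = (es, peak, lead)
        size = len(members)
        nulls = np.empty(n_perm)
        for i in range(n_perm):
            pm = np.zeros(n, dtype=bool)
            pm[rng.choice(n, size=size, replace=False)] = True
            nulls[i], _ = _es_and_peak(weights, pm)
        null_es[name] = nulls

    # NES normalization: divide by the mean magnitude of same-sign null scores
    def _nes(es: float, nulls: np.ndarray) -> float:
        same = nulls[nulls >= 0] if es >= 0 else -nulls[nulls < 0]
        if len(same) == 0 or same.mean() == 0:
            return 0.0
        return es / same.mean() if es >= 0 else -(-es) / same.mean()

    results: list[EnrichmentResult] = []
    nes_obs: dict[str, float] = {}
    nes_null_pool: list[float] = []
    for name, nulls in null_es.items():
        es = observed[name][0]
        nes_obs[name] = _nes(es, nulls)
        nes_null_pool.extend(_nes(e, nulls) for e in nulls)
    pool = np.asarray(nes_null_pool)

    all_nes = np.asarray(list(nes_obs.values()))
    for name, members in kept.items():
        es, _, lead = observed[name]
        nulls = null_es[name]
        if es >= 0:
            same = nulls[nulls >= 0]
            p = float((same >= es - 1e-12).sum() / max(len(same), 1)) if len(same) else 1.0
        else:
            same = nulls[nulls < 0]
            p = float((same <= es + 1e-12).sum() / max(len(same), 1)) if len(same) else 1.0
        nes = nes_obs[name]
        if nes >= 0:
            frac_null = float((pool >= nes - 1e-12).sum() / max((pool >= 0).sum(), 1))
            frac_obs = float((all_nes >= nes - 1e-12).sum() / max((all_nes >= 0).sum(), 1))
        else:
            frac_null = float((pool <= nes + 1e-12).sum() / max((pool < 0).sum(), 1))
            frac_obs = float((all_nes <= nes + 1e-12).sum() / max((all_nes < 0).sum(), 1))
        q = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        results.append(
            EnrichmentResult(
                name=name, es=es, nes=nes, p=p, fdr_q=q,
                size=len(members), leading_edge=tuple(lead),
            )
        )
    return results
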