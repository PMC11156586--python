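"""Gene-set statistics on component weights.

The central statistic is the aggregate fold change (AFC): the mean component
weight of a gene set, compared with the same statistic under random
permutations of the weights across the gene universe (default 5,000
permutations). Because every gene contributes its continuous weight, no
"in/out" threshold is needed. Significance is two-sided via symmetric
deviation from the null mean, with the add-one permutation floor
p >= 1/(n_perm + 1), and Benjamini-Hochberg FDR across sets.

Also provided: one-sided Fisher's exact overlap tests (for thresholded gene
lists such as laminar markers), consensus differential-expression lists
(genes reported by at least ``min_studies`` studies), and sign-restricted
subsets of a gene set by component weight.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "afc_enrichment",
    "fisher_enrichment",
    "subset_by_component_sign",
    "consensus_genes",
    "bh_fdr",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene lists intersected with a universe of retained genes.

    Gene ids are matched by exact string comparison after uppercasing; sets
    that are empty after intersection are kept but flagged in results.
    """

    sets: dict[str, tuple[str, ...]]
    universe: tuple[str, ...]

    @staticmethod
    def from_lists(sets: Mapping[str, Iterable[str]], universe: Iterable[str]) -> "GeneSetCollection":
        uni = tuple(dict.fromkeys(g.upper() for g in universe))
        uniset = set(uni)
        inter = {
            name: tuple(dict.fromkeys(g.upper() for g in genes if g.upper() in uniset))
            for name, genes in sets.items()
        }
        return GeneSetCollection(inter, uni)


@dataclass(frozen=True)
class EnrichmentResult:
    """AFC enrichment of one gene set on one component."""

    name: str
    n_genes: int
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float = float("nan")
    flagged: bool = False  # empty intersection or degenerate null


def _null_set_means(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``set_size`` weights drawn without replacement, ``n_perm``
    times — the permutation null of the AFC statistic."""
    g = weights.size
    out = np.empty(n_perm)
    chunk = max(1, int(4e6 // g))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        # without-replacement sampling via partial sort of uniform keys
        idx = rng.random((m, g)).argpartition(set_size - 1, axis=1)[:, :set_size]
        out[start : start + m] = weights[idx].mean(axis=1)
    return out


def afc_enrichment(
    weights: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 5000,
    seed: int = 0,
    two_sided: str = "deviation",
) -> list[EnrichmentResult]:
    """Aggregate-fold-change permutation enrichment of each gene set.

    ``weights`` holds one component's gene weights over the universe. The
    two-sided p value compares |observed - null mean| with the same deviation
    under each permutation (``two_sided="deviation"``; ``"double"`` doubles
    the smaller one-sided tail instead). Null distributions are shared across
    sets of equal size, so large batches cost one permutation pass per size.
    """
    if two_sided not in ("deviation", "double"):
        raise ValueError("two_sided must be 'deviation' or 'double'")
    w = weights.copy()
    w.index = [g.upper() for g in w.index]
    missing = [g for g in sets.universe if g not in w.index]
    if missing:
        raise ValueError(f"weights missing for universe genes, e.g. {missing[:3]}")
    wu = w.loc[list(sets.universe)].to_numpy(float)
    max_size = max((len(g) for g in sets.sets.values()), default=0)
    if max_size * 2 > wu.size:
        raise ValueError("universe must be at least twice the largest set")
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    pos = {g: i for i, g in enumerate(sets.universe)}
    results = []
    for name, genes in sets.sets.items():
        m = len(genes)
        if m == 0:
            results.append(
                EnrichmentResult(name, 0, float("nan"), float("nan"), float("nan"),
                                 float("nan"), 1.0, flagged=True)
            )
            continue
        obs = float(wu[[pos[g] for g in genes]].mean())
        if m not in nulls:
            nulls[m] = _null_set_means(wu, m, n_perm, rng)
        null = nulls[m]
        mu, sd = float(null.mean()), float(null.std())
        if sd == 0:
            results.append(EnrichmentResult(name, m, obs, mu, 0.0, 0.0, 1.0, flagged=True))
            continue
        z = (obs - mu) / sd
        if two_sided == "deviation":
            p = (1 + int(np.sum(np.abs(null - mu) >= abs(obs - mu)))) / (n_perm + 1)
        else:
            hi = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
            lo = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
            p = min(1.0, 2 * min(hi, lo))
        results.append(EnrichmentResult(name, m, obs, mu, sd, z, p))
    qs = bh_fdr(np.array([r.p for r in results]))
    return [
        EnrichmentResult(r.name, r.n_genes, r.observed, r.null_mean, r.null_sd,
                         r.z, r.p, q=float(q), flagged=r.flagged)
        for r, q in zip(results, qs)
    ]


def fisher_enrichment(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """One-sided Fisher's exact test for overlap enrichment of two gene sets.

    Returns (odds ratio, p). The p value is the hypergeometric upper tail of
    the observed overlap; the odds ratio uses Haldane's 0.5 correction when
    any cell of the 2x2 table is zero.
    """
    uni = list(dict.fromkeys(g.upper() for g in universe))
    if not uni:
        raise ValueError("empty universe")
    us = set(uni)
    a = {g.upper() for g in set_a} & us
    b = {g.upper() for g in set_b} & us
    if {g.upper() for g in set_a} - us or {g.upper() for g in set_b} - us:
        raise ValueError("both sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(us) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]])
    _, p = stats.fisher_exact(table, alternative="greater")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def subset_by_component_sign(
    genes: Sequence[str], weights: pd.DataFrame, component: str, sign: str = "positive"
) -> list[str]:
    """Members of a gene set with strictly positive (or negative) weight on a
    component; a weight of exactly 0 is excluded either way."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    w = weights[component]
    w.index = [g.upper() for g in w.index]
    out = []
    for g in genes:
        gu = g.upper()
        if gu not in w.index:
            continue
        v = float(w[gu])
        if (sign == "positive" and v > 0) or (sign == "negative" and v < 0):
            out.append(gu)
    return out


def consensus_genes(study_lists: Sequence[Iterable[str]], min_studies: int = 2) -> list[str]:
    """Genes reported by at least ``min_studies`` of the given study lists."""
    if not study_lists:
        raise ValueError("at least one study list required")
    counts: dict[str, int] = {}
    order: list[str] = []
    for lst in study_lists:
        for g in {x.upper() for x in lst}:
            if g not in counts:
                counts[g] = 0
                order.append(g)
            counts[g] += 1
    return [g for g in order if counts[g] >= min_studies]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, capped at 1."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
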