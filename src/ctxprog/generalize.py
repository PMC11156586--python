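"""Triplet-split generalizability of spatial components.

An even cohort of donors is split into all unordered pairs of disjoint
half-cohorts ("triplets" for six donors: 10 disjoint pairs). The full
pipeline — probe handling, normalization, DS and coverage filters,
decomposition — runs independently on each side; components are then greedily
matched across each pair by absolute Pearson correlation of their region
scores on the intersection of surviving regions, and ranked by the mean
variance explained of each matched pair. The generalizability of rank i is

    g_i = median over disjoint pairs of |r| of the rank-i matched components,

a cross-donor reproducibility index in [0, 1]. ``grid_search`` sweeps the DS
retention fraction and the minimum-donor region filter and reports g together
with the surviving matrix size for each grid cell.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import cross_pearson
from .decompose import ComponentSet, dme, pca
from .preprocess import preprocess_cohort
from .synthdata import DonorExpression

__all__ = [
    "TripletReport",
    "split_disjoint",
    "greedy_match",
    "match_components",
    "generalizability",
    "grid_search",
]


@dataclass(frozen=True)
class TripletReport:
    """Per-pair matched components and the per-rank generalizability g."""

    pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    matches: pd.DataFrame  # pair, rank, comp_a, comp_b, r, abs_r, mean_ve, n_shared_regions
    g: pd.Series  # rank -> median |r| over usable pairs
    n_usable_pairs: int = 0

    def __post_init__(self) -> None:
        if ((self.g < -1e-12) | (self.g > 1 + 1e-12)).any():
            raise ValueError("g must lie in [0, 1]")


def split_disjoint(donor_ids: list[str]) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All unordered pairs (S, complement) with |S| = n/2.

    Six donors give the 10 disjoint triplet pairs (half of the 20 possible
    triplets); four donors give 3 pairs. Odd donor counts are invalid.
    """
    n = len(donor_ids)
    if n < 4 or n % 2:
        raise ValueError("disjoint splitting needs an even donor count >= 4")
    ids = list(donor_ids)
    anchor = ids[0]
    pairs = []
    for combo in combinations(ids, n // 2):
        if anchor not in combo:  # keep one of each (S, complement) pair
            continue
        side_a = tuple(combo)
        side_b = tuple(d for d in ids if d not in combo)
        pairs.append((side_a, side_b))
    return pairs


def greedy_match(absr: np.ndarray) -> list[tuple[int, int]]:
    """Greedy pairing of a |correlation| matrix: repeatedly take the global
    maximum and delete its row and column. Equal maxima resolve to the
    lexicographically smallest (row, column) cell (row-major argmax)."""
    active = np.asarray(absr, float).copy()
    if active.ndim != 2 or active.shape[0] != active.shape[1]:
        raise ValueError("greedy matching needs a square matrix")
    out = []
    for _ in range(active.shape[0]):
        i, j = np.unravel_index(int(np.argmax(active)), active.shape)
        out.append((int(i), int(j)))
        active[i, :] = -np.inf
        active[:, j] = -np.inf
    return out


def match_components(
    set_a: ComponentSet,
    set_b: ComponentSet,
    top_k: int = 5,
    shared_regions: list[str] | None = None,
) -> pd.DataFrame:
    """Greedy one-to-one matching of components by |Pearson r| of region scores.

    The global maximum of the top_k x top_k |r| matrix is taken, its row and
    column removed, and the step repeated until all components are matched
    (ties resolve to the lexicographically smallest (row, column) cell).
    Matches are then ranked by the mean variance explained of each pair.
    """
    if set_a.k < top_k or set_b.k < top_k:
        raise ValueError(f"both component sets need >= {top_k} components")
    if shared_regions is None:
        shared_regions = list(set_a.scores.index.intersection(set_b.scores.index))
    if len(shared_regions) < 3:
        raise ValueError("fewer than 3 shared regions")
    a = set_a.scores.loc[shared_regions].to_numpy()[:, :top_k]
    b = set_b.scores.loc[shared_regions].to_numpy()[:, :top_k]
    r = cross_pearson(a, b)
    absr = np.abs(np.nan_to_num(r))
    rows = []
    for i, j in greedy_match(absr):
        rows.append(
            {
                "comp_a": set_a.scores.columns[i],
                "comp_b": set_b.scores.columns[j],
                "r": float(r[i, j]),
                "abs_r": float(absr[i, j]),
                "mean_ve": float((set_a.ve[i] + set_b.ve[j]) / 2),
                "n_shared_regions": len(shared_regions),
            }
        )
    df = pd.DataFrame(rows).sort_values("mean_ve", ascending=False, kind="stable")
    df["rank"] = np.arange(1, top_k + 1)
    return df.reset_index(drop=True)


def _decompose(matrix, method: str, k: int, alpha: float) -> ComponentSet:
    return dme(matrix, k, alpha=alpha) if method == "dme" else pca(matrix, k)


def generalizability(
    donors: list[DonorExpression],
    ds_fraction: float = 0.5,
    min_donors: int = 3,
    method: str = "dme",
    top_k: int = 5,
    alpha: float = 1.0,
    min_shared_regions: int = 10,
    intensity_min_fraction: float = 0.5,
) -> TripletReport:
    """Run the full pipeline independently per disjoint split side and
    aggregate matched-component correlations into per-rank g.

    Pairs whose sides fail preprocessing or share fewer than
    ``min_shared_regions`` regions are skipped with a warning; fewer than 50%
    usable pairs is an error. g uses the standard midpoint median over the
    (even) usable pair count.
    """
    ids = [d.donor_id for d in donors]
    by_id = {d.donor_id: d for d in donors}
    pairs = split_disjoint(ids)
    all_matches = []
    usable = 0
    for p_idx, (side_a, side_b) in enumerate(pairs):
        try:
            sets = []
            for side in (side_a, side_b):
                mat, _ = preprocess_cohort(
                    [by_id[i] for i in side],
                    ds_fraction=ds_fraction,
                    min_donors=min_donors,
                    intensity_min_fraction=intensity_min_fraction,
                )
                sets.append(_decompose(mat, method, top_k, alpha))
            shared = list(sets[0].scores.index.intersection(sets[1].scores.index))
            if len(shared) < min_shared_regions:
                warnings.warn(f"pair {p_idx}: only {len(shared)} shared regions; skipped")
                continue
            m = match_components(sets[0], sets[1], top_k=top_k, shared_regions=shared)
        except ValueError as exc:
            warnings.warn(f"pair {p_idx} skipped: {exc}")
            continue
        m.insert(0, "pair", p_idx)
        all_matches.append(m)
        usable += 1
    if usable < len(pairs) / 2:
        raise ValueError(f"only {usable}/{len(pairs)} usable disjoint pairs")
    matches = pd.concat(all_matches, ignore_index=True)
    g = matches.groupby("rank")["abs_r"].median()
    g.name = "g"
    return TripletReport(tuple(pairs), matches, g, n_usable_pairs=usable)


def grid_search(
    donors: list[DonorExpression],
    ds_fractions: list[float],
    min_donors_values: list[int],
    method: str = "dme",
    top_k: int = 5,
    alpha: float = 1.0,
    min_shared_regions: int = 10,
    default_cell: tuple[float, int] = (0.5, 3),
) -> pd.DataFrame:
    """Sweep the DS gene filter and the region coverage filter.

    One row per grid cell with per-rank g and the full-cohort matrix size; no
    automatic winner is chosen. ``pareto`` flags cells not dominated on
    (g_1..g_top_k, n_genes, n_regions); ``default`` flags ``default_cell``.
    """
    if not ds_fractions or not min_donors_values:
        raise ValueError("grids must be non-empty")
    rows = []
    for frac in ds_fractions:
        for min_d in min_donors_values:
            mat, _ = preprocess_cohort(donors, ds_fraction=frac, min_donors=min_d)
            rep = generalizability(
                donors,
                ds_fraction=frac,
                min_donors=min_d,
                method=method,
                top_k=top_k,
                alpha=alpha,
                min_shared_regions=min_shared_regions,
            )
            row = {"ds_fraction": frac, "min_donors": min_d}
            for rank, val in rep.g.items():
                row[f"g{rank}"] = val
            row["n_genes"] = mat.values.shape[1]
            row["n_regions"] = mat.values.shape[0]
            rows.append(row)
    df = pd.DataFrame(rows)
    obj_cols = [c for c in df.columns if c.startswith("g")] + ["n_genes", "n_regions"]
    obj = df[obj_cols].to_numpy(float)
    n = len(df)
    pareto = np.ones(n, bool)
    for i in range(n):
        for j in range(n):
            if i != j and np.all(obj[j] >= obj[i]) and np.any(obj[j] > obj[i]):
                pareto[i] = False
                break
    df["pareto"] = pareto
    df["default"] = [
        (f, m) == default_cell for f, m in zip(df["ds_fraction"], df["min_donors"])
    ]
    return df
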