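"""Projection of component gene weights onto external datasets.

Three projections, all driven by the gene x K weight matrix of a fitted
component set:

* single cells — per cell j and component i, the weighted expression of the
  positively weighted genes (s+_{j,Ci}) and of the negatively weighted genes
  (s-_{j,Ci}); their within-cell-type correlation measures whether the
  component is an intracellular program rather than a cell-composition
  artifact. The default convention follows the weighted-average reading
  (dividing by the summed |weights| of the used genes and weighting the
  negative set by |u-|), so intracellular coupling appears as a negative
  r(s+, s-); the raw signed dot products are available via
  ``convention="dot"``.

* external cohorts — gene expression is z-normalized over regions within
  each external donor, averaged across donors (for example, within an age
  window), and projected as y_j = b_j . u; the Pearson correlation of y with
  the reference component scores over matched regions measures consistency.

* developmental trajectories — per gene, a Gaussian GAM of expression on
  log10 post-conception days with a 12-function cubic B-spline basis
  (smoothing penalty weight alpha = 1) and additive sex and region
  covariates; fitted curves averaged within each decile of a component's
  gene weights show when the component's gene program is expressed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

from ._utils import colwise_pearson
from .synthdata import years_to_log10_pcd

__all__ = [
    "CellScores",
    "TrajectoryFit",
    "score_cells",
    "coupling_correlation",
    "external_consistency",
    "consistency_by_age_window",
    "fit_trajectory",
    "fit_trajectories",
    "decile_curves",
]


@dataclass(frozen=True)
class CellScores:
    """Per-cell positive/negative component scores (columns "C1+", "C1-", ...)."""

    scores: pd.DataFrame
    cell_types: pd.Series | None
    convention: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("cell scores must be finite")


@dataclass(frozen=True)
class TrajectoryFit:
    """Fitted developmental curve for one gene on a shared age grid."""

    gene: str
    age_grid_years: np.ndarray
    curve: np.ndarray
    n_obs: int


def score_cells(
    cells: pd.DataFrame,
    weights: pd.DataFrame,
    cell_types: pd.Series | None = None,
    convention: str = "weighted_average",
    min_shared_genes: int = 50,
) -> CellScores:
    """Project cells onto the positive and negative gene sets of each component.

    ``cells`` is cell x gene expression restricted (internally) to the genes
    shared with ``weights``. With the default weighted-average convention,
    s+ = (E_pos . u+) / sum(u+) and s- = (E_neg . |u-|) / sum(|u-|); with
    ``convention="dot"``, s+ = E . u+ and s- = E . u- (signed, unnormalized).
    """
    if convention not in ("weighted_average", "dot"):
        raise ValueError("convention must be 'weighted_average' or 'dot'")
    cg = {g.upper(): g for g in cells.columns}
    wg = [g for g in weights.index if g.upper() in cg]
    if len(wg) < min_shared_genes:
        raise ValueError(f"only {len(wg)} shared genes (< {min_shared_genes})")
    e = cells[[cg[g.upper()] for g in wg]].to_numpy(float)
    out = {}
    for comp in weights.columns:
        u = weights.loc[wg, comp].to_numpy(float)
        pos, neg = u > 0, u < 0
        if not pos.any() or not neg.any():
            raise ValueError(f"{comp}: empty positive or negative gene set")
        if convention == "weighted_average":
            out[f"{comp}+"] = e[:, pos] @ u[pos] / u[pos].sum()
            out[f"{comp}-"] = e[:, neg] @ np.abs(u[neg]) / np.abs(u[neg]).sum()
        else:
            out[f"{comp}+"] = e[:, pos] @ u[pos]
            out[f"{comp}-"] = e[:, neg] @ u[neg]
    scores = pd.DataFrame(out, index=cells.index)
    types = cell_types.reindex(cells.index) if cell_types is not None else None
    return CellScores(scores, types, convention)


def coupling_correlation(
    cell_scores: CellScores,
    group_by: str = "cell_type",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson r(s+, s-) per component within each cell-type group.

    ``group_by="all"`` pools every cell. Groups with fewer than 3 cells are
    skipped with a warning. Bootstrap percentile CIs use ``n_boot`` resamples.
    """
    s = cell_scores.scores
    comps = sorted({c[:-1] for c in s.columns})
    if group_by == "all" or cell_scores.cell_types is None:
        groups = {"all": np.arange(len(s))}
    elif group_by == "cell_type":
        groups = {
            str(t): np.flatnonzero((cell_scores.cell_types == t).to_numpy())
            for t in pd.unique(cell_scores.cell_types)
        }
    else:
        raise ValueError("group_by must be 'cell_type' or 'all'")
    rng = np.random.default_rng(seed)
    rows = []
    for gname, idx in groups.items():
        if len(idx) < 3:
            warnings.warn(f"group {gname!r} has {len(idx)} cells; skipped")
            continue
        for comp in comps:
            a = s[f"{comp}+"].to_numpy()[idx]
            b = s[f"{comp}-"].to_numpy()[idx]
            r = float(np.corrcoef(a, b)[0, 1])
            bs = rng.integers(0, len(idx), size=(n_boot, len(idx)))
            boot_r = colwise_pearson(a[bs].T, b[bs].T)
            lo, hi = np.nanquantile(boot_r, [0.025, 0.975])
            rows.append(
                {"group": gname, "component": comp, "n_cells": len(idx),
                 "r": r, "ci_low": float(lo), "ci_high": float(hi)}
            )
    return pd.DataFrame(rows)


def _znorm_over_regions(table: pd.DataFrame) -> pd.DataFrame:
    """z-normalize each gene (column) over regions within one donor table."""
    arr = table.to_numpy(float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mu) / sd
    z[:, sd == 0] = 0.0
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def external_consistency(
    external: Sequence[pd.DataFrame] | pd.DataFrame,
    weights: pd.DataFrame,
    reference_scores: pd.DataFrame,
    region_map: Mapping[str, str] | None = None,
    log1p: bool = False,
) -> pd.Series:
    """Per-component correlation of projected external scores with reference
    component scores.

    ``external``: one region x gene table per donor (or a single table). Each
    gene is z-normalized over regions within each donor, donors are averaged,
    scores y = Z . u are computed on the shared genes, and Pearson r(y,
    reference) is taken over the matched regions (``region_map`` maps external
    region ids onto the reference index; identity by default).
    """
    tables = [external] if isinstance(external, pd.DataFrame) else list(external)
    if not tables:
        raise ValueError("no external tables")
    zs = []
    for t in tables:
        if log1p:
            t = np.log1p(t)
        zs.append(_znorm_over_regions(t))
    stacked = pd.concat(zs)
    avg = stacked.groupby(level=0).mean()
    shared_genes = [g for g in weights.index if g in avg.columns]
    if len(shared_genes) < 3:
        raise ValueError("fewer than 3 shared genes")
    rmap = dict(region_map) if region_map is not None else {r: r for r in avg.index}
    matched = [r for r in avg.index if rmap.get(r) in set(reference_scores.index)]
    if len(matched) < 3:
        raise ValueError("fewer than 3 matched regions")
    y = avg.loc[matched, shared_genes].to_numpy() @ weights.loc[shared_genes].to_numpy(float)
    ref = reference_scores.loc[[rmap[r] for r in matched]].to_numpy(float)
    r = colwise_pearson(y, ref)
    return pd.Series(r, index=list(weights.columns), name="r")


def consistency_by_age_window(
    development: pd.DataFrame,
    weights: pd.DataFrame,
    reference_scores: pd.DataFrame,
    windows: Mapping[str, tuple[float, float]],
    region_map: Mapping[str, str] | None = None,
    log1p: bool = False,
) -> pd.DataFrame:
    """External consistency per age window of a long developmental table.

    ``development`` columns: donor, age_years, region, gene, value. Donors
    whose age falls in [lo, hi) form each window's donor group.
    """
    rows = {}
    for name, (lo, hi) in windows.items():
        sub = development[(development["age_years"] >= lo) & (development["age_years"] < hi)]
        tables = [
            d.pivot_table(index="region", columns="gene", values="value")
            for _, d in sub.groupby("donor")
        ]
        rows[name] = external_consistency(
            tables, weights, reference_scores, region_map=region_map, log1p=log1p
        )
    return pd.DataFrame(rows).T


def _trajectory_design(df: pd.DataFrame):
    """Shared design pieces: log10 post-conception days, covariate dummies."""
    x = np.asarray(years_to_log10_pcd(df["age_years"].to_numpy(float)), float)
    dummies = pd.get_dummies(df[["sex", "region"]].astype(str), drop_first=True, dtype=float)
    exog = np.column_stack([np.ones(len(df)), dummies.to_numpy()])
    return x, exog, dummies.columns


def fit_trajectory(
    expr: pd.DataFrame,
    n_splines: int = 12,
    degree: int = 3,
    alpha: float = 1.0,
    n_grid: int = 50,
) -> TrajectoryFit:
    """Penalized B-spline GAM of one gene's expression over developmental age.

    ``expr`` is a long table (age_years, sex, region, value) for one gene.
    The smoother is a ``n_splines``-function, degree-``degree`` B-spline basis
    on log10 post-conception days with penalty weight ``alpha``; sex and
    region enter as additive intercepts. The returned curve is evaluated on a
    fixed age grid spanning the observed range, averaged over the observed
    sex/region mix.
    """
    fits = fit_trajectories(
        expr.assign(gene="_g"), genes=["_g"], n_splines=n_splines, degree=degree,
        alpha=alpha, n_grid=n_grid,
    )
    fit = fits["_g"]
    return TrajectoryFit(
        expr["gene"].iloc[0] if "gene" in expr.columns else "_g",
        fit.age_grid_years, fit.curve, fit.n_obs,
    )


def fit_trajectories(
    development: pd.DataFrame,
    genes: Sequence[str] | None = None,
    n_splines: int = 12,
    degree: int = 3,
    alpha: float = 1.0,
    n_grid: int = 50,
) -> dict[str, TrajectoryFit]:
    """Fit the developmental GAM for each gene of a long table.

    The design (spline basis on log10 post-conception days, sex and region
    dummies) is shared across genes; observations must therefore be complete
    per gene. Requires >= 20 observations spanning >= 3 distinct ages.
    """
    req = {"age_years", "sex", "region", "gene", "value"}
    if not req <= set(development.columns):
        raise ValueError(f"development table needs columns {sorted(req)}")
    wide = development.pivot_table(
        index=["age_years", "sex", "region", "donor"] if "donor" in development.columns
        else ["age_years", "sex", "region"],
        columns="gene",
        values="value",
    )
    if genes is not None:
        wide = wide[list(genes)]
    if wide.isna().any().any():
        raise ValueError("incomplete observations: every gene needs a value per sample")
    meta = wide.index.to_frame(index=False)
    if len(meta) < 20:
        raise ValueError("need at least 20 observations")
    if meta["age_years"].nunique() < 3:
        raise ValueError("need at least 3 distinct ages")
    x, exog, _ = _trajectory_design(meta)
    bs = BSplines(x, df=[n_splines], degree=[degree])
    grid_log = np.linspace(x.min(), x.max(), n_grid)
    from .synthdata import CONCEPTION_OFFSET_DAYS, DAYS_PER_YEAR

    grid_years = (10.0**grid_log - CONCEPTION_OFFSET_DAYS) / DAYS_PER_YEAR
    exog_mean = np.tile(exog.mean(axis=0), (n_grid, 1))
    fits: dict[str, TrajectoryFit] = {}
    for gene in wide.columns:
        y = wide[gene].to_numpy(float)
        model = GLMGam(y, exog=exog, smoother=bs, alpha=alpha)
        res = model.fit()
        curve = np.asarray(res.predict(exog=exog_mean, exog_smooth=grid_log))
        fits[str(gene)] = TrajectoryFit(str(gene), grid_years, curve, len(y))
    return fits


def decile_curves(
    fits: Mapping[str, TrajectoryFit], weights: pd.Series
) -> pd.DataFrame:
    """Mean fitted curve within each decile of a component's gene weights.

    Genes are ordered by (weight, gene id) — the id breaks ties — and split
    into 10 near-equal bins; decile 1 holds the most negative weights and
    decile 10 the most positive. Returns an age-grid x decile table.
    """
    genes = [g for g in fits if g in weights.index]
    if len(genes) < 10:
        raise ValueError("need fits for at least 10 weighted genes")
    order = sorted(genes, key=lambda g: (float(weights[g]), g))
    bins = np.array_split(order, 10)
    grid = next(iter(fits.values())).age_grid_years
    out = {}
    for d, members in enumerate(bins, start=1):
        out[d] = np.mean([fits[g].curve for g in members], axis=0)
    return pd.DataFrame(out, index=pd.Index(grid, name="age_years"))
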