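"""Donor-level filtering, normalization and aggregation.

Turns per-donor expression (probe- or region-level) into the single filtered,
normalized, donor-averaged region x gene matrix that decomposition consumes:

1. probe intensity filter — keep probes above background in >= 50% of samples
   pooled across donors;
2. probe -> gene aggregation — per gene, the probe whose regional profile has
   the highest mean inter-donor correlation;
3. differential stability (DS) — per gene, the mean over donor pairs of the
   Pearson correlation of regional expression profiles; genes are ranked by DS
   and the top fraction retained;
4. region coverage filter — keep regions sampled by at least ``min_donors``
   donors;
5. scaled robust sigmoid (SRS) normalization per donor — first each sample
   across genes, then each gene across samples — followed by an unweighted
   mean over the donors covering each region.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import colwise_pearson
from .synthdata import DonorExpression

__all__ = [
    "RegionGeneMatrix",
    "DifferentialStability",
    "srs_normalize",
    "filter_probes_by_intensity",
    "aggregate_probes_to_genes",
    "differential_stability",
    "filter_genes_by_ds",
    "filter_regions_by_coverage",
    "assemble_group_matrix",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class RegionGeneMatrix:
    """Donor-aggregated, normalized region x gene matrix.

    ``values`` holds SRS-normalized expression (each donor's values lie in
    [0, 1] before averaging); ``provenance`` records the filter settings that
    produced it.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("assembled matrix must have no missing entries")

    @property
    def regions(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class DifferentialStability:
    """Per-gene differential stability: mean over donor pairs of the Pearson
    correlation of regional expression profiles (in [-1, 1]; NaN when no pair
    yields a defined correlation)."""

    ds: pd.Series

    def __post_init__(self) -> None:
        finite = self.ds.dropna()
        if ((finite < -1 - 1e-9) | (finite > 1 + 1e-9)).any():
            raise ValueError("DS values must lie in [-1, 1]")


def _srs_1d(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        return np.full_like(x, 0.5, dtype=float)
    s = expit((x - med) / (iqr / 1.35))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(x, 0.5, dtype=float)
    return (s - lo) / (hi - lo)


def srs_normalize(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median) / (IQR / 1.35)), min-max
    rescaled to [0, 1].

    Robust to outliers and rank-preserving. IQR uses linear-interpolation
    quantiles. A zero-IQR input maps to all 0.5 (documented degenerate case).
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("srs_normalize needs a 1-D vector of length >= 2")
    return _srs_1d(x)


def _srs_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sample-normalize (each row across genes), then gene-normalize (each
    column across samples), the order used before donor aggregation."""
    arr = df.to_numpy(float)
    arr = np.apply_along_axis(_srs_1d, 1, arr)
    arr = np.apply_along_axis(_srs_1d, 0, arr)
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def filter_probes_by_intensity(
    donors: list[DonorExpression], min_fraction: float = 0.5
) -> list[DonorExpression]:
    """Keep probes whose above-background fraction, pooled over all samples of
    all donors, is at least ``min_fraction``."""
    if not donors or any(d.background is None for d in donors):
        raise ValueError("intensity filter needs probe-level donors with background flags")
    flags = pd.concat([d.background for d in donors], axis=0)
    frac = flags.mean(axis=0)
    keep = frac.index[frac >= min_fraction]
    if len(keep) == 0:
        raise ValueError("no probes survive the intensity filter")
    out = []
    for d in donors:
        cols = [c for c in d.values.columns if c in set(keep)]
        out.append(
            DonorExpression(
                d.donor_id,
                d.values[cols],
                level="probe",
                probe_gene=d.probe_gene[cols],
                background=d.background[cols],
            )
        )
    return out


def _mean_pair_correlation(profiles: list[pd.Series]) -> float:
    """Mean Pearson r over donor pairs of one probe/gene's regional profiles;
    NaN if no pair yields a defined correlation."""
    rs = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i].align(profiles[j], join="inner")
            if len(a) < 3:
                continue
            av, bv = a.to_numpy(float), b.to_numpy(float)
            if av.std() == 0 or bv.std() == 0:
                continue
            rs.append(float(np.corrcoef(av, bv)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def aggregate_probes_to_genes(donors: list[DonorExpression]) -> list[DonorExpression]:
    """Collapse probes to genes by picking, per gene, the probe with the
    highest mean inter-donor correlation of regional profiles.

    Ties break to the lowest probe id; single-probe genes pass through.
    """
    if len(donors) < 2:
        raise ValueError("probe aggregation needs >= 2 donors")
    if any(d.level != "probe" for d in donors):
        raise ValueError("donors must be probe-level")
    probe_gene = donors[0].probe_gene
    genes = sorted(set(probe_gene))
    chosen: dict[str, str] = {}
    for gene in genes:
        probes = sorted(probe_gene.index[probe_gene == gene])
        if len(probes) == 1:
            p = probes[0]
            if all(d.values[p].std() == 0 for d in donors):
                warnings.warn(f"gene {gene}: sole probe has zero variance; kept")
            chosen[gene] = p
            continue
        scores = {p: _mean_pair_correlation([d.values[p] for d in donors]) for p in probes}
        # NaN scores sort last; ties resolve to the lowest probe id
        best = min(probes, key=lambda p: (-(scores[p] if not math.isnan(scores[p]) else -2.0), p))
        chosen[gene] = best
    out = []
    for d in donors:
        df = d.values[[chosen[g] for g in genes]].copy()
        df.columns = genes
        out.append(DonorExpression(d.donor_id, df, level="gene"))
    return out


def differential_stability(donors: list[DonorExpression]) -> DifferentialStability:
    """Per-gene mean over donor pairs of the Pearson correlation between the
    donors' regional expression profiles, computed on each pair's shared
    regions. Pairs where a gene is constant contribute no (undefined)
    correlation and are excluded from that gene's mean."""
    if len(donors) < 2:
        raise ValueError("differential stability needs >= 2 donors")
    genes = donors[0].values.columns
    acc = np.zeros(len(genes))
    cnt = np.zeros(len(genes))
    n_undefined = 0
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            shared = donors[i].regions.intersection(donors[j].regions)
            if len(shared) < 3:
                raise ValueError(
                    f"donors {donors[i].donor_id},{donors[j].donor_id} share < 3 regions"
                )
            a = donors[i].values.loc[shared, genes].to_numpy(float)
            b = donors[j].values.loc[shared, genes].to_numpy(float)
            r = colwise_pearson(a, b)
            ok = ~np.isnan(r)
            n_undefined += int((~ok).sum())
            acc[ok] += r[ok]
            cnt[ok] += 1
    if n_undefined:
        warnings.warn(f"{n_undefined} donor-pair correlations undefined (constant gene); excluded")
    with np.errstate(invalid="ignore"):
        ds = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return DifferentialStability(pd.Series(ds, index=genes, name="ds"))


def filter_genes_by_ds(ds: DifferentialStability, retain_fraction: float) -> list[str]:
    """Retain the ceil(fraction * G) genes with the highest DS.

    Ties at the cut break by gene id ascending; genes with undefined DS rank
    last.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    s = ds.ds
    n_keep = math.ceil(retain_fraction * len(s))
    order = sorted(s.index, key=lambda g: (-(s[g] if not math.isnan(s[g]) else -math.inf), g))
    return order[:n_keep]


def filter_regions_by_coverage(donors: list[DonorExpression], min_donors: int) -> list[str]:
    """Regions sampled (non-missing) by at least ``min_donors`` donors, in
    first-appearance order across donors."""
    if not 1 <= min_donors <= len(donors):
        raise ValueError("min_donors must be between 1 and the donor count")
    order: list[str] = []
    counts: dict[str, int] = {}
    for d in donors:
        for r in d.regions:
            if r not in counts:
                counts[r] = 0
                order.append(r)
            counts[r] += 1
    keep = [r for r in order if counts[r] >= min_donors]
    if not keep:
        raise ValueError("no region sampled by enough donors")
    return keep


def assemble_group_matrix(
    donors: list[DonorExpression],
    genes: list[str] | None = None,
    regions: list[str] | None = None,
    provenance: dict | None = None,
) -> RegionGeneMatrix:
    """SRS-normalize each donor (samples across genes, then genes across
    samples) and average across donors, ignoring each donor's missing regions.
    """
    if any(d.level != "gene" for d in donors):
        raise ValueError("assemble expects gene-level donors")
    genes = list(genes) if genes is not None else list(donors[0].values.columns)
    regions = (
        list(regions) if regions is not None else filter_regions_by_coverage(donors, 1)
    )
    total = pd.DataFrame(0.0, index=regions, columns=genes)
    count = pd.Series(0, index=regions, dtype=int)
    for d in donors:
        avail = [r for r in regions if r in set(d.regions)]
        if not avail:
            continue
        norm = _srs_frame(d.values.loc[avail, genes])
        total.loc[avail] += norm
        count.loc[avail] += 1
    if (count == 0).any():
        empty = list(count.index[count == 0])
        raise ValueError(f"regions covered by zero donors: {empty[:5]}")
    values = total.div(count, axis=0)
    return RegionGeneMatrix(values, provenance=dict(provenance or {}))


def preprocess_cohort(
    donors: list[DonorExpression],
    ds_fraction: float = 0.5,
    min_donors: int = 3,
    intensity_min_fraction: float = 0.5,
) -> tuple[RegionGeneMatrix, DifferentialStability]:
    """Full preprocessing chain: (intensity filter + probe aggregation when
    probe-level) -> DS gene filter -> region coverage filter -> SRS
    normalization and donor averaging."""
    if donors and donors[0].level == "probe":
        donors = aggregate_probes_to_genes(
            filter_probes_by_intensity(donors, intensity_min_fraction)
        )
    ds = differential_stability(donors)
    genes = filter_genes_by_ds(ds, ds_fraction)
    min_d = min(min_donors, len(donors))
    regions = filter_regions_by_coverage(donors, min_d)
    prov = {
        "ds_fraction": ds_fraction,
        "min_donors": min_d,
        "n_donors": len(donors),
        "n_genes": len(genes),
        "n_regions": len(regions),
    }
    return assemble_group_matrix(donors, genes, regions, provenance=prov), ds
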