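"""Synthetic cohorts with known latent spatial structure.

Generates the four kinds of data the pipeline consumes — a spherical parcel
atlas, multi-donor region x gene expression, single-cell matrices and
age-resolved developmental expression — from a shared ground truth
(:class:`SyntheticTruth`) of smooth latent spatial components with per-component
signal-to-noise ratios. Every downstream stage (filtering, decomposition,
triplet generalizability, enrichment, spin tests, projection) can therefore be
tested against a known answer without downloading any real atlas.

The model: each latent component k is a Gaussian-process map on the unit
sphere with covariance exp(-d/l) (d the great-circle distance, l the
smoothness length in radians), orthogonalized and z-scored across parcels.
A donor's expression matrix is

    sum_k snr_k * noise_sd * latent_k  loading_k^T  +  donor offset  +  noise,

so ``snr_k`` is the ratio of component-k signal sd to the iid noise sd.
Donor offsets (one draw per donor per gene) emulate between-donor batch
structure; per-donor parcel dropout emulates incomplete sampling; optional
probe expansion emulates microarray probe redundancy and background flags.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import great_circle_distance

__all__ = [
    "ParcelAtlas",
    "SyntheticTruth",
    "DonorExpression",
    "CohortConfig",
    "generate_atlas",
    "generate_cohort",
    "generate_single_cells",
    "generate_development",
    "default_age_amplitudes",
    "years_to_log10_pcd",
    "DAYS_PER_YEAR",
    "CONCEPTION_OFFSET_DAYS",
]

# Age conversion: post-conception days = 365.25 * years + 280. The 280-day
# gestational offset is a documented constant of this package.
DAYS_PER_YEAR = 365.25
CONCEPTION_OFFSET_DAYS = 280.0


def years_to_log10_pcd(age_years: float | np.ndarray) -> float | np.ndarray:
    """Convert age in years to log10 post-conception days.

    Raises ValueError if any age maps to <= 0 post-conception days.
    """
    days = DAYS_PER_YEAR * np.asarray(age_years, float) + CONCEPTION_OFFSET_DAYS
    if np.any(days <= 0):
        raise ValueError("age before conception: post-conception days <= 0")
    return np.log10(days)


@dataclass(frozen=True)
class ParcelAtlas:
    """Cortical parcels with unit-sphere centroids.

    The spatial frame for all maps: component scores, spin nulls and Moran's I
    are computed on these centroids. ``class_label`` optionally carries a
    cytoarchitectural class per parcel.
    """

    parcel_ids: tuple[str, ...]
    centroids: np.ndarray  # (n, 3), unit norm
    hemisphere: str = "L"
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, float)
        object.__setattr__(self, "centroids", c)
        if len(self.parcel_ids) < 10:
            raise ValueError("atlas needs at least 10 parcels")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel ids must be unique")
        if c.shape != (len(self.parcel_ids), 3):
            raise ValueError("centroids must be (n_parcels, 3)")
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere")
        if self.class_labels is not None and len(self.class_labels) != len(self.parcel_ids):
            raise ValueError("class_labels length mismatch")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "parcel_id": list(self.parcel_ids),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "hemisphere": self.hemisphere,
            }
        )
        if self.class_labels is not None:
            df["class"] = list(self.class_labels)
        return df


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated cohort.

    ``latent_scores`` columns are mutually orthogonal after centering and
    z-scored per component; ``component_snr`` is signal sd / noise sd.
    """

    parcel_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    latent_scores: np.ndarray  # (n_parcels, K)
    loadings: np.ndarray  # (n_genes, K)
    component_snr: np.ndarray  # (K,)
    noise_sd: float
    donor_missing_frac: float
    length_scale: float
    age_amplitude: tuple[Callable[[float], float], ...] | None = None

    def __post_init__(self) -> None:
        ls = np.asarray(self.latent_scores, float)
        snr = np.asarray(self.component_snr, float)
        object.__setattr__(self, "latent_scores", ls)
        object.__setattr__(self, "loadings", np.asarray(self.loadings, float))
        object.__setattr__(self, "component_snr", snr)
        if self.k < 1:
            raise ValueError("at least one latent component required")
        if np.any(snr <= 0):
            raise ValueError("snr must be positive")
        # orthogonality of centered, z-scored columns == zero correlation
        c = ls - ls.mean(axis=0)
        g = c.T @ c
        off = g - np.diag(np.diag(g))
        n = ls.shape[0]
        if np.max(np.abs(off)) / n > 1e-6:
            raise ValueError("latent score columns must be orthogonal after centering")

    @property
    def k(self) -> int:
        return self.latent_scores.shape[1]


@dataclass(frozen=True)
class DonorExpression:
    """One donor's expression.

    ``level == "gene"``: ``values`` is a region x gene matrix indexed by the
    donor's sampled (non-missing) regions. ``level == "probe"``: ``values`` is
    region x probe with a ``probe_gene`` map and an optional ``background``
    flag matrix (True = signal above background noise).
    """

    donor_id: str
    values: pd.DataFrame
    level: str = "gene"  # "gene" | "probe"
    probe_gene: pd.Series | None = None
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in ("gene", "probe"):
            raise ValueError("level must be 'gene' or 'probe'")
        if self.values.shape[0] == 0:
            raise ValueError(f"donor {self.donor_id}: all regions missing")
        if self.level == "probe" and self.probe_gene is None:
            raise ValueError("probe-level donor needs a probe->gene map")
        if self.level == "gene" and self.values.columns.duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def regions(self) -> pd.Index:
        return self.values.index

    def missing_mask(self, atlas: ParcelAtlas) -> pd.Series:
        """True for atlas parcels this donor did not sample."""
        return pd.Series(
            [p not in set(self.regions) for p in atlas.parcel_ids],
            index=list(atlas.parcel_ids),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic multi-donor cohort.

    Defaults emulate a six-donor microarray atlas cohort: three latent
    components with signal-to-noise 8/4/2 (relative to the base noise sd of
    the spatially stable genes), smoothness length 0.5 rad, a quarter of
    parcels missing per donor, donor offsets at 0.2x the total signal sd, and
    heavy per-gene noise — 90% of genes carry 100x the base noise sd, so only
    a minority of genes have a spatially reliable profile, mirroring the low
    median differential stability of real expression atlases.
    """

    k: int = 3
    snr: tuple[float, ...] = (8.0, 4.0, 2.0)
    noise_sd: float = 1.0
    length_scale: float = 0.5
    missing_frac: float = 0.25
    donor_offset_sd: float | None = None  # None -> 0.2 * total signal sd
    frac_noisy_genes: float = 0.9  # fraction of genes with inflated noise
    noisy_gene_mult: float = 100.0  # noise-sd multiplier for those genes
    expand_probes: bool = False
    max_probes_per_gene: int = 3
    probe_noise_sd: float = 0.5
    dark_probe_frac: float = 0.1  # probes that fail to hybridize
    dark_above_background_p: float = 0.3

    def __post_init__(self) -> None:
        if len(self.snr) != self.k:
            raise ValueError("snr must have one entry per component")


def generate_atlas(
    n_parcels: int,
    seed: int,
    n_classes: int | None = None,
    hemisphere: str = "L",
) -> ParcelAtlas:
    """Quasi-uniform spherical atlas via a randomly rotated Fibonacci lattice.

    Deterministic for a fixed seed; ``n_classes`` optionally assigns
    spatially contiguous class labels by polar bands.
    """
    if n_parcels < 10:
        raise ValueError("n_parcels must be >= 10")
    rng = np.random.default_rng(seed)
    i = np.arange(n_parcels)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n_parcels
    theta = 2 * math.pi * i / golden
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # random rotation keeps the lattice quasi-uniform while varying with seed
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = pts @ q.T
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    labels = None
    if n_classes is not None:
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        band = np.minimum((np.argsort(np.argsort(pts[:, 2])) * n_classes) // n_parcels, n_classes - 1)
        labels = tuple(f"class{b + 1}" for b in band)
    ids = tuple(f"P{j:03d}" for j in range(n_parcels))
    return ParcelAtlas(ids, pts, hemisphere=hemisphere, class_labels=labels)


def _gp_maps(atlas: ParcelAtlas, k: int, length_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw k smooth maps from a GP with covariance exp(-d / length_scale)."""
    d = great_circle_distance(atlas.centroids)
    cov = np.exp(-d / length_scale)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((atlas.n_parcels, k))


def _orthogonalize_zscore(maps: np.ndarray) -> np.ndarray:
    """Center, Gram-Schmidt orthogonalize in order, z-score each column."""
    c = maps - maps.mean(axis=0)
    q, r = np.linalg.qr(c)
    q = q * np.sign(np.diag(r))  # keep each column aligned with its source map
    q = q - q.mean(axis=0)  # numerically re-center (already ~0)
    return q / q.std(axis=0)


def generate_cohort(
    atlas: ParcelAtlas,
    n_donors: int,
    n_genes: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[DonorExpression], SyntheticTruth]:
    """Generate a multi-donor cohort sharing smooth latent spatial components.

    Returns the per-donor expression (gene- or probe-level) and the
    :class:`SyntheticTruth` used to generate it.
    """
    cfg = config or CohortConfig()
    if n_donors < 2:
        raise ValueError("need at least two donors")
    if cfg.k > min(atlas.n_parcels, n_genes) / 4:
        raise ValueError("infeasible component count for this atlas/gene count")
    rng = np.random.default_rng(seed)

    latent = _orthogonalize_zscore(_gp_maps(atlas, cfg.k, cfg.length_scale, rng))
    loadings = rng.standard_normal((n_genes, cfg.k))
    loadings /= np.sqrt((loadings**2).mean(axis=0))  # rms 1 per component

    gene_ids = tuple(f"G{j:04d}" for j in range(n_genes))
    snr = np.asarray(cfg.snr, float)
    # component amplitude = snr * noise sd; a noiseless cohort keeps unit-scale
    # signal so the zero-noise limit stays informative
    amp = snr * (cfg.noise_sd if cfg.noise_sd > 0 else 1.0)
    signal = latent @ np.diag(amp) @ loadings.T  # regions x genes
    signal_sd = float(np.sqrt(np.sum(amp**2)))
    if cfg.donor_offset_sd is not None:
        offset_sd = cfg.donor_offset_sd
    else:
        # donor offsets are between-donor noise: they vanish in the zero-noise limit
        offset_sd = 0.2 * signal_sd if cfg.noise_sd > 0 else 0.0

    gene_noise_sd = np.full(n_genes, cfg.noise_sd)
    if cfg.frac_noisy_genes > 0:
        n_noisy = int(round(cfg.frac_noisy_genes * n_genes))
        noisy_idx = rng.choice(n_genes, size=n_noisy, replace=False)
        gene_noise_sd[noisy_idx] *= cfg.noisy_gene_mult

    region_index = pd.Index(list(atlas.parcel_ids), name="region")
    donors: list[DonorExpression] = []
    for d in range(n_donors):
        donor_id = f"D{d + 1}"
        offsets = rng.standard_normal(n_genes) * offset_sd
        noise = rng.standard_normal((atlas.n_parcels, n_genes)) * gene_noise_sd
        vals = signal + offsets + noise
        missing = rng.random(atlas.n_parcels) < cfg.missing_frac
        if missing.all():  # guarantee no all-missing donor
            missing[rng.integers(atlas.n_parcels)] = False
        df = pd.DataFrame(vals, index=region_index, columns=list(gene_ids))[~missing]
        if cfg.expand_probes:
            donors.append(_expand_probes(donor_id, df, cfg, rng))
        else:
            donors.append(DonorExpression(donor_id, df))

    truth = SyntheticTruth(
        parcel_ids=tuple(atlas.parcel_ids),
        gene_ids=gene_ids,
        latent_scores=latent,
        loadings=loadings,
        component_snr=snr,
        noise_sd=cfg.noise_sd,
        donor_missing_frac=cfg.missing_frac,
        length_scale=cfg.length_scale,
        age_amplitude=default_age_amplitudes(cfg.k),
    )
    return donors, truth


def _expand_probes(
    donor_id: str, gene_df: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator
) -> DonorExpression:
    """Expand a gene-level matrix to probe level with background flags.

    Probe counts per gene are drawn once per cohort seed stream; "dark"
    probes carry no gene signal and mostly sit below background.
    """
    n_regions = gene_df.shape[0]
    cols, probe_ids, gene_of_probe, dark = [], [], [], []
    for g in gene_df.columns:
        n_probes = int(rng.integers(1, cfg.max_probes_per_gene + 1))
        for p in range(n_probes):
            is_dark = rng.random() < cfg.dark_probe_frac
            base = (
                rng.standard_normal(n_regions) * cfg.noise_sd
                if is_dark
                else gene_df[g].to_numpy() + rng.standard_normal(n_regions) * cfg.probe_noise_sd
            )
            cols.append(base)
            probe_ids.append(f"{g}_p{p + 1}")
            gene_of_probe.append(g)
            dark.append(is_dark)
    values = pd.DataFrame(np.column_stack(cols), index=gene_df.index, columns=probe_ids)
    dark = np.asarray(dark)
    above = np.ones(values.shape, bool)
    above[:, dark] = rng.random((n_regions, int(dark.sum()))) < cfg.dark_above_background_p
    background = pd.DataFrame(above, index=values.index, columns=values.columns)
    return DonorExpression(
        donor_id,
        values,
        level="probe",
        probe_gene=pd.Series(gene_of_probe, index=probe_ids),
        background=background,
    )


def generate_single_cells(
    truth: SyntheticTruth,
    n_cells: int,
    cell_types: Mapping[str, float],
    seed: int = 0,
    coupling_sd: float = 1.0,
    baseline_sd: float = 2.0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Single-cell matrix in which component gene programs covary within cells.

    Cell expression = type baseline + sum_k t_jk * loading_k + noise, with the
    per-cell latent activation t_jk ~ N(0, coupling_sd^2). Genes with positive
    and negative loadings on the same component therefore anti-covary within
    every cell type. Returns (cells x genes, cell -> type labels).
    """
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    props = np.asarray(list(cell_types.values()), float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("cell type proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = list(cell_types)
    type_idx = rng.choice(len(labels), size=n_cells, p=props)
    n_genes = len(truth.gene_ids)
    baselines = rng.standard_normal((len(labels), n_genes)) * baseline_sd
    t = rng.standard_normal((n_cells, truth.k)) * coupling_sd
    expr = baselines[type_idx] + t @ truth.loadings.T + rng.standard_normal((n_cells, n_genes)) * noise_sd
    cell_ids = [f"cell{j:05d}" for j in range(n_cells)]
    cells = pd.DataFrame(expr, index=cell_ids, columns=list(truth.gene_ids))
    types = pd.Series([labels[i] for i in type_idx], index=cell_ids, name="cell_type")
    return cells, types


def default_age_amplitudes(k: int) -> tuple[Callable[[float], float], ...]:
    """Default developmental amplitude curves, one per component.

    Components 1-2 are expressed in near-adult form from the earliest ages
    (constant amplitude); component 3 rises logistically through adolescence
    (midpoint 14 y); any further components are constant.
    """

    def constant(age: float) -> float:
        return 1.0

    def adolescent_rise(age: float) -> float:
        return 1.0 / (1.0 + math.exp(-(age - 14.0) / 1.5))

    amps: list[Callable[[float], float]] = [constant] * k
    if k >= 3:
        amps[2] = adolescent_rise
    return tuple(amps)


def generate_development(
    truth: SyntheticTruth,
    ages: Sequence[float],
    regions: Sequence[str] | None = None,
    seed: int = 0,
    noise_sd: float = 0.3,
    signal_scale: float = 2.0,
    latent_mean_offset: float = 1.0,
) -> pd.DataFrame:
    """Age-annotated regional expression with component-specific amplitudes.

    One synthetic donor per entry of ``ages`` (years; mid-gestation = -0.5).
    expression(region, gene, age) =
    sum_k signal_scale * amplitude_k(age) * (latent_k(region) + latent_mean_offset)
    * loading_k(gene) + noise.

    The positive ``latent_mean_offset`` makes a rising amplitude raise the
    cortex-wide mean expression of a component's positively loaded genes —
    a transcriptional program switching on — with the spatial gradient
    superimposed. Per-gene z-normalization over regions (as used by the
    consistency analysis) is invariant to it.
    Returns a long table (donor, age_years, sex, region, gene, value).
    """
    if truth.age_amplitude is None or len(truth.age_amplitude) < truth.k:
        raise ValueError("truth.age_amplitude must be defined for every component")
    ages = list(ages)
    if any(a < -0.75 or a > 40 for a in ages):
        raise ValueError("ages must lie within [-0.75, 40] years")
    years_to_log10_pcd(np.asarray(ages))  # raises for pre-conception ages
    region_list = list(regions) if regions is not None else list(truth.parcel_ids)
    unknown = set(region_list) - set(truth.parcel_ids)
    if unknown:
        raise ValueError(f"regions not in truth: {sorted(unknown)}")
    ridx = [list(truth.parcel_ids).index(r) for r in region_list]
    rng = np.random.default_rng(seed)
    frames = []
    for j, age in enumerate(ages):
        amp = np.array([f(age) for f in truth.age_amplitude[: truth.k]])
        spatial = truth.latent_scores[ridx] + latent_mean_offset
        signal = spatial @ np.diag(signal_scale * amp) @ truth.loadings.T
        vals = signal + rng.standard_normal(signal.shape) * noise_sd
        sex = "F" if rng.random() < 0.5 else "M"
        df = pd.DataFrame(vals, index=region_list, columns=list(truth.gene_ids))
        long = df.stack().rename("value").reset_index()
        long.columns = ["region", "gene", "value"]
        long.insert(0, "donor", f"B{j + 1:02d}")
        long.insert(1, "age_years", age)
        long.insert(2, "sex", sex)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
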