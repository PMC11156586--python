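"""Spatial component extraction: PCA and diffusion map embedding (DME).

Both methods reduce a region x gene matrix to K per-region component scores
C_i. PCA takes the top left singular directions of the column-centered matrix.
DME builds a normalized-angle affinity between regional expression profiles,

    a_ij = 1 - arccos(cosine_similarity(row_i, row_j)) / pi,

applies anisotropic normalization with alpha = 1 (dividing by row-sum degrees
on both sides), row-normalizes to a Markov operator and takes its leading
nontrivial eigenvectors scaled by lambda / (1 - lambda) (the diffusion-time-0
convention). The constant stationary eigenvector is dropped.

Gene weights u_{g,i} are the Pearson correlations of each gene's regional
expression profile with the component scores. Because DME eigenvalues do not
measure expression variance, variance explained is computed for any score set
by sequentially regressing every gene on components 1..i and differencing the
total residual variance: VE_i = (V_{i-1} - V_i) / V_0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import colwise_pearson, cross_pearson
from .preprocess import RegionGeneMatrix

__all__ = [
    "ComponentSet",
    "pca",
    "dme",
    "gene_weights",
    "variance_explained",
    "align_sign",
    "strongly_weighted",
]


@dataclass(frozen=True)
class ComponentSet:
    """Extracted spatial components.

    ``scores``: region x K, z-scored per component; ``weights``: gene x K
    Pearson correlations in [-1, 1]; ``ve``: per-component share of the total
    expression variance; ``method``: extraction metadata (method, kernel,
    alpha, raw variance differences, ...).
    """

    scores: pd.DataFrame
    weights: pd.DataFrame
    ve: np.ndarray
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ve", np.asarray(self.ve, float))
        sd = self.scores.to_numpy().std(axis=0)
        if not np.allclose(sd, 1.0, atol=1e-6):
            raise ValueError("score columns must have unit sd")
        w = self.weights.to_numpy()
        if np.nanmax(np.abs(w)) > 1 + 1e-9:
            raise ValueError("gene weights must lie in [-1, 1]")
        if np.any(self.ve < -1e-9) or self.ve.sum() > 1 + 1e-9:
            raise ValueError("variance explained must be >= 0 and sum to <= 1")

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def component_names(self) -> list[str]:
        return list(self.scores.columns)


def _component_frame(arr: np.ndarray, index: pd.Index) -> pd.DataFrame:
    cols = [f"C{i + 1}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=index, columns=cols)


def pca(matrix: RegionGeneMatrix, k: int) -> ComponentSet:
    """Top-k principal component scores over regions with eigenvalue-share VE."""
    x = matrix.values.to_numpy(float)
    r, g = x.shape
    if not 1 <= k <= min(r - 1, g):
        raise ValueError(f"k={k} out of range for a {r}x{g} matrix")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :k] * np.sqrt(r)  # unit-norm columns -> unit sd
    ve = (s**2 / (s**2).sum())[:k]
    sdf = _component_frame(scores, matrix.regions)
    w = gene_weights(matrix, sdf)
    cs = ComponentSet(sdf, w, ve, method={"method": "pca", "k": k})
    return align_sign(cs)


def dme(
    matrix: RegionGeneMatrix,
    k: int,
    alpha: float = 1.0,
    diffusion_time: int = 0,
) -> ComponentSet:
    """Diffusion map embedding of regions with the normalized-angle kernel.

    Rows are used as given (post-SRS, in [0, 1]) without re-centering, no
    affinity sparsification, anisotropic normalization exponent ``alpha``
    (default 1). ``diffusion_time`` 0 scales eigenvectors by
    lambda / (1 - lambda); t >= 1 scales by lambda^t.
    """
    x = matrix.values.to_numpy(float)
    r = x.shape[0]
    if not 1 <= k <= r - 2:
        raise ValueError(f"k={k} out of range for {r} regions")
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm region profile")
    cos = np.clip((x / norms[:, None]) @ (x / norms[:, None]).T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    if np.allclose(aff, aff[0, 0]):
        raise ValueError("degenerate input: all region profiles identical")
    # anisotropic normalization (alpha) then symmetric conjugate of the Markov operator
    d = aff.sum(axis=1)
    w = aff / np.outer(d**alpha, d**alpha)
    d1 = w.sum(axis=1)
    sym = w / np.outer(np.sqrt(d1), np.sqrt(d1))
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d1)[:, None]
    psi = psi / psi[0, 0]  # normalize so the trivial eigenvector equals 1
    lam = evals[1 : k + 1]
    if np.any(np.abs(1 - lam) < 1e-12):
        raise ValueError("degenerate spectrum: eigenvalue 1 with multiplicity > 1")
    scale = lam / (1 - lam) if diffusion_time == 0 else lam**diffusion_time
    emb = psi[:, 1 : k + 1] * scale
    sd = emb.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate embedding: constant component")
    scores = (emb - emb.mean(axis=0)) / sd
    sdf = _component_frame(scores, matrix.regions)
    wdf = gene_weights(matrix, sdf)
    ve, raw = variance_explained(matrix, sdf, return_raw=True)
    cs = ComponentSet(
        sdf,
        wdf,
        ve,
        method={
            "method": "dme",
            "kernel": "normalized-angle",
            "alpha": alpha,
            "diffusion_time": diffusion_time,
            "k": k,
            "eigenvalues": lam.tolist(),
            "raw_variance_differences": raw.tolist(),
        },
    )
    return align_sign(cs)


def gene_weights(matrix: RegionGeneMatrix, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each gene's regional profile with each component.

    Zero-variance genes get weight 0 (with a warning).
    """
    if not matrix.regions.equals(scores.index):
        raise ValueError("matrix and scores must share the region index")
    w = cross_pearson(matrix.values.to_numpy(float), scores.to_numpy(float))
    nan_rows = np.isnan(w).any(axis=1)
    if nan_rows.any():
        warnings.warn(f"{int(nan_rows.sum())} zero-variance genes assigned weight 0")
        w[nan_rows] = 0.0
    return pd.DataFrame(w, index=matrix.genes, columns=scores.columns)


def variance_explained(
    matrix: RegionGeneMatrix, scores: pd.DataFrame, return_raw: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Share of total expression variance explained by each component in order.

    Every gene is sequentially regressed (with intercept) on components 1..i;
    V_i is the summed residual variance and VE_i = (V_{i-1} - V_i) / V_0.
    ``return_raw`` additionally returns the unnormalized differences
    V_{i-1} - V_i.
    """
    x = matrix.values.to_numpy(float)
    s = scores.to_numpy(float)
    r = x.shape[0]
    design = np.column_stack([np.ones(r), s])
    q, rr = np.linalg.qr(design)
    if np.min(np.abs(np.diag(rr))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(rr)))):
        raise ValueError("collinear score columns")
    xc = x - x.mean(axis=0)
    v0 = float((xc**2).sum() / r)
    if v0 == 0:
        raise ValueError("matrix has zero total variance")
    proj = q.T @ x  # (k+1, genes); row 0 is the intercept direction
    raw = (proj[1:] ** 2).sum(axis=1) / r  # V_{i-1} - V_i per component
    ve = raw / v0
    return (ve, raw) if return_raw else ve


def align_sign(
    components: ComponentSet, reference: pd.DataFrame | None = None
) -> ComponentSet:
    """Resolve eigenvector sign ambiguity.

    With a reference score set, each component is flipped so its correlation
    with the matching reference column is >= 0; otherwise so the skewness of
    its gene weights is >= 0. Idempotent.
    """
    if reference is not None:
        ref = reference.to_numpy(float)
        r = colwise_pearson(components.scores.to_numpy(), ref)
        flip = np.where(np.nan_to_num(r) < 0, -1.0, 1.0)
    else:
        skew = stats.skew(components.weights.to_numpy(), axis=0)
        flip = np.where(skew < 0, -1.0, 1.0)
    return ComponentSet(
        components.scores * flip,
        components.weights * flip,
        components.ve,
        dict(components.method),
    )


def strongly_weighted(weights: pd.DataFrame, threshold: float = 0.5) -> dict[str, list[str]]:
    """Genes with |weight| >= threshold, per component."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return {
        c: list(weights.index[np.abs(weights[c].to_numpy()) >= threshold])
        for c in weights.columns
    }
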