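# ctxprog

Spatial components of cortical gene expression: a tested pipeline for
extracting generalizable transcriptional programs from multi-donor regional
expression atlases, and for relating them to gene sets, other brain maps,
single-cell data and developmental trajectories.

## The problem

Bulk expression atlases of the human cortex (a few donors, hundreds of
sampled regions, ~20,000 genes) suggest that cortical organization reflects a
small number of *transcriptional programs*: spatial patterns C_i shared by
hundreds of genes. The first such component — a sensorimotor-to-association
gradient — is well established, but higher-order components are fragile: they
are easily dominated by donor-specific noise, and naive permutation tests
wildly overstate the significance of their alignment with other brain maps
because smooth spatial maps are not exchangeable.

`ctxprog` implements the analysis chain that makes higher-order components
measurable and testable:

1. **Filtering and normalization** — microarray probes are kept when they
   beat background in ≥ 50% of samples and collapsed to one probe per gene by
   inter-donor consistency; genes are ranked by *differential stability*
   (DS: mean inter-donor Pearson correlation of regional profiles) and the
   top fraction retained; regions are kept when sampled by ≥ `min_donors`
   donors; each donor is normalized with the scaled robust sigmoid
   (σ((x − median)/(IQR/1.35)), min–max rescaled) per sample then per gene,
   and donors are averaged.
2. **Decomposition** — PCA, or diffusion map embedding (DME) with the
   normalized-angle kernel `a_ij = 1 − arccos(cos_sim(x_i, x_j))/π`,
   anisotropic normalization α = 1, and λ/(1−λ) diffusion-time-0 scaling.
   Gene weights `u_{g,i}` are Pearson correlations of each gene's regional
   profile with the component scores; variance explained is computed by
   sequential regression, `VE_i = (V_{i−1} − V_i)/V_0`.
3. **Generalizability** — the cohort is split into all disjoint half-cohort
   ("triplet") pairs; the whole pipeline runs per side; components are
   greedily matched by |r| on shared regions and ranked by mean variance
   explained; `g_i` is the median |r| at rank i over the 10 disjoint pairs.
4. **Statistics** — aggregate-fold-change (AFC) permutation enrichment (mean
   set weight vs. 5,000 weight permutations), Fisher's exact overlap tests,
   BH-FDR, Moran's I, and spin permutation nulls (random sphere rotations
   with nearest-centroid reassignment) for map–map correlation, class ANOVA
   and per-class z-scores.
5. **Projection** — per-cell positive/negative program scores `s⁺ = E·u⁺`,
   `s⁻` (weighted-average convention by default), external-cohort consistency
   via per-donor z-normalization and dot-product scores `y_j = b_j·u`, and
   per-gene developmental GAMs (12 cubic B-splines on log10 post-conception
   days, penalty α = 1, sex and region covariates) averaged within deciles of
   gene weight.

Every stage is exercised on synthetic cohorts from `ctxprog.synthdata`,
which generates spherical parcel atlases, donors sharing smooth
Gaussian-process latent maps with known per-component signal-to-noise,
single-cell matrices with intracellular program coupling, and age-resolved
expression with component-specific amplitude curves — so parameter recovery
is checkable against ground truth without downloading any atlas.

## Worked example

```python
import ctxprog as cp

atlas = cp.generate_atlas(n_parcels=120, seed=1)
donors, truth = cp.generate_cohort(atlas, n_donors=6, n_genes=2000, seed=1)

matrix, ds = cp.preprocess_cohort(donors, ds_fraction=0.5, min_donors=3)
print(f"filtered matrix: {matrix.values.shape[0]} regions x {matrix.values.shape[1]} genes")

comps = cp.dme(matrix, k=5)
print("variance explained (%):", [round(float(v) * 100, 1) for v in comps.ve[:3]])
print("genes with |weight| >= 0.5 on C1:",
      len(cp.strongly_weighted(comps.weights, 0.5)["C1"]))

report = cp.generalizability(donors, ds_fraction=0.5, min_donors=3)
print("generalizability g by rank:",
      {r: round(float(v), 3) for r, v in report.g.items()})
```

prints

```
filtered matrix: 113 regions x 1000 genes
variance explained (%): [26.8, 10.5, 5.0]
genes with |weight| >= 0.5 on C1: 161
generalizability g by rank: {1: 0.998, 2: 0.976, 3: 0.974, 4: 0.149, 5: 0.86}
```

Reading the output: the six simulated donors carry three latent spatial
components with signal-to-noise 8/4/2; after DS filtering (1,000 of 2,000
genes) and region coverage filtering (113 of 120 parcels), DME recovers them
as C1–C3 with 26.8/10.5/5.0% of expression variance, and the triplet analysis
shows they replicate across disjoint donor halves (g ≈ 0.97–1.0) while the
4th-ranked component does not (g = 0.15). Deeper ranks can occasionally pair
up again with tiny variance explained (rank 5 here); the methods note
discusses why.

A command-line interface mirrors the library:

```bash
ctxprog simulate cohort --n-parcels 120 --n-donors 6 --n-genes 2000 --seed 1 --out cohort/
ctxprog preprocess --cohort cohort/ --ds-fraction 0.5 --min-donors 3 --out matrix.tsv
ctxprog decompose --matrix matrix.tsv --method dme --k 5 --out comps/
ctxprog triplets --cohort cohort/ --out triplets/
```

## Layout

```
src/ctxprog/
  synthdata.py    atlases, cohorts, single cells, development (ground truth)
  preprocess.py   probe/gene/region filters, SRS normalization, donor averaging
  decompose.py    PCA, DME, gene weights, variance explained
  generalize.py   triplet splits, greedy matching, g, filter grid search
  enrich.py       AFC permutation enrichment, Fisher, consensus lists, BH-FDR
  spatial.py      spin nulls, spin correlation/ANOVA/z-tests, Moran's I
  project.py      single-cell scores, external consistency, trajectory GAMs
  io.py           config, TSV/CSV/GMT/manifest readers and writers, pipeline driver
  cli.py          `ctxprog` command-line interface
```
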