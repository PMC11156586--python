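"""Shared readers/writers, strict pipeline configuration, and the end-to-end
pipeline driver.

All interchange is delimited text: region x gene matrices as TSV/CSV with a
gene-id header row and a region-id first column, gene sets as GMT, atlases
and maps as CSV, cohorts as one TSV per donor plus a JSON manifest. Output
files carry a provenance header (``#`` comment lines with the config hash and
stage) that the readers skip.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import decompose as _decompose
from .enrich import GeneSetCollection
from .generalize import generalizability
from .preprocess import RegionGeneMatrix, preprocess_cohort
from .synthdata import DonorExpression, ParcelAtlas

__all__ = [
    "PipelineConfig",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_atlas",
    "write_atlas",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("ctxprog")

VERSION = "0.1.0"


class PipelineConfig(BaseModel):
    """Every tunable of the pipeline, with strict (unknown-key-rejecting)
    validation. Defaults are the reference analysis choices: DS fraction 0.5,
    regions covered by >= 3 donors, DME with the normalized-angle kernel and
    alpha = 1, 5 components, 5,000 permutations and 5,000 spins."""

    model_config = ConfigDict(extra="forbid")

    ds_fraction: float = 0.5
    min_donors: int = 3
    method: str = "dme"  # "dme" | "pca"
    kernel: str = "normalized-angle"
    alpha: float = 1.0
    k: int = 5
    n_perm: int = 5000
    n_spins: int = 5000
    seed: int = 0
    diffusion_time: int = 0
    match_top_k: int = 5
    min_shared_regions: int = 10
    intensity_min_fraction: float = 0.5
    two_sided: str = "deviation"  # AFC two-sided convention
    score_convention: str = "weighted_average"  # single-cell s+/s- convention
    run_triplets: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _provenance_lines(stage: str, config: PipelineConfig | None) -> list[str]:
    lines = [f"# ctxprog v{VERSION} stage={stage}"]
    if config is not None:
        lines.append(f"# config_hash={config.hash()} seed={config.seed}")
    return lines


def write_matrix(
    matrix: RegionGeneMatrix | pd.DataFrame,
    path: str | Path,
    stage: str = "matrix",
    config: PipelineConfig | None = None,
) -> None:
    """Write a region x gene matrix with a provenance comment header."""
    path = Path(path)
    df = matrix.values if isinstance(matrix, RegionGeneMatrix) else matrix
    with open(path, "w") as fh:
        for line in _provenance_lines(stage, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep=_delimiter(path))


def read_matrix(path: str | Path) -> RegionGeneMatrix:
    """Read a region x gene matrix (delimiter chosen by extension).

    Duplicate region or gene ids and ragged rows raise a parse error.
    """
    path = Path(path)
    sep = _delimiter(path)
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    cols = header.split(sep)[1:]
    if len(set(cols)) != len(cols):  # pandas silently renames duplicates
        dup = next(c for c in cols if cols.count(c) > 1)
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated region id {dup!r}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing entries")
    return RegionGeneMatrix(df, provenance={"source": str(path)})


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, tab-separated genes).

    Gene ids are uppercased; duplicates within a set are dropped with a
    warning. Use :meth:`GeneSetCollection.from_lists` to attach a universe.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *genes = fields
            genes = [g.upper() for g in genes if g]
            dedup = list(dict.fromkeys(genes))
            if len(dedup) < len(genes):
                log.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets[name] = dedup
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def read_atlas(path: str | Path) -> ParcelAtlas:
    df = pd.read_csv(path, comment="#")
    labels = tuple(df["class"]) if "class" in df.columns else None
    hemi = str(df["hemisphere"].iloc[0]) if "hemisphere" in df.columns else "L"
    return ParcelAtlas(
        tuple(str(p) for p in df["parcel_id"]),
        df[["x", "y", "z"]].to_numpy(float),
        hemisphere=hemi,
        class_labels=labels,
    )


def write_cohort(donors: list[DonorExpression], out_dir: str | Path) -> Path:
    """One TSV per donor (regions x genes or regions x probes) plus a JSON
    manifest; probe-level donors also write a probe map and background flags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": VERSION, "donors": []}
    for d in donors:
        fname = f"{d.donor_id}.tsv"
        d.values.to_csv(out / fname, sep="\t")
        entry = {"donor_id": d.donor_id, "file": fname, "level": d.level}
        if d.level == "probe":
            pm = f"{d.donor_id}.probes.tsv"
            d.probe_gene.rename("gene_id").to_csv(out / pm, sep="\t", index_label="probe_id")
            entry["probe_map"] = pm
            if d.background is not None:
                bg = f"{d.donor_id}.background.tsv"
                d.background.astype(int).to_csv(out / bg, sep="\t")
                entry["background"] = bg
        manifest["donors"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out / "manifest.json"


def read_cohort(cohort_dir: str | Path) -> list[DonorExpression]:
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    donors = []
    for entry in manifest["donors"]:
        values = pd.read_csv(cohort_dir / entry["file"], sep="\t", index_col=0)
        probe_gene = background = None
        if entry["level"] == "probe":
            pm = pd.read_csv(cohort_dir / entry["probe_map"], sep="\t", index_col=0)
            probe_gene = pm["gene_id"]
            if "background" in entry:
                background = (
                    pd.read_csv(cohort_dir / entry["background"], sep="\t", index_col=0)
                    .astype(bool)
                )
        donors.append(
            DonorExpression(
                entry["donor_id"], values, level=entry["level"],
                probe_gene=probe_gene, background=background,
            )
        )
    return donors


def run_pipeline(
    config: PipelineConfig, cohort_dir: str | Path, out_dir: str | Path
) -> dict:
    """Preprocess a cohort, decompose it, optionally run the triplet analysis,
    and write every artifact with a provenance stamp.

    Returns (and writes) a manifest of the produced files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    donors = read_cohort(cohort_dir)
    log.info("loaded %d donors from %s", len(donors), cohort_dir)
    matrix, ds = preprocess_cohort(
        donors,
        ds_fraction=config.ds_fraction,
        min_donors=config.min_donors,
        intensity_min_fraction=config.intensity_min_fraction,
    )
    log.info(
        "preprocess: %d regions x %d genes retained (%s)",
        matrix.values.shape[0], matrix.values.shape[1], matrix.provenance,
    )
    if config.k > matrix.values.shape[0] - 2:
        raise ValueError(
            f"decompose: k={config.k} too large for {matrix.values.shape[0]} regions"
        )
    if config.method == "dme":
        comps = _decompose.dme(
            matrix, config.k, alpha=config.alpha, diffusion_time=config.diffusion_time
        )
    elif config.method == "pca":
        comps = _decompose.pca(matrix, config.k)
    else:
        raise ValueError(f"unknown method {config.method!r}")
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "files": {},
        "preprocess": matrix.provenance,
    }

    def _save(df: pd.DataFrame, name: str, stage: str) -> None:
        path = out / name
        write_matrix(df, path, stage=stage, config=config)
        manifest["files"][stage] = name

    _save(matrix.values, "matrix.tsv", "preprocess")
    _save(comps.scores, "scores.tsv", "scores")
    _save(comps.weights, "weights.tsv", "weights")
    _save(
        pd.DataFrame({"ve": comps.ve}, index=comps.component_names()), "ve.csv", "ve"
    )
    ds.ds.to_csv(out / "differential_stability.tsv", sep="\t")
    manifest["files"]["differential_stability"] = "differential_stability.tsv"
    if config.run_triplets:
        report = generalizability(
            donors,
            ds_fraction=config.ds_fraction,
            min_donors=config.min_donors,
            method=config.method,
            top_k=config.match_top_k,
            alpha=config.alpha,
            min_shared_regions=config.min_shared_regions,
        )
        report.matches.to_csv(out / "triplet_matches.csv", index=False)
        report.g.to_csv(out / "generalizability.csv")
        manifest["files"]["triplet_matches"] = "triplet_matches.csv"
        manifest["files"]["generalizability"] = "generalizability.csv"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
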