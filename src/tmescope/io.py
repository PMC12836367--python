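"""Plain-text readers and writers for the package's standard formats.

Cohorts travel as Matrix Market counts + features/barcodes TSVs + a
cell-metadata CSV (the tidy 10x-style layout); spatial data as a single
tidy CSV per sample; pseudobulk tensors as one wide CSV per sample plus a
JSON index; configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .preprocess import PseudobulkTensor
from .spatial import SpatialDataset


def write_cohort(adata: AnnData, outdir) -> None:
    """MTX (genes x cells, 10x orientation) + features/barcodes TSV + metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(outdir / "metadata.csv")


def read_cohort(indir) -> AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "metadata.csv", index_col=0)
    obs.index = obs.index.astype(str)
    adata = AnnData(
        X=X,
        obs=obs.loc[barcodes.astype(str)],
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    return adata


def write_pseudobulk(tensor: PseudobulkTensor, outdir) -> None:
    """One wide gene x cell-type CSV per sample plus a JSON index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {"normalized": tensor.normalized, "samples": {}}
    for sample in tensor.samples:
        cols = [c for c in tensor.values.columns if c[0] == sample]
        block = tensor.values[cols]
        block.columns = [c[2] for c in cols]
        fname = f"pseudobulk_{sample}.csv"
        block.to_csv(outdir / fname)
        index["samples"][str(sample)] = {
            "file": fname,
            "cell_types": {c[2]: c[1] for c in cols},
            "cell_counts": {c[2]: int(tensor.cell_counts[c]) for c in cols},
        }
    (outdir / "pseudobulk_index.json").write_text(json.dumps(index, indent=2))


def read_pseudobulk(indir) -> PseudobulkTensor:
    indir = Path(indir)
    index = json.loads((indir / "pseudobulk_index.json").read_text())
    frames, counts = [], {}
    for sample, entry in index["samples"].items():
        block = pd.read_csv(indir / entry["file"], index_col=0)
        block.columns = pd.MultiIndex.from_tuples(
            [(sample, entry["cell_types"][ct], ct) for ct in block.columns],
            names=["sample", "population", "cell_type"],
        )
        frames.append(block)
        for ct, n in entry["cell_counts"].items():
            counts[(sample, entry["cell_types"][ct], ct)] = n
    values = pd.concat(frames, axis=1)
    return PseudobulkTensor(
        values=values,
        cell_counts=pd.Series(counts).reindex(values.columns),
        normalized=bool(index["normalized"]),
    )


def write_spatial(d: SpatialDataset, path) -> None:
    """Tidy CSV: spot, x, y, region, necrotic, weight columns, gene columns."""
    df = d.spots.copy()
    df["necrotic"] = d.necrotic
    for ct in d.weights.columns:
        df[f"weight_{ct}"] = d.weights[ct]
    for gene in d.expression.columns:
        df[f"expr_{gene}"] = d.expression[gene]
    df.to_csv(path)


def read_spatial(path) -> SpatialDataset:
    df = pd.read_csv(path, index_col=0)
    wcols = [c for c in df.columns if c.startswith("weight_")]
    ecols = [c for c in df.columns if c.startswith("expr_")]
    keep = [c for c in df.columns if c not in wcols + ecols + ["necrotic"]]
    return SpatialDataset(
        spots=df[keep],
        necrotic=df["necrotic"].astype(bool),
        expression=df[ecols].rename(columns=lambda c: c[len("expr_"):]),
        weights=df[wcols].rename(columns=lambda c: c[len("weight_"):]),
    )


def write_config(config, path) -> None:
    """Dataclass config as YAML (numpy values coerced to plain python)."""

    def coerce(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: coerce(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [coerce(x) for x in v]
        if dataclasses.is_dataclass(v):
            return coerce(dataclasses.asdict(v))
        return v

    Path(path).write_text(
        yaml.safe_dump(coerce(dataclasses.asdict(config)), sort_keys=False)
    )


def read_lr_pairs(path) -> pd.DataFrame:
    """Two-column ligand,receptor CSV (extra annotation columns preserved)."""
    pairs = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError("LR pair list needs 'ligand' and 'receptor' columns")
    if pairs.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows in pair list")
    return pairs
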