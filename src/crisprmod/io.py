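"""Readers and writers for the pipeline's plain-text interchange formats.

* guide counts: TSV with columns guide_id, gene_id, then one column per sample
* screen design: TSV with columns sample_id, drug, dose, replicate
* expression: GCT v1.2 ("#1.2" header, dims line, Name/Description columns)
  with matching categorical CLS phenotype labels
* gene sets: GMT (tab-separated: name, description, member genes)
* dose matrices: CSV grid, first row/column are dose headers in nM
* survival: TSV with columns id, time, event, expression
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .gsea import GeneSetCollection
from .screen_qc import GuideCountMatrix, ScreenDesign

__all__ = [
    "write_guide_counts", "read_guide_counts",
    "write_design", "read_design",
    "write_gct", "read_gct", "write_cls", "read_cls",
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "write_dose_matrix", "read_dose_matrix",
    "write_survival", "read_survival",
    "load_yaml_config",
]


def write_guide_counts(gcm: GuideCountMatrix, path) -> None:
    out = gcm.counts.copy()
    out.insert(0, "gene_id", gcm.gene_map.loc[out.index].to_numpy())
    out.index.name = "guide_id"
    out.to_csv(path, sep="\t")


def read_guide_counts(path) -> GuideCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    gene_map = df["gene_id"]
    counts = df.drop(columns="gene_id").astype(int)
    return GuideCountMatrix(counts=counts, gene_map=gene_map)


def write_design(design: ScreenDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_design(path, vehicle_label: str = "DMSO") -> ScreenDesign:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ScreenDesign(table=table, vehicle_label=vehicle_label)


def write_gct(values: pd.DataFrame, path, descriptions=None) -> None:
    """GCT v1.2: '#1.2' line, 'n_genes\tn_samples' line, Name/Description columns."""
    n_genes, n_samples = values.shape
    if descriptions is None:
        descriptions = ["na"] * n_genes
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for (gene, row), desc in zip(values.iterrows(), descriptions):
            fh.write(str(gene) + "\t" + str(desc) + "\t"
                     + "\t".join(format(v, "g") for v in row) + "\n")


def read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"not a GCT v1.2 file (header {version!r})")
        n_genes, n_samples = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col="Name")
    df = df.drop(columns="Description")
    if df.shape != (n_genes, n_samples):
        raise ValueError(f"GCT dims line says {(n_genes, n_samples)}, data is {df.shape}")
    return df.astype(float)


def write_cls(labels, path) -> None:
    """Categorical CLS: 'n k 1', '# class names', one label token per sample."""
    labels = list(labels)
    classes = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(map(str, classes)) + "\n")
        fh.write(" ".join(map(str, labels)) + "\n")


def read_cls(path) -> list:
    with open(path) as fh:
        n, k, _ = fh.readline().split()
        names_line = fh.readline().strip()
        if not names_line.startswith("#"):
            raise ValueError("second CLS line must start with '#'")
        class_names = names_line[1:].split()
        tokens = fh.readline().split()
    if len(tokens) != int(n):
        raise ValueError(f"CLS header promises {n} samples, found {len(tokens)}")
    # tokens may be class names or 0-based indices
    if all(t.isdigit() for t in tokens) and not set(tokens) <= set(class_names):
        return [class_names[int(t)] for t in tokens]
    return tokens


def write_expression(matrix: ExpressionMatrix, gct_path, cls_path) -> None:
    write_gct(matrix.values, gct_path)
    write_cls([matrix.phenotypes[s] for s in matrix.values.columns], cls_path)


def read_expression(gct_path, cls_path) -> ExpressionMatrix:
    values = read_gct(gct_path)
    labels = read_cls(cls_path)
    if len(labels) != values.shape[1]:
        raise ValueError("CLS label count does not match GCT sample count")
    return ExpressionMatrix(values=values,
                            phenotypes=pd.Series(labels, index=values.columns))


def read_gmt(path) -> GeneSetCollection:
    out = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            members = tuple(m for m in members if m)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            out[name] = members
    return out


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_dose_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="dose_a_nM")


def read_dose_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(float)
    df.columns = df.columns.astype(float)
    return df


def write_survival(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in ("id", "time", "event", "expression") if c in cohort.columns]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["event"] = df["event"].astype(bool)
    return df


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {Path(path)} must hold a mapping")
    return data
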