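"""Readers and writers for the plain-text formats the package consumes.

GMT (gene matrix transposed): one named gene set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.  Signatures may also be
given as one-gene-per-line text files, one file per signature.
Expression matrices are TSVs with features as rows and a header of
sample IDs; labels and feature-to-gene mappings are 2-column TSVs.
All readers accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into an ordered name -> gene-set mapping."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"{path}: line {lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene identifier per line; blank lines ignored."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_signature_files(paths: Iterable[str | Path]) -> dict[str, set[str]]:
    """One-gene-per-line files, named after their basename sans suffix."""
    sigs: dict[str, set[str]] = {}
    for p in paths:
        name = Path(p).stem
        if name in sigs:
            raise ValueError(f"duplicate signature name {name!r}")
        genes = read_gene_list(p)
        if not genes:
            raise ValueError(f"{p}: empty signature")
        sigs[name] = genes
    return sigs


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with a header row of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs: {dupes[:5]}")
    return df.astype(float)


def read_labels(path: str | Path) -> pd.Series:
    """2-column TSV (sample, class); classes must be binary."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    series = df.set_index("sample")["label"]
    classes = sorted(series.unique())
    if len(classes) != 2:
        raise ValueError(f"{path}: expected exactly 2 classes, found {classes}")
    return series.map({classes[0]: 0, classes[1]: 1}).astype(int)


def read_feature_mapping(path: str | Path) -> dict[str, str]:
    """2-column TSV (feature, gene); many features may share one gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature", "gene"], dtype=str)
    if df["feature"].duplicated().any():
        raise ValueError(f"{path}: duplicate feature IDs in mapping")
    return dict(zip(df["feature"], df["gene"]))


def write_matrix_tsv(values: np.ndarray, index: Iterable[str], columns: Iterable[str], path: str | Path) -> None:
    pd.DataFrame(values, index=list(index), columns=list(columns)).to_csv(path, sep="\t")
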