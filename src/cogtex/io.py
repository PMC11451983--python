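"""Readers and writers for the text formats the pipeline touches.

Formats: GCT v1.2 expression matrices (the dialect GTEx distributes), GTEx-style
sample-attribute / subject-phenotype TSV tables, GMT gene-set collections,
network edge lists with association probabilities, ChIP-peak gene tables, and
the persisted coexpression results (gene index + dense matrix + long-form TSV).

Gene identifiers are Ensembl-style by default; version suffixes ("ENSG...\\.12")
are stripped on load so identifiers join cleanly against gene-set and network
files, which ship unversioned ids.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import FormatError, CogtexError

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_gct",
    "write_gct",
    "read_sample_attributes",
    "read_gmt",
    "read_edge_list",
    "read_peak_table",
    "save_result_matrix",
    "load_result_matrix",
    "export_long_format",
]


class Scale(str, enum.Enum):
    """Declared scale of an expression matrix."""

    TPM = "TPM"
    LOG10P1 = "LOG10P1"
    ZSCORE = "ZSCORE"


@dataclass
class ExpressionMatrix:
    """A dense genes x samples expression matrix with a declared scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    TPM-scale matrices must be non-negative and free of missing values.
    """

    values: pd.DataFrame
    scale: Scale = Scale.TPM
    gene_annotations: pd.Series | None = None  # e.g. the GCT Description column

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise CogtexError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated gene id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicated sample id: {dup!r}")
        if self.scale == Scale.TPM and (self.values.to_numpy() < 0).any():
            raise CogtexError("TPM-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.scale)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); sets below ``min_size`` are dropped on load."""

    sets: dict[str, list[str]]
    min_size: int = 2
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


def _strip_version(gene_id: str) -> str:
    # GTEx ships versioned Ensembl ids (ENSG00000000003.14); strip for joinability
    if gene_id.startswith("ENS") and "." in gene_id:
        return gene_id.rsplit(".", 1)[0]
    return gene_id


def read_gct(path, strip_versions: bool = True) -> ExpressionMatrix:
    """Read a GCT v1.2 file into a TPM-scale :class:`ExpressionMatrix`.

    The dims line must match the data exactly; any non-numeric cell raises a
    :class:`FormatError` naming the row and column.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise FormatError(f"{path.name}: first line {version!r} is not a GCT version token")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path.name}: second line must give n_genes<TAB>n_samples")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-integer dims line: {dims!r}") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "Name":
            raise FormatError(f"{path.name}: header must start with 'Name\\tDescription'")
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise FormatError(
                f"{path.name}: dims line declares {n_samples} samples but header has {len(sample_ids)}"
            )
        gene_ids: list[str] = []
        descriptions: list[str] = []
        rows = np.empty((n_genes, n_samples), dtype=np.float64)
        i = 0
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_samples + 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {n_samples + 2} fields, found {len(fields)}"
                )
            if i >= n_genes:
                raise FormatError(f"{path.name}: more data rows than the declared {n_genes} genes")
            gid = _strip_version(fields[0]) if strip_versions else fields[0]
            for j, cell in enumerate(fields[2:]):
                try:
                    rows[i, j] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}:{lineno}: non-numeric value {cell!r} for gene "
                        f"{fields[0]!r}, sample {sample_ids[j]!r}"
                    ) from exc
            gene_ids.append(gid)
            descriptions.append(fields[1])
            i += 1
    if i != n_genes:
        raise FormatError(f"{path.name}: dims line declares {n_genes} genes but found {i} data rows")
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    ann = pd.Series(descriptions, index=gene_ids, name="Description")
    return ExpressionMatrix(values, Scale.TPM, gene_annotations=ann)


def write_gct(expr: ExpressionMatrix, path) -> None:
    """Write a GCT v1.2 file; round-trips :func:`read_gct` at full precision."""
    path = Path(path)
    ann = expr.gene_annotations
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in expr.values.iterrows():
            desc = str(ann.loc[gid]) if ann is not None and gid in ann.index else gid
            fh.write(gid + "\t" + desc + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# GTEx column conventions for the two metadata tables
_ATTR_COLUMNS = {
    "SAMPID": "sample_id",
    "SMTSD": "tissue",
    "SMNABTCH": "extraction_batch",
    "SMGEBTCH": "sequencing_batch",
    "SMTSISCH": "ischemia_time",
}
_PHENO_COLUMNS = {"SUBJID": "subject_id", "SEX": "sex", "AGE": "age"}


def _subject_of(sample_id: str) -> str:
    # GTEx convention: subject id = first two dash-separated tokens of the sample id
    return "-".join(sample_id.split("-")[:2])


def _parse_age(value) -> float:
    """Accept numeric ages or GTEx-style decade brackets ('60-69' -> midpoint)."""
    if isinstance(value, str) and "-" in value:
        lo, hi = value.split("-", 1)
        return (float(lo) + float(hi)) / 2.0
    return float(value)


def _parse_sex(value) -> str:
    if isinstance(value, str) and value.lower() in ("male", "female"):
        return value.lower()
    code = int(value)  # GTEx encodes 1=male, 2=female
    if code not in (1, 2):
        raise FormatError(f"unrecognized sex code {value!r}")
    return "male" if code == 1 else "female"


def read_sample_attributes(attr_path, pheno_path, sample_ids=None) -> pd.DataFrame:
    """Join a sample-attribute table with a subject-phenotype table.

    Returns one row per sample with columns ``sample_id, subject_id, tissue,
    extraction_batch, sequencing_batch, sex, age, ischemia_time``. Missing batch
    fields are kept as NA (flagged, not dropped). If ``sample_ids`` is given,
    every id must be present in the attribute table.
    """
    attrs = pd.read_csv(attr_path, sep="\t", dtype=str)
    for col in _ATTR_COLUMNS:
        if col not in attrs.columns:
            raise FormatError(f"{Path(attr_path).name}: missing required column {col!r}")
    pheno = pd.read_csv(pheno_path, sep="\t", dtype=str)
    for col in _PHENO_COLUMNS:
        if col not in pheno.columns:
            raise FormatError(f"{Path(pheno_path).name}: missing required column {col!r}")
    attrs = attrs[list(_ATTR_COLUMNS)].rename(columns=_ATTR_COLUMNS)
    pheno = pheno[list(_PHENO_COLUMNS)].rename(columns=_PHENO_COLUMNS)
    if attrs["sample_id"].duplicated().any():
        dup = attrs.loc[attrs["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicated sample id in attributes: {dup!r}")
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(attrs["sample_id"]))
        if missing:
            raise CogtexError(
                f"{len(missing)} expression sample(s) absent from attributes: {missing[:10]}"
            )
        attrs = attrs[attrs["sample_id"].isin(set(sample_ids))]
    attrs = attrs.copy()
    attrs["subject_id"] = attrs["sample_id"].map(_subject_of)
    table = attrs.merge(pheno, on="subject_id", how="left")
    table["sex"] = table["sex"].map(_parse_sex)
    table["age"] = table["age"].map(_parse_age)
    if (table["age"] < 0).any():
        raise CogtexError("negative age in phenotype table")
    table["ischemia_time"] = pd.to_numeric(table["ischemia_time"], errors="coerce")
    for col in ("extraction_batch", "sequencing_batch"):
        table[col] = table[col].replace("", pd.NA)
    cols = [
        "sample_id",
        "subject_id",
        "tissue",
        "extraction_batch",
        "sequencing_batch",
        "sex",
        "age",
        "ischemia_time",
    ]
    return table[cols].set_index("sample_id", drop=False)


def read_gmt(path, min_size: int = 2) -> GeneSetCollection:
    """Read a GMT file, dropping sets with fewer than ``min_size`` genes."""
    sets: dict[str, list[str]] = {}
    dropped = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"{Path(path).name}: empty GMT file")
        return GeneSetCollection({}, min_size=min_size)
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{Path(path).name}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{Path(path).name}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in fields[2:] if g]
        if len(genes) < min_size:
            dropped += 1
            continue
        sets[name] = genes
    return GeneSetCollection(sets, min_size=min_size, n_dropped=dropped)


def read_edge_list(path) -> pd.DataFrame:
    """Read a (gene_a, gene_b, probability) TSV; probabilities must lie in [0, 1]."""
    edges = pd.read_csv(path, sep="\t", header=0, names=["gene_a", "gene_b", "probability"])
    edges["probability"] = pd.to_numeric(edges["probability"], errors="raise")
    if ((edges["probability"] < 0) | (edges["probability"] > 1)).any():
        bad = edges.loc[(edges["probability"] < 0) | (edges["probability"] > 1)].index[0]
        raise FormatError(f"{Path(path).name}: probability outside [0,1] at data row {bad}")
    if (edges["gene_a"] == edges["gene_b"]).any():
        bad = edges.loc[edges["gene_a"] == edges["gene_b"]].index[0]
        raise FormatError(f"{Path(path).name}: self-edge at data row {bad}")
    return edges


def read_peak_table(path) -> pd.Series:
    """Read a (gene_id, has_peak) TSV into a boolean Series indexed by gene."""
    table = pd.read_csv(path, sep="\t", header=0, names=["gene_id", "has_peak"])
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{Path(path).name}: duplicated gene id {dup!r}")
    truthy = {"1", "true", "yes"}
    flags = table["has_peak"].map(
        lambda v: bool(int(v)) if str(v).isdigit() else str(v).lower() in truthy
    )
    return pd.Series(flags.to_numpy(), index=table["gene_id"].to_numpy(), name="has_peak")


def save_result_matrix(matrix: pd.DataFrame, prefix, metadata: dict | None = None) -> None:
    """Persist a symmetric gene x gene result as an index file + dense float matrix.

    Writes ``<prefix>.genes.txt`` (one id per line), ``<prefix>.npy`` (float64
    dense matrix) and ``<prefix>.json`` (metadata: metric, modality, ...).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(str(prefix) + ".genes.txt", "w") as fh:
        fh.write("\n".join(matrix.index) + "\n")
    np.save(str(prefix) + ".npy", matrix.to_numpy(dtype=np.float64))
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(metadata or {}, fh, indent=1, sort_keys=True)


def load_result_matrix(prefix) -> tuple[pd.DataFrame, dict]:
    prefix = str(prefix)
    with open(prefix + ".genes.txt") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    values = np.load(prefix + ".npy")
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    return pd.DataFrame(values, index=genes, columns=genes), meta


def export_long_format(matrix: pd.DataFrame, metric: str, modality: str, path) -> None:
    """Export the upper triangle as long-form TSV (gene_a, gene_b, metric, modality, value)."""
    genes = list(matrix.index)
    iu = np.triu_indices(len(genes), k=1)
    vals = matrix.to_numpy()[iu]
    out = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[0]],
            "gene_b": [genes[j] for j in iu[1]],
            "metric": metric,
            "modality": modality,
            "value": vals,
        }
    )
    out.to_csv(path, sep="\t", index=False)
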