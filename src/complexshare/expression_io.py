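"""Readers and normalizers for gene-level abundance matrices.

Three input flavors are normalized to a single in-memory representation, a
non-negative pandas ``DataFrame`` of abundance values indexed by gene symbol
(rows) x sample identifier (columns) with a unit label in ``df.attrs``:

* gene-level TPM matrices in GCT 1.2 or plain TSV (GTEx-style); duplicate
  gene rows are summed,
* transcript-level TPM tables with per-sample normalization factors
  (CAGE-style); transcripts are summed to gene level after excluding samples
  with extreme normalization factors,
* probe-level microarray tables with a probe-to-gene map; probes are
  averaged to gene level.

A sample annotation maps each sample identifier to exactly one tissue-group
label; these labels form the families over which enrichment FDR is computed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionIOWarning",
    "validate_abundance",
    "read_gct",
    "read_expression_tsv",
    "write_expression_tsv",
    "TranscriptTable",
    "read_transcript_table",
    "filter_by_norm_factor",
    "aggregate_transcripts",
    "ProbeTable",
    "read_probe_table",
    "aggregate_probes",
    "read_annotation",
    "write_annotation",
]

_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9._@-]*$")


class ExpressionIOWarning(UserWarning):
    """Warning about a data decision made while reading expression input."""


def validate_abundance(df: pd.DataFrame, unit_label: str | None = None) -> pd.DataFrame:
    """Validate an abundance matrix: non-negative, finite, unique ids.

    Sets ``df.attrs["unit_label"]`` when ``unit_label`` is given and returns
    the same frame for chaining.
    """
    if df.index.has_duplicates:
        raise ValueError("abundance matrix has duplicated gene identifiers")
    if df.columns.has_duplicates:
        raise ValueError("abundance matrix has duplicated sample identifiers")
    values = df.to_numpy(dtype=float, copy=False)
    if values.size and not np.isfinite(values).all():
        raise ValueError("abundance matrix contains non-finite values")
    if values.size and (values < 0).any():
        raise ValueError("abundance matrix contains negative values")
    if unit_label is not None:
        df.attrs["unit_label"] = unit_label
    return df


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        warnings.warn(
            f"summed duplicated gene row(s): {dupes}", ExpressionIOWarning, stacklevel=3
        )
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_gct(path: str | Path, unit_label: str = "TPM") -> pd.DataFrame:
    """Read a GCT 1.2 expression matrix to a gene x sample abundance frame.

    Gene symbols are taken from the Description column when it looks like a
    symbol (GTEx GCT stores Ensembl ids in Name), else from Name.  Duplicate
    gene rows are summed.  The declared dimensions must match the table.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (version line {version!r})")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        try:
            n_rows, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed GCT dimension line") from exc
        table = pd.read_csv(fh, sep="\t", header=0, dtype={0: str, 1: str})
    if table.shape[1] != n_samples + 2:
        raise ValueError(
            f"{path}: header declares {n_samples} samples but table has "
            f"{table.shape[1] - 2} value columns"
        )
    if table.shape[0] != n_rows:
        raise ValueError(
            f"{path}: header declares {n_rows} rows but table has {table.shape[0]}"
        )
    name = table.iloc[:, 0].astype(str)
    desc = table.iloc[:, 1].astype(str)
    use_desc = desc.map(lambda s: bool(_SYMBOL_RE.match(s)) and not s.startswith("ENSG"))
    symbols = desc.where(use_desc, name)
    values = table.iloc[:, 2:].astype(float)
    values.index = pd.Index(symbols, name="gene")
    values = _collapse_duplicate_genes(values)
    return validate_abundance(values, unit_label)


def read_expression_tsv(path: str | Path, unit_label: str = "TPM") -> pd.DataFrame:
    """Read a plain TSV matrix (first column gene symbol, then samples).

    Duplicate gene rows are summed, consistent with the transcript rule.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df = _collapse_duplicate_genes(df.astype(float))
    return validate_abundance(df, unit_label)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an abundance matrix as TSV with a ``gene`` index column."""
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


@dataclass
class TranscriptTable:
    """Transcript-level TPM with per-sample normalization factors.

    ``table`` columns: ``transcript``, ``gene``, then one column per sample.
    ``norm_factors`` indexes the same samples; factors must be positive.
    """

    table: pd.DataFrame
    norm_factors: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.table.columns[2:])
        missing = [s for s in samples if s not in self.norm_factors.index]
        if missing:
            raise ValueError(f"normalization factor missing for sample(s) {missing}")
        if (self.norm_factors.loc[samples] <= 0).any():
            raise ValueError("normalization factors must be > 0")

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns[2:])


def read_transcript_table(path: str | Path, norm_path: str | Path) -> TranscriptTable:
    """Read a transcript TSV (``transcript``, ``gene``, samples...) and a
    one-row normalization-factor file with the same sample columns."""
    table = pd.read_csv(path, sep="\t", dtype={"transcript": str, "gene": str})
    if list(table.columns[:2]) != ["transcript", "gene"]:
        raise ValueError(f"{path}: first columns must be 'transcript', 'gene'")
    factors = pd.read_csv(norm_path, sep="\t")
    if factors.shape[0] != 1:
        raise ValueError(f"{norm_path}: expected a one-row normalization-factor table")
    return TranscriptTable(table=table, norm_factors=factors.iloc[0].astype(float))


def filter_by_norm_factor(
    table: TranscriptTable, low: float = 0.7, high: float = 1.4
) -> TranscriptTable:
    """Drop samples with extreme normalization factors.

    Retains samples with ``low <= factor <= high``; the exclusion is strict
    (a factor exactly at a boundary is kept).
    """
    keep = [
        s for s in table.samples if low <= table.norm_factors[s] <= high
    ]
    dropped = [s for s in table.samples if s not in keep]
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} sample(s) with extreme normalization "
            f"factors: {dropped}",
            ExpressionIOWarning,
            stacklevel=2,
        )
    new_table = table.table[list(table.table.columns[:2]) + keep]
    return TranscriptTable(table=new_table, norm_factors=table.norm_factors.loc[keep])


def aggregate_transcripts(table: TranscriptTable, unit_label: str = "TPM") -> pd.DataFrame:
    """Sum transcript TPM to gene level, per sample.

    Transcripts with no gene mapping (empty/NaN gene) are excluded with a
    warning.
    """
    df = table.table
    mapped = df["gene"].notna() & (df["gene"].astype(str).str.strip() != "")
    if (~mapped).any():
        warnings.warn(
            f"excluded {int((~mapped).sum())} transcript(s) with no gene mapping",
            ExpressionIOWarning,
            stacklevel=2,
        )
    df = df[mapped]
    if df.empty:
        out = pd.DataFrame(index=pd.Index([], name="gene"), columns=table.samples, dtype=float)
        return validate_abundance(out, unit_label)
    out = df.groupby("gene", sort=False)[table.samples].sum()
    out.index.name = "gene"
    return validate_abundance(out.astype(float), unit_label)


@dataclass
class ProbeTable:
    """Probe-level microarray expression with a probe-to-gene map.

    ``table`` columns: ``probe``, ``gene``, then one column per sample.
    Each probe maps to exactly one gene symbol.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["probe"].duplicated().any():
            dupes = sorted(self.table["probe"][self.table["probe"].duplicated()])
            raise ValueError(f"probe(s) mapped more than once: {dupes}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns[2:])


def read_probe_table(path: str | Path) -> ProbeTable:
    """Read a probe TSV (``probe``, ``gene``, samples...)."""
    table = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str})
    if list(table.columns[:2]) != ["probe", "gene"]:
        raise ValueError(f"{path}: first columns must be 'probe', 'gene'")
    return ProbeTable(table=table)


def aggregate_probes(table: ProbeTable, unit_label: str = "intensity") -> pd.DataFrame:
    """Average probe expression to gene level, per sample (arithmetic mean)."""
    if table.table.empty:
        out = pd.DataFrame(index=pd.Index([], name="gene"), columns=table.samples, dtype=float)
        return validate_abundance(out, unit_label)
    out = table.table.groupby("gene", sort=False)[table.samples].mean()
    out.index.name = "gene"
    return validate_abundance(out.astype(float), unit_label)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a sample-to-tissue annotation TSV (``sample``, ``tissue``).

    Each sample must map to exactly one tissue label; a sample repeated with
    conflicting labels is a validation error, a repeat with the same label is
    accepted once.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two columns (sample, tissue)")
    df = df.iloc[:, :2]
    df.columns = ["sample", "tissue"]
    df = df.drop_duplicates()
    conflicts = df["sample"][df["sample"].duplicated()].unique()
    if len(conflicts):
        raise ValueError(
            f"sample(s) annotated with conflicting tissue labels: {sorted(conflicts)}"
        )
    ann = df.set_index("sample")["tissue"]
    ann.index.name = "sample"
    ann.name = "tissue"
    return ann


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    """Write a sample-to-tissue annotation as a two-column TSV."""
    annotation.rename("tissue").rename_axis("sample").to_csv(path, sep="\t")
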