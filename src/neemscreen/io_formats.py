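"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV (gene symbols never contain tabs). Sequencing
reads are plain 4-line FASTQ, optionally gzipped, parsed with Biopython.
Pathway gene sets use the GMT convention (name, description, members).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import (
    DataError,
    ParseError,
    ReconciliationError,
    ValidationError,
)

logger = logging.getLogger("neemscreen")

VALID_CONDITIONS = frozenset({"treated", "rescue", "control"})
_DNA = frozenset("ACGT")

SAMPLESHEET_COLUMNS = ["sample_id", "condition", "time_min", "batch", "dose"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShrnaLibraryRecord:
    """One shRNA construct: its ID, the DNA barcode that identifies it in
    sequencing reads, and the HGNC-style symbol of the gene it knocks down."""

    shrna_id: str
    barcode: str
    gene: str

    def __post_init__(self):
        if not self.barcode or set(self.barcode) - _DNA:
            raise ValidationError(
                f"barcode for {self.shrna_id!r} must be a non-empty uppercase "
                f"ACGT string, got {self.barcode!r}"
            )


@dataclass
class PathwayGeneSet:
    """A named pathway gene set (GMT line)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class ExpressionMatrix:
    """Probe/gene x sample intensity grid with its sample metadata.

    ``values`` rows are probes or genes, columns are sample IDs matching the
    ``samples`` sheet (columns: sample_id, condition, time_min, batch, dose).
    ``scale`` records whether intensities are raw or log2-transformed.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"  # {"raw", "log2"}

    def __post_init__(self):
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        validate_sample_sheet(self.samples)
        sheet_ids = list(self.samples["sample_id"])
        matrix_ids = list(self.values.columns)
        missing_in_sheet = sorted(set(matrix_ids) - set(sheet_ids))
        missing_in_matrix = sorted(set(sheet_ids) - set(matrix_ids))
        if missing_in_sheet or missing_in_matrix:
            raise ReconciliationError(
                "expression matrix and sample sheet disagree: "
                f"columns absent from sheet: {missing_in_sheet}; "
                f"sheet rows absent from matrix: {missing_in_matrix}"
            )

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, samples=self.samples.copy(),
                                scale=self.scale if scale is None else scale)

    def columns_for(self, condition: str, time_min: float | None = None,
                    dose: str | None = None) -> list[str]:
        """Sample IDs matching a condition (and optionally a time point / dose)."""
        sheet = self.samples
        mask = sheet["condition"] == condition
        if time_min is not None:
            mask &= sheet["time_min"] == time_min
        if dose is not None:
            mask &= sheet["dose"] == dose
        return list(sheet.loc[mask, "sample_id"])


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    required = {"sample_id", "condition", "time_min", "batch"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["condition"]) - VALID_CONDITIONS
    if bad:
        raise ValidationError(
            f"sample sheet conditions must be in {sorted(VALID_CONDITIONS)}, got {sorted(bad)}"
        )
    if sheet["sample_id"].duplicated().any():
        dups = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample IDs in sheet: {dups}")
    if (sheet["time_min"] < 0).any():
        raise ValidationError("time_min must be non-negative")
    # (condition, time, dose) combinations must be unique within each batch
    key_cols = ["batch", "condition", "time_min"]
    if "dose" in sheet.columns:
        key_cols.append("dose")
    dup = sheet.duplicated(subset=key_cols)
    if dup.any():
        raise ValidationError(
            "duplicate (condition, time_min, dose) combinations within a batch: "
            f"{sheet.loc[dup, key_cols].to_dict('records')}"
        )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Lazily yield ``(read_id, sequence, quality)`` from a 4-line FASTQ.

    Gzip is detected from a ``.gz`` extension. Truncated records or
    sequence/quality length mismatches raise :class:`ParseError` with the
    approximate line of the offending record.
    """
    n = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record: {exc}", path=path,
                                 line=4 * n + 1) from exc
            n += 1
            yield title.split()[0] if title else title, seq, qual


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write ``(read_id, sequence, quality)`` records as 4-line FASTQ; returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read_id, seq, qual in records:
            if len(seq) != len(qual):
                raise ValidationError(
                    f"read {read_id!r}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# GMT pathway gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[PathwayGeneSet]:
    """Parse a GMT file into pathway gene sets.

    Each line: ``name<TAB>description<TAB>gene1<TAB>gene2...``. Duplicate
    genes within one line are deduplicated with a logged warning; a line with
    fewer than three fields is a parse error.
    """
    sets: list[PathwayGeneSet] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, need >=3 (name, description, genes)",
                    path=path, line=lineno,
                )
            name, description, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "GMT set %r (line %d): %d duplicate gene symbols removed",
                    name, lineno, len(genes) - len(unique),
                )
            sets.append(PathwayGeneSet(name=name, description=description, genes=unique))
    return sets


def write_gmt(path, gene_sets: Iterable[PathwayGeneSet]) -> None:
    with _open_text(path, "wt") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# shRNA library table
# ---------------------------------------------------------------------------

def read_shrna_library(path) -> list[ShrnaLibraryRecord]:
    """Read a library TSV with columns shrna_id, barcode, gene (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"shrna_id", "barcode", "gene"}
    if missing := required - set(df.columns):
        raise ParseError(f"library table missing columns: {sorted(missing)}", path=path)
    if df["shrna_id"].duplicated().any():
        dups = sorted(df.loc[df["shrna_id"].duplicated(), "shrna_id"])
        raise ValidationError(f"duplicate shRNA IDs in library: {dups[:10]}")
    return [
        ShrnaLibraryRecord(shrna_id=r.shrna_id, barcode=r.barcode, gene=r.gene)
        for r in df.itertuples(index=False)
    ]


def write_shrna_library(path, library: Iterable[ShrnaLibraryRecord]) -> None:
    df = pd.DataFrame(
        [(r.shrna_id, r.barcode, r.gene) for r in library],
        columns=["shrna_id", "barcode", "gene"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str,
                                               "batch": str, "dose": str})
    if "dose" not in sheet.columns:
        sheet["dose"] = pd.NA
    validate_sample_sheet(sheet)
    return sheet


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    cols = [c for c in SAMPLESHEET_COLUMNS if c in sheet.columns]
    sheet[cols].to_csv(path, sep="\t", index=False)


def read_expression_matrix(matrix_path, samplesheet_path, *,
                           impute_missing: bool = False,
                           scale: str = "raw") -> ExpressionMatrix:
    """Load a probe x sample TSV plus its sample sheet into an ExpressionMatrix.

    The first column is the probe/gene ID; remaining column headers must match
    the sheet's sample_id values exactly (reconciliation error otherwise).
    Missing values are rejected unless ``impute_missing`` (row-mean imputation
    with a logged warning). Non-numeric cells raise a parse error naming the
    offending coordinates.
    """
    sheet = read_sample_sheet(samplesheet_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0,
                      float_precision="round_trip")
    values = raw.apply(pd.to_numeric, errors="coerce")
    # Distinguish non-numeric text from genuinely missing cells
    bad = values.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"non-numeric value {raw.iat[r, c]!r} at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}", path=matrix_path,
        )
    if values.isna().any().any():
        n_missing = int(values.isna().sum().sum())
        if not impute_missing:
            raise DataError(
                f"{n_missing} missing values in {matrix_path}; pass impute_missing=True "
                "to row-mean impute"
            )
        logger.warning("imputing %d missing values with row means", n_missing)
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
    return ExpressionMatrix(values=values, samples=sheet, scale=scale)


def write_expression_matrix(matrix_path, samplesheet_path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    write_sample_sheet(samplesheet_path, matrix.samples)


def collapse_probes_to_genes(matrix: ExpressionMatrix,
                             probe_to_gene: dict[str, str],
                             method: str = "max_mean") -> ExpressionMatrix:
    """Collapse multi-probe genes to one row per gene.

    ``max_mean`` (default) keeps, per gene, the probe with the highest mean
    intensity — the convention for Illumina-style probe-level arrays.
    ``mean`` averages all of a gene's probes instead.
    """
    if method not in ("max_mean", "mean"):
        raise ValidationError(f"unknown collapse method {method!r}")
    values = matrix.values
    genes = pd.Series({p: probe_to_gene.get(p, p) for p in values.index}, name="gene")
    if method == "mean":
        collapsed = values.groupby(genes).mean()
    else:
        means = values.mean(axis=1)
        best = means.groupby(genes).idxmax()
        collapsed = values.loc[best.values]
        collapsed.index = best.index
    n_dropped = len(values) - len(collapsed)
    if n_dropped:
        logger.info("probe collapse (%s): %d probes -> %d genes", method,
                    len(values), len(collapsed))
    return matrix.copy_with(collapsed.sort_index())


# ---------------------------------------------------------------------------
# Interaction / drug tables and JSON truth records
# ---------------------------------------------------------------------------

def read_interaction_table(path) -> pd.DataFrame:
    """TSV of gene-gene interactions: columns gene_a, gene_b, optional type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"gene_a", "gene_b"} - set(df.columns):
        raise ParseError(f"interaction table missing columns: {sorted(missing)}", path=path)
    if "type" not in df.columns:
        df["type"] = "interaction"
    return df


def read_drug_table(path) -> pd.DataFrame:
    """TSV of drug-target records: drug, target, fda_approved (bool), n_trials (int)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"drug", "target"} - set(df.columns):
        raise ParseError(f"drug table missing columns: {sorted(missing)}", path=path)
    if "fda_approved" not in df.columns:
        df["fda_approved"] = "false"
    if "n_trials" not in df.columns:
        df["n_trials"] = "0"
    truthy = {"true": True, "false": False, "1": True, "0": False,
              "yes": True, "no": False}
    flags = df["fda_approved"].str.lower().map(truthy)
    if flags.isna().any():
        lineno = int(flags.index[flags.isna()][0]) + 2  # header + 1-based
        raise ParseError(
            f"fda_approved must be boolean-like, got {df.loc[flags.isna(), 'fda_approved'].iloc[0]!r}",
            path=path, line=lineno,
        )
    df["fda_approved"] = flags
    try:
        df["n_trials"] = df["n_trials"].astype(int)
    except ValueError as exc:
        raise ParseError(f"n_trials must be integer: {exc}", path=path) from exc
    return df


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=default)
        handle.write("\n")


def read_json(path):
    with open(path) as handle:
        return json.load(handle)
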