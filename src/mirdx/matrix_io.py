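"""Tabular I/O for expression matrices, sample metadata, target maps and gene lists.

Canonical on-disk dialect is TSV (CSV accepted via ``sep=","``); missing values
are written as ``NA``.  Expression matrices are feature × sample with the
feature identifier in the first column.  Gene lists are written one symbol per
line with no header (GRP convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

LAYERS = ("miRNA", "mRNA", "protein")
HISTOLOGIES = ("NSCLC", "SCLC", "carcinoid", "normal")
STAGES = ("I", "II", "III", "IV")
CLASSES = ("tumor", "normal")

METADATA_COLUMNS = (
    "class_label",
    "pair_id",
    "histology",
    "stage",
    "radiotherapy",
    "time_months",
    "event",
)


def read_expression(path: str | Path, layer: str = "miRNA", sep: str = "\t") -> pd.DataFrame:
    """Read a feature × sample expression matrix (log2 units).

    Duplicate feature or sample identifiers and ragged rows are rejected.
    Missing cells (``NA``) become NaN, never zero.
    """
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                         keep_default_na=False, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    dup_feat = df.index[df.index.duplicated()].unique().tolist()
    if dup_feat:
        raise FormatError(f"{path}: duplicate feature id(s): {dup_feat}")
    dup_samp = [c for c in df.columns[df.columns.duplicated()]]
    if dup_samp:
        raise FormatError(f"{path}: duplicate sample id(s): {dup_samp}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    if np.isinf(values.to_numpy(dtype=float, na_value=np.nan)).any():
        raise FormatError(f"{path}: non-finite expression value")
    values.index = values.index.astype(str)
    values.index.name = "feature_id"
    values.columns = values.columns.astype(str)
    values.attrs["layer"] = layer
    return values


def write_expression(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write an expression matrix, missing values as ``NA``, 6-decimal precision."""
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%.6f")


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata keyed by ``sample_id``.

    Enumerated columns are validated; columns outside the schema are dropped
    with a logged warning.  ``event`` requires ``time_months``.
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    extra = [c for c in df.columns if c != "sample_id" and c not in METADATA_COLUMNS]
    if extra:
        log.warning("%s: ignoring columns outside metadata schema: %s", path, extra)
        df = df.drop(columns=extra)
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample id(s): {dups}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(METADATA_COLUMNS)]
    df["time_months"] = pd.to_numeric(df["time_months"], errors="raise")
    for col in ("radiotherapy", "event"):
        bad = df[col].dropna()[~df[col].dropna().isin(["0", "1", "True", "False", "true", "false"])]
        if len(bad):
            raise FormatError(f"{path}: column {col} must be boolean, got {bad.iloc[0]!r}")
        df[col] = df[col].map({"1": True, "True": True, "true": True,
                               "0": False, "False": False, "false": False})
    validate_metadata(df)
    return df


def validate_metadata(meta: pd.DataFrame) -> None:
    """Enforce the metadata invariants (enums, pairing, survival consistency)."""
    bad_class = meta["class_label"].dropna()[~meta["class_label"].dropna().isin(CLASSES)]
    if len(bad_class):
        raise ValidationError(
            f"unknown class_label {bad_class.iloc[0]!r}; accepted values: {CLASSES}")
    bad_hist = meta["histology"].dropna()[~meta["histology"].dropna().isin(HISTOLOGIES)]
    if len(bad_hist):
        raise ValidationError(
            f"unknown histology {bad_hist.iloc[0]!r}; accepted values: {HISTOLOGIES}")
    bad_stage = meta["stage"].dropna()[~meta["stage"].dropna().isin(STAGES)]
    if len(bad_stage):
        raise ValidationError(
            f"unknown stage {bad_stage.iloc[0]!r}; accepted values: {STAGES}")
    has_event = meta["event"].notna() & meta["event"].astype("boolean").fillna(False)
    if (has_event & meta["time_months"].isna()).any():
        sid = meta.index[has_event & meta["time_months"].isna()][0]
        raise ValidationError(f"sample {sid!r} has event=1 but no time_months")
    if (meta["time_months"].dropna() < 0).any():
        raise ValidationError("time_months must be >= 0")
    paired = meta[meta["pair_id"].notna()]
    for pid, grp in paired.groupby("pair_id"):
        classes = sorted(grp["class_label"].tolist())
        if classes != ["normal", "tumor"]:
            raise ValidationError(
                f"pair_id {pid!r} must occur on exactly one tumor and one normal "
                f"sample, found classes {classes}")


def write_metadata(meta: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    out = meta.copy()
    for col in ("radiotherapy", "event"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def read_target_map(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a miRNA → gene target map with columns (mirna_id, gene_id, source)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"mirna_id", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: target map needs columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    dup = df.duplicated(subset=["mirna_id", "gene_id"])
    if dup.any():
        df = df[~dup].reset_index(drop=True)
        log.warning("%s: dropped %d duplicate (mirna, gene) records", path, int(dup.sum()))
    return df[["mirna_id", "gene_id", "source"]]


def write_gene_lists(lists: "SignatureLists", out_dir: str | Path) -> list[Path]:
    """Write one GRP file per list (``<label>_up.grp`` / ``<label>_down.grp``).

    One gene symbol per line, no header; duplicates removed keeping first
    occurrence; input order preserved.  Empty lists produce empty files with a
    logged warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix, genes in (("up", lists.up), ("down", lists.down)):
        dedup = list(dict.fromkeys(genes))
        if not dedup:
            log.warning("gene list %s_%s is empty", lists.label, suffix)
        path = out_dir / f"{lists.label}_{suffix}.grp"
        path.write_text("".join(g + "\n" for g in dedup))
        written.append(path)
    return written


def read_drug_panel(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format drug-response table (cell_line, drug, measure, value, source)."""
    df = pd.read_csv(path, sep=sep, dtype={"cell_line": str, "drug": str,
                                           "measure": str, "source": str})
    required = {"cell_line", "drug", "measure", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: drug panel needs columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return df[["cell_line", "drug", "measure", "value", "source"]]


def write_drug_panel(panel: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    panel.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.6f")
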