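"""Readers and writers for the pipeline's plain-text formats.

Canonical dialect is TSV with row keys in the first column (CSV via
``sep=","``). Gene sets use the GMT dialect (name, description, then gene ids,
tab-separated). Every pipeline run also emits a JSON audit record carrying the
package version, the configuration echo and its hash, and the RNG seed, so that
equal seed + config reruns are byte-identical and attributable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import (
    FormatError,
    GeneSignature,
    RawCountMatrix,
    ValidationError,
    validate_annotation,
    validate_design,
)

logger = logging.getLogger(__name__)

# Fixed float formatting keeps writes reproducible byte-for-byte.
FLOAT_FORMAT = "%.10g"


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a keyed table (first column is the row key)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def _read_counts(path: str | Path, sep: str) -> pd.DataFrame:
    counts = read_table(path, sep=sep)
    vals = counts.apply(pd.to_numeric, errors="coerce")
    bad_rows = vals.isna().any(axis=1) | counts.isna().any(axis=1)
    if bad_rows.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad_rows.to_numpy())]
        raise FormatError(
            f"{path}: non-numeric counts at line(s) {lines[:20]}"
        )
    arr = vals.to_numpy()
    nonint = ~np.isclose(arr, np.round(arr)) | (arr < 0)
    if nonint.any():
        lines = [int(i) + 2 for i in np.flatnonzero(nonint.any(axis=1))]
        raise FormatError(
            f"{path}: negative or non-integer counts at line(s) {lines[:20]}"
        )
    return vals.round().astype(np.int64)


def read_count_matrix(
    counts_path: str | Path,
    annotation_path: str | Path,
    design_path: str | Path,
    sep: str = "\t",
) -> RawCountMatrix:
    """Read and cross-validate a probe × sample count matrix.

    Validation failures enumerate every offending probe or sample id.
    """
    counts = _read_counts(counts_path, sep)
    annotation = read_table(annotation_path, sep=sep)
    design = read_table(design_path, sep=sep)
    return RawCountMatrix(counts=counts, annotation=annotation, design=design)


def write_count_matrix(
    raw: RawCountMatrix,
    counts_path: str | Path,
    annotation_path: str | Path,
    design_path: str | Path,
    sep: str = "\t",
) -> None:
    write_table(raw.counts, counts_path, sep=sep)
    write_table(raw.annotation, annotation_path, sep=sep)
    write_table(raw.design, design_path, sep=sep)


def read_gene_sets(path: str | Path) -> list[GeneSignature]:
    """Read a GMT file: one signature per line (name, description, genes...).

    Duplicate genes within a line are collapsed with a logged warning; an empty
    line or a line with fewer than 3 fields is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    signatures: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            fields = line.split("\t")
            if line.strip() == "" or len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: no gene ids")
            signatures.append(
                GeneSignature.from_genes(name, genes, description=description)
            )
    return signatures


def write_gene_sets(signatures: list[GeneSignature], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sig in signatures:
            if len(sig) == 0:
                raise ValidationError(f"cannot write empty signature {sig.name!r}")
            desc = sig.description or "-"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_audit(path: str | Path, config: dict, seed: int | None) -> dict:
    """Write the JSON audit record for a pipeline stage; returns the record."""
    record = {
        "package": "screensig",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": config_hash(config),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return record
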