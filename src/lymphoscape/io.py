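"""Readers and writers for the formats the pipeline touches.

Expression matrices come as tab-separated text (gene rows, sample columns,
header row of sample IDs) or as GCT 1.2. Gene signatures come as GMT with the
direction of a set encoded in its name: a ``_up`` / ``_down`` suffix (or an
``up``/``down`` token in the description field as a fallback). Gene IDs are
treated as opaque strings throughout; symbol/Ensembl mapping is the caller's
responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("lymphoscape")

__all__ = [
    "ExpressionMatrix",
    "Signature",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with IDs and optional subtype labels.

    Invariants: unique gene and sample IDs, finite values, dimensions of
    ``values`` matching the ID lists. Violations raise ``ValueError`` at
    construction time.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} ID: {i!r}")
                seen.add(i)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.sample_labels is not None:
            unknown = set(self.sample_labels) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def labels_array(self) -> np.ndarray:
        """Subtype label per sample, in sample order."""
        if self.sample_labels is None:
            raise ValueError("matrix carries no sample labels")
        return np.array([self.sample_labels[s] for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), np.array(values),
            dict(self.sample_labels) if self.sample_labels else None,
        )


@dataclass(frozen=True)
class Signature:
    """A directional gene set (e.g. a literature classifier's *_up half)."""

    name: str
    direction: str  # "up" or "down"
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))


def _check_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Parse cells to float (correctly rounded, so write->read round-trips
    bit-exactly), raising with the row/column of the first bad cell."""
    raw = df.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for g in range(raw.shape[0]):
        for s in range(raw.shape[1]):
            cell = raw[g, s]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or (isinstance(cell, str) and not cell.strip()):
                out[g, s] = np.nan
                continue
            try:
                out[g, s] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[g]!r}, sample {df.columns[s]!r}"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _finish(df: pd.DataFrame, path: str, impute_missing: bool) -> ExpressionMatrix:
    df = _check_numeric(df, path)
    if df.isna().any().any():
        if not impute_missing:
            g, s = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at gene {df.index[g]!r}, sample "
                f"{df.columns[s]!r} (pass impute_missing=True to impute by gene mean)"
            )
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
        logger.warning("%s: imputed missing entries by gene mean", path)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def read_expression(path: str | Path, format: str | None = None,
                    impute_missing: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    ``format`` is inferred from the extension when omitted (.gct -> gct,
    anything else -> tsv). Row and column order are preserved from the file.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        return _finish(df, str(path), impute_missing)
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: expected GCT 1.2 header, got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", dtype=str)
        if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
            raise ValueError(
                f"{path}: GCT dimension line declares {n_rows} x {n_cols} but the "
                f"matrix holds {df.shape[0]} x {df.shape[1] - 2}"
            )
        df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
        df.index = df.index.astype(str)
        return _finish(df, str(path), impute_missing)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(em: ExpressionMatrix, path: str | Path,
                     format: str | None = None) -> None:
    """Write TSV or GCT 1.2 with full float precision (round-trip exact)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    frame = em.to_frame()
    if format == "tsv":
        frame.to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.n_genes}\t{em.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(em.sample_ids) + "\n")
            for g, row in zip(em.gene_ids, em.values):
                fh.write(g + "\tna\t" + "\t".join("%.17g" % v for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def _direction_of(name: str, description: str) -> str:
    low = name.lower()
    if low.endswith("_up"):
        return "up"
    if low.endswith("_down"):
        return "down"
    tokens = description.lower().split()
    if "down" in tokens:
        return "down"
    if "up" in tokens:
        return "up"
    logger.warning("signature %r: no direction token found, assuming 'up'", name)
    return "up"


def read_gmt(path: str | Path) -> list[Signature]:
    """Read signatures from a GMT file (name, description, gene IDs...).

    Duplicate genes within a line are collapsed with a logged warning; a line
    with fewer than three fields or an empty gene list is a hard error.
    """
    sigs: list[Signature] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            tokens = [t for t in fields[2:] if t.strip()]
            genes = set(tokens)
            if len(genes) < len(tokens):
                logger.warning("%s:%d: %d duplicate gene(s) collapsed in %r",
                               path, lineno, len(tokens) - len(genes), name)
            if not genes:
                raise ValueError(f"{path}:{lineno}: signature {name!r} has no genes")
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate signature name {name!r}")
            names.add(name)
            sigs.append(Signature(name, _direction_of(name, description),
                                  frozenset(genes), provenance=description))
    return sigs


def write_gmt(sigs: list[Signature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            desc = sig.provenance or sig.direction
            fh.write(sig.name + "\t" + desc + "\t" + "\t".join(sorted(sig.genes)) + "\n")
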