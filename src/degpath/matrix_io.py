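"""Tabular I/O for expression matrices, study designs, gene sets and result tables.

The central container is :class:`ExpressionMatrix`: a gene-by-sample block of
intensities (raw fluorescence units, or log2 units after normalization) with an
optional parallel block of per-value detection/quality scores in [0, 1], as
produced by bead-array scanners. Gene identifiers are HGNC-style symbols and
are case-normalized to uppercase before any matching, because public gene-set
collections and journal tables mix cases freely.

All files are plain text: TSV with a header row for matrices and results,
CSV/TSV for designs, and the standard GMT dialect for gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_by_quality",
    "collapse_probes",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_results_table",
]

RAW = "raw"
LOG2_CENTERED = "log2_centered"


def _normalize_ids(ids: Iterable[str]) -> list[str]:
    return [str(i).strip().upper() for i in ids]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression values with optional quality scores.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier (uppercase, unique) with one
        column per sample. Raw intensities are arbitrary fluorescence units;
        after :func:`degpath.preprocess.normalize` they are log2 units centered
        to per-sample median zero.
    quality
        Optional DataFrame of the same shape with per-value detection scores
        in [0, 1].
    scale
        Either ``"raw"`` or ``"log2_centered"``.
    """

    values: pd.DataFrame
    quality: pd.DataFrame | None = None
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2_CENTERED):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        idx = list(self.values.index)
        if len(idx) != len(set(idx)):
            dupes = pd.Index(idx)[pd.Index(idx).duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            raise ValidationError("duplicate sample identifiers")
        if self.values.isna().any().any():
            raise ValidationError("expression values contain missing entries")
        if self.quality is not None:
            if self.quality.shape != self.values.shape:
                raise ValidationError(
                    f"quality shape {self.quality.shape} != values shape {self.values.shape}"
                )
            if not (self.quality.index.equals(self.values.index)
                    and self.quality.columns.equals(self.values.columns)):
                raise ValidationError("quality gene/sample labels differ from values")
            q = self.quality.to_numpy()
            if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
                raise ValidationError("quality scores must lie in [0, 1]")

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

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Return a matrix restricted to ``keep`` (order preserved as given)."""
        missing = [g for g in keep if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        q = self.quality.loc[list(keep)] if self.quality is not None else None
        return ExpressionMatrix(self.values.loc[list(keep)], q, self.scale)


@dataclass(frozen=True)
class StudyDesign:
    """Assignment of samples to exactly two groups (control vs treatment)."""

    assignments: Mapping[str, str]
    control_label: str
    treatment_label: str

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels != {self.control_label, self.treatment_label}:
            raise ValidationError(
                f"design groups {sorted(labels)} do not match "
                f"({self.control_label!r}, {self.treatment_label!r})"
            )
        if self.control_label == self.treatment_label:
            raise ValidationError("control and treatment labels must differ")
        for label in (self.control_label, self.treatment_label):
            if len(self.samples_for(label)) < 2:
                raise ValidationError(
                    f"group {label!r} has fewer than 2 samples; a t-test needs variance"
                )

    def samples_for(self, label: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == label]

    @property
    def control_samples(self) -> list[str]:
        return self.samples_for(self.control_label)

    @property
    def treatment_samples(self) -> list[str]:
        return self.samples_for(self.treatment_label)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered, named gene sets (KEGG/GO style), members uppercase and unique."""

    sets: "dict[str, tuple[str, tuple[str, ...]]]"  # name -> (description, members)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression matrices


def _read_numeric_tsv(path: str | Path, value_name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV ({exc})") from None
    if raw.columns.isna().any():
        raise ParseError(f"{path}: header row has empty sample names")
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any().any():
        g, s = next(zip(*np.nonzero(bad.to_numpy())))
        raise ParseError(
            f"{path}: non-numeric {value_name} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}: {raw.iat[g, s]!r}"
        )
    if num.isna().any().any():
        g, s = next(zip(*np.nonzero(num.isna().to_numpy())))
        raise ParseError(
            f"{path}: missing {value_name} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} (ragged row?)"
        )
    num.index = _normalize_ids(num.index)
    num.index.name = "gene_id"
    num.columns = [str(c).strip() for c in num.columns]
    dup = pd.Index(num.index)[pd.Index(num.index).duplicated()].unique().tolist()
    if dup:
        raise ValidationError(
            f"{path}: duplicate gene identifiers after case normalization: {dup[:5]}"
        )
    # final conversion through numpy's strtod: correctly rounded to the ulp,
    # unlike the fast pandas parser, so write->read round-trips are exact
    exact = raw.to_numpy(dtype=str).astype(np.float64)
    return pd.DataFrame(exact, index=num.index, columns=num.columns)


def read_expression_matrix(path: str | Path,
                           quality_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a raw expression TSV (gene_id column + one column per sample).

    An optional parallel quality TSV of identical shape supplies per-value
    detection scores. Duplicate gene rows (after uppercasing) are rejected.
    """
    values = _read_numeric_tsv(path, "expression value")
    quality = None
    if quality_path is not None:
        quality = _read_numeric_tsv(quality_path, "quality score")
        quality = quality.reindex(index=values.index, columns=values.columns)
        if quality.isna().any().any():
            raise ValidationError(
                f"{quality_path}: quality table does not cover every gene/sample of {path}"
            )
    return ExpressionMatrix(values, quality, RAW)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            quality_path: str | Path | None = None) -> None:
    """Write values (and optionally quality) as TSV, full float precision."""
    m.values.to_csv(path, sep="\t", index_label="gene_id",
                    float_format="%.17g", lineterminator="\n")
    if quality_path is not None:
        if m.quality is None:
            raise ConfigurationError("matrix has no quality scores to write")
        m.quality.to_csv(quality_path, sep="\t", index_label="gene_id",
                         float_format="%.17g", lineterminator="\n")


def filter_by_quality(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep genes whose quality score is strictly above ``threshold`` in every sample.

    The retained gene count defines the enrichment background size N (the
    "total number of genes measured"). Strict ``>`` and all-sample stringency:
    on one-probe-one-gene arrays a gene is only considered reliably measured
    if it is detected in every hybridization.
    """
    if m.quality is None:
        raise ConfigurationError("quality scores are required for quality filtering")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    keep_mask = (m.quality.to_numpy() > threshold).all(axis=1)
    keep = [g for g, k in zip(m.gene_ids, keep_mask) if k]
    return ExpressionMatrix(m.values.loc[keep], m.quality.loc[keep], m.scale)


def collapse_probes(values: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level, keeping the probe with the
    highest mean intensity per gene (standard max-mean convention)."""
    genes = pd.Series({p: probe_to_gene[p].upper() for p in values.index})
    mean = values.mean(axis=1)
    best = mean.groupby(genes).idxmax()
    out = values.loc[best.values]
    out.index = best.index
    out.index.name = "gene_id"
    return out.sort_index()


# ---------------------------------------------------------------------------
# study designs


def read_design(path: str | Path, control: str,
                treatment: str | None = None) -> StudyDesign:
    """Read a sample_id/group table (CSV or TSV by extension).

    ``control`` names the control group; the remaining label is the treatment
    unless ``treatment`` is given explicitly.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise ParseError(f"{path}: design needs 'sample_id' and 'group' columns")
    assignments = dict(zip(df[cols["sample_id"]].str.strip(),
                           df[cols["group"]].str.strip()))
    if len(assignments) != len(df):
        raise ValidationError(f"{path}: duplicate sample_id in design")
    labels = sorted(set(assignments.values()))
    if control not in labels:
        raise ValidationError(f"{path}: control group {control!r} not among {labels}")
    if treatment is None:
        others = [g for g in labels if g != control]
        if len(others) != 1:
            raise ValidationError(f"{path}: expected exactly two groups, found {labels}")
        treatment = others[0]
    return StudyDesign(assignments, control, treatment)


def write_design(d: StudyDesign, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame({"sample_id": list(d.assignments),
                  "group": list(d.assignments.values())}
                 ).to_csv(path, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member TAB member ..."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = parts[0].strip(), parts[1].strip()
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for member in _normalize_ids(parts[2:]):
                if member and member not in seen:
                    seen.add(member)
                    members.append(member)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, (desc, members) in collection:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables


def write_results_table(rows: Sequence, path: str | Path,
                        columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous sequence of dataclasses/dicts/tuples as a TSV.

    Floats are rendered with 8 significant digits; row order is preserved.
    An empty sequence yields a header-only file (``columns`` required then,
    unless rows is a DataFrame).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif len(rows) == 0:
        if columns is None:
            raise ConfigurationError("columns are required to write an empty table")
        df = pd.DataFrame(columns=list(columns))
    elif is_dataclass(rows[0]):
        df = pd.DataFrame([_flatten_dataclass(r) for r in rows])
    elif isinstance(rows[0], Mapping):
        df = pd.DataFrame(list(rows))
    else:
        if columns is None:
            raise ConfigurationError("columns are required for tuple rows")
        df = pd.DataFrame(list(rows), columns=list(columns))
    if columns is not None and len(df):
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def _flatten_dataclass(obj) -> dict:
    """asdict, but nested dataclasses become dotted columns and sequences join with ';'."""
    out: dict = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if is_dataclass(v):
            for k, sub in _flatten_dataclass(v).items():
                out[f"{f.name}.{k}"] = sub
        elif isinstance(v, (list, tuple)):
            out[f.name] = ";".join(str(x) for x in v)
        else:
            out[f.name] = v
    return out
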