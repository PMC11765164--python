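"""Delimited-text I/O for beta-value matrices, sample metadata and result tables.

Beta values are methylation fractions in [0, 1] (methylated signal over total
signal) as exported from 450K-style array pipelines.  Matrices are held
internally as samples x sites; readers accept either orientation because GEO
series-matrix exports are typically sites x samples.  Missing cells ("NA" or
empty) are represented as NaN, never as zero.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "MethylationMatrix",
    "SampleMetadataTable",
    "DEFAULT_TISSUES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_result_table",
    "read_result_table",
    "read_gene_lookup",
]

#: Tissue vocabulary of the six-tissue degenerative-disease cohort design
#: (brain/Alzheimer's, saliva and whole blood/Parkinson's, kidney, lung,
#: breast/their respective cancers).
DEFAULT_TISSUES: tuple[str, ...] = (
    "brain",
    "saliva",
    "whole blood",
    "kidney",
    "lung",
    "breast",
)

_STATUS_MAP = {
    "0": 0,
    "1": 1,
    "healthy": 0,
    "disease": 1,
    "control": 0,
    "normal": 0,
}


class ValidationError(ValueError):
    """A table violates an invariant (bounds, uniqueness, vocabulary)."""


class ParseError(ValueError):
    """A file could not be interpreted as the expected table."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class MethylationMatrix:
    """Samples x CpG sites matrix of beta values.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    site_ids : sequence of str
        Unique CpG identifiers (e.g. ``"cg16732616"``), one per column.
    betas : ndarray of shape (n_samples, n_sites)
        Methylation fractions in [0, 1]; NaN marks a missing measurement.
    """

    sample_ids: list[str]
    site_ids: list[str]
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        self.betas = np.asarray(self.betas, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.site_ids, "site_id")
        if self.betas.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValidationError(
                f"matrix shape {self.betas.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.site_ids)} sites)"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.betas < 0.0) | (self.betas > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.betas[i, j]!r} outside [0, 1] at "
                f"sample {self.sample_ids[i]!r}, site {self.site_ids[j]!r}"
            )

    # -- conveniences ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_index(self, site_ids: Sequence[str]) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.site_ids)}
        try:
            return np.array([pos[s] for s in site_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown site_id {exc.args[0]!r}") from None

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None

    def subset_sites(self, site_ids: Sequence[str]) -> "MethylationMatrix":
        idx = self.site_index(site_ids)
        return MethylationMatrix(
            list(self.sample_ids), [str(s) for s in site_ids], self.betas[:, idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = self.sample_index(sample_ids)
        return MethylationMatrix(
            [str(s) for s in sample_ids], list(self.site_ids), self.betas[idx, :]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.betas, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.site_ids,
        )


@dataclass
class SampleMetadataTable:
    """Per-sample tissue label and binary health status.

    ``status`` is 0 for healthy, 1 for disease.  The tissue vocabulary is
    declared at construction; labels outside it are rejected.
    """

    frame: pd.DataFrame
    tissue_vocabulary: tuple[str, ...] = DEFAULT_TISSUES

    def __post_init__(self) -> None:
        self.tissue_vocabulary = tuple(self.tissue_vocabulary)
        df = self.frame
        required = {"sample_id", "tissue", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns {sorted(missing)}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad_tissue = ~df["tissue"].isin(self.tissue_vocabulary)
        if bad_tissue.any():
            lab = df.loc[bad_tissue, "tissue"].iloc[0]
            raise ValidationError(
                f"unknown tissue label {lab!r}; vocabulary is "
                f"{list(self.tissue_vocabulary)}"
            )
        df["status"] = [_normalize_status(v) for v in df["status"]]
        if "dataset_id" not in df.columns:
            df["dataset_id"] = ""
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def tissues_present(self) -> list[str]:
        return sorted(set(self.frame["tissue"]))

    def status_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        m = dict(zip(self.frame["sample_id"], self.frame["status"]))
        return np.array([m[s] for s in sample_ids], dtype=int)

    def tissue_for(self, sample_ids: Sequence[str]) -> list[str]:
        m = dict(zip(self.frame["sample_id"], self.frame["tissue"]))
        return [m[s] for s in sample_ids]

    def select(self, tissue: str | None = None, status: int | None = None) -> list[str]:
        """Sample ids matching the given tissue and/or status."""
        df = self.frame
        mask = pd.Series(True, index=df.index)
        if tissue is not None:
            mask &= df["tissue"] == tissue
        if status is not None:
            mask &= df["status"] == status
        return list(df.loc[mask, "sample_id"])


def _normalize_status(value: object) -> int:
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    key = str(value).strip().lower()
    if key in _STATUS_MAP:
        return _STATUS_MAP[key]
    raise ValidationError(f"status {value!r} not interpretable as healthy/disease")


def _sep_for(path: str | os.PathLike, dialect: str | None) -> str:
    if dialect is not None:
        return {"tab": "\t", "tsv": "\t", "comma": ",", "csv": ","}.get(
            dialect, dialect
        )
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(
    path: str | os.PathLike,
    dialect: str | None = None,
    orientation: str = "samples-by-sites",
) -> MethylationMatrix:
    """Read a beta matrix from delimited text.

    The first row holds column identifiers and the first column row
    identifiers.  With ``orientation="sites-by-samples"`` (the usual GEO
    series-matrix layout) the table is transposed on load.  Empty cells and
    ``"NA"`` become NaN.
    """
    if orientation not in ("samples-by-sites", "sites-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: header row holds no identifiers")
    if orientation == "sites-by-samples":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    site_ids = [str(s) for s in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # a cell that held text but failed numeric conversion is a parse error
    bad = numeric.isna() & df.notna() & (df.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at sample "
            f"{sample_ids[i]!r}, site {site_ids[j]!r}"
        )
    return MethylationMatrix(sample_ids, site_ids, numeric.to_numpy(dtype=float))


def write_beta_matrix(
    matrix: MethylationMatrix,
    path: str | os.PathLike,
    dialect: str | None = None,
    orientation: str = "samples-by-sites",
) -> None:
    """Write a beta matrix as delimited text (inverse of :func:`read_beta_matrix`)."""
    sep = _sep_for(path, dialect)
    df = matrix.to_frame()
    if orientation == "sites-by-samples":
        df = df.T
        df.index.name = "site_id"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.12g")


def read_sample_metadata(
    path: str | os.PathLike,
    tissue_vocabulary: Sequence[str] = DEFAULT_TISSUES,
    dialect: str | None = None,
) -> SampleMetadataTable:
    """Read a sample metadata table (columns sample_id, tissue, status)."""
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return SampleMetadataTable(df, tuple(tissue_vocabulary))


def write_sample_metadata(
    table: SampleMetadataTable, path: str | os.PathLike, dialect: str | None = None
) -> None:
    sep = _sep_for(path, dialect)
    table.frame.to_csv(path, sep=sep, index=False)


def _record_to_dict(rec: object) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    if isinstance(rec, Mapping):
        return dict(rec)
    raise TypeError(f"cannot serialize record of type {type(rec).__name__}")


def write_result_table(
    rows: Iterable[object],
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
    dialect: str | None = None,
) -> None:
    """Write homogeneous result records (dataclasses or mappings) as delimited text.

    Column order is the record's own field order (deterministic); an empty
    record set still produces a header-only file when ``columns`` is given.
    """
    sep = _sep_for(path, dialect)
    dicts = [_record_to_dict(r) for r in rows]
    if dicts:
        cols = list(columns) if columns is not None else list(dicts[0])
        df = pd.DataFrame(dicts, columns=cols)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.12g")


def read_result_table(
    path: str | os.PathLike, dialect: str | None = None
) -> pd.DataFrame:
    sep = _sep_for(path, dialect)
    return pd.read_csv(path, sep=sep, na_values=["NA"])


def read_gene_lookup(path: str | os.PathLike, dialect: str | None = None) -> dict[str, str]:
    """Read an optional two-column cpg_id -> gene symbol lookup (pass-through only).

    No annotation is computed; the mapping is merely carried into summary
    outputs when provided.
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: gene lookup needs two columns (cpg_id, gene)")
    first, second = df.columns[:2]
    return dict(zip(df[first].astype(str), df[second].astype(str)))
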