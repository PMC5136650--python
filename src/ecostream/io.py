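"""Readers, writers and validated containers for the four CSV input kinds.

The package exchanges data exclusively through a single strict CSV
dialect: comma separated, UTF-8, ``.`` decimal point, first row a header,
first column row labels.  Four table kinds exist:

``CommunityMatrix``
    rows = samples, columns = species, cells = non-negative abundances
    (counts or biomass).
``AggregationTable``
    rows = species, columns = taxonomic ranks ordered lowest (e.g. genus)
    to highest; cells = category names.  The classification must be
    hierarchical.
``FactorVector``
    rows = samples, one qualitative grouping column.
``EnvMatrix``
    rows = samples, columns = quantitative environmental variables.

Orientation is never guessed: a community file is always rows = samples.
Species matching between community and aggregation tables is by exact
name and any mismatch is a hard error, because distinctness indices
silently change meaning if the species pool shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CommunityMatrix",
    "AggregationTable",
    "FactorVector",
    "EnvMatrix",
    "read_community_csv",
    "read_aggregation_csv",
    "read_factor_csv",
    "read_env_csv",
    "write_community_csv",
    "write_aggregation_csv",
    "write_factor_csv",
    "write_env_csv",
    "align_by_sample",
    "write_square_dist_csv",
    "read_square_dist_csv",
]

# enough digits that float64 round-trips exactly through text
_FLOAT_FMT = ".17g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CommunityMatrix:
    """Samples x species abundance matrix.

    Attributes
    ----------
    sample_ids : list of str
        Row labels, unique, in file order.
    species_ids : list of str
        Column labels, unique, in file order.
    abundance : ndarray of shape (n_samples, n_species)
        Non-negative abundances.
    """

    sample_ids: list[str]
    species_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        self.abundance = np.asarray(self.abundance, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.species_ids, "species")
        if self.abundance.ndim != 2:
            raise ValidationError("abundance must be 2-dimensional")
        n, s = self.abundance.shape
        if n != len(self.sample_ids) or s != len(self.species_ids):
            raise ValidationError("abundance shape does not match labels")
        if n < 1 or s < 2:
            raise ValidationError("need at least 1 sample and 2 species")
        if not np.isfinite(self.abundance).all():
            raise ValidationError("non-numeric or missing abundance cell")
        if (self.abundance < 0).any():
            raise ValidationError("negative abundance cell")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.sample_ids, columns=self.species_ids
        )


@dataclass
class AggregationTable:
    """Species classification across ordered taxonomic ranks.

    ``rank_names`` run from the lowest rank (first column after the
    species name, e.g. genus) to the highest.  The classification must be
    hierarchical: two species sharing a category at some rank share
    categories at every higher rank.
    """

    species_ids: list[str]
    rank_names: list[str]
    labels: np.ndarray  # (S, K) array of category strings

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.rank_names = [str(r) for r in self.rank_names]
        self.labels = np.asarray(self.labels, dtype=object)
        _check_unique(self.species_ids, "species")
        _check_unique(self.rank_names, "rank")
        if self.labels.ndim != 2:
            raise ValidationError("labels must be 2-dimensional")
        s, k = self.labels.shape
        if s != len(self.species_ids) or k != len(self.rank_names):
            raise ValidationError("labels shape does not match ids/ranks")
        if k < 1:
            raise ValidationError("need at least one taxonomic rank")
        for row in range(s):
            for col in range(k):
                cell = self.labels[row, col]
                if cell is None or str(cell).strip() == "" or str(cell) == "nan":
                    raise ValidationError(
                        f"empty classification cell for species "
                        f"{self.species_ids[row]!r} at rank {self.rank_names[col]!r}"
                    )
        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        # sharing a category at rank k must imply sharing at rank k+1;
        # induction then covers all higher ranks
        s, k = self.labels.shape
        for col in range(k - 1):
            parent_of: dict[str, tuple[str, int]] = {}
            for row in range(s):
                cat = str(self.labels[row, col])
                par = str(self.labels[row, col + 1])
                if cat in parent_of:
                    par0, row0 = parent_of[cat]
                    if par0 != par:
                        raise ValidationError(
                            "non-hierarchical classification: species "
                            f"{self.species_ids[row0]!r} and "
                            f"{self.species_ids[row]!r} share "
                            f"{self.rank_names[col]!r}={cat!r} but differ at "
                            f"rank {self.rank_names[col + 1]!r} "
                            f"({par0!r} vs {par!r})"
                        )
                else:
                    parent_of[cat] = (par, row)

    @property
    def n_species(self) -> int:
        return self.labels.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.labels, index=self.species_ids, columns=self.rank_names
        )


@dataclass
class FactorVector:
    """A qualitative grouping of samples (one level string per sample)."""

    sample_ids: list[str]
    levels: list[str]
    name: str = "factor"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.levels = [str(v) for v in self.levels]
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.levels):
            raise ValidationError("factor length does not match sample ids")
        for sid, lev in zip(self.sample_ids, self.levels):
            if lev.strip() == "" or lev == "nan":
                raise ValidationError(f"empty factor level for sample {sid!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_levels(self) -> int:
        return len(set(self.levels))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=object)


@dataclass
class EnvMatrix:
    """Samples x quantitative environmental variables."""

    sample_ids: list[str]
    var_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.var_names = [str(v) for v in self.var_names]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.var_names, "variable")
        if self.values.ndim != 2:
            raise ValidationError("env values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), len(self.var_names)):
            raise ValidationError("env values shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("missing or non-numeric environmental cell")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.var_names
        )


# ---------------------------------------------------------------------------
# readers


def _read_table(path: Union[str, Path], col_kind: str = "column") -> pd.DataFrame:
    # pandas silently renames duplicate header names; check the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(",")
    cols = [c.strip() for c in header[1:]]
    _check_unique(cols, col_kind)
    try:
        df = pd.read_csv(path, index_col=0, header=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse CSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table in {path}")
    return df


def _numeric(df: pd.DataFrame, path, what: str) -> np.ndarray:
    try:
        values = df.to_numpy(dtype=object)
        out = np.empty(values.shape, dtype=float)
        for idx, cell in np.ndenumerate(values):
            text = str(cell).strip()
            if text == "":
                raise ValueError("empty cell")
            out[idx] = float(text)
    except ValueError as exc:
        raise ValidationError(
            f"non-numeric or missing {what} cell in {path} "
            f"(row {df.index[idx[0]]!r}, column {df.columns[idx[1]]!r})"
        ) from exc
    return out


def read_community_csv(path: Union[str, Path]) -> CommunityMatrix:
    """Read an abundance matrix (rows = samples, columns = species)."""
    df = _read_table(path, "species")
    values = _numeric(df, path, "abundance")
    return CommunityMatrix(list(df.index), list(df.columns), values)


def read_aggregation_csv(path: Union[str, Path]) -> AggregationTable:
    """Read a classification aggregation file (rows = species, columns =
    ranks ordered lowest to highest)."""
    df = _read_table(path, "rank")
    return AggregationTable(list(df.index), list(df.columns),
                            df.to_numpy(dtype=object))


def read_factor_csv(path: Union[str, Path], column: str | None = None) -> FactorVector:
    """Read a qualitative factor file; ``column`` picks one of possibly
    several factor columns (default: the first)."""
    df = _read_table(path, "factor")
    if column is None:
        column = df.columns[0]
    elif column not in df.columns:
        raise ValidationError(f"factor column {column!r} not in {path}")
    return FactorVector(list(df.index), list(df[column]), name=str(column))


def read_env_csv(path: Union[str, Path]) -> EnvMatrix:
    """Read a quantitative environmental data file (rows = samples)."""
    df = _read_table(path, "variable")
    values = _numeric(df, path, "environmental")
    return EnvMatrix(list(df.index), list(df.columns), values)


# ---------------------------------------------------------------------------
# writers


def _write_frame(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, float_format=f"%{_FLOAT_FMT}")


def write_community_csv(comm: CommunityMatrix, path: Union[str, Path]) -> None:
    _write_frame(comm.to_frame(), path)


def write_aggregation_csv(agg: AggregationTable, path: Union[str, Path]) -> None:
    _write_frame(agg.to_frame(), path)


def write_factor_csv(factor: FactorVector, path: Union[str, Path]) -> None:
    df = pd.DataFrame({factor.name: factor.levels}, index=factor.sample_ids)
    _write_frame(df, path)


def write_env_csv(env: EnvMatrix, path: Union[str, Path]) -> None:
    _write_frame(env.to_frame(), path)


# ---------------------------------------------------------------------------
# alignment


def align_by_sample(comm: CommunityMatrix,
                    other: Union[FactorVector, EnvMatrix]):
    """Reorder ``other`` to the sample order of ``comm``.

    The two sample id sets must be identical; missing or extra ids are a
    hard error listing the offenders.
    """
    want = comm.sample_ids
    have = other.sample_ids
    missing = sorted(set(want) - set(have))
    extra = sorted(set(have) - set(want))
    if missing or extra:
        raise ValidationError(
            f"sample id mismatch: missing from other file {missing}, "
            f"extra in other file {extra}"
        )
    pos = {s: i for i, s in enumerate(have)}
    order = [pos[s] for s in want]
    if isinstance(other, FactorVector):
        return FactorVector(list(want), [other.levels[i] for i in order],
                            name=other.name)
    if isinstance(other, EnvMatrix):
        return EnvMatrix(list(want), list(other.var_names),
                         other.values[order, :])
    raise TypeError(f"cannot align object of type {type(other).__name__}")


# ---------------------------------------------------------------------------
# square distance matrices (possibly streamed row-block by row-block)


def write_square_dist_csv(
    path: Union[str, Path],
    labels: Sequence[str],
    rows: Union[np.ndarray, Iterable[np.ndarray]],
) -> None:
    """Write a square labelled distance matrix as CSV.

    ``rows`` is either the full square matrix or an iterable of row
    blocks (2-d arrays) whose concatenation is the square matrix; blocks
    are written as they arrive so the full matrix need never be resident.
    Values are written with 17 significant digits so that reading the
    file back reproduces them exactly.
    """
    labels = [str(x) for x in labels]
    n = len(labels)
    if isinstance(rows, np.ndarray):
        if rows.shape != (n, n):
            raise ValidationError(
                f"matrix shape {rows.shape} does not match {n} labels")
        blocks: Iterable[np.ndarray] = (rows,)
    else:
        blocks = rows
    written = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for block in blocks:
            block = np.atleast_2d(np.asarray(block, dtype=float))
            if block.shape[1] != n:
                raise ValidationError(
                    f"block has {block.shape[1]} columns, expected {n}")
            for row in block:
                if written >= n:
                    raise ValidationError("more rows than labels")
                fh.write(labels[written] + ","
                         + ",".join(format(v, _FLOAT_FMT) for v in row) + "\n")
                written += 1
    if written != n:
        raise ValidationError(f"wrote {written} rows for {n} labels")


def read_square_dist_csv(path: Union[str, Path]) -> tuple[list[str], np.ndarray]:
    """Read a square labelled distance matrix; returns (labels, matrix)."""
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        raise ValidationError(
            f"{path}: row and column labels differ; not a square distance matrix")
    values = _numeric(df, path, "distance")
    return list(df.index), values
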