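"""Tabular formats and core data carriers.

The pipeline exchanges three kinds of tables, all plain TSV (CSV accepted on
read, dialect inferred from the file extension):

* expression matrices — genes as rows (gene identifier in the first column),
  samples as columns, signal in arbitrary units (AU); negative
  background-subtracted signals are preserved on read, clamping is an
  analysis stage, not an I/O behaviour;
* sample sheets — one row per sample with its diagnostic group
  (``active_cd`` / ``treated_cd`` / ``control``) and cell population
  (``IEC`` / ``IEL``); extra clinical columns are carried as opaque metadata;
* qPCR CT tables — one row per (gene, sample) with replicate CT columns
  ``ct_rep1..ct_repK``, plus a standard dilution series as (amount_pg, ct).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("iecdeg")

GROUPS = ("active_cd", "treated_cd", "control")
POPULATIONS = ("IEC", "IEL")


class IecdegError(ValueError):
    """Base class for all errors raised by this package."""


class ConfigError(IecdegError):
    """Invalid configuration value."""


class InputError(IecdegError):
    """Invalid or inconsistent input data."""


class ParseError(IecdegError):
    """A file could not be parsed; the message carries the line number."""


class DegenerateReferenceError(IecdegError):
    """A reference profile carries no usable signal."""


class FitError(IecdegError):
    """A model fit failed a sanity constraint (e.g. positive-slope curve)."""


class StateError(IecdegError):
    """An operation was invoked before its prerequisites were computed."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Gene x sample signal matrix in AU with optional sample metadata.

    ``signals`` is indexed by unique gene identifiers (case-sensitive opaque
    strings, HGNC symbols in practice) with unique sample identifiers as
    columns.  ``samples`` — when present — is indexed by sample identifier
    and carries at least ``group`` and ``population`` columns.
    """

    signals: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.signals.index.has_duplicates:
            dup = self.signals.index[self.signals.index.duplicated()][0]
            raise InputError(f"duplicate gene identifier: {dup!r}")
        if self.signals.columns.has_duplicates:
            dup = self.signals.columns[self.signals.columns.duplicated()][0]
            raise InputError(f"duplicate sample identifier: {dup!r}")
        if self.samples is not None:
            missing = self.signals.columns.difference(self.samples.index)
            if len(missing):
                raise InputError(
                    f"samples missing from sample sheet: {list(missing)}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.signals.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.signals.columns

    def subset(self, *, group: str | None = None,
               population: str | None = None) -> "ExpressionMatrix":
        """Columns restricted to samples matching the metadata query."""
        if self.samples is None:
            raise StateError("subset() requires sample metadata")
        keep = pd.Series(True, index=self.samples.index)
        if group is not None:
            keep &= self.samples["group"] == group
        if population is not None:
            keep &= self.samples["population"] == population
        ids = [s for s in self.sample_ids if keep.get(s, False)]
        return ExpressionMatrix(self.signals[ids],
                                self.samples.loc[ids])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.signals.copy(),
            None if self.samples is None else self.samples.copy(),
        )


def read_matrix(path: str | Path,
                samples: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a gene x sample TSV/CSV matrix.

    Finite values, including negatives, round-trip losslessly through
    :func:`write_matrix`.  Duplicate gene identifiers, ragged rows and
    non-numeric cells are rejected with the offending line number.
    """
    path = Path(path)
    sep = _sep_for(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          skip_blank_lines=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene identifier {dup!r}")
    data = {}
    for col in raw.columns:
        try:
            data[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
            row = int(np.where(bad.isna() & raw[col].notna())[0][0])
            # +2: 1-based line numbering plus the header line
            raise ParseError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} in column "
                f"{col!r}, line {row + 2}"
            ) from None
    signals = pd.DataFrame(data, index=raw.index)
    signals.index.name = "gene_id"
    return ExpressionMatrix(signals, samples)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.signals.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet indexed by sample_id, with controlled-vocabulary checks."""
    path = Path(path)
    sheet = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample_id", "group", "population"):
        if col not in sheet.columns:
            raise ParseError(f"{path}: sample sheet lacks column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample identifier {dup!r}")
    bad_group = set(sheet["group"]) - set(GROUPS)
    if bad_group:
        raise ParseError(f"{path}: unknown group value(s) {sorted(bad_group)}")
    bad_pop = set(sheet["population"]) - set(POPULATIONS)
    if bad_pop:
        raise ParseError(f"{path}: unknown population value(s) {sorted(bad_pop)}")
    return sheet.set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(Path(path), sep=_sep_for(Path(path)), index_label="sample_id")


@dataclass
class QpcrTable:
    """CT measurements: one row per (gene, sample), replicate CT columns.

    ``ct`` has columns ``gene_id``, ``sample_id``, ``ct_rep1..ct_repK``
    (missing replicates as NaN); ``samples`` is metadata indexed by
    sample_id with at least a ``group`` column.
    """

    ct: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("gene_id", "sample_id"):
            if col not in self.ct.columns:
                raise InputError(f"CT table lacks column {col!r}")
        if not self.replicate_columns:
            raise InputError("CT table has no ct_rep* columns")
        reps = self.ct[self.replicate_columns]
        if (reps.notna().sum(axis=1) < 1).any():
            raise InputError("every (gene, sample) row needs >=1 replicate CT")
        if (reps.stack() <= 0).any():
            raise InputError("CT values must be positive cycles")

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.ct.columns if c.startswith("ct_rep")]

    def mean_ct(self) -> pd.DataFrame:
        """Replicates collapsed to their arithmetic mean per (gene, sample)."""
        out = self.ct[["gene_id", "sample_id"]].copy()
        out["ct"] = self.ct[self.replicate_columns].mean(axis=1)
        return out

    def genes(self) -> list[str]:
        return list(pd.unique(self.ct["gene_id"]))


def read_qpcr_table(path: str | Path,
                    samples: pd.DataFrame | None = None) -> QpcrTable:
    path = Path(path)
    ct = pd.read_csv(path, sep=_sep_for(path))
    return QpcrTable(ct, samples)


def write_qpcr_table(table: QpcrTable, path: str | Path) -> None:
    table.ct.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def read_standard_series(path: str | Path) -> pd.DataFrame:
    """Dilution series as rows of (amount_pg, ct), one row per replicate."""
    path = Path(path)
    series = pd.read_csv(path, sep=_sep_for(path))
    for col in ("amount_pg", "ct"):
        if col not in series.columns:
            raise ParseError(f"{path}: standard series lacks column {col!r}")
    return series


def write_standard_series(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def split_case_ctrl(matrix: ExpressionMatrix,
                    case_group: str = "active_cd",
                    ctrl_group: str = "control",
                    population: str = "IEC",
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split one matrix-plus-sheet into case and control IEC matrices."""
    case = matrix.subset(group=case_group, population=population)
    ctrl = matrix.subset(group=ctrl_group, population=population)
    if case.signals.shape[1] == 0:
        raise InputError(f"no {population} samples in group {case_group!r}")
    if ctrl.signals.shape[1] == 0:
        raise InputError(f"no {population} samples in group {ctrl_group!r}")
    return case, ctrl
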