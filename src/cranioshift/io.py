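"""Measurement-table data model, variable registry and CSV input/output.

Tables hold linear cranial measurements (mm), one row per specimen, with
columns keyed by Martin numbers. Missing cells are carried as an explicit
boolean mask (``NaN`` in the value matrix). Files are plain CSV with a
header row; blank cells and the literal string ``NA`` both denote missing
values on read, and blanks are written back out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical measurement order per skull element. Reports, loading signs and
#: file output are stable because internal column order always follows this.
VAULT_CODES: tuple[str, ...] = ("M1", "M5", "M8", "M9", "M11", "M12", "M17")
FACE_CODES: tuple[str, ...] = ("M40", "M45", "M48", "M51", "M52", "M54", "M55")
ALL_CODES: tuple[str, ...] = (
    "M1", "M5", "M8", "M9", "M11", "M11b", "M12", "M17",
    "M40", "M45", "M48", "M51", "M52", "M54", "M55",
)

PERIODS = ("pre", "post")
META_COLUMNS = ("specimen_id", "region", "period")
#: Optional passthrough columns kept alongside the measurements.
PASSTHROUGH_COLUMNS = ("sex",)

MISSING_SENTINELS = ("", "NA")


@dataclass(frozen=True)
class Variable:
    """One registered cranial measurement."""

    code: str
    name: str
    element: str  # "vault" or "face"
    definition: str


class VariableRegistry:
    """Registry of the 15 supported Martin-number measurements.

    The registry fixes the canonical variable order and resolves the
    element/region-specific 7-variable sets, including the substitution of
    biradicular breadth (M11b) for biauricular breadth (M11) in Levant
    vault data, where inferior vault breadth was recorded differently.
    """

    def __init__(self, variables: Iterable[Variable]):
        entries = list(variables)
        codes = [v.code for v in entries]
        if sorted(codes) != sorted(ALL_CODES):
            missing = set(ALL_CODES) - set(codes)
            extra = set(codes) - set(ALL_CODES)
            raise ValueError(
                f"registry must contain exactly the {len(ALL_CODES)} supported "
                f"codes; missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for v in entries:
            if v.element not in ("vault", "face"):
                raise ValueError(f"unknown element {v.element!r} for {v.code}")
        self._by_code = {v.code: v for v in entries}

    @classmethod
    def default(cls) -> "VariableRegistry":
        """Load the registry shipped with the package."""
        with resources.files("cranioshift.data").joinpath("variables.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls(Variable(r.code, r.name, r.element, r.definition) for r in df.itertuples())

    def __getitem__(self, code: str) -> Variable:
        return self._by_code[code]

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    @property
    def codes(self) -> tuple[str, ...]:
        return ALL_CODES

    def partition_codes(self, element: str, region: str | None = None) -> tuple[str, ...]:
        """Canonical 7-variable set for an element, after the region-specific
        M11/M11b choice (Levant vaults use M11b in the M11 slot)."""
        if element == "vault":
            if region is not None and region.strip().lower() == "levant":
                return tuple("M11b" if c == "M11" else c for c in VAULT_CODES)
            return VAULT_CODES
        if element == "face":
            return FACE_CODES
        raise ValueError(f"element must be 'vault' or 'face', got {element!r}")


@dataclass
class MeasurementTable:
    """Specimens x variables measurement matrix with missingness mask.

    ``values`` holds measurements in mm with ``NaN`` at missing cells;
    ``missing_mask`` is True exactly where no value is recorded. Observed
    values must be strictly positive and finite, and specimen ids unique.
    """

    specimen_id: np.ndarray
    region: np.ndarray
    period: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    variable_codes: tuple[str, ...]
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.specimen_id = np.asarray(self.specimen_id, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        self.period = np.asarray(self.period, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.variable_codes = tuple(self.variable_codes)
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.variable_codes) != p:
            raise ValueError("variable_codes length does not match value matrix")
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape does not match value matrix")
        for arr, name in ((self.specimen_id, "specimen_id"),
                          (self.region, "region"), (self.period, "period")):
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match value matrix")
        ids, counts = np.unique(self.specimen_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dups = ids[counts > 1].tolist()
            raise ValueError(f"duplicate specimen_id values: {dups}")
        bad_period = sorted(set(self.period) - set(PERIODS))
        if bad_period:
            raise ValueError(
                f"unknown period labels {bad_period}; expected one of {list(PERIODS)}"
            )
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("NaN value in a cell not flagged missing")
        observed = self.values[~self.missing_mask]
        if observed.size:
            if not np.isfinite(observed).all() or (observed <= 0).any():
                i, j = self._first_bad_cell()
                raise ValueError(
                    f"non-positive or non-finite measurement for specimen "
                    f"{self.specimen_id[i]!r}, variable {self.variable_codes[j]}"
                )
        # masked cells are canonically NaN
        self.values[self.missing_mask] = np.nan

    def _first_bad_cell(self) -> tuple[int, int]:
        bad = (~self.missing_mask) & ~((self.values > 0) & np.isfinite(self.values))
        i, j = np.argwhere(bad)[0]
        return int(i), int(j)

    # -- convenience -------------------------------------------------------

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(
            self.specimen_id.copy(), self.region.copy(), self.period.copy(),
            self.values.copy(), self.missing_mask.copy(), self.variable_codes,
            None if self.extra is None else self.extra.copy(),
        )

    def subset_rows(self, index: np.ndarray) -> "MeasurementTable":
        return MeasurementTable(
            self.specimen_id[index], self.region[index], self.period[index],
            self.values[index], self.missing_mask[index], self.variable_codes,
            None if self.extra is None else self.extra.iloc[index].reset_index(drop=True),
        )

    def subset_period(self, period: str) -> "MeasurementTable":
        if period not in PERIODS:
            raise ValueError(f"unknown period {period!r}")
        return self.subset_rows(np.flatnonzero(self.period == period))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "specimen_id": self.specimen_id,
            "region": self.region,
            "period": self.period,
        })
        if self.extra is not None:
            for col in self.extra.columns:
                df[col] = self.extra[col].to_numpy()
        for j, code in enumerate(self.variable_codes):
            df[code] = self.values[:, j]
        return df


def read_measurements(
    path: str | Path,
    registry: VariableRegistry | None = None,
) -> MeasurementTable:
    """Read a measurement CSV into a :class:`MeasurementTable`.

    The file needs ``specimen_id``, ``region`` and ``period`` columns plus
    any subset of the registered Martin-code columns. Blank cells and "NA"
    are treated as missing. Unregistered columns (other than the optional
    passthroughs, e.g. ``sex``) are ignored with a warning.
    """
    registry = registry or VariableRegistry.default()
    df = pd.read_csv(
        path, dtype={c: str for c in META_COLUMNS + PASSTHROUGH_COLUMNS},
        na_values=list(MISSING_SENTINELS), keep_default_na=False,
    )
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} absent from {path}")

    codes = [c for c in registry.codes if c in df.columns]
    known = set(META_COLUMNS) | set(PASSTHROUGH_COLUMNS) | set(codes)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown columns in %s: %s", path, unknown)

    values = df[codes].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    mask = np.isnan(values)
    extra_cols = [c for c in PASSTHROUGH_COLUMNS if c in df.columns]
    extra = df[extra_cols].reset_index(drop=True) if extra_cols else None
    return MeasurementTable(
        specimen_id=df["specimen_id"].to_numpy(dtype=object),
        region=df["region"].to_numpy(dtype=object),
        period=df["period"].to_numpy(dtype=object),
        values=values, missing_mask=mask, variable_codes=tuple(codes),
        extra=extra,
    )


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a table to CSV; missing cells become empty strings."""
    table.to_frame().to_csv(path, index=False, na_rep="")


def select_partition(
    table: MeasurementTable,
    registry: VariableRegistry,
    element: str,
    region: str,
) -> MeasurementTable:
    """Restrict a table to one region and its 7-variable element set.

    Variable order follows the canonical registry order; for Levant vault
    data M11b replaces M11. Raises if any required column is absent.
    """
    codes = registry.partition_codes(element, region)
    missing = [c for c in codes if c not in table.variable_codes]
    if missing:
        raise ValueError(
            f"columns required for {element}/{region} absent: {missing}"
        )
    col_idx = [table.variable_codes.index(c) for c in codes]
    row_idx = np.flatnonzero(table.region == region)
    if row_idx.size == 0:
        raise ValueError(f"no specimens with region {region!r}")
    sub = table.subset_rows(row_idx)
    return MeasurementTable(
        sub.specimen_id, sub.region, sub.period,
        sub.values[:, col_idx], sub.missing_mask[:, col_idx], codes,
        extra=sub.extra,
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table (or any tabular artifact) to CSV at full precision."""
    scores.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in META_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def write_report(result, path: str | Path) -> None:
    """Write a per-axis, per-statistic comparison report to CSV.

    ``result`` is a :class:`cranioshift.compare.ComparisonResult`; one row
    per (axis, statistic) with the pre-group value, its estimation-error
    interval, the subsampled post-group interval and the overlap flag.
    """
    result.to_frame().to_csv(path, index=False)
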