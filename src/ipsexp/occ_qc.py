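"""Occurrence-record cleaning and the minimum-record species filter.

Cleaning applies five rules in a fixed, documented order:

1. ``bad_name`` — the raw name fails the validity predicate (pluggable;
   default is a regex accepting binomial-style names);
2. ``invalid_coordinate`` — non-numeric or out-of-range lon/lat (an artifact
   addition, tallied separately; it must run before any coordinate rule);
3. ``zero_zero`` — both longitude and latitude exactly 0;
4. ``lon_eq_lat`` — longitude equals latitude exactly (including negative
   pairs);
5. ``cell_duplicate`` — a second record of the same species in the same grid
   cell; the first record in input order is kept.

A record failing several rules is tallied once, under the earliest rule in
this order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "RULES",
    "QcReport",
    "default_name_validator",
    "clean_occurrences",
    "filter_species",
]

RULES: tuple[str, ...] = (
    "bad_name",
    "invalid_coordinate",
    "zero_zero",
    "lon_eq_lat",
    "cell_duplicate",
)

_NAME_RE = re.compile(r"^[A-Z][a-z]+(?: [a-z][a-z0-9.\-]*)+$")


def default_name_validator(name: object) -> bool:
    """Accept binomial-style names: capitalised genus + lowercase epithet(s)."""
    return isinstance(name, str) and bool(_NAME_RE.match(name))


@dataclass
class QcReport:
    """Tallies from cleaning and/or species filtering.

    ``rule_counts`` gives removals per rule; ``species_counts`` has one row
    per species with per-rule removals, input and retained counts.  After
    :func:`filter_species`, ``retained_species`` / ``dropped_species`` list
    the species kept or dropped by the minimum-record rule.
    """

    rule_counts: dict[str, int] = field(default_factory=dict)
    species_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    retained_species: list[str] = field(default_factory=list)
    dropped_species: list[str] = field(default_factory=list)
    min_records: int | None = None

    @property
    def n_removed(self) -> int:
        return int(sum(self.rule_counts.values()))

    def to_frame(self) -> pd.DataFrame:
        return self.species_counts.reset_index(names="species")


def clean_occurrences(
    table: pd.DataFrame,
    grid: GridSpec,
    name_validator: Callable[[object], bool] = default_name_validator,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the cleaning rules; return the cleaned table and a report.

    The input must have columns ``species, lon, lat`` and optionally
    ``name_raw`` (when absent, ``species`` is validated instead).  Cleaning
    is idempotent and the per-rule counts are invariant to input order; only
    the identity of the kept cell-duplicate representative depends on order
    ("keep first in input order").
    """
    df = table.copy()
    n = len(df)
    empty = pd.DataFrame({r: pd.Series(dtype=int) for r in RULES})
    if n == 0:
        report = QcReport(rule_counts={r: 0 for r in RULES}, species_counts=empty)
        return df, report

    names = df["name_raw"] if "name_raw" in df.columns else df["species"]
    lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy(dtype=float)

    reason = np.full(n, "", dtype=object)

    bad_name = ~names.map(name_validator).to_numpy(dtype=bool)
    reason[bad_name] = "bad_name"

    invalid = np.isnan(lon) | np.isnan(lat) | (np.abs(lon) > 180) | (np.abs(lat) > 90)
    reason[invalid & (reason == "")] = "invalid_coordinate"

    zero_zero = (lon == 0.0) & (lat == 0.0)
    reason[zero_zero & (reason == "")] = "zero_zero"

    lon_eq_lat = lon == lat
    reason[lon_eq_lat & (reason == "")] = "lon_eq_lat"

    # cell duplicates among records still alive, per species, keep first;
    # NaNs are already dead but must not crash the integer cast
    alive = reason == ""
    row_idx, col_idx = grid.cell_of(np.nan_to_num(lon), np.nan_to_num(lat))
    key = pd.DataFrame(
        {"species": df["species"].to_numpy(), "row": row_idx, "col": col_idx}
    )
    alive_key = key[alive]
    dup_alive = alive_key.duplicated(keep="first").to_numpy()
    dup = np.zeros(n, dtype=bool)
    dup[np.nonzero(alive)[0][dup_alive]] = True
    reason[dup] = "cell_duplicate"

    removed = reason != ""
    rule_counts = {r: int((reason == r).sum()) for r in RULES}

    per_species = (
        pd.DataFrame({"species": df["species"].to_numpy(), "reason": reason})
        .groupby("species")["reason"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for r in RULES:
        if r not in per_species.columns:
            per_species[r] = 0
    species_counts = per_species[list(RULES)].copy()
    species_counts["input"] = df.groupby("species").size()
    species_counts["retained"] = (
        species_counts["input"] - species_counts[list(RULES)].sum(axis=1)
    )

    cleaned = df.loc[~removed].copy()
    report = QcReport(rule_counts=rule_counts, species_counts=species_counts)
    return cleaned, report


def filter_species(
    table: pd.DataFrame,
    min_records: int = 100,
    strict: bool = True,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop species with too few cleaned records.

    With ``strict=True`` (default) a species needs *more than*
    ``min_records`` records to be kept ("over 100" read as > 100); with
    ``strict=False`` exactly ``min_records`` suffices.
    """
    if len(table) == 0:
        return table.copy(), QcReport(min_records=min_records)
    counts = table.groupby("species").size()
    keep = counts > min_records if strict else counts >= min_records
    retained = sorted(counts.index[keep])
    dropped = sorted(counts.index[~keep])
    out = table[table["species"].isin(retained)].copy()
    report = QcReport(
        species_counts=counts.to_frame("retained"),
        retained_species=retained,
        dropped_species=dropped,
        min_records=min_records,
    )
    return out, report
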