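"""Production-panel I/O and aggregation.

The substrate of every analysis in this package is a *production panel*: a
tidy table of annual aquaculture production records keyed by
(year, country, species, environment).  Panels are read either from the
package's own tidy CSV schema or from FAO FishStatJ-style wide exports
(descriptor columns followed by one column per year).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("marine", "brackish", "freshwater", "unknown")
GROUPS = ("fish", "bivalve", "crustacean", "alga", "other")

#: canonical tidy-CSV column order
TIDY_COLUMNS = [
    "year", "country", "species", "environment", "group",
    "quantity_t", "value_kusd",
]

KEY_COLUMNS = ["year", "country", "species", "environment"]

YEAR_MIN, YEAR_MAX = 1900, 2100


class PanelFormatError(ValueError):
    """Malformed input file (missing columns, unparseable cells)."""


class PanelValidationError(ValueError):
    """Structurally valid file whose content violates panel invariants."""


@dataclass
class ProductionPanel:
    """Tidy collection of annual production records.

    Attributes
    ----------
    df
        DataFrame with columns ``year, country, species, environment,
        group, quantity_t, value_kusd``.  ``quantity_t`` is tonnes live
        weight, ``value_kusd`` thousand US$; either may be NaN (missing).
    provenance
        Free-text note on where the records came from.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = _normalise_frame(self.df)
        _validate_frame(self.df)

    # -- derived properties -------------------------------------------------

    @property
    def year_range(self) -> tuple[int, int]:
        years = self.df["year"]
        return int(years.min()), int(years.max())

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def __len__(self) -> int:
        return len(self.df)

    # -- transforms ---------------------------------------------------------

    def filter_countries(
        self,
        include: Iterable[str] | None = None,
        exclude: Iterable[str] | None = None,
    ) -> "ProductionPanel":
        """Restrict the panel to a country subset.

        National FAO totals cannot be split below country level (e.g. by
        coastline); this filter is the supported way to restrict scope.
        """
        df = self.df
        if include is not None:
            df = df[df["country"].isin(set(include))]
        if exclude is not None:
            df = df[~df["country"].isin(set(exclude))]
        return ProductionPanel(df.reset_index(drop=True), provenance=self.provenance)

    def apply_aliases(self, aliases: dict[str, str], column: str = "species") -> "ProductionPanel":
        """Relabel entities (species groupings, historic country names)."""
        df = self.df.copy()
        df[column] = df[column].map(lambda x: aliases.get(x, x))
        df = _sum_duplicates(df)
        return ProductionPanel(df, provenance=self.provenance)


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("environment", "group"):
        if col not in df.columns:
            df[col] = "unknown" if col == "environment" else "other"
    if "value_kusd" not in df.columns:
        df["value_kusd"] = np.nan
    df["year"] = df["year"].astype(int)
    for col in ("country", "species", "environment", "group"):
        df[col] = df[col].astype(str).str.strip()
    df["quantity_t"] = pd.to_numeric(df["quantity_t"])
    df["value_kusd"] = pd.to_numeric(df["value_kusd"])
    return df[TIDY_COLUMNS].reset_index(drop=True)


def _validate_frame(df: pd.DataFrame) -> None:
    bad_year = df[(df["year"] < YEAR_MIN) | (df["year"] > YEAR_MAX)]
    if len(bad_year):
        raise PanelValidationError(
            f"year out of range [{YEAR_MIN}, {YEAR_MAX}] at row {bad_year.index[0]}"
        )
    neg = df[df["quantity_t"] < 0]
    if len(neg):
        raise PanelValidationError(f"negative quantity at row {neg.index[0]}")
    negv = df[df["value_kusd"] < 0]
    if len(negv):
        raise PanelValidationError(f"negative value at row {negv.index[0]}")
    for col in ("country", "species"):
        empty = df[df[col] == ""]
        if len(empty):
            raise PanelValidationError(f"empty {col} label at row {empty.index[0]}")
    if df.duplicated(KEY_COLUMNS).any():
        row = df[df.duplicated(KEY_COLUMNS)].index[0]
        raise PanelValidationError(
            f"duplicate (year, country, species, environment) key at row {row}"
        )


def _sum_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    grouped = df.groupby(KEY_COLUMNS, as_index=False, dropna=False).agg(
        group=("group", "first"),
        quantity_t=("quantity_t", lambda s: s.sum(min_count=1)),
        value_kusd=("value_kusd", lambda s: s.sum(min_count=1)),
    )
    return grouped[TIDY_COLUMNS]


# ---------------------------------------------------------------------------
# tidy CSV
# ---------------------------------------------------------------------------

def read_tidy_panel(path: str | Path, strict: bool = False) -> ProductionPanel:
    """Read a tidy-schema CSV into a :class:`ProductionPanel`.

    Parameters
    ----------
    path
        CSV file with at least ``year, country, species`` and a quantity
        column (``quantity_t`` or ``quantity``).
    strict
        When True, duplicate (year, country, species, environment) keys are
        rejected; when False (default) their quantities and values are
        summed, matching FAO exports that split a series by sub-environment.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns={"quantity": "quantity_t", "value": "value_kusd"})
    required = ["year", "country", "species", "quantity_t"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path.name}: missing required column(s) {missing}")
    extra = set(df.columns) - set(TIDY_COLUMNS)
    if extra:
        logger.warning("%s: ignoring extra columns %s", path.name, sorted(extra))
    df = _normalise_frame(df[[c for c in TIDY_COLUMNS if c in df.columns]])
    if not strict:
        df = _sum_duplicates(df)
    return ProductionPanel(df, provenance=str(path))


def write_tidy_panel(panel: ProductionPanel, path: str | Path) -> None:
    """Write the tidy-CSV schema; round-trips quantities exactly."""
    panel.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FishStatJ-style wide CSV
# ---------------------------------------------------------------------------

_DESCRIPTOR_ALIASES = {
    "country": "country",
    "country (name)": "country",
    "land area": "country",
    "species": "species",
    "species (asfis species)": "species",
    "asfis species (name)": "species",
    "environment": "environment",
    "environment (name)": "environment",
    "production area": "area",
    "unit": "unit",
}

_FLAG_RE = re.compile(r"^(?P<num>.*\S)\s+(?P<flag>[A-Za-z])$")


def _parse_wide_cell(raw: object, row: int, col: str) -> float:
    """Apply FishStatJ sentinel/flag conventions to one cell.

    ``...`` and empty → missing; ``-`` → 0; a trailing whitespace-separated
    single-letter flag (``F`` FAO estimate, ``E`` expert estimate, ...) is
    stripped before the numeric parse and logged.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s in ("", "...", ".."):
        return np.nan
    if s == "-":
        return 0.0
    m = _FLAG_RE.match(s)
    if m:
        logger.info("flagged cell (row %d, column %r): flag %r", row, col, m.group("flag"))
        s = m.group("num").strip()
    s = s.replace(" ", "")
    try:
        return float(s)
    except ValueError:
        raise PanelFormatError(
            f"unparseable cell {raw!r} at row {row}, column {col!r}"
        ) from None


def read_fishstat_wide(path: str | Path) -> ProductionPanel:
    """Read a FishStatJ wide export (descriptor columns + one column per year).

    Year columns are recognised by an all-digit header; descriptor columns
    are mapped by common FishStatJ header names, falling back to positional
    order (country, species, environment).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    year_cols = [c for c in df.columns if str(c).strip().isdigit()]
    if not year_cols:
        raise PanelFormatError(f"{path.name}: no year columns found")
    desc_cols = [c for c in df.columns if c not in year_cols]
    rename: dict[str, str] = {}
    for c in desc_cols:
        key = str(c).strip().lower()
        if key in _DESCRIPTOR_ALIASES:
            rename[c] = _DESCRIPTOR_ALIASES[key]
    df = df.rename(columns=rename)
    fallback = ["country", "species", "environment"]
    for c, name in zip([c for c in desc_cols if c not in rename], fallback):
        if name not in df.columns:
            df = df.rename(columns={c: name})
    for required in ("country", "species"):
        if required not in df.columns:
            raise PanelFormatError(f"{path.name}: cannot identify a {required!r} column")
    if "environment" not in df.columns:
        df["environment"] = "unknown"

    records = []
    for i, row in df.iterrows():
        for yc in year_cols:
            q = _parse_wide_cell(row[yc], int(i), str(yc))
            records.append(
                {
                    "year": int(str(yc).strip()),
                    "country": row["country"],
                    "species": row["species"],
                    "environment": str(row["environment"]).strip().lower(),
                    "quantity_t": q,
                }
            )
    tidy = pd.DataFrame.from_records(records)
    tidy.loc[~tidy["environment"].isin(ENVIRONMENTS), "environment"] = "unknown"
    tidy = _sum_duplicates(_normalise_frame(tidy))
    return ProductionPanel(tidy, provenance=str(path))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(
    panel: ProductionPanel,
    keys: Sequence[str],
    measure: str = "quantity",
) -> pd.DataFrame:
    """Sum a measure over the chosen key subset.

    Missing measures are excluded from sums; the grand total of the output
    equals the total of the non-missing inputs (conservation).

    Parameters
    ----------
    keys
        Non-empty subset of ``{year, country, species, environment, group}``.
    measure
        ``"quantity"`` (tonnes) or ``"value"`` (thousand US$).
    """
    keys = list(keys)
    if not keys:
        raise ValueError("keys must be non-empty")
    allowed = {"year", "country", "species", "environment", "group"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"unknown aggregation keys: {sorted(bad)}")
    col = {"quantity": "quantity_t", "value": "value_kusd"}.get(measure)
    if col is None:
        raise ValueError(f"unknown measure {measure!r}")
    if col == "value_kusd" and panel.df[col].isna().all():
        raise PanelValidationError("panel carries no value data")
    df = panel.df.dropna(subset=[col])
    out = df.groupby(keys, as_index=False)[col].sum()
    return out.sort_values(keys).reset_index(drop=True)
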