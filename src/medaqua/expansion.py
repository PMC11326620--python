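"""Temporal and geographic profiling of farmed species and producing countries.

For each entity the module measures:

* **persistence** — number of distinct years with positive production
  ("years of farming"; gaps do not count);
* **diffusiveness** — how many countries farm a species, either cumulatively
  over the whole record (ever) or per year (the annual country count C_t);
* **GER**, the geographical expansion rate — the trailing-window average of
  year-over-year percent change in C_t (positive = expansion);
* a four-way quadrant class crossing persistence against diffusiveness
  (historic-core vs emergent, widespread vs localized);
* **relative productivity** — production per unit national area over a
  trailing window, t/km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ProductionPanel, aggregate

#: "farmed for more than 60 years" → historic core
PERSISTENCE_CUT = 60
#: "farmed in more than 20 countries" → widespread
DIFFUSIVENESS_CUT = 20
#: GER averages the last 10 annual expansion rates
GER_WINDOW = 10

QUADRANTS = ("core_widespread", "core_localized", "emergent", "transient")


@dataclass
class GeoProfile:
    """Per-entity geographic/temporal summary."""

    entity: str
    cumulative_volume: float
    persistence: int
    diffusiveness_ever: int | None          # species axis only
    diffusiveness_by_year: pd.Series | None  # annual country counts C_t
    ger: float | None                        # percent per year; None if undefined
    quadrant: str | None


def _entity_table(panel: ProductionPanel, axis: str) -> pd.DataFrame:
    if axis not in ("species", "country"):
        raise ValueError("axis must be 'species' or 'country'")
    return aggregate(panel, ["year", axis], measure="quantity")


def persistence(panel: ProductionPanel, entity: str, axis: str = "species") -> int:
    """Count of distinct years with positive production for the entity."""
    table = _entity_table(panel, axis)
    sub = table[table[axis] == entity]
    if sub.empty:
        raise KeyError(f"{axis} {entity!r} not present in panel")
    return int((sub.groupby("year")["quantity_t"].sum() > 0).sum())


def diffusiveness_series(panel: ProductionPanel, species: str) -> tuple[pd.Series, int]:
    """Annual country counts C_t for one species, plus the cumulative count.

    Returns ``(C_t, C_ever)``: C_t indexed by every year in the panel's
    range (0 where the species is absent), and the number of distinct
    countries that ever reported positive production.
    """
    df = panel.df
    sub = df[(df["species"] == species) & (df["quantity_t"] > 0)]
    if df[df["species"] == species].empty:
        raise KeyError(f"species {species!r} not present in panel")
    start, end = panel.year_range
    counts = sub.groupby("year")["country"].nunique()
    c_t = counts.reindex(range(start, end + 1), fill_value=0).astype(int)
    c_t.name = species
    return c_t, int(sub["country"].nunique())


def geographical_expansion_rate(counts: pd.Series, window: int = GER_WINDOW) -> float | None:
    """Trailing-window mean of year-over-year percent change in country counts.

    Per-year rate = 100 × (C_t − C_{t−1}) / C_{t−1}; years whose previous
    count is zero are skipped.  Returns None when no valid rate falls inside
    the trailing window (an undefined result, not an error).
    """
    counts = counts.sort_index()
    if len(counts) < 2:
        raise ValueError("need at least 2 years of counts")
    prev = counts.shift(1)
    rates = 100.0 * (counts - prev) / prev
    rates = rates[prev > 0].dropna()
    last_year = counts.index.max()
    in_window = rates[rates.index > last_year - window]
    if in_window.empty:
        return None
    return float(in_window.mean())


def geometric_expansion_rate(counts: pd.Series, window: int = GER_WINDOW) -> float | None:
    """Geometric-mean variant of the expansion rate, percent per year."""
    counts = counts.sort_index()
    if len(counts) < 2:
        raise ValueError("need at least 2 years of counts")
    prev = counts.shift(1)
    ratios = (counts / prev)[prev > 0].dropna()
    last_year = counts.index.max()
    in_window = ratios[ratios.index > last_year - window]
    if in_window.empty or (in_window <= 0).any():
        return None
    return float(100.0 * (np.exp(np.log(in_window).mean()) - 1.0))


def classify_quadrant(
    persistence_years: int,
    diffusiveness_countries: int,
    persistence_cut: int = PERSISTENCE_CUT,
    diffusiveness_cut: int = DIFFUSIVENESS_CUT,
) -> str:
    """Four-way class from (persistence, diffusiveness), strict cuts.

    "More than" 60 years / 20 countries: an entity exactly at a cut is not
    core / not widespread.
    """
    core = persistence_years > persistence_cut
    wide = diffusiveness_countries > diffusiveness_cut
    if core and wide:
        return "core_widespread"
    if core:
        return "core_localized"
    if wide:
        return "emergent"
    return "transient"


def profile_species(
    panel: ProductionPanel,
    species: str,
    ger_window: int = GER_WINDOW,
    persistence_cut: int = PERSISTENCE_CUT,
    diffusiveness_cut: int = DIFFUSIVENESS_CUT,
) -> GeoProfile:
    """Full geographic profile of one species."""
    pers = persistence(panel, species, axis="species")
    c_t, c_ever = diffusiveness_series(panel, species)
    ger = geographical_expansion_rate(c_t, window=ger_window) if len(c_t) >= 2 else None
    vol = float(panel.df.loc[panel.df["species"] == species, "quantity_t"].sum())
    return GeoProfile(
        entity=species,
        cumulative_volume=vol,
        persistence=pers,
        diffusiveness_ever=c_ever,
        diffusiveness_by_year=c_t,
        ger=ger,
        quadrant=classify_quadrant(pers, c_ever, persistence_cut, diffusiveness_cut),
    )


def profile_all_species(panel: ProductionPanel, **kwargs) -> pd.DataFrame:
    """One-row-per-species table of persistence, diffusiveness, GER, quadrant."""
    rows = []
    for sp in panel.species:
        p = profile_species(panel, sp, **kwargs)
        rows.append(
            {
                "species": sp,
                "cumulative_volume_t": p.cumulative_volume,
                "persistence_y": p.persistence,
                "diffusiveness_ever": p.diffusiveness_ever,
                "ger_pct": p.ger if p.ger is not None else math.nan,
                "quadrant": p.quadrant,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "cumulative_volume_t", ascending=False).reset_index(drop=True)


def relative_productivity(
    panel: ProductionPanel,
    areas: pd.Series | dict,
    window: int = 5,
    measure: str = "quantity",
) -> pd.DataFrame:
    """Country production per km² over the trailing window, sorted descending.

    ``areas`` maps country → km².  Every country present in the panel must
    have an area.  The window covers the last ``window`` panel years
    (closed), mirroring "relative productivity in the last 5 years".
    """
    areas = pd.Series(areas, dtype=float)
    table = aggregate(panel, ["year", "country"], measure=measure)
    last = table["year"].max()
    sub = table[table["year"] > last - window]
    totals = sub.groupby("country")[sub.columns[-1]].sum()
    missing = set(totals.index) - set(areas.index)
    if missing:
        raise KeyError(f"no area for country {sorted(missing)[0]!r}")
    out = pd.DataFrame(
        {
            "country": totals.index,
            "total": totals.to_numpy(),
            "area_km2": areas.reindex(totals.index).to_numpy(),
        }
    )
    out["per_km2"] = out["total"] / out["area_km2"]
    return out.sort_values("per_km2", ascending=False).reset_index(drop=True)
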