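"""Annual diversity statistics: richness, Shannon index, Pareto dominance.

Two complementary views of how concentrated production is among entities
(species or producing countries):

* the Shannon index H = −Σ p_i ln p_i on annual volume shares, together
  with richness S;
* a Pareto dominance decomposition, splitting each year's entities into
  *dominant* (the smallest descending-sorted set jointly producing ≥ 80% of
  annual volume), *relevant* (≥ 99%) and *minor* (the rest), and the Pareto
  index 100 × dominant/relevant — the "80/20" structure of production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ProductionPanel, aggregate

#: shares jointly accounting for 99% of annual production
RELEVANT_SHARE = 0.99
#: shares jointly accounting for 80% of annual production
DOMINANT_SHARE = 0.80

_REL_TOL = 1e-9


@dataclass
class DiversityResult:
    """Richness, Shannon index and shares for one year."""

    year: int
    S: int
    H: float
    p: np.ndarray
    labels: list[str] | None = None


@dataclass
class DominanceDecomposition:
    """One year's partition of entities into dominant / relevant / minor."""

    year: int
    total: int
    relevant: int
    dominant: int
    minor: int
    pareto_index: float  # 100 * dominant / relevant, percent
    thresholds: tuple[float, float]
    dominant_labels: list[str]
    relevant_labels: list[str]
    minor_labels: list[str]


def shannon_index(volumes, labels=None, year: int = 0) -> DiversityResult:
    """Shannon diversity of an annual volume vector (natural log).

    Zero-volume entities are excluded from both richness and the share
    vector; shares are proportions of the annual total.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0 or np.all(v <= 0):
        raise ValueError("need at least one strictly positive volume")
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    if labels is not None:
        labels = [l for l, x in zip(labels, v) if x > 0]
    v = v[v > 0]
    p = v / v.sum()
    H = float(-(p * np.log(p)).sum())
    return DiversityResult(year=year, S=int(p.size), H=H, p=p, labels=labels)


def dominance_decompose(
    volumes,
    labels=None,
    thresholds: tuple[float, float] = (RELEVANT_SHARE, DOMINANT_SHARE),
    year: int = 0,
    dominant_base: str = "total",
) -> DominanceDecomposition:
    """Partition one year's entities by cumulative share of annual volume.

    Entities are sorted by volume descending (ties broken by label,
    ascending).  ``relevant`` is the size of the smallest prefix whose
    cumulative share reaches the relevant threshold (default 99%) of the
    annual total, ``dominant`` likewise for the dominant threshold (default
    80%); ``minor = total − relevant``; the Pareto index is
    100 × dominant / relevant.

    ``dominant_base="relevant"`` measures the dominant prefix against the
    relevant subset's subtotal instead of the annual total (an alternative
    reading of "80% of production, based on relevant species"); the default
    total-based rule reproduces the canonical worked example
    (shares 50, 30, 8, 4, 3, 2, 2, 0.4, 0.3, 0.3 → 7 relevant, 2 dominant,
    index 28.6%).
    """
    relevant_share, dominant_share = thresholds
    if not (0 < dominant_share < relevant_share <= 1):
        raise ValueError("need 0 < dominant_share < relevant_share <= 1")
    if dominant_base not in ("total", "relevant"):
        raise ValueError("dominant_base must be 'total' or 'relevant'")
    v = np.asarray(volumes, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(v.size)]
    labels = [str(l) for l in labels]
    if len(labels) != v.size:
        raise ValueError("labels and volumes must have equal length")
    if v.size == 0 or np.all(v <= 0):
        raise ValueError("need at least one strictly positive volume")
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")

    keep = v > 0
    v, labels = v[keep], [l for l, k in zip(labels, keep) if k]
    order = sorted(range(v.size), key=lambda i: (-v[i], labels[i]))
    v = v[order]
    labels = [labels[i] for i in order]

    total_vol = v.sum()
    cum = np.cumsum(v)
    # tolerate float round-off when a prefix lands exactly on the threshold
    relevant = int(np.argmax(cum >= relevant_share * total_vol * (1 - _REL_TOL)) + 1)
    if dominant_base == "total":
        dom_target = dominant_share * total_vol
    else:
        dom_target = dominant_share * cum[relevant - 1]
    dominant = int(np.argmax(cum >= dom_target * (1 - _REL_TOL)) + 1)

    total = int(v.size)
    return DominanceDecomposition(
        year=year,
        total=total,
        relevant=relevant,
        dominant=dominant,
        minor=total - relevant,
        pareto_index=100.0 * dominant / relevant,
        thresholds=(relevant_share, dominant_share),
        dominant_labels=labels[:dominant],
        relevant_labels=labels[:relevant],
        minor_labels=labels[relevant:],
    )


def _annual_volumes(panel: ProductionPanel, axis: str) -> pd.DataFrame:
    if axis not in ("species", "country"):
        raise ValueError("axis must be 'species' or 'country'")
    return aggregate(panel, ["year", axis], measure="quantity")


def pareto_series(
    panel: ProductionPanel,
    axis: str = "species",
    thresholds: tuple[float, float] = (RELEVANT_SHARE, DOMINANT_SHARE),
    dominant_base: str = "total",
) -> list[DominanceDecomposition]:
    """Dominance decomposition per year along the species or country axis."""
    table = _annual_volumes(panel, axis)
    out = []
    for year, grp in table.groupby("year"):
        if not (grp["quantity_t"] > 0).any():
            continue
        out.append(dominance_decompose(
            grp["quantity_t"].to_numpy(), labels=grp[axis].tolist(),
            thresholds=thresholds, year=int(year), dominant_base=dominant_base))
    return out


def diversity_series(panel: ProductionPanel, axis: str = "species") -> list[DiversityResult]:
    """Shannon index and richness per year along the chosen axis."""
    table = _annual_volumes(panel, axis)
    out = []
    for year, grp in table.groupby("year"):
        if not (grp["quantity_t"] > 0).any():
            continue
        out.append(shannon_index(
            grp["quantity_t"].to_numpy(), labels=grp[axis].tolist(), year=int(year)))
    return out


def pareto_frame(decomps: list[DominanceDecomposition]) -> pd.DataFrame:
    """Tabular view of a decomposition series (one row per year)."""
    return pd.DataFrame(
        {
            "year": [d.year for d in decomps],
            "total": [d.total for d in decomps],
            "relevant": [d.relevant for d in decomps],
            "dominant": [d.dominant for d in decomps],
            "minor": [d.minor for d in decomps],
            "pareto_index": [d.pareto_index for d in decomps],
        }
    )


def diversity_frame(results: list[DiversityResult]) -> pd.DataFrame:
    """Tabular view of a diversity series (one row per year)."""
    return pd.DataFrame(
        {
            "year": [r.year for r in results],
            "S": [r.S for r in results],
            "H": [r.H for r in results],
        }
    )
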