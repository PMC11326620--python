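"""Species × year matrices, row scaling, clustering, and succession phases.

Seventy years of production can be read as an ecological succession of
farmed species: pioneer species dominate early, are replaced, and the
system approaches a stable ("climax") composition.  This module builds the
species × year production matrix behind heatmap-style views, z-scales rows
so each species' trajectory is comparable regardless of volume, clusters
rows hierarchically (Ward or centroid linkage on Euclidean distances), and
extracts the per-year dominant entity and its run-length phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .panel import ProductionPanel, aggregate


@dataclass
class SuccessionMatrix:
    """Entities × years matrix, raw tonnes or row-standardised."""

    data: pd.DataFrame            # rows: entities, columns: years
    scaled: bool = False
    row_stats: pd.DataFrame | None = None  # per-row mu, sd recorded when scaled

    @property
    def row_labels(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_labels(self) -> list[int]:
        return list(self.data.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence plus the heatmap leaf order.

    ``linkage_matrix`` is in scipy linkage form: each row
    (cluster_a, cluster_b, height, size) creates cluster ``n + i``.
    """

    linkage_matrix: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + i] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
            heights[n + i] = float(h)
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def species_year_matrix(
    panel: ProductionPanel,
    rows: list[str] | None = None,
    axis: str = "species",
    fill: float = 0.0,
) -> SuccessionMatrix:
    """Entity × year matrix of total production.

    Columns span the panel's full year range; combinations absent from the
    panel are filled with ``fill`` (default 0, i.e. nothing farmed).
    """
    table = aggregate(panel, ["year", axis], measure="quantity")
    mat = table.pivot(index=axis, columns="year", values="quantity_t")
    start, end = panel.year_range
    mat = mat.reindex(columns=range(start, end + 1))
    if rows is not None:
        unknown = set(rows) - set(mat.index)
        if unknown:
            raise KeyError(f"unknown row label {sorted(unknown)[0]!r}")
        mat = mat.loc[rows]
    mat = mat.fillna(fill)
    return SuccessionMatrix(data=mat, scaled=False)


def zscale_rows(matrix: SuccessionMatrix) -> SuccessionMatrix:
    """Standardise each row with its own mean and sample s.d.

    Rows with zero variance map to all zeros (guarded division), keeping the
    scaled matrix finite.
    """
    if matrix.scaled:
        raise ValueError("matrix already scaled")
    values = matrix.data.to_numpy(dtype=float)
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    scaled = (values - mu[:, None]) / safe[:, None]
    scaled[sd == 0, :] = 0.0
    stats = pd.DataFrame({"mu": mu, "sd": sd}, index=matrix.data.index)
    return SuccessionMatrix(
        data=pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns),
        scaled=True,
        row_stats=stats,
    )


def cluster_rows(
    matrix: SuccessionMatrix,
    metric: str = "euclidean",
    linkage: str = "ward",
) -> Dendrogram:
    """Agglomerative clustering of matrix rows.

    Euclidean distances with Ward linkage (the Lance–Williams "Ward.D2"
    update on the distance matrix, scipy's convention) or centroid linkage.
    Deterministic given row order; returns the merge sequence and the
    dendrogram leaf order used for heatmap display.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    if linkage not in ("ward", "centroid"):
        raise ValueError("linkage must be 'ward' or 'centroid'")
    values = matrix.data.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(values, method=linkage, metric="euclidean")
    order = hierarchy.leaves_list(Z).tolist()
    return Dendrogram(linkage_matrix=Z, leaf_order=order,
                      labels=matrix.row_labels)


@dataclass
class Phase:
    """A maximal run of consecutive years with the same dominant entity."""

    start: int
    end: int
    label: str


def dominant_per_year(matrix: SuccessionMatrix) -> tuple[pd.DataFrame, list[Phase]]:
    """Per-year dominant row and its share, plus run-length phases.

    For each year column the argmax row (ties broken by label order) and its
    share of the column total; all-zero columns get label ``"none"``.
    Consecutive years with the same dominant label are reported as phases.
    """
    if matrix.scaled:
        raise ValueError("dominant_per_year needs the unscaled matrix")
    df = matrix.data.sort_index()  # label order breaks ties via idxmax
    labels, shares = [], []
    for year in df.columns:
        col = df[year]
        total = col.sum()
        if total <= 0:
            labels.append("none")
            shares.append(np.nan)
        else:
            lab = col.idxmax()
            labels.append(lab)
            shares.append(float(col.loc[lab] / total))
    out = pd.DataFrame({"year": list(df.columns), "dominant": labels, "share": shares})

    phases: list[Phase] = []
    for year, lab in zip(out["year"], out["dominant"]):
        if phases and phases[-1].label == lab:
            phases[-1].end = int(year)
        else:
            phases.append(Phase(start=int(year), end=int(year), label=lab))
    return out, phases
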