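"""Evaluation metrics: marker Spearman correlation, Moran's I, JS distance.

These mirror the standard way deconvolution output is validated when no
ground truth exists: a cell type's inferred proportion field should
correlate with the expression of its marker genes across spots, should be
spatially autocorrelated when the type occupies coherent tissue regions,
and its composition rows should be close (in Jensen-Shannon distance) to a
marker-derived reference composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .errors import DomainError
from .io import CountMatrix, ProportionMatrix, SpotCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "SpatialGraph",
    "marker_correlation",
    "morans_i",
    "js_distance",
    "evaluate_run",
    "read_markers",
    "write_markers",
]


@dataclass
class MarkerSet:
    """Ordered marker gene lists per cell type (top-ranked first)."""

    markers: dict[str, list[str]]

    def types(self) -> list[str]:
        return list(self.markers)


def read_markers(path) -> MarkerSet:
    """Read a marker TSV with columns (cell_type, gene, rank)."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise DomainError(f"marker TSV {path} needs columns cell_type, gene")
    if "rank" in df.columns:
        df = df.sort_values(["cell_type", "rank"], kind="stable")
    out: dict[str, list[str]] = {}
    for t, sub in df.groupby("cell_type", sort=False):
        out[str(t)] = [str(g) for g in sub["gene"]]
    return MarkerSet(out)


def write_markers(markers: MarkerSet, path) -> None:
    rows = [
        {"cell_type": t, "gene": g, "rank": r + 1}
        for t, genes in markers.markers.items()
        for r, g in enumerate(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SpatialGraph:
    """k-nearest-neighbour graph with row-standardized binary weights."""

    row_ids: list[str]
    neighbors: np.ndarray  # N x k integer indices
    weights: np.ndarray  # N x k, each row sums to 1

    @classmethod
    def from_coordinates(cls, coords: SpotCoordinates, k: int = 6) -> "SpatialGraph":
        n = coords.xy.shape[0]
        if n < 2:
            raise DomainError("need at least 2 spots to build a spatial graph")
        k = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords.xy)
        _, idx = nn.kneighbors(coords.xy)
        neigh = idx[:, 1:]  # drop self
        w = np.full((n, k), 1.0 / k)
        return cls(list(coords.row_ids), neigh, w)


def marker_correlation(
    props: ProportionMatrix, spatial: CountMatrix, markers: MarkerSet
) -> pd.DataFrame:
    """Spearman rho between each type's proportions and its marker expression.

    One row per (cell type, marker gene). Missing markers are skipped with a
    log line; zero-variance vectors yield rho = NaN (never imputed as 0).
    """
    gene_index = {g: j for j, g in enumerate(spatial.gene_ids)}
    rows = []
    for t, genes in markers.markers.items():
        if t not in props.type_order:
            raise DomainError(f"marker cell type {t!r} not in proportion matrix")
        p = props.values[:, props.type_order.index(t)]
        for g in genes:
            j = gene_index.get(g)
            if j is None:
                logger.info("marker %s for type %s absent from spatial data; skipped", g, t)
                continue
            expr = spatial.values[:, j].astype(float)
            if np.ptp(p) == 0 or np.ptp(expr) == 0:
                rho = np.nan
            else:
                rho = float(spearmanr(p, expr).statistic)
            rows.append({"cell_type": t, "gene": g, "spearman_rho": rho})
    return pd.DataFrame(rows, columns=["cell_type", "gene", "spearman_rho"])


def morans_i(values: np.ndarray, graph: SpatialGraph) -> float:
    """Moran's I spatial autocorrelation under row-standardized weights.

    I = (n / sum(W)) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    With row-standardized weights sum(W) = n. Constant input -> NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n != len(graph.row_ids):
        raise DomainError("value vector length does not match the graph")
    d = x - x.mean()
    denom = (d**2).sum()
    if denom == 0:
        return float("nan")
    num = (graph.weights * d[graph.neighbors] * d[:, None]).sum()
    w_total = graph.weights.sum()
    return float((n / w_total) * num / denom)


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance (base-2 logarithm): metric in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(p < 0) or np.any(q < 0):
        raise DomainError("JS distance requires nonnegative vectors")
    for name, v in (("p", p), ("q", q)):
        off = abs(v.sum() - 1.0)
        if off > 1e-6:
            raise DomainError(f"{name} is not on the simplex (sum off by {off:.2e})")
        if off > 0:
            logger.debug("renormalizing %s (off simplex by %.2e)", name, off)
    return float(jensenshannon(p, q, base=2.0))


def evaluate_run(
    props: ProportionMatrix,
    spatial: CountMatrix,
    coords: SpotCoordinates | None,
    markers: MarkerSet,
    k_neighbors: int = 6,
) -> pd.DataFrame:
    """Per-type report: median marker rho, Moran's I, and mean per-spot JS distance.

    The JS comparator is a marker-derived composition per spot: each type's
    mean marker expression, normalized across types (spots with no marker
    signal get the uniform composition). Summary medians are appended as a
    row with cell_type = "__summary__"; undefined (NaN) correlations are
    excluded from medians rather than imputed.
    """
    corr = marker_correlation(props, spatial, markers)
    graph = (
        SpatialGraph.from_coordinates(coords, k=k_neighbors) if coords is not None else None
    )
    gene_index = {g: j for j, g in enumerate(spatial.gene_ids)}

    # marker-derived composition over the evaluated types
    types = [t for t in props.type_order if t in markers.markers]
    M = np.zeros((spatial.n_rows, len(types)))
    for c, t in enumerate(types):
        cols = [gene_index[g] for g in markers.markers[t] if g in gene_index]
        if cols:
            M[:, c] = spatial.values[:, cols].mean(axis=1)
    row_sums = M.sum(axis=1, keepdims=True)
    uniform = np.full(len(types), 1.0 / len(types))
    comp = np.where(row_sums > 0, M / np.maximum(row_sums, 1e-300), uniform)

    sub = props.values[:, [props.type_order.index(t) for t in types]]
    sub_sums = sub.sum(axis=1, keepdims=True)
    sub_norm = np.where(sub_sums > 0, sub / np.maximum(sub_sums, 1e-300), uniform)
    js_per_spot = np.array(
        [js_distance(sub_norm[i], comp[i]) for i in range(sub_norm.shape[0])]
    )

    rows = []
    for t in types:
        rhos = corr.loc[corr["cell_type"] == t, "spearman_rho"].dropna()
        moran = (
            morans_i(props.values[:, props.type_order.index(t)], graph)
            if graph is not None
            else np.nan
        )
        rows.append(
            {
                "cell_type": t,
                "median_marker_rho": float(rhos.median()) if len(rhos) else np.nan,
                "morans_i": moran,
                "mean_js_distance": float(np.nanmean(js_per_spot)),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "cell_type": "__summary__",
        "median_marker_rho": float(df["median_marker_rho"].dropna().median()),
        "morans_i": float(df["morans_i"].dropna().median()) if graph is not None else np.nan,
        "mean_js_distance": float(np.nanmedian(js_per_spot)),
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
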