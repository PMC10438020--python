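"""Areal spatial statistics for polygon lattices.

Covers the exploratory spatial workflow applied to per-department
substance-use rates: queen/rook contiguity weights, global spatial
autocorrelation (Moran's I, Geary's C, Getis–Ord G) with permutation
inference, local Moran (LISA) quadrant maps, choropleth classification
with the ADCM fit criterion, and spatially constrained Ward
regionalization.

Global statistics use binary weights (the classical definitions); the
local Moran uses row-standardized weights so each unit's spatial lag is
the mean of its neighbours.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse
from shapely.geometry import mapping, shape
from shapely.ops import unary_union
from shapely.strtree import STRtree
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = [
    "SpatialLattice",
    "WeightsMatrix",
    "GlobalStat",
    "LisaResult",
    "Classification",
    "contiguity_weights",
    "morans_I",
    "gearys_C",
    "getis_ord_G",
    "local_morans",
    "classify_choropleth",
    "adcm",
    "select_classifier",
    "regionalize",
    "select_n_regions",
    "region_coherence",
    "CLASSIFIERS",
]


class GeometryError(ValueError):
    """A unit's polygon is invalid or unusable."""


class ClassificationError(ValueError):
    """A choropleth classification cannot be built as requested."""


# ---------------------------------------------------------------------------
# lattice container and GeoJSON I/O


@dataclass
class SpatialLattice:
    """Areal units: id, polygon geometry, scalar attribute, optional
    multivariate feature matrix (n_units x n_features)."""

    ids: tuple[str, ...]
    geometry: tuple
    values: np.ndarray
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("unit ids must be unique")
        if not (len(self.ids) == len(self.geometry) == len(self.values)):
            raise ValueError("ids, geometry and values must align")
        self.values = np.asarray(self.values, dtype=float)
        if self.features is not None:
            self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
            if self.features.shape[0] != len(self.ids):
                raise ValueError("features must have one row per unit")

    @property
    def n(self) -> int:
        return len(self.ids)

    def feature_matrix(self) -> np.ndarray:
        """Features if provided, else the attribute as a single column."""
        return self.features if self.features is not None else self.values[:, None]

    @classmethod
    def from_geojson(
        cls,
        path: str | Path,
        value_column: str,
        id_column: str = "id",
        feature_columns: Sequence[str] | None = None,
    ) -> "SpatialLattice":
        gj = json.loads(Path(path).read_text())
        ids, geoms, vals, feats = [], [], [], []
        for i, feat in enumerate(gj["features"]):
            props = feat.get("properties", {})
            ids.append(str(props.get(id_column, i)))
            geoms.append(shape(feat["geometry"]))
            vals.append(float(props[value_column]))
            if feature_columns:
                feats.append([float(props[c]) for c in feature_columns])
        return cls(tuple(ids), tuple(geoms), np.array(vals),
                   np.array(feats) if feature_columns else None)

    def to_geojson(self, path: str | Path, extra: dict[str, Sequence] | None = None) -> None:
        feats = []
        for i in range(self.n):
            props: dict = {"id": self.ids[i], "value": float(self.values[i])}
            for key, col in (extra or {}).items():
                v = col[i]
                props[key] = v.item() if isinstance(v, np.generic) else v
            feats.append({"type": "Feature", "geometry": mapping(self.geometry[i]),
                          "properties": props})
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------------------
# contiguity weights


@dataclass
class WeightsMatrix:
    """Binary symmetric contiguity structure with sorted neighbour lists."""

    neighbors: tuple[tuple[int, ...], ...]

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def islands(self) -> tuple[int, ...]:
        return tuple(i for i, nb in enumerate(self.neighbors) if not nb)

    @property
    def s0(self) -> float:
        """Sum of all binary weights."""
        return float(sum(len(nb) for nb in self.neighbors))

    def to_sparse(self, row_standardized: bool = False) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                rows.append(i)
                cols.append(j)
                data.append(1.0 / len(nb) if row_standardized else 1.0)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nb)
        return g


def contiguity_weights(
    lattice: SpatialLattice, rule: Literal["queen", "rook"] = "queen"
) -> WeightsMatrix:
    """Polygon contiguity: queen = any shared boundary point, rook = a
    shared boundary segment (positive-length intersection).

    Islands (units without neighbours) are allowed; they keep empty
    neighbour lists and a warning is emitted.
    """
    geoms = list(lattice.geometry)
    for i, g in enumerate(geoms):
        if g is None or g.is_empty or not g.is_valid:
            raise GeometryError(f"unit {lattice.ids[i]!r} has an invalid geometry")
    tree = STRtree(geoms)
    neighbors: list[set[int]] = [set() for _ in geoms]
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            touches = inter.length > 0 if rule == "rook" else True
            if touches:
                neighbors[i].add(j)
                neighbors[j].add(i)
    w = WeightsMatrix(tuple(tuple(sorted(nb)) for nb in neighbors))
    if w.islands:
        warnings.warn(
            f"{len(w.islands)} island unit(s) without neighbours: "
            f"{[lattice.ids[i] for i in w.islands]}",
            stacklevel=2,
        )
    return w


# ---------------------------------------------------------------------------
# global autocorrelation with permutation inference


@dataclass(frozen=True)
class GlobalStat:
    statistic: float
    p_value: float
    permutations: int
    perm_mean: float


def _perm_pvalue(observed: float, sims: np.ndarray) -> tuple[float, float]:
    """Two-sided pseudo p-value around the permutation mean."""
    mu = float(sims.mean())
    extreme = int(np.sum(np.abs(sims - mu) >= abs(observed - mu) - 1e-12))
    return (extreme + 1) / (len(sims) + 1), mu


def _check_y(y: np.ndarray, n_min: int = 3) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size < n_min:
        raise ValueError(f"need at least {n_min} units")
    if np.ptp(y) == 0:
        raise ValueError("attribute is constant; statistic undefined")
    return y


def _moran_stat(z: np.ndarray, wb: sparse.csr_matrix, s0: float) -> float:
    return float(len(z) / s0 * (z @ (wb @ z)) / (z @ z))


def morans_I(
    y: np.ndarray, w: WeightsMatrix, permutations: int = 999, seed: int = 0,
    *, row_standardized: bool = False,
) -> GlobalStat:
    """Global Moran's I with a random-permutation null.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2, z = y - mean(y).
    """
    y = _check_y(y)
    wb = w.to_sparse(row_standardized)
    s0 = float(wb.sum())
    z = y - y.mean()
    obs = _moran_stat(z, wb, s0)
    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    for k in range(permutations):
        zp = rng.permutation(z)
        sims[k] = _moran_stat(zp, wb, s0)
    p, mu = _perm_pvalue(obs, sims)
    return GlobalStat(obs, p, permutations, mu)


def gearys_C(
    y: np.ndarray, w: WeightsMatrix, permutations: int = 999, seed: int = 0
) -> GlobalStat:
    """Global Geary's C (binary weights); C < 1 signals positive
    autocorrelation."""
    y = _check_y(y)
    wb = w.to_sparse().tocoo()
    s0 = w.s0
    z = y - y.mean()
    denom = 2.0 * s0 * (z @ z)

    def stat(v: np.ndarray) -> float:
        return float((len(v) - 1) * np.sum((v[wb.row] - v[wb.col]) ** 2) / denom)

    obs = stat(y)
    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    for k in range(permutations):
        sims[k] = stat(rng.permutation(y))
    p, mu = _perm_pvalue(obs, sims)
    return GlobalStat(obs, p, permutations, mu)


def getis_ord_G(
    y: np.ndarray, w: WeightsMatrix, permutations: int = 999, seed: int = 0
) -> GlobalStat:
    """Global Getis–Ord G for non-negative attributes (binary weights)."""
    y = _check_y(y)
    if np.any(y < 0):
        raise ValueError("Getis-Ord G requires non-negative attribute values")
    wb = w.to_sparse()
    total = float(np.sum(np.outer(y, y)) - np.sum(y**2))

    def stat(v: np.ndarray) -> float:
        return float((v @ (wb @ v)) / total)

    obs = stat(y)
    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    for k in range(permutations):
        sims[k] = stat(rng.permutation(y))
    p, mu = _perm_pvalue(obs, sims)
    return GlobalStat(obs, p, permutations, mu)


# ---------------------------------------------------------------------------
# LISA (local Moran)


@dataclass
class LisaResult:
    local_i: np.ndarray
    p_values: np.ndarray
    quadrants: tuple[str, ...]  # HH, LH, LL, HL, ns
    raw_quadrants: tuple[str, ...] = ()  # sign classification before the p filter
    significance: float = 0.05


def local_morans(
    y: np.ndarray, w: WeightsMatrix, permutations: int = 999, seed: int = 0,
    significance: float = 0.05,
) -> LisaResult:
    """Local Moran I_i with conditional-permutation p-values.

    I_i = (z_i / m2) * sum_j w_ij z_j with row-standardized weights and
    m2 = sum z^2 / n.  Quadrants follow the sign of (z_i, lag_i):
    (+,+)=HH, (-,+)=LH, (-,-)=LL, (+,-)=HL; a unit is 'ns' exactly when
    its pseudo p-value exceeds ``significance``.
    """
    y = _check_y(y)
    n = len(y)
    z = y - y.mean()
    m2 = float(z @ z) / n
    wr = w.to_sparse(row_standardized=True)
    lag = wr @ z
    local = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    others = [np.delete(np.arange(n), i) for i in range(n)]
    for i in range(n):
        k = len(w.neighbors[i])
        if k == 0:
            continue
        # condition on z_i: draw neighbour values from the other units
        draws = np.empty(permutations)
        oi = z[others[i]]
        for r in range(permutations):
            picks = rng.choice(oi, size=k, replace=False)
            draws[r] = z[i] * picks.mean() / m2
        extreme = int(np.sum(np.abs(draws - draws.mean())
                             >= abs(local[i] - draws.mean()) - 1e-12))
        p[i] = (extreme + 1) / (permutations + 1)

    raw, quads = [], []
    for i in range(n):
        if z[i] >= 0:
            raw.append("HH" if lag[i] >= 0 else "HL")
        else:
            raw.append("LH" if lag[i] >= 0 else "LL")
        if p[i] > significance or len(w.neighbors[i]) == 0:
            quads.append("ns")
        else:
            quads.append(raw[-1])
    return LisaResult(local, p, tuple(quads), tuple(raw), significance)


# ---------------------------------------------------------------------------
# choropleth classification and ADCM


@dataclass(frozen=True)
class Classification:
    """Ordered upper class bounds and per-unit class indices."""

    method: str
    bins: tuple[float, ...]
    labels: np.ndarray

    @property
    def k(self) -> int:
        return len(self.bins)


def _assign(y: np.ndarray, bins: Sequence[float]) -> np.ndarray:
    # value equal to an upper bound goes to that (lower) class
    b = np.asarray(bins, dtype=float)
    lab = np.searchsorted(b, y, side="left")
    return np.minimum(lab, len(b) - 1)


def _make(method: str, y: np.ndarray, bins: Sequence[float]) -> Classification:
    bins = tuple(float(b) for b in bins)
    return Classification(method, bins, _assign(y, bins))


def _equal_interval(y: np.ndarray, k: int) -> Classification:
    lo, hi = y.min(), y.max()
    bins = lo + (hi - lo) * np.arange(1, k + 1) / k
    bins[-1] = hi
    return _make("equal_interval", y, bins)


def _quantiles(y: np.ndarray, k: int) -> Classification:
    qs = np.quantile(y, np.arange(1, k + 1) / k)
    return _make("quantiles", y, np.unique(qs))


def _maximum_breaks(y: np.ndarray, k: int) -> Classification:
    u = np.unique(y)
    if len(u) < k:
        raise ClassificationError(f"maximum breaks needs >= {k} distinct values")
    gaps = np.diff(u)
    cut_idx = np.sort(np.argsort(gaps)[::-1][: k - 1])
    bins = list((u[cut_idx] + u[cut_idx + 1]) / 2) + [u[-1]]
    return _make("maximum_breaks", y, sorted(bins))


def _box_plot(y: np.ndarray, hinge: float = 1.5) -> Classification:
    q1, q2, q3 = np.percentile(y, [25, 50, 75])
    iqr = q3 - q1
    bins = [q1 - hinge * iqr, q1, q2, q3, q3 + hinge * iqr, y.max()]
    bins = sorted(set(np.maximum.accumulate(bins)))
    if bins[-1] < y.max():
        bins[-1] = y.max()
    # outlier classes may be empty when no value falls beyond a fence
    labels = _assign(y, bins)
    bins = [b for j, b in enumerate(bins) if np.any(labels == j)]
    return _make("box_plot", y, bins)


def _head_tail(y: np.ndarray) -> Classification:
    """Head/tail breaks for heavy-tailed data: split at the mean while
    the head (above-mean part) stays a minority."""
    bins: list[float] = []
    part = y
    while len(part) > 1:
        mu = part.mean()
        head = part[part > mu]
        if len(head) == 0 or len(head) >= len(part) * 0.5:
            break
        bins.append(float(mu))
        part = head
    bins.append(float(y.max()))
    return _make("head_tail", y, bins)


def _jenks_caspall(y: np.ndarray, k: int, max_iter: int = 100) -> Classification:
    """Quantile-seeded iterative reassignment to the nearest class mean
    (1-D k-means); in one dimension the converged classes are contiguous."""
    centers = np.quantile(y, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    if len(centers) < k:
        u = np.unique(y)
        if len(u) < k:
            raise ClassificationError(f"jenks-caspall needs >= {k} distinct values")
        centers = u[np.linspace(0, len(u) - 1, k).astype(int)].astype(float)
    for _ in range(max_iter):
        lab = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
        new = np.array([y[lab == j].mean() if np.any(lab == j) else centers[j]
                        for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = np.sort(new)
    lab = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
    bins = [y[lab == j].max() for j in range(k) if np.any(lab == j)]
    bins[-1] = y.max()
    return _make("jenks_caspall", y, sorted(set(bins)))


def _fisher_jenks_split(ys: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact natural-breaks partition of sorted data by dynamic
    programming on within-class sum of squared deviations."""
    n = len(ys)
    c1 = np.concatenate([[0.0], np.cumsum(ys)])
    c2 = np.concatenate([[0.0], np.cumsum(ys**2)])

    def ssq(i: int, j: int) -> float:  # class covering ys[i:j]
        s, s2, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = np.inf, g - 1
            for i in range(g - 1, j):
                v = cost[g - 1, i] + ssq(i, j)
                if v < best - 1e-12:  # ties toward the lower break
                    best, arg = v, i
            cost[g, j] = best
            back[g, j] = arg
    cuts = []
    j = n
    for g in range(k, 0, -1):
        i = back[g, j]
        cuts.append((i, j))
        j = i
    return [ys[i:j] for i, j in reversed(cuts)]


def _fisher_jenks(y: np.ndarray, k: int) -> Classification:
    if len(np.unique(y)) < k:
        raise ClassificationError(f"fisher-jenks needs >= {k} distinct values")
    parts = _fisher_jenks_split(np.sort(y), k)
    bins = [float(p[-1]) for p in parts]
    return _make("fisher_jenks", y, bins)


def _max_p(y: np.ndarray, k: int, restarts: int = 20, seed: int = 0) -> Classification:
    """Heuristic 1-D max-p style classifier: randomized contiguous
    partitions of the sorted values, locally improved by boundary moves
    to minimize ADCM.  Not an exact optimizer."""
    ys = np.sort(y)
    n = len(ys)
    if k > len(np.unique(ys)):
        raise ClassificationError(f"max-p needs >= {k} distinct values")
    rng = np.random.default_rng(seed)

    def cost(cuts: np.ndarray) -> float:
        edges = [0, *cuts.tolist(), n]
        return sum(float(np.abs(ys[a:b] - np.median(ys[a:b])).sum())
                   for a, b in zip(edges[:-1], edges[1:]))

    best_cuts, best_cost = None, np.inf
    for _ in range(restarts):
        cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
        improved = True
        c = cost(cuts)
        while improved:
            improved = False
            for idx in range(k - 1):
                for delta in (-1, 1):
                    cand = cuts.copy()
                    cand[idx] += delta
                    if not (0 < cand[idx] < n) or len(set(cand)) < k - 1:
                        continue
                    if np.any(np.diff(cand) <= 0):
                        continue
                    cc = cost(cand)
                    if cc < c - 1e-12:
                        cuts, c = cand, cc
                        improved = True
        if c < best_cost:
            best_cuts, best_cost = cuts, c
    edges = [0, *best_cuts.tolist(), n]
    bins = [float(ys[b - 1]) for b in edges[1:]]
    return _make("max_p", y, sorted(set(bins)))


CLASSIFIERS = (
    "equal_interval", "quantiles", "maximum_breaks", "box_plot",
    "head_tail", "jenks_caspall", "fisher_jenks", "max_p",
)


def classify_choropleth(
    y: np.ndarray, k: int = 5, method: str = "fisher_jenks", seed: int = 0
) -> Classification:
    """Classify an attribute into choropleth classes.

    ``box_plot`` and ``head_tail`` determine their own number of
    classes; the others honour ``k``.  Fisher–Jenks is the exact
    optimizer of within-class squared deviation (dynamic programming).
    """
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ClassificationError("k must be >= 1")
    if len(y) < k:
        raise ClassificationError("more classes than units")
    if k > len(np.unique(y)) and method not in ("box_plot", "head_tail"):
        raise ClassificationError(f"k={k} exceeds the number of distinct values")
    if k == 1 and method not in ("box_plot", "head_tail"):
        return _make(method, y, [y.max()])
    if method == "equal_interval":
        return _equal_interval(y, k)
    if method == "quantiles":
        return _quantiles(y, k)
    if method == "maximum_breaks":
        return _maximum_breaks(y, k)
    if method == "box_plot":
        return _box_plot(y)
    if method == "head_tail":
        return _head_tail(y)
    if method == "jenks_caspall":
        return _jenks_caspall(y, k)
    if method == "fisher_jenks":
        return _fisher_jenks(y, k)
    if method == "max_p":
        return _max_p(y, k, seed=seed)
    raise ClassificationError(f"unknown method {method!r}")


def adcm(y: np.ndarray, classification: Classification) -> float:
    """Absolute deviation around class medians; lower is better."""
    y = np.asarray(y, dtype=float)
    total = 0.0
    for j in range(classification.k):
        members = y[classification.labels == j]
        if len(members) == 0:
            raise ClassificationError(f"class {j} of {classification.method} is empty")
        total += float(np.abs(members - np.median(members)).sum())
    return total


def select_classifier(
    y: np.ndarray, k: int = 5, methods: Sequence[str] = CLASSIFIERS, seed: int = 0
) -> pd.DataFrame:
    """Rank classifiers by the ADCM of their own classification
    (ascending; ties keep the input method order)."""
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    rows = []
    for m in methods:
        c = classify_choropleth(y, k=k, method=m, seed=seed)
        rows.append({"method": m, "k": c.k, "adcm": adcm(y, c)})
    return (pd.DataFrame(rows)
            .sort_values("adcm", kind="stable")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# regionalization


def _connected_weights(lattice: SpatialLattice, w: WeightsMatrix) -> WeightsMatrix:
    """Attach islands to their nearest (centroid distance) unit."""
    if not w.islands:
        return w
    warnings.warn(
        f"attaching {len(w.islands)} island(s) to their nearest neighbour",
        stacklevel=3,
    )
    cent = np.array([[g.centroid.x, g.centroid.y] for g in lattice.geometry])
    nb = [set(x) for x in w.neighbors]
    for i in w.islands:
        d = np.linalg.norm(cent - cent[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        nb[i].add(j)
        nb[j].add(i)
    return WeightsMatrix(tuple(tuple(sorted(s)) for s in nb))


def regionalize(lattice: SpatialLattice, w: WeightsMatrix, n_regions: int) -> np.ndarray:
    """Spatially constrained hierarchical clustering (Ward linkage with
    merges restricted to contiguous clusters).  Every returned region
    induces a connected subgraph of the contiguity graph."""
    if n_regions > lattice.n:
        raise ValueError("more regions than units")
    x = lattice.feature_matrix()
    if n_regions == lattice.n:
        return np.arange(lattice.n)
    w = _connected_weights(lattice, w)
    conn = w.to_sparse()
    if n_regions == 1:
        return np.zeros(lattice.n, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns if it must repair connectivity
        model = AgglomerativeClustering(
            n_clusters=n_regions, linkage="ward", connectivity=conn
        )
        labels = model.fit_predict(x)
    return labels


def select_n_regions(
    lattice: SpatialLattice, w: WeightsMatrix, k_range: Sequence[int]
) -> pd.DataFrame:
    """Diagnostics per candidate region count: average silhouette on the
    feature space and total within-region variance.  No automatic
    choice is made."""
    x = lattice.feature_matrix()
    rows = []
    for k in k_range:
        if not 2 <= k <= lattice.n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        labels = regionalize(lattice, w, k)
        wss = sum(float(((x[labels == j] - x[labels == j].mean(axis=0)) ** 2).sum())
                  for j in np.unique(labels))
        sil = silhouette_score(x, labels) if len(np.unique(labels)) > 1 else np.nan
        rows.append({"k": k, "silhouette": sil, "within_ss": wss})
    return pd.DataFrame(rows)


def region_coherence(
    lattice: SpatialLattice, labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Per-region isoperimetric compactness plus a global feature fit.

    Compactness is the isoperimetric quotient 4*pi*A/P^2 of the dissolved
    region polygon (1 for a circle, -> 0 for a thin strip).  Feature fit
    is 1 - within-region SS / total SS over the feature vectors.
    """
    labels = np.asarray(labels)
    x = lattice.feature_matrix()
    tss = float(((x - x.mean(axis=0)) ** 2).sum())
    rows = []
    wss = 0.0
    for j in np.unique(labels):
        mask = labels == j
        poly = unary_union([g for g, m in zip(lattice.geometry, mask) if m])
        if poly.is_empty or poly.length == 0:
            compact = np.nan
        else:
            compact = 4.0 * np.pi * poly.area / poly.length**2
        wj = float(((x[mask] - x[mask].mean(axis=0)) ** 2).sum())
        wss += wj
        rows.append({"region": int(j), "n_units": int(mask.sum()),
                     "compactness": compact, "within_ss": wj})
    fit = 1.0 - wss / tss if tss > 0 else np.nan
    return pd.DataFrame(rows), fit
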