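"""Population-structure diagnostics.

Principal coordinates analysis (classical metric MDS), an individual-based
Mantel test of isolation by distance, Evanno's delta-K post-processing of
STRUCTURE log-likelihood tables, and mutual k-nearest-neighbour networks.
Geographic distances come from latitude/longitude via the haversine formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

__all__ = [
    "PcoaResult",
    "DeltaKTable",
    "MutualKnnGraph",
    "pcoa",
    "mantel",
    "evanno_delta_k",
    "mutual_knn",
    "haversine_distances",
]

EARTH_RADIUS_KM = 6371.0088


def _check_square_symmetric(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


@dataclass
class PcoaResult:
    """Coordinates on the positive principal axes, all eigenvalues sorted
    descending, and each axis's share of the positive-eigenvalue total."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_explained: np.ndarray


def pcoa(d: np.ndarray) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Double-centre ``B = -1/2 J D^2 J``, eigendecompose, and scale the
    eigenvectors of the positive eigenvalues by their square roots.  Negative
    eigenvalues (non-Euclidean input) are reported but contribute no axes.
    """
    d = _check_square_symmetric(d, "distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals).max()) if n else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    pct = np.where(pos, vals / pos_sum, 0.0) * 100 if pos_sum > 0 else np.zeros(n)
    return PcoaResult(coordinates=coords, eigenvalues=vals, percent_explained=pct)


def mantel(
    dg: np.ndarray,
    dx: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices over matching units.

    ``r`` is the Pearson correlation of the upper-triangle entries; the
    one-sided p-value counts permutations (joint row/column reshuffles of the
    second matrix) with ``r`` at least as large:
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``.
    """
    dg = _check_square_symmetric(dg, "genetic distance matrix")
    dx = _check_square_symmetric(dx, "geographic distance matrix")
    if dg.shape != dx.shape:
        raise ValueError("matrices must have matching shapes")
    iu = np.triu_indices(dg.shape[0], k=1)
    x, y = dg[iu], dx[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")
    x = (x - x.mean()) / x.std()
    r_obs = float(np.mean(x * (y - y.mean()) / y.std()))
    if n_perm == 0:
        return r_obs, float("nan")
    if rng is None:
        raise ValueError("permutation test needs an rng")
    n = dg.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = dx[np.ix_(perm, perm)][iu]
        r_perm = np.mean(x * (yp - yp.mean()) / yp.std())
        if r_perm >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def haversine_distances(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from latitude/longitude in degrees."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class DeltaKTable:
    """Evanno post-processing of STRUCTURE runs: per K the mean and SD of
    lnP(D) across runs and, for interior K, delta K."""

    table: pd.DataFrame
    best_k: int | None


def evanno_delta_k(runs: pd.DataFrame) -> DeltaKTable:
    """Delta K from a (K, run, lnP) table.

    ``deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``,
    defined only for interior K; K values where the across-run SD is zero are
    flagged NaN.  Needs at least 3 consecutive K values with >= 2 runs each.
    """
    required = {"K", "lnP"}
    if not required.issubset(runs.columns):
        raise ValueError(f"table must have columns {sorted(required)} (plus a run id)")
    grouped = runs.groupby("K")["lnP"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    counts = grouped.count()
    ks = np.asarray(sorted(mean.index))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need at least 3 consecutive K values")
    if (counts < 2).any():
        raise ValueError("need at least 2 runs per K")
    delta = pd.Series(np.nan, index=ks, dtype=float)
    for k in ks[1:-1]:
        second_diff = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        delta[k] = second_diff / sd[k] if sd[k] > 0 else np.nan
    table = pd.DataFrame(
        {"mean_lnP": mean, "sd_lnP": sd, "n_runs": counts, "delta_K": delta}
    )
    table.index.name = "K"
    interior = delta.dropna()
    best_k = int(interior.idxmax()) if len(interior) else None
    return DeltaKTable(table=table, best_k=best_k)


@dataclass
class MutualKnnGraph:
    """Undirected graph over individuals; an edge joins i and j iff each is
    among the other's k nearest neighbours (ties broken by index order)."""

    n_nodes: int
    k: int
    edges: np.ndarray  # (n_edges, 2), i < j

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj

    def n_components(self) -> int:
        from scipy.sparse.csgraph import connected_components

        return int(connected_components(self.adjacency(), directed=False)[0])


def mutual_knn(d: np.ndarray, k: int) -> MutualKnnGraph:
    """Mutual k-nearest-neighbour graph from a distance matrix."""
    d = _check_square_symmetric(d, "distance matrix")
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    neighbours = []  # k nearest of each node, self excluded, ties by index
    for i in range(n):
        order = [int(j) for j in np.argsort(d[i], kind="stable") if j != i]
        neighbours.append(set(order[:k]))
    edges = [
        (i, j)
        for i in range(n)
        for j in neighbours[i]
        if i < j and i in neighbours[j]
    ]
    return MutualKnnGraph(n_nodes=n, k=k, edges=np.array(sorted(edges), dtype=np.int64).reshape(-1, 2))
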