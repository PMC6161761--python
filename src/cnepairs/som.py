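"""Kohonen self-organizing map on a hexagonal grid, plus unit-level analyses.

The SOM is trained online: at each step a row is drawn uniformly at random
from the input, its best-matching unit (BMU, nearest codebook by Euclidean
distance) is found, and every codebook within the bubble neighborhood of the
BMU moves toward the sample,

    m_i(t+1) = m_i(t) + alpha(t) * 1[grid_dist(c, i) <= r(t)] * (x(t) - m_i(t)).

The learning rate alpha and bubble radius r decrease linearly over the run.
The radius starts at the 2/3 quantile of the grid distances and ends at 0,
so roughly the first half of training orders the map while the second half
updates best-matching units alone, letting each codebook settle on the
centroid of its members (the scheme the classic SOM packages default to).
The estimator follows the scikit-learn protocol (fit / predict /
get_params), so it composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .io import HISTONE_MARKS
from .epigenetics import SORTED_REGIONS


def hexagonal_grid(n_rows: int, n_cols: int) -> np.ndarray:
    """Unit-center coordinates of an offset hexagonal grid (n_rows x n_cols).

    Odd rows are shifted half a cell; row pitch is sqrt(3)/2, giving unit
    distance between neighboring centers.  Units are numbered row-major,
    starting at 1 to match the usual SOM-package convention.
    """
    coords = []
    for r in range(n_rows):
        for c in range(n_cols):
            coords.append((c + 0.5 * (r % 2), r * np.sqrt(3) / 2))
    return np.asarray(coords)


class KohonenSOM(ClusterMixin, BaseEstimator):
    """Self-organizing map with hexagonal topology and bubble neighborhood.

    Parameters
    ----------
    n_rows, n_cols : grid shape (default 4 x 3 = 12 units).
    n_iter : online training steps (default 1000).
    alpha_start, alpha_end : linear learning-rate schedule.
    radius_start : initial bubble radius; None = 2/3 quantile of grid distances.
    radius_end : final bubble radius (default 0.0, i.e. BMU only).
    random_state : seed for initialization and sample order.

    Attributes
    ----------
    codebooks_ : (n_units, n_features) codebook vectors after training.
    quantization_error_ : mean distance of training rows to their BMU.
    initial_quantization_error_ : same, for the random initialization.
    labels_ : BMU (1-based unit id) of each training row.
    """

    def __init__(self, n_rows: int = 4, n_cols: int = 3, n_iter: int = 1000,
                 alpha_start: float = 0.05, alpha_end: float = 0.01,
                 radius_start: float | None = None, radius_end: float = 0.0,
                 random_state: int | None = 0):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.n_iter = n_iter
        self.alpha_start = alpha_start
        self.alpha_end = alpha_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.random_state = random_state

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        n, _d = X.shape
        if n < self.n_units:
            raise ValueError(f"need >= {self.n_units} rows, got {n}")
        rng = np.random.default_rng(self.random_state)
        grid = hexagonal_grid(self.n_rows, self.n_cols)
        grid_dist = cdist(grid, grid)
        init_idx = rng.choice(n, size=self.n_units, replace=False)
        codebooks = X[init_idx].copy()
        self.initial_quantization_error_ = float(
            cdist(X, codebooks).min(axis=1).mean())

        r0 = self.radius_start
        if r0 is None:
            r0 = float(np.quantile(grid_dist, 2 / 3))
        for t in range(self.n_iter):
            frac = t / max(self.n_iter - 1, 1)
            alpha = self.alpha_start + frac * (self.alpha_end - self.alpha_start)
            radius = r0 + frac * (self.radius_end - r0)
            x = X[rng.integers(n)]
            bmu = int(np.argmin(((codebooks - x) ** 2).sum(axis=1)))
            hood = grid_dist[bmu] <= radius
            codebooks[hood] += alpha * (x - codebooks[hood])

        self.codebooks_ = codebooks
        self.grid_coords_ = grid
        self.labels_ = self._assign(X)
        self.quantization_error_ = float(cdist(X, codebooks).min(axis=1).mean())
        return self

    def _assign(self, X) -> np.ndarray:
        d = cdist(np.asarray(X, dtype=float), self.codebooks_)
        return d.argmin(axis=1) + 1  # argmin breaks ties toward lowest unit id

    def predict(self, X) -> np.ndarray:
        """1-based BMU id per row; Euclidean ties break to the lowest id."""
        check_is_fitted(self, "codebooks_")
        return self._assign(X)


def train_som(matrix: pd.DataFrame, seed: int = 0, **params) -> KohonenSOM:
    """Convenience wrapper: fit a :class:`KohonenSOM` on a feature matrix."""
    som = KohonenSOM(random_state=seed, **params)
    return som.fit(matrix.to_numpy())


# ---------------------------------------------------------------------------
# unit summaries, reciprocal matching, unit clustering
# ---------------------------------------------------------------------------

def unit_summaries(features: pd.DataFrame, assignments: np.ndarray,
                   n_units: int, marks=HISTONE_MARKS) -> pd.DataFrame:
    """Mean enrichment per (region x mark), averaged over tissues and members.

    Feature columns must be named ``tissue|region|mark`` (the feature-matrix
    convention).  Rows are units (1..n_units); empty units yield NaN rows.
    This is the tissue-free unit fingerprint used to match units across
    species-specific maps trained on different tissue panels.
    """
    marks = sorted(marks)
    cols = [f"{r}|{m}" for r in SORTED_REGIONS for m in marks]
    parsed = [c.split("|") for c in features.columns]
    rows = []
    for u in range(1, n_units + 1):
        member = features.iloc[np.asarray(assignments) == u]
        if len(member) == 0:
            rows.append([np.nan] * len(cols))
            continue
        row = []
        for r in SORTED_REGIONS:
            for m in marks:
                sel = [c for c, (_t, cr, cm) in zip(features.columns, parsed)
                       if cr == r and cm == m]
                row.append(float(member[sel].to_numpy().mean()))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.RangeIndex(1, n_units + 1, name="unit"),
                        columns=cols)


def reciprocal_unit_matching(summaries_a: pd.DataFrame,
                             summaries_b: pd.DataFrame):
    """Reciprocally nearest (Euclidean) unit pairs between two maps.

    Unit a matches unit b iff b is a's nearest unit in B and a is b's
    nearest unit in A.  Returns (matches, unmatched_a, unmatched_b) with
    matches as a list of (unit_a, unit_b).  Units with undefined (empty)
    summaries never match.
    """
    a_valid = summaries_a.dropna()
    b_valid = summaries_b.dropna()
    if len(a_valid) == 0 or len(b_valid) == 0:
        return [], list(summaries_a.index), list(summaries_b.index)
    d = cdist(a_valid.to_numpy(), b_valid.to_numpy())
    best_b = d.argmin(axis=1)
    best_a = d.argmin(axis=0)
    matches = []
    for i in range(len(a_valid)):
        j = best_b[i]
        if best_a[j] == i:
            matches.append((a_valid.index[i], b_valid.index[j]))
    matched_a = {m[0] for m in matches}
    matched_b = {m[1] for m in matches}
    unmatched_a = [u for u in summaries_a.index if u not in matched_a]
    unmatched_b = [u for u in summaries_b.index if u not in matched_b]
    return matches, unmatched_a, unmatched_b


def cluster_units(summaries: pd.DataFrame, k: int = 4,
                  matched_units: list | None = None) -> dict:
    """Complete-linkage hierarchical clustering of unit fingerprints.

    Cut at ``k`` clusters.  When ``matched_units`` is given (the cross-map
    case), only those units define the clusters and every remaining unit is
    assigned to the cluster of its nearest (Euclidean) matched unit.
    Returns unit -> cluster id (1..k).
    """
    valid = summaries.dropna()
    units = list(valid.index)
    if matched_units is not None:
        core = [u for u in units if u in set(matched_units)]
    else:
        core = units
    if len(core) < k:
        raise ValueError(f"cannot form {k} clusters from {len(core)} units")
    core_X = valid.loc[core].to_numpy()
    Z = linkage(core_X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    out = dict(zip(core, (int(l) for l in labels)))
    rest = [u for u in units if u not in out]
    if rest:
        d = cdist(valid.loc[rest].to_numpy(), core_X)
        for u, row in zip(rest, d):
            out[u] = out[core[int(row.argmin())]]
    return out
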