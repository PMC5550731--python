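"""Emergent self-organizing map (ESOM) with U-matrix and watershed clustering.

A large Kohonen lattice — by default a 50 x 80 toroid, i.e. opposite edges
connected — is trained online on the drug x process matrix.  Each neuron
carries a weight vector in the feature space; training presents every data
row per epoch in a seeded shuffled order, moves the best-matching unit
(BMU) and its grid neighbourhood toward the row with a Gaussian kernel, and
decays the learning rate and radius linearly across epochs.

Cluster structure is read off the *U-matrix*: the per-neuron mean distance
to its 8 grid neighbours' weights.  Valleys are clusters and ridges are
cluster borders; a steepest-descent watershed assigns every neuron to the
basin of the local minimum it drains into, and the repurposing candidates
are the data rows whose BMUs share a basin with the virtual drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class EsomConfig:
    """Grid geometry and training schedule of an emergent SOM.

    Defaults follow Databionics-ESOM conventions for a 50 x 80 toroid
    lattice trained for 50 epochs: Gaussian neighbourhood, radius decaying
    linearly 24 -> 1 and learning rate 0.5 -> 0.1.
    """

    rows: int = 50
    cols: int = 80
    epochs: int = 50
    toroid: bool = True
    radius_start: float = 24.0
    radius_end: float = 1.0
    rate_start: float = 0.5
    rate_end: float = 0.1
    seed: int | None = None
    smooth_umatrix: bool = True
    min_basin_depth: float = 0.3

    def __post_init__(self):
        if self.rows * self.cols < 4:
            raise ValueError("grid needs at least 4 neurons")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.radius_start >= self.radius_end >= 0):
            raise ValueError("need radius_start >= radius_end >= 0")


def grid_distance(
    p: tuple[int, int],
    q: tuple[int, int],
    rows: int,
    cols: int,
    toroid: bool = True,
) -> float:
    """Euclidean grid distance between neuron coordinates, wrapped on a toroid.

    On the toroid each axis difference is ``min(|delta|, size - |delta|)``.
    """
    for (r, c) in (p, q):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"coordinate {(r, c)} outside the {rows}x{cols} grid")
    dr = abs(p[0] - q[0])
    dc = abs(p[1] - q[1])
    if toroid:
        dr = min(dr, rows - dr)
        dc = min(dc, cols - dc)
    return float(np.hypot(dr, dc))


def _axis_delta(size: int, origin: int, toroid: bool) -> np.ndarray:
    d = np.abs(np.arange(size) - origin)
    if toroid:
        d = np.minimum(d, size - d)
    return d.astype(float)


class EsomMap(BaseEstimator):
    """Scikit-learn style emergent SOM estimator.

    Parameters mirror :class:`EsomConfig`.  After :meth:`fit`:

    Attributes
    ----------
    weights_ : ndarray, shape (rows, cols, n_features)
        Trained weight field.
    u_matrix_ : ndarray, shape (rows, cols)
        Mean weight distance to the 8 grid neighbours.
    quantization_error_ : float
        Mean distance of training rows to their BMU weights.
    """

    def __init__(
        self,
        rows: int = 50,
        cols: int = 80,
        epochs: int = 50,
        toroid: bool = True,
        radius_start: float = 24.0,
        radius_end: float = 1.0,
        rate_start: float = 0.5,
        rate_end: float = 0.1,
        seed: int | None = None,
        smooth_umatrix: bool = True,
        min_basin_depth: float = 0.3,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.toroid = toroid
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.rate_start = rate_start
        self.rate_end = rate_end
        self.seed = seed
        self.smooth_umatrix = smooth_umatrix
        self.min_basin_depth = min_basin_depth

    # -- configuration ------------------------------------------------------
    @property
    def config(self) -> EsomConfig:
        return EsomConfig(
            rows=self.rows,
            cols=self.cols,
            epochs=self.epochs,
            toroid=self.toroid,
            radius_start=self.radius_start,
            radius_end=self.radius_end,
            rate_start=self.rate_start,
            rate_end=self.rate_end,
            seed=self.seed,
            smooth_umatrix=self.smooth_umatrix,
            min_basin_depth=self.min_basin_depth,
        )

    # -- fitting ------------------------------------------------------------
    def init_weights(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Per-component uniform draws from each data column's range.

        A constant column pins that weight component to the constant.
        """
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        w = rng.uniform(lo, hi, size=(self.rows * self.cols, X.shape[1]))
        const = hi == lo
        if np.any(const):
            w[:, const] = lo[const]
        return w

    def fit(self, X, y=None):
        cfg = self.config  # validates parameters
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-d array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        ss = np.random.SeedSequence(self.seed)
        init_ss, shuffle_ss = ss.spawn(2)
        weights = self.init_weights(X, np.random.default_rng(init_ss))
        shuffle_rng = np.random.default_rng(shuffle_ss)

        n_samples = X.shape[0]
        denom = max(self.epochs - 1, 1)
        for epoch in range(self.epochs):
            frac = epoch / denom if self.epochs > 1 else 0.0
            rate = self.rate_start + (self.rate_end - self.rate_start) * frac
            radius = self.radius_start + (self.radius_end - self.radius_start) * frac
            order = shuffle_rng.permutation(n_samples)
            for i in order:
                x = X[i]
                flat_bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                r0, c0 = divmod(flat_bmu, self.cols)
                if radius > 0:
                    dr = _axis_delta(self.rows, r0, self.toroid)
                    dc = _axis_delta(self.cols, c0, self.toroid)
                    g2 = dr[:, None] ** 2 + dc[None, :] ** 2
                    h = np.exp(-g2 / (2.0 * radius**2)).ravel()
                    weights += rate * h[:, None] * (x - weights)
                else:  # radius 0: only the BMU moves (kernel limit)
                    weights[flat_bmu] += rate * (x - weights[flat_bmu])
            if not np.all(np.isfinite(weights)):
                raise FloatingPointError(
                    f"non-finite weights appeared in epoch {epoch}"
                )

        self.weights_ = weights.reshape(self.rows, self.cols, X.shape[1])
        self.n_features_in_ = X.shape[1]
        self.u_matrix_ = self.compute_umatrix()
        bmus = self.transform(X)
        self.quantization_error_ = float(
            np.mean(
                np.linalg.norm(
                    X - self.weights_[bmus[:, 0], bmus[:, 1]], axis=1
                )
            )
        )
        return self

    # -- lookup -------------------------------------------------------------
    def best_matching_unit(self, x) -> tuple[int, int]:
        """Coordinate of the neuron with the closest weight vector.

        Ties resolve to the smallest (row, col) in lexicographic order —
        the row-major argmin.
        """
        self._check_fitted()
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features_in_,):
            raise ValueError(
                f"expected a vector of length {self.n_features_in_}, got {x.shape}"
            )
        flat = self.weights_.reshape(-1, self.n_features_in_)
        idx = int(np.argmin(((flat - x) ** 2).sum(axis=1)))
        return divmod(idx, self.cols)

    def transform(self, X) -> np.ndarray:
        """BMU coordinates for each row of X, shape (n_samples, 2)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return np.array([self.best_matching_unit(x) for x in X], dtype=int)

    def bmu_map(self, X, labels: Sequence[str]) -> dict[str, tuple[int, int]]:
        """Label -> BMU coordinate; several labels may share a neuron."""
        coords = self.transform(X)
        if len(labels) != len(coords):
            raise ValueError("labels and rows of X differ in length")
        return {lab: (int(r), int(c)) for lab, (r, c) in zip(labels, coords)}

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of rows to their BMU weights."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        bmus = self.transform(X)
        return float(
            np.mean(np.linalg.norm(X - self.weights_[bmus[:, 0], bmus[:, 1]], axis=1))
        )

    # -- U-matrix -----------------------------------------------------------
    def compute_umatrix(self) -> np.ndarray:
        """Mean weight distance of each neuron to its 8 grid neighbours.

        On a planar grid, border neurons average over their existing
        neighbours only.
        """
        self._check_fitted()
        return umatrix_heights(self.weights_, toroid=self.toroid)

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("EsomMap is not fitted yet; call fit(X) first")


def umatrix_heights(weights: np.ndarray, toroid: bool = True) -> np.ndarray:
    """U-matrix of a (rows, cols, d) weight field: mean 8-neighbour distance."""
    rows, cols, _ = weights.shape
    total = np.zeros((rows, cols))
    count = np.zeros((rows, cols))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(weights, -dr, axis=0), -dc, axis=1)
            dist = np.linalg.norm(weights - shifted, axis=2)
            if toroid:
                total += dist
                count += 1.0
            else:
                valid = np.ones((rows, cols), dtype=bool)
                if dr == -1:
                    valid[0, :] = False
                elif dr == 1:
                    valid[-1, :] = False
                if dc == -1:
                    valid[:, 0] = False
                elif dc == 1:
                    valid[:, -1] = False
                total[valid] += dist[valid]
                count[valid] += 1.0
    return total / count


def smooth_heights(heights: np.ndarray, toroid: bool = True) -> np.ndarray:
    """Single-pass 3x3 mean filter; suppresses single-neuron micro-basins."""
    rows, cols = heights.shape
    total = np.zeros_like(heights, dtype=float)
    count = np.zeros_like(heights, dtype=float)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            shifted = np.roll(np.roll(heights, -dr, axis=0), -dc, axis=1)
            if toroid:
                total += shifted
                count += 1.0
            else:
                valid = np.ones((rows, cols), dtype=bool)
                if dr == -1:
                    valid[0, :] = False
                elif dr == 1:
                    valid[-1, :] = False
                if dc == -1:
                    valid[:, 0] = False
                elif dc == 1:
                    valid[:, -1] = False
                total[valid] += shifted[valid]
                count[valid] += 1.0
    return total / count


def _neighbours(r: int, c: int, rows: int, cols: int, toroid: bool):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nr, nc = r + dr, c + dc
            if toroid:
                nr %= rows
                nc %= cols
            elif not (0 <= nr < rows and 0 <= nc < cols):
                continue
            yield nr, nc


def watershed_basins(heights: np.ndarray, toroid: bool = True) -> np.ndarray:
    """Steepest-descent watershed labelling of a height field.

    Every cell follows its lowest neighbour downhill until a local minimum;
    cells draining into the same minimum share a basin id.  Plateau
    tie-break: prefer the strictly lower neighbour with (lowest height,
    then lexicographic coordinate); on an exact plateau, move to the
    lexicographically smallest equal-height neighbour that precedes the
    cell, which funnels plateaus deterministically and terminates.  Basin
    ids are consecutive integers in scan order of their minima.
    """
    rows, cols = heights.shape
    step = -np.ones((rows, cols, 2), dtype=int)
    for r in range(rows):
        for c in range(cols):
            h = heights[r, c]
            best = None  # (height, coord) of downhill target
            plateau = None
            for nr, nc in _neighbours(r, c, rows, cols, toroid):
                nh = heights[nr, nc]
                if nh < h:
                    cand = (nh, (nr, nc))
                    if best is None or cand < best:
                        best = cand
                elif nh == h and (nr, nc) < (r, c):
                    if plateau is None or (nr, nc) < plateau:
                        plateau = (nr, nc)
            if best is not None:
                step[r, c] = best[1]
            elif plateau is not None:
                step[r, c] = plateau
            else:
                step[r, c] = (r, c)  # local minimum

    basins = -np.ones((rows, cols), dtype=int)
    next_id = 0
    for r in range(rows):
        for c in range(cols):
            if basins[r, c] >= 0:
                continue
            path = []
            cur = (r, c)
            while basins[cur] < 0:
                path.append(cur)
                basins[cur] = -2  # on current path
                nxt = tuple(step[cur])
                if nxt == cur:
                    break
                cur = nxt
            if basins[cur] == -2:  # reached a minimum (or closed the path)
                bid = next_id
                next_id += 1
            else:
                bid = basins[cur]
            for cell in path:
                basins[cell] = bid
    return basins


def merge_shallow_basins(
    heights: np.ndarray,
    basins: np.ndarray,
    min_depth: float,
    toroid: bool = True,
) -> np.ndarray:
    """Merge watershed basins whose pour depth is below *min_depth*.

    A raw steepest-descent watershed splits at every ridge regardless of
    amplitude, so a map texture of shallow folds over-segments badly.  This
    persistence criterion removes basins whose *dynamics* — the height
    difference between the lowest saddle to a deeper neighbouring basin and
    the basin's own minimum — is less than ``min_depth`` (absolute height
    units).  Shallowest basins are merged first; deep valleys survive.
    """
    if min_depth <= 0:
        return basins
    rows, cols = heights.shape
    basins = basins.copy()
    while True:
        ids = np.unique(basins)
        if len(ids) <= 1:
            return basins
        mins = {int(b): float(heights[basins == b].min()) for b in ids}
        saddle: dict[tuple[int, int], float] = {}
        for r in range(rows):
            for c in range(cols):
                b = int(basins[r, c])
                for nr, nc in _neighbours(r, c, rows, cols, toroid):
                    b2 = int(basins[nr, nc])
                    if b2 != b:
                        s = max(float(heights[r, c]), float(heights[nr, nc]))
                        key = (min(b, b2), max(b, b2))
                        if s < saddle.get(key, np.inf):
                            saddle[key] = s
        best = None
        for (a, b), s in saddle.items():
            shallow, deep = (a, b) if mins[a] >= mins[b] else (b, a)
            dyn = s - mins[shallow]
            cand = (dyn, shallow, deep)
            if dyn < min_depth and (best is None or cand < best):
                best = cand
        if best is None:
            return basins
        _, shallow, deep = best
        basins[basins == shallow] = deep


@dataclass(frozen=True)
class ClusterResult:
    """Watershed basins plus the membership of the seed drug's basin."""

    basins: np.ndarray  # (rows, cols) int basin ids
    seed_basin: int
    members: tuple[str, ...]  # labels sharing the seed's basin, seed excluded
    excluded: tuple[str, ...]
    heights: np.ndarray = field(repr=False, default=None)

    @property
    def n_basins(self) -> int:
        return int(self.basins.max()) + 1


def extract_cluster(
    heights: np.ndarray,
    bmus: Mapping[str, tuple[int, int]],
    seed_label: str = "PainInsensitivity",
    toroid: bool = True,
    smooth: bool = True,
    min_basin_depth: float = 0.3,
) -> ClusterResult:
    """Labels whose BMUs fall into the watershed basin of *seed_label*.

    The U-heights are optionally smoothed (3x3 mean, default on) before the
    watershed, and basins shallower than ``min_basin_depth`` times the
    height range are merged into their deeper neighbours (set 0 to keep the
    raw watershed).  The seed itself is excluded from the member list.
    """
    if seed_label not in bmus:
        raise KeyError(f"seed label {seed_label!r} missing from the BMU map")
    used = smooth_heights(heights, toroid=toroid) if smooth else heights
    basins = watershed_basins(used, toroid=toroid)
    span = float(used.max() - used.min())
    if min_basin_depth > 0 and span > 0:
        basins = merge_shallow_basins(
            used, basins, min_depth=min_basin_depth * span, toroid=toroid
        )
        # re-index basin ids consecutively for a stable external contract
        remap = {int(b): i for i, b in enumerate(np.unique(basins))}
        basins = np.vectorize(remap.__getitem__)(basins)
    seed_basin = int(basins[bmus[seed_label]])
    members = tuple(
        sorted(
            lab
            for lab, coord in bmus.items()
            if lab != seed_label and int(basins[coord]) == seed_basin
        )
    )
    excluded = tuple(
        sorted(
            lab
            for lab, coord in bmus.items()
            if lab != seed_label and int(basins[coord]) != seed_basin
        )
    )
    return ClusterResult(
        basins=basins,
        seed_basin=seed_basin,
        members=members,
        excluded=excluded,
        heights=used,
    )


def render_umatrix(heights: np.ndarray, bmus: Mapping[str, tuple[int, int]] | None = None, path=None):
    """Optional PNG rendering of the U-matrix with BMU dots (visual aid only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(heights, cmap="terrain", origin="upper")
    fig.colorbar(im, ax=ax, label="U-height")
    if bmus:
        rr = [coord[0] for coord in bmus.values()]
        cc = [coord[1] for coord in bmus.values()]
        ax.scatter(cc, rr, s=12, c="crimson", edgecolors="white", linewidths=0.3)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
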