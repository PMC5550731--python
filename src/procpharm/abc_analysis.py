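"""Computed ABC analysis: partition positive values into "important few" and the rest.

The ABC curve plots, for items sorted in decreasing order of magnitude, the
cumulative fraction of items (x) against the cumulative fraction of the
total sum (y).  Set A ("the important few") runs up to the x-position where
the curve's slope falls to 1; the slope is evaluated on the discrete curve
segments, so for item i (1-based) the segment slope is ``n * v_(i) / sum(v)``.
Applying the analysis to its own A set ("nested" ABC) prunes aggressively
while remaining scale invariant.

Used here on the reciprocals of drug-to-virtual-drug distances: large
reciprocals (close drugs) are the important few worth clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class AbcCurve:
    """Empirical ABC curve of a positive value set.

    ``order`` maps curve position to the original index of the value
    (stable decreasing sort).  ``x[i]`` and ``y[i]`` are the cumulative
    item and sum fractions after the (i+1)-th largest value.
    """

    values: np.ndarray  # sorted decreasing
    order: np.ndarray  # original indices in sorted order
    x: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def slopes(self) -> np.ndarray:
        """Per-segment slopes; non-increasing for decreasing-sorted values."""
        return self.n * self.values / self.values.sum()


@dataclass(frozen=True)
class AbcPartition:
    """Disjoint A/B/C index sets (original indexing) with their boundaries."""

    A: tuple[int, ...]
    B: tuple[int, ...]
    C: tuple[int, ...]
    boundary_ab: int  # item count in A
    boundary_bc: int  # item count in A ∪ B


def _validated(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("ABC analysis needs a non-empty 1-d value vector")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("ABC analysis is defined for positive finite values only")
    return v


def abc_curve(values) -> AbcCurve:
    """Build the ABC curve of *values* (all positive and finite).

    Ties in the decreasing sort are broken by original index (stable sort),
    so the curve — and everything derived from it — is deterministic.
    """
    v = _validated(values)
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    n = len(v)
    x = np.arange(1, n + 1) / n
    y = np.cumsum(sorted_v) / sorted_v.sum()
    return AbcCurve(values=sorted_v, order=order, x=x, y=y)


def a_boundary(curve: AbcCurve) -> int:
    """Item count of set A: where the curve's slope falls to 1.

    With segment slopes ``s_i`` non-increasing, the boundary is the smallest
    i with ``s_i <= 1``; A ends just before it when the slope there is
    strictly below 1 (and i > 1), otherwise A includes item i.  A is never
    empty, and for all-equal values (the diagonal) it shrinks to the single
    first item so that nested application terminates.
    """
    s = curve.slopes
    idx = int(np.argmax(s <= 1.0)) + 1  # 1-based; exists since mean slope is 1
    if s[idx - 1] < 1.0 and idx > 1:
        return idx - 1
    return idx


def abc_partition(values) -> AbcPartition:
    """Full A/B/C partition of *values* (original indices).

    A comes from :func:`a_boundary`; the B|C split is placed at the curve
    point after A closest (Euclidean) to the point (1, 1).
    """
    curve = abc_curve(values)
    n_a = a_boundary(curve)
    if n_a >= curve.n:
        n_bc = curve.n
    else:
        tail = np.arange(n_a, curve.n)  # 0-based positions after A
        d2 = (1.0 - curve.x[tail]) ** 2 + (1.0 - curve.y[tail]) ** 2
        n_bc = int(tail[np.argmin(d2)]) + 1
    order = curve.order
    return AbcPartition(
        A=tuple(int(i) for i in order[:n_a]),
        B=tuple(int(i) for i in order[n_a:n_bc]),
        C=tuple(int(i) for i in order[n_bc:]),
        boundary_ab=n_a,
        boundary_bc=n_bc,
    )


def nested_abc(values, depth: int = 2) -> tuple[int, ...]:
    """Indices surviving *depth* successive A-selections.

    Depth 1 equals the plain A set; each further level re-submits the
    surviving values, so the result shrinks monotonically with depth.
    Returned indices refer to the original vector, sorted ascending.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    v = _validated(values)
    current = np.arange(len(v))
    for _ in range(depth):
        if len(current) == 0:
            break
        part = abc_partition(v[current])
        current = current[list(part.A)]
    return tuple(sorted(int(i) for i in current))


def nested_abc_stages(values, depth: int = 2) -> list[tuple[int, ...]]:
    """Original-index A-sets after each of *depth* successive selections."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    v = _validated(values)
    current = np.arange(len(v))
    stages: list[tuple[int, ...]] = []
    for _ in range(depth):
        if len(current):
            part = abc_partition(v[current])
            current = current[list(part.A)]
        stages.append(tuple(sorted(int(i) for i in current)))
    return stages


def select_by_reciprocal_distance(
    distances, depth: int = 2
) -> tuple[int, ...]:
    """Nested ABC selection on reciprocal distances, tolerant of zeros.

    A zero distance (an item identical to the reference) has an undefined
    reciprocal; such items bypass the ABC analysis and are force-retained.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1-d distance vector")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")
    zero = np.flatnonzero(d == 0)
    positive = np.flatnonzero(d > 0)
    selected = set(int(i) for i in zero)
    if len(positive):
        kept = nested_abc(1.0 / d[positive], depth=depth)
        selected.update(int(positive[i]) for i in kept)
    return tuple(sorted(selected))


class NestedAbcSelector(BaseEstimator):
    """Scikit-learn style selector wrapping :func:`nested_abc`.

    Parameters
    ----------
    depth : int, default 2
        Number of successive A-selections.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_values,)
        Mask of the surviving items.
    selected_indices_ : tuple of int
        Surviving original indices, ascending.
    """

    def __init__(self, depth: int = 2):
        self.depth = depth

    def fit(self, X, y=None):
        v = _validated(np.ravel(np.asarray(X, dtype=float)))
        self.selected_indices_ = nested_abc(v, depth=self.depth)
        self.support_ = np.zeros(len(v), dtype=bool)
        self.support_[list(self.selected_indices_)] = True
        self.n_features_in_ = len(v)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_
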