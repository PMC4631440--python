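"""Similarity-network construction for one-dimensional samples.

Two values are linked when they lie within ``±zeta`` of each other.  The
resulting graph is a unit-interval (indifference) graph: on the sorted
values, connected components are exactly the maximal runs whose consecutive
gaps are all ``<= zeta``.  Two constructors are provided:

* :func:`build_network_reference` — the literal O(n^2) pairwise rule, with an
  explicit boolean adjacency matrix.  Intended as the oracle for testing and
  for small inputs (n up to ~1000).
* :func:`build_network_fast` — an O(n log n) equivalent using binary search
  on the sorted values; never materializes the adjacency matrix.

The graph is simple: the diagonal is excluded, so a value with no neighbours
has degree 0.  Exact duplicates are distinct nodes and are adjacent for any
``zeta >= 0`` (including ``zeta == 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InvalidParameterError, InvalidSampleError

__all__ = [
    "Sample",
    "SimilarityNetwork",
    "build_network_reference",
    "build_network_fast",
    "giant_cluster_proportion",
]


@dataclass(frozen=True, eq=False)
class Sample:
    """An ordered multiset of finite real values plus provenance metadata.

    Parameters
    ----------
    values
        One-dimensional sequence of finite reals.  NaN and ±inf are rejected.
    label
        Free-text provenance (file name, distribution name, ...).
    meta
        Optional ingestion/bookkeeping metadata (rejected-row counts, scale).
    """

    values: np.ndarray
    label: str = ""
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.array(self.values, dtype=float, copy=True)
        if arr.ndim != 1:
            raise InvalidSampleError("sample values must be one-dimensional")
        if arr.size == 0:
            raise InvalidSampleError("sample must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise InvalidSampleError("sample values must be finite (no NaN/inf)")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Sample(n={self.n}, label={self.label!r})"


@dataclass(eq=False)
class SimilarityNetwork:
    """The ±zeta similarity graph of a sample at a fixed bandwidth.

    ``cluster_labels`` are canonical: clusters are numbered in increasing
    order of their smallest member value, so label 0 always contains the
    sample minimum.  ``giant_label`` is the label of the largest cluster;
    ties among equal-size largest clusters resolve to the cluster containing
    the smallest value (i.e. the lowest label among the tied ones).
    """

    sample: Sample
    zeta: float
    degrees: np.ndarray          # per value, original input order
    edge_count: int
    cluster_labels: np.ndarray   # per value, original input order
    giant_size: int
    giant_label: int
    order: np.ndarray            # argsort of the values (stable)

    @property
    def n(self) -> int:
        return self.sample.n

    @property
    def values(self) -> np.ndarray:
        return self.sample.values

    @property
    def sorted_values(self) -> np.ndarray:
        return self.sample.values[self.order]

    @property
    def sorted_degrees(self) -> np.ndarray:
        return self.degrees[self.order]

    @property
    def sorted_labels(self) -> np.ndarray:
        return self.cluster_labels[self.order]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_labels)

    @property
    def giant_mask(self) -> np.ndarray:
        """Boolean mask (original order): membership in the largest cluster."""
        return self.cluster_labels == self.giant_label


def _check_zeta(zeta: float) -> float:
    z = float(zeta)
    if math.isnan(z) or z < 0:
        raise InvalidParameterError(f"zeta must be a non-negative real, got {zeta!r}")
    return z


def _as_sample(sample: Sample | Sequence[float]) -> Sample:
    return sample if isinstance(sample, Sample) else Sample(np.asarray(sample, dtype=float))


def build_network_reference(sample: Sample | Sequence[float], zeta: float) -> SimilarityNetwork:
    """Build the similarity network by the literal pairwise rule (oracle path).

    An edge joins i and j (i != j) iff ``x_i - zeta <= x_j <= x_i + zeta``.
    Materializes the full n-by-n boolean adjacency; intended for n up to
    about 1000 (testing / small inputs).
    """
    sample = _as_sample(sample)
    z = _check_zeta(zeta)
    x = sample.values
    n = sample.n
    adj = (x[None, :] >= x[:, None] - z) & (x[None, :] <= x[:, None] + z)
    np.fill_diagonal(adj, False)
    degrees = adj.sum(axis=1).astype(np.int64)
    edge_count = int(degrees.sum()) // 2
    _, raw = connected_components(csr_matrix(adj), directed=False)

    # canonical relabel: clusters numbered by their smallest member value
    order = np.argsort(x, kind="stable")
    remap: dict[int, int] = {}
    for idx in order:
        r = int(raw[idx])
        if r not in remap:
            remap[r] = len(remap)
    labels = np.array([remap[int(r)] for r in raw], dtype=np.int64)
    sizes = np.bincount(labels)
    giant_label = int(np.argmax(sizes))  # first max = smallest-value cluster
    return SimilarityNetwork(
        sample=sample,
        zeta=z,
        degrees=degrees,
        edge_count=edge_count,
        cluster_labels=labels,
        giant_size=int(sizes[giant_label]),
        giant_label=giant_label,
        order=order,
    )


def build_network_fast(sample: Sample | Sequence[float], zeta: float) -> SimilarityNetwork:
    """Build the similarity network in O(n log n) via binary search.

    Degree of value x is (number of values in ``[x - zeta, x + zeta]``) - 1;
    clusters are maximal runs of the sorted values with consecutive gaps
    ``<= zeta``.  Output is identical to :func:`build_network_reference`.
    """
    sample = _as_sample(sample)
    z = _check_zeta(zeta)
    x = sample.values
    n = sample.n
    order = np.argsort(x, kind="stable")
    s = x[order]
    lo = np.searchsorted(s, x - z, side="left")
    hi = np.searchsorted(s, x + z, side="right")
    degrees = (hi - lo - 1).astype(np.int64)
    edge_count = int(degrees.sum()) // 2

    breaks = np.diff(s) > z
    labels_sorted = np.concatenate(([0], np.cumsum(breaks))).astype(np.int64)
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    sizes = np.bincount(labels_sorted)
    giant_label = int(np.argmax(sizes))
    return SimilarityNetwork(
        sample=sample,
        zeta=z,
        degrees=degrees,
        edge_count=edge_count,
        cluster_labels=labels,
        giant_size=int(sizes[giant_label]),
        giant_label=giant_label,
        order=order,
    )


def giant_cluster_proportion(net: SimilarityNetwork) -> float:
    """Proportion of nodes in the largest cluster, ``p_g = V_g / V``."""
    return net.giant_size / net.n
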