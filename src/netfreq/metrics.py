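"""Mode extraction and network spread measures.

The degree of each node, plotted against its value, is a binless frequency
curve; its argmax is the mode.  Ties at the maximum degree are resolved by
arithmetic averaging of all tied values.  Spread is summarized by the
diameter of the largest cluster and the average shortest-path length over
connected pairs (paths never cross clusters — the distance between
disconnected nodes is infinite and such pairs are excluded).

Two shortest-path engines are provided: a literal breadth-first-search
reference (:func:`shortest_paths_bfs`) and an O(n·D) greedy engine that
exploits the interval structure of the graph (:func:`shortest_paths_interval`).
On a sorted interval graph the greedy farthest-reach jump is an optimal
step, so both produce identical hop counts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidParameterError
from .network import Sample, SimilarityNetwork

__all__ = [
    "ModeResult",
    "SpreadMetrics",
    "mode_estimate",
    "boundary_check",
    "local_modes",
    "shortest_paths_bfs",
    "shortest_paths_interval",
]


@dataclass(frozen=True, eq=False)
class ModeResult:
    """The mode of a sample read off the degree curve.

    ``mode_value`` is the arithmetic mean of every value attaining the
    maximum degree (a single value when there is no tie).  ``boundary_flag``
    marks a suspected edge artifact: the mode lies within one zeta of the
    sample minimum or maximum.
    """

    mode_value: float
    max_degree: int
    tied_values: np.ndarray
    boundary_flag: bool

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModeResult):
            return NotImplemented
        return (self.mode_value == other.mode_value
                and self.max_degree == other.max_degree
                and np.array_equal(self.tied_values, other.tied_values)
                and self.boundary_flag == other.boundary_flag)


@dataclass(frozen=True)
class SpreadMetrics:
    """Hop-based spread of the network; ``None`` when not computable.

    ``diameter`` is the longest shortest path within the largest cluster;
    ``avg_path_length`` averages shortest paths over all connected unordered
    pairs in every cluster.  An edgeless network has neither.
    """

    diameter: Optional[int]
    avg_path_length: Optional[float]

    @property
    def computable(self) -> bool:
        return self.diameter is not None


def boundary_check(mode_value: float, sample: Sample, zeta: float) -> bool:
    """True when the mode sits within one zeta of the sample's support edge.

    Distributions with a density maximum at their support boundary (e.g.
    exponential, power-law) produce spurious degree peaks there; this is the
    operational detector for that artifact.
    """
    if zeta < 0:
        raise InvalidParameterError("zeta must be non-negative")
    return bool(mode_value <= sample.min + zeta or mode_value >= sample.max - zeta)


def mode_estimate(net: SimilarityNetwork) -> ModeResult:
    """Mode = value of maximum degree; ties resolve to the tied values' mean."""
    degrees = net.degrees
    max_degree = int(degrees.max())
    tied = np.sort(net.values[degrees == max_degree])
    mode_value = float(tied.mean())
    flag = boundary_check(mode_value, net.sample, net.zeta)
    return ModeResult(mode_value=mode_value, max_degree=max_degree,
                      tied_values=tied, boundary_flag=flag)


def local_modes(net: SimilarityNetwork, min_prominence_frac: float = 0.10) -> List[ModeResult]:
    """Candidate modes of the degree-vs-sorted-value curve.

    A plateau-collapsed local maximum is kept when its degree exceeds both
    flanking minima (the valleys toward the neighbouring peaks; absent on
    the open side of an edge peak) by at least
    ``min_prominence_frac * max_degree``.  The global mode — exactly
    :func:`mode_estimate` — is always first; secondary peaks follow in
    decreasing degree order.

    Prominence is the standard topographic one (how far the degree must
    drop before reaching higher terrain), so shallow wiggles riding on a
    real peak are not reported separately.  Secondary candidates are
    interior peaks only; a monotone curve reports just the global mode.
    The default threshold fraction is a pragmatic choice, exposed as a
    parameter; tune it to the noise level of the data.
    """
    if not 0.0 <= min_prominence_frac <= 1.0:
        raise InvalidParameterError("min_prominence_frac must be in [0, 1]")
    s = net.sorted_values
    d = net.sorted_degrees.astype(float)
    max_degree = int(d.max())
    threshold = min_prominence_frac * max_degree

    peaks, props = find_peaks(d, prominence=threshold, plateau_size=1)

    # merge neighbouring peaks whose separating valley is shallower than the
    # threshold (equal-height twins otherwise both get full prominence)
    groups: list[list[int]] = []
    for k in range(len(peaks)):
        if groups:
            prev = groups[-1][-1]
            valley = d[peaks[prev]:peaks[k] + 1].min()
            if valley > min(d[peaks[prev]], d[peaks[k]]) - threshold:
                groups[-1].append(k)
                continue
        groups.append([k])

    results = [mode_estimate(net)]
    secondary = []
    for group in groups:
        height = max(d[peaks[k]] for k in group)
        if int(height) == max_degree:
            continue  # folded into the global mode entry
        members = np.concatenate([
            np.arange(props["left_edges"][k], props["right_edges"][k] + 1)
            for k in group if d[peaks[k]] == height
        ])
        vals = s[members]
        mv = float(vals.mean())
        secondary.append(ModeResult(
            mode_value=mv,
            max_degree=int(height),
            tied_values=np.sort(vals),
            boundary_flag=boundary_check(mv, net.sample, net.zeta),
        ))
    secondary.sort(key=lambda m: (-m.max_degree, m.mode_value))
    return results + secondary


# ---------------------------------------------------------------------------
# shortest paths


def _bfs_all_hops(net: SimilarityNetwork) -> np.ndarray:
    """All-pairs hop counts by literal BFS; -1 marks disconnected pairs.

    Quadratic in both time and memory — reference engine for testing and
    small n.
    """
    x = net.values
    n = net.n
    z = net.zeta
    neighbors = []
    for i in range(n):
        mask = np.abs(x - x[i]) <= z
        mask[i] = False
        neighbors.append(np.nonzero(mask)[0])
    dist = np.full((n, n), -1, dtype=np.int64)
    for src in range(n):
        dist[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            du = dist[src, u]
            for v in neighbors[u]:
                if dist[src, v] < 0:
                    dist[src, v] = du + 1
                    queue.append(v)
    return dist


def _interval_jump(net: SimilarityNetwork) -> np.ndarray:
    """Farthest sorted index reachable in one hop from each sorted index."""
    s = net.sorted_values
    return np.searchsorted(s, s + net.zeta, side="right") - 1


def _interval_all_hops(net: SimilarityNetwork) -> np.ndarray:
    """All-pairs hop counts by greedy farthest-reach jumps (sorted order).

    Returns the matrix indexed in ORIGINAL input order, matching
    :func:`_bfs_all_hops`.  Quadratic output; for testing and diagnostics.
    """
    n = net.n
    jump = _interval_jump(net)
    labels = net.sorted_labels
    ends = np.searchsorted(labels, labels, side="right") - 1
    dist_sorted = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        dist_sorted[i, i] = 0
        r = ends[i]
        reach = i
        level = 0
        while reach < r:
            new = jump[reach]
            level += 1
            dist_sorted[i, reach + 1:new + 1] = level
            dist_sorted[reach + 1:new + 1, i] = level
            reach = new
    dist = np.full((n, n), -1, dtype=np.int64)
    order = net.order
    dist[np.ix_(order, order)] = dist_sorted
    return dist


def shortest_paths_bfs(net: SimilarityNetwork) -> SpreadMetrics:
    """Reference spread metrics via breadth-first search from every node."""
    if net.edge_count == 0:
        return SpreadMetrics(diameter=None, avg_path_length=None)
    dist = _bfs_all_hops(net)
    iu, ju = np.triu_indices(net.n, k=1)
    pair_d = dist[iu, ju]
    connected = pair_d > 0
    avg = float(pair_d[connected].mean())
    giant = np.nonzero(net.giant_mask)[0]
    diameter = int(dist[np.ix_(giant, giant)].max())
    return SpreadMetrics(diameter=diameter, avg_path_length=avg)


def shortest_paths_interval(net: SimilarityNetwork) -> SpreadMetrics:
    """Fast spread metrics exploiting the interval structure (O(n·D)).

    From any sorted position the greedy jump to the farthest value within
    zeta is a step of an optimal path, so hop counts between sorted
    positions i < j are the number of greedy jumps, and the diameter of a
    cluster is the hop count between its extreme members.
    """
    if net.edge_count == 0:
        return SpreadMetrics(diameter=None, avg_path_length=None)
    n = net.n
    jump = _interval_jump(net)
    labels = net.sorted_labels
    ends = np.searchsorted(labels, labels, side="right") - 1

    total_hops = 0
    total_pairs = 0
    for i in range(n - 1):
        r = int(ends[i])
        if r == i:
            continue
        total_pairs += r - i
        reach = i
        level = 0
        while reach < r:
            new = int(jump[reach])
            level += 1
            total_hops += level * (new - reach)
            reach = new
    avg = total_hops / total_pairs

    giant_pos = np.nonzero(labels == net.giant_label)[0]
    g0, g1 = int(giant_pos[0]), int(giant_pos[-1])
    diameter = 0
    reach = g0
    while reach < g1:
        reach = int(jump[reach])
        diameter += 1
    return SpreadMetrics(diameter=diameter, avg_path_length=float(avg))
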