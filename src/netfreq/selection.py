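"""Bandwidth (zeta) sweep and stability-based selection.

The working bandwidth is chosen by sweeping zeta over a grid — by default
ten equally spaced values from 1% to 10% of the sample median — and looking
for the first run of grid points over which the giant-cluster size stops
changing.  Stability is judged on the integer node count of the giant
cluster, not on the floating-point proportion.  The smallest zeta of the
first qualifying run is returned; if no run qualifies the sweep is reported
unstable and the largest grid value is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateSampleError, InvalidParameterError, UndefinedIndexError
from .metrics import shortest_paths_interval
from .network import Sample, build_network_fast

__all__ = [
    "ZetaSweep",
    "ZetaSelection",
    "default_grid",
    "sweep_zeta",
    "select_zeta",
    "homogeneity_index",
]


@dataclass(frozen=True)
class ZetaSweep:
    """Network summaries evaluated over an increasing grid of zeta values.

    ``d_curve``/``l_curve`` hold NaN where the network had no edges, and are
    ``None`` entirely when the sweep was run without path metrics.
    """

    grid: np.ndarray
    vg_curve: np.ndarray          # giant-cluster node counts (integers)
    pg_curve: np.ndarray          # vg / n
    e_curve: np.ndarray           # edge counts
    n: int
    d_curve: Optional[np.ndarray] = None
    l_curve: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.vg_curve) or len(self.grid) != len(self.e_curve):
            raise InvalidParameterError("sweep curves must match the grid length")


@dataclass(frozen=True)
class ZetaSelection:
    """Outcome of stability selection on a sweep."""

    zeta_s: float
    stable: bool
    pg_at_selection: float
    index: int                    # grid index of zeta_s
    vg_at_selection: int
    stability_window: int
    homogeneity: Optional[float] = None


def default_grid(
    sample: Sample,
    min_frac: float = 0.01,
    max_frac: float = 0.10,
    steps: int = 10,
) -> np.ndarray:
    """Equally spaced zeta grid from ``min_frac·L`` to ``max_frac·L``.

    The scale L is the sample median when positive; otherwise the sample
    range (max - min) — the method's own convention only covers positive
    data, and the range keeps zeta positive for any non-constant sample.
    """
    if not 0 < min_frac <= max_frac:
        raise InvalidParameterError("need 0 < min_frac <= max_frac")
    if steps < 2:
        raise InvalidParameterError("grid needs at least 2 steps")
    med = sample.median
    scale = med if med > 0 else sample.max - sample.min
    if scale <= 0:
        raise DegenerateSampleError(
            "no positive scale for the zeta grid (constant, non-positive sample)"
        )
    return np.linspace(min_frac * scale, max_frac * scale, steps)


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise InvalidParameterError("grid must be a non-empty 1-D sequence")
    if not np.all(g > 0):
        raise InvalidParameterError("grid entries must be positive")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise InvalidParameterError("grid must be strictly increasing")
    return g


def sweep_zeta(
    sample: Sample,
    grid: Sequence[float],
    with_paths: bool = False,
) -> ZetaSweep:
    """Evaluate the network at every grid zeta.

    Records the giant-cluster count/proportion and edge count; with
    ``with_paths`` also the diameter and average path length of each
    network (NaN when edgeless).
    """
    g = _check_grid(grid)
    m = g.size
    vg = np.empty(m, dtype=np.int64)
    e = np.empty(m, dtype=np.int64)
    d = np.full(m, np.nan) if with_paths else None
    l = np.full(m, np.nan) if with_paths else None
    for k, z in enumerate(g):
        net = build_network_fast(sample, float(z))
        vg[k] = net.giant_size
        e[k] = net.edge_count
        if with_paths:
            spread = shortest_paths_interval(net)
            if spread.computable:
                d[k] = spread.diameter
                l[k] = spread.avg_path_length
    return ZetaSweep(
        grid=g,
        vg_curve=vg,
        pg_curve=vg / sample.n,
        e_curve=e,
        n=sample.n,
        d_curve=d,
        l_curve=l,
    )


def select_zeta(
    sweep: ZetaSweep,
    window_frac: float = 0.30,
    min_pg: Optional[float] = None,
) -> ZetaSelection:
    """Pick the smallest zeta of the first stable run of the sweep.

    A run is stable when at least ``ceil(window_frac * len(grid))``
    consecutive grid points (never fewer than 2) share the same integer
    giant-cluster count; when ``min_pg`` is given the run must also reach
    that giant-cluster proportion.  Absence of a stable run is a reported
    state — the selection falls back to the last grid value with
    ``stable=False`` — not an error.
    """
    if not 0 < window_frac <= 1:
        raise InvalidParameterError("window_frac must be in (0, 1]")
    m = len(sweep.grid)
    window = max(2, math.ceil(window_frac * m))

    if window <= m:
        i = 0
        while i < m:
            j = i
            while j + 1 < m and sweep.vg_curve[j + 1] == sweep.vg_curve[i]:
                j += 1
            run_len = j - i + 1
            if run_len >= window and (min_pg is None or sweep.pg_curve[i] >= min_pg):
                return ZetaSelection(
                    zeta_s=float(sweep.grid[i]),
                    stable=True,
                    pg_at_selection=float(sweep.pg_curve[i]),
                    index=i,
                    vg_at_selection=int(sweep.vg_curve[i]),
                    stability_window=window,
                )
            i = j + 1

    last = m - 1
    return ZetaSelection(
        zeta_s=float(sweep.grid[last]),
        stable=False,
        pg_at_selection=float(sweep.pg_curve[last]),
        index=last,
        vg_at_selection=int(sweep.vg_curve[last]),
        stability_window=window,
    )


def homogeneity_index(zeta_s: float, mode_value: float) -> float:
    """Homogeneity index ``H = zeta_s / M``.

    Dimensionless; small for homogeneous distributions.  H can exceed 1 in
    principle (then every value below the mode is linked) but usually lies
    in [0, 1].  Undefined for a zero mode value.
    """
    if mode_value == 0:
        raise UndefinedIndexError("homogeneity index undefined for mode value 0")
    return zeta_s / mode_value
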