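"""Cluster-based outlier detection and seeded subsampling.

An outlier is any value outside the largest cluster of the similarity
network (normally the network at the selected stable zeta).  Because no
edges cross clusters, removing outliers cannot change any degree inside the
giant cluster, so the mode is unaffected.

``subsample`` draws a fixed fraction of the values uniformly without
replacement for large inputs (described as "bootstrapping with no
replacement" in parts of the literature; it is plain subsampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .network import Sample, SimilarityNetwork

__all__ = ["OutlierReport", "detect_outliers", "subsample"]


@dataclass(frozen=True, eq=False)
class OutlierReport:
    """Partition of a sample into giant-cluster members and outliers."""

    outlier_values: np.ndarray
    outlier_count: int
    retained: Sample            # giant-cluster members, original order
    outlier_indices: np.ndarray  # positions in the original sample


def detect_outliers(net: SimilarityNetwork) -> OutlierReport:
    """Every value outside the largest cluster is an outlier."""
    mask = net.giant_mask
    outlier_idx = np.nonzero(~mask)[0]
    retained = Sample(
        net.values[mask],
        label=(net.sample.label + " [giant cluster]").strip(),
        meta=dict(net.sample.meta),
    )
    return OutlierReport(
        outlier_values=net.values[outlier_idx],
        outlier_count=int(outlier_idx.size),
        retained=retained,
        outlier_indices=outlier_idx,
    )


def subsample(sample: Sample, fraction: float, seed: int) -> Sample:
    """Uniform draw without replacement of ``round(fraction * n)`` values.

    Deterministic for a fixed seed; the retained values keep their original
    relative order.  At least one value is always kept.
    """
    if not 0 < fraction <= 1:
        raise InvalidParameterError("fraction must be in (0, 1]")
    n = sample.n
    k = max(1, int(round(fraction * n)))
    if k >= n:
        return sample
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    meta = dict(sample.meta)
    meta.update(subsample_fraction=fraction, subsample_seed=seed, parent_n=n)
    return Sample(sample.values[idx], label=sample.label, meta=meta)
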