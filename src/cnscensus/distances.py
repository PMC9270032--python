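"""Inter-nuclei distance distributions and scalar baseline features.

"Inter-nuclei distances" are all unordered pairwise Euclidean distances
within a cloud (n(n-1)/2 for n points).  The scalar features summarising
the distribution — mean, variance, skewness, kurtosis and Sarle's
bimodality coefficient — are the "simple" descriptors used as the
baseline classifier input, in contrast to the topological summaries.

Population (biased) moments are used throughout: distance counts are of
order 1e7 for real clouds, so small-sample corrections are immaterial.
The bimodality coefficient is (skewness^2 + 1) / kurtosis with the
non-excess kurtosis; values above 5/9 (the uniform distribution's value)
suggest bimodality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .core import InsufficientDataError, ParameterError, PointCloud

__all__ = ["DistanceSummary", "pairwise_distances", "summarize_distances",
           "feature_matrix", "FEATURE_NAMES"]

FEATURE_NAMES = ("mean", "variance", "skewness", "excess_kurtosis",
                 "bimodality_coefficient")


@dataclass
class DistanceSummary:
    """Pairwise distances (um) plus optional moment features and histogram."""

    distances: np.ndarray
    features: dict[str, float] = field(default_factory=dict)
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (edges, counts)


def pairwise_distances(cloud: PointCloud) -> DistanceSummary:
    """All unordered-pair Euclidean distances, lexicographic pair order."""
    if cloud.n_points < 2:
        raise InsufficientDataError(
            f"need >= 2 points for pairwise distances, got {cloud.n_points}")
    return DistanceSummary(distances=pdist(cloud.points))


def summarize_distances(ds: DistanceSummary,
                        bin_width_um: float = 1.0) -> DistanceSummary:
    """Fill moment features and a fixed-bin-width histogram in place.

    Raises for fewer than 2 distances; the bimodality coefficient is set
    to NaN (flagged) when the distance distribution is degenerate
    (zero variance).
    """
    d = np.asarray(ds.distances, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("need >= 2 distances to summarise")
    if bin_width_um <= 0:
        raise ParameterError("bin width must be > 0")
    mean = float(d.mean())
    centred = d - mean
    m2 = float(np.mean(centred**2))
    features = {"mean": mean, "variance": m2}
    if m2 == 0.0:
        features.update(skewness=0.0, excess_kurtosis=float("nan"),
                        bimodality_coefficient=float("nan"))
    else:
        skew = float(np.mean(centred**3)) / m2**1.5
        kurt = float(np.mean(centred**4)) / m2**2
        features.update(skewness=skew, excess_kurtosis=kurt - 3.0,
                        bimodality_coefficient=(skew**2 + 1.0) / kurt)
    ds.features = features
    hi = float(d.max())
    edges = np.arange(0.0, hi + bin_width_um, bin_width_um)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width_um)
    counts, edges = np.histogram(d, bins=edges)
    ds.histogram = (edges, counts)
    return ds


def feature_matrix(clouds, which: tuple[str, ...] = ("mean", "variance")
                   ) -> np.ndarray:
    """One feature row per cloud, columns in the order of ``which``.

    The default subset (mean, variance) is the baseline feature pair fed
    through an RBF kernel.
    """
    unknown = set(which) - set(FEATURE_NAMES)
    if unknown:
        raise ParameterError(f"unknown feature(s): {sorted(unknown)}")
    rows = []
    for cloud in clouds:
        ds = summarize_distances(pairwise_distances(cloud))
        rows.append([ds.features[name] for name in which])
    return np.asarray(rows, dtype=float)
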