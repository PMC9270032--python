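"""Topological summaries and kernels between them.

A point cloud is summarised by the degree-1 persistence diagram of its
alpha complex: one (birth, death) pair per unfilled loop, in squared-radius
units (um^2).  Diagrams are compared with the persistence scale-space heat
kernel: diagram points diffuse as Gaussians of variance 2*sigma, with
mirrored negative mass across the diagonal so that near-diagonal (noise)
points carry little weight, and the kernel is the inner product of the two
resulting heat solutions:

    k_sigma(F, G) = 1/(8 pi sigma) * sum_{p in F, q in G}
                    [exp(-|p-q|^2 / 8 sigma) - exp(-|p-qbar|^2 / 8 sigma)]

with qbar the mirror image of q across the diagonal.  The kernel is
symmetric and positive definite, and k(empty, G) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alpha import alpha_diagram_degree1
from .core import (InsufficientDataError, KernelGram, ParameterError,
                   PersistenceDiagram, PointCloud)

__all__ = [
    "SubsampleSet",
    "subsample_cloud",
    "alpha_persistence_degree1",
    "heat_kernel",
    "gram_matrix",
    "rbf_feature_gram",
    "truncate_diagram",
    "to_radius_units",
]


@dataclass
class SubsampleSet:
    """Repeated without-replacement subsamples of one animal's cloud."""

    parent_animal_id: str
    clouds: list[PointCloud]
    m: int
    repeats: int
    seed: int


def subsample_cloud(cloud: PointCloud, m: int, repeats: int,
                    seed: int) -> SubsampleSet:
    """Draw ``repeats`` subsamples of exactly ``m`` points, no replacement.

    Deterministic for a fixed seed; raises if the parent has fewer than
    ``m`` points (no silent fallback).
    """
    if m < 1 or repeats < 1:
        raise ParameterError("m and repeats must be positive")
    if cloud.n_points < m:
        raise InsufficientDataError(
            f"cloud {cloud.animal_id!r} has {cloud.n_points} points, "
            f"cannot subsample {m}")
    rng = np.random.default_rng(seed)
    subs = []
    for r in range(repeats):
        idx = rng.choice(cloud.n_points, size=m, replace=False)
        subs.append(PointCloud(
            animal_id=cloud.animal_id, line=cloud.line, sex=cloud.sex,
            points=cloud.points[np.sort(idx)]))
    return SubsampleSet(parent_animal_id=cloud.animal_id, clouds=subs,
                        m=m, repeats=repeats, seed=seed)


def alpha_persistence_degree1(cloud: PointCloud | np.ndarray,
                              min_persistence: float = 1e-12
                              ) -> PersistenceDiagram:
    """Degree-1 alpha-complex persistence diagram of a cloud (um^2 units)."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud)
    return alpha_diagram_degree1(pts, min_persistence=min_persistence)


def to_radius_units(diagram: PersistenceDiagram) -> PersistenceDiagram:
    """Convert squared-radius diagram values to radius (um) by square root."""
    return PersistenceDiagram(degree=diagram.degree,
                              points=np.sqrt(diagram.points))


def truncate_diagram(diagram: PersistenceDiagram,
                     max_points: int) -> PersistenceDiagram:
    """Keep the ``max_points`` highest-persistence pairs (stable order)."""
    if max_points < 1:
        raise ParameterError("max_points must be positive")
    if len(diagram) <= max_points:
        return diagram
    pers = diagram.persistence
    # Stable selection: sort by (-persistence, index), keep the head.
    order = np.lexsort((np.arange(len(pers)), -pers))[:max_points]
    return PersistenceDiagram(degree=diagram.degree,
                              points=diagram.points[np.sort(order)])


def heat_kernel(f: PersistenceDiagram, g: PersistenceDiagram,
                sigma: float) -> float:
    """Persistence scale-space kernel between two diagrams (closed form)."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if len(f) == 0 or len(g) == 0:
        return 0.0
    p = f.points
    q = g.points
    qbar = q[:, ::-1]
    d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    d2bar = ((p[:, None, :] - qbar[None, :, :]) ** 2).sum(axis=2)
    s8 = 8.0 * sigma
    total = float((np.exp(-d2 / s8) - np.exp(-d2bar / s8)).sum())
    return total / (8.0 * np.pi * sigma)


def _stack_diagrams(diagrams, max_points):
    pts = []
    owners = []
    for i, d in enumerate(diagrams):
        dd = truncate_diagram(d, max_points) if max_points else d
        if len(dd):
            pts.append(dd.points)
            owners.append(np.full(len(dd), i, dtype=np.int64))
    if not pts:
        return np.empty((0, 2)), np.empty(0, dtype=np.int64)
    return np.vstack(pts), np.concatenate(owners)


def gram_matrix(diagrams, group_ids, sigma: float,
                item_ids=None, max_points: int | None = None,
                dtype=np.float64) -> KernelGram:
    """Heat-kernel Gram matrix over persistence diagrams.

    ``K[i, j] = heat_kernel(D_i, D_j, sigma)``, evaluated blockwise over
    the stacked diagram points and symmetrised as (K + K^T)/2.  With
    ``max_points`` set, each diagram is first truncated to its strongest
    pairs — the exact kernel on pruned diagrams, which bounds the runtime
    of large experiments while keeping every prominent loop.  ``dtype``
    controls the working precision of the blockwise evaluation; float32
    roughly halves the cost of large Gram matrices.
    """
    diagrams = list(diagrams)
    if len(diagrams) == 0:
        raise ParameterError("need at least one diagram")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    n = len(diagrams)
    group_ids = [str(g) for g in group_ids]
    if len(group_ids) != n:
        raise ParameterError("group_ids must match diagram count")
    if item_ids is None:
        item_ids = [f"item{i:05d}" for i in range(n)]
    item_ids = [str(i) for i in item_ids]

    flat, owner = _stack_diagrams(diagrams, max_points)
    gram = np.zeros((n, n))
    if flat.shape[0]:
        inv_s8 = 1.0 / (8.0 * sigma)
        flat = flat.astype(dtype)
        flatbar = np.ascontiguousarray(flat[:, ::-1])
        sq = (flat**2).sum(axis=1)
        # owner is non-decreasing (diagrams stacked in order); segment
        # boundaries let reduceat collapse point sums to diagram sums.
        nz_idx, counts = np.unique(owner, return_counts=True)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        pos_of_owner = np.searchsorted(nz_idx, owner)
        nnz = len(nz_idx)
        acc = np.zeros((nnz, nnz))
        # Diagram-aligned row chunks against the column suffix: the kernel
        # is symmetric, so only pairs (i, j) with j >= chunk start are
        # evaluated and the strict upper triangle is mirrored afterwards.
        target = max(1, int(4e7 // max(flat.shape[0], 1)))
        chunk_bounds = [0]
        for s in starts[1:]:
            if s - chunk_bounds[-1] >= target:
                chunk_bounds.append(int(s))
        chunk_bounds.append(flat.shape[0])
        for start, stop in zip(chunk_bounds[:-1], chunk_bounds[1:]):
            p = flat[start:stop]
            psq = sq[start:stop, None]
            cols = slice(start, flat.shape[0])
            d2 = psq + sq[None, cols] - 2.0 * (p @ flat[cols].T)
            np.maximum(d2, 0.0, out=d2)
            d2 *= -inv_s8
            np.exp(d2, out=d2)
            d2bar = psq + sq[None, cols] - 2.0 * (p @ flatbar[cols].T)
            np.maximum(d2bar, 0.0, out=d2bar)
            d2bar *= -inv_s8
            np.exp(d2bar, out=d2bar)
            d2 -= d2bar
            col_starts = starts[starts >= start] - start
            if col_starts.size == 0 or col_starts[0] != 0:
                col_starts = np.concatenate([[0], col_starts])
            col_agg = np.add.reduceat(d2.astype(np.float64), col_starts, axis=1)
            first_col_diag = np.searchsorted(starts, start)
            np.add.at(acc[:, first_col_diag:],
                      pos_of_owner[start:stop], col_agg)
        acc = np.triu(acc) + np.triu(acc, 1).T
        gram[np.ix_(nz_idx, nz_idx)] = acc
        gram /= 8.0 * np.pi * sigma
        gram = 0.5 * (gram + gram.T)
    return KernelGram(matrix=gram, item_ids=item_ids, group_ids=group_ids,
                      kernel_kind="persistence_heat")


def rbf_feature_gram(features: np.ndarray, bandwidth: float, group_ids,
                     item_ids=None, convention: str = "half_gamma_sq"
                     ) -> KernelGram:
    """Gaussian RBF Gram matrix over scalar feature rows.

    ``convention`` selects the bandwidth meaning: ``"half_gamma_sq"``
    (default) gives exp(-d^2 / (2 * bandwidth^2)); ``"gamma"`` gives
    exp(-d^2 / bandwidth), for replication sweeps against SVM-literature
    notations where "bandwidth" is ambiguous.
    """
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be > 0")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    group_ids = [str(g) for g in group_ids]
    if len(group_ids) != n:
        raise ParameterError("group_ids must match feature rows")
    if item_ids is None:
        item_ids = [f"item{i:05d}" for i in range(n)]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    if convention == "half_gamma_sq":
        mat = np.exp(-d2 / (2.0 * bandwidth**2))
    elif convention == "gamma":
        mat = np.exp(-d2 / bandwidth)
    else:
        raise ParameterError(f"unknown RBF convention {convention!r}")
    mat = 0.5 * (mat + mat.T)
    return KernelGram(matrix=mat, item_ids=[str(i) for i in item_ids],
                      group_ids=group_ids, kernel_kind="feature_rbf")
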