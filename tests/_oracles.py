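"""Independent brute-force oracles used only by the test suite.

These deliberately share no code path with the package implementation:

* :func:`brute_alpha_diagram_degree1` enumerates *all* vertex subsets of a
  tiny cloud, derives each simplex's alpha filtration value from first
  principles (constrained minimisation over the Voronoi-restricted
  equidistant set, solved exactly by active-set enumeration), and reduces
  the full dense Z/2 boundary matrix across all dimensions.
* :func:`numeric_heat_kernel` evaluates the persistence scale-space
  kernel as the inner product of two explicit heat solutions on a grid
  (diagram points diffused as Gaussians with mirrored negative mass).
"""

from __future__ import annotations

import itertools

import numpy as np

_TOL = 1e-9


def _equidistant_foot(points: np.ndarray, subset: tuple[int, ...]):
    """Closest point equidistant to all ``subset`` vertices, plus r^2.

    Minimises |y - v0|^2 subject to the linear equalities
    2 (v_i - v_0) . y = |v_i|^2 - |v_0|^2; returns None for degenerate
    (affinely dependent) subsets.
    """
    v = points[list(subset)]
    v0 = v[0]
    if len(v) == 1:
        return v0, 0.0
    a = 2.0 * (v[1:] - v0)
    c = (v[1:] ** 2).sum(axis=1) - (v0**2).sum()
    gram = a @ a.T
    if abs(np.linalg.det(gram)) < 1e-12 * max(np.abs(gram).max(), 1.0) ** len(gram):
        return None
    mu = np.linalg.solve(gram, c - a @ v0)
    y = v0 + a.T @ mu
    return y, float(((y - v0) ** 2).sum())


def _alpha_value(points: np.ndarray, simplex: tuple[int, ...]):
    """Alpha filtration value of a simplex, or None if never in the complex.

    The entry value is min over y of max_i |y - v_i|^2 where y ranges over
    the common intersection of the vertices' Voronoi cells (on which the
    distances to all simplex vertices agree).  The minimiser's active set
    is some superset of the simplex with at most d+1 affinely independent
    points, so enumerating all candidate feet and keeping the feasible
    ones is exact.
    """
    n, d = points.shape
    others = [i for i in range(n) if i not in simplex]
    best = None
    max_size = d + 1
    for extra in range(0, max_size - len(simplex) + 1):
        for add in itertools.combinations(others, extra):
            foot = _equidistant_foot(points, tuple(simplex) + add)
            if foot is None:
                continue
            y, r2 = foot
            dist2 = ((points - y) ** 2).sum(axis=1)
            ref = dist2[simplex[0]]
            # Feasible: no point strictly closer than the simplex vertices.
            if np.all(dist2 >= ref - _TOL * max(ref, 1.0)):
                if best is None or r2 < best:
                    best = r2
    return best


def brute_alpha_diagram_degree1(points: np.ndarray,
                                min_persistence: float = 1e-12) -> np.ndarray:
    """Degree-1 persistence pairs of the alpha filtration, brute force.

    Suitable for clouds of up to ~10 points in R^3 in general position.
    Returns an (k, 2) array of (birth, death), sorted by (birth, death).
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    simplices = []  # (value, dim, vertex tuple)
    for i in range(n):
        simplices.append((0.0, 0, (i,)))
    for size in range(2, d + 2):
        for comb in itertools.combinations(range(n), size):
            value = _alpha_value(points, comb)
            if value is not None:
                simplices.append((value, size - 1, comb))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: k for k, s in enumerate(simplices)}

    # Dense Z/2 boundary matrix over the full filtration.
    m = len(simplices)
    cols = []
    for value, dim, verts in simplices:
        col = np.zeros(m, dtype=bool)
        if dim > 0:
            for facet in itertools.combinations(verts, dim):
                col[index[facet]] = True
        cols.append(col)
    lows: dict[int, int] = {}
    pairs = []
    for j in range(m):
        col = cols[j]
        while col.any():
            low = int(np.flatnonzero(col)[-1])
            if low in lows:
                col = col ^ cols[lows[low]]
            else:
                lows[low] = j
                pairs.append((low, j))
                break
        cols[j] = col

    out = []
    for low, j in pairs:
        birth_val, birth_dim, _ = simplices[low]
        death_val, _, _ = simplices[j]
        if birth_dim == 1 and death_val - birth_val > min_persistence:
            out.append((birth_val, death_val))
    out = np.asarray(sorted(out), dtype=float).reshape(-1, 2)
    return out


def numeric_heat_kernel(f: np.ndarray, g: np.ndarray, sigma: float,
                        h: float = 0.005, pad: float = 2.0) -> float:
    """Grid quadrature of the scale-space kernel: 0.5 * <u_F, u_G>_{R^2}.

    ``u_D`` is the heat solution at time ``sigma`` whose initial condition
    is Dirac masses at the diagram points and mirrored negative masses
    across the diagonal, i.e. a sum of Gaussians of covariance
    ``2 sigma I`` minus their mirror images.
    """
    f = np.asarray(f, float).reshape(-1, 2)
    g = np.asarray(g, float).reshape(-1, 2)
    allpts = np.vstack([f, g, f[:, ::-1], g[:, ::-1]])
    lo = allpts.min(axis=0) - pad
    hi = allpts.max(axis=0) + pad
    xs = np.arange(lo[0], hi[0] + h, h)
    ys = np.arange(lo[1], hi[1] + h, h)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    def field(diagram):
        u = np.zeros_like(gx)
        norm = 1.0 / (4.0 * np.pi * sigma)
        for px, py in diagram:
            u += norm * np.exp(-((gx - px) ** 2 + (gy - py) ** 2)
                               / (4.0 * sigma))
            u -= norm * np.exp(-((gx - py) ** 2 + (gy - px) ** 2)
                               / (4.0 * sigma))
        return u

    return 0.5 * float((field(f) * field(g)).sum()) * h * h
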