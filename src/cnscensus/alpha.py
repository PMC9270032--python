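"""Alpha-complex filtration and degree-1 persistent homology.

The alpha complex of a point cloud X in R^3 is the nerve of the balls
B(x, r) intersected with the Voronoi cells of X; it is a subcomplex of the
Delaunay triangulation, and its filtration value for a simplex is the
squared radius at which the simplex enters.  Degree-1 persistence pairs
track unfilled loops: each pair (birth, death) is the squared radius at
which a loop forms and at which it is filled in.

Filtration values follow the standard computational-geometry convention:

* a top simplex enters at its squared circumradius;
* a lower simplex enters at its own squared circumradius if it is Gabriel
  (its smallest circumsphere contains no neighbouring vertex), otherwise
  when its first coface enters (min over coface values).

Planar inputs (affine rank 2, e.g. clouds jittered out of a plane by less
than ~1e-5 of their extent) are projected onto their best-fit plane and
handled with the 2D alpha complex, so analytic test cases like a triangle
or a circle behave exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .core import DegenerateInputError, PersistenceDiagram

__all__ = ["alpha_diagram_degree1", "alpha_filtration_simplices"]

_RANK_RTOL = 1e-5
_JITTER_SEED = 987654321


def _affine_rank_projection(points: np.ndarray) -> np.ndarray:
    """Project onto the affine span if the cloud is (nearly) planar.

    Returns coordinates of dimension 2 or 3; raises for rank <= 1.
    """
    centred = points - points.mean(axis=0)
    # SVD of the centred cloud: singular values measure extent per axis.
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise DegenerateInputError("all points coincide")
    rank = int(np.sum(s > _RANK_RTOL * s[0]))
    if rank <= 1:
        raise DegenerateInputError("points are collinear or coincident")
    if rank == 2:
        return centred @ vt[:2].T
    return points


def _circumsphere_top(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcentre and squared circumradius of full-dimensional simplices.

    ``verts`` has shape (m, d+1, d).  Solves 2(v_i - v_0) . c' = |v_i|^2 - |v_0|^2.
    """
    v0 = verts[:, 0, :]
    rest = verts[:, 1:, :]
    a = 2.0 * (rest - v0[:, None, :])
    b = (rest**2).sum(axis=2) - (v0**2).sum(axis=1)[:, None]
    centre = np.linalg.solve(a, b[..., None])[..., 0]
    r2 = ((centre - v0) ** 2).sum(axis=1)
    return centre, r2


def _circum_triangle(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcentre (in the triangle plane) and squared circumradius.

    ``verts``: (m, 3, d) with d = 2 or 3.
    """
    a = verts[:, 0, :]
    u = verts[:, 1, :] - a
    v = verts[:, 2, :] - a
    uu = (u * u).sum(axis=1)
    vv = (v * v).sum(axis=1)
    uv = (u * v).sum(axis=1)
    det = uu * vv - uv * uv
    # Degenerate (collinear) triangles cannot occur in a valid Delaunay
    # triangulation; guard anyway to avoid division warnings.
    det = np.where(det == 0, np.finfo(float).tiny, det)
    s = 0.5 * (vv * uu - uv * vv) / det
    t = 0.5 * (uu * vv - uv * uu) / det
    offset = s[:, None] * u + t[:, None] * v
    centre = a + offset
    r2 = (offset**2).sum(axis=1)
    return centre, r2


def _min_over_cofaces(n_faces: int, face_idx: np.ndarray,
                      coface_values: np.ndarray) -> np.ndarray:
    """Per-face minimum of incident coface values (inf where no coface)."""
    out = np.full(n_faces, np.inf)
    np.minimum.at(out, face_idx, coface_values)
    return out


def _any_inside(n_faces: int, face_idx: np.ndarray,
                inside: np.ndarray) -> np.ndarray:
    out = np.zeros(n_faces, dtype=bool)
    np.logical_or.at(out, face_idx, inside)
    return out


def alpha_filtration_simplices(points: np.ndarray):
    """Build the alpha filtration over the Delaunay triangulation.

    Returns ``(edges, edge_values, triangles, triangle_values)`` where the
    simplices are vertex-index arrays and values are squared radii.
    """
    pts = np.asarray(points, dtype=float)
    pts = _affine_rank_projection(pts)
    dim = pts.shape[1]
    try:
        dela = Delaunay(pts)
    except QhullError:
        rng = np.random.default_rng(_JITTER_SEED)
        diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        try:
            dela = Delaunay(pts + rng.normal(0.0, 1e-6 * diag, pts.shape))
        except QhullError as exc:  # pragma: no cover - extreme degeneracy
            raise DegenerateInputError(f"triangulation failed: {exc}") from exc
    top = np.sort(dela.simplices, axis=1)

    if dim == 3:
        _, tet_r2 = _circumsphere_top(pts[top])
        # The four facets of each tetrahedron; facet k is opposite vertex k.
        face_cols = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        faces = top[:, face_cols]                       # (m, 4, 3)
        opp = top                                       # (m, 4) opposite vertex
        tris, tri_of_face = np.unique(faces.reshape(-1, 3), axis=0,
                                      return_inverse=True)
        tri_centre, tri_r2 = _circum_triangle(pts[tris])
        # Gabriel test of each triangle against each coface's opposite vertex.
        opp_pts = pts[opp.reshape(-1)]
        d2 = ((opp_pts - tri_centre[tri_of_face]) ** 2).sum(axis=1)
        inside = d2 < tri_r2[tri_of_face]
        non_gabriel = _any_inside(len(tris), tri_of_face, inside)
        coface_min = _min_over_cofaces(len(tris), tri_of_face,
                                       np.repeat(tet_r2, 4))
        tri_values = np.where(non_gabriel, coface_min, tri_r2)
    else:
        tris = top                                      # (m, 3) triangles
        _, tri_values = _circumsphere_top(pts[tris])
        tri_centre = None  # recomputed below as needed

    # Edges: facet e of a triangle is opposite vertex e.
    edge_cols = np.array([[1, 2], [0, 2], [0, 1]])
    edge_faces = tris[:, edge_cols]                     # (t, 3, 2)
    edge_opp = tris                                     # (t, 3)
    edges, edge_of_face = np.unique(edge_faces.reshape(-1, 2), axis=0,
                                    return_inverse=True)
    mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    edge_r2 = 0.25 * ((pts[edges[:, 1]] - pts[edges[:, 0]]) ** 2).sum(axis=1)
    opp_pts = pts[edge_opp.reshape(-1)]
    d2 = ((opp_pts - mid[edge_of_face]) ** 2).sum(axis=1)
    inside = d2 < edge_r2[edge_of_face]
    non_gabriel = _any_inside(len(edges), edge_of_face, inside)
    coface_min = _min_over_cofaces(len(edges), edge_of_face,
                                   np.repeat(tri_values, 3))
    edge_values = np.where(non_gabriel, coface_min, edge_r2)
    # A face never enters after its cofaces.
    edge_values = np.minimum(edge_values, coface_min)

    return edges, edge_values, tris, tri_values


def _n_components(n_vertices: int, edges: np.ndarray) -> int:
    parent = np.arange(n_vertices)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    comps = n_vertices
    for a, b in edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
            comps -= 1
    return comps


def alpha_diagram_degree1(points: np.ndarray,
                          min_persistence: float = 1e-12) -> PersistenceDiagram:
    """Degree-1 persistence diagram of the alpha complex of a point cloud.

    Pairs with persistence below ``min_persistence`` (numerical noise and
    simplices entering simultaneously) are dropped.  Values are squared
    radii in um^2.  Clouds with fewer than 3 points have no loops and give
    an empty diagram.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or (pts.size and pts.shape[1] != 3):
        raise DegenerateInputError("expected an (n, 3) coordinate array")
    if pts.shape[0] < 3:
        return PersistenceDiagram(degree=1, points=np.empty((0, 2)))
    if np.unique(pts, axis=0).shape[0] < 3:
        raise DegenerateInputError("fewer than 3 distinct points")

    edges, edge_values, tris, tri_values = alpha_filtration_simplices(pts)

    # Global filtration order: value, then dimension (edges precede
    # triangles at ties), then index for determinism.
    edge_order = np.lexsort((np.arange(len(edges)), edge_values))
    edge_rank = np.empty(len(edges), dtype=np.int64)
    edge_rank[edge_order] = np.arange(len(edges))
    tri_order = np.lexsort((np.arange(len(tris)), tri_values))

    # Edge index pairs per triangle, as filtration ranks (vectorized
    # lookup via the sorted edge key array).
    edge_cols = np.array([[1, 2], [0, 2], [0, 1]])
    stride = np.int64(pts.shape[0] + 1)
    key = edges[:, 0].astype(np.int64) * stride + edges[:, 1]
    # np.unique returns edges sorted lexicographically, so key is sorted.
    tri_edge_ranks = np.empty((len(tris), 3), dtype=np.int64)
    for j in range(3):
        ek = (tris[:, edge_cols[j, 0]].astype(np.int64) * stride
              + tris[:, edge_cols[j, 1]])
        tri_edge_ranks[:, j] = edge_rank[np.searchsorted(key, ek)]

    # Standard Z/2 boundary-matrix reduction of the triangle columns; the
    # lowest-one pairing yields the (edge, triangle) = (birth, death)
    # pairs.  Columns are kept as Python integer bitsets (bit r set =
    # edge of filtration rank r present), so column addition is XOR and
    # the pivot is bit_length - 1.
    pivot: dict[int, int] = {}
    births = []
    deaths = []
    one = 1
    for t in tri_order:
        r0, r1, r2 = tri_edge_ranks[t]
        col = (one << int(r0)) | (one << int(r1)) | (one << int(r2))
        while col:
            low = col.bit_length() - 1
            other = pivot.get(low)
            if other is None:
                pivot[low] = col
                births.append(edge_values[edge_order[low]])
                deaths.append(tri_values[t])
                break
            col ^= other

    births = np.asarray(births)
    deaths = np.asarray(deaths)

    # Sanity check: in an alpha filtration every loop is eventually filled,
    # so the pair count must equal the number of cycle-creating edges.
    expected = len(edges) - (pts.shape[0] - _n_components(pts.shape[0], edges))
    if len(births) != expected:  # pragma: no cover - numerics guard
        raise DegenerateInputError(
            f"persistence pairing inconsistent: {len(births)} pairs, "
            f"expected {expected} (degenerate geometry?)")

    if births.size:
        keep = (deaths - births) > min_persistence
        births, deaths = births[keep], deaths[keep]
        order = np.lexsort((deaths, births))
        births, deaths = births[order], deaths[order]
    return PersistenceDiagram(degree=1, points=np.column_stack([births, deaths]))
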