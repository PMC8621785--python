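"""Oriented triangulated surfaces spanning covalent loops.

The piercing calculus needs, for every covalent loop, a surface whose
boundary is the loop's CA polygon (closed across the bridge) and whose
triangles carry a consistent orientation: each triangle normal follows the
right-hand rule around the loop traversed in increasing residue order.
Piercing signs are defined against these normals.

The surface is initialised as a centroid fan and relaxed toward minimal
area by per-vertex gradient descent with the boundary held fixed.  Exact
minimality is not required downstream — crossing *topology* is what
matters — so the minimiser favours determinism and monotonicity over
speed of convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TriangulatedSurface",
    "MinParams",
    "DegenerateSurfaceError",
    "triangulate_loop",
    "minimize_surface",
    "write_obj",
]


class DegenerateSurfaceError(ValueError):
    """Loop geometry admits no non-degenerate spanning surface."""


@dataclass
class MinParams:
    """Controls for surface relaxation.

    max_iter : maximum vertex-update sweeps (>= 1)
    rel_tol  : stop when the relative total-area change per sweep falls
               below this value
    max_edge : edges longer than this (Angstrom) are split once before
               relaxation; None = mean boundary edge length
    """

    max_iter: int = 200
    rel_tol: float = 1e-4
    max_edge: float | None = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")


@dataclass
class TriangulatedSurface:
    """Oriented triangle mesh with its boundary pinned to a loop polygon."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int, consistent winding
    boundary: np.ndarray  # ordered indices tracing the loop polygon
    converged: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=int)

    @property
    def area(self) -> float:
        """Total surface area (Angstrom^2)."""
        return float(np.sum(self._triangle_areas()))

    def _triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def interior_indices(self) -> np.ndarray:
        mask = np.ones(len(self.vertices), dtype=bool)
        mask[self.boundary] = False
        return np.nonzero(mask)[0]

    def copy(self) -> "TriangulatedSurface":
        return TriangulatedSurface(
            self.vertices.copy(), self.triangles.copy(), self.boundary.copy(),
            self.converged,
        )


def triangulate_loop(loop, chain) -> TriangulatedSurface:
    """Fan-triangulate the CA polygon of a covalent loop.

    The boundary polygon visits the loop residues in increasing residue
    order and closes across the bridge edge (last -> first CA).  Triangles
    are wound so their normals follow the right-hand rule of that
    traversal.

    Raises
    ------
    DegenerateSurfaceError
        If the loop CAs are (numerically) collinear.
    """
    idx = list(range(loop.res_i, loop.res_j + 1))
    points = np.array([chain.residues[i - 1].ca for i in idx], dtype=float)
    return triangulate_polygon(points)


def triangulate_polygon(points: np.ndarray) -> TriangulatedSurface:
    """Centroid-fan triangulation of an ordered closed polygon."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise DegenerateSurfaceError("loop polygon needs at least 3 vertices")
    centroid = points.mean(axis=0)
    vertices = np.vstack([points, centroid])
    tris = np.array([[k, (k + 1) % n, n] for k in range(n)], dtype=int)
    surf = TriangulatedSurface(vertices, tris, np.arange(n))
    if surf.area < 1e-10 * max(1.0, float(np.ptp(points))) ** 2:
        raise DegenerateSurfaceError("collinear loop: spanning surface degenerate")
    return surf


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _refine_long_edges(surf: TriangulatedSurface, max_edge: float) -> TriangulatedSurface:
    """Split every edge longer than ``max_edge`` at its midpoint (one round).

    Midpoints are shared between adjacent triangles; 1/2/3 split edges per
    triangle produce 2/3/4 child triangles with the parent's winding.
    Boundary edges are never split so the boundary polygon stays pinned to
    the loop CAs.
    """
    V = surf.vertices
    boundary_edges = set()
    b = surf.boundary
    for k in range(len(b)):
        e = (int(b[k]), int(b[(k + 1) % len(b)]))
        boundary_edges.add(tuple(sorted(e)))

    midpoint: dict[tuple[int, int], int] = {}
    new_vertices = [V]

    def mid(i: int, j: int) -> int | None:
        key = (i, j) if i < j else (j, i)
        if key in boundary_edges:
            return None
        if np.linalg.norm(V[i] - V[j]) <= max_edge:
            return None
        if key not in midpoint:
            midpoint[key] = len(V) + len(midpoint)
            new_vertices.append(0.5 * (V[i] + V[j])[None, :])
        return midpoint[key]

    new_tris: list[list[int]] = []
    for a, bb, c in surf.triangles:
        a, bb, c = int(a), int(bb), int(c)
        mab, mbc, mca = mid(a, bb), mid(bb, c), mid(c, a)
        k = sum(m is not None for m in (mab, mbc, mca))
        if k == 0:
            new_tris.append([a, bb, c])
        elif k == 3:
            new_tris += [[a, mab, mca], [mab, bb, mbc], [mca, mbc, c], [mab, mbc, mca]]
        elif k == 1:
            # rotate so the split edge is (a, bb)
            if mbc is not None:
                a, bb, c, mab = bb, c, a, mbc
            elif mca is not None:
                a, bb, c, mab = c, a, bb, mca
            new_tris += [[a, mab, c], [mab, bb, c]]
        else:  # k == 2: rotate so the un-split edge is (a, bb)
            if mab is None:
                pass
            elif mbc is None:
                a, bb, c, mbc, mca = bb, c, a, mca, mab
            else:
                a, bb, c, mbc, mca = c, a, bb, mab, mbc
            new_tris += [[a, bb, mbc], [a, mbc, mca], [mca, mbc, c]]
    return TriangulatedSurface(
        np.vstack(new_vertices), np.array(new_tris, dtype=int), surf.boundary.copy()
    )


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

def _total_area(V: np.ndarray, tris: np.ndarray) -> float:
    a, b, c = V[tris[:, 0]], V[tris[:, 1]], V[tris[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


def _area_gradient(V: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """d(total area)/d(vertex), accumulated over all triangles.

    For triangle (v, p, q) the contribution to vertex v is
    0.5 * n_hat x (q - p), with n_hat the unit triangle normal.
    """
    a, b, c = V[tris[:, 0]], V[tris[:, 1]], V[tris[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nn[nn < 1e-300] = 1.0
    nhat = n / nn
    grad = np.zeros_like(V)
    np.add.at(grad, tris[:, 0], 0.5 * np.cross(nhat, c - b))
    np.add.at(grad, tris[:, 1], 0.5 * np.cross(nhat, a - c))
    np.add.at(grad, tris[:, 2], 0.5 * np.cross(nhat, b - a))
    return grad


def minimize_surface(surface: TriangulatedSurface, params: MinParams | None = None) -> TriangulatedSurface:
    """Relax interior vertices toward minimal area with the boundary fixed.

    Deterministic damped gradient descent on the total area: every sweep
    moves all interior vertices along the negative area gradient with a
    backtracked global step, accepted only when the total area strictly
    decreases, so the area is non-increasing across sweeps.  Stops when
    the relative area change of a sweep drops below ``rel_tol`` or after
    ``max_iter`` sweeps (then ``converged`` is False).
    """
    params = params or MinParams()
    surf = surface.copy()
    max_edge = params.max_edge
    if max_edge is None:
        b = surf.vertices[surf.boundary]
        max_edge = float(np.mean(np.linalg.norm(np.roll(b, -1, axis=0) - b, axis=1)))
    # one refinement round when any edge exceeds max_edge
    edges = surf.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    lengths = np.linalg.norm(
        surf.vertices[edges[:, 0]] - surf.vertices[edges[:, 1]], axis=1)
    if np.any(lengths > max_edge):
        surf = _refine_long_edges(surf, max_edge)

    V = surf.vertices
    tris = surf.triangles
    interior = surf.interior_indices()
    if interior.size == 0:
        surf.converged = True
        return surf

    def objective(x: np.ndarray):
        V[interior] = x.reshape(-1, 3)
        return _total_area(V, tris), _area_gradient(V, tris)[interior].ravel()

    # L-BFGS-B with a sufficient-decrease line search: area is monotone
    # non-increasing across iterations; the stopping rule matches the
    # relative-area-change-per-sweep semantics of rel_tol
    from scipy.optimize import minimize as _minimize

    res = _minimize(
        objective, V[interior].ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": params.max_iter, "ftol": params.rel_tol,
                 "gtol": 1e-12, "maxls": 50},
    )
    V[interior] = res.x.reshape(-1, 3)
    surf.converged = "ITERATIONS REACHED LIMIT" not in str(res.message).upper()
    return surf


def write_obj(surface: TriangulatedSurface, path) -> None:
    """Export the mesh as Wavefront OBJ (visual debugging)."""
    with open(path, "w") as fh:
        for v in surface.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for a, b, c in surface.triangles + 1:
            fh.write(f"f {a} {b} {c}\n")
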