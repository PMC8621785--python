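"""Oriented tail-through-surface crossings and their reduction to piercings.

Every CA-CA segment of a terminal tail is tested against every triangle of
the loop's spanning surface with exact-style signed-volume (orientation)
predicates.  A crossing is *positive* when the chain direction (increasing
residue index) agrees with the local triangle normal, negative otherwise.

Raw crossings are then reduced to topologically meaningful piercings:
adjacent opposite-sign crossings closer than ``cancel_eps`` (surface
wobble) annihilate pairwise, and crossings with fewer than
``min_tail_depth`` residues of tail beyond them are discarded as too
shallow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .surface import TriangulatedSurface

__all__ = [
    "Crossing",
    "Piercing",
    "ReduceParams",
    "find_crossings",
    "reduce_crossings",
    "bridge_piercing_distance",
    "UndefinedDistanceError",
]

Sign = Literal["+", "-"]


class UndefinedDistanceError(ValueError):
    """No piercings: the bridge-piercing distance is undefined."""


@dataclass(frozen=True)
class Crossing:
    """One oriented intersection of a tail segment with the surface."""

    tail: str  # "N" or "C"
    segment: tuple[int, int]  # chain residue indices of the CA-CA segment
    sign: Sign
    point: np.ndarray  # 3D intersection coordinate
    t: float  # parametric position on the segment, in [0, 1]
    outward_index: int  # 0-based segment rank counted from the loop outward

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))


@dataclass(frozen=True)
class Piercing:
    crossing: Crossing
    depth: int  # tail residues beyond the crossing
    rank: int  # 1-based order along the tail from the loop outward


@dataclass
class ReduceParams:
    """Thresholds for crossing reduction.

    min_tail_depth : minimum residues of tail beyond a crossing (default 3)
    cancel_eps     : spatial tolerance for wobble cancellation (Angstrom)
    cancel_sep     : maximum residue separation of a cancelling pair
    """

    min_tail_depth: int = 3
    cancel_eps: float = 2.0
    cancel_sep: int = 1

    def __post_init__(self):
        if min(self.min_tail_depth, self.cancel_eps, self.cancel_sep) < 0:
            raise ValueError("reduction thresholds must be >= 0")


def _orient(a, b, c, p) -> float:
    """Signed volume predicate: > 0 when p lies on the normal side of (a,b,c)."""
    return float(np.dot(np.cross(b - a, c - a), p - a))


# degenerate-contact policy: a tail point lying exactly in a triangle's
# plane (orientation volume below _EPS * scale^3) crosses nothing — the
# contact is tangential, and treating it so on both adjacent segments keeps
# the count consistent without random jitter.  Crossings exactly through a
# shared mesh edge or vertex are accepted by every incident triangle and
# merged afterwards by their parametric position.
_EPS = 1e-12


def find_crossings(
    surface: TriangulatedSurface,
    tail: Sequence[np.ndarray] | np.ndarray,
    tail_label: str,
    residue_indices: Sequence[int] | None = None,
    chain_direction: int = 1,
    flip_signs: bool = False,
) -> list[Crossing]:
    """All oriented intersections of a tail polyline with the surface.

    Parameters
    ----------
    tail
        CA points ordered from the loop outward; ``tail[0]`` is the CA of
        the loop residue the tail hangs off, so segment *m* joins tail
        residues *m* and *m+1* counted from the loop.
    residue_indices
        Chain residue indices parallel to ``tail`` (for reporting); by
        default the outward positions themselves are used.
    chain_direction
        +1 when outward order equals increasing residue index (C-tail),
        -1 for the N-tail, whose chain direction runs toward the loop.
    flip_signs
        Globally mirror the sign convention (calibration flag).

    Returns crossings ordered along the tail away from the loop;
    intersections on shared triangle edges are counted once.
    """
    pts = np.asarray(tail, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("tail must be an (n, 3) polyline")
    if residue_indices is None:
        residue_indices = list(range(len(pts)))
    V = surface.vertices
    tris = surface.triangles
    A = V[tris[:, 0]]
    B = V[tris[:, 1]]
    C = V[tris[:, 2]]
    scale = float(np.max(np.abs(np.concatenate([V, pts])))) + 1.0
    eps = _EPS * scale**3

    normals = np.cross(B - A, C - A)
    out: list[Crossing] = []
    for m in range(len(pts) - 1):
        p0, p1 = pts[m], pts[m + 1]
        d0 = np.einsum("ij,ij->i", normals, p0 - A)
        d1 = np.einsum("ij,ij->i", normals, p1 - A)
        hits: list[tuple[float, str, np.ndarray]] = []
        for k in np.nonzero((np.abs(d0) > eps) & (np.abs(d1) > eps)
                            & (d0 * d1 < 0))[0]:
            s0, s1 = d0[k], d1[k]
            a, b, c = A[k], B[k], C[k]
            u = _orient(p0, p1, a, b)
            v = _orient(p0, p1, b, c)
            w = _orient(p0, p1, c, a)
            tol = 1e-9 * max(abs(u), abs(v), abs(w))
            if not (min(u, v, w) >= -tol or max(u, v, w) <= tol):
                continue
            t = s0 / (s0 - s1)
            point = p0 + t * (p1 - p0)
            geom: Sign = "+" if s1 > s0 else "-"
            hits.append((t, geom, point))
        hits.sort(key=lambda h: h[0])
        merged: list[tuple[float, str, np.ndarray]] = []
        for h in hits:
            if merged and abs(h[0] - merged[-1][0]) < 1e-9 and h[1] == merged[-1][1]:
                continue  # same point via a shared triangle edge
            merged.append(h)
        for t, geom, point in merged:
            sign: Sign = geom if chain_direction > 0 else ("-" if geom == "+" else "+")
            if flip_signs:
                sign = "-" if sign == "+" else "+"
            lo = min(residue_indices[m], residue_indices[m + 1])
            hi = max(residue_indices[m], residue_indices[m + 1])
            out.append(
                Crossing(tail_label, (lo, hi), sign, point, float(t), m)
            )
    return out


def reduce_crossings(
    crossings: Sequence[Crossing],
    tail_len: int,
    params: ReduceParams | None = None,
) -> list[Piercing]:
    """Reduce raw crossings to genuine piercings.

    First cancels adjacent opposite-sign pairs whose intersection points
    lie within ``cancel_eps`` and whose segments are within ``cancel_sep``
    residues (local surface wobble), iterating to a fixed point; then
    drops crossings with fewer than ``min_tail_depth`` tail residues
    beyond them.  Surviving piercings are re-ranked 1..k from the loop.
    """
    params = params or ReduceParams()
    work = list(crossings)
    changed = True
    while changed:
        changed = False
        for k in range(len(work) - 1):
            a, b = work[k], work[k + 1]
            if (
                a.sign != b.sign
                and abs(a.outward_index - b.outward_index) <= params.cancel_sep
                and float(np.linalg.norm(a.point - b.point)) <= params.cancel_eps
            ):
                del work[k : k + 2]
                changed = True
                break
    out: list[Piercing] = []
    for c in work:
        depth = tail_len - c.outward_index
        if depth >= params.min_tail_depth:
            out.append(Piercing(c, depth, rank=len(out) + 1))
    return out


def bridge_piercing_distance(loop, piercings: Sequence[Piercing]) -> int:
    """Sequential distance between the bridge and its nearest piercing.

    For each piercing this is the number of residues separating the
    bridge-forming residue on the piercing tail's side from the piercing
    segment (0 when the very first tail segment pierces); the minimum over
    all piercings is returned.
    """
    if not piercings:
        raise UndefinedDistanceError("no piercings: distance undefined")
    return min(p.crossing.outward_index for p in piercings)
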