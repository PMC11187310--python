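"""Knot typing of open and closed 3D polylines.

The engine decides the knot type of a backbone curve in four steps:

1. :func:`kmt_reduce` — geometric chain simplification that removes a
   vertex whenever the triangle spanned with its neighbours is pierced by
   no other segment, preserving the underlying knot.
2. :func:`close_chain` — an open chain has no knot type until its termini
   are joined; closure is done directly or stochastically through points
   on a large sphere, and the final call is a majority vote over closures.
3. :func:`alexander_invariants` — project the closed curve to a generic
   plane diagram, build the Alexander matrix from its crossings and arcs,
   and evaluate the Alexander polynomial at t = -1 and t = -2 over exact
   integer arithmetic.  The pair (|Δ(-1)|, |Δ(-2)|) separates all knot
   types this package cares about, including the composite 3₁#3₁ from the
   6₁ knot, which share |Δ(-1)| = 9.
4. :func:`classify_knot` — look the invariant pair up in a fixed table.

Determinants are multiplicative under connected sum and blind to
chirality, so the composite label is reported as 3_1#3_1 without a
granny/square distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .structure_io import Polyline3D

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedPolyline",
    "InvariantPair",
    "KnotCall",
    "ClosureConfig",
    "ProjectionError",
    "KNOT_TABLE",
    "UNKNOT",
    "kmt_reduce",
    "close_chain",
    "alexander_invariants",
    "classify_knot",
    "knot_type",
]

UNKNOT = "0_1"

#: (|Δ(-1)|, |Δ(-2)|) -> knot label, from the tabulated Alexander polynomials
#: (3_1: t-1+1/t, 4_1: -t+3-1/t, 5_1: t²-t+1-1/t+1/t², 5_2: 2t-3+2/t,
#:  6_1: 2t-5+2/t, 6_2: -t²+3t-3+3/t-1/t², 6_3: t²-3t+5-3/t+1/t²),
#: cleared of monomial units and evaluated at -1 and -2; the composite
#: 3_1#3_1 entry follows from multiplicativity: (3·3, 7·7).
KNOT_TABLE: dict[tuple[int, int], str] = {
    (1, 1): UNKNOT,
    (3, 7): "3_1",
    (5, 11): "4_1",
    (5, 31): "5_1",
    (7, 16): "5_2",
    (9, 20): "6_1",
    (11, 59): "6_2",
    (13, 67): "6_3",
    (9, 49): "3_1#3_1",
}


class ProjectionError(RuntimeError):
    """No generic planar projection found within the retry budget."""


@dataclass(frozen=True)
class InvariantPair:
    """|Δ(-1)| and |Δ(-2)| of a closed curve, exact nonnegative integers."""

    det1: int
    det2: int

    def __post_init__(self):
        if self.det1 < 1 or self.det2 < 0:
            raise ValueError(f"invalid invariant pair ({self.det1}, {self.det2})")
        if self.det1 % 2 == 0:
            raise ValueError(f"|Δ(-1)| must be odd, got {self.det1}")

    def as_tuple(self) -> tuple[int, int]:
        return (self.det1, self.det2)


@dataclass(frozen=True)
class ReducedPolyline:
    """KMT-simplified polyline; ``provenance`` is the original point count."""

    points: np.ndarray
    provenance: int
    labels: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.points)

    def as_polyline(self) -> Polyline3D:
        return Polyline3D(self.points, self.labels)


@dataclass(frozen=True)
class ClosureConfig:
    """How to close an open chain before computing invariants.

    ``sphere_random`` extends both termini to random points on a sphere of
    radius ``sphere_radius_factor`` times the chain's maximal centroid
    distance and joins them outside the sphere; ``two_ray`` extends along
    the terminal segment directions instead; ``direct`` joins the termini
    with a single segment (one deterministic closure).
    """

    strategy: str = "sphere_random"
    n_closures: int = 100
    seed: int = 0
    sphere_radius_factor: float = 2.0

    def __post_init__(self):
        if self.strategy not in ("direct", "sphere_random", "two_ray"):
            raise ValueError(f"unknown closure strategy {self.strategy!r}")
        if self.n_closures < 1:
            raise ValueError("n_closures must be >= 1")
        if self.strategy == "direct" and self.n_closures != 1:
            object.__setattr__(self, "n_closures", 1)

    def replace(self, **kw) -> "ClosureConfig":
        d = dict(strategy=self.strategy, n_closures=self.n_closures,
                 seed=self.seed, sphere_radius_factor=self.sphere_radius_factor)
        d.update(kw)
        return ClosureConfig(**d)


@dataclass(frozen=True)
class KnotCall:
    """Majority knot label over stochastic closures with its support."""

    label: str
    support: float
    invariants: InvariantPair
    n_closures: int = 1

    @property
    def is_knotted(self) -> bool:
        return self.label not in (UNKNOT,) and not self.label.startswith("unresolved")


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------

_KMT_TOL = 1e-9


def _cross_mk(ax, ay, az, bx, by, bz):
    """Component-wise cross product of broadcastable coordinate arrays."""
    return (ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx)


def _batch_triangle_pierce(tris: np.ndarray, starts: np.ndarray,
                           dirs: np.ndarray, excluded) -> np.ndarray:
    """Möller–Trumbore for m triangles against k segments at once.

    ``excluded[m, k]`` (or None) masks segments adjacent to each
    triangle.  Returns the boolean hit matrix.  Conservative:
    near-boundary and near-parallel hits count as piercing, so a vertex
    is only removed when clearly safe.
    """
    a = tris[:, 0]
    e1 = tris[:, 1] - a
    e2 = tris[:, 2] - a
    # shapes: triangles (m, 1), segments (1, k)
    e1x, e1y, e1z = (e1[:, i, None] for i in range(3))
    e2x, e2y, e2z = (e2[:, i, None] for i in range(3))
    dx, dy, dz = (dirs[None, :, i] for i in range(3))
    hx, hy, hz = _cross_mk(dx, dy, dz, e2x, e2y, e2z)
    det = hx * e1x + hy * e1y + hz * e1z
    parallel = np.abs(det) < _KMT_TOL
    det_safe = np.where(parallel, 1.0, det)
    sx = starts[None, :, 0] - a[:, 0, None]
    sy = starts[None, :, 1] - a[:, 1, None]
    sz = starts[None, :, 2] - a[:, 2, None]
    u = (sx * hx + sy * hy + sz * hz) / det_safe
    qx, qy, qz = _cross_mk(sx, sy, sz, e1x, e1y, e1z)
    v = (dx * qx + dy * qy + dz * qz) / det_safe
    t = (e2x * qx + e2y * qy + e2z * qz) / det_safe
    tol = 1e-9
    hit = (
        ~parallel
        & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)
        & (t >= -tol) & (t <= 1 + tol)
    )
    if excluded is not None:
        hit &= ~excluded
    return hit


def kmt_reduce(polyline: Polyline3D | ReducedPolyline, closed: bool = False) -> ReducedPolyline:
    """Simplify a chain by repeated topology-preserving vertex removal.

    A vertex is removable when the triangle it spans with its two
    neighbours is pierced by no other segment of the chain, so deleting
    it (replacing two segments by the triangle base) is an isotopy.  Each
    sweep tests all vertices against all segments at once and removes a
    non-adjacent subset of the safe ones; sweeps repeat until one removes
    nothing.  Endpoints of open chains are never removed; closed chains
    are treated cyclically.
    """
    pts = np.asarray(polyline.points, dtype=float)
    labels = getattr(polyline, "labels", None)
    orig_n = len(pts)
    if orig_n < 3:
        raise ValueError("need at least 3 points")

    # drop exact duplicates / zero-length segments up front
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dup = np.where(d < 1e-12)[0]
    if len(dup):
        logger.warning("kmt_reduce: %d duplicate consecutive points cleaned", len(dup))
        keep = np.ones(orig_n, dtype=bool)
        keep[dup + 1] = False
        pts = pts[keep]
        if labels is not None:
            labels = np.asarray(labels)[keep]

    idx = np.arange(len(pts))
    while True:
        n = len(idx)
        if n < 3 or (closed and n == 3):
            break
        cur = pts[idx]
        if closed:
            cand = np.arange(n)
            prev = (cand - 1) % n
            nxt = (cand + 1) % n
            seg_starts = cur
            seg_dirs = np.roll(cur, -1, axis=0) - cur
            n_seg = n
        else:
            cand = np.arange(1, n - 1)
            prev = cand - 1
            nxt = cand + 1
            seg_starts = cur[:-1]
            seg_dirs = cur[1:] - cur[:-1]
            n_seg = n - 1
        tris = np.stack([cur[prev], cur[cand], cur[nxt]], axis=1)
        # segments adjacent to the triangle (sharing a vertex) are excluded
        seg_ids = np.arange(n_seg)[None, :]
        excl = np.zeros((len(cand), n_seg), dtype=bool)
        for off in (-2, -1, 0, 1):
            adj = (cand[:, None] + off)
            adj = adj % n_seg if closed else adj
            excl |= seg_ids == adj
        # degenerate (near-collinear) triangles are always removable
        e1 = tris[:, 1] - tris[:, 0]
        e2 = tris[:, 2] - tris[:, 0]
        cx, cy, cz = _cross_mk(e1[:, 0], e1[:, 1], e1[:, 2],
                               e2[:, 0], e2[:, 1], e2[:, 2])
        area2 = np.sqrt(cx * cx + cy * cy + cz * cz)
        pierced = _batch_triangle_pierce(tris, seg_starts, seg_dirs, excl).any(axis=1)
        removable = ~pierced | (area2 < 2 * _KMT_TOL)
        if not removable.any():
            break
        # take a non-adjacent subset: two neighbouring vertices must not go
        # in the same sweep (each removal reshapes its neighbour's triangle)
        sel: list[int] = []
        last_dropped = -2
        for c in cand[removable]:
            if c - last_dropped >= 2:
                sel.append(int(c))
                last_dropped = int(c)
        if closed and len(sel) > 1 and sel[0] == 0 and sel[-1] == n - 1:
            sel.pop()
        sel_arr = np.asarray(sel)
        sel_k = np.searchsorted(cand, sel_arr)
        # a removal's replacement chord must not pierce another removed
        # vertex's triangle; chords sharing a triangle vertex only touch
        # the boundary and are safe
        if len(sel) > 1:
            ch_starts = tris[sel_k, 0]
            ch_dirs = tris[sel_k, 2] - tris[sel_k, 0]
            dist = np.abs(sel_arr[:, None] - sel_arr[None, :])
            if closed:
                dist = np.minimum(dist, n - dist)
            share = dist <= 2
            bad = _batch_triangle_pierce(tris[sel_k], ch_starts, ch_dirs, share).any(axis=1)
            sel_arr = sel_arr[~bad]
        if len(sel_arr) == 0:
            break
        max_remove = n - 3 if closed else n - 2
        sel_arr = sel_arr[:max_remove]
        if len(sel_arr) == 0:
            break
        drop = np.zeros(n, dtype=bool)
        drop[sel_arr] = True
        idx = idx[~drop]

    out_pts = pts[idx]
    out_labels = labels[idx] if labels is not None else None
    return ReducedPolyline(out_pts, provenance=orig_n, labels=out_labels)


# ---------------------------------------------------------------------------
# Chain closure
# ---------------------------------------------------------------------------


def _outside_join(first: np.ndarray, last: np.ndarray, centroid: np.ndarray,
                  radius: float, u_last: np.ndarray, u_first: np.ndarray) -> np.ndarray:
    """Points closing ``last`` -> sphere -> ``first`` outside the sphere."""
    a = centroid + radius * u_last
    b = centroid + radius * u_first
    a2 = centroid + 2.0 * radius * u_last
    b2 = centroid + 2.0 * radius * u_first
    w = u_last + u_first
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        # antipodal: pick any perpendicular direction for the far waypoint
        trial = np.array([1.0, 0.0, 0.0])
        if abs(u_last @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        w = np.cross(u_last, trial)
        nw = np.linalg.norm(w)
    m = centroid + 3.0 * radius * (w / nw)
    return np.vstack([a, a2, m, b2, b])


def close_chain(polyline: Polyline3D | ReducedPolyline,
                config: ClosureConfig) -> list[Polyline3D]:
    """Produce ``config.n_closures`` closed curves from an open chain.

    The returned polylines are to be read cyclically (last point connects
    back to the first).  Identical config (including seed) gives identical
    closures.
    """
    pts = np.asarray(polyline.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if config.strategy == "direct":
        return [Polyline3D(pts.copy())]

    centroid = pts.mean(axis=0)
    radius = config.sphere_radius_factor * float(
        np.max(np.linalg.norm(pts - centroid, axis=1))
    )
    radius = max(radius, 1.0)
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_closures):
        if config.strategy == "sphere_random":
            # extend BOTH termini along one uniformly random direction to
            # beyond the sphere, then join the far points directly: their
            # chord is the translate of the first-last chord, far outside
            # the chain, so the join itself cannot entangle
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            shift = 2.0 * radius * u
            extra = np.vstack([pts[-1] + shift, pts[0] + shift])
            out.append(Polyline3D(np.vstack([pts, extra])))
        else:  # two_ray: extend along terminal directions
            d_last = pts[-1] - pts[-2]
            d_first = pts[0] - pts[1]
            u_last = _ray_to_sphere(pts[-1], d_last, centroid, radius)
            u_first = _ray_to_sphere(pts[0], d_first, centroid, radius)
            extra = _outside_join(pts[0], pts[-1], centroid, radius,
                                  u_last, u_first)
            out.append(Polyline3D(np.vstack([pts, extra])))
    return out


def _ray_to_sphere(origin: np.ndarray, direction: np.ndarray,
                   centroid: np.ndarray, radius: float) -> np.ndarray:
    """Unit vector from centroid to where the ray meets the sphere."""
    d = direction / max(np.linalg.norm(direction), 1e-12)
    o = origin - centroid
    b = o @ d
    c = o @ o - radius * radius
    disc = max(b * b - c, 0.0)
    s = -b + np.sqrt(disc)
    p = o + s * d
    return p / max(np.linalg.norm(p), 1e-12)


# ---------------------------------------------------------------------------
# Alexander invariants from a planar diagram
# ---------------------------------------------------------------------------

_MAX_PROJECTION_RETRIES = 25
_GENERIC_TOL = 1e-6


def _projection_directions(seed: int, n: int) -> np.ndarray:
    """Deterministic sequence of candidate projection directions."""
    dirs = [np.array([0.12, 0.35, 0.93])]  # fixed, mildly oblique first try
    rng = np.random.default_rng(seed)
    extra = rng.normal(size=(n, 3))
    extra /= np.linalg.norm(extra, axis=1, keepdims=True)
    dirs.extend(extra)
    return np.array(dirs[:n])


def _diagram_crossings(pts2: np.ndarray, depth: np.ndarray):
    """All transversal crossings of the cyclic projected chain.

    Returns a list of crossings ``(seg_over, s_over, seg_under, s_under,
    sign)`` or None when the projection is non-generic (near-tangent,
    near-vertex, coincident crossings, or ambiguous depth).
    """
    n = len(pts2)
    starts = pts2
    r = np.roll(pts2, -1, axis=0) - pts2
    seglen = np.linalg.norm(r, axis=1)
    scale = float(np.max(seglen)) + 1e-30

    ii, jj = np.triu_indices(n, k=2)
    wrap = (ii == 0) & (jj == n - 1)
    ii, jj = ii[~wrap], jj[~wrap]

    qp = starts[jj] - starts[ii]
    cross_rr = r[ii, 0] * r[jj, 1] - r[ii, 1] * r[jj, 0]
    denom_tol = 1e-12 * scale * scale
    nonpar = np.abs(cross_rr) > denom_tol
    s = np.where(nonpar, (qp[:, 0] * r[jj, 1] - qp[:, 1] * r[jj, 0]), 0.0)
    u = np.where(nonpar, (qp[:, 0] * r[ii, 1] - qp[:, 1] * r[ii, 0]), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(nonpar, s / cross_rr, -1.0)
        u = np.where(nonpar, u / cross_rr, -1.0)

    g = 1e-9
    hit = nonpar & (s > g) & (s < 1 - g) & (u > g) & (u < 1 - g)
    near = nonpar & (s > -g) & (s < 1 + g) & (u > -g) & (u < 1 + g) & ~hit
    if near.any():
        return None
    # near-parallel segments lying on one line with proper interior
    # overlap make the diagram ambiguous (collinear runs that merely
    # touch end-to-end are fine)
    if (~nonpar).any():
        for a, b in zip(ii[~nonpar], jj[~nonpar]):
            if seglen[a] < 1e-12 or seglen[b] < 1e-12:
                continue
            d = starts[b] - starts[a]
            perp = abs(d[0] * r[a][1] - d[1] * r[a][0]) / (seglen[a] + 1e-30)
            if perp >= _GENERIC_TOL * scale:
                continue
            axis = r[a] / seglen[a]
            ta = np.sort([0.0, r[a] @ axis])
            tb = np.sort([d @ axis, (d + r[b]) @ axis])
            overlap = min(ta[1], tb[1]) - max(ta[0], tb[0])
            if overlap > _GENERIC_TOL * scale:
                return None

    ks = np.where(hit)[0]
    if len(ks) == 0:
        return []
    pxy = starts[ii[ks]] + s[ks, None] * r[ii[ks]]
    # coincident crossing points are non-generic
    if len(ks) > 1:
        from scipy.spatial.distance import pdist

        if pdist(pxy).min() < _GENERIC_TOL * scale:
            return None

    depth_next = np.roll(depth, -1)
    crossings = []
    for k, (a, b) in zip(ks, zip(ii[ks], jj[ks])):
        za = depth[a] + s[k] * (depth_next[a] - depth[a])
        zb = depth[b] + u[k] * (depth_next[b] - depth[b])
        if abs(za - zb) < _GENERIC_TOL * scale:
            return None
        if za > zb:
            over, s_over, under, s_under = a, s[k], b, u[k]
            d_over, d_under = r[a], r[b]
        else:
            over, s_over, under, s_under = b, u[k], a, s[k]
            d_over, d_under = r[b], r[a]
        sign = 1 if (d_over[0] * d_under[1] - d_over[1] * d_under[0]) > 0 else -1
        crossings.append((int(over), float(s_over), int(under), float(s_under), sign))
    return crossings


def _alexander_matrix(crossings) -> tuple[np.ndarray, np.ndarray]:
    """Constant and t-linear parts of the Alexander matrix (one row/crossing).

    Arcs are the maximal runs of the cyclic chain between consecutive
    undercrossings.  At a crossing with over-arc i, incoming under-arc j
    and outgoing under-arc k, Fox calculus on the Wirtinger relation gives
    row entries (1-t, t, -1) for a positive crossing and (1-t, -1, t) for
    a negative one.
    """
    m = len(crossings)
    under_events = sorted(
        ((c[2], c[3], idx) for idx, c in enumerate(crossings))
    )
    # arc index a starts at under_events[a] and ends at under_events[a+1]
    positions = [(seg, pos) for seg, pos, _ in under_events]

    def arc_of(seg: int, pos: float) -> int:
        """Arc containing the point (seg, pos) of the cyclic chain."""
        import bisect

        a = bisect.bisect_right(positions, (seg, pos)) - 1
        return a % m

    M0 = np.zeros((m, m), dtype=np.int64)
    M1 = np.zeros((m, m), dtype=np.int64)
    event_arc = {idx: a for a, (_, _, idx) in enumerate(under_events)}
    for idx, (over, s_over, under, s_under, sign) in enumerate(crossings):
        arc_out = event_arc[idx]              # arc starting at this undercross
        arc_in = (arc_out - 1) % m            # arc ending here
        arc_over = arc_of(over, s_over)
        row = idx
        # over: 1 - t
        M0[row, arc_over] += 1
        M1[row, arc_over] -= 1
        if sign > 0:
            M1[row, arc_in] += 1              # + t
            M0[row, arc_out] -= 1             # - 1
        else:
            M0[row, arc_in] -= 1              # - 1
            M1[row, arc_out] += 1             # + t
    return M0, M1


def _int_det_bareiss(mat: list[list[int]]) -> int:
    """Exact determinant of an integer matrix (fraction-free Bareiss)."""
    n = len(mat)
    if n == 0:
        return 1
    m = [row[:] for row in mat]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        pivot = m[k][k]
        for i in range(k + 1, n):
            mik = m[i][k]
            row_i = m[i]
            row_k = m[k]
            for j in range(k + 1, n):
                row_i[j] = (row_i[j] * pivot - mik * row_k[j]) // prev
            row_i[k] = 0
        prev = pivot
    return sign * m[n - 1][n - 1]


def _det_poly_at(M0: np.ndarray, M1: np.ndarray, t: Fraction | int):
    """det(M0 + t·M1) with one row and column deleted, exact."""
    m = len(M0)
    if m <= 1:
        return 1
    sub0 = M0[: m - 1, : m - 1]
    sub1 = M1[: m - 1, : m - 1]
    if isinstance(t, Fraction) and t.denominator != 1:
        mat = [
            [Fraction(int(sub0[i, j])) + t * int(sub1[i, j]) for j in range(m - 1)]
            for i in range(m - 1)
        ]
        return _frac_det(mat)
    ti = int(t)
    mat = [
        [int(sub0[i, j]) + ti * int(sub1[i, j]) for j in range(m - 1)]
        for i in range(m - 1)
    ]
    return _int_det_bareiss(mat)


def _frac_det(mat: list[list[Fraction]]) -> Fraction:
    n = len(mat)
    if n == 0:
        return Fraction(1)
    m = [row[:] for row in mat]
    det = Fraction(1)
    for k in range(n):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    det = -det
                    break
            else:
                return Fraction(0)
        det *= m[k][k]
        inv = 1 / m[k][k]
        for i in range(k + 1, n):
            if m[i][k] != 0:
                f = m[i][k] * inv
                m[i] = [m[i][j] - f * m[k][j] for j in range(n)]
    return det


def _valuation_at_zero(M0: np.ndarray, M1: np.ndarray, max_deg: int) -> int:
    """Multiplicity of t = 0 as a root of det(M0 + t·M1) (minor-deleted).

    Found by exact interpolation of the determinant polynomial on
    ``max_deg + 1`` integer nodes (Newton divided differences).
    """
    nodes = []
    k = 0
    while len(nodes) < max_deg + 1:
        nodes.append(k)
        if k > 0:
            nodes.append(-k)
        k += 1
    nodes = nodes[: max_deg + 1]
    values = [Fraction(_det_poly_at(M0, M1, x)) for x in nodes]
    # Newton divided differences -> expand to monomial coefficients
    coeffs_newton = values[:]
    for j in range(1, len(nodes)):
        for i in range(len(nodes) - 1, j - 1, -1):
            coeffs_newton[i] = (coeffs_newton[i] - coeffs_newton[i - 1]) / (
                nodes[i] - nodes[i - j]
            )
    # Horner expansion of the Newton form into monomial coefficients
    poly = [Fraction(0)] * len(nodes)
    for i in range(len(nodes) - 1, -1, -1):
        new = [Fraction(0)] * len(nodes)
        new[0] = coeffs_newton[i]
        for d in range(len(nodes) - 1):
            new[d] += poly[d] * (-nodes[i])
            new[d + 1] += poly[d]
        poly = new
    val = 0
    for c in poly:
        if c != 0:
            break
        val += 1
    if val >= len(poly):
        return -1  # identically zero
    return val


def alexander_invariants(closed: Polyline3D | ReducedPolyline,
                         seed: int = 0) -> InvariantPair:
    """(|Δ(-1)|, |Δ(-2)|) of a closed polyline, over exact integers.

    The curve is projected along a deterministic seeded sequence of
    directions until a generic diagram is found (distinct transversal
    crossings, unambiguous depths); the Alexander matrix determinant is
    evaluated at t = -1 and t = -2 and normalised by the monomial unit
    t^k so the result is independent of the diagram.
    """
    pts = np.asarray(closed.points, dtype=float)
    # cyclic dedup: zero-length segments break the genericity tests
    if len(pts) > 1:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        pts = pts[keep]
        if len(pts) > 1 and np.linalg.norm(pts[-1] - pts[0]) < 1e-12:
            pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("closed curve needs at least 3 points")
    dirs = _projection_directions(seed, _MAX_PROJECTION_RETRIES)
    last_reason = "no directions tried"
    for d in dirs:
        d = d / np.linalg.norm(d)
        # orthonormal frame
        trial = np.array([1.0, 0.0, 0.0])
        if abs(d @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, trial)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        pts2 = pts @ np.vstack([e1, e2]).T
        depth = pts @ d
        crossings = _diagram_crossings(pts2, depth)
        if crossings is None:
            last_reason = "non-generic projection"
            continue
        if len(crossings) == 0:
            return InvariantPair(1, 1)
        M0, M1 = _alexander_matrix(crossings)
        d1 = abs(_det_poly_at(M0, M1, -1))
        d2_raw = abs(_det_poly_at(M0, M1, -2))
        if d1 == 0 or d1 % 2 == 0:
            # a valid knot diagram cannot give an even determinant; the
            # diagram bookkeeping must have hit a degeneracy - retry
            last_reason = f"inconsistent determinant {d1}"
            continue
        if d2_raw == 0:
            last_reason = "zero determinant at t=-2"
            continue
        # strip the monomial unit: det(minor) = ±t^k Δ(t)
        k = 0
        if _det_poly_at(M0, M1, 0) == 0:
            k = _valuation_at_zero(M0, M1, max_deg=len(M0) - 1)
            if k < 0:
                last_reason = "identically zero determinant"
                continue
        d2 = d2_raw // (2 ** k)
        if d2 * (2 ** k) != d2_raw:
            last_reason = "unit normalisation failed"
            continue
        return InvariantPair(int(d1), int(d2))
    raise ProjectionError(
        f"no generic projection in {_MAX_PROJECTION_RETRIES} attempts "
        f"({last_reason})"
    )


def classify_knot(inv: InvariantPair) -> str:
    """Map an invariant pair to a knot label, or ``unresolved(d1,d2)``."""
    label = KNOT_TABLE.get(inv.as_tuple())
    if label is None:
        return f"unresolved({inv.det1},{inv.det2})"
    return label


def knot_type(polyline: Polyline3D | ReducedPolyline,
              config: Optional[ClosureConfig] = None,
              call_threshold: float = 0.5) -> KnotCall:
    """Full pipeline: reduce, close ``n`` times, vote on the invariants.

    The majority invariant pair over closures gives the label; ``support``
    is the majority fraction, and a label below ``call_threshold`` is
    demoted to unresolved.
    """
    if config is None:
        config = ClosureConfig()
    reduced = kmt_reduce(polyline, closed=False)
    if len(reduced) < 3:
        pair = InvariantPair(1, 1)
        return KnotCall(UNKNOT, 1.0, pair, config.n_closures)
    closures = close_chain(reduced, config)
    tally: dict[tuple[int, int], int] = {}
    for i, closure in enumerate(closures):
        tight = kmt_reduce(closure, closed=True)
        curve = tight if len(tight) >= 3 else closure
        try:
            pair = alexander_invariants(curve, seed=config.seed + 7919 * i)
        except ProjectionError:
            pair = alexander_invariants(closure, seed=config.seed + 104729 + i)
        tally[pair.as_tuple()] = tally.get(pair.as_tuple(), 0) + 1
    best_pair, count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
    support = count / len(closures)
    inv = InvariantPair(*best_pair)
    label = classify_knot(inv)
    if support < call_threshold and label != UNKNOT:
        label = f"unresolved({inv.det1},{inv.det2})"
    return KnotCall(label, support, inv, len(closures))
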