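"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: open backbone
curves with zero, one or two deeply knotted trefoil cores (plus slipknots
and unknotted coils), closed parametric reference curves (torus knots and
geometric braid closures), pseudo-PDB files, domain-annotation tables with
planted doubly-entangled architectures among decoys, homology-hit tables,
and gene-locus exemplars for the four co-location classes.

Knotted arcs are built from the (2, q) torus-knot parametrization.  For
p = 2 the planar projection has its crossings at the parameter values
where cos(q t) = 0, so the sub-arc t ∈ [π/6, 11π/6] (for q = 3) is the
smallest arc containing all three crossings: the generated knotted core
interval therefore coincides with the minimal knotted region by
construction, up to a small margin.  Chain termini leave the knot body
strictly below (or above) its z-range before heading outward, so tails
never thread the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .architecture_screen import (
    ArchitectureRecord,
    EntangledDomainRegistry,
    GeneLocus,
    HomologyHit,
    RegistryEntry,
)
from .structure_io import Polyline3D

__all__ = [
    "CurveSpec",
    "PlantedTruth",
    "make_curve",
    "closed_torus_knot",
    "closed_curve_from_braid",
    "BRAID_WORDS",
    "TABLE1_ARCHITECTURES",
    "DEFAULT_REGISTRY",
    "make_annotation_fixture",
    "make_gene_fixture",
]

#: Cα-like spacing of generated backbones, Å
CA_SPACING = 3.8

#: torus-knot base geometry (ring radius, tube amplitude), Å before scaling
RING_RADIUS = 10.0
TUBE_RADIUS = 4.0

#: the five doubly entangled domain architectures used as planting defaults
TABLE1_ARCHITECTURES = (
    "PF00194-PF00194",
    "PF01699-PF01699-PF01699-PF01699",
    "PF00588-PF00588",
    "PF03587-PF03587",
    "PF01746-PF09936",
)

#: a small default registry of entangled domain families (class, minimal
#: knotted-core length in residues, knots contributed per domain copy).
#: PF01699 domains pair up: two copies together form one knot.
DEFAULT_REGISTRY = EntangledDomainRegistry(
    {
        "PF00194": RegistryEntry("knot", 210, 1.0),
        "PF01699": RegistryEntry("knot", 120, 0.5),
        "PF00588": RegistryEntry("knot", 110, 1.0),
        "PF03587": RegistryEntry("knot", 130, 1.0),
        "PF01746": RegistryEntry("knot", 150, 1.0),
        "PF09936": RegistryEntry("knot", 140, 1.0),
    }
)

#: verified braid words for the knot types the engine's lookup table covers
#: (σ_k as +k, σ_k^{-1} as -k); each word's closure was checked against the
#: closed-form Alexander polynomial with an independent reduced-Burau oracle.
BRAID_WORDS: dict[str, tuple[int, ...]] = {
    "3_1": (1, 1, 1),
    "4_1": (1, -2, 1, -2),
    "5_1": (1, 1, 1, 1, 1),
    "5_2": (1, 1, 1, 2, -1, 2),
    "6_1": (1, 1, 2, -1, -3, 2, -3),
    "6_2": (1, 1, 1, -2, 1, -2),
    "6_3": (1, 1, -2, 1, -2, -2),
    "3_1#3_1": (1, 1, 1, 2, 2, 2),
    "3_1#4_1": (1, 1, 1, 2, -3, 2, -3),
}


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic open backbone curve.

    ``kind`` is one of ``unknot``, ``torus`` (with ``q`` ∈ {3, 5} and
    p = 2), ``connected_sum`` (``summand_qs`` torus summands joined by a
    straight spacer), ``slipknot`` or ``random_coil``.  ``n_points``
    counts the knot body (cores, escapes, spacers); tails are extra.
    """

    kind: str
    n_points: int = 80
    noise_sigma: float = 0.2
    tail_n: int = 20
    tail_c: int = 20
    seed: int = 0
    q: int = 3
    summand_qs: tuple[int, ...] = (3, 3)

    def __post_init__(self):
        kinds = ("unknot", "torus", "connected_sum", "slipknot", "random_coil")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "torus":
            if self.q % 2 == 0 or self.q < 3:
                raise ValueError("torus knots here are (2, q) with odd q >= 3")
        if self.kind == "connected_sum":
            for q in self.summand_qs:
                if q % 2 == 0 or q < 3:
                    raise ValueError("summands must be (2, q) torus knots, odd q")
            if self.n_points < 30 * len(self.summand_qs):
                raise ValueError("n_points too small for the number of summands")
        if self.n_points < 30:
            raise ValueError("n_points must be >= 30")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tail_n < 0 or self.tail_c < 0:
            raise ValueError("tail lengths must be >= 0")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth carried alongside a generated object."""

    expected_label: str
    core_intervals: tuple[tuple[int, int], ...] = ()  # 0-based half-open
    arrangement: Optional[str] = None

    def check_consistent(self, n_residues: int) -> None:
        prev_end = -1
        for start, end in self.core_intervals:
            if not (0 <= start < end <= n_residues):
                raise AssertionError("core interval outside chain")
            if start <= prev_end:
                raise AssertionError("core intervals overlap")
            prev_end = end


# ---------------------------------------------------------------------------
# parametric curve machinery
# ---------------------------------------------------------------------------


def _torus_point(t: np.ndarray, q: int, ring: float = RING_RADIUS,
                 tube: float = TUBE_RADIUS) -> np.ndarray:
    """(2, q) torus-knot parametrization, t ∈ [0, 2π) closes the curve."""
    rho = ring + tube * np.cos(q * t)
    return np.column_stack(
        [rho * np.cos(2 * t), rho * np.sin(2 * t), -tube * np.sin(q * t)]
    )


def _resample(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a dense polyline to n points at uniform arclength."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    want = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(want, s, points[:, k]) for k in range(3)])


def _arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def _crossing_bracket(pts: np.ndarray, n_dirs: int = 48) -> Optional[tuple[int, int]]:
    """Median bracket of projected-crossing indices over many directions.

    For each projection direction the entanglement of an open arc spans
    the residues between its outermost diagram crossings; a chain closure
    can stand in for crossings outside the trimmed subchain in roughly
    half of the directions, so the minimal subchain that stays knotted
    under majority closure is bracketed by the *median* (over directions)
    of the outermost-crossing indices.  Pure geometry — no knot engine.
    """
    n = len(pts)
    if n < 4:
        return None
    ii, jj = np.triu_indices(n - 1, k=2)
    lo_list, hi_list = [], []
    for d in _fibonacci_directions(n_dirs):
        trial = np.array([1.0, 0.0, 0.0])
        if abs(d @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, trial)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        p2 = pts @ np.column_stack([e1, e2])
        r = np.diff(p2, axis=0)
        qp = p2[jj] - p2[ii]
        denom = r[ii, 0] * r[jj, 1] - r[ii, 1] * r[jj, 0]
        ok = np.abs(denom) > 1e-12
        s = np.where(ok, qp[:, 0] * r[jj, 1] - qp[:, 1] * r[jj, 0], -1.0)
        u = np.where(ok, qp[:, 0] * r[ii, 1] - qp[:, 1] * r[ii, 0], -1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(ok, s / np.where(ok, denom, 1.0), -1.0)
            u = np.where(ok, u / np.where(ok, denom, 1.0), -1.0)
        hit = ok & (s > 0) & (s < 1) & (u > 0) & (u < 1)
        if not hit.any():
            continue
        lo_list.append(int(ii[hit].min()))
        hi_list.append(int(jj[hit].max()) + 1)
    if not lo_list:
        return None
    return int(np.median(lo_list)), int(np.median(hi_list))


def _open_trefoil_body(q: int = 3, margin: float = 0.10,
                       n_dense: int = 1200):
    """Dense open knotted arc with entry/exit escapes and marked core.

    Returns ``(points, core_start_s, core_end_s)`` where the latter are
    arclength positions bracketing the knotted core (the torus sub-arc
    containing all projected crossings).

    The crossings of the (2, q) projection sit at cos(q t) = 0, i.e.
    t = π/(2q) + k·π/q; the arc spans from the first to the last of them
    plus ``margin`` radians.  The entry terminus dives below the knot
    body before escaping radially; the exit terminus climbs above it.
    """
    t0 = math.pi / (2 * q) - margin
    t1 = 2 * math.pi - math.pi / (2 * q) + margin
    t = np.linspace(t0, t1, n_dense)
    body = _torus_point(t, q)

    def escape(end_point: np.ndarray, below: bool) -> np.ndarray:
        zdir = -1.0 if below else 1.0
        drop = end_point + np.array([0.0, 0.0, zdir * 1.8 * TUBE_RADIUS])
        radial = drop[:2] / max(np.linalg.norm(drop[:2]), 1e-9)
        far = np.concatenate([radial * (RING_RADIUS + 3.2 * TUBE_RADIUS), [drop[2]]])
        n_steps = 6
        path = np.linspace(drop, far, n_steps)
        return np.vstack([drop, path[1:]])

    # z at the entry end is -tube·sin(q t0) ≈ -tube (below ring plane)
    entry_below = -math.sin(q * t0) < 0
    entry = escape(body[0], below=entry_below)[::-1]
    exit_ = escape(body[-1], below=not entry_below)
    pts = np.vstack([entry, body, exit_])
    s = _arclength(pts)
    # arclength span of the knot-bearing arc (escapes excluded); the core
    # interval inside it is located geometrically after resampling
    body_start_s = s[len(entry)]
    body_end_s = s[len(entry) + len(body) - 1]
    return pts, body_start_s, body_end_s


def _gentle_tail(start: np.ndarray, direction: np.ndarray, n: int,
                 spacing: float = CA_SPACING) -> np.ndarray:
    """A gently helical tail of n points leaving ``start`` along ``direction``."""
    if n == 0:
        return np.empty((0, 3))
    d = direction / max(np.linalg.norm(direction), 1e-9)
    trial = np.array([0.0, 0.0, 1.0])
    if abs(d @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    radius = 2.0
    pitch_step = spacing * 0.9
    turn = 0.5  # radians per residue
    k = np.arange(1, n + 1)
    return (
        start
        + np.outer(k * pitch_step, d)
        + np.outer(radius * np.cos(turn * k), e1)
        + np.outer(radius * np.sin(turn * k), e2)
        - radius * e1
    )


def _assemble(body_dense: np.ndarray, knot_spans_s: list[tuple[float, float]],
              spec: CurveSpec, expected_label: str):
    """Scale the dense body to Cα spacing, resample, add tails and noise.

    ``knot_spans_s`` are arclength spans of the knot-bearing arcs in the
    dense body; each planted core interval is then located geometrically
    (median crossing bracket) on the noiseless resampled chain.
    """
    n = spec.n_points
    length = _arclength(body_dense)[-1]
    scale = (n - 1) * CA_SPACING / length
    scaled = body_dense * scale
    pts = _resample(scaled, n)
    s = _arclength(pts)

    def idx_of(arc_pos: float) -> int:
        return int(np.searchsorted(s, arc_pos * scale))

    cores = []
    for a, b in knot_spans_s:
        i0 = idx_of(a)
        i1 = min(idx_of(b) + 1, n)
        bracket = _crossing_bracket(pts[i0:i1])
        if bracket is None:
            raise AssertionError("knot-bearing arc shows no crossings")
        lo, hi = bracket
        cores.append((spec.tail_n + i0 + lo, min(spec.tail_n + i0 + hi, spec.tail_n + n)))

    tail_n = _gentle_tail(pts[0], pts[0] - pts[1], spec.tail_n)[::-1]
    tail_c = _gentle_tail(pts[-1], pts[-1] - pts[-2], spec.tail_c)
    full = np.vstack([tail_n, pts, tail_c])

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        full = full + rng.normal(scale=spec.noise_sigma, size=full.shape)

    truth = PlantedTruth(expected_label, tuple(cores))
    truth.check_consistent(len(full))
    return Polyline3D(full, np.arange(len(full))), truth


def make_curve(spec: CurveSpec) -> tuple[Polyline3D, PlantedTruth]:
    """Generate an open backbone curve and its planted truth."""
    if spec.kind == "unknot":
        # a smooth open arc: half of a large circle, no entanglement
        t = np.linspace(0.0, math.pi, 600)
        body = np.column_stack(
            [RING_RADIUS * 2 * np.cos(t), RING_RADIUS * 2 * np.sin(t), 0.3 * RING_RADIUS * np.sin(2 * t)]
        )
        return _assemble(body, [], spec, "0_1")

    if spec.kind == "random_coil":
        # persistent random walk: stiff enough that spontaneous knotting
        # is negligible at these lengths
        rng = np.random.default_rng(spec.seed + 9173)
        n = spec.n_points
        d = np.array([1.0, 0.0, 0.0])
        pts = [np.zeros(3)]
        for _ in range(n - 1):
            d = d + 0.45 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            pts.append(pts[-1] + CA_SPACING * d)
        return _assemble(np.asarray(pts), [], spec, "0_1")

    if spec.kind == "torus":
        body, a, b = _open_trefoil_body(spec.q)
        label = {3: "3_1", 5: "5_1"}.get(spec.q, f"(2,{spec.q})")
        return _assemble(body, [(a, b)], spec, label)

    if spec.kind == "connected_sum":
        return _make_connected_sum(spec)

    if spec.kind == "slipknot":
        return _make_slipknot(spec)

    raise AssertionError("unreachable")


def _make_connected_sum(spec: CurveSpec):
    """Torus summands side by side, joined by a straight spacer."""
    offset_x = 2 * (RING_RADIUS + 3.2 * TUBE_RADIUS) + 14.0
    pieces = []
    for k, q in enumerate(spec.summand_qs):
        body, a, b = _open_trefoil_body(q)
        # orient: exit toward +x for all but last; entry toward -x for all but first
        exit_ang = math.atan2(body[-1][1], body[-1][0])
        rot = _rot_z(-exit_ang)
        body = body @ rot.T
        entry_ang = math.atan2(body[0][1], body[0][0])
        # a second rotation cannot fix both ends; flip entry side by mirroring
        # across xz-plane when the entry lands on +x side
        if math.cos(entry_ang) > 0.2:
            # mirror across xz to move the entry to the -x side; the
            # determinant invariants are chirality-blind so the planted
            # label is unaffected
            body = body * np.array([1.0, -1.0, 1.0])
        shift = np.array([k * offset_x, 0.0, 0.0])
        pieces.append((body + shift, a, b))

    dense_parts = []
    spans = []
    pos = 0.0
    for k, (body, a, b) in enumerate(pieces):
        if k > 0:
            prev_end = dense_parts[-1][-1]
            gap = np.linalg.norm(body[0] - prev_end)
            n_spacer = max(int(gap / 1.0), 12)
            spacer = np.linspace(prev_end, body[0], n_spacer)[1:-1]
            dense_parts.append(spacer)
            pos += _arclength(np.vstack([prev_end[None], spacer, body[0][None]]))[-1]
        start_s = pos
        dense_parts.append(body)
        seg = _arclength(body)
        spans.append((start_s + a, start_s + b))
        pos = start_s + seg[-1]
    body_dense = np.vstack(dense_parts)
    labels = [{3: "3_1", 5: "5_1"}[q] for q in spec.summand_qs]
    label = "#".join(labels)
    return _assemble(body_dense, spans, spec, label)


def _make_slipknot(spec: CurveSpec):
    """A trefoil whose terminal strand is retracted back out of the loop.

    The forward pass lays a complete trefoil arc; the chain then doubles
    back alongside itself past two of the three crossings, undoing the
    threading: the full chain is unknotted while the forward subchain is
    a trefoil.
    """
    q = 3
    margin = 0.10
    t0 = math.pi / (2 * q) - margin
    t1 = 2 * math.pi - math.pi / (2 * q) + margin
    t_fwd = np.linspace(t0, t1, 900)
    fwd = _torus_point(t_fwd, q)

    # entry escape below the body (as in the open trefoil)
    drop = fwd[0] + np.array([0.0, 0.0, -1.8 * TUBE_RADIUS])
    radial = drop[:2] / np.linalg.norm(drop[:2])
    far = np.concatenate([radial * (RING_RADIUS + 3.2 * TUBE_RADIUS), [drop[2]]])
    entry = np.linspace(far, drop, 6)

    # retrace from t1 back to 4π/3 with a small radial offset: removes the
    # last two crossings from the projection, unknotting the full chain
    t_back = np.linspace(t1, 4 * math.pi / 3, 500)
    back = _torus_point(t_back, q)
    radial_dir = back[:, :2] / np.linalg.norm(back[:, :2], axis=1, keepdims=True)
    back_offset = back.copy()
    back_offset[:, :2] += 1.6 * radial_dir
    back_offset[:, 2] += 0.9

    # exit radially outward from the outer equator (ρ = ring + tube, z ≈ 0)
    end = back_offset[-1]
    out_dir = np.concatenate([end[:2] / np.linalg.norm(end[:2]), [0.15]])
    exit_ = end + np.outer(np.linspace(1.0, 10.0, 6), out_dir)

    body_dense = np.vstack([entry, fwd, back_offset[1:], exit_])
    s = _arclength(body_dense)
    knot_end_s = s[len(entry) + len(fwd) - 1]

    poly, _ = _assemble(body_dense, [], spec, "0_1")
    # knotted subchain: from the chain start through the forward trefoil
    n_body = spec.n_points
    length = s[-1]
    idx_end = spec.tail_n + int(knot_end_s / length * (n_body - 1)) + 1
    truth = PlantedTruth(
        "0_1", core_intervals=((0, min(idx_end, len(poly))),)
    )
    return poly, truth


# ---------------------------------------------------------------------------
# closed reference curves
# ---------------------------------------------------------------------------


def closed_torus_knot(p: int = 2, q: int = 3, n: int = 300,
                      noise_sigma: float = 0.0, seed: int = 0) -> Polyline3D:
    """A closed (p, q) torus knot resampled to n points (p = 2 supported)."""
    if p != 2:
        raise ValueError("only p = 2 torus curves are generated")
    if math.gcd(p, q) != 1:
        raise ValueError("torus knot needs gcd(p, q) = 1")
    t = np.linspace(0.0, 2 * math.pi, 4 * n, endpoint=False)
    pts = _resample(np.vstack([_torus_point(t, q), _torus_point(t[:1], q)]), n + 1)[:-1]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(scale=noise_sigma, size=pts.shape)
    return Polyline3D(pts)


def closed_curve_from_braid(word: Sequence[int], n_strands: Optional[int] = None) -> Polyline3D:
    """Geometric trace closure of a braid word as a closed 3D polyline.

    ``word`` lists Artin generators (±k for σ_k^{±1}).  Crossings are
    realised as over/under bridges at distinct rows; the closing return
    arcs run in layers far below the braid body, so they pass under
    everything and realise the standard trace closure.  The permutation
    must be a single cycle (a knot, not a link).
    """
    word = list(word)
    if not word:
        raise ValueError("empty braid word")
    if n_strands is None:
        n_strands = max(abs(w) for w in word) + 1
    x = 10.0 * np.arange(n_strands)
    row_h = 10.0

    # journeys[j] = list of 3D waypoints for the strand starting in slot j
    journeys = [[np.array([x[j], 0.0, 0.0])] for j in range(n_strands)]
    slot_of = list(range(n_strands))  # journey currently in each slot

    for r, letter in enumerate(word):
        k = abs(letter) - 1
        y0 = r * row_h
        y1 = (r + 1) * row_h
        ja, jb = slot_of[k], slot_of[k + 1]
        # ja moves right (k -> k+1), jb moves left; positive letter: the
        # strand moving right passes over
        za = 3.0 if letter > 0 else -3.0
        mid_y = (y0 + y1) / 2
        journeys[ja].append(np.array([(x[k] + x[k + 1]) / 2, mid_y, za]))
        journeys[ja].append(np.array([x[k + 1], y1, 0.0]))
        journeys[jb].append(np.array([(x[k] + x[k + 1]) / 2, mid_y, -za]))
        journeys[jb].append(np.array([x[k], y1, 0.0]))
        for j in range(n_strands):
            if j not in (k, k + 1):
                journeys[slot_of[j]].append(np.array([x[j], y1, 0.0]))
        slot_of[k], slot_of[k + 1] = jb, ja

    y_top = len(word) * row_h
    # permutation: journey j ends in slot end_slot[j]
    end_slot = [0] * n_strands
    for slot, j in enumerate(slot_of):
        end_slot[j] = slot

    # single-cycle check
    seen, j = set(), 0
    while j not in seen:
        seen.add(j)
        j = end_slot[j]
    if len(seen) != n_strands:
        raise ValueError("braid closure is a link, not a knot")

    points: list[np.ndarray] = []
    j = 0
    for step in range(n_strands):
        points.extend(journeys[j])
        e = end_slot[j]
        depth = -15.0 - 4.0 * step
        points.append(np.array([x[e], y_top + row_h, depth]))
        nxt = e  # trace closure: top of slot e returns to bottom of slot e
        points.append(np.array([x[nxt], -row_h, depth]))
        j = nxt
    arr = np.asarray(points)
    # drop coincident consecutive waypoints (including the cyclic wrap)
    keep = np.ones(len(arr), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-9
    arr = arr[keep]
    if np.linalg.norm(arr[-1] - arr[0]) < 1e-9:
        arr = arr[:-1]
    return Polyline3D(arr)


# ---------------------------------------------------------------------------
# annotation and gene fixtures
# ---------------------------------------------------------------------------


def _layout_domains(arch: str, registry: EntangledDomainRegistry,
                    margin: int, rng) -> tuple[int, list[tuple[str, int, int]]]:
    """Give each domain of an architecture a plausible residue range."""
    fams = arch.split("-")
    domains = []
    pos = 1 + int(rng.integers(1, 15))
    for fam in fams:
        entry = registry.entries.get(fam)
        size = entry.min_core_length + int(rng.integers(10, 40)) if entry else int(rng.integers(60, 200))
        domains.append((fam, pos, pos + size - 1))
        pos += size + int(rng.integers(1, 12))
    length = pos + margin
    return length, domains


def make_annotation_fixture(
    n_decoys: int = 200,
    planted: Sequence[str] = TABLE1_ARCHITECTURES,
    registry: EntangledDomainRegistry = DEFAULT_REGISTRY,
    seed: int = 0,
) -> tuple[list[ArchitectureRecord], list[HomologyHit], PlantedTruth]:
    """Annotation + homology tables with planted candidate architectures.

    Planted proteins have adequate length and a significant knotted
    homology hit.  Decoys fail at least one gate: too few entangled
    domains, inadequate length, an insignificant e-value, or an
    unknotted best homolog.  ``truth.arrangement`` joins the planted
    protein IDs with commas.
    """
    rng = np.random.default_rng(seed)
    records: list[ArchitectureRecord] = []
    hits: list[HomologyHit] = []

    for arch in planted:
        for fam in arch.split("-"):
            if fam not in registry.entries:
                raise ValueError(f"planted family {fam} absent from registry")

    planted_ids = []
    for i, arch in enumerate(planted):
        pid = f"PLANT_{i + 1}"
        planted_ids.append(pid)
        length, domains = _layout_domains(arch, registry, margin=30, rng=rng)
        records.append(ArchitectureRecord(pid, length, domains))
        evalue = 10.0 ** (-float(rng.uniform(7, 30)))
        hits.append(HomologyHit(pid, f"HOM_{i + 1}", evalue, True))

    entangled_fams = [f for f, e in registry.entries.items()
                      if e.entanglement_class in ("knot", "both")]
    for i in range(n_decoys):
        pid = f"DEC_{i + 1:03d}"
        mode = i % 5
        if mode == 0:  # no entangled domains at all
            fam = f"PF{int(rng.integers(20000, 99999)):05d}"
            arch = f"{fam}-{fam}"
            length, domains = _layout_domains(arch, registry, 20, rng)
            records.append(ArchitectureRecord(pid, length, domains))
            hits.append(HomologyHit(pid, f"DH_{i}", 10.0 ** (-float(rng.uniform(4, 20))), True))
        elif mode == 1:  # one entangled domain only
            fam = entangled_fams[int(rng.integers(len(entangled_fams)))]
            length, domains = _layout_domains(fam, registry, 40, rng)
            records.append(ArchitectureRecord(pid, length, domains))
            hits.append(HomologyHit(pid, f"DH_{i}", 10.0 ** (-float(rng.uniform(4, 20))), True))
        elif mode == 2:  # two entangled domains but protein too short
            fam = entangled_fams[int(rng.integers(len(entangled_fams)))]
            entry = registry.entries[fam]
            need = 2 * entry.min_core_length
            length = int(need * rng.uniform(0.45, 0.85))
            half = length // 2
            domains = [(fam, 1, half), (fam, half + 1, length)]
            records.append(ArchitectureRecord(pid, length, domains))
            hits.append(HomologyHit(pid, f"DH_{i}", 10.0 ** (-float(rng.uniform(4, 20))), True))
        elif mode == 3:  # adequate but insignificant e-value
            arch = planted[int(rng.integers(len(planted)))]
            length, domains = _layout_domains(arch, registry, 35, rng)
            records.append(ArchitectureRecord(pid, length, domains))
            hits.append(HomologyHit(pid, f"DH_{i}", float(rng.uniform(1e-3, 10.0)), True))
        else:  # adequate but best homolog unknotted
            arch = planted[int(rng.integers(len(planted)))]
            length, domains = _layout_domains(arch, registry, 35, rng)
            records.append(ArchitectureRecord(pid, length, domains))
            hits.append(HomologyHit(pid, f"DH_{i}", 10.0 ** (-float(rng.uniform(4, 20))), False))

    truth = PlantedTruth("candidates", arrangement=",".join(planted_ids))
    return records, hits, truth


def make_gene_fixture() -> list[tuple[GeneLocus, GeneLocus, str]]:
    """The four gene co-location exemplars: separated, adjacent (11 nt),
    overlapping (7 nt) and a single fused ORF."""
    fixtures = []
    a = GeneLocus("trmD_separated", 1000, 1750, "+")
    b = GeneLocus("tm1570_separated", 5751, 6400, "+")
    fixtures.append((a, b, "separated"))  # gap of 4,000 nt

    a = GeneLocus("trmD_adjacent", 1000, 1750, "+")
    b = GeneLocus("tm1570_adjacent", 1762, 2400, "+")
    fixtures.append((a, b, "adjacent"))  # 11 nt apart

    a = GeneLocus("trmD_overlap", 1000, 1750, "+")
    b = GeneLocus("tm1570_overlap", 1744, 2400, "+")
    fixtures.append((a, b, "overlapping"))  # overlapping by 7 nt

    fused = GeneLocus("trmD_tm1570_fusion", 1000, 2400, "+")
    fixtures.append((fused, fused, "fused"))
    return fixtures
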