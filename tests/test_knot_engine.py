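"""Knot engine: reduction, closure, invariants, classification."""

import numpy as np
import pytest

from compknot.knot_engine import (
    ClosureConfig,
    InvariantPair,
    alexander_invariants,
    classify_knot,
    close_chain,
    kmt_reduce,
    knot_type,
)
from compknot.structure_io import Polyline3D
from compknot.synthetic_data import (
    BRAID_WORDS,
    closed_curve_from_braid,
    closed_torus_knot,
)
from conftest import random_rotation
from oracles import burau_determinants


def planar_circle(n=50, r=10.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polyline3D(np.column_stack([r * np.cos(th), r * np.sin(th), 0 * th]))


class TestAlexanderInvariants:
    def test_unknot_circle(self):
        assert alexander_invariants(planar_circle()).as_tuple() == (1, 1)

    @pytest.mark.parametrize("q,expected", [(3, (3, 7)), (5, (5, 31))])
    def test_torus_knots(self, q, expected):
        curve = closed_torus_knot(2, q, n=300)
        assert alexander_invariants(curve).as_tuple() == expected

    @pytest.mark.parametrize("name", sorted(BRAID_WORDS))
    def test_braid_closures_match_burau_oracle(self, name):
        """Geometric invariants equal the algebraic reduced-Burau values."""
        word = BRAID_WORDS[name]
        curve = closed_curve_from_braid(word)
        reduced = kmt_reduce(curve, closed=True)
        got = alexander_invariants(reduced.as_polyline()).as_tuple()
        assert got == burau_determinants(word)

    def test_composite_is_product_of_factors(self):
        """Determinants multiply under connected sum: 3_1 # 4_1."""
        d1_3, d2_3 = burau_determinants(BRAID_WORDS["3_1"])
        d1_4, d2_4 = burau_determinants(BRAID_WORDS["4_1"])
        curve = closed_curve_from_braid(BRAID_WORDS["3_1#4_1"])
        got = alexander_invariants(kmt_reduce(curve, closed=True).as_polyline())
        assert got.as_tuple() == (d1_3 * d1_4, d2_3 * d2_4) == (15, 77)

    def test_rigid_motion_invariance(self):
        curve = closed_torus_knot(2, 3, n=200)
        rng = np.random.default_rng(7)
        base = alexander_invariants(curve).as_tuple()
        for _ in range(5):
            rot = random_rotation(rng)
            moved = Polyline3D(curve.points @ rot.T + rng.normal(size=3) * 40)
            assert alexander_invariants(moved).as_tuple() == base

    def test_mirror_invariance(self):
        for name in ("3_1", "5_2", "3_1#3_1"):
            curve = closed_curve_from_braid(BRAID_WORDS[name])
            mirrored = Polyline3D(curve.points * np.array([1.0, 1.0, -1.0]))
            assert (alexander_invariants(mirrored).as_tuple()
                    == alexander_invariants(curve).as_tuple())

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            alexander_invariants(Polyline3D(np.zeros((2, 3)) + np.arange(2)[:, None]))

    def test_invariant_pair_validation(self):
        with pytest.raises(ValueError):
            InvariantPair(4, 7)  # |Δ(-1)| is always odd
        with pytest.raises(ValueError):
            InvariantPair(0, 1)


class TestClassifyKnot:
    @pytest.mark.parametrize("pair,label", [
        ((1, 1), "0_1"), ((3, 7), "3_1"), ((5, 11), "4_1"), ((5, 31), "5_1"),
        ((7, 16), "5_2"), ((9, 20), "6_1"), ((9, 49), "3_1#3_1"),
    ])
    def test_lookup(self, pair, label):
        assert classify_knot(InvariantPair(*pair)) == label

    def test_det1_alone_cannot_separate_6_1_from_double_trefoil(self):
        """(9, 20) and (9, 49) share det1; the pair disambiguates."""
        assert classify_knot(InvariantPair(9, 20)) == "6_1"
        assert classify_knot(InvariantPair(9, 49)) == "3_1#3_1"

    def test_unknown_pair_is_unresolved(self):
        assert classify_knot(InvariantPair(17, 100)) == "unresolved(17,100)"


class TestKmtReduce:
    def test_straight_open_segment_collapses(self):
        pts = np.column_stack([np.linspace(0, 100, 50),
                               np.zeros(50), np.zeros(50)])
        red = kmt_reduce(Polyline3D(pts))
        assert len(red) == 2
        assert red.provenance == 50

    def test_noisy_circle_reduces_to_few_points(self):
        rng = np.random.default_rng(3)
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([30 * np.cos(th), 30 * np.sin(th), np.zeros(200)])
        pts += rng.normal(scale=0.4, size=pts.shape)
        red = kmt_reduce(Polyline3D(pts), closed=True)
        assert len(red) <= 10
        assert alexander_invariants(red.as_polyline()).as_tuple() == (1, 1)

    def test_monotone_and_invariant_on_noisy_trefoils(self):
        """Reduction shrinks the chain and never changes the knot."""
        for seed in range(10):
            curve = closed_torus_knot(2, 3, n=150, noise_sigma=0.3, seed=seed)
            red = kmt_reduce(curve, closed=True)
            assert len(red) <= len(curve)
            assert alexander_invariants(red.as_polyline()).as_tuple() == (3, 7)

    def test_open_endpoints_preserved(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 3
        red = kmt_reduce(Polyline3D(pts))
        np.testing.assert_array_equal(red.points[0], pts[0])
        np.testing.assert_array_equal(red.points[-1], pts[-1])

    def test_duplicate_points_cleaned(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0],
                        [3, 1, 0], [4, 0, 0]], dtype=float)
        red = kmt_reduce(Polyline3D(pts))
        assert len(red) >= 2


class TestCloseChain:
    def test_direct_single_closure(self, deep_trefoil, direct_cfg):
        poly, _ = deep_trefoil
        out = close_chain(poly, direct_cfg)
        assert len(out) == 1
        assert len(out[0]) == len(poly)

    def test_seeded_closures_are_bitwise_identical(self, deep_trefoil):
        poly, _ = deep_trefoil
        cfg = ClosureConfig(seed=7, n_closures=100)
        a = close_chain(poly, cfg)
        b = close_chain(poly, cfg)
        assert len(a) == len(b) == 100
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.points, y.points)

    def test_deep_trefoil_closure_insensitive(self, deep_trefoil):
        """>= 90 of 100 random closures of a deep trefoil give det1 = 3."""
        poly, _ = deep_trefoil
        reduced = kmt_reduce(poly)
        hits = 0
        for i, closure in enumerate(close_chain(reduced, ClosureConfig(seed=7))):
            inv = alexander_invariants(kmt_reduce(closure, closed=True).as_polyline(),
                                       seed=i)
            hits += inv.det1 == 3
        assert hits >= 90

    def test_strategy_validation(self):
        with pytest.raises(ValueError):
            ClosureConfig(strategy="banana")
        assert ClosureConfig(strategy="direct", n_closures=50).n_closures == 1


class TestKnotType:
    def test_closed_trefoil_direct(self, direct_cfg):
        call = knot_type(closed_torus_knot(2, 3, n=200), direct_cfg)
        assert call.label == "3_1"
        assert call.support == 1.0

    def test_open_composite_chain(self, double_trefoil, closure_cfg):
        poly, truth = double_trefoil
        call = knot_type(poly, closure_cfg)
        assert call.label == "3_1#3_1" == truth.expected_label
        assert call.support >= 0.9
        assert call.invariants.as_tuple() == (9, 49)

    def test_near_straight_coil_is_unknotted(self, closure_cfg):
        rng = np.random.default_rng(1)
        pts = np.column_stack([np.linspace(0, 110, 30), np.zeros(30), np.zeros(30)])
        pts += rng.normal(scale=0.5, size=pts.shape)
        call = knot_type(Polyline3D(pts), closure_cfg)
        assert call.label == "0_1"

    def test_determinism_under_fixed_seed(self, deep_trefoil):
        poly, _ = deep_trefoil
        cfg = ClosureConfig(seed=42, n_closures=50)
        a = knot_type(poly, cfg)
        b = knot_type(poly, cfg)
        assert a == b

    def test_low_support_demoted_to_unresolved(self, deep_trefoil):
        poly, _ = deep_trefoil
        call = knot_type(poly, ClosureConfig(seed=3, n_closures=100),
                         call_threshold=1.01)
        assert call.label.startswith("unresolved") or call.label == "0_1"
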