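"""Core localization, composite and slipknot calls, domain classification."""

import numpy as np
import pytest

from compknot.knot_engine import ClosureConfig, InvariantPair, KnotCall, knot_type
from compknot.structure_io import Polyline3D
from compknot.synthetic_data import CurveSpec, make_curve
from compknot.topology_scan import (
    KnottedCore,
    TopologyReport,
    analyze_topology,
    classify_domain_entanglement,
    fingerprint,
    locate_cores,
    min_core_length,
)


def make_report(core_lengths=(), slipknotted=False, label="3_1"):
    """Handmade TopologyReport for the aggregation operations."""
    cores = tuple(
        KnottedCore(10 * (i + 1), 10 * (i + 1) + ln, label, 0.95,
                    10 * (i + 1), 40, InvariantPair(3, 7))
        for i, ln in enumerate(core_lengths)
    )
    call = (KnotCall(label, 0.95, InvariantPair(3, 7), 100)
            if cores and not slipknotted
            else KnotCall("0_1", 0.95, InvariantPair(1, 1), 100))
    return TopologyReport("A", call, cores, slipknotted, False)


class TestFingerprint:
    def test_unknotted_coil_all_entries_trivial(self):
        poly, _ = make_curve(CurveSpec("unknot", n_points=60, tail_n=0, tail_c=0, seed=2))
        fp = fingerprint(poly, ClosureConfig(seed=3), stride=10, n_closures=5)
        assert all(call.label == "0_1" for call in fp.entries.values())
        assert (0, len(poly)) in fp.entries

    def test_entries_cover_core_when_knotted(self, deep_trefoil):
        poly, truth = deep_trefoil
        (cs, ce), = truth.core_intervals
        fp = fingerprint(poly, ClosureConfig(seed=3), stride=10, n_closures=10)
        containing = [iv for iv in fp.knotted_intervals()
                      if iv[0] <= cs and iv[1] >= ce]
        assert containing, "no knotted entry contains the planted core"
        excluded = fp.entries.get((0, 30))
        if excluded is not None:
            assert excluded.label == "0_1"

    def test_stride_too_large_rejected(self, deep_trefoil):
        poly, _ = deep_trefoil
        with pytest.raises(ValueError):
            fingerprint(poly, ClosureConfig(seed=1), stride=len(poly))

    def test_deterministic_under_seed(self, deep_trefoil):
        poly, _ = deep_trefoil
        cfg = ClosureConfig(seed=9)
        a = fingerprint(poly, cfg, stride=20, n_closures=5)
        b = fingerprint(poly, cfg, stride=20, n_closures=5)
        assert a.entries == b.entries


class TestLocateCores:
    def test_unknot_gives_no_cores(self):
        poly, _ = make_curve(CurveSpec("unknot", n_points=60, seed=4))
        cfg = ClosureConfig(seed=5)
        fp = fingerprint(poly, cfg, stride=10, n_closures=5)
        assert locate_cores(fp, poly, cfg) == []

    def test_single_planted_core_recovered(self, deep_trefoil):
        poly, truth = deep_trefoil
        cfg = ClosureConfig(seed=6)
        fp = fingerprint(poly, cfg, stride=5, n_closures=10)
        cores = locate_cores(fp, poly, cfg)
        assert len(cores) == 1
        (ps, pe), = truth.core_intervals
        assert abs(cores[0].start - ps) <= 5
        assert abs(cores[0].end - pe) <= 5
        assert cores[0].label == "3_1"

    def test_double_planted_cores_disjoint(self, double_trefoil):
        poly, truth = double_trefoil
        cfg = ClosureConfig(seed=6)
        fp = fingerprint(poly, cfg, stride=8, n_closures=10)
        cores = locate_cores(fp, poly, cfg)
        assert len(cores) == 2
        assert cores[0].end <= cores[1].start
        for core, (ps, pe) in zip(cores, truth.core_intervals):
            assert abs(core.start - ps) <= 5
            assert abs(core.end - pe) <= 5
            assert core.label == "3_1"

    def test_core_minimality(self, deep_trefoil):
        """Trimming a few residues off either end loses the knot."""
        poly, _ = deep_trefoil
        cfg = ClosureConfig(seed=6)
        fp = fingerprint(poly, cfg, stride=5, n_closures=10)
        core, = locate_cores(fp, poly, cfg)
        tol = 3
        left = knot_type(poly.subchain(core.start + tol, core.end),
                         ClosureConfig(seed=77))
        right = knot_type(poly.subchain(core.start, core.end - tol),
                          ClosureConfig(seed=78))
        assert not left.is_knotted or left.support < 0.7
        assert not right.is_knotted or right.support < 0.7


class TestAnalyzeTopology:
    def test_composite_chain(self, double_trefoil):
        poly, _ = double_trefoil
        rep = analyze_topology(poly, ClosureConfig(seed=8))
        assert rep.global_call.label == "3_1#3_1"
        assert rep.composite
        assert not rep.slipknotted
        assert len(rep.cores) == 2
        prod = rep.cores[0].invariants.det1 * rep.cores[1].invariants.det1
        assert prod == rep.global_call.invariants.det1 == 9

    def test_single_trefoil_not_composite(self, deep_trefoil):
        rep = analyze_topology(deep_trefoil[0], ClosureConfig(seed=8))
        assert rep.global_call.label == "3_1"
        assert not rep.composite
        assert not rep.slipknotted
        assert len(rep.cores) == 1

    def test_slipknot_flagged(self, slipknot_chain):
        poly, truth = slipknot_chain
        rep = analyze_topology(poly, ClosureConfig(seed=8))
        assert rep.global_call.label == "0_1"
        assert rep.slipknotted
        assert not rep.composite
        # the knotted subchain lies within the planted forward pass
        (_, ke), = truth.core_intervals
        assert rep.cores and rep.cores[0].end <= ke + 5

    def test_depths_are_tail_lengths(self, deep_trefoil):
        poly, _ = deep_trefoil
        rep = analyze_topology(poly, ClosureConfig(seed=8))
        core, = rep.cores
        assert core.depth_n == core.start
        assert core.depth_c == len(poly) - core.end

    def test_report_serializes(self, deep_trefoil):
        rep = analyze_topology(deep_trefoil[0], ClosureConfig(seed=8))
        d = rep.to_dict()
        assert d["global"]["label"] == "3_1"
        assert d["cores"][0]["interval"][0] == rep.cores[0].start + 1


class TestAggregation:
    def test_min_core_length(self):
        reports = [make_report((62,)), make_report((70,)), make_report((58,))]
        assert min_core_length(reports) == 58

    def test_min_core_length_single(self):
        assert min_core_length([make_report((45,))]) == 45

    def test_min_core_length_requires_cores(self):
        with pytest.raises(ValueError, match="not entangled"):
            min_core_length([make_report(()), make_report(())])

    @pytest.mark.parametrize("reports,expected", [
        ([make_report((60,))] * 3, "knot"),
        ([make_report((60,)), make_report((58,)),
          make_report((55,), slipknotted=True)], "both"),
        ([make_report((50,), slipknotted=True)], "slipknot"),
        ([make_report(()), make_report(())], "none"),
    ])
    def test_classify_domain_entanglement(self, reports, expected):
        assert classify_domain_entanglement(reports) == expected

    def test_classify_needs_reports(self):
        with pytest.raises(ValueError):
            classify_domain_entanglement([])
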