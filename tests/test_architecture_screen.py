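"""Architecture candidate screen, homology gate, gene arrangements."""

import pytest
from hypothesis import given, settings, strategies as st

from compknot.architecture_screen import (
    ArchitectureRecord,
    EntangledDomainRegistry,
    GeneLocus,
    HomologyHit,
    RegistryEntry,
    build_registry,
    classify_gene_arrangement,
    homology_gate,
    read_annotation_table,
    read_homology_table,
    screen,
    summarize_architectures,
)
from test_topology_scan import make_report

REGISTRY = EntangledDomainRegistry({
    "PF00194": RegistryEntry("knot", 200, 1.0),
    "PF01699": RegistryEntry("knot", 120, 0.5),
    "PF01746": RegistryEntry("knot", 150, 1.0),
    "PF09936": RegistryEntry("knot", 140, 1.0),
    "PFSLIP": RegistryEntry("slipknot", 80, 1.0),
})


def rec(pid, length, fams_and_sizes):
    domains, pos = [], 5
    for fam, size in fams_and_sizes:
        domains.append((fam, pos, pos + size - 1))
        pos += size + 2
    return ArchitectureRecord(pid, length, domains)


class TestScreen:
    def test_tandem_knotted_domains_pass(self):
        r = rec("P1", 500, [("PF00194", 236), ("PF00194", 236)])
        rep, = screen([r], REGISTRY)
        assert rep.verdict == "candidate"
        assert rep.architecture_string == "PF00194-PF00194"
        assert rep.n_entangled_domains == 2

    def test_single_entangled_domain_rejected(self):
        r = rec("P2", 400, [("PF00194", 236), ("PFX0001", 100)])
        rep, = screen([r], REGISTRY)
        assert rep.verdict == "rejected(n_entangled<2)"

    def test_too_short_rejected(self):
        r = rec("P3", 350, [("PF00194", 170), ("PF00194", 170)])
        rep, = screen([r], REGISTRY)
        assert rep.verdict == "rejected(too_short)"
        assert not rep.passed_length

    def test_paired_domain_rule(self):
        """Four half-knot domains reach the two-knot requirement; two do not."""
        four = rec("P4", 520, [("PF01699", 125)] * 4)
        two = rec("P5", 260, [("PF01699", 125)] * 2)
        rep4, rep5 = screen([four, two], REGISTRY)
        assert rep4.verdict == "candidate"
        assert rep4.architecture_string == "PF01699-PF01699-PF01699-PF01699"
        assert rep4.expected_knots == pytest.approx(2.0)
        assert rep5.verdict == "rejected(n_entangled<2)"

    def test_mixed_fusion_architecture(self):
        r = rec("P6", 440, [("PF01746", 210), ("PF09936", 200)])
        rep, = screen([r], REGISTRY)
        assert rep.verdict == "candidate"
        assert rep.architecture_string == "PF01746-PF09936"

    def test_slipknot_class_does_not_count(self):
        r = rec("P7", 500, [("PFSLIP", 120), ("PFSLIP", 120)])
        rep, = screen([r], REGISTRY)
        assert rep.verdict == "rejected(n_entangled<2)"

    def test_invalid_record_isolated(self):
        bad = ArchitectureRecord("BAD", 100, [("PF00194", 1, 300)])
        good = rec("P1", 500, [("PF00194", 236), ("PF00194", 236)])
        reports = screen([bad, good], REGISTRY)
        assert reports[0].verdict == "rejected(invalid_record)"
        assert reports[1].verdict == "candidate"

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            screen([], EntangledDomainRegistry({}))

    def test_report_completeness(self):
        records = [rec(f"P{i}", 300 + 50 * i, [("PF00194", 100 + 40 * i)])
                   for i in range(8)]
        reports = screen(records, REGISTRY)
        assert [r.protein_id for r in reports] == [r.protein_id for r in records]

    @given(extra=st.integers(min_value=0, max_value=300))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_raising_min_core_length_never_adds_candidates(self, extra):
        base = REGISTRY
        stricter = EntangledDomainRegistry({
            fam: RegistryEntry(e.entanglement_class, e.min_core_length + extra,
                               e.knots_per_domain)
            for fam, e in base.entries.items()
        })
        records = [
            rec("A", 500, [("PF00194", 236), ("PF00194", 236)]),
            rec("B", 440, [("PF01746", 210), ("PF09936", 200)]),
            rec("C", 520, [("PF01699", 125)] * 4),
        ]
        loose = {r.protein_id for r in screen(records, base) if r.is_candidate}
        tight = {r.protein_id for r in screen(records, stricter) if r.is_candidate}
        assert tight <= loose


class TestHomologyGate:
    def _candidate(self):
        return screen([rec("P1", 500, [("PF00194", 236), ("PF00194", 236)])],
                      REGISTRY)

    def test_significant_knotted_hit_kept(self):
        out, = homology_gate(self._candidate(),
                             [HomologyHit("P1", "H", 1e-7, True)])
        assert out.is_candidate and out.passed_homology is True

    def test_insignificant_hit_rejected(self):
        out, = homology_gate(self._candidate(),
                             [HomologyHit("P1", "H", 0.01, True)])
        assert out.verdict == "rejected(homology)"

    def test_boundary_evalue_is_strict(self):
        """e-value exactly 10^-3 fails the strict < comparison."""
        out, = homology_gate(self._candidate(),
                             [HomologyHit("P1", "H", 1e-3, True)])
        assert out.verdict == "rejected(homology)"

    def test_unknotted_best_hit_rejected(self):
        out, = homology_gate(self._candidate(), [
            HomologyHit("P1", "H1", 1e-20, False),
            HomologyHit("P1", "H2", 1e-5, True),
        ])
        assert out.verdict == "rejected(homology)"

    def test_no_hits_flagged_not_dropped(self):
        out, = homology_gate(self._candidate(), [])
        assert out.is_candidate and out.passed_homology is None

    @given(thr=st.floats(min_value=1e-10, max_value=1e-3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_lowering_threshold_never_adds_candidates(self, thr):
        hits = [HomologyHit("P1", "H", 5e-5, True)]
        base = {r.protein_id for r in homology_gate(self._candidate(), hits, 1e-3)
                if r.is_candidate and r.passed_homology}
        low = {r.protein_id for r in homology_gate(self._candidate(), hits, thr)
               if r.is_candidate and r.passed_homology}
        assert low <= base


class TestGeneArrangement:
    def test_fig_exemplars(self):
        a = GeneLocus("trmD", 1000, 1750)
        assert classify_gene_arrangement(
            a, GeneLocus("tm1570", 5751, 6400)) == "separated"  # 4,000 nt gap
        assert classify_gene_arrangement(
            a, GeneLocus("tm1570", 1762, 2400)) == "adjacent"  # 11 nt apart
        assert classify_gene_arrangement(
            a, GeneLocus("tm1570", 1744, 2400)) == "overlapping"  # 7 nt overlap
        assert classify_gene_arrangement(a, a) == "fused"

    def test_explicit_fusion_flag(self):
        a = GeneLocus("g1", 10, 100)
        b = GeneLocus("g2", 200, 300)
        assert classify_gene_arrangement(a, b, fused=True) == "fused"

    def test_adjacency_cutoff_configurable(self):
        a = GeneLocus("g1", 10, 100)
        b = GeneLocus("g2", 161, 300)  # 60 nt gap
        assert classify_gene_arrangement(a, b) == "separated"
        assert classify_gene_arrangement(a, b, adjacency_max_gap=60) == "adjacent"

    def test_order_independence(self):
        a = GeneLocus("g1", 10, 100)
        b = GeneLocus("g2", 130, 300)
        assert (classify_gene_arrangement(a, b)
                == classify_gene_arrangement(b, a))

    def test_locus_validation(self):
        with pytest.raises(ValueError):
            GeneLocus("bad", 100, 10)


class TestBuildRegistry:
    def test_knotted_family(self):
        reg = build_registry({"PF_A": [make_report((60,)), make_report((58,))]})
        assert reg.entries["PF_A"].entanglement_class == "knot"
        assert reg.entries["PF_A"].min_core_length == 58

    def test_slipknot_family(self):
        reg = build_registry(
            {"PF_S": [make_report((50,), slipknotted=True)]})
        assert reg.entries["PF_S"].entanglement_class == "slipknot"
        assert reg.entries["PF_S"].min_core_length == 50

    def test_unentangled_family_omitted(self):
        reg = build_registry({
            "PF_A": [make_report((60,))],
            "PF_N": [make_report(()), make_report(())],
        })
        assert "PF_N" not in reg.entries

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_registry({})


class TestTabularIO:
    def test_annotation_and_hit_round_trip(self, tmp_path):
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "protein_id\tlength\tdomain_id\tstart\tend\n"
            "P1\t500\tPF00194\t5\t240\n"
            "P1\t500\tPF00194\t260\t495\n"
            "P2\t200\tPF09936\t10\t180\n"
        )
        records = read_annotation_table(ann)
        assert len(records) == 2
        assert records[0].architecture_string == "PF00194-PF00194"

        hits_path = tmp_path / "hits.tsv"
        hits_path.write_text(
            "query_id\tsubject_id\tevalue\tknotted\n"
            "P1\tH1\t1e-08\t1\n"
        )
        hits = read_homology_table(hits_path)
        assert hits[0].subject_knotted is True

    def test_summary_table_format(self):
        reports = homology_gate(
            screen([rec("P1", 500, [("PF00194", 236), ("PF00194", 236)])],
                   REGISTRY),
            [HomologyHit("P1", "H", 1e-9, True)],
        )
        df = summarize_architectures(reports, {"PF00194-PF00194": "3_1#3_1"})
        assert list(df.columns) == ["architecture", "n_proteins",
                                    "example_protein", "knot_type"]
        assert df.iloc[0]["knot_type"] == "3_1#3_1"
        assert df.iloc[0]["n_proteins"] == 1
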