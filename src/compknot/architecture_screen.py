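"""Candidate screen for doubly entangled domain architectures.

Given a registry of domain families known to carry a knot (or slipknot)
and a table of protein domain architectures, the screen keeps proteins
whose architecture can host at least two knots and which are long enough
for two minimal knotted cores; a homology gate then keeps candidates
whose best homolog is significant (e-value < 10⁻³, strict) and knotted.
A separate operation classifies how two gene loci are co-located on a
genome (separated / adjacent / overlapping / fused).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "RegistryEntry",
    "EntangledDomainRegistry",
    "ArchitectureRecord",
    "HomologyHit",
    "CandidateReport",
    "GeneLocus",
    "screen",
    "homology_gate",
    "classify_gene_arrangement",
    "build_registry",
    "read_annotation_table",
    "read_homology_table",
    "write_candidate_reports",
    "summarize_architectures",
    "EVALUE_THRESHOLD",
    "ADJACENCY_MAX_GAP",
]

#: strict e-value significance threshold for the homology gate
EVALUE_THRESHOLD = 1e-3

#: genes at most this many nucleotides apart count as adjacent
ADJACENCY_MAX_GAP = 50


@dataclass(frozen=True)
class RegistryEntry:
    """How a domain family contributes to entanglement.

    ``knots_per_domain`` is 1.0 for a self-contained knotted domain and
    0.5 for families whose domains pair up, two copies forming one knot.
    """

    entanglement_class: str  # knot | slipknot | both
    min_core_length: int
    knots_per_domain: float = 1.0

    def __post_init__(self):
        if self.entanglement_class not in ("knot", "slipknot", "both"):
            raise ValueError(f"bad entanglement class {self.entanglement_class!r}")
        if self.min_core_length < 1:
            raise ValueError("min_core_length must be >= 1")
        if not (0 < self.knots_per_domain <= 1):
            raise ValueError("knots_per_domain must be in (0, 1]")


@dataclass(frozen=True)
class EntangledDomainRegistry:
    """Map from domain family ID (e.g. PF00194) to its entanglement entry."""

    entries: dict[str, RegistryEntry]

    def __post_init__(self):
        if not isinstance(self.entries, dict):
            raise TypeError("entries must be a dict")


@dataclass(frozen=True)
class ArchitectureRecord:
    """A protein's ordered domain composition (1-based inclusive ranges)."""

    protein_id: str
    length: int
    domains: Sequence[tuple[str, int, int]]

    def validate(self) -> None:
        prev_start = 0
        for fam, start, end in self.domains:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"{self.protein_id}: domain {fam} range [{start}, {end}] "
                    f"outside protein length {self.length}"
                )
            if start < prev_start:
                raise ValueError(f"{self.protein_id}: domains not ordered by start")
            prev_start = start

    @property
    def architecture_string(self) -> str:
        return "-".join(fam for fam, _, _ in self.domains)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    evalue: float
    subject_knotted: bool

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class CandidateReport:
    """Per-protein screening verdict with the reasons for any rejection."""

    protein_id: str
    architecture_string: str
    n_entangled_domains: int
    expected_knots: float
    passed_length: bool
    passed_homology: Optional[bool]  # None = no hits, flagged unknown
    verdict: str  # "candidate" or "rejected(<reason>)"

    @property
    def is_candidate(self) -> bool:
        return self.verdict == "candidate"


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic interval, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def screen(records: Iterable[ArchitectureRecord],
           registry: EntangledDomainRegistry) -> list[CandidateReport]:
    """Keep proteins whose architecture can carry at least two knots.

    A record passes when (a) the expected knot count of its registry
    domains of class knot/both reaches 2 (domains of paired families
    count ``knots_per_domain`` each), and (b) the protein is at least as
    long as the summed minimal knotted-core length those knots require.
    Every rejection carries its reason; invalid records are reported, not
    fatal.
    """
    if not registry.entries:
        raise ValueError("registry is empty")
    reports = []
    for rec in records:
        try:
            rec.validate()
        except ValueError:
            reports.append(CandidateReport(
                rec.protein_id, rec.architecture_string, 0, 0.0,
                False, None, "rejected(invalid_record)",
            ))
            continue
        qualifying = [
            (fam, registry.entries[fam])
            for fam, _, _ in rec.domains
            if fam in registry.entries
            and registry.entries[fam].entanglement_class in ("knot", "both")
        ]
        n_entangled = len(qualifying)
        expected = sum(e.knots_per_domain for _, e in qualifying)
        required_length = int(math.ceil(
            sum(e.min_core_length * e.knots_per_domain for _, e in qualifying)
        ))
        passed_length = rec.length >= required_length
        if expected < 2 or n_entangled < 2:
            verdict = "rejected(n_entangled<2)"
        elif not passed_length:
            verdict = "rejected(too_short)"
        else:
            verdict = "candidate"
        reports.append(CandidateReport(
            rec.protein_id, rec.architecture_string, n_entangled,
            float(expected), passed_length, None, verdict,
        ))
    return reports


def homology_gate(candidates: Iterable[CandidateReport],
                  hits: Iterable[HomologyHit],
                  threshold: float = EVALUE_THRESHOLD) -> list[CandidateReport]:
    """Keep candidates whose best homolog is significant and knotted.

    The comparison is strict (e-value < threshold).  A candidate without
    any hit is kept but flagged ``passed_homology = None`` rather than
    silently dropped: the gate prioritises modelling, it does not
    disprove a knot.  Non-candidate reports pass through unchanged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    by_query: dict[str, HomologyHit] = {}
    for h in hits:
        best = by_query.get(h.query_id)
        if best is None or h.evalue < best.evalue:
            by_query[h.query_id] = h
    out = []
    for cand in candidates:
        if not cand.is_candidate:
            out.append(cand)
            continue
        best = by_query.get(cand.protein_id)
        if best is None:
            out.append(replace(cand, passed_homology=None))
        elif best.evalue < threshold and best.subject_knotted:
            out.append(replace(cand, passed_homology=True))
        else:
            out.append(replace(
                cand, passed_homology=False, verdict="rejected(homology)"
            ))
    return out


def classify_gene_arrangement(a: GeneLocus, b: GeneLocus,
                              adjacency_max_gap: int = ADJACENCY_MAX_GAP,
                              fused: bool = False) -> str:
    """Classify how two gene loci are co-located on a genome.

    ``fused`` when both loci denote the same ORF (same gene ID, or the
    explicit flag); ``overlapping`` when the intervals intersect;
    ``adjacent`` when the gap between nearest ends is at most
    ``adjacency_max_gap`` nucleotides; ``separated`` otherwise.
    """
    if adjacency_max_gap < 0:
        raise ValueError("adjacency_max_gap must be >= 0")
    if fused or a.gene_id == b.gene_id:
        return "fused"
    if a.start <= b.end and b.start <= a.end:
        return "overlapping"
    left, right = (a, b) if a.end < b.start else (b, a)
    gap = right.start - left.end - 1
    return "adjacent" if gap <= adjacency_max_gap else "separated"


def build_registry(domain_instances: dict) -> EntangledDomainRegistry:
    """Derive a registry from per-family topology reports.

    Each family's entanglement class comes from
    :func:`compknot.topology_scan.classify_domain_entanglement` over its
    reports, and its minimal core length from
    :func:`compknot.topology_scan.min_core_length`; families with no
    entanglement are omitted.
    """
    from .topology_scan import classify_domain_entanglement, min_core_length

    if not domain_instances:
        raise ValueError("no domain instances supplied")
    entries = {}
    for fam, reports in domain_instances.items():
        if not reports:
            raise ValueError(f"family {fam}: no reports")
        cls = classify_domain_entanglement(reports)
        if cls == "none":
            continue
        entries[fam] = RegistryEntry(cls, min_core_length(reports))
    return EntangledDomainRegistry(entries)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_annotation_table(path) -> list[ArchitectureRecord]:
    """TSV with columns protein_id, length, domain_id, start, end
    (one row per domain instance, rows of one protein contiguous)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("start")
        records.append(ArchitectureRecord(
            str(pid),
            int(grp["length"].iloc[0]),
            [(str(r.domain_id), int(r.start), int(r.end)) for r in grp.itertuples()],
        ))
    return records


def read_homology_table(path) -> list[HomologyHit]:
    """TSV with columns query_id, subject_id, evalue, knotted (0/1)."""
    df = pd.read_csv(path, sep="\t")
    return [
        HomologyHit(str(r.query_id), str(r.subject_id), float(r.evalue),
                    bool(int(r.knotted)))
        for r in df.itertuples()
    ]


def write_candidate_reports(reports: Sequence[CandidateReport], path) -> None:
    payload = [
        {
            "protein_id": r.protein_id,
            "architecture": r.architecture_string,
            "n_entangled_domains": r.n_entangled_domains,
            "expected_knots": r.expected_knots,
            "passed_length": r.passed_length,
            "passed_homology": r.passed_homology,
            "verdict": r.verdict,
        }
        for r in reports
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def summarize_architectures(reports: Sequence[CandidateReport],
                            knot_types: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Summary table of accepted candidates, one row per architecture:
    architecture, number of proteins, an example protein and the knot
    type (from structure analysis, when supplied per architecture)."""
    rows = []
    accepted = [r for r in reports if r.is_candidate and r.passed_homology is not False]
    for arch in sorted({r.architecture_string for r in accepted}):
        members = [r for r in accepted if r.architecture_string == arch]
        rows.append({
            "architecture": arch,
            "n_proteins": len(members),
            "example_protein": members[0].protein_id,
            "knot_type": (knot_types or {}).get(arch, ""),
        })
    return pd.DataFrame(rows, columns=["architecture", "n_proteins",
                                       "example_protein", "knot_type"])
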