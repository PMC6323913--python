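"""Release-time quality control, release statistics and curation heuristics.

Before a release, every property must be reachable from the organisational
hierarchy (as a member of a category or as evidence within a metapath),
every InterPro accession used as evidence must be valid for the targeted
InterProScan release, and every property that needs a FASTA sidecar of
example sequences must have one covering its InterPro-evidenced steps.

Also here: the evidence-selection heuristic used when a protein matches
several candidate InterPro entries (semi-automatic property generation
from complex/pathway resources) -- prefer entries of type *family*, then
the most specific entry (deepest in its InterPro hierarchy), breaking ties
by broader taxonomic coverage and finally by accession.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .desc import FastaSidecar
from .model import EvidenceKind, PropertyRegistry, PropertyType

__all__ = [
    "EntryType",
    "CandidateEvidence",
    "QcReport",
    "check_connectivity",
    "check_evidence_validity",
    "check_fasta_presence",
    "release_stats",
    "select_evidence",
    "run_release_checks",
]


class EntryType(enum.Enum):
    FAMILY = "FAMILY"
    DOMAIN = "DOMAIN"
    HOMOLOGOUS_SUPERFAMILY = "HOMOLOGOUS_SUPERFAMILY"
    OTHER = "OTHER"


@dataclass(frozen=True)
class CandidateEvidence:
    """One InterPro entry competing to be the evidence for a step.

    ``hierarchy_depth`` counts levels below the root of the entry's
    InterPro hierarchy (0 = root, larger = more specific);
    ``taxonomic_breadth`` is an optional count of matched taxa.
    """

    accession: str
    entry_type: EntryType
    hierarchy_depth: int = 0
    taxonomic_breadth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hierarchy_depth < 0:
            raise ValueError("hierarchy_depth must be >= 0")


@dataclass
class QcReport:
    """Aggregate of release checks; empty iff the data set is release-ready."""

    orphans: list[str] = field(default_factory=list)
    invalid_evidence: list[tuple[str, str]] = field(default_factory=list)
    missing_fasta: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.orphans or self.invalid_evidence or self.missing_fasta or self.warnings
        )

    def as_rows(self) -> list[tuple[str, str, str]]:
        rows = [("orphan", acc, "") for acc in self.orphans]
        rows += [("invalid_evidence", prop, acc) for prop, acc in self.invalid_evidence]
        rows += [
            ("missing_fasta", acc, ",".join(map(str, steps)))
            for acc, steps in self.missing_fasta
        ]
        rows += [("warning", msg, "") for msg in self.warnings]
        return rows


def _default_roots(registry: PropertyRegistry) -> list[str]:
    """Categories not cited by any other property act as hierarchy roots."""
    cited = {
        child
        for prop in registry
        for child in prop.genprop_children()
    }
    return [
        prop.accession
        for prop in registry
        if prop.is_category and prop.accession not in cited
    ]


def check_connectivity(
    registry: PropertyRegistry,
    roots: Optional[Sequence[str]] = None,
) -> list[str]:
    """Accessions unreachable from the organisational hierarchy roots.

    Connectivity guarantees a browse path to every property: traversal
    follows property-evidence edges from the root categories (only
    categories and metapaths carry property evidence, so the edges *are*
    the category-membership/metapath-evidence relation).  ``roots``
    defaults to the categories nothing else cites.
    """
    if roots is None:
        roots = _default_roots(registry)
    graph = registry.evidence_graph.subgraph(registry.accessions())
    reachable: set[str] = set()
    for root in roots:
        if root not in registry:
            raise KeyError(f"declared root {root} is not registered")
        reachable.add(root)
        reachable |= nx.descendants(graph, root)
    return [acc for acc in registry.accessions() if acc not in reachable]


def check_evidence_validity(
    registry: PropertyRegistry,
    valid_accessions: Iterable[str],
) -> list[tuple[str, str]]:
    """(property, accession) pairs whose InterPro evidence is not in the universe.

    ``valid_accessions`` is the accession universe of the targeted
    InterProScan release.  Property-to-property evidence is resolved by
    the registry itself and never checked against this universe.
    """
    universe = set(valid_accessions)
    out = []
    for prop in registry:
        for step in prop.steps:
            for ev in step.evidences:
                if ev.kind is EvidenceKind.INTERPRO and ev.accession not in universe:
                    out.append((prop.accession, ev.accession))
    return out


def check_fasta_presence(
    registry: PropertyRegistry,
    sidecars: Mapping[str, FastaSidecar],
) -> list[tuple[str, tuple[int, ...]]]:
    """Properties whose FASTA sidecar is missing or does not cover every step.

    Each non-category property with at least one InterPro-evidenced step
    needs a sidecar with at least one example sequence per such step.
    Returned as (accession, uncovered step numbers).  Categories are
    exempt (they carry only organisational property evidence).
    """
    out = []
    for prop in registry:
        if prop.is_category:
            continue
        ipr_steps = tuple(
            step.number
            for step in prop.steps
            if any(ev.kind is EvidenceKind.INTERPRO for ev in step.evidences)
        )
        if not ipr_steps:
            continue
        sidecar = sidecars.get(prop.accession)
        covered = sidecar.covered_steps() if sidecar else set()
        missing = tuple(n for n in ipr_steps if n not in covered)
        if missing:
            out.append((prop.accession, missing))
    return out


def release_stats(
    old_registry: PropertyRegistry,
    new_registry: PropertyRegistry,
) -> dict:
    """Counts of newly added properties per type, for the release notes."""
    added = [
        new_registry[acc]
        for acc in new_registry.accessions()
        if acc not in old_registry
    ]
    per_type = Counter(prop.type.value for prop in added)
    return {
        "added_per_type": {t.value: per_type.get(t.value, 0) for t in PropertyType},
        "added_total": len(added),
        "old_total": len(old_registry),
        "new_total": len(new_registry),
    }


def select_evidence(candidates: Sequence[CandidateEvidence]) -> str:
    """Pick the evidence accession for a step from competing InterPro entries.

    Entries of type *family* are preferred over domains and homologous
    superfamilies (they tend to be more specific).  Among the remaining
    candidates the most specific entry -- deepest in its InterPro
    hierarchy -- wins; ties go to the greater taxonomic breadth, then to
    the lexicographically smallest accession.  Deterministic and invariant
    to candidate order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    pool = [c for c in candidates if c.entry_type is EntryType.FAMILY] or list(candidates)
    def key(c: CandidateEvidence):
        breadth = c.taxonomic_breadth if c.taxonomic_breadth is not None else -1
        return (-c.hierarchy_depth, -breadth, c.accession)
    return min(pool, key=key).accession


def run_release_checks(
    registry: PropertyRegistry,
    valid_accessions: Optional[Iterable[str]] = None,
    sidecars: Optional[Mapping[str, FastaSidecar]] = None,
    roots: Optional[Sequence[str]] = None,
    threshold_warnings: bool = True,
) -> QcReport:
    """Run every release check and aggregate the findings.

    ``valid_accessions=None`` skips the evidence-universe check;
    ``sidecars=None`` skips FASTA coverage.  Structural warnings (cycles,
    dangling citations, properties with no required steps) are always
    collected.
    """
    report = QcReport()
    for cycle in registry.validate_graph():
        report.warnings.append("evidence cycle: " + " -> ".join(cycle))
    for prop_acc, child in registry.unresolved_evidence():
        report.warnings.append(f"dangling evidence {prop_acc} -> {child}")
    if not report.warnings:  # connectivity needs an acyclic, resolved graph
        report.orphans = check_connectivity(registry, roots)
    if valid_accessions is not None:
        report.invalid_evidence = check_evidence_validity(registry, valid_accessions)
    if sidecars is not None:
        report.missing_fasta = check_fasta_presence(registry, sidecars)
    if threshold_warnings:
        for prop in registry:
            n_req = len(prop.required_steps)
            if prop.steps and n_req == 0:
                report.warnings.append(
                    f"{prop.accession}: no required steps; can never be YES"
                )
            elif n_req > 0 and prop.threshold >= n_req:
                report.warnings.append(
                    f"{prop.accession}: threshold {prop.threshold} >= required "
                    f"step count {n_req}"
                )
    return report
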