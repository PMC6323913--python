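"""Domain model for genome properties.

A genome property describes a higher-order functional attribute of an
organism -- a pathway, a macromolecular complex, a transport system, a
guild, a metapath (a property whose steps are themselves properties) or a
purely organisational category.  Each property is an ordered list of
steps; each step carries one or more lines of evidence (an InterPro entry
or another property) and is flagged required or optional.  A property is
asserted YES for a proteome when every required step has matching
evidence, PARTIAL when the count of matched required steps exceeds the
property's curated threshold, and NO otherwise.

This module holds the in-memory types and the registry that indexes
properties and their evidence dependency graph.  Serialisation lives in
:mod:`genprops.desc`, evaluation in :mod:`genprops.assign`.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import networkx as nx

__all__ = [
    "INTERPRO_PATTERN",
    "GENPROP_PATTERN",
    "EvidenceKind",
    "PropertyType",
    "ResultState",
    "Evidence",
    "Step",
    "Reference",
    "CrossRef",
    "GenomeProperty",
    "PropertyRegistry",
    "GraphCycleError",
    "DuplicateAccessionError",
    "MalformedAccessionError",
]

INTERPRO_PATTERN = re.compile(r"IPR\d{6}\Z")
GENPROP_PATTERN = re.compile(r"GenProp\d{4}\Z")


class MalformedAccessionError(ValueError):
    """An accession does not match the InterPro or GenProp pattern."""


class DuplicateAccessionError(ValueError):
    """A property accession is already registered."""


class GraphCycleError(ValueError):
    """The evidence dependency graph contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("evidence cycle: " + " -> ".join(self.cycle))


class EvidenceKind(enum.Enum):
    INTERPRO = "INTERPRO"
    GENPROP = "GENPROP"


class PropertyType(enum.Enum):
    PATHWAY = "PATHWAY"
    METAPATH = "METAPATH"
    SYSTEM = "SYSTEM"
    GUILD = "GUILD"
    COMPLEX = "COMPLEX"
    CATEGORY = "CATEGORY"


class ResultState(enum.IntEnum):
    """Assignment outcome for one property in one proteome.

    The integer values are the numeric encoding used for profiling
    statistics (NO=0, PARTIAL=1, YES=2); the ordering reflects increasing
    evidence of presence.
    """

    NO = 0
    PARTIAL = 1
    YES = 2

    @property
    def numeric(self) -> int:
        return int(self)

    @classmethod
    def from_numeric(cls, value: int) -> "ResultState":
        return cls(value)

    def __str__(self) -> str:  # report-facing label
        return self.name


def classify_accession(accession: str, permissive: bool = False) -> EvidenceKind:
    """Derive the evidence kind from an accession string.

    Strict mode accepts only ``IPRnnnnnn`` and ``GenPropnnnn``.  Permissive
    mode admits legacy identifiers (e.g. raw member-database signatures),
    treating anything that does not start with ``GenProp`` as InterPro-side
    evidence.
    """
    if INTERPRO_PATTERN.match(accession):
        return EvidenceKind.INTERPRO
    if GENPROP_PATTERN.match(accession):
        return EvidenceKind.GENPROP
    if permissive:
        if accession.startswith("GenProp"):
            return EvidenceKind.GENPROP
        return EvidenceKind.INTERPRO
    raise MalformedAccessionError(
        f"accession {accession!r} matches neither IPR\\d{{6}} nor GenProp\\d{{4}}"
    )


@dataclass(frozen=True)
class Evidence:
    """One line of evidence for a step.

    ``raw_signatures`` carries the member-database signature identifiers
    listed alongside the InterPro accession in the flatfile; they are
    informational, except under signature-level fallback matching.
    """

    accession: str
    raw_signatures: tuple[str, ...] = ()
    kind: EvidenceKind = field(init=False)
    permissive: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", classify_accession(self.accession, self.permissive))
        object.__setattr__(self, "raw_signatures", tuple(self.raw_signatures))


@dataclass(frozen=True)
class Step:
    """One functional component of a property.

    Satisfied when any of its evidence lines matches.  Only required steps
    count toward the YES/PARTIAL/NO decision; optional steps are reported
    but never change the state.
    """

    number: int
    id: str
    required: bool = True
    display_name: Optional[str] = None
    evidences: tuple[Evidence, ...] = ()
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"step number must be >= 1, got {self.number}")
        if not self.evidences:
            raise ValueError(f"step {self.number} ({self.id!r}) has no evidence")
        object.__setattr__(self, "evidences", tuple(self.evidences))
        object.__setattr__(self, "go_terms", tuple(self.go_terms))


class Reference(NamedTuple):
    number: int
    pmid: str
    title: str
    authors: str
    journal: str


class CrossRef(NamedTuple):
    database: str
    id: str


@dataclass
class GenomeProperty:
    """One genome property record.

    The header half (accession, name, type, threshold, description,
    references, cross-references) describes the property as a whole; the
    step list is the molecular reconstruction.  ``public`` reflects the
    status sidecar.  ``extras`` preserves unknown flatfile annotation
    codes verbatim for forward compatibility.
    """

    accession: str
    name: str
    type: PropertyType
    threshold: int = 0
    description: str = ""
    author: str = ""
    references: tuple[Reference, ...] = ()
    xrefs: tuple[CrossRef, ...] = ()
    steps: tuple[Step, ...] = ()
    public: bool = True
    extras: tuple[tuple[str, str], ...] = ()
    permissive: bool = False

    def __post_init__(self) -> None:
        if not self.permissive and not GENPROP_PATTERN.match(self.accession):
            raise MalformedAccessionError(
                f"property accession {self.accession!r} does not match GenProp\\d{{4}}"
            )
        if not isinstance(self.type, PropertyType):
            self.type = PropertyType(str(self.type).upper())
        if self.threshold < 0:
            raise ValueError(f"{self.accession}: threshold must be >= 0")
        self.steps = tuple(self.steps)
        self.references = tuple(self.references)
        self.xrefs = tuple(self.xrefs)
        self.extras = tuple(self.extras)
        numbers = [s.number for s in self.steps]
        if len(numbers) != len(set(numbers)):
            raise ValueError(f"{self.accession}: duplicate step numbers {numbers}")
        if self.type is PropertyType.CATEGORY:
            bad = [
                ev.accession
                for step in self.steps
                for ev in step.evidences
                if ev.kind is not EvidenceKind.GENPROP
            ]
            if bad:
                raise ValueError(
                    f"{self.accession}: CATEGORY properties may only cite other "
                    f"properties as evidence, found {bad}"
                )
        n_required = len(self.required_steps)
        if n_required > 0 and self.threshold >= n_required:
            warnings.warn(
                f"{self.accession}: threshold {self.threshold} >= required step "
                f"count {n_required}; a PARTIAL result is unreachable",
                stacklevel=2,
            )

    @property
    def required_steps(self) -> tuple[Step, ...]:
        return tuple(s for s in self.steps if s.required)

    @property
    def is_category(self) -> bool:
        return self.type is PropertyType.CATEGORY

    def interpro_evidence(self) -> set[str]:
        """All InterPro accessions cited by any step."""
        return {
            ev.accession
            for step in self.steps
            for ev in step.evidences
            if ev.kind is EvidenceKind.INTERPRO
        }

    def genprop_children(self) -> set[str]:
        """All property accessions cited as evidence by any step."""
        return {
            ev.accession
            for step in self.steps
            for ev in step.evidences
            if ev.kind is EvidenceKind.GENPROP
        }


class PropertyRegistry:
    """Accession-indexed collection of properties with the evidence graph.

    The directed graph has an edge ``property -> cited property`` for every
    line of GenProp evidence; the browse hierarchy is derived solely from
    these edges.  The graph must be acyclic for evaluation; cycles are
    reported by :meth:`validate_graph`.
    """

    def __init__(self, properties: Iterable[GenomeProperty] = ()):
        self._properties: dict[str, GenomeProperty] = {}
        self._graph = nx.DiGraph()
        for prop in properties:
            self.register(prop)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._properties)

    def __contains__(self, accession: str) -> bool:
        return accession in self._properties

    def __getitem__(self, accession: str) -> GenomeProperty:
        return self._properties[accession]

    def __iter__(self) -> Iterator[GenomeProperty]:
        for acc in self.accessions():
            yield self._properties[acc]

    def get(self, accession: str, default=None):
        return self._properties.get(accession, default)

    def accessions(self) -> list[str]:
        return sorted(self._properties)

    @property
    def evidence_graph(self) -> nx.DiGraph:
        return self._graph

    # -- mutation -----------------------------------------------------------
    def register(self, prop: GenomeProperty) -> "PropertyRegistry":
        if prop.accession in self._properties:
            raise DuplicateAccessionError(
                f"accession {prop.accession} already registered"
            )
        self._properties[prop.accession] = prop
        self._graph.add_node(prop.accession)
        for child in sorted(prop.genprop_children()):
            self._graph.add_edge(prop.accession, child)
        return self

    # -- validation ---------------------------------------------------------
    def unresolved_evidence(self) -> list[tuple[str, str]]:
        """(property, cited accession) pairs where the citation is dangling."""
        out = []
        for acc in self.accessions():
            for child in sorted(self._properties[acc].genprop_children()):
                if child not in self._properties:
                    out.append((acc, child))
        return out

    def validate_graph(self) -> list[list[str]]:
        """Cycles in the evidence graph, each as an accession sequence.

        Empty iff the graph is acyclic.  Dangling citations are reported
        separately by :meth:`unresolved_evidence`, never as cycles.
        """
        sub = self._graph.subgraph(self._properties)
        return [sorted(c) for c in nx.simple_cycles(sub)]

    def topological_order(self) -> list[str]:
        """Accessions ordered so every cited property precedes its citers.

        Deterministic (lexicographic among ready nodes).  Raises
        :class:`GraphCycleError` when the graph is cyclic.
        """
        sub = self._graph.subgraph(self._properties).reverse(copy=True)
        sub = nx.DiGraph(sub)
        sub.add_nodes_from(self._properties)
        try:
            return list(nx.lexicographical_topological_sort(sub))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(self._graph.subgraph(self._properties))
            raise GraphCycleError([u for u, _ in cycle] + [cycle[0][0]]) from None

    # -- queries ------------------------------------------------------------
    def search_names(self, query: str) -> list[str]:
        """Case-insensitive substring search on property names.

        Mirrors the browse-tree search of the public website.  Returns
        matching accessions sorted; an empty result is not an error.
        """
        if not query:
            raise ValueError("query must be non-empty")
        q = query.lower()
        return [acc for acc in self.accessions() if q in self._properties[acc].name.lower()]

    def evidence_accessions(self) -> set[str]:
        """All InterPro accessions used as step evidence anywhere."""
        out: set[str] = set()
        for prop in self._properties.values():
            out |= prop.interpro_evidence()
        return out
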